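"""Generator-level ground-truth guarantees: geometry of the categories,
containment, Poisson consistency, determinism."""

import numpy as np
import pytest
from scipy import stats

from twobox import (
    EnsembleConfig,
    GroundTruthCell,
    generate_ensemble,
    generate_session,
    generate_spikes,
    generate_trajectory,
    generate_waveforms,
)
from twobox.ratemaps import MapGrid, sample_speeds
from twobox.synth import Trajectory, effective_centers
from twobox.tracking import tolias_d1


# ---------------------------------------------------------------------- path
def test_trajectory_sample_count(geometry):
    traj = generate_trajectory(geometry, 600.0, seed=0)
    assert len(traj) == 30000  # 600 s at 50 Hz


def test_trajectory_stays_inside_box(geometry):
    traj = generate_trajectory(geometry, 300.0, seed=3)
    assert traj.x.min() >= 0 and traj.x.max() <= geometry.width
    assert traj.y.min() >= 0 and traj.y.max() <= geometry.height


def test_door_closed_containment_is_absolute(geometry):
    for comp in (1, 2):
        traj = generate_trajectory(
            geometry, 300.0, seed=7, door_open=False, compartment=comp
        )
        x_lo, x_hi, y_lo, y_hi = geometry.compartment_bounds(comp)
        assert traj.x.min() >= x_lo and traj.x.max() <= x_hi
        assert traj.y.min() >= y_lo and traj.y.max() <= y_hi


def test_trajectory_covers_both_compartments(geometry):
    """A 900 s open-door trial visits >= 90% of 3x3 cm bins per compartment."""
    traj = generate_trajectory(geometry, 900.0, seed=1)
    comp = geometry.compartment_of(traj.x)
    grid = MapGrid((geometry.compartment_width, geometry.height))
    for c in (1, 2):
        sel = comp == c
        occ = grid.accumulate(
            traj.x[sel] - (c - 1) * geometry.compartment_width, traj.y[sel]
        )
        assert (occ > 0).mean() >= 0.9


def test_trajectory_speed_distribution(geometry):
    v = sample_speeds(generate_trajectory(geometry, 900.0, seed=5))
    assert 0.01 < (v < 5).mean() < 0.3  # genuine slow epochs exist
    assert (v > 100).mean() == 0.0


def test_trajectory_determinism(geometry):
    a = generate_trajectory(geometry, 120.0, seed=9)
    b = generate_trajectory(geometry, 120.0, seed=9)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


def test_trajectory_rejects_bad_arguments(geometry):
    with pytest.raises(ValueError):
        generate_trajectory(geometry, 0.0, seed=0)
    with pytest.raises(ValueError):
        generate_trajectory(geometry, 100.0, seed=0, door_open=False)


# ------------------------------------------------------------------ ensemble
def test_repeat_cells_share_global_frame_position(geometry):
    cfg = EnsembleConfig(n_cells=10, category_proportions={"repeat": 1.0},
                         rng_seed=4)
    for cell in generate_ensemble(cfg, geometry):
        local1 = geometry.to_local(cell.field_centers[1], 1)
        local2 = geometry.to_local(cell.field_centers[2], 2)
        np.testing.assert_allclose(local1, local2)


def test_rotate_cells_have_reversed_local_positions(geometry):
    cfg = EnsembleConfig(n_cells=5, category_proportions={"rotate": 1.0},
                         rng_seed=4)
    for cell in generate_ensemble(cfg, geometry):
        local1 = geometry.to_local(cell.field_centers[1], 1)
        local2 = geometry.to_local(cell.field_centers[2], 2)
        np.testing.assert_allclose(geometry.local_rot180(local1), local2)


def test_remap_single_has_one_field(geometry):
    cfg = EnsembleConfig(
        n_cells=20, category_proportions={"remap_single": 1.0}, rng_seed=2
    )
    assert all(
        len(c.field_centers) == 1 for c in generate_ensemble(cfg, geometry)
    )


def test_category_counts_within_binomial_bounds(geometry):
    props = {"repeat": 0.133, "remap_single": 0.5, "remap_shift": 0.367}
    cfg = EnsembleConfig(n_cells=1000, category_proportions=props, rng_seed=7)
    cells = generate_ensemble(cfg, geometry)
    for cat, p in props.items():
        n = sum(c.category == cat for c in cells)
        lo, hi = stats.binom.interval(0.99, 1000, p)
        assert lo <= n <= hi, f"{cat}: {n} outside [{lo}, {hi}]"


def test_ensemble_rejects_off_simplex_proportions(geometry):
    with pytest.raises(ValueError):
        EnsembleConfig(category_proportions={"repeat": 0.7, "remap_shift": 0.7})


# -------------------------------------------------------------------- spikes
def test_silent_cell_produces_no_spikes(geometry):
    traj = generate_trajectory(geometry, 60.0, seed=0)
    cell = GroundTruthCell("z", "distractor", {}, 8.0, 0.0, 0.0)
    assert generate_spikes(cell, traj, geometry, seed=0).n == 0


def test_stationary_spike_count_in_poisson_interval(geometry):
    """100 s parked on the field centre at 5 Hz peak -> ~Poisson(500)."""
    n = 5000
    traj = Trajectory(
        t=np.arange(n) * 0.02,
        x=np.full(n, 30.0),
        y=np.full(n, 45.0),
        duration=100.0,
    )
    cell = GroundTruthCell(
        "s", "remap_single", {1: np.array([30.0, 45.0])}, 8.0, 5.0, 0.0
    )
    count = generate_spikes(cell, traj, geometry, seed=11).n
    lo, hi = stats.poisson.interval(0.99, 500)
    assert lo <= count <= hi


def test_poisson_count_consistency(geometry):
    """Observed counts track Poisson(integral of lambda dt) across seeds."""
    from twobox.synth import rate_on_trajectory

    traj = generate_trajectory(geometry, 300.0, seed=21)
    cell = GroundTruthCell(
        "p", "repeat",
        {1: np.array([20.0, 30.0]), 2: np.array([80.0, 30.0])},
        9.0, 6.0, 0.2,
    )
    expected = rate_on_trajectory(cell, traj, geometry).sum() * traj.dt
    lo, hi = stats.poisson.interval(0.999, expected)
    outside = sum(
        not lo <= generate_spikes(cell, traj, geometry, seed=s).n <= hi
        for s in range(20)
    )
    assert outside <= 1


def test_spikes_respect_refractory_period(geometry):
    traj = generate_trajectory(geometry, 300.0, seed=2)
    cell = GroundTruthCell(
        "r", "repeat",
        {1: np.array([30.0, 45.0]), 2: np.array([90.0, 45.0])},
        10.0, 10.0, 0.3,
    )
    st = generate_spikes(cell, traj, geometry, seed=5).spike_times
    assert np.diff(st).min() >= 0.002


def test_odor_switch_rotates_repeat_cell_field(geometry):
    cell = GroundTruthCell(
        "w", "repeat",
        {1: np.array([20.0, 30.0]), 2: np.array([80.0, 30.0])},
        8.0, 5.0, 0.1,
    )
    eff = effective_centers(cell, geometry, odor_switched=True)
    np.testing.assert_allclose(eff[1], geometry.rotate180(cell.field_centers[2]))
    np.testing.assert_allclose(eff[2], geometry.rotate180(cell.field_centers[1]))


# ----------------------------------------------------------------- waveforms
def test_waveforms_without_drift_or_noise_are_identical():
    wfs = generate_waveforms("a", 3, drift=0.0, seed=0, shape_noise=0.0)
    for wf in wfs[1:]:
        np.testing.assert_array_equal(wfs[0], wf)


def test_distinct_templates_have_positive_shape_distance():
    wa = generate_waveforms("a", 1, 0.0, seed=1, shape_noise=0.0)[0]
    wb = generate_waveforms("b", 1, 0.0, seed=2, shape_noise=0.0)[0]
    assert tolias_d1(wa, wa) == pytest.approx(0.0, abs=1e-12)
    assert tolias_d1(wa, wb) > tolias_d1(wa, wa)


def test_template_peak_trough_exceeds_pyramidal_bound():
    from twobox.selection import peak_trough_time

    for seed in range(5):
        wf = generate_waveforms("c", 1, 0.0, seed=seed, shape_noise=0.0)[0]
        assert peak_trough_time(wf, 48000.0) > 250.0


# ------------------------------------------------------------------ sessions
def test_session_protocol_structure(small_session):
    names = [t.name for t in small_session.trials]
    assert names == ["baseline1", "rotation", "single1", "single2", "baseline2"]
    door_closed = [t.index for t in small_session.trials if not t.door_open]
    assert door_closed == [3, 4]  # door closed exactly for trials 3 and 4
    assert small_session.trial("rotation").rotation_deg == 180


def test_session_determinism(geometry):
    cfg = EnsembleConfig(n_cells=4, rng_seed=3)
    a = generate_session(cfg, geometry, seed=17, two_box_duration=60.0,
                         single_duration=45.0)
    b = generate_session(cfg, geometry, seed=17, two_box_duration=60.0,
                         single_duration=45.0)
    for ta, tb in zip(a.trials, b.trials):
        np.testing.assert_array_equal(ta.traj.x, tb.traj.x)
        for cid in ta.spikes:
            np.testing.assert_array_equal(
                ta.spikes[cid].spike_times, tb.spikes[cid].spike_times
            )
            np.testing.assert_array_equal(ta.waveforms[cid], tb.waveforms[cid])


def test_rotation_trial_positions_are_room_frame(geometry):
    cfg = EnsembleConfig(n_cells=2, rng_seed=1)
    b = generate_session(cfg, geometry, seed=23, two_box_duration=60.0,
                         single_duration=45.0, rotation_angle=90)
    rot = b.trial("rotation")
    # 90-degree rotated footprint swaps the extents
    assert rot.traj.x.max() <= geometry.height
    assert rot.traj.y.max() <= geometry.width
    back = rot.traj_box(geometry)
    assert back.x.max() <= geometry.width and back.y.max() <= geometry.height
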