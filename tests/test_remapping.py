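"""Map correlations, null calibration machinery, orientation detection and
the repeat/remap/rotate decision rule."""

import numpy as np
import pytest
from scipy import stats

from twobox import (
    EnsembleConfig,
    build_null,
    classify_cell,
    correct_orientation,
    correlate_maps,
    detect_ensemble_rotation,
    generate_session,
    run_pipeline,
)
from twobox.ratemaps import RateMap
from twobox.remapping import pad_to_common, split_compartments


def _ratemap(rate, bin_size=3.0):
    rate = np.asarray(rate, float)
    mask = np.isfinite(rate)
    return RateMap(
        rate=rate, dwell=mask.astype(float), dwell_raw=mask.astype(float),
        spike_count=np.zeros_like(rate), mask=mask, bin_size=bin_size,
        extent=(rate.shape[1] * bin_size, rate.shape[0] * bin_size),
    )


def _bump(center, shape=(30, 40), sigma=8.0, peak=5.0, noise=0.0, rng=None):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]] * 3.0 + 1.5
    rate = peak * np.exp(
        -((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2)
    )
    if noise and rng is not None:
        rate = rate * rng.lognormal(0, noise, shape) + rng.uniform(0, 0.1, shape)
    return rate


# ------------------------------------------------------------- correlations
def test_self_correlation_is_one(rng):
    a = rng.gamma(1.0, 1.0, (30, 40))
    c = correlate_maps(_ratemap(a), _ratemap(a), "none")
    assert c.r == pytest.approx(1.0)
    assert c.n_bins_used == 1200


def test_negated_map_correlates_minus_one(rng):
    a = rng.gamma(1.0, 1.0, (30, 40))
    assert correlate_maps(_ratemap(a), _ratemap(-a), "none").r == pytest.approx(-1.0)


def test_rot180_correlation_matches_hand_reversed_pearson(rng):
    a = rng.gamma(1.0, 1.0, (4, 4))
    b = rng.gamma(1.0, 1.0, (4, 4))
    got = correlate_maps(_ratemap(a), _ratemap(b), "rot180", min_bins=4).r
    want = stats.pearsonr(a.ravel(), b[::-1, ::-1].ravel()).statistic
    assert got == pytest.approx(want, rel=1e-12)


def test_correlation_symmetry_under_inverse_transform(rng):
    a = rng.gamma(1.0, 1.0, (20, 20))
    b = rng.gamma(1.0, 1.0, (20, 20))
    a[rng.random(a.shape) < 0.1] = np.nan
    for t, tinv in [("none", "none"), ("rot180", "rot180"),
                    ("rot90", "rot270")]:
        f = correlate_maps(_ratemap(a), _ratemap(b), t)
        g = correlate_maps(_ratemap(b), _ratemap(a), tinv)
        assert f.r == pytest.approx(g.r, rel=1e-10)


def test_too_few_joint_bins_is_undefined():
    a = np.full((10, 10), np.nan)
    a[0, :5] = 1.0
    c = correlate_maps(_ratemap(a), _ratemap(a), "none")
    assert not c.defined and c.n_bins_used == 5


def test_padding_aligns_origins():
    a = np.arange(6.0).reshape(2, 3)
    b = np.arange(12.0).reshape(3, 4)
    pa, pb = pad_to_common(a, b)
    assert pa.shape == pb.shape == (3, 4)
    np.testing.assert_array_equal(pa[:2, :3], a)
    assert np.isnan(pa[2]).all()


# ------------------------------------------------------------------- nulls
def test_orthogonal_one_hot_pool_threshold_nonpositive():
    maps, ids = [], []
    for i in range(24):
        m = np.zeros((5, 5))
        m[i % 5, (i // 5) % 5] = 1.0
        maps.append(m)
        ids.append(f"c{i}")
    nd = build_null(maps, ids, n=500, seed=0, min_bins=10)
    assert nd.threshold <= 0.0


def test_null_requires_pool_diversity(rng):
    maps = [rng.random((10, 10)) for _ in range(25)]
    with pytest.raises(ValueError):
        build_null(maps, ["same"] * 25, n=100, seed=0)


def test_null_pairs_never_same_cell(rng):
    # distinct-cell constraint: a pool of per-cell constant maps in which
    # same-cell pairs would correlate 1.0 must never produce r == 1 draws
    maps, ids = [], []
    for c in range(12):
        base = rng.random((10, 10))
        for _ in range(2):
            maps.append(base + rng.normal(0, 0.3, (10, 10)))
            ids.append(f"c{c}")
    nd = build_null(maps, ids, n=300, seed=1, min_bins=10)
    assert nd.values.max() < 0.999


# ---------------------------------------------------- orientation detection
def test_identical_ensembles_are_not_switched(rng):
    # centres away from the box centre (a central bump is rotation-symmetric
    # and legitimately abstains)
    maps = {f"c{i}": _ratemap(_bump((15 + 6 * i, 20))) for i in range(6)}
    ori = detect_ensemble_rotation(maps, maps, threshold=0.4)
    assert not ori.switched and ori.n_switched_cells == 0
    assert ori.n_consistent_cells == 6


def test_majority_rule_three_consistent_two_switched():
    maps_a, maps_b = {}, {}
    centers = [(20, 20), (40, 60), (80, 30), (100, 70), (60, 45)]
    for i, ctr in enumerate(centers):
        maps_a[f"c{i}"] = _ratemap(_bump(ctr))
        if i < 3:
            maps_b[f"c{i}"] = _ratemap(_bump(ctr))
        else:
            maps_b[f"c{i}"] = _ratemap(np.rot90(_bump(ctr), 2))
    ori = detect_ensemble_rotation(maps_a, maps_b, threshold=0.4)
    assert ori.n_consistent_cells >= 3 and ori.n_switched_cells >= 1
    assert not ori.switched


def test_fully_rotated_ensemble_is_switched():
    maps_a = {f"c{i}": _ratemap(_bump((15 + 10 * i, 30 + 5 * i)))
              for i in range(6)}
    maps_b = {cid: _ratemap(np.rot90(m.rate, 2)) for cid, m in maps_a.items()}
    ori = detect_ensemble_rotation(maps_a, maps_b, threshold=0.4)
    assert ori.switched


def test_detection_needs_enough_cells():
    maps = {"c0": _ratemap(_bump((20, 20)))}
    with pytest.raises(ValueError):
        detect_ensemble_rotation(maps, maps, threshold=0.4)


# ------------------------------------------------------ orientation correction
def test_correction_identity_without_switches():
    maps = {"baseline1": {"c0": _ratemap(_bump((20, 20)))}}
    out, done = correct_orientation(maps, {"baseline1": False})
    np.testing.assert_array_equal(
        out["baseline1"]["c0"].rate, maps["baseline1"]["c0"].rate
    )
    assert done == set()


def test_correction_is_idempotent_and_content_preserving():
    m = _ratemap(_bump((20, 20)))
    maps = {"rotation": {"c0": m}}
    once, done = correct_orientation(maps, {"rotation": True})
    twice, done2 = correct_orientation(once, {"rotation": True}, done)
    np.testing.assert_array_equal(
        once["rotation"]["c0"].rate, twice["rotation"]["c0"].rate
    )
    np.testing.assert_array_equal(
        np.sort(once["rotation"]["c0"].rate, axis=None),
        np.sort(m.rate, axis=None),
    )  # pixel multiset unchanged, only orientation


# ------------------------------------------------------------ classification
def _whole_map(c1_local, c2_local, geometry, sigma=8.0, peak=5.0):
    """Whole-box bump map with per-compartment local field centres."""
    rate = np.zeros((30, 40))
    rate += _bump((c1_local[0], c1_local[1]), sigma=sigma, peak=peak)
    rate += _bump((60 + c2_local[0], c2_local[1]), sigma=sigma, peak=peak)
    return _ratemap(rate)


@pytest.mark.parametrize(
    "c1,c2,expected",
    [
        ((20, 70), (20, 70), "repeat"),
        ((20, 70), (40, 20), "rotate"),  # 180-reversed local position
        ((20, 70), (45, 75), "remap"),
    ],
)
def test_category_geometry(c1, c2, expected, geometry):
    m = _whole_map(c1, c2, geometry)
    res = classify_cell(m, geometry, threshold=0.45)
    assert res.category == expected


@pytest.mark.parametrize(
    "r_t,r_r,expected",
    [
        (0.66, -0.12, "repeat"),  # the typical repeating-cell signature
        (0.041, -0.004, "remap"),
        (0.5, 0.5, "ambiguous"),  # doorway-straddling case
    ],
)
def test_category_rule_from_correlations(r_t, r_r, expected):
    hi_t, hi_r = r_t > 0.45, r_r > 0.45
    cat = ("ambiguous" if hi_t and hi_r else "repeat" if hi_t
           else "rotate" if hi_r else "remap")
    assert cat == expected


def test_silent_compartment_demotes_rotate_call(geometry):
    rate = np.zeros((30, 40))
    rate += _bump((20, 70), sigma=8.0, peak=5.0)
    rate[:, 20:] *= 0.05  # second compartment nearly silent (< 1 Hz)
    rng = np.random.default_rng(0)
    # noise that happens to mimic the rotated position
    rate[:, 20:] += 0.12 * _bump((100, 20))[:, 20:]
    res = classify_cell(_ratemap(rate), geometry, threshold=0.1)
    assert res.low_confidence
    assert res.category != "rotate"


def test_split_compartments_shapes(geometry):
    m = _whole_map((20, 70), (20, 70), geometry)
    s1, s2 = split_compartments(m, geometry)
    assert s1.shape == s2.shape == (30, 20)


# ---------------------------------------------- odor-gated single-box recall
def test_odor_gated_ensemble_recalls_same_odor_map(geometry):
    cfg = EnsembleConfig(
        n_cells=25, rng_seed=8,
        category_proportions={"remap_shift": 1.0},
    )
    bundle = generate_session(cfg, geometry, seed=70, two_box_duration=600.0,
                              single_duration=300.0)
    rep = run_pipeline(bundle)
    odor = rep.odor_retrieval
    assert odor is not None
    assert odor.median_same > odor.median_diff
    assert odor.median_paired_diff > 0.3


def test_odor_blind_ensemble_shows_no_retrieval_effect(geometry):
    cfg = EnsembleConfig(
        n_cells=25, rng_seed=8,
        category_proportions={"repeat": 1.0}, odor_gated=False,
    )
    bundle = generate_session(cfg, geometry, seed=71, two_box_duration=600.0,
                              single_duration=300.0)
    rep = run_pipeline(bundle)
    odor = rep.odor_retrieval
    assert odor is not None
    # paired same-vs-different differences indistinguishable from zero
    assert odor.wilcoxon_p > 0.01
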