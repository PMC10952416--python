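"""Synthetic 2-box sessions with known ground truth.

Generates everything the analysis consumes: rat-like foraging trajectories
(bounded Ornstein-Uhlenbeck velocity process with wall reflection and a
doorway), place-cell ensembles whose per-compartment Gaussian fields realise
one of the remapping categories (repeat / remap_single / remap_shift / rotate,
plus non-spatial distractors), inhomogeneous-Poisson spike trains with an
absolute refractory period, tetrode waveforms with slow across-session
amplitude drift, and the five-trial session protocol (baseline, rotation,
two single-compartment door-closed trials, second baseline).

Every stage is seeded through :class:`numpy.random.SeedSequence`, so identical
seeds give bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BoxGeometry, rotate_point, rotated_extent

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(**kwargs):
        def deco(f):
            return f

        return deco


CATEGORIES = ("repeat", "remap_single", "remap_shift", "rotate", "distractor")

#: minimum separation between a drawn field centre and the locus that would
#: realise a *different* category, in units of the cell's field sigma.  At
#: 2.2 sigma the bump-overlap correlation with the competing locus is <= 0.3,
#: keeping the generated categories geometrically identifiable.
IDENTIFIABILITY_SEP = 2.2

WAVEFORM_FS = 48000.0  # Hz, acquisition-system sampling of snippets
WAVEFORM_SAMPLES = 48  # 1 ms snippet


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Uniformly sampled tracked position, cm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    duration: float
    fs: float = 50.0

    def __len__(self):
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


@dataclass
class SpikeTrain:
    cell_id: str
    spike_times: np.ndarray  # s, strictly increasing
    waveform: np.ndarray | None = None  # (4, S) mean waveform, uV
    sampling_rate_wf: float = WAVEFORM_FS

    @property
    def n(self) -> int:
        return len(self.spike_times)


@dataclass
class GroundTruthCell:
    """A generated cell and the geometric relation its fields realise.

    ``field_centers`` maps compartment index (1/2) to the field centre in the
    *box* frame; a missing key means no field in that compartment.
    """

    cell_id: str
    category: str
    field_centers: dict
    field_width: float  # Gaussian sigma, cm
    peak_rate: float  # Hz above baseline at the field centre
    baseline_rate: float  # Hz
    tetrode: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.peak_rate >= 0 or not self.baseline_rate >= 0:
            raise ValueError("rates must be non-negative")
        if self.category != "distractor" and self.peak_rate <= self.baseline_rate:
            raise ValueError("peak_rate must exceed baseline_rate")


@dataclass
class EnsembleConfig:
    n_cells: int = 200
    category_proportions: dict = field(
        default_factory=lambda: {
            "repeat": 0.15,
            "remap_single": 0.45,
            "remap_shift": 0.40,
        }
    )
    odor_switch_trials: frozenset = frozenset()
    rng_seed: int = 0
    odor_gated: bool = True  # do cells use odor to retrieve single-box maps?
    peak_rate_range: tuple = (1.5, 10.0)
    sigma_range: tuple = (6.0, 12.0)
    baseline_range: tuple = (0.1, 0.3)
    distractor_rate_range: tuple = (0.3, 1.5)

    def __post_init__(self):
        p = self.category_proportions
        if any(k not in CATEGORIES for k in p):
            raise ValueError(f"unknown categories in proportions: {set(p) - set(CATEGORIES)}")
        if any(v < 0 for v in p.values()) or abs(sum(p.values()) - 1.0) > 1e-8:
            raise ValueError("category_proportions must lie on the simplex")
        self.odor_switch_trials = frozenset(self.odor_switch_trials)


@dataclass
class Trial:
    """One trial of a session, positions stored in the *room* frame."""

    index: int  # 1-based, 1..5
    name: str  # baseline1, rotation, single1, single2, baseline2
    door_open: bool
    rotation_deg: int  # box rotation relative to room, CCW
    single_compartment: int | None  # compartment for door-closed trials
    odor_switched: bool  # ground truth: ensemble rotated 180 vs odor frame
    traj: Trajectory  # room frame
    spikes: dict = field(default_factory=dict)  # cell_id -> SpikeTrain
    waveforms: dict = field(default_factory=dict)  # cell_id -> (4, S)

    @property
    def is_two_box(self) -> bool:
        return self.door_open

    def traj_box(self, geometry: BoxGeometry) -> Trajectory:
        """Positions rotated back from the room frame into the box frame."""
        if self.rotation_deg % 360 == 0:
            return self.traj
        w, h = rotated_extent(self.rotation_deg, geometry.width, geometry.height)
        pts = np.stack([self.traj.x, self.traj.y], axis=-1)
        back = rotate_point(pts, -self.rotation_deg % 360, w, h)
        return replace(self.traj, x=back[..., 0], y=back[..., 1])


@dataclass
class SessionBundle:
    session_id: str
    geometry: BoxGeometry
    config: EnsembleConfig
    cells: list
    trials: list

    def trial(self, name: str) -> Trial:
        for tr in self.trials:
            if tr.name == name:
                return tr
        raise KeyError(name)


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------


@njit(cache=False)
def _ou_path(noise, targets, pull, dt, decay, kick, x0, y0, vx0, vy0,
             xmin, xmax, ymin, ymax, wall_x, door_lo, door_hi, has_wall):
    n = noise.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    x, y, vx, vy = x0, y0, vx0, vy0
    door_cy = 0.5 * (door_lo + door_hi)
    for i in range(n):
        # attraction toward the current foraging target, routed through the
        # doorway when the target lies in the other compartment
        tx, ty = targets[i, 0], targets[i, 1]
        if has_wall and (x < wall_x) != (tx < wall_x):
            tx, ty = wall_x, door_cy
        ddx, ddy = tx - x, ty - y
        dist = math.sqrt(ddx * ddx + ddy * ddy)
        if dist > 1.0:
            vx += pull * ddx / dist * dt
            vy += pull * ddy / dist * dt
        vx = decay * vx + kick * noise[i, 0]
        vy = decay * vy + kick * noise[i, 1]
        nx = x + vx * dt
        ny = y + vy * dt
        if nx < xmin:
            nx = 2.0 * xmin - nx
            vx = -vx
        elif nx > xmax:
            nx = 2.0 * xmax - nx
            vx = -vx
        if ny < ymin:
            ny = 2.0 * ymin - ny
            vy = -vy
        elif ny > ymax:
            ny = 2.0 * ymax - ny
            vy = -vy
        if has_wall and (x - wall_x) * (nx - wall_x) < 0.0:
            f = (wall_x - x) / (nx - x)
            yc = y + f * (ny - y)
            if yc < door_lo or yc > door_hi:
                nx = 2.0 * wall_x - nx
                vx = -vx
        x, y = nx, ny
        xs[i] = x
        ys[i] = y
    return xs, ys


def generate_trajectory(
    geometry: BoxGeometry,
    duration: float,
    seed,
    fs: float = 50.0,
    door_open: bool = True,
    compartment: int | None = None,
    speed_sigma: float = 13.0,
    speed_tau: float = 0.7,
    goal_interval: float = 6.0,
    goal_pull: float = 15.0,
    edge_bias: float = 0.4,
) -> Trajectory:
    """Foraging path in the *box* frame.

    A bounded Ornstein-Uhlenbeck velocity process (per-axis stationary s.d.
    ``speed_sigma`` cm/s, correlation time ``speed_tau`` s) integrated at
    ``fs`` Hz with specular wall reflection, plus a weak attraction
    (``goal_pull`` cm/s^2) toward a foraging target resampled every
    ``goal_interval`` s - emulating food scattered across both compartments,
    which is what keeps real rats circulating between them.  Each target
    coordinate is pushed into the wall band with probability ``edge_bias``
    (thigmotaxis), so edges and corners are visited like the interior.
    Targets in the other compartment are routed through the doorway.  With
    the door closed the path and targets are confined to ``compartment``.
    """

    if duration <= 0:
        raise ValueError("duration must be positive")
    if not door_open and compartment not in (1, 2):
        raise ValueError("door-closed trials need a designated compartment")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    decay = math.exp(-dt / speed_tau)
    kick = speed_sigma * math.sqrt(1.0 - decay * decay)
    if door_open:
        xmin, xmax, ymin, ymax = 0.0, geometry.width, 0.0, geometry.height
        has_wall = True
    else:
        xmin, xmax, ymin, ymax = geometry.compartment_bounds(compartment)
        has_wall = False
    door_lo, door_hi = geometry.door_span
    # rats always start in compartment 1 (or the designated compartment)
    x0 = 0.5 * (xmin + min(xmax, geometry.compartment_width)) if door_open \
        else 0.5 * (xmin + xmax)
    y0 = 0.5 * (ymin + ymax)
    vx0, vy0 = rng.normal(0.0, speed_sigma, 2)
    noise = rng.standard_normal((n, 2))
    n_goals = int(np.ceil(duration / goal_interval))
    margin, band = 2.0, 6.0
    gx = rng.uniform(xmin + margin, xmax - margin, n_goals)
    gy = rng.uniform(ymin + margin, ymax - margin, n_goals)
    for i in range(n_goals):
        if rng.random() < edge_bias:
            gx[i] = (
                rng.uniform(xmin + margin, xmin + band)
                if rng.random() < 0.5
                else rng.uniform(xmax - band, xmax - margin)
            )
        if rng.random() < edge_bias:
            gy[i] = (
                rng.uniform(ymin + margin, ymin + band)
                if rng.random() < 0.5
                else rng.uniform(ymax - band, ymax - margin)
            )
    targets = np.repeat(
        np.stack([gx, gy], axis=1), int(round(goal_interval * fs)), axis=0
    )[:n]
    xs, ys = _ou_path(
        noise, targets, goal_pull, dt, decay, kick, x0, y0, vx0, vy0,
        xmin, xmax, ymin, ymax,
        geometry.compartment_width, door_lo, door_hi, has_wall,
    )
    t = np.arange(n) * dt
    return Trajectory(t=t, x=xs, y=ys, duration=duration, fs=fs)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def _local_rot_sep(geometry: BoxGeometry, p_local) -> float:
    """Distance between a local point and its in-compartment 180 rotation."""
    return float(np.linalg.norm(np.asarray(p_local) - geometry.local_rot180(p_local)))


def _draw_local(rng, geometry: BoxGeometry, margin: float = 3.0) -> np.ndarray:
    return np.array(
        [
            rng.uniform(margin, geometry.compartment_width - margin),
            rng.uniform(margin, geometry.compartment_height - margin),
        ]
    )


def generate_ensemble(config: EnsembleConfig, geometry: BoxGeometry) -> list:
    """Draw ``config.n_cells`` ground-truth cells.

    Categories are drawn per ``category_proportions``.  Field centres are
    uniform within the compartment subject to the category's geometric
    constraint, rejection-sampled so every cell is consistent with exactly one
    category (see :data:`IDENTIFIABILITY_SEP`).
    """

    rng = np.random.default_rng(config.rng_seed)
    names = sorted(config.category_proportions)
    probs = np.array([config.category_proportions[k] for k in names])
    cats = rng.choice(names, size=config.n_cells, p=probs)
    cells = []
    for i, cat in enumerate(cats):
        sigma = rng.uniform(*config.sigma_range)
        peak = rng.uniform(*config.peak_rate_range)
        base = rng.uniform(*config.baseline_range)
        sep = IDENTIFIABILITY_SEP * sigma
        centers = {}
        if cat == "distractor":
            base = rng.uniform(*config.distractor_rate_range)
            peak = 0.0
        elif cat in ("repeat", "rotate"):
            while True:
                c1 = _draw_local(rng, geometry)
                if _local_rot_sep(geometry, c1) >= sep:
                    break
            centers[1] = geometry.to_global(c1, 1)
            c2_local = c1 if cat == "repeat" else geometry.local_rot180(c1)
            centers[2] = geometry.to_global(c2_local, 2)
        elif cat == "remap_single":
            comp = int(rng.integers(1, 3))
            centers[comp] = geometry.to_global(_draw_local(rng, geometry), comp)
        elif cat == "remap_shift":
            c1 = _draw_local(rng, geometry)
            while True:
                c2 = _draw_local(rng, geometry)
                if (
                    np.linalg.norm(c2 - c1) >= sep
                    and np.linalg.norm(c2 - geometry.local_rot180(c1)) >= sep
                ):
                    break
            centers[1] = geometry.to_global(c1, 1)
            centers[2] = geometry.to_global(c2, 2)
        cells.append(
            GroundTruthCell(
                cell_id=f"c{i:03d}",
                category=str(cat),
                field_centers=centers,
                field_width=sigma,
                peak_rate=peak,
                baseline_rate=base,
                tetrode=int(rng.integers(16)),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def effective_centers(
    cell: GroundTruthCell,
    geometry: BoxGeometry,
    odor_switched: bool = False,
    single_compartment: int | None = None,
    odor_gated: bool = True,
) -> dict:
    """Per-compartment field centres actually expressed on a trial, box frame.

    An odor-switched trial rotates the whole firing pattern 180 degrees
    relative to the odor frame: lambda'(p) = lambda(R(p)), i.e. the centre
    expressed in compartment c is R applied to the canonical centre of the
    other compartment.  On door-closed trials an odor-blind cell ignores the
    odor and anchors a single field to the visual scene instead (the scene
    position of its canonical field).
    """

    m = cell.field_centers
    if single_compartment is not None and not odor_gated:
        comp = single_compartment
        src = 1 if 1 in m else (2 if 2 in m else None)
        if src is None:
            return {}
        scene = geometry.scene_position(geometry.to_local(m[src], src), src)
        local = scene if comp == 1 else geometry.local_rot180(scene)
        return {comp: geometry.to_global(local, comp)}
    if odor_switched:
        out = {}
        for comp in (1, 2):
            other = 3 - comp
            if other in m:
                out[comp] = geometry.rotate180(m[other])
        return out
    return dict(m)


def rate_on_trajectory(
    cell: GroundTruthCell,
    traj: Trajectory,
    geometry: BoxGeometry,
    centers: dict | None = None,
) -> np.ndarray:
    """Instantaneous firing rate lambda(t) along a box-frame trajectory:
    baseline + peak * exp(-d^2 / 2 sigma^2), d the distance to the field
    centre of the currently occupied compartment."""

    if centers is None:
        centers = dict(cell.field_centers)
    lam = np.full(len(traj), cell.baseline_rate)
    if cell.peak_rate > 0 and centers:
        comp = geometry.compartment_of(traj.x)
        for c, ctr in centers.items():
            sel = comp == c
            if not np.any(sel):
                continue
            d2 = (traj.x[sel] - ctr[0]) ** 2 + (traj.y[sel] - ctr[1]) ** 2
            lam[sel] += cell.peak_rate * np.exp(-d2 / (2.0 * cell.field_width**2))
    return lam


def _poisson_spikes(lam, traj, rng, refractory: float = 0.002) -> np.ndarray:
    dt = traj.dt
    counts = rng.poisson(lam * dt)
    idx = np.repeat(np.arange(len(lam)), counts)
    if len(idx) == 0:
        return np.empty(0)
    times = traj.t[idx] + rng.uniform(0.0, dt, size=len(idx))
    times.sort()
    if refractory > 0 and len(times) > 1:
        keep = np.ones(len(times), dtype=bool)
        last = times[0]
        for i in range(1, len(times)):
            if times[i] - last < refractory:
                keep[i] = False
            else:
                last = times[i]
        times = times[keep]
    return times


def generate_spikes(
    cell: GroundTruthCell,
    traj: Trajectory,
    geometry: BoxGeometry,
    seed,
    odor_switched: bool = False,
    single_compartment: int | None = None,
    odor_gated: bool = True,
    refractory: float = 0.002,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes along a box-frame trajectory.

    Spike counts per sample interval are Poisson(lambda * dt), positioned
    uniformly within the interval; a short absolute refractory period then
    removes near-coincident spikes (real pyramidal cells are refractory, and
    the downstream ISI quality control assumes so).
    """

    rng = np.random.default_rng(seed)
    centers = effective_centers(
        cell, geometry, odor_switched, single_compartment, odor_gated
    )
    lam = rate_on_trajectory(cell, traj, geometry, centers)
    times = _poisson_spikes(lam, traj, rng, refractory)
    return SpikeTrain(cell_id=cell.cell_id, spike_times=times)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def _pyramidal_template(rng, n_samples: int = WAVEFORM_SAMPLES) -> np.ndarray:
    """Unit-amplitude pyramidal-like extracellular template: a sharp positive
    peak followed by a slower trough, peak-to-trough time ~350 us > 250 us."""

    t = np.arange(n_samples) / WAVEFORM_FS * 1e3  # ms
    t_peak = 0.25 + rng.uniform(-0.02, 0.02)
    t_trough = t_peak + 0.35 + rng.uniform(-0.03, 0.05)
    w_peak = 0.08 + rng.uniform(-0.01, 0.01)
    w_trough = 0.18 + rng.uniform(-0.02, 0.02)
    depth = 0.55 + rng.uniform(-0.1, 0.1)
    w = np.exp(-((t - t_peak) ** 2) / (2 * w_peak**2)) - depth * np.exp(
        -((t - t_trough) ** 2) / (2 * w_trough**2)
    )
    return w / np.abs(w).max()


def generate_waveforms(
    cell_id: str,
    n_sessions: int,
    drift: float,
    seed,
    shape_noise: float = 0.01,
) -> list:
    """Per-session 4-channel mean waveforms (uV) for one cell.

    A cell-specific template and per-channel amplitude vector are drawn once;
    each successive session multiplies the amplitudes by ``1 + drift * eps``
    (eps standard normal, cumulative across sessions) and adds a small amount
    of shape noise, emulating slow electrode drift.
    """

    if drift < 0:
        raise ValueError("drift must be >= 0")
    rng = np.random.default_rng(seed)
    template = _pyramidal_template(rng)
    amps = rng.uniform(60.0, 250.0, size=4)
    # channels far from the cell see less of it
    amps *= np.sort(rng.uniform(0.3, 1.0, size=4))[::-1]
    out = []
    a = amps.copy()
    for _ in range(n_sessions):
        wf = a[:, None] * template[None, :]
        if shape_noise > 0:
            wf = wf + rng.normal(0.0, shape_noise, wf.shape) * a[:, None]
        out.append(wf)
        if drift > 0:
            a = a * np.clip(1.0 + drift * rng.standard_normal(4), 0.2, 5.0)
    return out


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def generate_session(
    config: EnsembleConfig,
    geometry: BoxGeometry,
    seed,
    session_id: str = "session",
    two_box_duration: float = 900.0,
    single_duration: float = 600.0,
    rotation_angle: int = 180,
    fs: float = 50.0,
    waveform_drift: float = 0.0,
) -> SessionBundle:
    """One five-trial recording session.

    Trials: baseline 1; rotation (box rotated ``rotation_angle``, fields follow
    the box cues so box-frame activity is unchanged); two door-closed
    single-compartment trials (compartment 1 then 2); baseline 2.  Trials whose
    1-based index is in ``config.odor_switch_trials`` have the whole ensemble's
    firing pattern rotated 180 degrees relative to the odor frame.
    """

    if rotation_angle % 90 != 0:
        raise ValueError("rotation_angle must be a multiple of 90")
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(7)
    cells = generate_ensemble(config, geometry)
    wf_rng = np.random.default_rng(kids[5])
    session_wfs = {
        c.cell_id: generate_waveforms(
            c.cell_id, 1, waveform_drift,
            int(wf_rng.integers(2**31)),
        )[0]
        for c in cells
    }
    trial_specs = [
        (1, "baseline1", True, None, 0),
        (2, "rotation", True, None, rotation_angle),
        (3, "single1", False, 1, 0),
        (4, "single2", False, 2, 0),
        (5, "baseline2", True, None, 0),
    ]
    trials = []
    spike_rng = np.random.default_rng(kids[6])
    for (idx, name, door_open, comp, rot), kid in zip(trial_specs, ss.spawn(5)):
        duration = two_box_duration if door_open else single_duration
        traj = generate_trajectory(
            geometry, duration, kid, fs=fs, door_open=door_open, compartment=comp
        )
        switched = idx in config.odor_switch_trials
        spikes = {}
        waveforms = {}
        for cell in cells:
            st = generate_spikes(
                cell,
                traj,
                geometry,
                int(spike_rng.integers(2**31)),
                odor_switched=switched,
                single_compartment=comp,
                odor_gated=config.odor_gated,
            )
            base_wf = session_wfs[cell.cell_id]
            jitter = 1.0 + 0.01 * wf_rng.standard_normal(4)
            wf = base_wf * jitter[:, None]
            wf = wf + wf_rng.normal(0.0, 0.005, wf.shape) * np.abs(wf).max()
            st.waveform = wf
            spikes[cell.cell_id] = st
            waveforms[cell.cell_id] = wf
        if rot % 360 != 0:
            pts = rotate_point(
                np.stack([traj.x, traj.y], axis=-1), rot, geometry.width,
                geometry.height,
            )
            traj = replace(traj, x=pts[..., 0], y=pts[..., 1])
        trials.append(
            Trial(
                index=idx,
                name=name,
                door_open=door_open,
                rotation_deg=rot,
                single_compartment=comp,
                odor_switched=switched,
                traj=traj,
                spikes=spikes,
                waveforms=waveforms,
            )
        )
    return SessionBundle(
        session_id=session_id,
        geometry=geometry,
        config=config,
        cells=cells,
        trials=trials,
    )


# ---------------------------------------------------------------------------
# cross-session corpus for unit tracking
# ---------------------------------------------------------------------------


@dataclass
class TrackedUnit:
    """One cell as recorded in one session of a tracking corpus."""

    label: str  # per-session label, what the tracker sees
    true_id: str  # ground-truth identity, hidden from the tracker
    session: int
    tetrode: int
    waveform: np.ndarray  # (4, S) session-mean waveform
    trial_waveforms: list  # per two-box trial, for classifier training
    ratemap: np.ndarray  # whole-box rate map with NaN at unvisited bins


def generate_tracking_corpus(
    n_cells: int = 24,
    n_sessions: int = 3,
    drift: float = 0.05,
    seed=0,
    geometry: BoxGeometry | None = None,
    n_tetrodes: int = 4,
    bin_size: float = 3.0,
    map_noise: float = 0.15,
):
    """Multi-session corpus with ground-truth identities.

    Every cell persists across all sessions with a stable place field (the
    tracking method's core assumption) and a waveform that drifts slowly in
    amplitude.  Rate maps are direct Gaussian-bump maps with multiplicative
    noise rather than full spiking simulations - the tracker only consumes
    their correlations.
    """

    geometry = geometry or BoxGeometry()
    rng = np.random.default_rng(seed)
    nx = int(np.ceil(geometry.width / bin_size))
    ny = int(np.ceil(geometry.height / bin_size))
    gx, gy = np.meshgrid(
        (np.arange(nx) + 0.5) * bin_size, (np.arange(ny) + 0.5) * bin_size
    )
    sessions = [[] for _ in range(n_sessions)]
    for i in range(n_cells):
        tet = int(rng.integers(n_tetrodes))
        ctr = np.array(
            [rng.uniform(5, geometry.width - 5), rng.uniform(5, geometry.height - 5)]
        )
        sigma = rng.uniform(6, 12)
        peak = rng.uniform(2, 8)
        base_map = 0.1 + peak * np.exp(
            -((gx - ctr[0]) ** 2 + (gy - ctr[1]) ** 2) / (2 * sigma**2)
        )
        wfs = generate_waveforms(f"u{i:03d}", n_sessions, drift, rng.integers(2**31))
        for s in range(n_sessions):
            noisy = base_map * rng.lognormal(0.0, map_noise, base_map.shape)
            trial_wfs = []
            for _ in range(3):
                jit = 1.0 + 0.01 * rng.standard_normal(4)
                w = wfs[s] * jit[:, None]
                w = w + rng.normal(0.0, 0.005, w.shape) * np.abs(w).max()
                trial_wfs.append(w)
            sessions[s].append(
                TrackedUnit(
                    label=f"s{s}_t{tet}_c{i:03d}",
                    true_id=f"u{i:03d}",
                    session=s,
                    tetrode=tet,
                    waveform=wfs[s],
                    trial_waveforms=trial_wfs,
                    ratemap=noisy,
                )
            )
    return sessions
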