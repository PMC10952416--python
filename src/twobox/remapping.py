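"""Rate-map correlations, Monte-Carlo null thresholds and the
repeat / remap / rotate classification.

The logic mirrors the 2-box analysis: smoothed rate maps are compared with
Pearson correlations over jointly visited bins, the chance level for "same
place field" is the 95th percentile of correlations between randomly paired
maps of distinct cells (one null for whole-apparatus maps, one for
single-compartment maps), and each admitted cell is classified by comparing
its two compartment maps in the global frame (translational) and with one
compartment rotated 180 degrees into the other's local layout (rotational).
En-bloc "odor-switching" - the whole ensemble rotating 180 degrees relative
to the odor frame on a trial - is detected from the population of
baseline-versus-rotation correlations and corrected before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import BoxGeometry
from .ratemaps import RateMap

MIN_JOINT_BINS = 20  # Pearson r is unstable below this

TRANSFORMS = {"none": 0, "rot90": 1, "rot180": 2, "rot270": 3}
TRANSFORM_INVERSE = {"none": "none", "rot90": "rot270", "rot180": "rot180",
                     "rot270": "rot90"}


def _as_array(m) -> np.ndarray:
    return m.rate if isinstance(m, RateMap) else np.asarray(m, dtype=float)


def map_pearson(a, b, min_bins: int = MIN_JOINT_BINS) -> tuple:
    """Pearson r over bins visited in both maps; ``(nan, n)`` when fewer than
    ``min_bins`` joint bins or either map is constant there."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        a, b = pad_to_common(a, b)
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < min_bins:
        return float("nan"), n
    av, bv = a[ok], b[ok]
    sa, sb = av.std(), bv.std()
    if sa == 0 or sb == 0:
        return float("nan"), n
    r = float(np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
    return r, n


def pad_to_common(a: np.ndarray, b: np.ndarray) -> tuple:
    """NaN-pad the smaller map to the larger's extent, origins aligned (both
    maps share the box's lower-left corner)."""
    ny, nx = max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1])

    def pad(m):
        out = np.full((ny, nx), np.nan)
        out[: m.shape[0], : m.shape[1]] = m
        return out

    return pad(a), pad(b)


@dataclass
class MapCorrelation:
    r: float
    n_bins_used: int
    transform: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def correlate_maps(a, b, transform: str = "none",
                   min_bins: int = MIN_JOINT_BINS) -> MapCorrelation:
    """Correlate map ``a`` with map ``b`` after rotating ``b`` by
    ``transform`` (counter-clockwise quarter turns; 180 degrees reverses both
    axes).  Bins missing in either map are excluded pairwise; fewer than
    ``min_bins`` joint bins leaves the correlation undefined (NaN)."""
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    bb = np.rot90(_as_array(b), TRANSFORMS[transform])
    r, n = map_pearson(_as_array(a), bb, min_bins)
    return MapCorrelation(r=r, n_bins_used=n, transform=transform)


def realign_to_box(m: RateMap, rotation_deg: int) -> RateMap:
    """Rotate a room-frame map of a rotation trial back into the box frame."""
    return m.rotated((rotation_deg // 90) % 4)


def split_compartments(m: RateMap, geometry: BoxGeometry) -> tuple:
    """Per-compartment submaps (rate arrays) of a whole-box map."""
    ncol = int(round(geometry.compartment_width / m.bin_size))
    return m.rate[:, :ncol], m.rate[:, ncol : 2 * ncol]


# ---------------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    comparison_kind: str  # "whole" or "sub"
    values: np.ndarray
    threshold: float
    percentile: float = 95.0


def build_null(
    maps: list,
    cell_ids: list,
    kind: str = "whole",
    n: int = 10000,
    seed=0,
    percentile: float = 95.0,
    min_bins: int = MIN_JOINT_BINS,
) -> NullDistribution:
    """Chance-level map similarity from randomly paired distinct-cell maps.

    Draws ``n`` map pairs from distinct cells, correlates each, and returns
    the empirical distribution with its 95th-percentile threshold.  Pairs
    with undefined correlations are redrawn.
    """

    if len(maps) < 20 or len(set(cell_ids)) < 10:
        raise ValueError("null pool needs >= 20 maps from >= 10 distinct cells")
    rng = np.random.default_rng(seed)
    arrs = [_as_array(m) for m in maps]
    ids = list(cell_ids)
    values = np.empty(n)
    got = 0
    attempts = 0
    while got < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("could not draw enough defined null pairs")
        i, j = rng.integers(len(arrs), size=2)
        if ids[i] == ids[j]:
            continue
        r, nb = map_pearson(arrs[i], arrs[j], min_bins)
        if np.isfinite(r):
            values[got] = r
            got += 1
    return NullDistribution(
        comparison_kind=kind,
        values=values,
        threshold=float(np.percentile(values, percentile)),
        percentile=percentile,
    )


# ---------------------------------------------------------------------------
# ensemble orientation ("odor-switching")
# ---------------------------------------------------------------------------


@dataclass
class EnsembleOrientation:
    trial_pair: tuple
    per_cell: dict  # cell_id -> (r_unrotated, r_rotated, quadrant)
    switched: bool
    determined: bool
    n_switched_cells: int
    n_consistent_cells: int


def detect_ensemble_rotation(
    maps_a: dict,
    maps_b: dict,
    threshold: float,
    trial_pair: tuple = ("baseline1", "rotation"),
    min_cells: int = 5,
) -> EnsembleOrientation:
    """Decide whether trial ``b``'s ensemble is 180-degree rotated w.r.t.
    trial ``a``.

    ``maps_a`` / ``maps_b`` map cell ids to whole-box rate maps already in a
    common (box) frame.  Each cell is assigned a quadrant against the
    whole-box null threshold: *consistent* (unrotated correlation high,
    rotated low), *switched* (the reverse) or abstaining.  The trial is
    switched when switched cells outnumber consistent ones (strict majority);
    with no informative cells the orientation is undetermined.
    """

    common = sorted(set(maps_a) & set(maps_b))
    if len(common) < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells in both trials, got {len(common)}"
        )
    per_cell = {}
    n_sw = n_co = 0
    for cid in common:
        r_u = correlate_maps(maps_a[cid], maps_b[cid], "none").r
        r_r = correlate_maps(maps_a[cid], maps_b[cid], "rot180").r
        hi_u = np.isfinite(r_u) and r_u > threshold
        hi_r = np.isfinite(r_r) and r_r > threshold
        if hi_u and not hi_r:
            quad = "consistent"
            n_co += 1
        elif hi_r and not hi_u:
            quad = "switched"
            n_sw += 1
        else:
            quad = "abstain"
        per_cell[cid] = (r_u, r_r, quad)
    determined = (n_sw + n_co) > 0
    return EnsembleOrientation(
        trial_pair=trial_pair,
        per_cell=per_cell,
        switched=bool(determined and n_sw > n_co),
        determined=determined,
        n_switched_cells=n_sw,
        n_consistent_cells=n_co,
    )


def correct_orientation(
    maps_by_trial: dict,
    switched: dict,
    already_corrected: set | None = None,
) -> tuple:
    """Rotate every map of the trials flagged switched by 180 degrees, so all
    trials share the canonical odor frame.

    ``maps_by_trial`` maps trial name -> {cell_id -> RateMap}.  Returns the
    corrected mapping together with the set of trials now corrected; passing
    that set back in makes the operation idempotent.  Trials with an
    undetermined orientation (``switched[trial] is None``) are left untouched.
    """

    done = set(already_corrected or ())
    out = {}
    for trial, cellmaps in maps_by_trial.items():
        flag = switched.get(trial, False)
        if flag and trial not in done:
            out[trial] = {cid: m.rotated(2) for cid, m in cellmaps.items()}
            done.add(trial)
        else:
            out[trial] = dict(cellmaps)
    return out, done


# ---------------------------------------------------------------------------
# per-cell classification
# ---------------------------------------------------------------------------


@dataclass
class RemapResult:
    cell_id: str
    r_translational: float
    r_rotational: float
    threshold: float
    category: str  # repeat | remap | rotate | ambiguous
    low_confidence: bool = False
    stability_r: float = float("nan")
    cue_control_r: float = float("nan")
    notes: list = field(default_factory=list)


def classify_cell(
    whole_map: RateMap,
    geometry: BoxGeometry,
    threshold: float,
    cell_id: str = "",
    stability_r: float = float("nan"),
    cue_control_r: float = float("nan"),
    silent_peak: float = 1.0,
) -> RemapResult:
    """Classify one cell's compartment encoding from an orientation-corrected
    whole-box map.

    ``r_translational`` compares the two compartment maps overlaid in the
    global frame; ``r_rotational`` compares them with one rotated 180 degrees
    (same position relative to each compartment's reversed local layout).
    Both are judged against the sub-compartment null threshold: high/low =>
    repeat, low/high => rotate, both low => remap, both high => ambiguous.

    A compartment whose map never reaches ``silent_peak`` (1 Hz, the place-
    field peak criterion) cannot contain a field, so repeat/rotate calls that
    hinge on it are spurious few-spike correlations: such cells are flagged
    low-confidence and reported as remap.
    """

    sub1, sub2 = split_compartments(whole_map, geometry)
    r_t, _ = map_pearson(sub1, sub2)
    r_r, _ = map_pearson(sub1, np.rot90(sub2, 2))
    hi_t = np.isfinite(r_t) and r_t > threshold
    hi_r = np.isfinite(r_r) and r_r > threshold
    if hi_t and hi_r:
        category = "ambiguous"
    elif hi_t:
        category = "repeat"
    elif hi_r:
        category = "rotate"
    else:
        category = "remap"
    peaks = [np.nanmax(s) if np.isfinite(s).any() else 0.0 for s in (sub1, sub2)]
    low_conf = any(p < silent_peak for p in peaks)
    notes = []
    if low_conf and category in ("repeat", "rotate"):
        notes.append(f"demoted_{category}_silent_compartment")
        category = "remap"
    return RemapResult(
        cell_id=cell_id,
        r_translational=r_t,
        r_rotational=r_r,
        threshold=threshold,
        category=category,
        low_confidence=low_conf,
        stability_r=stability_r,
        cue_control_r=cue_control_r,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# single-compartment odor-retrieval comparison
# ---------------------------------------------------------------------------


@dataclass
class OdorRetrievalResult:
    records: list  # (cell_id, single trial, r_same_odor, r_diff_odor)
    median_same: float
    median_diff: float
    median_paired_diff: float
    wilcoxon_statistic: float
    wilcoxon_p: float


def _scene(sub: np.ndarray, comp: int) -> np.ndarray:
    """Compartment submap in the visual-scene frame (cue card up)."""
    return sub if comp == 1 else np.rot90(sub, 2)


def single_compartment_comparison(
    rotation_maps: dict,
    single_maps_by_trial: dict,
    single_compartments: dict,
    geometry: BoxGeometry,
) -> OdorRetrievalResult:
    """Same-odor versus different-odor map retrieval in closed single boxes.

    For each cell and each door-closed trial, the occupied compartment's map
    is compared (after aligning compartments by their visual scene) with the
    same compartment's map from the preceding rotation trial (same odor) and
    with the other compartment's map (different odor).  Odor-based map
    retrieval predicts higher same-odor correlations; the paired difference
    and a Wilcoxon signed-rank descriptor summarise the effect.
    """

    if not single_maps_by_trial:
        raise ValueError("no single-compartment trials supplied")
    records = []
    same_all, diff_all = [], []
    for trial, cellmaps in single_maps_by_trial.items():
        comp = single_compartments[trial]
        other = 3 - comp
        for cid, smap in cellmaps.items():
            if cid not in rotation_maps:
                continue
            rot_subs = split_compartments(rotation_maps[cid], geometry)
            single_sub = split_compartments(smap, geometry)[comp - 1]
            r_same, _ = map_pearson(
                _scene(rot_subs[comp - 1], comp), _scene(single_sub, comp)
            )
            r_diff, _ = map_pearson(
                _scene(rot_subs[other - 1], other), _scene(single_sub, comp)
            )
            records.append((cid, trial, r_same, r_diff))
            if np.isfinite(r_same) and np.isfinite(r_diff):
                same_all.append(r_same)
                diff_all.append(r_diff)
    same_all = np.asarray(same_all)
    diff_all = np.asarray(diff_all)
    paired = same_all - diff_all
    if len(paired) and np.any(paired != 0):
        w = stats.wilcoxon(same_all, diff_all)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    else:
        w_stat, w_p = float("nan"), 1.0
    return OdorRetrievalResult(
        records=records,
        median_same=float(np.median(same_all)) if len(same_all) else float("nan"),
        median_diff=float(np.median(diff_all)) if len(diff_all) else float("nan"),
        median_paired_diff=float(np.median(paired)) if len(paired) else float("nan"),
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
    )
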