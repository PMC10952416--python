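"""Unit quality control, place-field detection and the spatial-tuning shuffle
test that together decide which cells enter the remapping analysis.

A unit is admitted when (i) fewer than 0.2% of its inter-spike intervals are
below 2 ms, its mean rate lies in [0.1, 5] Hz in both baseline trials and its
waveform peak-to-trough time exceeds 250 us (putative pyramidal cell);
(ii) its rate map contains at least one place field (>= 16 contiguous pixels
above 40% of a > 1 Hz peak) without being "messy" (fields covering more than
half the visited pixels); and (iii) its Skaggs spatial information exceeds
the 95th percentile of a 100-fold circular spike-shift shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ratemaps import (
    SPEED_MAX,
    SPEED_MIN,
    FilteredTrial,
    MapGrid,
    RateMap,
    sample_speeds,
    spike_sample_indices,
)
from .synth import SpikeTrain, Trajectory

ISI_REFRACTORY = 0.002  # s
ISI_MAX_FRACTION = 0.002
RATE_RANGE = (0.1, 5.0)  # Hz, putative pyramidal mean rate in baselines
PEAK_TROUGH_MIN_US = 250.0


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class UnitQCResult:
    isi_violation_fraction: float
    mean_rate_baseline1: float
    mean_rate_baseline2: float
    peak_trough_us: float
    passed: bool
    reasons: list = field(default_factory=list)


def peak_trough_time(waveform: np.ndarray, fs: float) -> float:
    """Peak-to-trough duration (us) on the largest-amplitude channel."""
    wf = np.asarray(waveform, dtype=float)
    ch = int(np.argmax(wf.max(axis=1)))
    w = wf[ch]
    i_peak = int(np.argmax(w))
    after = w[i_peak:]
    i_trough = i_peak + int(np.argmin(after))
    return (i_trough - i_peak) / fs * 1e6


def isi_violation_fraction(
    spike_trains: list, refractory: float = ISI_REFRACTORY
) -> float:
    """Fraction of ISIs below ``refractory``, pooled over within-trial trains."""
    n_viol = 0
    n_isi = 0
    for st in spike_trains:
        st = np.asarray(st)
        if len(st) > 1:
            isi = np.diff(st)
            n_viol += int(np.sum(isi < refractory))
            n_isi += len(isi)
    return n_viol / n_isi if n_isi else 0.0


def qc_unit(
    filtered_by_trial: dict,
    waveform: np.ndarray | None,
    waveform_fs: float = 48000.0,
    isi_refractory: float = ISI_REFRACTORY,
    isi_max_fraction: float = ISI_MAX_FRACTION,
    rate_range: tuple = RATE_RANGE,
    peak_trough_min_us: float = PEAK_TROUGH_MIN_US,
) -> UnitQCResult:
    """Apply the session-level unit QC.

    ``filtered_by_trial`` maps trial names to :class:`FilteredTrial`; both
    ``baseline1`` and ``baseline2`` must be present.  Mean rates are retained
    spikes over retained dwell time.
    """

    for need in ("baseline1", "baseline2"):
        if need not in filtered_by_trial:
            raise ValueError(f"missing required trial {need!r}")
    viol = isi_violation_fraction(
        [f.spike_times for f in filtered_by_trial.values()], isi_refractory
    )
    rates = {}
    for name in ("baseline1", "baseline2"):
        f: FilteredTrial = filtered_by_trial[name]
        rates[name] = f.n_spikes / f.total_dwell if f.total_dwell > 0 else 0.0
    reasons = []
    if viol > isi_max_fraction:
        reasons.append("isi_violations")
    lo, hi = rate_range
    if not all(lo <= rates[n] <= hi for n in rates):
        reasons.append("baseline_rate")
    if waveform is None:
        pt = float("nan")
        reasons.append("missing_waveform")
    else:
        pt = peak_trough_time(waveform, waveform_fs)
        if pt <= peak_trough_min_us:
            reasons.append("peak_trough")
    return UnitQCResult(
        isi_violation_fraction=viol,
        mean_rate_baseline1=rates["baseline1"],
        mean_rate_baseline2=rates["baseline2"],
        peak_trough_us=pt,
        passed=not reasons,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# place fields
# ---------------------------------------------------------------------------


@dataclass
class PlaceField:
    pixels: set  # {(iy, ix)}
    area: float  # cm^2
    peak_rate: float
    centroid: tuple  # (x, y) cm


def detect_fields(
    ratemap: RateMap,
    min_pixels: int = 16,
    frac_of_peak: float = 0.4,
    peak_min: float = 1.0,
    messy_fraction: float = 0.5,
    connectivity: int = 8,
) -> tuple:
    """Threshold-and-label place-field extraction.

    Returns ``(fields, messy)``.  Fields exist only when the map peak exceeds
    ``peak_min``; pixels above ``frac_of_peak`` of the peak are grouped into
    connected components (8-connectivity by default) and components with at
    least ``min_pixels`` pixels are kept.  ``messy`` is set when the kept
    field pixels cover more than ``messy_fraction`` of the visited pixels.
    """

    if ratemap.n_visited == 0:
        raise ValueError("rate map has no visited bins")
    rate = ratemap.rate
    peak = ratemap.peak
    if not peak > peak_min:
        return [], False
    above = np.where(np.isfinite(rate), rate, -np.inf) > frac_of_peak * peak
    structure = (
        np.ones((3, 3), dtype=int)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n = ndimage.label(above, structure=structure)
    fields = []
    total_px = 0
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < min_pixels:
            continue
        total_px += len(ys)
        rates = rate[ys, xs]
        w = rates / rates.sum()
        cx = float(((xs + 0.5) * ratemap.bin_size * w).sum())
        cy = float(((ys + 0.5) * ratemap.bin_size * w).sum())
        fields.append(
            PlaceField(
                pixels=set(zip(ys.tolist(), xs.tolist())),
                area=len(ys) * ratemap.bin_size**2,
                peak_rate=float(rates.max()),
                centroid=(cx, cy),
            )
        )
    messy = total_px > messy_fraction * ratemap.n_visited
    return fields, messy


# ---------------------------------------------------------------------------
# spatial information
# ---------------------------------------------------------------------------


def spatial_information(ratemap_or_rate, dwell=None) -> float:
    """Skaggs spatial information, bits/spike.

    ``I = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar)`` with occupancy
    probabilities ``p_i`` from the (smoothed) dwell map over visited bins and
    ``lam_bar = sum_i p_i lam_i``.  Bins with zero rate contribute zero.
    Returns NaN when the mean rate is zero (information undefined).
    """

    if isinstance(ratemap_or_rate, RateMap):
        rate, dwell = ratemap_or_rate.rate, ratemap_or_rate.dwell
    else:
        rate = ratemap_or_rate
    rate = np.asarray(rate, dtype=float).ravel()
    dwell = np.asarray(dwell, dtype=float).ravel()
    ok = np.isfinite(rate) & (dwell > 0)
    rate, dwell = rate[ok], dwell[ok]
    if rate.size == 0:
        return float("nan")
    p = dwell / dwell.sum()
    lam_bar = float(np.sum(p * rate))
    if lam_bar <= 0:
        return float("nan")
    pos = rate > 0
    ratio = rate[pos] / lam_bar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


# ---------------------------------------------------------------------------
# shuffle test
# ---------------------------------------------------------------------------


@dataclass
class SpatialInfoResult:
    info: float
    shuffle_values: np.ndarray
    percentile_95: float
    is_spatial: bool


class _InfoEngine:
    """Cached trajectory-side quantities so that repeated shuffles only
    re-bin the spikes.  Produces maps identical to :func:`make_ratemap`."""

    def __init__(self, traj: Trajectory, extent, bin_size, sigma, cutoff, min_dwell):
        self.traj = traj
        self.grid = MapGrid(extent, bin_size, sigma, cutoff)
        v = sample_speeds(traj)
        self.speeds = v
        keep = v <= SPEED_MAX
        dwell_raw = self.grid.accumulate(traj.x[keep], traj.y[keep], weight=traj.dt)
        self.mask = dwell_raw >= min_dwell
        if not self.mask.any():
            raise ValueError("all bins unvisited")
        self.den = self.grid.smooth(np.where(self.mask, dwell_raw, 0.0))
        norm = self.grid.smooth(self.mask.astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            self.dwell_s = np.where(self.mask, self.den / norm, 0.0)
        self._flat_bin = None

    def info_for(self, spike_times: np.ndarray) -> float:
        idx = spike_sample_indices(self.traj, spike_times)
        sv = self.speeds[idx]
        keep = (sv >= SPEED_MIN) & (sv <= SPEED_MAX)
        idx = idx[keep]
        iy, ix = self.grid.bin_of(self.traj.x[idx], self.traj.y[idx])
        spike_map = np.bincount(
            iy * self.grid.nx + ix, minlength=self.grid.ny * self.grid.nx
        ).reshape(self.grid.shape).astype(float)
        num = self.grid.smooth(np.where(self.mask, spike_map, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.mask, num / self.den, np.nan)
        return spatial_information(rate, self.dwell_s)


def shuffle_test(
    traj: Trajectory,
    spikes: SpikeTrain,
    extent,
    n_shuffles: int = 100,
    margin: float = 20.0,
    seed=0,
    bin_size: float = 3.0,
    sigma: float = 5.0,
    cutoff: float = 9.0,
    min_dwell: float = 0.1,
    percentile: float = 95.0,
) -> SpatialInfoResult:
    """Circular spike-shift test of spatial tuning.

    Each shuffle adds a uniform offset in ``[margin, T - margin]`` to all
    spike times modulo the trial duration, preserving the train's temporal
    structure while dissociating it from position, then recomputes the rate
    map (against the un-shifted trajectory) and the spatial information.
    The cell is spatially modulated when its observed information exceeds the
    95th percentile of the shuffled values.
    """

    T = traj.duration
    if T <= 2 * margin:
        raise ValueError("trial too short for the circular-shift shuffle")
    rng = np.random.default_rng(seed)
    eng = _InfoEngine(traj, extent, bin_size, sigma, cutoff, min_dwell)
    st = np.asarray(spikes.spike_times, dtype=float)
    observed = eng.info_for(st)
    values = np.empty(n_shuffles)
    for i in range(n_shuffles):
        off = rng.uniform(margin, T - margin)
        values[i] = eng.info_for(np.sort((st + off) % T))
    pct = float(np.percentile(values, percentile))
    is_spatial = bool(np.isfinite(observed) and observed > pct)
    return SpatialInfoResult(
        info=float(observed),
        shuffle_values=values,
        percentile_95=pct,
        is_spatial=is_spatial,
    )
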