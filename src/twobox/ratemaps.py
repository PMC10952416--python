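"""Speed filtering and occupancy-normalised firing-rate maps.

Construction follows the standard recipe for tetrode place-cell data: spikes
occurring while the animal moves slower than 5 cm/s are removed (non-local
spiking), position samples and spikes faster than 100 cm/s are treated as
tracking errors, positions and spikes are accumulated into 3 x 3 cm bins,
dwell and spike maps are smoothed separately with a truncated Gaussian kernel
(sigma 5 cm, zero weight beyond 9 cm, renormalised over visited in-range
bins), and the rate map is their ratio.  Bins occupied for less than 0.1 s
are unvisited and carry NaN.

Grid convention: origin at the box's lower-left corner, x rightward, y upward;
arrays are indexed ``[iy, ix]`` with row 0 at y = 0.  All rotations in the
package act on this convention via :func:`numpy.rot90`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import SpikeTrain, Trajectory

SPEED_MIN = 5.0  # cm/s, spikes below this are non-local and removed
SPEED_MAX = 100.0  # cm/s, faster samples are tracking errors


def sample_speeds(traj: Trajectory) -> np.ndarray:
    """Instantaneous speed per sample, central difference of position."""
    if len(traj) < 2:
        raise ValueError("trajectory too short for speed estimation")
    x, y, dt = traj.x, traj.y, traj.dt
    v = np.empty(len(traj))
    v[1:-1] = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2]) / (2.0 * dt)
    v[0] = np.hypot(x[1] - x[0], y[1] - y[0]) / dt
    v[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) / dt
    return v


def spike_sample_indices(traj: Trajectory, spike_times: np.ndarray) -> np.ndarray:
    """Index of the nearest position sample for each spike."""
    idx = np.rint(np.asarray(spike_times) * traj.fs).astype(np.int64)
    return np.clip(idx, 0, len(traj) - 1)


@dataclass
class FilteredTrial:
    """Speed-filtered positions and spikes of one trial (one cell)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    spike_times: np.ndarray
    spike_x: np.ndarray
    spike_y: np.ndarray
    n_samples_removed: int
    n_spikes_removed_slow: int
    n_spikes_removed_fast: int

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def total_dwell(self) -> float:
        return len(self.t) * self.dt


def speed_filter(
    traj: Trajectory,
    spikes: SpikeTrain,
    speed_min: float = SPEED_MIN,
    speed_max: float = SPEED_MAX,
) -> FilteredTrial:
    """Apply the 5 cm/s spike filter and the 100 cm/s tracking-error filter.

    Slow position samples are *kept* (they are genuine dwell); only their
    spikes are dropped.  Each spike takes the speed and position of its
    nearest position sample.
    """

    if len(traj) == 0:
        raise ValueError("empty trajectory")
    v = sample_speeds(traj)
    keep_sample = v <= speed_max
    st = np.asarray(spikes.spike_times, dtype=float)
    idx = spike_sample_indices(traj, st)
    sv = v[idx]
    slow = sv < speed_min
    fast = sv > speed_max
    keep_spike = ~(slow | fast)
    idx_kept = idx[keep_spike]
    return FilteredTrial(
        t=traj.t[keep_sample],
        x=traj.x[keep_sample],
        y=traj.y[keep_sample],
        dt=traj.dt,
        spike_times=st[keep_spike],
        spike_x=traj.x[idx_kept],
        spike_y=traj.y[idx_kept],
        n_samples_removed=int(np.sum(~keep_sample)),
        n_spikes_removed_slow=int(np.sum(slow)),
        n_spikes_removed_fast=int(np.sum(fast)),
    )


class MapGrid:
    """Binning grid and truncated-Gaussian smoother for one box extent.

    Partial edge bins are included, so ``nx = ceil(width / bin_size)``.
    Kernel weights are ``exp(-d^2 / 2 sigma^2)`` for centre-to-centre
    distances ``d <= cutoff`` and zero beyond; smoothing renormalises over
    visited in-range bins (the renormalisation cancels in the spike/dwell
    ratio but matters for the smoothed dwell itself).
    """

    def __init__(
        self,
        extent: tuple,
        bin_size: float = 3.0,
        sigma: float = 5.0,
        cutoff: float = 9.0,
    ):
        self.width, self.height = float(extent[0]), float(extent[1])
        self.bin_size = float(bin_size)
        self.sigma = float(sigma)
        self.cutoff = float(cutoff)
        self.nx = int(np.ceil(self.width / self.bin_size - 1e-9))
        self.ny = int(np.ceil(self.height / self.bin_size - 1e-9))
        r = int(np.floor(self.cutoff / self.bin_size + 1e-9))
        oy, ox = np.mgrid[-r : r + 1, -r : r + 1]
        d = self.bin_size * np.hypot(ox, oy)
        k = np.exp(-(d**2) / (2.0 * self.sigma**2))
        k[d > self.cutoff + 1e-9] = 0.0
        self.kernel = k

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx)

    def bin_of(self, x, y) -> tuple:
        ix = np.clip((np.asarray(x) / self.bin_size).astype(np.int64), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.bin_size).astype(np.int64), 0, self.ny - 1)
        return iy, ix

    def accumulate(self, x, y, weight: float = 1.0) -> np.ndarray:
        iy, ix = self.bin_of(x, y)
        flat = np.bincount(iy * self.nx + ix, minlength=self.ny * self.nx)
        return flat.reshape(self.ny, self.nx).astype(float) * weight

    def smooth(self, arr: np.ndarray) -> np.ndarray:
        return ndimage.convolve(arr, self.kernel, mode="constant", cval=0.0)


@dataclass
class RateMap:
    """Smoothed occupancy-normalised firing-rate map.

    ``rate`` is NaN at unvisited bins; ``dwell`` is the smoothed occupancy
    (s), ``dwell_raw`` and ``spike_count`` are pre-smoothing, so their sums
    equal retained sample time and retained spike count.
    """

    rate: np.ndarray
    dwell: np.ndarray
    dwell_raw: np.ndarray
    spike_count: np.ndarray
    mask: np.ndarray
    bin_size: float
    extent: tuple

    @property
    def peak(self) -> float:
        return float(np.nanmax(self.rate)) if self.mask.any() else float("nan")

    @property
    def n_visited(self) -> int:
        return int(self.mask.sum())

    def rotated(self, k: int) -> "RateMap":
        """Map rotated by ``k`` quarter turns counter-clockwise."""
        rot = lambda a: np.rot90(a, k)
        ext = self.extent if k % 2 == 0 else (self.extent[1], self.extent[0])
        return RateMap(
            rate=rot(self.rate),
            dwell=rot(self.dwell),
            dwell_raw=rot(self.dwell_raw),
            spike_count=rot(self.spike_count),
            mask=rot(self.mask),
            bin_size=self.bin_size,
            extent=ext,
        )


def make_ratemap(
    filtered: FilteredTrial,
    extent: tuple,
    bin_size: float = 3.0,
    sigma: float = 5.0,
    cutoff: float = 9.0,
    min_dwell: float = 0.1,
    grid: MapGrid | None = None,
) -> RateMap:
    """Build the smoothed rate map of one cell on one trial.

    ``rate = smooth(spikes) / smooth(dwell)`` with both maps restricted to
    visited bins before smoothing; since the same renormalisation applies to
    numerator and denominator it cancels, so a single visited bin keeps its
    exact raw rate.
    """

    if len(filtered.t) == 0:
        raise ValueError("no position samples after filtering")
    g = grid or MapGrid(extent, bin_size, sigma, cutoff)
    dwell_raw = g.accumulate(filtered.x, filtered.y, weight=filtered.dt)
    spike_count = g.accumulate(filtered.spike_x, filtered.spike_y)
    mask = dwell_raw >= min_dwell
    if not mask.any():
        raise ValueError("all bins unvisited")
    num = g.smooth(np.where(mask, spike_count, 0.0))
    den = g.smooth(np.where(mask, dwell_raw, 0.0))
    norm = g.smooth(mask.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(mask, num / den, np.nan)
        dwell_s = np.where(mask, den / norm, 0.0)
    return RateMap(
        rate=rate,
        dwell=dwell_s,
        dwell_raw=dwell_raw,
        spike_count=spike_count,
        mask=mask,
        bin_size=g.bin_size,
        extent=(g.width, g.height),
    )
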