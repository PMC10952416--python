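"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def flood_fill_fields(rate, min_pixels=16, frac_of_peak=0.4, peak_min=1.0,
                      connectivity=8):
    """Exhaustive threshold-and-label field extraction.

    Breadth-first flood fill over the boolean above-threshold grid; returns a
    list of frozensets of (iy, ix) pixels, independent of scipy labeling.
    """

    finite = np.isfinite(rate)
    if not finite.any():
        return []
    peak = np.nanmax(rate)
    if not peak > peak_min:
        return []
    above = finite & (np.nan_to_num(rate, nan=-np.inf) > frac_of_peak * peak)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(above, dtype=bool)
    ny, nx = above.shape
    fields = []
    for sy in range(ny):
        for sx in range(nx):
            if not above[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            comp = []
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy, dx in steps:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx and above[yy, xx] \
                            and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            if len(comp) >= min_pixels:
                fields.append(frozenset(comp))
    return fields


def grid_search_d1(wf_a, wf_b, n_iter=6, n_grid=201):
    """Tolias shape distance via iteratively refined grid search over the
    per-channel scale factor (no closed form used)."""

    a = np.asarray(wf_a, float)
    b = np.asarray(wf_b, float)
    resid_total = 0.0
    for c in range(a.shape[0]):
        lo, hi = -10.0, 10.0
        best = None
        for _ in range(n_iter):
            alphas = np.linspace(lo, hi, n_grid)
            resid = np.linalg.norm(
                a[c][None, :] - alphas[:, None] * b[c][None, :], axis=1
            )
            k = int(np.argmin(resid))
            best = resid[k]
            step = alphas[1] - alphas[0]
            lo, hi = alphas[k] - step, alphas[k] + step
        resid_total += best
    return resid_total / np.linalg.norm(a, axis=1).sum()
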