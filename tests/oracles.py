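"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with simple loops (or refined sums)
so the vectorised implementations are checked against code that shares no
internals with them.
"""

import numpy as np
from scipy import ndimage

from axonquant.io import DetectorParams


def bruteforce_crossings(fibers, positions):
    """Loop-based plane-crossing counts with the half-open [min, max) rule."""
    counts = np.zeros(len(positions), dtype=np.int64)
    for f in fibers:
        x = f.points[:, 0]
        for x1, x2 in zip(x[:-1], x[1:]):
            lo, hi = min(x1, x2), max(x1, x2)
            for i, p in enumerate(positions):
                if lo <= p < hi:
                    counts[i] += 1
    return counts


def bruteforce_spots(plane, params: DetectorParams):
    """Exhaustive local-maximum search with the same threshold/suppression rule."""
    plane = np.asarray(plane, dtype=float)
    step = params.plane_step_um
    sigma_px = params.sigma_um / step
    resp = -ndimage.gaussian_laplace(plane, sigma_px) * sigma_px**2
    mad = np.median(np.abs(plane - np.median(plane)))
    noise = 1.4826 * mad
    floor = params.peak_floor_frac * resp.max() if resp.size and resp.max() > 0 else 0.0
    threshold = max(params.rel_threshold * noise, floor)
    h, w = plane.shape
    cands = []
    for r in range(h):
        for c in range(w):
            v = resp[r, c]
            if not (v > threshold and v > 0):
                continue
            is_max = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and resp[rr, cc] > v:
                        is_max = False
            if is_max:
                cands.append((r, c, v))
    cands.sort(key=lambda t: -t[2])  # stable: ties stay in row-major order
    kept = []
    for r, c, v in cands:
        ok = True
        for r2, c2, _ in kept:
            d2 = ((r - r2) ** 2 + (c - c2) ** 2) * step**2
            if d2 < params.min_sep_um**2:
                ok = False
                break
        if ok:
            kept.append((r, c, v))
    centers = np.array([[r * step, c * step] for r, c, _ in kept]).reshape(-1, 2)
    responses = np.array([v for _, _, v in kept])
    return centers, responses


def bruteforce_windowed_mean(values, half):
    """Direct-loop centred moving average, truncated at the edges, NaN-aware."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    n = values.size
    for i in range(n):
        seg = values[max(0, i - half) : min(n, i + half + 1)]
        seg = seg[np.isfinite(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out


def bruteforce_windowed_variance(img, size):
    """Windowed variance on interior voxels with an explicit triple loop."""
    img = np.asarray(img, dtype=float)
    hz, hy, hx = (s // 2 for s in size)
    out = np.full(img.shape, np.nan)
    nz, ny, nx = img.shape
    for z in range(hz, nz - hz):
        for y in range(hy, ny - hy):
            for x in range(hx, nx - hx):
                block = img[z - hz : z + hz + 1, y - hy : y + hy + 1, x - hx : x + hx + 1]
                out[z, y, x] = block.var()
    return out


def refined_riemann_auc(positions, values, a, b, refine=10):
    """Midpoint Riemann sum on a ``refine``×-finer grid of the piecewise-linear
    interpolant; converges to the trapezoid value as the grid refines."""
    positions = np.asarray(positions, dtype=float)
    step = 1.0 / refine
    fine = np.arange(a + step / 2, b, step)
    interp = np.interp(fine, positions, values)
    return interp.sum() * step


def mixed_anova_ss(y):
    """Sums of squares and F statistics of a balanced two-way mixed design.

    ``y`` has shape (2 groups, n subjects, k segments). Classical cell-mean
    decomposition: between factor tested against subjects-within-groups,
    within factor and interaction against the segment×subject residual.
    """
    y = np.asarray(y, dtype=float)
    g, n, k = y.shape
    assert g == 2
    gm = y.mean()
    group_means = y.mean(axis=(1, 2))
    subj_means = y.mean(axis=2)
    seg_means = y.mean(axis=(0, 1))
    cell_means = y.mean(axis=1)

    ss_group = n * k * np.sum((group_means - gm) ** 2)
    ss_subj = k * np.sum((subj_means - group_means[:, None]) ** 2)
    ss_seg = g * n * np.sum((seg_means - gm) ** 2)
    ss_inter = n * np.sum((cell_means - group_means[:, None] - seg_means[None, :] + gm) ** 2)
    resid = y - cell_means[:, None, :] - subj_means[:, :, None] + group_means[:, None, None]
    ss_err = np.sum(resid**2)

    df_group, df_subj = g - 1, g * (n - 1)
    df_seg, df_inter, df_err = k - 1, (g - 1) * (k - 1), g * (n - 1) * (k - 1)
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_seg = (ss_seg / df_seg) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return {
        "ss": {"group": ss_group, "segment": ss_seg, "interaction": ss_inter},
        "f": {"group": f_group, "segment": f_seg, "interaction": f_inter},
    }
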