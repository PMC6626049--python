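"""Lesion-aligned intersection profiles: alignment, normalization, smoothing.

The central quantity of the pipeline is the number of fiber intersections per
1 µm axial position on the closed integer grid −1000..2000 µm, with 0 at the
lesion plane and proximal→distal as increasing position. To pool nerves with
different numbers of labelled fibers, each profile is normalized to the mean
count over its pre-lesion baseline segment [−1000, −500] (501 samples,
endpoints included). Smoothing (50 µm centred moving average) is a display
aid only; statistics run on the unsmoothed normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingDataError, NormalizationError, ParameterError
from .io import DEFAULT_BASELINE_UM, DEFAULT_WINDOW_UM, make_grid


@dataclass(frozen=True)
class IntersectionProfile:
    """Counts (or NaN where unacquired) on a strictly increasing 1 µm grid."""

    positions_um: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions_um, dtype=np.int64)
        cnt = np.asarray(self.counts, dtype=float)
        if pos.shape != cnt.shape:
            raise ParameterError("positions_um and counts must have equal length")
        if pos.size > 1 and not np.all(np.diff(pos) == 1):
            raise ParameterError("position grid must be strictly increasing with step 1 µm")
        finite = np.isfinite(cnt)
        if finite.any() and float(cnt[finite].min()) < 0:
            raise ParameterError("counts must be ≥ 0 where present")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "counts", cnt)

    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.counts)))


@dataclass(frozen=True)
class NormalizedProfile:
    """Counts divided by the pre-lesion baseline mean (recorded as
    ``baseline_mean``); the mean of values over the baseline segment is 1."""

    positions_um: np.ndarray
    values: np.ndarray
    baseline_mean: float
    baseline_um: tuple[int, int] = DEFAULT_BASELINE_UM

    def __post_init__(self):
        pos = np.asarray(self.positions_um, dtype=np.int64)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape:
            raise ParameterError("positions_um and values must have equal length")
        if self.baseline_mean <= 0:
            raise NormalizationError(f"baseline_mean must be > 0, got {self.baseline_mean}")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "values", val)


def align_to_lesion(
    raw_positions_um,
    counts,
    lesion_position_um: float,
    window_um: tuple[int, int] = DEFAULT_WINDOW_UM,
) -> IntersectionProfile:
    """Re-express stack-axis positions relative to the lesion plane.

    The lesion maps to position 0; the grid is cropped/padded to the closed
    window, padding with *missing* (NaN), never zero. Raises
    :class:`MissingDataError` when the window and the acquired positions do
    not overlap at all.
    """
    raw_positions_um = np.asarray(raw_positions_um, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if raw_positions_um.shape != counts.shape:
        raise ParameterError("raw positions and counts must have equal length")
    grid = make_grid(window_um)
    out = np.full(grid.size, np.nan)
    rel = np.rint(raw_positions_um - lesion_position_um).astype(np.int64)
    inside = (rel >= grid[0]) & (rel <= grid[-1])
    if not inside.any():
        raise MissingDataError(
            f"analysis window {window_um} lies entirely outside the acquired positions"
        )
    out[rel[inside] - grid[0]] = counts[inside]
    return IntersectionProfile(grid, out)


def normalize_profile(
    profile: IntersectionProfile,
    baseline_um: tuple[int, int] = DEFAULT_BASELINE_UM,
    min_baseline_points: int = 100,
) -> NormalizedProfile:
    """Divide counts by the mean over the closed baseline segment.

    Requires at least ``min_baseline_points`` acquired baseline positions and
    a strictly positive baseline mean; otherwise the nerve cannot be
    normalized and must be excluded upstream (:class:`NormalizationError`).
    """
    lo, hi = int(baseline_um[0]), int(baseline_um[1])
    pos = profile.positions_um
    sel = (pos >= lo) & (pos <= hi)
    if not sel.any():
        raise NormalizationError(f"baseline segment {baseline_um} not on the profile grid")
    base = profile.counts[sel]
    finite = np.isfinite(base)
    if int(finite.sum()) < min_baseline_points:
        raise NormalizationError(
            f"only {int(finite.sum())} acquired baseline positions "
            f"(need ≥ {min_baseline_points})"
        )
    mean = float(base[finite].mean())
    if mean <= 0:
        raise NormalizationError("baseline mean is zero; sample must be excluded")
    return NormalizedProfile(pos, profile.counts / mean, mean, (lo, hi))


def smooth_profile(
    values,
    window_um: int = 50,
    boundary: str = "truncate",
    mode: str = "sliding",
) -> np.ndarray:
    """Centred moving average over a symmetric window on the 1 µm grid.

    A ``window_um`` of 50 gives a 51-sample window (±25 µm). Missing values
    are excluded from each local average; at the profile edges the average
    runs over the available samples (``boundary='truncate'``) or wraps
    (``boundary='periodic'``, which preserves the mean of a fully observed
    profile exactly). ``mode='binned'`` instead averages over disjoint
    ``window_um``-wide bins, assigning each position its bin mean.
    """
    values = np.asarray(values, dtype=float)
    if window_um < 1:
        raise ParameterError(f"window_um must be ≥ 1, got {window_um}")
    finite = np.isfinite(values)
    if not finite.any():
        raise MissingDataError("cannot smooth an all-missing profile")
    filled = np.where(finite, values, 0.0)

    if mode == "binned":
        width = int(window_um)
        out = np.empty_like(values)
        for start in range(0, values.size, width):
            seg = slice(start, min(start + width, values.size))
            n = int(finite[seg].sum())
            out[seg] = filled[seg].sum() / n if n else np.nan
        return out
    if mode != "sliding":
        raise ParameterError(f"unknown smoothing mode {mode!r}")

    half = int(window_um) // 2
    width = 2 * half + 1
    kernel = np.ones(width)
    if boundary == "truncate":
        sums = np.convolve(filled, kernel, mode="same")
        ns = np.convolve(finite.astype(float), kernel, mode="same")
    elif boundary == "periodic":
        sums = np.zeros_like(filled)
        ns = np.zeros_like(filled)
        for off in range(-half, half + 1):
            sums += np.roll(filled, off)
            ns += np.roll(finite.astype(float), off)
    else:
        raise ParameterError(f"unknown boundary mode {boundary!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ns > 0, sums / ns, np.nan)
    return out
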