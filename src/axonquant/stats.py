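"""Per-sample segment AUCs and between-group statistics.

Each nerve is summarised by the trapezoidal area under its normalized
intersection curve over fixed axial segments (proximal [−1000, 0], distal
[0, 2000] and the two 1000 µm distal halves). Groups are compared per
segment with a two-tailed unpaired t-test (pooled variance by default,
Welch optional) and, across the three 1000 µm segments jointly, with a
two-way mixed ANOVA (between factor: treatment; within factor: segment)
followed by Bonferroni-adjusted per-segment comparisons. Significance is
called at p ≤ alpha (default 0.05). No sphericity correction is applied to
the within factor — a documented limitation with only three levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingDataError, ParameterError
from .io import DEFAULT_SEGMENTS_UM, read_profile_csv
from .profiles import IntersectionProfile, NormalizedProfile, normalize_profile

ANOVA_SEGMENTS = ("proximal", "distal_1", "distal_2")


def auc_segment(profile: NormalizedProfile, a: float, b: float) -> float:
    """Trapezoidal integral of the normalized values over positions a..b (µm).

    The segment endpoints must lie on the grid; missing values inside the
    segment raise :class:`MissingDataError` naming the positions.
    """
    if not a < b:
        raise ParameterError(f"segment must be ordered, got ({a}, {b})")
    pos = profile.positions_um
    if a < pos[0] or b > pos[-1]:
        raise ParameterError(f"segment ({a}, {b}) outside the profile grid [{pos[0]}, {pos[-1]}]")
    sel = (pos >= a) & (pos <= b)
    vals = profile.values[sel]
    missing = pos[sel][~np.isfinite(vals)]
    if missing.size:
        shown = ", ".join(str(int(m)) for m in missing[:10])
        more = "" if missing.size <= 10 else f" (+{missing.size - 10} more)"
        raise MissingDataError(f"missing values inside segment ({a}, {b}) at positions {shown}{more}")
    return float(np.trapezoid(vals, pos[sel]))


@dataclass(frozen=True)
class SampleAUC:
    """Segment AUCs for one nerve."""

    sample_id: str
    group: str
    aucs: dict

    def __getitem__(self, segment: str) -> float:
        return self.aucs[segment]


def compute_sample_aucs(
    profile: NormalizedProfile,
    sample_id: str,
    group: str,
    segments_um: dict = DEFAULT_SEGMENTS_UM,
) -> SampleAUC:
    return SampleAUC(
        sample_id, group, {name: auc_segment(profile, a, b) for name, (a, b) in segments_um.items()}
    )


def ttest_unpaired(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test: (t, df, p).

    Student's pooled-variance test by default (the conventional unpaired
    default of mainstream statistics packages), Welch on request. Zero
    variance with equal means returns (0, df, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError(f"each group needs n ≥ 2 (got {a.size} and {b.size})")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("groups must be finite")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            return 0.0, df if np.isfinite(df) else a.size + b.size - 2.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), df, 0.0
    return t, df, p


def bonferroni(p: float, k: int) -> float:
    """Bonferroni adjustment: min(1, k·p); never below the raw p."""
    return min(1.0, float(p) * int(k))


def mixed_anova_bonferroni(
    samples,
    segments: tuple[str, ...] = ANOVA_SEGMENTS,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way mixed ANOVA over ``segments`` plus Bonferroni post-hoc tests.

    ``samples`` is an iterable of :class:`SampleAUC` from exactly two groups;
    every sample must carry all requested segments. Returns ``(anova_table,
    posthoc_table)``: the ANOVA has rows for the between factor (treatment),
    the within factor (segment) and their interaction; the post-hoc table has
    one Bonferroni-adjusted between-group t-test per segment (multiplier =
    number of segments).
    """
    samples = list(samples)
    groups = sorted({s.group for s in samples})
    if len(groups) != 2:
        raise ParameterError(f"mixed ANOVA needs exactly two groups, found {groups}")
    rows = []
    for s in samples:
        for seg in segments:
            if seg not in s.aucs:
                raise MissingDataError(f"sample {s.sample_id!r} is missing segment {seg!r}")
            rows.append({"sample": s.sample_id, "group": s.group, "segment": seg, "auc": s.aucs[seg]})
    long = pd.DataFrame(rows)

    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.mixed_anova(
            data=long, dv="auc", within="segment", subject="sample", between="group",
            correction=False,
        )
    anova = table.rename(columns={"Source": "source", "p-unc": "p", "p_unc": "p"})[
        ["source", "SS", "DF1", "DF2", "F", "p"]
    ]

    k = len(segments)
    post = []
    ga, gb = groups
    for seg in segments:
        a = long.query("group == @ga and segment == @seg")["auc"].to_numpy()
        b = long.query("group == @gb and segment == @seg")["auc"].to_numpy()
        t, df, p = ttest_unpaired(a, b, welch=welch)
        post.append(
            {
                "segment": seg,
                "group_a": ga,
                "group_b": gb,
                "t": t,
                "df": df,
                "p_raw": p,
                "p_bonferroni": bonferroni(p, k),
            }
        )
    return anova, pd.DataFrame(post)


@dataclass(frozen=True)
class GroupComparison:
    """Full statistical read-out of a two-group study."""

    table: pd.DataFrame          # per-segment means, SD, n, t, df, p, significance
    anova: pd.DataFrame          # mixed ANOVA over the three 1000 µm segments
    posthoc: pd.DataFrame        # Bonferroni-adjusted per-segment comparisons
    samples: tuple[SampleAUC, ...]
    alpha: float = 0.05


def compare_groups(
    samples,
    segments_um: dict = DEFAULT_SEGMENTS_UM,
    anova_segments: tuple[str, ...] = ANOVA_SEGMENTS,
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Segment-wise group comparison from per-sample AUCs."""
    samples = tuple(samples)
    groups = sorted({s.group for s in samples})
    if len(groups) != 2:
        raise ParameterError(f"need exactly two groups, found {groups}")
    ga, gb = groups
    n_by = {g: sum(1 for s in samples if s.group == g) for g in groups}
    for g, n in n_by.items():
        if n < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 valid samples (n={n})")

    anova, posthoc = mixed_anova_bonferroni(samples, anova_segments, welch=welch)
    padj = dict(zip(posthoc["segment"], posthoc["p_bonferroni"]))

    rows = []
    for seg in segments_um:
        a = np.array([s[seg] for s in samples if s.group == ga])
        b = np.array([s[seg] for s in samples if s.group == gb])
        t, df, p = ttest_unpaired(a, b, welch=welch)
        p_b = padj.get(seg, np.nan)
        rows.append(
            {
                "segment": seg,
                f"mean_{ga}": a.mean(),
                f"sd_{ga}": a.std(ddof=1),
                f"n_{ga}": a.size,
                f"mean_{gb}": b.mean(),
                f"sd_{gb}": b.std(ddof=1),
                f"n_{gb}": b.size,
                "t": t,
                "df": df,
                "p_raw": p,
                "p_bonferroni": p_b,
                "significant": bool(p <= alpha),
            }
        )
    return GroupComparison(pd.DataFrame(rows), anova, posthoc, samples, alpha)


def run_group_study(
    group_dirs: dict,
    segments_um: dict = DEFAULT_SEGMENTS_UM,
    baseline_um=( -1000, -500),
    alpha: float = 0.05,
    welch: bool = False,
    out_csv=None,
):
    """End-to-end comparison of two directories of raw count profile CSVs.

    Each CSV holds one nerve's lesion-aligned raw counts (columns
    ``position_um`` and one value column). Samples whose baseline cannot be
    normalized are excluded (reported in the returned ``exclusions``); each
    group needs ≥ 2 valid samples. Writes the statistics table to ``out_csv``
    when given. Returns ``(GroupComparison, exclusions)``.
    """
    from .errors import NormalizationError

    sample_aucs = []
    exclusions = []
    for group, directory in group_dirs.items():
        directory = Path(directory)
        if not directory.is_dir():
            raise FileNotFoundError(f"profile directory for group {group!r} not found: {directory}")
        for path in sorted(directory.glob("*.csv")):
            positions, counts, _ = read_profile_csv(path)
            profile = IntersectionProfile(positions, counts)
            try:
                norm = normalize_profile(profile, baseline_um)
            except NormalizationError as exc:
                exclusions.append((group, path.name, str(exc)))
                continue
            sample_aucs.append(compute_sample_aucs(norm, path.stem, group, segments_um))
    for group in group_dirs:
        n = sum(1 for s in sample_aucs if s.group == group)
        if n < 2:
            raise ParameterError(
                f"group {group!r} has fewer than 2 valid samples after exclusions (n={n})"
            )
    comparison = compare_groups(sample_aucs, segments_um, alpha=alpha, welch=welch)
    if out_csv is not None:
        comparison.table.to_csv(out_csv, index=False)
    return comparison, exclusions
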