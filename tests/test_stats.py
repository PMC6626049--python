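"""Segment AUCs, t-tests, mixed ANOVA with Bonferroni post-hoc."""

import numpy as np
import pytest

import axonquant as aq
from axonquant.errors import MissingDataError, ParameterError
from axonquant.io import make_grid
from axonquant.profiles import NormalizedProfile
from axonquant.stats import (
    SampleAUC,
    auc_segment,
    bonferroni,
    compare_groups,
    compute_sample_aucs,
    mixed_anova_bonferroni,
    run_group_study,
    ttest_unpaired,
)
from oracles import mixed_anova_ss, refined_riemann_auc


def _profile(values):
    return NormalizedProfile(make_grid(), np.asarray(values, dtype=float), baseline_mean=10.0)


def test_constant_unit_profile_auc_is_segment_length():
    prof = _profile(np.ones(3001))
    assert auc_segment(prof, 0, 2000) == pytest.approx(2000.0)


def test_linear_ramp_auc_is_triangle_area():
    values = np.zeros(3001)
    sel = (make_grid() >= 0) & (make_grid() <= 1000)
    values[sel] = np.linspace(0.0, 1.0, 1001)
    assert auc_segment(_profile(values), 0, 1000) == pytest.approx(500.0)


def test_auc_matches_refined_riemann_sum(rng):
    values = rng.random(3001) * 5
    prof = _profile(values)
    trapz = auc_segment(prof, -500, 1500)
    ref = refined_riemann_auc(make_grid(), values, -500, 1500, refine=10)
    assert trapz == pytest.approx(ref, rel=1e-6)


def test_auc_additive_over_adjacent_segments(rng):
    prof = _profile(rng.random(3001))
    total = auc_segment(prof, 0, 2000)
    assert auc_segment(prof, 0, 1000) + auc_segment(prof, 1000, 2000) == pytest.approx(total, abs=1e-12)


def test_auc_refuses_missing_positions():
    values = np.ones(3001)
    values[1500] = np.nan  # position +500
    with pytest.raises(MissingDataError, match="500"):
        auc_segment(_profile(values), 0, 1000)


def test_auc_segment_bounds_checked():
    with pytest.raises(ParameterError):
        auc_segment(_profile(np.ones(3001)), 1000, 0)
    with pytest.raises(ParameterError):
        auc_segment(_profile(np.ones(3001)), 0, 5000)


def test_identical_groups_t_zero_p_one():
    t, df, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0 and df == 4


def test_zero_variance_equal_means_convention():
    t, df, p = ttest_unpaired([2.0, 2.0], [2.0, 2.0])
    assert t == 0.0 and p == 1.0


def test_swapping_groups_negates_t_keeps_p():
    a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0, 7.0]
    t1, _, p1 = ttest_unpaired(a, b)
    t2, _, p2 = ttest_unpaired(b, a)
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


def test_pooled_t_matches_closed_form():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 4.0, 6.0])
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    t, df, _ = ttest_unpaired(a, b)
    assert t == pytest.approx(t_ref) and df == a.size + b.size - 2


def test_t_invariant_under_common_affine_rescale(rng):
    a, b = rng.random(8), rng.random(6) + 0.3
    t1, _, p1 = ttest_unpaired(a, b)
    t2, _, p2 = ttest_unpaired(3.5 * a + 2.0, 3.5 * b + 2.0)
    assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)


def test_small_groups_rejected():
    with pytest.raises(ParameterError):
        ttest_unpaired([1.0], [1.0, 2.0])


def test_bonferroni_monotone_and_capped():
    assert bonferroni(0.01, 3) == pytest.approx(0.03)
    assert bonferroni(0.5, 3) == 1.0
    assert bonferroni(0.2, 3) >= 0.2


def _samples_from_array(y, groups=("ctrl", "ntf"), segments=("proximal", "distal_1", "distal_2")):
    out = []
    for gi, g in enumerate(groups):
        for j in range(y.shape[1]):
            out.append(SampleAUC(f"{g}{j}", g, dict(zip(segments, y[gi, j]))))
    return out


def test_identical_groups_give_null_anova_and_posthoc(rng):
    block = rng.random((1, 4, 3)) * 10
    y = np.concatenate([block, block])
    anova, post = mixed_anova_bonferroni(_samples_from_array(y))
    p_group = float(anova.loc[anova["source"] == "group", "p"].iloc[0])
    assert p_group > 0.99 or np.isnan(p_group)
    assert np.all(post["t"] == 0) and np.all(post["p_raw"] == 1.0)


def test_posthoc_adjustment_is_three_times_raw():
    rng = np.random.default_rng(5)
    y = rng.random((2, 5, 3)) * 4
    y[1] += 0.8
    _, post = mixed_anova_bonferroni(_samples_from_array(y))
    for _, row in post.iterrows():
        assert row["p_bonferroni"] == pytest.approx(min(1.0, 3 * row["p_raw"]))
        assert row["p_bonferroni"] >= row["p_raw"]


def test_mixed_anova_matches_bruteforce_decomposition():
    rng = np.random.default_rng(11)
    y = rng.integers(1, 20, size=(2, 4, 3)).astype(float)
    anova, _ = mixed_anova_bonferroni(_samples_from_array(y))
    ref = mixed_anova_ss(y)
    by_source = {s.lower(): (ss, f) for s, ss, f in zip(anova["source"], anova["SS"], anova["F"])}
    assert by_source["group"][0] == pytest.approx(ref["ss"]["group"])
    assert by_source["group"][1] == pytest.approx(ref["f"]["group"])
    assert by_source["segment"][0] == pytest.approx(ref["ss"]["segment"])
    assert by_source["segment"][1] == pytest.approx(ref["f"]["segment"])
    assert by_source["interaction"][0] == pytest.approx(ref["ss"]["interaction"])
    assert by_source["interaction"][1] == pytest.approx(ref["f"]["interaction"])


def test_sample_missing_a_segment_rejected():
    samples = [
        SampleAUC("a0", "a", {"proximal": 1.0, "distal_1": 2.0, "distal_2": 3.0}),
        SampleAUC("a1", "a", {"proximal": 1.0, "distal_1": 2.0, "distal_2": 3.0}),
        SampleAUC("b0", "b", {"proximal": 1.0, "distal_1": 2.0}),
        SampleAUC("b1", "b", {"proximal": 1.0, "distal_1": 2.0, "distal_2": 3.0}),
    ]
    with pytest.raises(MissingDataError, match="distal_2"):
        mixed_anova_bonferroni(samples)


def test_compare_identical_groups_flags_nothing(rng):
    block = rng.random((1, 5, 3)) * 10
    y = np.concatenate([block, block])
    samples = _samples_from_array(y)
    comp = compare_groups(
        samples,
        segments_um={"proximal": (-1000, 0), "distal_1": (0, 1000), "distal_2": (1000, 2000)},
    )
    assert not comp.table["significant"].any()


def test_compute_sample_aucs_distal_sum(rng):
    prof = _profile(rng.random(3001) + 0.5)
    s = compute_sample_aucs(prof, "s1", "ctrl")
    assert s["distal"] == pytest.approx(s["distal_1"] + s["distal_2"])


def test_run_group_study_end_to_end(tmp_path, rng):
    grid = make_grid()
    for group, boost in (("ctrl", 0.0), ("ntf", 8.0)):
        d = tmp_path / group
        d.mkdir()
        for i in range(4):
            counts = rng.integers(15, 25, size=3001).astype(float)
            counts[grid > 0] += boost
            aq.write_profile_csv(grid, counts, d / f"{group}_{i}.csv", "count")
    comp, exclusions = run_group_study({"ctrl": tmp_path / "ctrl", "ntf": tmp_path / "ntf"},
                                       out_csv=tmp_path / "stats.csv")
    assert not exclusions
    assert (tmp_path / "stats.csv").exists()
    row = comp.table.set_index("segment").loc["distal"]
    assert row["p_raw"] < 0.05 and row["significant"]


def test_run_group_study_excludes_zero_baseline_samples(tmp_path, rng):
    grid = make_grid()
    for group in ("a", "b"):
        d = tmp_path / group
        d.mkdir()
        for i in range(3):
            counts = rng.integers(10, 20, size=3001).astype(float)
            aq.write_profile_csv(grid, counts, d / f"{group}_{i}.csv", "count")
    dead = np.zeros(3001)
    aq.write_profile_csv(grid, dead, tmp_path / "a" / "a_dead.csv", "count")
    comp, exclusions = run_group_study({"a": tmp_path / "a", "b": tmp_path / "b"})
    assert len(exclusions) == 1 and exclusions[0][0] == "a"


def test_run_group_study_missing_directory(tmp_path):
    with pytest.raises(FileNotFoundError):
        run_group_study({"a": tmp_path / "nope", "b": tmp_path / "alsono"})
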