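"""Method I (global averaging + t-test) and Method II (depth-covariate OLS)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from redoxscan.groupstats import (
    comparisons_to_frame,
    method_one,
    method_two,
    run_full_comparison,
)


def summary_frame(rows):
    """Minimal per-section summary table for statistics tests."""
    return pd.DataFrame(rows)


def make_rows(values_by_animal, group, statistic="fp_ratio_mean", depths=None):
    rows = []
    for animal, values in values_by_animal.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "group": group,
                    "animal_id": animal,
                    "depth_um": depths[animal][i] if depths else 200.0 + 100.0 * i,
                    statistic: v,
                }
            )
    return rows


def test_symmetric_animal_values_give_zero_effect_p_one():
    data = summary_frame(
        make_rows({"c1": [1.0], "c2": [2.0], "c3": [3.0]}, "control")
        + make_rows({"p1": [1.0], "p2": [2.0], "p3": [3.0]}, "pten_null")
    )
    result = method_one(data, "fp_ratio_mean")
    assert result.effect == pytest.approx(0.0)
    assert result.p_value == pytest.approx(1.0)
    assert result.n_units == 6


def test_zero_within_group_variance_is_flagged():
    data = summary_frame(
        make_rows({"c1": [0.0], "c2": [0.0], "c3": [0.0]}, "control")
        + make_rows({"p1": [1.0], "p2": [1.0], "p3": [1.0]}, "pten_null")
    )
    result = method_one(data, "fp_ratio_mean")
    assert "degenerate_variance" in result.flags
    assert result.p_value == 0.0
    assert result.effect == pytest.approx(1.0)


def test_method_one_needs_two_animals_per_group():
    data = summary_frame(
        make_rows({"c1": [1.0, 2.0]}, "control")
        + make_rows({"p1": [1.0], "p2": [2.0]}, "pten_null")
    )
    with pytest.raises(ValueError, match=">= 2"):
        method_one(data, "fp_ratio_mean")


def test_method_one_matches_manual_welch():
    vals_c = {"c1": [0.30], "c2": [0.34], "c3": [0.38]}
    vals_p = {"p1": [0.42], "p2": [0.36], "p3": [0.47]}
    data = summary_frame(make_rows(vals_c, "control") + make_rows(vals_p, "pten_null"))
    result = method_one(data, "fp_ratio_mean")
    ref = stats.ttest_ind([0.42, 0.36, 0.47], [0.30, 0.34, 0.38], equal_var=False)
    assert result.p_value == pytest.approx(ref.pvalue)
    assert result.effect == pytest.approx(np.mean([0.42, 0.36, 0.47]) - np.mean([0.30, 0.34, 0.38]))


def test_method_two_exact_recovery_on_noise_free_linear_data():
    rows = []
    for g, indicator in (("control", 0.0), ("pten_null", 1.0)):
        for i in range(6):
            depth = 200.0 + 150.0 * i
            rows.append(
                {
                    "group": g,
                    "animal_id": f"{g}_{i % 3}",
                    "depth_um": depth,
                    "fp_ratio_mean": 0.3 + 0.05 * indicator + 2e-5 * depth,
                }
            )
    result = method_two(summary_frame(rows), "fp_ratio_mean")
    assert result.effect == pytest.approx(0.05, abs=1e-12)
    assert result.depth_coefficient == pytest.approx(2e-5, abs=1e-15)


def test_balanced_design_group_estimates_match_method_one():
    """With equal sections per animal, the pooled section mean equals the
    mean of per-animal means, so both methods report the same group means."""
    rng = np.random.default_rng(0)
    rows = []
    for g in ("control", "pten_null"):
        for a in range(3):
            for i in range(3):
                rows.append(
                    {
                        "group": g,
                        "animal_id": f"{g}_{a}",
                        "depth_um": 200.0 + 100.0 * i,
                        "fp_ratio_mean": rng.normal(0.3 if g == "control" else 0.36, 0.02),
                    }
                )
    data = summary_frame(rows)
    m1 = method_one(data, "fp_ratio_mean")
    m2 = method_two(data, "fp_ratio_mean")
    for g in ("control", "pten_null"):
        assert m1.group_estimates[g][0] == pytest.approx(m2.group_estimates[g][0], rel=1e-12)


def test_collinear_depth_is_flagged_but_computed():
    rows = (
        make_rows({"c1": [0.3], "c2": [0.31], "c3": [0.32]}, "control",
                  depths={"c1": [200.0], "c2": [200.0], "c3": [200.0]})
        + make_rows({"p1": [0.35], "p2": [0.36], "p3": [0.37]}, "pten_null",
                    depths={"p1": [800.0], "p2": [800.0], "p3": [800.0]})
    )
    result = method_two(summary_frame(rows), "fp_ratio_mean")
    assert "depth_group_collinear" in result.flags
    assert np.isfinite(result.p_value)


def test_pseudo_replication_behavior_differs_between_methods():
    """Duplicating one section inside an animal enters Method I only through
    that animal's mean but shifts Method II, which counts sections."""
    base = (
        make_rows({"c1": [0.30, 0.32], "c2": [0.31, 0.33], "c3": [0.30, 0.34]}, "control")
        + make_rows({"p1": [0.35, 0.40], "p2": [0.37, 0.41], "p3": [0.36, 0.42]}, "pten_null")
    )
    data = summary_frame(base)
    dup_row = dict(base[0])
    dup_row["depth_um"] += 50.0  # same value resampled at a nearby depth
    duplicated = summary_frame(base + [dup_row])

    m1_base = method_one(data, "fp_ratio_mean")
    m1_dup = method_one(duplicated, "fp_ratio_mean")
    # animal c1's mean moves from 0.31 to mean(0.30, 0.32, 0.30)
    assert m1_dup.group_estimates["control"][0] != pytest.approx(
        m1_base.group_estimates["control"][0]
    )
    assert m1_dup.n_units == m1_base.n_units  # still 6 animals

    m2_base = method_two(data, "fp_ratio_mean")
    m2_dup = method_two(duplicated, "fp_ratio_mean")
    assert m2_dup.n_units == m2_base.n_units + 1  # sections are the unit


def test_null_p_values_are_uniform_for_both_methods():
    """200 null replicates: Kolmogorov-Smirnov cannot reject uniformity at 1%."""
    rng = np.random.default_rng(2024)
    p1, p2 = [], []
    for _ in range(200):
        rows = []
        for g, animals, n_sections in (("control", 3, [3, 3, 3]), ("pten_null", 3, [5, 5, 4])):
            for a in range(animals):
                depth = rng.uniform(200, 600)
                for _ in range(n_sections[a]):
                    rows.append(
                        {
                            "group": g,
                            "animal_id": f"{g}_{a}",
                            "depth_um": depth,
                            "fp_ratio_mean": rng.normal(0.33, 0.03),
                        }
                    )
                    depth += rng.uniform(100, 400)
        data = summary_frame(rows)
        p1.append(method_one(data, "fp_ratio_mean").p_value)
        p2.append(method_two(data, "fp_ratio_mean").p_value)
    assert stats.kstest(p1, "uniform").pvalue > 0.01
    assert stats.kstest(p2, "uniform").pvalue > 0.01


def test_full_comparison_row_count_and_shape(analyzed_study):
    summaries, fits, _ = analyzed_study
    comparisons = run_full_comparison(summaries, fits)
    assert len(comparisons) == 34  # 2 methods x (10 summary + 7 fit statistics)
    frame = comparisons_to_frame(comparisons)
    assert set(frame["method"]) == {"I", "II"}
    assert frame["p_value"].between(0, 1).all()
    assert {"control_mean", "pten_null_mean", "effect"} <= set(frame.columns)


def test_default_study_heterogeneity_contrast(analyzed_study):
    """The default phantom reproduces the headline contrast: SD(fp_ratio)
    separates the groups by both methods."""
    summaries, _, _ = analyzed_study
    m1 = method_one(summaries, "fp_ratio_sd")
    m2 = method_two(summaries, "fp_ratio_sd")
    assert m1.effect > 0 and m2.effect > 0
    assert m1.p_value < 0.05
    assert m2.p_value < 0.05
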