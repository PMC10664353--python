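"""Frequencies, CVs, t-test, spectra and fold changes — including the
published rat liver summary table the counts mode must reproduce."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peccseq import (
    TrinucleotideSpectrum,
    class_summary,
    coefficient_of_variation,
    correlation_r2,
    fold_change,
    fold_changes,
    group_mean_frequency,
    mutation_frequency,
    one_sided_t_test,
    summarize_counts,
)
from peccseq.consensus import CandidateMutation
from peccseq.datasets import rat_liver_den_study


def _mut(pos, ref, alt, context, contig="chr1", group_id=0):
    return CandidateMutation(
        contig=contig, pos=pos, ref=ref, alt=alt, context=context, group_id=group_id
    )


# ---------------------------------------------------------------------------
# frequencies


def test_published_per_sample_frequencies():
    # the study's per-sample (mutations, analysed bases) pairs reproduce
    # its printed frequencies after 2-decimal rounding (x 1e-6 scale)
    table = rat_liver_den_study()
    printed = [0.51, 0.93, 1.57, 7.34, 6.14, 6.21]
    for (_, row), expected in zip(table.iterrows(), printed):
        freq = mutation_frequency(row["mutations"], row["analyzed_bases"])
        assert round(freq * 1e6, 2) == expected


def test_frequency_edge_cases():
    assert mutation_frequency(0, 10**6) == 0.0
    assert mutation_frequency(20, 38_838_583) == pytest.approx(5.1495e-7, rel=1e-4)
    with pytest.raises(ValueError):
        mutation_frequency(1, 0)


def test_group_mean_modes():
    freqs = [2e-6, 4e-6]
    assert group_mean_frequency(freqs) == pytest.approx(3e-6)
    pooled = group_mean_frequency(
        freqs, "pooled", mutations=[2, 40], analyzed_bases=[10**6, 10**7]
    )
    assert pooled == pytest.approx(42 / 11e6)
    # identical samples: the two modes coincide
    same = group_mean_frequency([1e-6] * 3)
    same_pooled = group_mean_frequency(
        [1e-6] * 3, "pooled", mutations=[1, 1, 1], analyzed_bases=[10**6] * 3
    )
    assert same == pytest.approx(same_pooled)
    with pytest.raises(ValueError):
        group_mean_frequency([])


def test_published_group_means():
    table = rat_liver_den_study()
    for group, mean_printed in [("control", 1.00), ("treated", 6.56)]:
        sub = table[table["group"] == group]
        freqs = (sub["mutations"] / sub["analyzed_bases"]).to_list()
        mean = group_mean_frequency(freqs)
        assert abs(mean * 1e6 - mean_printed) <= 0.01  # printed precision
        pooled = group_mean_frequency(
            freqs, "pooled",
            mutations=sub["mutations"].to_list(),
            analyzed_bases=sub["analyzed_bases"].to_list(),
        )
        assert abs(pooled * 1e6 - mean_printed) <= 0.04  # pooled DEN mean is 6.59


# ---------------------------------------------------------------------------
# CV


def test_published_cvs():
    table = rat_liver_den_study()
    ctrl = table[table["group"] == "control"]
    trt = table[table["group"] == "treated"]
    assert round(coefficient_of_variation(ctrl["mutations"] / ctrl["analyzed_bases"]), 2) == 0.53
    assert round(coefficient_of_variation(trt["mutations"] / trt["analyzed_bases"]), 2) == 0.10
    assert round(coefficient_of_variation(ctrl["external_mf"]), 2) == 0.60
    assert round(coefficient_of_variation(trt["external_mf"]), 2) == 0.45


def test_cv_of_constant_is_zero():
    assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=8),
    k=st.floats(0.01, 50.0),
)
def test_cv_scale_invariance(values, k):
    arr = np.asarray(values)
    if arr.mean() == 0:
        return
    assert coefficient_of_variation(k * arr) == pytest.approx(
        coefficient_of_variation(arr), rel=1e-9, abs=1e-12
    )


# ---------------------------------------------------------------------------
# t-test and correlation


def test_published_group_comparison():
    table = rat_liver_den_study()
    freqs = table["mutations"] / table["analyzed_bases"]
    res = one_sided_t_test(
        freqs[table["group"] == "treated"], freqs[table["group"] == "control"]
    )
    assert res.df == 4
    assert res.statistic == pytest.approx(11.19, abs=0.05)
    assert res.pvalue < 0.05


def test_identical_groups_give_p_half():
    res = one_sided_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(0.5)


def test_r2_perfect_and_null():
    x = np.arange(10, dtype=float)
    assert correlation_r2(x, 3 * x + 2) == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    a, b = rng.random(3000), rng.random(3000)
    assert correlation_r2(a, b) < 0.01
    with pytest.raises(ValueError):
        correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# spectra


def test_spectrum_counts_and_normalization():
    muts = [
        _mut(10, "A", "T", "CAG"),   # -> C[T>A]G
        _mut(20, "C", "T", "ACG"),   # -> A[C>T]G
        _mut(30, "T", "A", "CTG"),   # -> C[T>A]G again
        _mut(40, "G", "A", "CGT"),   # -> A[C>T]G on the pyrimidine strand
    ]
    spec = TrinucleotideSpectrum.from_mutations(muts, analyzed_bases=10**6)
    assert spec.total == 4
    frame = spec.to_frame()
    assert frame.loc[frame["context"] == "C[T>A]G", "count"].item() == 2
    assert frame.loc[frame["context"] == "A[C>T]G", "count"].item() == 2
    # frequencies sum exactly to the overall mutation frequency
    assert spec.frequencies.sum() == pytest.approx(
        mutation_frequency(4, 10**6), rel=0, abs=0
    )
    assert spec.class_counts() == {
        "C>A": 0, "C>G": 0, "C>T": 2, "T>A": 2, "T>C": 0, "T>G": 0,
    }


def test_edge_context_mutations_skipped_with_diagnostic():
    muts = [_mut(0, "A", "T", None)]
    spec = TrinucleotideSpectrum.from_mutations(muts, analyzed_bases=100)
    assert spec.total == 0
    assert spec.n_skipped_no_context == 1


def test_empty_spectrum_is_zero():
    spec = TrinucleotideSpectrum.from_mutations([], analyzed_bases=100)
    assert spec.total == 0
    assert not spec.normalized().any()


# ---------------------------------------------------------------------------
# fold changes


def test_published_at_ta_fold_change():
    # group-average A:T>T:A class frequencies: 1.87e-6 treated vs 4.36e-8
    # control -> ~43-fold
    assert fold_change(1.87e-6, 4.36e-8) == pytest.approx(42.9, abs=0.1)
    assert np.isnan(fold_change(1.0, 0.0))


def test_identical_groups_fold_change_one():
    spec = TrinucleotideSpectrum.from_mutations(
        [_mut(10, "T", "A", "CTG")], analyzed_bases=1000, sample="s"
    )
    table = class_summary([spec])
    fc = fold_changes(table, table)
    assert fc.loc[fc["class"] == "T>A", "fold_change"].item() == pytest.approx(1.0)
    assert fc.loc[fc["class"] == "C>A", "fold_change"].isna().item()


def test_fold_change_modes_differ_by_bases_ratio():
    """With one sample per group, frequency ratio = count ratio x
    (control bases / treated bases) — an algebraic identity."""
    t = TrinucleotideSpectrum.from_mutations(
        [_mut(10, "T", "A", "CTG")] * 1, analyzed_bases=2000, sample="t"
    )
    t.counts[t.counts > 0] = 6
    c = TrinucleotideSpectrum.from_mutations(
        [_mut(10, "T", "A", "CTG")], analyzed_bases=500, sample="c"
    )
    c.counts[c.counts > 0] = 2
    ft = fold_changes(class_summary([t]), class_summary([c]), "frequency_ratio")
    fc = fold_changes(class_summary([t]), class_summary([c]), "count_ratio")
    ratio_t = ft.loc[ft["class"] == "T>A", "fold_change"].item()
    ratio_c = fc.loc[fc["class"] == "T>A", "fold_change"].item()
    assert ratio_t == pytest.approx(ratio_c * (500 / 2000))


# ---------------------------------------------------------------------------
# counts-mode summary


def test_summarize_counts_full_report():
    report = summarize_counts(rat_liver_den_study())
    ctrl = report["groups"]["control"]
    trt = report["groups"]["treated"]
    assert abs(ctrl["mean_of_samples"] * 1e6 - 1.00) <= 0.01
    assert round(trt["mean_of_samples"] * 1e6, 2) == 6.56
    assert round(ctrl["cv"], 2) == 0.53
    assert round(trt["cv"], 2) == 0.10
    assert report["t_test"]["pvalue"] < 0.05
    ext = report["external_assay"]
    assert round(ext["cv"]["control"], 2) == 0.60
    assert round(ext["cv"]["treated"], 2) == 0.45
    # the cross-assay R^2 recomputed from the summary values is ~0.84
    assert 0.7 < ext["r2_vs_frequency"] < 0.95


def test_summarize_counts_missing_columns():
    with pytest.raises(ValueError):
        summarize_counts(pd.DataFrame({"sample": ["a"], "group": ["g"]}))
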