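"""Mutation-frequency statistics, trinucleotide spectra, and group tests.

Frequencies are exact ratios of accepted mutations to analysed bases.
Spectra are SBS96 counts with per-category frequencies normalised by the
*total* analysed bases (not per-context opportunity), so the 96
frequencies sum exactly to the sample's overall mutation frequency;
opportunity-normalised output is available as a separately labelled column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import sbs96
from .consensus import CandidateMutation


def mutation_frequency(n_mutations: int, analyzed_bases: int) -> float:
    """Mutations per analysed base (exact ratio)."""
    if analyzed_bases <= 0:
        raise ValueError("analyzed_bases must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be nonnegative")
    return n_mutations / analyzed_bases


def group_mean_frequency(
    per_sample_freqs: "list[float] | np.ndarray",
    mode: str = "mean_of_samples",
    mutations: "list[int] | None" = None,
    analyzed_bases: "list[int] | None" = None,
) -> float:
    """Group-average mutation frequency.

    ``mean_of_samples`` (default) is the arithmetic mean of per-sample
    frequencies; ``pooled`` is total mutations over total analysed bases
    and requires the per-sample counts.  The two agree when samples have
    equal denominators and differ slightly otherwise; reports emit both.
    """
    freqs = np.asarray(per_sample_freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty group")
    if mode == "mean_of_samples":
        return float(freqs.mean())
    if mode == "pooled":
        if mutations is None or analyzed_bases is None:
            raise ValueError("pooled mode needs mutations and analyzed_bases")
        return float(np.sum(mutations) / np.sum(analyzed_bases))
    raise ValueError(f"unknown mode {mode!r}")


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    df: int


def one_sided_t_test(treated, control) -> TTestResult:
    """Two-sample equal-variance Student's t, alternative treated > control."""
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    res = sps.ttest_ind(a, b, equal_var=True, alternative="greater")
    df = a.size + b.size - 2
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance")
    return TTestResult(float(res.statistic), float(res.pvalue), df)


def correlation_r2(x, y) -> float:
    """Squared Pearson correlation of the simple least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r = sps.linregress(x, y).rvalue
    return float(r * r)


# ---------------------------------------------------------------------------
# spectra


@dataclass
class TrinucleotideSpectrum:
    """SBS96 counts for one sample plus its analysed-base denominator."""

    counts: np.ndarray  # (96,) int
    analyzed_bases: int
    sample: str = "sample"
    n_skipped_no_context: int = 0

    @classmethod
    def from_mutations(
        cls,
        mutations: list[CandidateMutation],
        analyzed_bases: int,
        sample: str = "sample",
    ) -> "TrinucleotideSpectrum":
        counts = np.zeros(96, dtype=np.int64)
        skipped = 0
        for m in mutations:
            key = m.context_key
            if key is None:  # contig-edge mutation without full context
                skipped += 1
                continue
            counts[sbs96.sbs96_index(key)] += 1
        return cls(counts, analyzed_bases, sample=sample, n_skipped_no_context=skipped)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.analyzed_bases <= 0:
            raise ValueError("analyzed_bases must be positive")
        return self.counts / self.analyzed_bases

    def normalized(self) -> np.ndarray:
        """Counts as a probability vector (all-zero stays all-zero)."""
        t = self.total
        return self.counts / t if t else self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample,
                "context": list(sbs96.SBS96_CONTEXTS),
                "class": [sbs96.key_class(k) for k in sbs96.SBS96_CONTEXTS],
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )

    def class_counts(self) -> dict[str, int]:
        out = {cls: 0 for cls in sbs96.SUB_TYPES}
        for key, n in zip(sbs96.SBS96_CONTEXTS, self.counts):
            out[sbs96.key_class(key)] += int(n)
        return out

    def class_frequencies(self) -> dict[str, float]:
        return {cls: n / self.analyzed_bases for cls, n in self.class_counts().items()}


def class_summary(spectra: list[TrinucleotideSpectrum]) -> pd.DataFrame:
    """Per-sample 6-class table in base-pair notation, one row per
    (sample, class), with counts and frequencies."""
    rows = []
    for spec in spectra:
        freqs = spec.class_frequencies()
        for cls, count in spec.class_counts().items():
            rows.append(
                {
                    "sample": spec.sample,
                    "class": cls,
                    "pair_notation": sbs96.CLASS_TO_PAIR_NOTATION[cls],
                    "count": count,
                    "frequency": freqs[cls],
                }
            )
    return pd.DataFrame(rows)


def fold_change(treated_value: float, control_value: float) -> float:
    """Scalar ratio; NaN when the control value is 0 (reported as NA)."""
    if control_value == 0:
        return float("nan")
    return treated_value / control_value


def fold_changes(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    mode: str = "frequency_ratio",
) -> pd.DataFrame:
    """Per-class fold changes between two groups of class summaries.

    Inputs are ``class_summary`` frames.  ``frequency_ratio`` (default)
    divides group-average per-sample class frequencies; ``count_ratio``
    divides summed class counts.  Zero control classes yield NaN.
    """
    if mode not in ("frequency_ratio", "count_ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    col = "frequency" if mode == "frequency_ratio" else "count"
    agg = "mean" if mode == "frequency_ratio" else "sum"
    t = treated.groupby("class")[col].agg(agg)
    c = control.groupby("class")[col].agg(agg)
    rows = []
    for cls in sbs96.SUB_TYPES:
        tv = float(t.get(cls, 0.0))
        cv = float(c.get(cls, 0.0))
        rows.append(
            {
                "class": cls,
                "pair_notation": sbs96.CLASS_TO_PAIR_NOTATION[cls],
                "treated": tv,
                "control": cv,
                "fold_change": fold_change(tv, cv),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts-mode summary (per-sample totals in, full report out)


@dataclass
class GroupStats:
    label: str
    samples: list[str]
    frequencies: list[float]
    mean_of_samples: float
    pooled: float | None
    cv: float | None


def summarize_counts(
    table: pd.DataFrame,
    control_label: str = "control",
    treated_label: str = "treated",
) -> dict:
    """Full frequency/comparison report from a per-sample counts table.

    ``table`` needs columns ``sample``, ``group``, ``mutations``,
    ``analyzed_bases``; an optional ``external_mf`` column (e.g. a
    transgene reporter assay's mutant frequencies) adds its group CVs and
    the cross-assay R^2.  Returns a plain dict ready for JSON export.
    """
    required = {"sample", "group", "mutations", "analyzed_bases"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    table = table.copy()
    table["frequency"] = table["mutations"] / table["analyzed_bases"]

    out: dict = {"samples": table.to_dict(orient="records"), "groups": {}}
    for label, sub in table.groupby("group", sort=False):
        freqs = sub["frequency"].to_list()
        stats = GroupStats(
            label=str(label),
            samples=sub["sample"].to_list(),
            frequencies=freqs,
            mean_of_samples=group_mean_frequency(freqs),
            pooled=group_mean_frequency(
                freqs, "pooled",
                mutations=sub["mutations"].to_list(),
                analyzed_bases=sub["analyzed_bases"].to_list(),
            ),
            cv=coefficient_of_variation(freqs) if len(freqs) >= 2 else None,
        )
        out["groups"][stats.label] = vars(stats)

    have = set(table["group"])
    if control_label in have and treated_label in have:
        ctrl = table[table["group"] == control_label]
        trt = table[table["group"] == treated_label]
        if len(ctrl) >= 2 and len(trt) >= 2:
            test = one_sided_t_test(trt["frequency"], ctrl["frequency"])
            out["t_test"] = vars(test)
    if "external_mf" in table.columns and table["external_mf"].notna().all():
        out["external_assay"] = {
            "cv": {
                str(label): coefficient_of_variation(sub["external_mf"])
                for label, sub in table.groupby("group", sort=False)
                if len(sub) >= 2
            },
            "r2_vs_frequency": correlation_r2(table["external_mf"], table["frequency"]),
        }
    return out
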