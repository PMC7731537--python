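"""Precursor-normalized enrichment statistics and the CD138+/CD138- contrast.

The in vivo tracing design does not require isotopic steady state inside
the sorted cells: each metabolite's mole percent enrichment (MPE) is
divided by the steady-state plasma glutamine tracer enrichment of the
same subject's bone marrow plasma (precursor-product normalization),
making relative enrichments comparable across subjects who reached
different plateau enrichments. The per-subject CD138+/CD138- ratio of
relative enrichments then contrasts (pre-)malignant plasma cells with
the paired remainder of the marrow mononuclear cells; a ratio > 1 means
higher labeling in the CD138+ fraction.

Group comparisons follow the study's statistics: two-sided paired t
tests for enrichment contrasts, Mann-Whitney U for concentrations
(exact for small samples without ties), ordinary least squares with
Pearson r for concentration correlations. Enrichment summaries are
mean +/- SEM, ratios are summarized by geometric mean. No
multiple-testing correction is applied by default; Benjamini-Hochberg
is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleRecord",
    "RelativeEnrichment",
    "FractionalRatio",
    "normalize_to_precursor",
    "fractional_ratio",
    "paired_group_test",
    "unpaired_group_test",
    "correlate",
    "PairedTestResult",
    "UnpairedTestResult",
    "CorrelationResult",
    "metabolite_contrast_table",
    "subject_ratio_table",
]

logger = logging.getLogger(__name__)

GROUPS = ("volunteer", "MGUS", "MM")
FRACTIONS = ("CD138+", "CD138-")


@dataclass
class SampleRecord:
    """One subject x compartment x cell-fraction measurement set."""

    subject_id: str
    group: str
    fraction: str  # "CD138+", "CD138-" or "none"
    mpe: dict[str, float]
    plasma_glutamine_enrichment: float
    compartment: str = "cells"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 < self.plasma_glutamine_enrichment < 1.0:
            raise ValueError(
                f"subject {self.subject_id}: plasma glutamine enrichment "
                f"{self.plasma_glutamine_enrichment} outside (0, 1)"
            )


@dataclass(frozen=True)
class RelativeEnrichment:
    """MPE of one metabolite divided by the subject's plasma glutamine
    tracer enrichment."""

    subject_id: str
    metabolite: str
    value: float


@dataclass(frozen=True)
class FractionalRatio:
    """Per-subject CD138+/CD138- ratio of relative enrichments."""

    subject_id: str
    metabolite: str
    value: float
    defined: bool = True


def normalize_to_precursor(record: SampleRecord) -> list[RelativeEnrichment]:
    """Divide each metabolite MPE by the subject's plasma glutamine
    enrichment (precursor-product normalization)."""
    e = record.plasma_glutamine_enrichment
    if e <= 0:
        raise ValueError(
            f"subject {record.subject_id}: nonpositive plasma glutamine "
            "enrichment"
        )
    return [
        RelativeEnrichment(record.subject_id, met, mpe / e)
        for met, mpe in record.mpe.items()
    ]


def fractional_ratio(
    pos: RelativeEnrichment, neg: RelativeEnrichment
) -> FractionalRatio:
    """CD138+/CD138- ratio for one subject and metabolite; 1 = equal
    labeling. A zero denominator yields a flagged (undefined) record."""
    if pos.subject_id != neg.subject_id or pos.metabolite != neg.metabolite:
        raise ValueError("ratio requires the same subject and metabolite")
    if neg.value == 0:
        logger.warning(
            "subject %s, %s: zero CD138- relative enrichment; ratio undefined",
            pos.subject_id, pos.metabolite,
        )
        return FractionalRatio(
            pos.subject_id, pos.metabolite, math.nan, defined=False
        )
    return FractionalRatio(pos.subject_id, pos.metabolite, pos.value / neg.value)


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    statistic: float  # paired t
    pvalue: float
    n: int


@dataclass(frozen=True)
class UnpairedTestResult:
    statistic: float  # Mann-Whitney U
    pvalue: float
    method: str


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r: float
    pvalue: float
    n: int


def paired_group_test(values_pos, values_neg) -> PairedTestResult:
    """Two-sided paired t test (CD138+ vs paired CD138-).

    Identical vectors give t = 0, p = 1 rather than the indeterminate
    0/0 form.
    """
    a = np.asarray(values_pos, dtype=float)
    b = np.asarray(values_neg, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"unpaired lengths {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("paired t test needs at least 3 pairs")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0) and np.allclose(diffs.mean(), 0.0):
        return PairedTestResult(0.0, 0.0, 1.0, len(a))
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        float(diffs.mean()), float(res.statistic), float(res.pvalue), len(a)
    )


def unpaired_group_test(values_a, values_b) -> UnpairedTestResult:
    """Two-sided Mann-Whitney U test.

    Exact p for small samples (<= 8 per arm, no ties); otherwise normal
    approximation with tie correction. Completely tied data give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("Mann-Whitney test needs n >= 3 per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return UnpairedTestResult(len(a) * len(b) / 2.0, 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return UnpairedTestResult(float(res.statistic), float(res.pvalue), method)


def correlate(x, y) -> CorrelationResult:
    """Ordinary least-squares line with Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return CorrelationResult(
        float(res.slope), float(res.intercept), float(res.rvalue),
        float(res.pvalue), len(x),
    )


def metabolite_contrast_table(
    relative: pd.DataFrame,
    group: str,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-metabolite paired CD138+ vs CD138- contrast for one group.

    ``relative`` is tidy with columns subject_id, group, fraction,
    metabolite, relative_enrichment. Subjects missing one fraction or
    metabolite are dropped per metabolite, not listwise. Returns mean,
    SEM per fraction and the paired-t mean difference and p-value;
    optional Benjamini-Hochberg adjusted p in ``p_adj``.
    """
    sub = relative[relative["group"] == group]
    rows = []
    for met, chunk in sub.groupby("metabolite", sort=True):
        wide = chunk.pivot_table(
            index="subject_id", columns="fraction",
            values="relative_enrichment", aggfunc="first",
        )
        if not {"CD138+", "CD138-"}.issubset(wide.columns):
            continue
        wide = wide.dropna(subset=["CD138+", "CD138-"])
        if len(wide) < 3:
            continue
        res = paired_group_test(wide["CD138+"], wide["CD138-"])
        rows.append({
            "group": group,
            "metabolite": met,
            "n_pairs": res.n,
            "mean_pos": float(wide["CD138+"].mean()),
            "sem_pos": float(wide["CD138+"].sem()),
            "mean_neg": float(wide["CD138-"].mean()),
            "sem_neg": float(wide["CD138-"].sem()),
            "mean_difference": res.mean_difference,
            "t": res.statistic,
            "p": res.pvalue,
        })
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def subject_ratio_table(relative: pd.DataFrame) -> pd.DataFrame:
    """Per-subject CD138+/CD138- fractional-enrichment ratios, tidy.

    Undefined ratios (zero denominator) are flagged and excluded from
    the geometric-mean summary callers typically compute.
    """
    rows = []
    for (subject, group, met), chunk in relative.groupby(
        ["subject_id", "group", "metabolite"], sort=True
    ):
        by_frac = chunk.set_index("fraction")["relative_enrichment"]
        if "CD138+" not in by_frac.index or "CD138-" not in by_frac.index:
            continue
        ratio = fractional_ratio(
            RelativeEnrichment(subject, met, float(by_frac["CD138+"])),
            RelativeEnrichment(subject, met, float(by_frac["CD138-"])),
        )
        rows.append({
            "subject_id": subject,
            "group": group,
            "metabolite": met,
            "ratio": ratio.value,
            "defined": ratio.defined,
        })
    return pd.DataFrame(rows)


def geometric_mean_ratio(ratios) -> float:
    """Geometric mean of defined, positive ratios (ratios multiply)."""
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r) & (r > 0)]
    if len(r) == 0:
        raise ValueError("no defined positive ratios")
    return float(np.exp(np.mean(np.log(r))))
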