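"""Precursor normalization, fractional ratios and group statistics."""

import numpy as np
import pandas as pd
import pytest

from tcatrace import (
    RelativeEnrichment,
    SampleRecord,
    correlate,
    fractional_ratio,
    geometric_mean_ratio,
    normalize_to_precursor,
    paired_group_test,
    unpaired_group_test,
)
from tcatrace.enrichment import metabolite_contrast_table, subject_ratio_table


def record(mpe, e=0.05, subject="s1", fraction="CD138+"):
    return SampleRecord(subject, "MM", fraction, mpe, e)


class TestNormalization:
    def test_divides_by_precursor(self):
        rel = normalize_to_precursor(record({"malate": 0.002}))
        assert rel[0].value == pytest.approx(0.04)
        rel = normalize_to_precursor(record({"malate": 0.0}))
        assert rel[0].value == 0.0

    def test_scale_invariance(self):
        a = normalize_to_precursor(record({"malate": 0.002}, e=0.05))
        b = normalize_to_precursor(record({"malate": 0.006}, e=0.15))
        assert a[0].value == pytest.approx(b[0].value)

    def test_zero_precursor_names_subject(self):
        with pytest.raises(ValueError, match="s7"):
            SampleRecord("s7", "MM", "CD138+", {}, 0.0)


class TestFractionalRatio:
    def test_basic_and_identity(self):
        pos = RelativeEnrichment("s1", "malate", 0.04)
        neg = RelativeEnrichment("s1", "malate", 0.02)
        assert fractional_ratio(pos, neg).value == pytest.approx(2.0)
        assert fractional_ratio(pos, pos).value == 1.0

    def test_zero_denominator_flagged(self):
        pos = RelativeEnrichment("s1", "malate", 0.04)
        zero = RelativeEnrichment("s1", "malate", 0.0)
        ratio = fractional_ratio(pos, zero)
        assert not ratio.defined
        assert np.isnan(ratio.value)

    def test_mismatched_records_rejected(self):
        pos = RelativeEnrichment("s1", "malate", 0.04)
        other = RelativeEnrichment("s2", "malate", 0.02)
        with pytest.raises(ValueError):
            fractional_ratio(pos, other)

    def test_geometric_mean_recovers_simulated_effect(self, rng):
        """Cohorts of 11 paired subjects generated at a true CD138+/CD138-
        ratio of 1.5 average (geometrically) back to ~1.5."""
        means = []
        for _ in range(200):
            base = rng.lognormal(np.log(0.2), 0.4, size=11)
            pos = base * 1.5 * rng.lognormal(0, 0.2, size=11)
            neg = base * rng.lognormal(0, 0.2, size=11)
            means.append(geometric_mean_ratio(pos / neg))
        assert np.mean(means) == pytest.approx(1.5, rel=0.05)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_three_pair_hand_calculation(self):
        # differences 1, 2, 3: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        res = paired_group_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == pytest.approx(2.0)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.pvalue == pytest.approx(0.074180, abs=1e-4)

    def test_null_type_one_error_rate(self, rng):
        rejections = sum(
            paired_group_test(rng.normal(size=10), rng.normal(size=10)).pvalue
            < 0.05
            for _ in range(1000)
        )
        # binomial(1000, 0.05): 3 sigma ~ +/- 0.021
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_group_test([1, 2, 3], [1, 2])


class TestMannWhitney:
    def test_disjoint_small_groups_exact(self):
        res = unpaired_group_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.method == "exact"
        assert res.statistic in (0.0, 16.0)
        assert res.pvalue == pytest.approx(2 / 70, abs=1e-9)

    def test_identical_groups(self):
        res = unpaired_group_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.pvalue == 1.0

    def test_tie_correction_path(self):
        res = unpaired_group_test([1, 1, 2, 3], [2, 3, 3, 4])
        assert res.method == "asymptotic"
        assert 0.0 < res.pvalue <= 1.0


class TestCorrelate:
    def test_exact_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = correlate(x, 2 * x)
        assert (res.slope, res.r) == pytest.approx((2.0, 1.0))
        res = correlate(x, 5 - x)
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_contrast_table_drops_missing_per_metabolite():
    """A subject missing one metabolite is excluded for that metabolite
    only (cf. per-metabolite analysis failures), not listwise."""
    rows = []
    rng = np.random.default_rng(5)
    for i in range(6):
        for fraction, offset in (("CD138+", 0.02), ("CD138-", 0.0)):
            rows.append({
                "subject_id": f"s{i}", "group": "MM", "fraction": fraction,
                "metabolite": "malate",
                "relative_enrichment": 0.05 + offset + rng.normal(0, 0.005),
            })
            if not (i == 0 and fraction == "CD138+"):
                rows.append({
                    "subject_id": f"s{i}", "group": "MM",
                    "fraction": fraction, "metabolite": "glutamate",
                    "relative_enrichment": 0.08 + rng.normal(0, 0.005),
                })
    table = metabolite_contrast_table(pd.DataFrame(rows), "MM")
    n_by_met = table.set_index("metabolite")["n_pairs"]
    assert n_by_met["malate"] == 6
    assert n_by_met["glutamate"] == 5
    adjusted = metabolite_contrast_table(pd.DataFrame(rows), "MM", adjust=True)
    assert "p_adj" in adjusted.columns


def test_subject_ratio_table_flags_undefined():
    rows = [
        {"subject_id": "s1", "group": "MM", "fraction": "CD138+",
         "metabolite": "malate", "relative_enrichment": 0.04},
        {"subject_id": "s1", "group": "MM", "fraction": "CD138-",
         "metabolite": "malate", "relative_enrichment": 0.0},
        {"subject_id": "s2", "group": "MM", "fraction": "CD138+",
         "metabolite": "malate", "relative_enrichment": 0.04},
        {"subject_id": "s2", "group": "MM", "fraction": "CD138-",
         "metabolite": "malate", "relative_enrichment": 0.02},
    ]
    ratios = subject_ratio_table(pd.DataFrame(rows))
    by_subject = ratios.set_index("subject_id")
    assert not by_subject.loc["s1", "defined"]
    assert by_subject.loc["s2", "ratio"] == pytest.approx(2.0)
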