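"""Contingency statistics: Fisher, odds/risk ratios, BH, co-occurrence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from evotraj.core import (SubcloneCluster, TumourSample, ValidationError)
from evotraj.stats import (Contingency2x2, bh_fdr, clonality_preference,
                           cooccurrence, demographic_comparison,
                           driver_count_test, event_enrichment,
                           fisher_two_tailed, odds_ratio, ranksum_p,
                           risk_ratio, signature_presence_test)


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by full hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    observed = prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = prob(x)
        if p <= observed * (1 + 1e-12):
            total += p
    return total


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_two_tailed(Contingency2x2(1, 1, 1, 1)) == 1.0

    def test_diagonal_table_closed_form(self):
        # 2 / C(10,5) = 1/126
        assert fisher_two_tailed(Contingency2x2(5, 0, 0, 5)) == \
            pytest.approx(1 / 126, abs=1e-12)

    @pytest.mark.parametrize("table", [
        (3, 7, 9, 2), (0, 5, 5, 0), (10, 10, 1, 20), (2, 2, 2, 2),
        (12, 3, 4, 18), (1, 0, 0, 1),
    ])
    def test_matches_enumeration_oracle(self, table):
        expected = fisher_oracle(*table)
        assert fisher_two_tailed(Contingency2x2(*table)) == pytest.approx(
            expected, abs=1e-12)

    def test_invariant_under_transposition(self):
        t = Contingency2x2(3, 8, 5, 13)
        transposed = Contingency2x2(3, 5, 8, 13)
        assert fisher_two_tailed(t) == pytest.approx(
            fisher_two_tailed(transposed), abs=1e-12)


class TestRatios:
    def test_printed_sbs4_table_reproduces_risk_ratio(self):
        # 9/17 SBS4+ vs 65/389 SBS4- tumours on the smoking trajectory
        table = Contingency2x2(9, 8, 65, 324)
        assert risk_ratio(table) == pytest.approx(3.17, abs=0.005)

    def test_unit_table(self):
        t = Contingency2x2(1, 1, 1, 1)
        assert odds_ratio(t) == 1.0 and risk_ratio(t) == 1.0

    def test_haldane_correction_on_zero_cell(self):
        t = Contingency2x2(5, 0, 2, 3)
        assert odds_ratio(t) == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_empty_row_risk_ratio_missing(self):
        assert math.isnan(risk_ratio(Contingency2x2(0, 0, 2, 3)))


class TestBH:
    def test_equal_adjustment_closed_form(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        out = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestEnrichment:
    def test_exclusive_event_flagged_with_haldane(self):
        presence = pd.DataFrame(
            {"ev": [True] * 10 + [False] * 10},
            index=[f"s{i}" for i in range(20)])
        groups = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        res = event_enrichment(presence, groups, (["A"], ["B"]))[0]
        assert res.flagged and res.odds_ratio > 1

    def test_empty_group_rejected(self):
        presence = pd.DataFrame({"ev": [True, False]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            event_enrichment(presence, {"a": "A", "b": "A"}, (["A"], ["B"]))

    def test_null_events_not_flagged(self):
        rng = np.random.default_rng(2)
        presence = pd.DataFrame(
            rng.random((60, 5)) < 0.5,
            index=[f"s{i}" for i in range(60)],
            columns=[f"e{i}" for i in range(5)])
        groups = {f"s{i}": ("A" if i % 2 else "B") for i in range(60)}
        res = event_enrichment(presence, groups, (["A"], ["B"]))
        assert sum(r.flagged for r in res) == 0


class TestDemographics:
    def make_cohort(self):
        samples = []
        # SBS4+ never-smokers: 9 on the smoking-like trajectory, 8 off it;
        # SBS4- never-smokers: 65 on, 324 off (the printed counts)
        layout = [(True, "SD", 9), (True, "NSD", 8),
                  (False, "SD", 65), (False, "NSD", 324)]
        labels = {}
        idx = 0
        for sbs4, label, count in layout:
            for _ in range(count):
                sid = f"s{idx}"
                idx += 1
                samples.append(TumourSample(
                    sample_id=sid, purity=0.5, nrpcc=20, wgd=False,
                    smoking="never", sbs4_positive=sbs4,
                    clusters=[SubcloneCluster("clonal", 0.98, 10)]))
                labels[sid] = label
        from evotraj.core import Cohort
        return Cohort(samples=samples), labels

    def test_sbs4_risk_ratio_matches_printed_value(self):
        cohort, labels = self.make_cohort()
        result, stacked = demographic_comparison(
            cohort, labels, "sbs4_positive", True, False, ("SD", "NSD"),
            sample_filter=lambda s: s.smoking == "never")
        assert result.risk_ratio == pytest.approx(3.17, abs=0.005)
        assert result.table.a == 9 and result.table.d == 324
        assert stacked[True]["SD"] == pytest.approx(9 / 17)

    def test_missing_level_after_filter_rejected(self):
        cohort, labels = self.make_cohort()
        with pytest.raises(ValidationError):
            demographic_comparison(cohort, labels, "sex", "M", "Z",
                                   ("SD", "NSD"),
                                   sample_filter=lambda s: False)


class TestDriverCount:
    def test_printed_counts_flag_the_driver_rich_subset(self):
        genes = [f"g{i}" for i in range(72)]
        per_subset = {"SD": set(genes[:45]),
                      "NSD-Loss": set(genes[:13]),
                      "NSD-Gain": set(genes[5:21])}
        results = driver_count_test(per_subset, universe_size=72)
        by_label = {r.item_id: r for r in results}
        assert by_label["SD"].fdr < 0.05
        assert by_label["SD"].odds_ratio > 1

    def test_equal_counts_are_null(self):
        genes = [f"g{i}" for i in range(72)]
        per_subset = {lab: set(genes[:20]) for lab in "ABC"}
        results = driver_count_test(per_subset, universe_size=72)
        assert all(r.p > 0.5 for r in results)

    def test_both_pooling_conventions_available(self):
        genes = [f"g{i}" for i in range(72)]
        per_subset = {"A": set(genes[:30]), "B": set(genes[:10]),
                      "C": set(genes[10:20])}
        union = driver_count_test(per_subset, 72, pooling="union")
        additive = driver_count_test(per_subset, 72, pooling="additive")
        ua = {r.item_id: r.table for r in union}
        aa = {r.item_id: r.table for r in additive}
        assert ua["A"].c == 20 and ua["A"].d == 52
        assert aa["A"].c == 20 and aa["A"].d == 124


class TestCooccurrence:
    def test_full_overlap_closed_form(self):
        presence = pd.DataFrame({
            "A": [True] * 5 + [False] * 5,
            "B": [True] * 5 + [False] * 5})
        out = cooccurrence(presence)
        # P(X >= 5) for X ~ Hypergeom(N=10, K=5, n=5) = 1/C(10,5)
        assert out.loc[0, "p_greater"] == pytest.approx(1 / 252, abs=1e-12)

    def test_expected_overlap_keeps_both_tails_large(self):
        # nA=nB=6, N=12 -> expected overlap 3
        a = [True] * 6 + [False] * 6
        b = [True] * 3 + [False] * 6 + [True] * 3
        out = cooccurrence(pd.DataFrame({"A": a, "B": b}))
        assert out.loc[0, "overlap"] == 3
        assert out.loc[0, "p_greater"] >= 0.5
        assert out.loc[0, "p_less"] >= 0.5

    def test_matches_hypergeom_enumeration(self):
        rng = np.random.default_rng(3)
        presence = pd.DataFrame(rng.random((15, 2)) < 0.4,
                                columns=["A", "B"])
        out = cooccurrence(presence)
        N = 15
        nA = int(presence["A"].sum())
        nB = int(presence["B"].sum())
        j = int((presence["A"] & presence["B"]).sum())

        def hyper_pmf(x):
            return (math.comb(nA, x) * math.comb(N - nA, nB - x)
                    / math.comb(N, nB))
        lo, hi = max(0, nA + nB - N), min(nA, nB)
        p_ge = sum(hyper_pmf(x) for x in range(j, hi + 1))
        p_le = sum(hyper_pmf(x) for x in range(lo, j + 1))
        assert out.loc[0, "p_greater"] == pytest.approx(p_ge, abs=1e-12)
        assert out.loc[0, "p_less"] == pytest.approx(p_le, abs=1e-12)


class TestClonality:
    def test_always_clonal_event_preferred(self):
        counts = {"E": (20, 0), "other1": (10, 10), "other2": (10, 10)}
        results = {r.item_id: r for r in clonality_preference(counts)}
        assert results["E"].odds_ratio > 1
        assert results["E"].fdr < 0.05

    def test_uniform_rates_are_null(self):
        counts = {f"e{i}": (10, 10) for i in range(4)}
        results = clonality_preference(counts)
        assert all(r.p == pytest.approx(1.0) for r in results)


class TestRanksum:
    def test_identical_distributions_near_one(self):
        x = np.arange(10)
        assert ranksum_p(x + 0.25, x + 0.21) > 0.6

    def test_matches_exact_permutation_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 5)
        y = rng.normal(1, 1, 6)
        observed = ranksum_p(x, y)
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        obs_u = ranks[:5].sum() - 5 * 6 / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(11), 5):
            u = ranks[list(combo)].sum() - 5 * 6 / 2
            if abs(u - 15) >= abs(obs_u - 15) - 1e-12:   # mean U = nA*nB/2
                count += 1
            total += 1
        assert observed == pytest.approx(count / total, abs=1e-12)


class TestSignatures:
    def test_group_specific_signature_enriched(self):
        acts = pd.DataFrame({
            "SV5": [3.0] * 10 + [0.0] * 10,
            "SBS1": [1.0] * 20},
            index=[f"s{i}" for i in range(20)])
        groups = {f"s{i}": ("SD" if i < 10 else "NSD") for i in range(20)}
        results = {r.item_id: r
                   for r in signature_presence_test(acts, groups,
                                                    (["SD"], ["NSD"]))}
        assert results["SV5"].fdr < 0.05 and results["SV5"].odds_ratio > 1

    def test_all_zero_signature_skipped(self, caplog):
        acts = pd.DataFrame({"dead": [0.0, 0.0], "live": [1.0, 0.0]},
                            index=["a", "b"])
        results = signature_presence_test(acts, {"a": "X", "b": "Y"},
                                          (["X"], ["Y"]))
        assert [r.item_id for r in results] == ["live"]
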