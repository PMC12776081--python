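"""Weighted copy-number profiles, burden metrics, and the instability model."""

import numpy as np
import pandas as pd
import pytest

from evotraj.core import (CNState, Cohort, CopyNumberSegment, SnvCall,
                          SubcloneCluster, TumourSample, ValidationError)
from evotraj.genome import (aberrant_signature_proportion,
                            amplification_magnitude, burden_metrics,
                            cn_deviation, instability_regression, latency,
                            per_locus_tests, union_profiles, weighted_cn)


def seg(chrom, start, end, *states):
    return CopyNumberSegment(chrom, start, end,
                             tuple(CNState(*s) for s in states))


def profile_sample(sid, segments, wgd=False, **kw):
    defaults = dict(clusters=[SubcloneCluster("clonal", 0.98, 100)])
    defaults.update(kw)
    return TumourSample(sample_id=sid, purity=0.5, nrpcc=20, wgd=wgd,
                        segments=segments, **defaults)


class TestWeightedCN:
    def test_even_mixture(self):
        w = weighted_cn(seg("chr1", 0, 10, (2, 1, 0.5), (1, 1, 0.5)))
        assert (w.major, w.minor, w.total) == (1.5, 1.0, 2.5)

    def test_clonal_segment_is_identity(self):
        w = weighted_cn(seg("chr1", 0, 10, (3, 2, 1.0)))
        assert (w.major, w.minor) == (3.0, 2.0)

    def test_uneven_mixture_total(self):
        # 0.3 * (3+1) + 0.7 * (1+1)
        w = weighted_cn(seg("chr1", 0, 10, (3, 1, 0.3), (1, 1, 0.7)))
        assert w.total == pytest.approx(2.6)


class TestUnionProfiles:
    def test_differing_breakpoint_splits_segmentation(self):
        a = profile_sample("a", [seg("chr1", 0, 100, (1, 1, 1.0))])
        b = profile_sample("b", [seg("chr1", 0, 40, (2, 1, 1.0)),
                                 seg("chr1", 40, 100, (1, 1, 1.0))])
        profiles = union_profiles([a, b])
        assert [s for s in profiles.segments] == \
            [("chr1", 0, 40), ("chr1", 40, 100)]
        assert profiles.major.loc["a"].tolist() == [1.0, 1.0]
        assert profiles.major.loc["b"].tolist() == [2.0, 1.0]

    def test_union_tiles_covered_territory_exactly_once(self):
        a = profile_sample("a", [seg("chr1", 0, 30, (2, 1, 1.0)),
                                 seg("chr1", 30, 100, (1, 1, 1.0)),
                                 seg("chr2", 10, 60, (1, 0, 1.0))])
        b = profile_sample("b", [seg("chr1", 5, 80, (1, 1, 1.0))])
        profiles = union_profiles([a, b])
        for chrom in ("chr1", "chr2"):
            segs = [(s, e) for c, s, e in profiles.segments if c == chrom]
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                assert e1 <= s2   # non-overlapping, sorted

    def test_diploid_subset_mean_track(self):
        samples = [profile_sample(f"s{i}",
                                  [seg("chr1", 0, 100, (1, 1, 1.0))])
                   for i in range(4)]
        tracks = union_profiles(samples).mean_tracks()
        assert tracks.loc[0, ["major", "minor", "total"]].tolist() == \
            [1.0, 1.0, 2.0]


class TestPerLocus:
    def make_profiles(self, n=12, effect=False):
        samples = []
        for i in range(n):
            state = (3, 1, 1.0) if (effect and i < n // 2) else (1, 1, 1.0)
            samples.append(profile_sample(
                f"s{i}", [seg("chr1", 0, 50, state),
                          seg("chr1", 50, 100, (1, 1, 1.0))]))
        return union_profiles(samples), [f"s{i}" for i in range(n // 2)], \
            [f"s{i}" for i in range(n // 2, n)]

    def test_identical_subsets_null(self):
        profiles, ids_a, ids_b = self.make_profiles(effect=False)
        out = per_locus_tests(profiles, ids_a, ids_b)
        assert (out["total_p"].dropna() > 0.9).all()

    def test_planted_gain_detected_with_positive_effect(self):
        profiles, ids_a, ids_b = self.make_profiles(n=24, effect=True)
        out = per_locus_tests(profiles, ids_a, ids_b)
        hit = out[(out["chrom"] == "chr1") & (out["start"] == 0)].iloc[0]
        assert hit["total_fdr"] < 0.05 and hit["total_effect"] > 0

    def test_low_support_segment_masked(self):
        # one subset covers the tested segment in under 25% of samples
        covered = [profile_sample("a0", [seg("chr1", 0, 100, (1, 1, 1.0))])]
        covered += [profile_sample(f"a{i}", [seg("chr1", 50, 100, (1, 1, 1.0))])
                    for i in range(1, 5)]   # 1/5 = 20% support on [0,50)
        others = [profile_sample(f"b{i}", [seg("chr1", 0, 100, (1, 1, 1.0))])
                  for i in range(5)]
        profiles = union_profiles(covered + others)
        out = per_locus_tests(profiles, [s.sample_id for s in covered],
                              [s.sample_id for s in others])
        first = out[(out["start"] == 0)].iloc[0]
        assert not first["total_supported"]
        assert np.isnan(first["total_p"])


class TestAmplification:
    LOCUS = ("chr12", 100, 200)

    def test_full_gene_gain(self):
        s = profile_sample("s", [seg("chr12", 50, 300, (6, 1, 1.0))])
        assert amplification_magnitude(s, self.LOCUS) == pytest.approx(6.0)

    def test_half_gene_gain_scaled(self):
        s = profile_sample("s", [seg("chr12", 100, 150, (6, 1, 1.0))])
        assert amplification_magnitude(s, self.LOCUS) == pytest.approx(3.0)

    def test_no_gain_is_missing(self):
        s = profile_sample("s", [seg("chr12", 100, 200, (1, 1, 1.0))])
        assert amplification_magnitude(s, self.LOCUS) is None


class TestDeviation:
    def test_methods_worked_example_scores_one(self):
        # half the genome 2+1 (gains), half 1+0 (LOH):
        # mean major 1.5, mean minor 0.5 -> deviation 0.5 + 0.5 = 1
        s = profile_sample("s", [seg("chr1", 0, 100, (2, 1, 1.0)),
                                 seg("chr1", 100, 200, (1, 0, 1.0))])
        assert cn_deviation(s) == pytest.approx(1.0)

    def test_baseline_profiles_score_zero(self):
        diploid = profile_sample("d", [seg("chr1", 0, 100, (1, 1, 1.0))])
        tetraploid = profile_sample(
            "t", [seg("chr1", 0, 100, (2, 2, 1.0))], wgd=True)
        assert cn_deviation(diploid) == 0.0
        assert cn_deviation(tetraploid) == 0.0

    def test_invariant_to_segment_resplitting(self):
        one = profile_sample("a", [seg("chr1", 0, 100, (2, 0, 1.0))])
        split = profile_sample("b", [seg("chr1", 0, 60, (2, 0, 1.0)),
                                     seg("chr1", 60, 100, (2, 0, 1.0))])
        assert cn_deviation(one) == pytest.approx(cn_deviation(split))


class TestBurden:
    def test_diploid_sample(self):
        s = profile_sample("s", [seg("chr1", 0, 100, (1, 1, 1.0))])
        rec = burden_metrics(s)
        assert rec.pga == 0.0 and rec.ploidy == pytest.approx(2.0)

    def test_half_genome_gained(self):
        s = profile_sample("s", [seg("chr1", 0, 100, (2, 1, 1.0)),
                                 seg("chr1", 100, 200, (1, 1, 1.0))])
        rec = burden_metrics(s)
        assert rec.pga == pytest.approx(0.5)
        assert rec.ploidy == pytest.approx(2.5)

    def test_wgd_counts_fully_towards_pga(self):
        s = profile_sample("s", [seg("chr1", 0, 100, (2, 2, 1.0))], wgd=True)
        rec = burden_metrics(s)
        assert rec.pga == 1.0 and rec.ploidy == pytest.approx(4.0)

    def test_pga_invariant_to_resplitting(self):
        a = profile_sample("a", [seg("chr1", 0, 100, (2, 1, 1.0))])
        b = profile_sample("b", [seg("chr1", 0, 30, (2, 1, 1.0)),
                                 seg("chr1", 30, 100, (2, 1, 1.0))])
        assert burden_metrics(a).pga == burden_metrics(b).pga


class TestLatency:
    def test_closed_form(self):
        assert latency(80, 20, 60.0) == pytest.approx(12.0)

    def test_no_subclonal_mutations_means_zero(self):
        assert latency(100, 0, 60.0) == 0.0

    def test_acceleration_shrinks_latency_towards_zero(self):
        values = [latency(80, 20, 60.0, a) for a in (1, 5, 50, 5000)]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[-1] < 0.01

    def test_bounded_by_age(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m_t = int(rng.integers(0, 5000))
            m_p = int(rng.integers(1, 5000))
            age = float(rng.uniform(20, 95))
            val = latency(m_t, m_p, age)
            assert 0.0 <= val <= age


class TestAberrant:
    def test_basic_proportion(self):
        assert aberrant_signature_proportion(
            {"CN1": 80, "CN9": 20}, wgd=False) == pytest.approx(0.2)

    def test_pure_baseline_is_zero(self):
        assert aberrant_signature_proportion({"CN2": 100}, wgd=True) == 0.0

    def test_wrong_baseline_counts_as_aberrant(self):
        assert aberrant_signature_proportion(
            {"CN2": 50, "CN1": 50}, wgd=False) == pytest.approx(0.5)

    def test_no_activity_is_missing(self):
        assert aberrant_signature_proportion({"SBS4": 10}, wgd=False) is None


class TestRegression:
    def make_cohort(self, n=400, effect=0.2, seed=0):
        rng = np.random.default_rng(seed)
        samples = []
        response = {}
        for i in range(n):
            mutated = rng.random() < 0.4
            snvs = [SnvCall("GENEA", "clonal")] if mutated else []
            s = TumourSample(
                sample_id=f"s{i}", purity=float(rng.uniform(0.3, 0.9)),
                nrpcc=20, wgd=bool(rng.random() < 0.5),
                smoking="ever" if rng.random() < 0.3 else "never",
                ancestry="EUR" if rng.random() < 0.6 else "EAS",
                sex="M" if rng.random() < 0.5 else "F",
                snvs=snvs, clusters=[SubcloneCluster("clonal", 0.98, 10)])
            samples.append(s)
            base = 0.3 + effect * mutated + rng.normal(0, 0.08)
            response[f"s{i}"] = float(np.clip(base, 0, 1))
        return Cohort(samples=samples, driver_list=["GENEA"]), \
            pd.Series(response)

    def test_planted_effect_recovered_within_ci(self):
        cohort, response = self.make_cohort(n=400, effect=0.2)
        report = instability_regression(cohort, ["GENEA"], response)
        row = report.params.loc["GENEA"]
        assert row["ci_low"] <= 0.2 <= row["ci_high"]
        assert row["p"] < 1e-6

    def test_vif_properties(self):
        cohort, response = self.make_cohort(n=200, effect=0.0, seed=1)
        report = instability_regression(cohort, ["GENEA"], response)
        assert (report.vif >= 1.0 - 1e-9).all()
        corr = report.correlations
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_orthogonal_design_gives_unit_vif(self):
        samples = []
        response = {}
        # balanced 2x2 factorial: smoking x sex, orthogonal by construction
        i = 0
        rng = np.random.default_rng(2)
        for smoking in ("ever", "never"):
            for sex in ("M", "F"):
                for _ in range(10):
                    sid = f"s{i}"
                    i += 1
                    samples.append(TumourSample(
                        sample_id=sid, purity=0.5, nrpcc=20, wgd=False,
                        smoking=smoking, sex=sex,
                        clusters=[SubcloneCluster("clonal", 0.98, 10)]))
                    response[sid] = float(rng.uniform(0, 1))
        cohort = Cohort(samples=samples)
        report = instability_regression(cohort, [], pd.Series(response))
        assert report.vif["smoking"] == pytest.approx(1.0)
        assert report.vif["sex_male"] == pytest.approx(1.0)

    def test_collinear_design_rejected(self):
        samples = []
        response = {}
        rng = np.random.default_rng(3)
        for i in range(30):
            mutated = i % 2 == 0
            snvs = [SnvCall(g, "clonal") for g in
                    (["GENEA", "GENEB"] if mutated else [])]
            samples.append(TumourSample(
                sample_id=f"s{i}", purity=0.5, nrpcc=20, wgd=False,
                snvs=snvs, clusters=[SubcloneCluster("clonal", 0.98, 10)]))
            response[f"s{i}"] = float(rng.uniform(0, 1))
        cohort = Cohort(samples=samples, driver_list=["GENEA", "GENEB"])
        with pytest.raises(ValidationError, match="collinear"):
            instability_regression(cohort, ["GENEA", "GENEB"],
                                   pd.Series(response))
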