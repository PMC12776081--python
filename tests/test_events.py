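"""SCNA classification, WGD-timing parsimony, recurrence scan, catalog."""

import math

import numpy as np
import pytest

from evotraj.core import CNState, Cohort, CopyNumberSegment, SnvCall, \
    SubcloneCluster, TumourSample, ValidationError
from evotraj.events import (SCNAClass, Timing, binomial_recurrence_p,
                            apply_filters, build_catalog, classify_scna,
                            classify_wgd_timing, event_presence,
                            scan_recurrent_scnas)
from evotraj.masks import miniature_genome, miniature_mask


class TestClassify:
    @pytest.mark.parametrize("major,minor,wgd,expected", [
        (2, 1, False, SCNAClass.GAIN),       # gain over diploid baseline
        (2, 1, True, SCNAClass.NON_LOH_LOSS),  # same state, WGD baseline 2+2
        (0, 0, False, SCNAClass.HD),
        (0, 0, True, SCNAClass.HD),
        (1, 1, False, SCNAClass.NONE),
        (1, 0, False, SCNAClass.LOH),
        (2, 0, True, SCNAClass.LOH),         # LOH precedence over total
        (3, 1, True, SCNAClass.NONE),        # mixed state at baseline total
        (2, 2, True, SCNAClass.NONE),
        (5, 1, True, SCNAClass.GAIN),
        (1, 1, True, SCNAClass.NON_LOH_LOSS),
    ])
    def test_classification(self, major, minor, wgd, expected):
        assert classify_scna(major, minor, wgd) is expected

    def test_exactly_one_class_per_state(self):
        for major in range(7):
            for minor in range(major + 1):
                for wgd in (False, True):
                    cls = classify_scna(major, minor, wgd)
                    assert isinstance(cls, SCNAClass)
                    if major + minor == 0:
                        assert cls is SCNAClass.HD
                    elif minor == 0:
                        assert cls is SCNAClass.LOH

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValidationError):
            classify_scna(-1, 0, False)


def parsimony_oracle(major, minor):
    """Exhaustive enumeration over event histories from 1+1 with exactly
    one doubling: breadth-first over (allele_a, allele_b, wgd_done) states
    with single-copy gains/losses (no regain of a lost allele), tracking
    whether any change precedes the doubling."""
    from collections import deque

    target = (major, minor)
    best = {}
    start = (1, 1, False, False)   # a, b, doubled?, changed-before-wgd?
    queue = deque([(start, 0)])
    seen = {start: 0}
    cap = 2 * (major + minor) + 8
    while queue:
        (a, b, doubled, pre), dist = queue.popleft()
        if doubled and tuple(sorted((a, b), reverse=True)) == target:
            key = pre
            if key not in best or dist < best[key]:
                best[key] = dist
        if dist >= cap:
            continue
        moves = []
        if not doubled:
            moves.append(((2 * a, 2 * b, True, pre), 0))
        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            na, nb = a + da, b + db
            if na < 0 or nb < 0:
                continue
            if (a == 0 and na > 0) or (b == 0 and nb > 0):
                continue   # a fully lost allele cannot come back
            moves.append(((na, nb, doubled, pre or not doubled), 1))
        for state, cost in moves:
            nd = dist + cost
            if state not in seen or seen[state] > nd:
                seen[state] = nd
                queue.append((state, nd))
    early = best.get(True, math.inf)
    late = best.get(False, math.inf)
    return Timing.EARLY_CLONAL if early <= late else Timing.LATE_CLONAL


class TestWGDTiming:
    @pytest.mark.parametrize("major,minor,expected", [
        (2, 1, Timing.LATE_CLONAL),    # the post-WGD non-LOH loss example
        (2, 0, Timing.EARLY_CLONAL),
        (4, 2, Timing.EARLY_CLONAL),
        (3, 2, Timing.LATE_CLONAL),
        (1, 0, Timing.EARLY_CLONAL),   # 2 steps pre-WGD vs 3 post
    ])
    def test_known_states(self, major, minor, expected):
        assert classify_wgd_timing(major, minor) is expected

    def test_matches_enumeration_oracle_exhaustively(self):
        for major in range(7):
            for minor in range(major + 1):
                if (major, minor) == (2, 2):
                    continue   # the WGD baseline itself carries no event
                assert classify_wgd_timing(major, minor) is \
                    parsimony_oracle(major, minor), (major, minor)


class TestBinomial:
    def test_tail_from_zero_is_one(self):
        assert binomial_recurrence_p(0, 50, 0.1) == 1.0

    def test_all_successes_closed_form(self):
        assert binomial_recurrence_p(12, 12, 0.5) == pytest.approx(
            0.5 ** 12, abs=1e-15)

    def test_matches_direct_pmf_summation(self):
        k, n, p = 20, 100, 0.05
        direct = sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
                     for i in range(k, n + 1))
        assert binomial_recurrence_p(k, n, p) == pytest.approx(
            direct, abs=1e-12)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            binomial_recurrence_p(1, 2, 1.5)


class TestFilters:
    def test_hla_region_removed(self):
        mask = miniature_mask()
        out = apply_filters({"chr6": [(26_000_000, 29_000_000)]}, mask)
        assert out == {}

    def test_sex_chromosome_removed(self):
        mask = miniature_mask()
        assert apply_filters({"chrX": [(10_000_000, 20_000_000)]}, mask) == {}

    def test_unmasked_interval_retained_unchanged(self):
        mask = miniature_mask()
        region = [(10_000_000, 20_000_000)]
        assert apply_filters({"chr1": region}, mask) == {"chr1": region}


def flat_sample(sid, segments, wgd=False, snvs=(), clusters=None):
    genome = miniature_genome()
    baseline = (2, 2) if wgd else (1, 1)
    full = []
    by_chrom = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, length in genome.items():
        placed = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        cursor = 0
        for seg in placed:
            if seg.start > cursor:
                full.append(CopyNumberSegment(
                    chrom, cursor, seg.start,
                    (CNState(*baseline, 1.0),)))
            full.append(seg)
            cursor = seg.end
        if cursor < length:
            full.append(CopyNumberSegment(chrom, cursor, length,
                                          (CNState(*baseline, 1.0),)))
    return TumourSample(sample_id=sid, purity=0.6, nrpcc=20, wgd=wgd,
                        segments=full, snvs=list(snvs),
                        clusters=clusters or
                        [SubcloneCluster("clonal", 0.98, 100)])


class TestScan:
    def test_shared_gain_recovered_with_low_background(self):
        locus = ("chr2", 60_000_000, 70_000_000)
        gain = CopyNumberSegment(locus[0], locus[1], locus[2],
                                 (CNState(2, 1, 1.0),))
        samples = []
        for i in range(100):
            segs = [gain] if i < 60 else []
            samples.append(flat_sample(f"s{i}", segs))
        cohort = Cohort(samples=samples)
        regions = scan_recurrent_scnas(cohort, miniature_mask(),
                                       bin_size=1_000_000, alpha=0.05)
        gain_regions = regions[SCNAClass.GAIN]
        assert len(gain_regions) == 1
        chrom, start, end = gain_regions[0]
        assert chrom == "chr2" and start <= locus[1] and end >= locus[2]
        assert regions[SCNAClass.LOH] == []

    def test_class_free_cohort_yields_no_regions(self):
        cohort = Cohort(samples=[flat_sample(f"s{i}", []) for i in range(10)])
        regions = scan_recurrent_scnas(cohort, miniature_mask())
        assert all(v == [] for v in regions.values())

    def test_invariant_to_sample_order(self):
        locus = ("chr3", 10_000_000, 20_000_000)
        loh = CopyNumberSegment(locus[0], locus[1], locus[2],
                                (CNState(1, 0, 1.0),))
        samples = [flat_sample(f"s{i}", [loh] if i % 2 == 0 else [])
                   for i in range(40)]
        a = scan_recurrent_scnas(Cohort(samples=samples), miniature_mask())
        b = scan_recurrent_scnas(Cohort(samples=samples[::-1]),
                                 miniature_mask())
        assert a == b


class TestCatalog:
    def make_cohort(self, n_mutated, n=200):
        samples = []
        loh = CopyNumberSegment("chr4", 10_000_000, 26_000_000,
                                (CNState(1, 0, 1.0),))
        for i in range(n):
            snvs = [SnvCall("TP53", "clonal")] if i < n_mutated else []
            samples.append(flat_sample(f"s{i}", [loh], snvs=snvs))
        return Cohort(samples=samples, driver_list=["TP53"])

    def test_gene_below_3pct_excluded_at_3pct_included(self):
        regions = {SCNAClass.LOH: [("chr4", 10_000_000, 26_000_000)]}
        low = build_catalog(self.make_cohort(5), regions, ["TP53"],
                            min_snv_prev=0.03)       # 5/200 = 2.5%
        assert "SNV_TP53" not in low.event_ids
        edge = build_catalog(self.make_cohort(6), regions, ["TP53"],
                             min_snv_prev=0.03)      # 6/200 = 3.0% exactly
        assert "SNV_TP53" in edge.event_ids

    def test_catalog_cardinality_and_prevalence(self):
        cohort = self.make_cohort(100, n=200)
        regions = {SCNAClass.LOH: [("chr4", 10_000_000, 26_000_000)]}
        catalog = build_catalog(cohort, regions, ["TP53"])
        # one region + one gene; every sample is non-WGD so no WGD item
        assert len(catalog) == 2
        loh_ev = [e for e in catalog if e.kind == "LOH"][0]
        assert loh_ev.prevalence == pytest.approx(1.0)
        assert catalog.event("SNV_TP53").prevalence == pytest.approx(0.5)

    def test_empty_catalog_is_an_error(self):
        cohort = Cohort(samples=[flat_sample("s0", [])])
        with pytest.raises(ValidationError, match="empty"):
            build_catalog(cohort, {}, [])


class TestPresence:
    def test_clonal_loh_covering_80pct_is_early_in_wgd_sample(self):
        region = ("chr5", 10_000_000, 20_000_000)
        seg = CopyNumberSegment("chr5", 10_000_000, 18_000_000,
                                (CNState(2, 0, 1.0),))
        sample = flat_sample("s0", [seg], wgd=True)
        regions = {SCNAClass.LOH: [region]}
        catalog = build_catalog(Cohort(samples=[sample]), regions, [],
                                min_overlap_frac=0.5)
        present = {p.event_id: p for p in event_presence(sample, catalog)}
        loh = [p for eid, p in present.items() if eid.startswith("LOH")][0]
        assert loh.clonality == "clonal"
        assert loh.timing is Timing.EARLY_CLONAL
        assert "WGD" in present

    def test_sample_without_events_yields_empty_set(self):
        region = ("chr5", 10_000_000, 20_000_000)
        carrier = flat_sample("carrier", [CopyNumberSegment(
            "chr5", 10_000_000, 20_000_000, (CNState(1, 0, 1.0),))])
        empty = flat_sample("empty", [])
        catalog = build_catalog(Cohort(samples=[carrier]),
                                {SCNAClass.LOH: [region]}, [])
        assert event_presence(empty, catalog) == []

    def test_subclonal_snv_takes_cluster_clonality(self):
        clusters = [SubcloneCluster("clonal", 0.98, 100),
                    SubcloneCluster("sub1", 0.5, 40)]
        sample = flat_sample("s0", [], snvs=[SnvCall("TP53", "sub1")],
                             clusters=clusters)
        carrier = flat_sample("c0", [], snvs=[SnvCall("TP53", "clonal")])
        catalog = build_catalog(
            Cohort(samples=[carrier], driver_list=["TP53"]),
            {}, ["TP53"], min_snv_prev=0.03)
        present = event_presence(sample, catalog)
        assert len(present) == 1
        assert present[0].clonality == "subclonal"
        assert present[0].cluster_id == "sub1"

    def test_coverage_below_threshold_absent(self):
        region = ("chr5", 10_000_000, 20_000_000)
        seg = CopyNumberSegment("chr5", 10_000_000, 14_000_000,
                                (CNState(1, 0, 1.0),))   # 40% coverage
        sample = flat_sample("s0", [seg])
        carrier = flat_sample("c0", [CopyNumberSegment(
            "chr5", 10_000_000, 20_000_000, (CNState(1, 0, 1.0),))])
        catalog = build_catalog(Cohort(samples=[carrier]),
                                {SCNAClass.LOH: [region]}, [])
        assert event_presence(sample, catalog, min_overlap_frac=0.5) == []
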