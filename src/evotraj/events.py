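"""Cohort-wide somatic event catalog: SCNA classes, recurrence scan, WGD
timing, and per-sample event presence.

Segments are classed as GAIN / LOH / NON_LOH_LOSS / HD / NONE relative to
the sample's baseline ploidy (1+1, or 2+2 after whole-genome duplication),
so e.g. a 2+1 segment is a gain in a non-WGD sample but a non-LOH loss in a
WGD sample.  Recurrently altered loci are found by tiling the unmasked
genome into bins and testing, per class, whether more samples carry the
class at a bin than expected from their genome-wide background rates
(exact binomial upper tail, Benjamini-Hochberg across bins x classes).
Clonal events in WGD samples are timed relative to the duplication by
maximum parsimony over single-copy gain/loss histories.
"""

from __future__ import annotations

import enum
import functools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._intervals import merge, overlap_length, total_length
from .core import Cohort, TumourSample, ValidationError
from .masks import FilterMask

logger = logging.getLogger(__name__)

CLONAL_CCF_BAND = 0.9      # cluster CCF at or above this is treated as clonal


class SCNAClass(str, enum.Enum):
    GAIN = "GAIN"
    LOH = "LOH"
    NON_LOH_LOSS = "NON_LOH_LOSS"
    HD = "HD"
    NONE = "NONE"


class Timing(str, enum.Enum):
    EARLY_CLONAL = "EARLY_CLONAL"
    LATE_CLONAL = "LATE_CLONAL"
    CLONAL = "CLONAL"          # clonal in a non-WGD sample (no WGD strata)
    SUBCLONAL = "SUBCLONAL"
    WGD = "WGD"                # the duplication marker itself


def classify_scna(major: int, minor: int, wgd: bool) -> SCNAClass:
    """Class of a copy-number state relative to the sample baseline.

    HD when everything is lost; LOH whenever the minor allele is absent
    (LOH takes precedence over total-based calls); otherwise gain or
    non-LOH loss by comparing total copies with the baseline total
    (2, or 4 after WGD).
    """
    if major < 0 or minor < 0:
        raise ValidationError(f"negative copy number {major}+{minor}")
    if minor > major:
        raise ValidationError(f"minor > major in {major}+{minor}")
    total = major + minor
    if total == 0:
        return SCNAClass.HD
    if minor == 0:
        return SCNAClass.LOH
    baseline = 4 if wgd else 2
    if total > baseline:
        return SCNAClass.GAIN
    if total < baseline:
        return SCNAClass.NON_LOH_LOSS
    return SCNAClass.NONE


def _steps(src: tuple, dst: tuple) -> float:
    """Single-copy steps between allele states along a monotone path;
    infinite when a fully lost allele would need to be regained."""
    (a, b), (c, d) = src, dst
    if (a == 0 and c > 0) or (b == 0 and d > 0):
        return np.inf
    return abs(c - a) + abs(d - b)


@functools.lru_cache(maxsize=None)
def _parsimony_timing(major: int, minor: int) -> Timing:
    late = _steps((2, 2), (major, minor))
    early = np.inf
    bound = max(major, 2) + 2
    for p in range(bound + 1):
        for q in range(p + 1):
            if (p, q) == (1, 1):
                continue
            cost = _steps((1, 1), (p, q)) + _steps((2 * p, 2 * q),
                                                   (major, minor))
            early = min(early, cost)
    return Timing.EARLY_CLONAL if early <= late else Timing.LATE_CLONAL


def classify_wgd_timing(major: int, minor: int,
                        scna_class: SCNAClass | None = None) -> Timing:
    """Pre- vs post-WGD timing of a clonal copy-number state in a WGD
    sample, by maximum parsimony (ties broken towards EARLY).

    Compares the minimum number of single-copy gain/loss steps from 1+1
    to (major, minor) when at least one step precedes the doubling with
    the minimum when every step follows it.
    """
    if major < 0 or minor < 0 or minor > major:
        raise ValidationError(f"invalid copy-number state {major}+{minor}")
    if scna_class is SCNAClass.NONE:
        raise ValidationError("timing undefined for baseline (NONE) states")
    return _parsimony_timing(major, minor)


# ---------------------------------------------------------------------------
# Event catalog


@dataclass(frozen=True)
class EventDef:
    """One cohort-wide event: a recurrent SCNA region, a driver-gene SNV,
    or whole-genome duplication."""

    event_id: str
    kind: str                      # GAIN | LOH | HD | SNV | WGD
    region: tuple | None = None    # (chrom, start, end) for SCNA kinds
    gene: str | None = None        # for SNV kind
    prevalence: float = 0.0

    def __post_init__(self):
        if self.kind in ("GAIN", "LOH", "HD") and self.region is None:
            raise ValidationError(f"{self.event_id}: SCNA event needs a region")
        if self.kind == "SNV" and self.gene is None:
            raise ValidationError(f"{self.event_id}: SNV event needs a gene")
        if self.kind == "WGD" and (self.region or self.gene):
            raise ValidationError("WGD event takes neither region nor gene")


@dataclass
class EventCatalog:
    events: list
    scope: str = "cohort"
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.event_id for e in self.events]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate event_ids in catalog")

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def event(self, event_id: str) -> EventDef:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(event_id)

    @property
    def event_ids(self):
        return [e.event_id for e in self.events]


# ---------------------------------------------------------------------------
# Per-sample class intervals


def sample_class_intervals(sample: TumourSample) -> dict:
    """Per SCNA class, the genomic intervals of that class in one sample,
    keyed (class -> chrom -> merged interval list).  Subclonal segments
    contribute through their altered (non-baseline-classed) state."""
    out: dict[SCNAClass, dict] = {c: {} for c in SCNAClass if c != SCNAClass.NONE}
    for seg in sample.segments:
        state = pick_altered_state(seg, sample.wgd)
        if state is None:
            continue
        cls = classify_scna(state.major, state.minor, sample.wgd)
        if cls == SCNAClass.NONE:
            continue
        out[cls].setdefault(seg.chrom, []).append((seg.start, seg.end))
    return {c: {ch: merge(iv) for ch, iv in per.items()}
            for c, per in out.items()}


def pick_altered_state(segment, wgd: bool):
    """The state of a segment that carries an SCNA, or None for baseline
    clonal segments."""
    if segment.clonal:
        state = segment.states[0]
        if classify_scna(state.major, state.minor, wgd) == SCNAClass.NONE:
            return None
        return state
    candidates = [s for s in segment.states
                  if classify_scna(s.major, s.minor, wgd) != SCNAClass.NONE]
    if not candidates:
        return None
    return max(candidates, key=lambda s: s.fraction)


def apply_filters(intervals_by_chrom: dict, mask: FilterMask) -> dict:
    """Intersect per-chromosome intervals with the mask's retained
    territory, dropping anything on masked loci."""
    out = {}
    for chrom, intervals in intervals_by_chrom.items():
        kept = []
        for start, end in intervals:
            kept.extend(mask.clip(chrom, start, end))
        if kept:
            out[chrom] = merge(kept)
    return out


# ---------------------------------------------------------------------------
# Binomial recurrence scan


def binomial_recurrence_p(k: int, n: int, p_bar: float) -> float:
    """Exact one-sided upper tail P(X >= k) for X ~ Binomial(n, p_bar)."""
    if not 0 <= k <= n:
        raise ValidationError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= p_bar <= 1.0:
        raise ValidationError(f"p_bar={p_bar} outside [0,1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p_bar))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    from .stats import bh_fdr
    return bh_fdr(p_values)


def _tile_bins(mask: FilterMask, bin_size: int):
    """Tile the retained autosomal territory into bins; returns a list of
    (chrom, start, end) and per-chromosome index ranges."""
    bins = []
    for chrom in mask.autosomes:
        for r_start, r_end in mask.retained(chrom):
            pos = r_start
            while pos < r_end:
                bins.append((chrom, pos, min(pos + bin_size, r_end)))
                pos += bin_size
    return bins


SCAN_CLASSES = (SCNAClass.GAIN, SCNAClass.LOH, SCNAClass.HD)


def scan_recurrent_scnas(cohort: Cohort, mask: FilterMask,
                         bin_size: int = 1_000_000,
                         alpha: float = 0.05) -> dict:
    """Identify recurrently gained / LOH / homozygously deleted loci.

    Per class, each sample's genome-wide background rate is its fraction
    of unmasked autosomal bases carrying the class; per bin, the number of
    samples overlapping the bin with the class is compared against the
    cohort-mean background rate by an exact binomial upper tail.  BH is
    applied across all bins x classes; adjacent significant bins are
    merged and extended to the union of the overlapping per-sample class
    segments.  Returns {SCNAClass: [(chrom, start, end), ...]}.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    if len(cohort) == 0:
        raise ValidationError("empty cohort")

    bins = _tile_bins(mask, bin_size)
    n_bins = len(bins)
    n_samples = len(cohort)
    genome_len = mask.total_retained()

    # per-sample filtered class intervals and background rates
    per_sample = []
    rates = {c: [] for c in SCAN_CLASSES}
    for s in cohort.samples:
        filtered = {c: apply_filters(per, mask)
                    for c, per in sample_class_intervals(s).items()}
        per_sample.append(filtered)
        for c in SCAN_CLASSES:
            covered = sum(total_length(iv)
                          for iv in filtered.get(c, {}).values())
            rates[c].append(covered / genome_len)

    bin_index: dict[str, list] = {}
    for i, (chrom, start, end) in enumerate(bins):
        bin_index.setdefault(chrom, []).append((start, end, i))

    counts = {c: np.zeros(n_bins, dtype=int) for c in SCAN_CLASSES}
    for filtered in per_sample:
        for c in SCAN_CLASSES:
            hit = np.zeros(n_bins, dtype=bool)
            for chrom, intervals in filtered.get(c, {}).items():
                for b_start, b_end, i in bin_index.get(chrom, []):
                    for start, end in intervals:
                        if overlap_length(start, end, b_start, b_end) > 0:
                            hit[i] = True
                            break
            counts[c] += hit

    p_values, keys = [], []
    for c in SCAN_CLASSES:
        p_bar = float(np.mean(rates[c])) if rates[c] else 0.0
        for i in range(n_bins):
            p_values.append(binomial_recurrence_p(int(counts[c][i]),
                                                  n_samples, p_bar))
            keys.append((c, i))
    fdr = bh_adjust(np.array(p_values))

    significant = {c: set() for c in SCAN_CLASSES}
    for (c, i), q in zip(keys, fdr):
        if q < alpha:
            significant[c].add(i)

    regions = {}
    for c in SCAN_CLASSES:
        merged_bins: dict[str, list] = {}
        for i in sorted(significant[c]):
            chrom, start, end = bins[i]
            merged_bins.setdefault(chrom, []).append((start, end))
        class_regions = []
        for chrom, intervals in merged_bins.items():
            for r_start, r_end in merge(intervals):
                # extend to the union of overlapping per-sample segments
                lo, hi = r_start, r_end
                for filtered in per_sample:
                    for start, end in filtered.get(c, {}).get(chrom, []):
                        if overlap_length(start, end, r_start, r_end) > 0:
                            lo, hi = min(lo, start), max(hi, end)
                class_regions.append((chrom, lo, hi))
        by_chrom: dict[str, list] = {}
        for chrom, lo, hi in class_regions:
            by_chrom.setdefault(chrom, []).append((lo, hi))
        regions[c] = [(chrom, lo, hi)
                      for chrom in sorted(by_chrom)
                      for lo, hi in merge(by_chrom[chrom])]
    return regions


# ---------------------------------------------------------------------------
# Catalog construction and per-sample presence


def _scna_presence_fraction(sample_intervals: dict, region: tuple,
                            min_overlap_frac: float) -> bool:
    chrom, start, end = region
    covered = sum(overlap_length(a, b, start, end)
                  for a, b in sample_intervals.get(chrom, []))
    return covered >= min_overlap_frac * (end - start)


def build_catalog(cohort: Cohort, regions: dict, driver_list: list,
                  min_snv_prev: float = 0.03,
                  min_overlap_frac: float = 0.5) -> EventCatalog:
    """Combine recurrent SCNA regions, driver-gene SNVs seen in at least
    ``min_snv_prev`` of samples (inclusive), and one WGD item into the
    cohort-wide event catalog with prevalences."""
    if not 0.0 < min_snv_prev < 1.0:
        raise ValidationError("min_snv_prev must be in (0,1)")
    n = len(cohort)
    if n == 0:
        raise ValidationError("empty cohort")

    per_sample = [sample_class_intervals(s) for s in cohort.samples]

    events = []
    for cls in SCAN_CLASSES:
        for chrom, start, end in regions.get(cls, []):
            carriers = sum(
                _scna_presence_fraction(intervals.get(cls, {}),
                                        (chrom, start, end), min_overlap_frac)
                for intervals in per_sample)
            mb_lo, mb_hi = start / 1e6, end / 1e6
            event_id = f"{cls.value}_{chrom}_{mb_lo:g}_{mb_hi:g}Mb"
            events.append(EventDef(event_id=event_id, kind=cls.value,
                                   region=(chrom, start, end),
                                   prevalence=carriers / n))

    gene_counts: dict[str, int] = {}
    for s in cohort.samples:
        for gene in {snv.gene for snv in s.snvs}:
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
    for gene in driver_list:
        count = gene_counts.get(gene, 0)
        if count / n >= min_snv_prev:
            events.append(EventDef(event_id=f"SNV_{gene}", kind="SNV",
                                   gene=gene, prevalence=count / n))

    wgd_prev = sum(s.wgd for s in cohort.samples) / n
    if wgd_prev > 0:
        events.append(EventDef(event_id="WGD", kind="WGD",
                               prevalence=wgd_prev))

    if not events:
        raise ValidationError("event catalog is empty: nothing to order")
    return EventCatalog(events=events, scope="cohort",
                        config={"min_snv_prev": min_snv_prev,
                                "min_overlap_frac": min_overlap_frac})


@dataclass(frozen=True)
class PresentEvent:
    """One event observed in one sample, with its clonality stratum."""

    event_id: str
    clonality: str                 # clonal | subclonal
    timing: Timing
    cluster_id: str | None = None  # subclone carrying the event, if subclonal


def _nearest_subclone(sample: TumourSample, fraction: float,
                      clonal_band: float = CLONAL_CCF_BAND):
    subclones = [c for c in sample.clusters if c.ccf < clonal_band]
    if not subclones:
        return None
    return min(subclones, key=lambda c: abs(c.ccf - fraction))


def event_presence(sample: TumourSample, catalog: EventCatalog,
                   min_overlap_frac: float = 0.5,
                   clonal_band: float = CLONAL_CCF_BAND) -> list:
    """Which catalog events a sample carries, each with clonality and
    (in WGD samples) pre/post-duplication timing.

    SCNA events are present when matching-class segments cover at least
    ``min_overlap_frac`` of the event region; their clonality follows the
    covering segments' state structure.  SNV events take clonality from
    the assigned cluster's CCF and, in WGD samples, timing from the
    mutant-allele multiplicity (>= 2 copies implies the mutation preceded
    the doubling).
    """
    present = []
    class_intervals = sample_class_intervals(sample)

    for event in catalog:
        if event.kind == "WGD":
            if sample.wgd:
                present.append(PresentEvent("WGD", "clonal", Timing.WGD))
            continue

        if event.kind == "SNV":
            calls = [snv for snv in sample.snvs if snv.gene == event.gene]
            if not calls:
                continue
            call = max(calls, key=lambda snv: sample.cluster(snv.cluster_id).ccf)
            cluster = sample.cluster(call.cluster_id)
            if cluster.ccf >= clonal_band:
                if sample.wgd:
                    timing = (Timing.EARLY_CLONAL if call.multiplicity >= 2
                              else Timing.LATE_CLONAL)
                else:
                    timing = Timing.CLONAL
                present.append(PresentEvent(event.event_id, "clonal", timing))
            else:
                present.append(PresentEvent(event.event_id, "subclonal",
                                            Timing.SUBCLONAL,
                                            cluster_id=cluster.cluster_id))
            continue

        # SCNA event
        cls = SCNAClass(event.kind)
        chrom, start, end = event.region
        if not _scna_presence_fraction(class_intervals.get(cls, {}),
                                       (chrom, start, end), min_overlap_frac):
            continue
        # covering segments of the matching class
        covering = []
        for seg in sample.segments:
            if seg.chrom != chrom:
                continue
            if overlap_length(seg.start, seg.end, start, end) == 0:
                continue
            state = pick_altered_state(seg, sample.wgd)
            if state is None:
                continue
            if classify_scna(state.major, state.minor, sample.wgd) == cls:
                covering.append((seg, state,
                                 overlap_length(seg.start, seg.end, start, end)))
        if not covering:
            continue
        seg, state, _ = max(covering, key=lambda t: t[2])
        subclonal = (not seg.clonal) and state.fraction < 1.0
        if subclonal:
            cluster = _nearest_subclone(sample, state.fraction, clonal_band)
            present.append(PresentEvent(
                event.event_id, "subclonal", Timing.SUBCLONAL,
                cluster_id=cluster.cluster_id if cluster else None))
        else:
            if sample.wgd:
                timing = classify_wgd_timing(state.major, state.minor, cls)
            else:
                timing = Timing.CLONAL
            present.append(PresentEvent(event.event_id, "clonal", timing))

    return present
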