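"""Genome-wide copy-number state metrics and the genomic-instability model.

Subclonal segments are summarized as CCF-weighted expectations of their
allele-specific copy numbers.  Cohort subsets are compared on a union
segmentation (breakpoints pooled across all samples), per-segment, with
Wilcoxon rank-sum tests.  Per-sample burden metrics (PGA, ploidy, SNV/SV
counts, latency) and the aberrant copy-number-signature proportion feed a
multivariate linear model of genomic instability with VIF diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._intervals import overlap_length
from .core import Cohort, TumourSample, ValidationError
from .masks import FilterMask
from .ordering import enumerate_trees
from .stats import bh_fdr, ranksum_p

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedCN:
    """CCF-weighted expected allele-specific copy number of a segment."""

    major: float
    minor: float

    @property
    def total(self) -> float:
        return self.major + self.minor


def weighted_cn(segment) -> WeightedCN:
    """Expectation of (major, minor) over a segment's cellular states,
    weighted by their cell fractions."""
    major = sum(s.major * s.fraction for s in segment.states)
    minor = sum(s.minor * s.fraction for s in segment.states)
    return WeightedCN(major=major, minor=minor)


# ---------------------------------------------------------------------------
# Union segmentation and per-locus comparisons


@dataclass
class UnionProfiles:
    """Per-sample weighted copy numbers on the pooled breakpoint grid."""

    segments: list                  # (chrom, start, end)
    major: pd.DataFrame             # samples x segments (NaN = uncovered)
    minor: pd.DataFrame
    sample_ids: list

    @property
    def total(self) -> pd.DataFrame:
        return self.major + self.minor

    def lengths(self) -> np.ndarray:
        return np.array([end - start for _, start, end in self.segments])

    def mean_tracks(self, sample_ids=None) -> pd.DataFrame:
        ids = list(self.sample_ids if sample_ids is None else sample_ids)
        rows = []
        for i, (chrom, start, end) in enumerate(self.segments):
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "major": float(self.major.iloc[:, i].loc[ids].mean()),
                "minor": float(self.minor.iloc[:, i].loc[ids].mean()),
                "total": float(self.total.iloc[:, i].loc[ids].mean()),
            })
        return pd.DataFrame(rows)


def union_profiles(samples) -> UnionProfiles:
    """Build the union segmentation over all samples and evaluate each
    sample's weighted copy number on every union segment.

    Breakpoints are pooled per chromosome across samples; a sample's value
    on a union segment comes from its own segment covering it (NaN where
    the sample has no call)."""
    samples = list(samples)
    if not samples:
        raise ValidationError("no samples for union segmentation")
    breakpoints: dict[str, set] = {}
    for s in samples:
        for seg in s.segments:
            breakpoints.setdefault(seg.chrom, set()).update(
                (seg.start, seg.end))
    segments = []
    for chrom in sorted(breakpoints):
        points = sorted(breakpoints[chrom])
        for lo, hi in zip(points, points[1:]):
            segments.append((chrom, lo, hi))

    sample_ids = [s.sample_id for s in samples]
    major = np.full((len(samples), len(segments)), np.nan)
    minor = np.full_like(major, np.nan)
    seg_index: dict[str, list] = {}
    for i, (chrom, lo, hi) in enumerate(segments):
        seg_index.setdefault(chrom, []).append((lo, hi, i))
    for r, s in enumerate(samples):
        for seg in s.segments:
            wcn = weighted_cn(seg)
            for lo, hi, i in seg_index.get(seg.chrom, []):
                if lo >= seg.start and hi <= seg.end:
                    major[r, i] = wcn.major
                    minor[r, i] = wcn.minor
    return UnionProfiles(
        segments=segments,
        major=pd.DataFrame(major, index=sample_ids),
        minor=pd.DataFrame(minor, index=sample_ids),
        sample_ids=sample_ids)


def per_locus_tests(profiles: UnionProfiles, ids_a, ids_b,
                    support_frac: float = 0.25) -> pd.DataFrame:
    """Per union segment and per statistic (major/minor/total), two-sided
    Wilcoxon rank-sum between two subsets, BH across segments.

    Segments covered by fewer than ``support_frac`` of the samples in
    either subset are masked (tested values unreliable)."""
    ids_a, ids_b = list(ids_a), list(ids_b)
    out_rows = []
    stat_frames = {"major": profiles.major, "minor": profiles.minor,
                   "total": profiles.total}
    p_cols = {name: [] for name in stat_frames}
    for i, (chrom, start, end) in enumerate(profiles.segments):
        row = {"chrom": chrom, "start": start, "end": end}
        for name, frame in stat_frames.items():
            x = frame.iloc[:, i].loc[ids_a].dropna()
            y = frame.iloc[:, i].loc[ids_b].dropna()
            supported = (len(x) >= support_frac * len(ids_a)
                         and len(y) >= support_frac * len(ids_b))
            row[f"{name}_supported"] = supported
            row[f"{name}_effect"] = (float(x.mean() - y.mean())
                                     if supported else np.nan)
            p = ranksum_p(x, y) if supported and len(x) and len(y) else np.nan
            row[f"{name}_p"] = p
            p_cols[name].append(p)
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    for name, ps in p_cols.items():
        ps = np.asarray(ps, dtype=float)
        fdr = np.full_like(ps, np.nan)
        tested = ~np.isnan(ps)
        if tested.any():
            fdr[tested] = bh_fdr(ps[tested])
        out[f"{name}_fdr"] = fdr
    return out


# ---------------------------------------------------------------------------
# Locus amplification magnitude (MDM2-style)


def amplification_magnitude(sample: TumourSample, locus: tuple):
    """Weighted major copy number of gains at a gene locus.

    Each gained segment overlapping the locus contributes its weighted
    major copy number scaled by the fraction of the gene it covers (the
    gain length is overlap-restricted, hence capped at the gene size).
    Returns None when the sample has no gain at the locus."""
    from .events import SCNAClass, classify_scna, pick_altered_state

    chrom, start, end = locus
    gene_len = end - start
    magnitude = 0.0
    found = False
    for seg in sample.segments:
        if seg.chrom != chrom:
            continue
        overlap = overlap_length(seg.start, seg.end, start, end)
        if overlap == 0:
            continue
        state = pick_altered_state(seg, sample.wgd)
        if state is None:
            continue
        if classify_scna(state.major, state.minor, sample.wgd) != SCNAClass.GAIN:
            continue
        magnitude += weighted_cn(seg).major * overlap / gene_len
        found = True
    return magnitude if found else None


# ---------------------------------------------------------------------------
# Deviation, burden, latency


def _segment_autosome_lengths(sample: TumourSample,
                              mask: FilterMask | None):
    """(segment, unmasked autosomal length) pairs for a sample."""
    out = []
    for seg in sample.segments:
        if seg.chrom in ("chrX", "chrY"):
            continue
        if mask is None:
            length = seg.length
        else:
            length = sum(hi - lo
                         for lo, hi in mask.clip(seg.chrom, seg.start, seg.end))
        if length > 0:
            out.append((seg, length))
    return out


def cn_deviation(sample: TumourSample, mask: FilterMask | None = None) -> float:
    """Length-weighted mean absolute deviation of the weighted
    allele-specific copy number from the sample baseline (1+1, or 2+2
    after WGD): |major - b| + |minor - b| averaged over the unmasked
    autosomes."""
    baseline = 2.0 if sample.wgd else 1.0
    total_len = 0
    acc = 0.0
    for seg, length in _segment_autosome_lengths(sample, mask):
        wcn = weighted_cn(seg)
        acc += (abs(wcn.major - baseline) + abs(wcn.minor - baseline)) * length
        total_len += length
    if total_len == 0:
        return 0.0
    return acc / total_len


def latency(m_truncal: int, m_post: int, age_dx: float,
            acceleration: float = 1.0) -> float:
    """Years between the most recent common ancestor and diagnosis under a
    constant per-year mutation rate, optionally accelerated post-MRCA:
    L = age * m_post / (a * m_truncal + m_post)."""
    if acceleration <= 0:
        raise ValidationError("acceleration must be positive")
    if m_post == 0:
        return 0.0
    if m_truncal + m_post <= 0:
        raise ValidationError("need a positive mutation count")
    return age_dx * m_post / (acceleration * m_truncal + m_post)


def _post_mrca_mutations(sample: TumourSample) -> int:
    """Mutation count along the highest-CCF root-to-leaf subclonal path of
    one feasible phylogeny (greedy descent by child CCF)."""
    if len(sample.clusters) <= 1:
        return 0
    tree = enumerate_trees(sample.clusters)[0]
    ccf = {c.cluster_id: c.ccf for c in sample.clusters}
    muts = {c.cluster_id: c.n_mutations for c in sample.clusters}
    node = tree.root
    total = 0
    while True:
        children = tree.children(node)
        if not children:
            return total
        node = max(children, key=lambda c: ccf[c])
        total += muts[node]


@dataclass
class BurdenRecord:
    sample_id: str
    snv_count: int
    pga: float
    ploidy: float
    sv_count: int
    kataegis: int
    latency_years: float

    def __post_init__(self):
        if not 0.0 <= self.pga <= 1.0:
            raise ValidationError(f"PGA {self.pga} outside [0,1]")


def burden_metrics(sample: TumourSample, mask: FilterMask | None = None,
                   acceleration: float = 1.0) -> BurdenRecord:
    """Genome-state burden of one sample.

    PGA is the fraction of the (unmasked autosomal) genome whose rounded
    weighted copy number differs from 1+1 — the diploid baseline is kept
    for WGD samples too, so a duplication contributes to PGA.  Ploidy is
    the length-weighted mean total copy number.
    """
    total_len = 0
    altered_len = 0
    ploidy_acc = 0.0
    for seg, length in _segment_autosome_lengths(sample, mask):
        wcn = weighted_cn(seg)
        if (round(wcn.major), round(wcn.minor)) != (1, 1):
            altered_len += length
        ploidy_acc += wcn.total * length
        total_len += length
    pga = altered_len / total_len if total_len else 0.0
    ploidy = ploidy_acc / total_len if total_len else 2.0

    clonal = sample.clonal_cluster
    m_truncal = clonal.n_mutations if clonal else 0
    m_post = _post_mrca_mutations(sample)
    lat = latency(m_truncal, m_post, sample.age_dx, acceleration) \
        if (m_truncal + m_post) > 0 else 0.0
    return BurdenRecord(sample_id=sample.sample_id, snv_count=sample.snv_total,
                        pga=pga, ploidy=ploidy, sv_count=sample.sv_count,
                        kataegis=sample.kataegis_count, latency_years=lat)


def burden_table(cohort: Cohort, mask: FilterMask | None = None,
                 acceleration: float = 1.0) -> pd.DataFrame:
    rows = [vars(burden_metrics(s, mask, acceleration))
            for s in cohort.samples]
    return pd.DataFrame(rows).set_index("sample_id")


def burden_comparisons(burdens: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon comparisons of every burden metric
    between trajectories, BH across metrics within each pair."""
    metrics = ["snv_count", "pga", "ploidy", "sv_count", "kataegis",
               "latency_years"]
    groups = sorted({l for l in labels.values() if l != "UNCLASSIFIABLE"})
    rows = []
    for i, lab_a in enumerate(groups):
        for lab_b in groups[i + 1:]:
            ids_a = [s for s in burdens.index if labels.get(s) == lab_a]
            ids_b = [s for s in burdens.index if labels.get(s) == lab_b]
            ps = []
            for metric in metrics:
                x = burdens.loc[ids_a, metric].dropna()
                y = burdens.loc[ids_b, metric].dropna()
                ps.append(ranksum_p(x, y))
            fdrs = bh_fdr(np.nan_to_num(ps, nan=1.0))
            for metric, p, q in zip(metrics, ps, fdrs):
                rows.append({"group_a": lab_a, "group_b": lab_b,
                             "metric": metric, "p": p, "fdr": q})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Aberrant signature proportion and the instability regression


def aberrant_signature_proportion(activities: dict, wgd: bool):
    """Fraction of copy-number signature activity not attributable to the
    baseline signature (CN1 diploid baseline, CN2 after WGD).  Returns
    None when no CN signature activity is present."""
    cn = {k: v for k, v in activities.items() if k.startswith("CN")}
    total = sum(cn.values())
    if total <= 0:
        return None
    baseline = "CN2" if wgd else "CN1"
    return 1.0 - cn.get(baseline, 0.0) / total


@dataclass
class RegressionReport:
    params: pd.DataFrame            # coef, ci_low, ci_high, p per predictor
    vif: pd.Series
    correlations: pd.DataFrame
    model: object = field(repr=False, default=None)


def _design_matrix(cohort: Cohort, driver_genes) -> pd.DataFrame:
    rows = []
    for s in cohort.samples:
        mutated = {snv.gene for snv in s.snvs}
        row = {"purity": s.purity,
               "smoking": 1.0 if s.smoking == "ever" else 0.0,
               "ancestry_eur": 1.0 if s.ancestry == "EUR" else 0.0,
               "sex_male": 1.0 if s.sex == "M" else 0.0,
               "WGD": 1.0 if s.wgd else 0.0}
        for gene in driver_genes:
            row[gene] = 1.0 if gene in mutated else 0.0
        rows.append(row)
    return pd.DataFrame(rows, index=[s.sample_id for s in cohort.samples])


def instability_regression(cohort: Cohort, driver_genes,
                           response: pd.Series | None = None) -> RegressionReport:
    """OLS of the aberrant copy-number-signature proportion on driver-gene
    and WGD indicators plus purity, smoking, ancestry and sex; with
    per-predictor VIFs and the predictor correlation matrix.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = _design_matrix(cohort, driver_genes)
    if response is None:
        values = {}
        for s in cohort.samples:
            prop = aberrant_signature_proportion(s.signature_activities, s.wgd)
            if prop is not None:
                values[s.sample_id] = prop
        response = pd.Series(values)
    keep = [sid for sid in X.index if sid in response.index]
    X = X.loc[keep]
    y = response.loc[keep].astype(float)
    if len(X) <= X.shape[1] + 1:
        raise ValidationError("more predictors than samples")

    varying = X.loc[:, X.std(axis=0) > 0]
    dropped = sorted(set(X.columns) - set(varying.columns))
    if dropped:
        logger.info("dropping constant predictors: %s", ", ".join(dropped))
    X = varying
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [(a, b) for a in corr.index for b in corr.columns
                 if a < b and corr.loc[a, b] > 1 - 1e-9]
        raise ValidationError(f"rank-deficient design; collinear: {pairs}")

    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    params = pd.DataFrame({
        "coef": model.params, "ci_low": ci[0], "ci_high": ci[1],
        "p": model.pvalues})

    vifs = {}
    Xv = X.to_numpy()
    for j, col in enumerate(X.columns):
        others = np.delete(Xv, j, axis=1)
        aux = sm.OLS(Xv[:, j], sm.add_constant(others)).fit()
        r2 = min(aux.rsquared, 1 - 1e-12)
        vifs[col] = 1.0 / (1.0 - r2)
    return RegressionReport(params=params, vif=pd.Series(vifs),
                            correlations=X.corr(), model=model)
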