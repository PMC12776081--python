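"""Contingency-table statistics over discovered trajectories.

Every comparison follows the same scheme: build a 2x2 table (presence of
an item by a binary partition of samples, or clonal vs subclonal
occurrences), compute a two-tailed Fisher exact p-value with odds and risk
ratios, and adjust across the family of tests with Benjamini-Hochberg.
Pairwise event co-occurrence uses the hypergeometric distribution with the
positive and negative tails adjusted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

logger = logging.getLogger(__name__)

OR_HI = 3.0 / 2.0
OR_LO = 2.0 / 3.0
ALPHA = 0.05


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]: rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("empty table")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_two_tailed(table: Contingency2x2) -> float:
    """Exact two-sided Fisher p (sum of hypergeometric probabilities not
    exceeding that of the observed table)."""
    _, p = sps.fisher_exact(table.array, alternative="two-sided")
    return float(p)


def odds_ratio(table: Contingency2x2) -> float:
    """(a*d)/(b*c), with the Haldane-Anscombe 0.5 correction applied to
    every cell iff any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def risk_ratio(table: Contingency2x2) -> float:
    """(a/(a+b)) / (c/(c+d)); NaN when a margin row is empty."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        logger.warning("risk ratio undefined for empty row in %s", table)
        return float("nan")
    top = table.a / (table.a + table.b)
    bottom = table.c / (table.c + table.d)
    if bottom == 0:
        return float("inf") if top > 0 else float("nan")
    return float(top / bottom)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving with
    running-minimum enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0,1]")
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class EnrichmentResult:
    item_id: str
    table: Contingency2x2
    odds_ratio: float
    risk_ratio: float
    p: float
    fdr: float = float("nan")
    flagged: bool = False


def _enrich(item_id: str, table: Contingency2x2) -> EnrichmentResult:
    return EnrichmentResult(item_id=item_id, table=table,
                            odds_ratio=odds_ratio(table),
                            risk_ratio=risk_ratio(table),
                            p=fisher_two_tailed(table))


def _finalize(results, or_hi=OR_HI, or_lo=OR_LO, alpha=ALPHA):
    if not results:
        return results
    fdrs = bh_fdr([r.p for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
        r.flagged = (r.odds_ratio > or_hi or r.odds_ratio < or_lo) \
            and r.fdr < alpha
    return results


def event_enrichment(presence: pd.DataFrame, groups: dict,
                     contrast: tuple, or_hi: float = OR_HI,
                     or_lo: float = OR_LO, alpha: float = ALPHA) -> list:
    """Per-event presence/absence 2x2 between two sample groups.

    ``presence`` is a boolean samples x events frame; ``groups`` maps
    sample_id to a trajectory label; ``contrast`` is a pair of label
    collections defining the binary partition (e.g. SD vs both NSD
    trajectories combined).  Events substantially and significantly
    enriched (odds ratio beyond 3/2 or 2/3, FDR < alpha) are flagged.
    """
    labels_a, labels_b = ({x} if isinstance(x, str) else set(x)
                          for x in contrast)
    in_a = [s for s in presence.index if groups.get(s) in labels_a]
    in_b = [s for s in presence.index if groups.get(s) in labels_b]
    if not in_a or not in_b:
        raise ValidationError("a contrast group has no samples")
    results = []
    for event in presence.columns:
        col = presence[event].astype(bool)
        a = int(col.loc[in_a].sum())
        c = int(col.loc[in_b].sum())
        table = Contingency2x2(a, len(in_a) - a, c, len(in_b) - c)
        results.append(_enrich(event, table))
    return _finalize(results, or_hi, or_lo, alpha)


def demographic_comparison(cohort, labels: dict, factor: str,
                           level_a, level_b, trajectory_split: tuple,
                           sample_filter=None):
    """Association of a demographic factor with the trajectory split.

    Builds the 2x2 of factor level (rows) by trajectory side (columns,
    e.g. SD vs NSD-combined) over the optionally filtered samples, and
    returns the enrichment result plus the stacked per-level trajectory
    proportions.  ``factor`` is an attribute of the sample records
    (smoking / ancestry / sex / sbs4_positive).
    """
    side_a, side_b = ({x} if isinstance(x, (str, int)) else set(x)
                      for x in trajectory_split)
    counts = {level_a: [0, 0], level_b: [0, 0]}
    proportions: dict = {}
    for sample in cohort.samples:
        if sample_filter is not None and not sample_filter(sample):
            continue
        label = labels.get(sample.sample_id)
        if label is None or label == "UNCLASSIFIABLE":
            continue
        value = getattr(sample, factor)
        proportions.setdefault(value, {}).setdefault(label, 0)
        proportions[value][label] += 1
        if value not in counts:
            continue
        if label in side_a:
            counts[value][0] += 1
        elif label in side_b:
            counts[value][1] += 1
    if sum(counts[level_a]) == 0 or sum(counts[level_b]) == 0:
        raise ValidationError(
            f"factor level missing after filtering: {level_a!r}/{level_b!r}")
    table = Contingency2x2(counts[level_a][0], counts[level_a][1],
                           counts[level_b][0], counts[level_b][1])
    stacked = {
        value: {lab: cnt / sum(per.values()) for lab, cnt in per.items()}
        for value, per in proportions.items()}
    return _enrich(f"{factor}:{level_a}_vs_{level_b}", table), stacked


def driver_count_test(per_subset_genes: dict, universe_size: int = 72,
                      pooling: str = "union") -> list:
    """Per trajectory, Fisher test of the number of driver genes with
    SNVs in >= 3% of its samples against the other trajectories pooled.

    ``per_subset_genes`` maps trajectory label -> set of qualifying gene
    symbols.  Pooling of "the other two combined" is the union of their
    qualifying genes over the same universe (primary reading); the
    additive reading (summed counts over a doubled universe) is available
    with pooling="additive".
    """
    if pooling not in {"union", "additive"}:
        raise ValidationError(f"unknown pooling {pooling!r}")
    max_count = max(len(g) for g in per_subset_genes.values())
    if universe_size < max_count:
        raise ValidationError("universe smaller than a subset's gene count")
    results = []
    for label, genes in per_subset_genes.items():
        others = [g for lab, g in per_subset_genes.items() if lab != label]
        a, b = len(genes), universe_size - len(genes)
        if pooling == "union":
            pooled = len(set().union(*others)) if others else 0
            c, d = pooled, universe_size - pooled
        else:
            pooled = sum(len(g) for g in others)
            c, d = pooled, universe_size * len(others) - pooled
        results.append(_enrich(str(label), Contingency2x2(a, b, c, d)))
    return _finalize(results)


def cooccurrence(presence: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Pairwise positive/negative event associations by hypergeometric
    tails, BH-adjusted separately within each direction.

    For events A, B with marginals nA, nB and overlap j over N samples,
    the co-occurrence count under independence is hypergeometric;
    p_greater = P(X >= j) tests positive association and
    p_less = P(X <= j) tests mutual exclusivity.
    """
    events = list(presence.columns)
    if len(events) < 2:
        raise ValidationError("need >= 2 events for co-occurrence")
    X = presence.astype(bool).to_numpy()
    N = X.shape[0]
    rows = []
    for i in range(len(events)):
        for k in range(i + 1, len(events)):
            nA, nB = int(X[:, i].sum()), int(X[:, k].sum())
            j = int((X[:, i] & X[:, k]).sum())
            rv = sps.hypergeom(N, nA, nB)
            rows.append({
                "event_a": events[i], "event_b": events[k],
                "n_a": nA, "n_b": nB, "overlap": j,
                "expected": nA * nB / N,
                "p_greater": float(rv.sf(j - 1)),
                "p_less": float(rv.cdf(j)),
                "effect": j - nA * nB / N,
            })
    out = pd.DataFrame(rows)
    out["fdr_greater"] = bh_fdr(out["p_greater"])
    out["fdr_less"] = bh_fdr(out["p_less"])
    return out


def clonality_preference(event_clonality: dict) -> list:
    """Per-event preference to occur clonally vs subclonally within one
    trajectory.

    ``event_clonality`` maps event_id -> (n_clonal, n_subclonal) counts
    over the subset's samples.  Each event is compared against all other
    events pooled; OR > 1 marks a clonal preference.
    """
    if len(event_clonality) < 2:
        raise ValidationError("need >= 2 distinct events")
    total_c = sum(v[0] for v in event_clonality.values())
    total_s = sum(v[1] for v in event_clonality.values())
    results = []
    for event, (n_c, n_s) in event_clonality.items():
        table = Contingency2x2(n_c, n_s, total_c - n_c, total_s - n_s)
        results.append(_enrich(event, table))
    return _finalize(results, or_hi=1.0, or_lo=1.0)


def ranksum_p(x, y, exact_limit: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact when both samples are
    small and untied, normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(x.size, y.size) <= exact_limit
                         and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue)


def prewgd_proportion_test(rankings, labels: dict, label_a, label_b,
                           iteration: int = 0):
    """Per-WGD-sample fraction of events ordered before the duplication,
    compared between two trajectories by Wilcoxon rank-sum.

    Uses one ordering iteration: given fixed timing strata the pre-WGD
    count is iteration-invariant.  Returns (fractions by label, p).
    """
    per_label: dict = {label_a: [], label_b: []}
    for sid in rankings.sample_ids:
        label = labels.get(sid)
        if label not in per_label:
            continue
        order = rankings.rankings[(sid, iteration)].order
        if "WGD" not in order:
            continue
        position = order.index("WGD")
        n_events = len(order) - 1   # the duplication marker is not an event
        if n_events == 0:
            continue
        per_label[label].append(position / n_events)
    if not per_label[label_a] or not per_label[label_b]:
        logger.warning("a trajectory has no WGD samples; no test performed")
        return per_label, float("nan")
    return per_label, ranksum_p(per_label[label_a], per_label[label_b])


def signature_presence_test(activities: pd.DataFrame, groups: dict,
                            contrast: tuple) -> list:
    """Presence (activity > 0) of each mutational signature between two
    trajectory groups, Fisher + BH.  All-zero signatures are skipped."""
    labels_a, labels_b = ({x} if isinstance(x, str) else set(x)
                          for x in contrast)
    in_a = [s for s in activities.index if groups.get(s) in labels_a]
    in_b = [s for s in activities.index if groups.get(s) in labels_b]
    if not in_a or not in_b:
        raise ValidationError("a contrast group has no samples")
    results = []
    for signature in activities.columns:
        col = activities[signature] > 0
        if not col.any():
            logger.warning("signature %s has zero activity everywhere; "
                           "skipped", signature)
            continue
        a = int(col.loc[in_a].sum())
        c = int(col.loc[in_b].sum())
        table = Contingency2x2(a, len(in_a) - a, c, len(in_b) - c)
        results.append(_enrich(signature, table))
    return _finalize(results)


def results_frame(results) -> pd.DataFrame:
    """Tabulate enrichment results (volcano-plot ready)."""
    rows = []
    for r in results:
        rows.append({
            "item": r.item_id, "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d,
            "odds_ratio": r.odds_ratio, "risk_ratio": r.risk_ratio,
            "p": r.p, "fdr": r.fdr, "flagged": r.flagged,
            "log2_or": np.log2(r.odds_ratio) if r.odds_ratio > 0 else np.nan,
            "neg_log10_fdr": -np.log10(r.fdr) if r.fdr > 0 else np.inf,
        })
    return pd.DataFrame(rows)
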