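"""End-to-end orchestration: QC -> event catalog -> randomized orderings
-> Plackett-Luce mixture model selection -> trajectory assignment ->
per-subset re-discovery and aggregate orderings -> downstream statistics.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import genome as gn
from . import stats as st
from .core import Cohort, qc_filter
from .masks import FilterMask, default_grch38_mask, miniature_mask
from .ordering import CohortRankings, order_cohort
from .plackett import (UNCLASSIFIABLE, AggregateOrdering, KSelection,
                       TrajectoryAssignment, aggregate_ordering,
                       consolidate_assignments, select_k)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full trajectory-discovery run."""

    genome: str = "miniature"          # miniature | grch38
    mask_bed: str | None = None
    min_nrpcc: float = 10.0
    min_purity: float = 0.30
    bin_size: int = 1_000_000
    alpha: float = 0.05
    min_snv_prev: float = 0.03
    min_overlap_frac: float = 0.5
    clonal_band: float = 0.9
    n_iterations: int = 1000           # desk-profile runs use ~25
    k_max: int = 5
    k_fixed: int | None = None         # skip model selection when set
    n_restarts: int = 5
    pseudocount: float = 0.1
    seed: int = 0
    acceleration: float = 1.0
    run_stats: bool = True
    run_genome_state: bool = True

    def resolve_mask(self) -> FilterMask:
        if self.genome == "miniature":
            mask = miniature_mask()
        elif self.genome == "grch38":
            mask = default_grch38_mask()
        else:
            raise ValueError(f"unknown genome {self.genome!r}")
        if self.mask_bed:
            mask = FilterMask.from_bed(self.mask_bed, mask.chrom_lengths)
        return mask


@dataclass
class SubsetResult:
    label: int
    sample_ids: list
    catalog: ev.EventCatalog
    rankings: CohortRankings
    aggregate: AggregateOrdering


@dataclass
class PipelineResult:
    cohort: Cohort
    catalog: ev.EventCatalog
    rankings: CohortRankings
    selection: KSelection | None
    assignment: TrajectoryAssignment
    subsets: dict                       # label -> SubsetResult
    presence: pd.DataFrame              # samples x events (bool)
    stats: dict = field(default_factory=dict)
    genome_state: dict = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)


def discover_catalog(cohort: Cohort, mask: FilterMask,
                     config: PipelineConfig) -> ev.EventCatalog:
    regions = ev.scan_recurrent_scnas(cohort, mask,
                                      bin_size=config.bin_size,
                                      alpha=config.alpha)
    return ev.build_catalog(cohort, regions, cohort.driver_list,
                            min_snv_prev=config.min_snv_prev,
                            min_overlap_frac=config.min_overlap_frac)


def presence_matrix(cohort: Cohort, catalog: ev.EventCatalog,
                    config: PipelineConfig) -> pd.DataFrame:
    ids = catalog.event_ids
    rows = {}
    for sample in cohort.samples:
        present = {p.event_id
                   for p in ev.event_presence(
                       sample, catalog,
                       min_overlap_frac=config.min_overlap_frac,
                       clonal_band=config.clonal_band)}
        rows[sample.sample_id] = [e in present for e in ids]
    return pd.DataFrame.from_dict(rows, orient="index", columns=ids,
                                  dtype=bool)


def _per_iteration_orders(rankings: CohortRankings) -> dict:
    return {it: [rankings.rankings[(sid, it)].order
                 for sid in rankings.sample_ids]
            for it in range(rankings.n_iterations)}


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the full discovery pipeline on an in-memory cohort."""
    config = config or PipelineConfig()
    mask = config.resolve_mask()

    cohort = qc_filter(cohort, config.min_nrpcc, config.min_purity)
    logger.info("stage qc: %d samples retained", len(cohort))

    catalog = discover_catalog(cohort, mask, config)
    logger.info("stage catalog: %d events", len(catalog))

    rankings = order_cohort(cohort, catalog,
                            n_iterations=config.n_iterations,
                            seed=config.seed,
                            min_overlap_frac=config.min_overlap_frac,
                            clonal_band=config.clonal_band)
    logger.info("stage order: %d samples x %d iterations "
                "(%d unclassifiable)", len(rankings.sample_ids),
                config.n_iterations, len(rankings.unclassifiable))

    per_iter = _per_iteration_orders(rankings)
    items = catalog.event_ids
    selection = None
    if config.k_fixed is None:
        selection = select_k(per_iter, k_max=config.k_max, items=items,
                             n_restarts=config.n_restarts, seed=config.seed,
                             pseudocount=config.pseudocount)
        best_k = selection.best_k
        fits = {it: selection.fits[(it, best_k)] for it in per_iter}
        logger.info("stage select_k: K=%d (median BIC %s)", best_k,
                    {k: round(v, 1) for k, v in selection.median_bic.items()})
    else:
        from .plackett import fit_iterations
        best_k = config.k_fixed
        fits = fit_iterations(per_iter, best_k, items=items,
                              n_restarts=config.n_restarts,
                              seed=config.seed,
                              pseudocount=config.pseudocount)

    assignment = consolidate_assignments(fits, rankings.sample_ids,
                                         rankings.unclassifiable)

    # per-subset re-discovery: rebuild the catalog within each subset so
    # subset-specific events enter its trajectory, then re-order and
    # collate the aggregate ordering
    subsets = {}
    for label in range(best_k):
        members = assignment.members(label)
        if len(members) < 2:
            logger.warning("subset %d has %d samples; skipped",
                           label, len(members))
            continue
        sub_cohort = Cohort(
            samples=[cohort.sample(sid) for sid in members],
            driver_list=list(cohort.driver_list))
        sub_catalog = discover_catalog(sub_cohort, mask, config)
        sub_rankings = order_cohort(sub_cohort, sub_catalog,
                                    n_iterations=config.n_iterations,
                                    seed=config.seed + 1 + label,
                                    min_overlap_frac=config.min_overlap_frac,
                                    clonal_band=config.clonal_band)
        aggregate = aggregate_ordering(
            _per_iteration_orders(sub_rankings),
            n_samples=len(sub_rankings.sample_ids),
            pseudocount=config.pseudocount)
        subsets[label] = SubsetResult(label=label, sample_ids=members,
                                      catalog=sub_catalog,
                                      rankings=sub_rankings,
                                      aggregate=aggregate)

    presence = presence_matrix(cohort, catalog, config)
    result = PipelineResult(cohort=cohort, catalog=catalog,
                            rankings=rankings, selection=selection,
                            assignment=assignment, subsets=subsets,
                            presence=presence, config=config)

    if config.run_stats and len(subsets) >= 2:
        result.stats = _downstream_stats(result)
    if config.run_genome_state:
        result.genome_state = _genome_state(result, mask)
    return result


def _downstream_stats(result: PipelineResult) -> dict:
    labels = result.assignment.labels
    presence = result.presence.loc[
        [s for s in result.presence.index
         if labels.get(s) not in (None, UNCLASSIFIABLE)]]
    out = {}
    subset_labels = sorted(result.subsets)
    # pairwise and one-vs-rest event enrichment
    enrich = {}
    for label in subset_labels:
        rest = [l for l in subset_labels if l != label]
        if not rest:
            continue
        enrich[f"{label}_vs_rest"] = st.event_enrichment(
            presence, labels, ([label], rest))
    for i, la in enumerate(subset_labels):
        for lb in subset_labels[i + 1:]:
            enrich[f"{la}_vs_{lb}"] = st.event_enrichment(
                presence, labels, ([la], [lb]))
    out["event_enrichment"] = enrich
    out["cooccurrence"] = st.cooccurrence(presence)

    # per-subset clonality preference
    clon = {}
    for label, subset in result.subsets.items():
        counts: dict[str, list] = {}
        for sid in subset.rankings.sample_ids:
            for p in subset.rankings.presence[sid]:
                entry = counts.setdefault(p.event_id, [0, 0])
                entry[0 if p.clonality == "clonal" else 1] += 1
        counts = {e: tuple(v) for e, v in counts.items()}
        if len(counts) >= 2:
            clon[label] = st.clonality_preference(counts)
    out["clonality_preference"] = clon

    if len(subset_labels) >= 2:
        la, lb = subset_labels[0], subset_labels[1]
        out["prewgd"] = st.prewgd_proportion_test(result.rankings, labels,
                                                  la, lb)
    acts = pd.DataFrame({
        s.sample_id: s.signature_activities
        for s in result.cohort.samples}).T.fillna(0.0)
    if not acts.empty and len(subset_labels) >= 2:
        label = subset_labels[-1]
        rest = subset_labels[:-1]
        out["signature_presence"] = st.signature_presence_test(
            acts, labels, ([label], rest))
    return out


def _genome_state(result: PipelineResult, mask: FilterMask) -> dict:
    out = {}
    out["burden"] = gn.burden_table(result.cohort, mask,
                                    result.config.acceleration)
    out["burden_comparisons"] = gn.burden_comparisons(
        out["burden"], result.assignment.labels)
    if len(result.subsets) >= 2:
        profiles = gn.union_profiles(result.cohort.samples)
        out["profiles"] = profiles
        locus_tests = {}
        subset_labels = sorted(result.subsets)
        for i, la in enumerate(subset_labels):
            for lb in subset_labels[i + 1:]:
                locus_tests[(la, lb)] = gn.per_locus_tests(
                    profiles, result.subsets[la].sample_ids,
                    result.subsets[lb].sample_ids)
        out["per_locus_tests"] = locus_tests
    if any(s.signature_activities for s in result.cohort.samples):
        try:
            out["instability_regression"] = gn.instability_regression(
                result.cohort, result.cohort.driver_list[:12])
        except Exception as exc:   # regression is diagnostic, not fatal
            logger.warning("instability regression skipped: %s", exc)
    return out


# ---------------------------------------------------------------------------
# Serialization


def write_results(result: PipelineResult, out_dir: str):
    """Persist the main pipeline outputs as TSV/JSON under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)

    rows = [{"event_id": e.event_id, "kind": e.kind,
             "chrom": e.region[0] if e.region else "",
             "start": e.region[1] if e.region else "",
             "end": e.region[2] if e.region else "",
             "gene": e.gene or "", "prevalence": e.prevalence}
            for e in result.catalog]
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "catalog.tsv"),
                              sep="\t", index=False)

    assign_rows = []
    for i, sid in enumerate(result.assignment.sample_ids):
        row = {"sample_id": sid, "label": result.assignment.labels[sid]}
        for k in range(result.assignment.K):
            row[f"vote_{k}"] = result.assignment.votes[i, k]
        assign_rows.append(row)
    for sid in result.rankings.unclassifiable:
        assign_rows.append({"sample_id": sid, "label": UNCLASSIFIABLE})
    pd.DataFrame(assign_rows).to_csv(
        os.path.join(out_dir, "assignment.tsv"), sep="\t", index=False)

    for label, subset in result.subsets.items():
        rows = [{"event_id": e, **vals}
                for e, vals in subset.aggregate.table.items()]
        pd.DataFrame(rows).sort_values("median_rank").to_csv(
            os.path.join(out_dir, f"trajectory_{label}.tsv"),
            sep="\t", index=False)

    if result.selection is not None:
        with open(os.path.join(out_dir, "model_selection.json"), "w") as fh:
            json.dump({"best_k": result.selection.best_k,
                       "median_bic": result.selection.median_bic}, fh,
                      indent=2)

    result.presence.astype(int).to_csv(
        os.path.join(out_dir, "presence.tsv"), sep="\t")

    if "event_enrichment" in result.stats:
        for name, res in result.stats["event_enrichment"].items():
            st.results_frame(res).to_csv(
                os.path.join(out_dir, f"enrichment_{name}.tsv"),
                sep="\t", index=False)
    if "cooccurrence" in result.stats:
        result.stats["cooccurrence"].to_csv(
            os.path.join(out_dir, "cooccurrence.tsv"), sep="\t", index=False)
    if "burden" in result.genome_state:
        result.genome_state["burden"].to_csv(
            os.path.join(out_dir, "burden.tsv"), sep="\t")
        result.genome_state["burden_comparisons"].to_csv(
            os.path.join(out_dir, "burden_comparisons.tsv"),
            sep="\t", index=False)
    if "instability_regression" in result.genome_state:
        report = result.genome_state["instability_regression"]
        report.params.to_csv(os.path.join(out_dir, "regression.tsv"),
                             sep="\t")
        report.vif.to_frame("vif").to_csv(
            os.path.join(out_dir, "regression_vif.tsv"), sep="\t")
        report.correlations.to_csv(
            os.path.join(out_dir, "regression_correlations.tsv"), sep="\t")

    manifest = {"config": asdict(result.config),
                "n_samples": len(result.cohort),
                "n_events": len(result.catalog),
                "subsets": {str(l): len(s.sample_ids)
                            for l, s in result.subsets.items()},
                "unclassifiable": result.rankings.unclassifiable}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def sankey_counts(result: PipelineResult) -> pd.DataFrame:
    """Smoking x SBS4 x trajectory path counts (Sankey-style export)."""
    rows = []
    labels = result.assignment.labels
    for sample in result.cohort.samples:
        rows.append({"smoking": sample.smoking,
                     "sbs4": "SBS4+" if sample.sbs4_positive else "SBS4-",
                     "trajectory": labels.get(sample.sample_id,
                                              UNCLASSIFIABLE)})
    frame = pd.DataFrame(rows)
    return frame.value_counts().rename("n").reset_index()
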