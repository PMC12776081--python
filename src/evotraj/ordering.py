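"""Randomized within-sample total orders of somatic events.

Each sample's present events are ordered under hard constraints — clonal
before subclonal, early-clonal before WGD before late-clonal in duplicated
samples, ancestor subclones before their descendants — with uniform random
tie-breaking inside each unordered stratum.  Subclonal structure comes from
a phylogenetic tree over the mutation clusters that satisfies the
pigeonhole principle (sibling CCFs may not sum above their parent's CCF);
when several trees are feasible one is drawn uniformly.  The whole
procedure is repeated across iterations to integrate over this
stochasticity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Cohort, TumourSample, ValidationError
from .events import (CLONAL_CCF_BAND, EventCatalog, PresentEvent, Timing,
                     event_presence)

logger = logging.getLogger(__name__)

MAX_SUBCLONES = 8


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree over cluster ids as a child -> parent map."""

    root: str
    parent: tuple  # tuple of (child_id, parent_id), root excluded

    @property
    def parent_map(self) -> dict:
        return dict(self.parent)

    def children(self, cluster_id: str) -> list:
        return [c for c, p in self.parent if p == cluster_id]


@dataclass(frozen=True)
class SampleRanking:
    sample_id: str
    iteration: int
    order: tuple   # event_ids, earliest first

    def __len__(self):
        return len(self.order)


def enumerate_trees(clusters, clonal_band: float = CLONAL_CCF_BAND) -> list:
    """All pigeonhole-consistent trees rooted at the clonal cluster.

    The clonal cluster's CCF is treated as 1.0; every subclone's parent
    must have CCF >= its own and the CCFs of any node's direct children
    may not sum above the node's CCF.  Enumeration order is deterministic
    (subclones processed by descending CCF, parents in processing order).
    """
    if not clusters:
        raise ValidationError("no clusters to build a tree from")
    root = max(clusters, key=lambda c: c.ccf)
    subclones = sorted((c for c in clusters if c is not root),
                       key=lambda c: (-c.ccf, c.cluster_id))
    if len(subclones) > MAX_SUBCLONES:
        raise ValidationError(
            f"{len(subclones)} subclones exceed the enumeration guard of "
            f"{MAX_SUBCLONES}; merge clusters upstream")

    ccf = {c.cluster_id: c.ccf for c in subclones}
    ccf[root.cluster_id] = 1.0

    trees = []
    order = [root.cluster_id] + [c.cluster_id for c in subclones]

    def recurse(idx, parent_pairs, child_load):
        if idx == len(order):
            trees.append(PhyloTree(root=root.cluster_id,
                                   parent=tuple(parent_pairs)))
            return
        child = order[idx]
        for parent in order[:idx]:
            if ccf[parent] < ccf[child]:
                continue
            load = child_load.get(parent, 0.0) + ccf[child]
            if load > ccf[parent] + 1e-9:
                continue
            child_load[parent] = load
            parent_pairs.append((child, parent))
            recurse(idx + 1, parent_pairs, child_load)
            parent_pairs.pop()
            child_load[parent] = load - ccf[child]

    recurse(1, [], {})
    return trees


def _emit_subclonal(events_by_cluster: dict, tree: PhyloTree,
                    rng: np.random.Generator) -> list:
    """Random topological traversal: repeatedly pick, uniformly, a cluster
    whose ancestors are all emitted, and append its events in shuffled
    order."""
    children: dict[str, list] = {}
    indegree = {tree.root: 0}
    for child, parent in tree.parent:
        children.setdefault(parent, []).append(child)
        indegree[child] = 1
    emitted = []
    ready = [tree.root]
    while ready:
        idx = rng.integers(len(ready))
        cluster = ready.pop(int(idx))
        cluster_events = list(events_by_cluster.get(cluster, []))
        rng.shuffle(cluster_events)
        emitted.extend(cluster_events)
        for child in children.get(cluster, []):
            ready.append(child)
    return emitted


def order_sample(sample: TumourSample, present_events, rng,
                 trees: list | None = None,
                 iteration: int = 0) -> SampleRanking:
    """Draw one randomized total order of a sample's present events."""
    if not present_events:
        raise ValidationError(f"{sample.sample_id}: no events to order")

    early, late, clonal_flat, wgd_marker = [], [], [], []
    by_cluster: dict[str, list] = {}
    unplaced_subclonal = []
    for ev in present_events:
        if ev.timing is Timing.WGD:
            wgd_marker.append(ev.event_id)
        elif ev.timing is Timing.EARLY_CLONAL:
            early.append(ev.event_id)
        elif ev.timing is Timing.LATE_CLONAL:
            late.append(ev.event_id)
        elif ev.timing is Timing.CLONAL:
            clonal_flat.append(ev.event_id)
        else:  # subclonal
            if ev.cluster_id is None:
                unplaced_subclonal.append(ev.event_id)
            else:
                by_cluster.setdefault(ev.cluster_id, []).append(ev.event_id)

    order = []
    if wgd_marker:
        rng.shuffle(early)
        rng.shuffle(late)
        order.extend(early)
        order.extend(wgd_marker)
        order.extend(late)
        rest = clonal_flat  # clonal events without WGD timing (none expected)
        rng.shuffle(rest)
        order.extend(rest)
    else:
        clonal = early + late + clonal_flat
        rng.shuffle(clonal)
        order.extend(clonal)

    if by_cluster or unplaced_subclonal:
        known = {c.cluster_id for c in sample.clusters}
        for cluster_id in by_cluster:
            if cluster_id not in known:
                raise ValidationError(
                    f"{sample.sample_id}: event references unknown cluster "
                    f"{cluster_id!r}")
        if trees is None:
            trees = enumerate_trees(sample.clusters)
        tree = trees[int(rng.integers(len(trees)))]
        # events whose subclone could not be resolved ride along with a
        # uniformly chosen subclone (after all clonal events)
        if unplaced_subclonal:
            subclone_ids = [c for c, _ in tree.parent] or [tree.root]
            for event_id in unplaced_subclonal:
                target = subclone_ids[int(rng.integers(len(subclone_ids)))]
                by_cluster.setdefault(target, []).append(event_id)
        order.extend(_emit_subclonal(by_cluster, tree, rng))

    return SampleRanking(sample_id=sample.sample_id, iteration=iteration,
                         order=tuple(order))


@dataclass
class CohortRankings:
    """Rankings indexed by (sample_id, iteration), plus samples excluded
    for carrying none of the catalog events."""

    rankings: dict
    sample_ids: list
    unclassifiable: list
    n_iterations: int
    presence: dict = field(default_factory=dict)

    def iteration(self, it: int) -> list:
        return [self.rankings[(sid, it)] for sid in self.sample_ids]


def order_cohort(cohort: Cohort, catalog: EventCatalog,
                 n_iterations: int = 1000, seed: int = 0,
                 min_overlap_frac: float = 0.5,
                 clonal_band: float = CLONAL_CCF_BAND) -> CohortRankings:
    """Randomized orderings for every sample across iterations.

    RNG streams are keyed by (seed, sample index, iteration) so results
    are reproducible and independent of execution order.  Samples with no
    present events are flagged unclassifiable and excluded.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    rankings = {}
    sample_ids, unclassifiable = [], []
    presence = {}
    for idx, sample in enumerate(cohort.samples):
        present = event_presence(sample, catalog,
                                 min_overlap_frac=min_overlap_frac,
                                 clonal_band=clonal_band)
        if not present:
            unclassifiable.append(sample.sample_id)
            continue
        presence[sample.sample_id] = present
        sample_ids.append(sample.sample_id)
        trees = enumerate_trees(sample.clusters) if sample.clusters else None
        for it in range(n_iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(idx, it)))
            rankings[(sample.sample_id, it)] = order_sample(
                sample, present, rng, trees=trees, iteration=it)
    if unclassifiable:
        logger.info("%d samples carry no catalog events and are "
                    "unclassifiable: %s", len(unclassifiable),
                    ", ".join(unclassifiable))
    return CohortRankings(rankings=rankings, sample_ids=sample_ids,
                          unclassifiable=unclassifiable,
                          n_iterations=n_iterations, presence=presence)
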