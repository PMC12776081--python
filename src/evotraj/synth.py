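"""Synthetic tumour cohorts with planted evolutionary trajectories.

The generator emulates the statistical structure the ordering pipeline
consumes — allele-specific copy-number segments, driver-SNV calls linked
to subclonal clusters with pigeonhole-consistent CCFs, WGD placement, and
correlated demographics — on a miniature genome (22 x 100 Mb) so that full
pipeline runs take seconds.  Three default archetypes mirror the broad
trajectory shapes seen in lung adenocarcinoma: a WGD-rich loss-dominated
path, a gain-dominated mostly-diploid path, and a smoking-like path with
many early driver mutations; each archetype carries its own canonical
event order (realized per sample as a noisy Plackett-Luce draw), per-event
prevalences, WGD rate and demographic biases.  Generated cohorts always
pass the core validation, and each planted copy-number state is chosen so
the classify-then-time round trip recovers the intended class and pre- or
post-WGD timing.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (CNState, Cohort, CopyNumberSegment, SnvCall,
                   SubcloneCluster, TumourSample, ValidationError)
from .events import SCNAClass, Timing
from .masks import miniature_genome, miniature_mask

logger = logging.getLogger(__name__)

MB = 1_000_000

# copy-number states realized per (event class, WGD status, timing);
# chosen so classification and parsimony timing round-trip exactly
CLONAL_STATES = {
    (SCNAClass.GAIN, False): (2, 1),
    (SCNAClass.LOH, False): (1, 0),
    (SCNAClass.HD, False): (0, 0),
    (SCNAClass.GAIN, True, Timing.EARLY_CLONAL): (4, 2),
    (SCNAClass.GAIN, True, Timing.LATE_CLONAL): (3, 2),
    (SCNAClass.LOH, True, Timing.EARLY_CLONAL): (2, 0),
    (SCNAClass.HD, True, Timing.EARLY_CLONAL): (0, 0),
}
SUBCLONAL_STATES = {
    (SCNAClass.GAIN, False): (3, 1),
    (SCNAClass.LOH, False): (1, 0),
    (SCNAClass.HD, False): (0, 0),
    (SCNAClass.GAIN, True): (6, 2),
    (SCNAClass.LOH, True): (2, 0),
    (SCNAClass.HD, True): (0, 0),
}


def default_driver_list() -> list:
    """The bundled 72-gene putative driver list."""
    text = importlib.resources.files("evotraj.data") \
        .joinpath("driver_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class PlantedEvent:
    event_id: str
    kind: str                       # GAIN | LOH | HD | SNV | WGD
    region: tuple | None = None
    gene: str | None = None


@dataclass
class ArchetypeSpec:
    """One planted trajectory: a canonical event order with decaying
    Plackett-Luce worths, per-event carry probabilities, WGD behaviour
    and demographic/burden biases."""

    label: str
    events: list                    # PlantedEvent, shared across archetypes
    canonical_order: list           # event_ids (WGD included when carried)
    worths: np.ndarray              # one per canonical_order entry, > 0
    prevalence: dict                # event_id -> carry probability
    wgd_rate: float
    demographic_bias: dict = field(default_factory=dict)
    burden: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.canonical_order) != len(self.worths):
            raise ValidationError("one worth per canonical-order event")
        if np.any(np.asarray(self.worths) <= 0):
            raise ValidationError("worths must be strictly positive")
        for p in self.prevalence.values():
            if not 0.0 < p <= 1.0:
                raise ValidationError("prevalence must lie in (0,1]")


@dataclass
class TruthRecord:
    sample_id: str
    label: str
    tree_parent: dict               # cluster_id -> parent cluster_id
    event_info: dict                # event_id -> (clonality, Timing, cluster)

    def canonical_rank(self, archetype: ArchetypeSpec) -> dict:
        order = archetype.canonical_order
        return {e: i for i, e in enumerate(order)}


def _scna_slots(genome: dict, region_mb: int = 16):
    """Disjoint unmasked candidate loci for SCNA events: one window on
    each arm of each miniature chromosome (acrocentric-like p-arms and
    the HLA-bearing window are skipped)."""
    acro = {"chr13", "chr14", "chr15", "chr21", "chr22"}
    slots = []
    for chrom in genome:
        if chrom not in acro:
            start = 32 * MB if chrom == "chr6" else 10 * MB
            slots.append((chrom, start, start + region_mb * MB))
        slots.append((chrom, 60 * MB, (60 + region_mb) * MB))
    return slots


def build_event_set(n_events: int = 30, genome: dict | None = None) -> list:
    """The shared planted event catalog: one WGD, ~40% driver-gene SNVs,
    the rest SCNA loci (alternating LOH / GAIN, one HD)."""
    if n_events < 10:
        raise ValidationError("need n_events >= 10")
    genome = genome or miniature_genome()
    n_snv = max(4, round(0.4 * (n_events - 1)))
    n_scna = n_events - 1 - n_snv
    genes = default_driver_list()[:n_snv]
    slots = _scna_slots(genome)
    if n_scna > len(slots):
        raise ValidationError(
            f"only {len(slots)} SCNA loci available on this genome")

    events = [PlantedEvent(f"SNV_{g}", "SNV", gene=g) for g in genes]
    kinds = []
    for i in range(n_scna):
        if i == n_scna - 1:
            kinds.append("HD")
        elif i % 2 == 0:
            kinds.append("LOH")
        else:
            kinds.append("GAIN")
    for kind, (chrom, start, end) in zip(kinds, slots):
        events.append(PlantedEvent(
            f"{kind}_{chrom}_{start // MB}_{end // MB}Mb", kind,
            region=(chrom, start, end)))
    events.append(PlantedEvent("WGD", "WGD"))
    return events


def _decaying_worths(n: int, ratio: float = 0.7) -> np.ndarray:
    w = ratio ** np.arange(n)
    return w / w.sum()


def default_archetypes(n_events: int = 30, seed: int = 0,
                       wgd_rates=(0.87, 0.31, 0.70)) -> list:
    """Three trajectory archetypes over a shared event set.

    * ``loss`` — WGD in 87% of samples, placed early; losses dominate the
      early order with gains late and at low prevalence.
    * ``gain`` — mostly diploid (WGD rate 31%, placed late); early
      frequent gains.
    * ``smoking`` — many early driver SNVs and the rotated loss block
      first among SCNAs; WGD early where present.
    """
    del seed  # archetype construction is deterministic; kept for interface
    events = build_event_set(n_events)
    snvs = [e.event_id for e in events if e.kind == "SNV"]
    losses = [e.event_id for e in events if e.kind == "LOH"]
    gains = [e.event_id for e in events if e.kind == "GAIN"]
    hds = [e.event_id for e in events if e.kind == "HD"]

    # characteristic early driver mutations per trajectory: the loss- and
    # gain-dominated paths share a small EGFR/TP53-style core, while the
    # smoking-like path is driver-rich with a distinct KRAS/STK11-style core
    n_core = min(3, len(snvs))
    loss_top = [snvs[i] for i in (0, 1, 4) if i < len(snvs)][:n_core]
    gain_top = [snvs[i] for i in (1, 0, 6) if i < len(snvs)][:n_core]
    smoke_top = [snvs[i] for i in (0, 2, 3, 5) if i < len(snvs)]
    loss_rest = [s for s in snvs if s not in loss_top]
    gain_rest = [s for s in snvs if s not in gain_top]
    smoke_rest = [s for s in snvs if s not in smoke_top]

    half_g = max(1, len(gains) // 2)
    rev_l = losses[::-1]

    # the loss-dominated and smoking-like paths share their high-prevalence
    # loss events but traverse them in opposite order, and place the
    # homozygous deletion post- vs pre-WGD — mirroring trajectories that
    # agree on content yet disagree on ordering
    orders = {
        "loss": (loss_top + losses[:3] + ["WGD"] + losses[3:] + hds
                 + loss_rest + gains),
        "gain": (gain_top + gains[:half_g] + losses[:2] + gains[half_g:]
                 + gain_rest + ["WGD"] + losses[2:] + hds),
        "smoking": (smoke_top + smoke_rest + rev_l[:2] + hds + ["WGD"]
                    + rev_l[2:] + gains),
    }

    # carry probabilities per block: each trajectory is dominated by its
    # characteristic events; the smoking-like path carries many driver
    # SNVs at moderate rates (the driver-count asymmetry), the others few
    prevalence_blocks = {
        "loss": [(loss_top, 0.85), (losses, 0.80), (hds, 0.40),
                 (loss_rest, 0.08), (gains, 0.25)],
        "gain": [(gain_top, 0.80), (gains, 0.80), (losses[:2], 0.50),
                 (losses[2:], 0.12), (gain_rest, 0.08), (hds, 0.10)],
        "smoking": [(smoke_top, 0.75), (smoke_rest, 0.50),
                    (rev_l[:2], 0.80), (rev_l[2:], 0.65), (hds, 0.40),
                    (gains, 0.20)],
    }

    def prevalences(label):
        prev = {}
        for block, p in prevalence_blocks[label]:
            for event_id in block:
                prev.setdefault(event_id, p)
        return prev

    bias = {
        "loss": {"smoking": {"never": 0.95, "ever": 0.05},
                 "ancestry": {"EUR": 0.45, "EAS": 0.48, "OTHER": 0.07},
                 "sex": {"F": 0.72, "M": 0.28}},
        "gain": {"smoking": {"never": 0.92, "ever": 0.08},
                 "ancestry": {"EUR": 0.48, "EAS": 0.45, "OTHER": 0.07},
                 "sex": {"F": 0.70, "M": 0.30}},
        "smoking": {"smoking": {"never": 0.35, "ever": 0.65},
                    "ancestry": {"EUR": 0.75, "EAS": 0.18, "OTHER": 0.07},
                    "sex": {"F": 0.45, "M": 0.55}},
    }
    burden = {
        # truncal / per-subclone mutation means set the latency scale;
        # sv means reflect the loss-trajectory's higher SV burden
        "loss": {"m_truncal": 5000, "m_sub": 1400, "sv_mean": 120,
                 "kataegis_mean": 4, "aberrant_beta": (4, 3),
                 "sv_sigs": {"SV4": 0.5, "SV6": 0.4, "SV5": 0.1}},
        "gain": {"m_truncal": 5200, "m_sub": 1200, "sv_mean": 60,
                 "kataegis_mean": 3, "aberrant_beta": (3, 4),
                 "sv_sigs": {"SV4": 0.4, "SV6": 0.35, "SV5": 0.12}},
        "smoking": {"m_truncal": 13000, "m_sub": 1500, "sv_mean": 80,
                    "kataegis_mean": 5, "aberrant_beta": (2, 5),
                    "sv_sigs": {"SV4": 0.1, "SV6": 0.1, "SV5": 0.55}},
    }

    specs = []
    for label, rate in zip(("loss", "gain", "smoking"), wgd_rates):
        order = orders[label]
        specs.append(ArchetypeSpec(
            label=label, events=events, canonical_order=list(order),
            worths=_decaying_worths(len(order)),
            prevalence=prevalences(label), wgd_rate=rate,
            demographic_bias=bias[label], burden=burden[label]))
    return specs


# ---------------------------------------------------------------------------
# Sampling machinery


def _pl_draw(event_ids, worths, rng, noise: float):
    """Sequential Plackett-Luce draw of a total order; ``noise`` in [0,1]
    flattens the worths towards uniform (1 = fully random)."""
    w = np.asarray([worths[e] for e in event_ids], dtype=float)
    w = np.power(w, 1.0 - noise)
    remaining = list(range(len(event_ids)))
    order = []
    while remaining:
        probs = w[remaining] / w[remaining].sum()
        pick = rng.choice(len(remaining), p=probs)
        order.append(event_ids[remaining.pop(int(pick))])
    return order


def _choose(rng, table: dict):
    levels = list(table)
    probs = np.array([table[l] for l in levels], dtype=float)
    return levels[int(rng.choice(len(levels), p=probs / probs.sum()))]


def _build_clusters(n_sub: int, rng, branch_prob: float = 0.1,
                    m_truncal: int = 5000, m_sub: int = 1200):
    """Clonal cluster plus a (mostly chain) subclone phylogeny built by
    stick-breaking, guaranteeing pigeonhole feasibility and distinct CCFs.

    Child CCFs take a large fraction of the parent budget so that most
    alternative attachments would violate the pigeonhole constraint: the
    resulting phylogeny is usually the unique feasible tree, as in
    well-powered subclonal reconstructions."""
    for _ in range(20):
        clonal_ccf = float(rng.uniform(0.95, 1.0))
        clusters = [SubcloneCluster("clonal", clonal_ccf,
                                    int(rng.poisson(m_truncal)) + 1)]
        parent = {}
        ccfs = {"clonal": clonal_ccf}
        budget = {"clonal": clonal_ccf}
        prev = "clonal"
        for i in range(1, n_sub + 1):
            cid = f"sub{i}"
            attach = prev
            if i > 1 and rng.random() < branch_prob:
                attach = "clonal" if budget["clonal"] > 0.15 else prev
            ccf = float(budget[attach] * rng.uniform(0.55, 0.8))
            if ccf <= 0.01 or ccf >= 0.9:
                break
            budget[attach] -= ccf
            budget[cid] = ccf
            ccfs[cid] = ccf
            parent[cid] = attach
            clusters.append(SubcloneCluster(cid, ccf,
                                            int(rng.poisson(m_sub)) + 1))
            prev = cid
        if len(clusters) == n_sub + 1 and \
                len({round(c.ccf, 6) for c in clusters}) == len(clusters):
            return clusters, parent
    raise ValidationError("could not build a feasible subclone phylogeny")


def _realize_segments(carried_scnas: dict, wgd: bool, ccfs: dict,
                      genome: dict):
    """Segments for the carried SCNA events plus baseline filler tiling
    the rest of every chromosome."""
    baseline = (2, 2) if wgd else (1, 1)
    by_chrom: dict[str, list] = {c: [] for c in genome}
    for event, (clonality, timing, cluster_id) in carried_scnas.items():
        chrom, start, end = event.region
        cls = SCNAClass(event.kind)
        if clonality == "clonal":
            key = (cls, True, timing) if wgd else (cls, False)
            major, minor = CLONAL_STATES[key]
            states = (CNState(major, minor, 1.0),)
        else:
            major, minor = SUBCLONAL_STATES[(cls, wgd)]
            frac = ccfs[cluster_id]
            states = (CNState(major, minor, frac),
                      CNState(baseline[0], baseline[1], 1.0 - frac))
        by_chrom[chrom].append(CopyNumberSegment(chrom, start, end, states))

    segments = []
    for chrom, length in genome.items():
        placed = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        cursor = 0
        for seg in placed:
            if seg.start > cursor:
                segments.append(CopyNumberSegment(
                    chrom, cursor, seg.start,
                    (CNState(baseline[0], baseline[1], 1.0),)))
            segments.append(seg)
            cursor = seg.end
        if cursor < length:
            segments.append(CopyNumberSegment(
                chrom, cursor, length,
                (CNState(baseline[0], baseline[1], 1.0),)))
    return segments


def _signature_activities(rng, archetype: ArchetypeSpec, wgd: bool,
                          sbs4: bool, mutated: set) -> dict:
    a, b = archetype.burden["aberrant_beta"]
    aberrant = float(rng.beta(a, b))
    # driver-linked instability: EGFR pushes copy-number activity up,
    # KRAS suppresses it
    if "EGFR" in mutated:
        aberrant = min(0.95, aberrant + 0.18)
    if "KRAS" in mutated:
        aberrant = max(0.02, aberrant - 0.15)
    total_cn = float(rng.uniform(80, 160))
    baseline_sig = "CN2" if wgd else "CN1"
    other_sig = "CN9" if rng.random() < 0.5 else "CN17"
    acts = {baseline_sig: total_cn * (1 - aberrant),
            other_sig: total_cn * aberrant}
    acts["SBS1"] = float(rng.uniform(200, 800))
    if sbs4:
        acts["SBS4"] = float(rng.uniform(1000, 6000))
    for sig, prob in archetype.burden["sv_sigs"].items():
        if rng.random() < prob:
            acts[sig] = float(rng.gamma(2.0, 15.0))
    return acts


def simulate_sample(archetype: ArchetypeSpec, sample_id: str, rng,
                    noise: float = 0.1, genome: dict | None = None,
                    clonal_frac_beta=(3.0, 2.0)):
    """Generate one sample from an archetype; returns (sample, truth)."""
    genome = genome or miniature_genome()
    worths = dict(zip(archetype.canonical_order, archetype.worths))
    events_by_id = {e.event_id: e for e in archetype.events}

    wgd = bool(rng.random() < archetype.wgd_rate)
    carried = [e for e in archetype.canonical_order
               if e != "WGD" and rng.random() < archetype.prevalence[e]]
    if not carried:
        carried = [archetype.canonical_order[0]]
    if wgd:
        carried.append("WGD")

    order = _pl_draw(carried, worths, rng, noise)

    # clonal/subclonal split along the drawn order
    n_total = len(order)
    clonal_frac = float(rng.beta(*clonal_frac_beta))
    n_clonal = max(1, int(round(clonal_frac * n_total)))
    if wgd and order.index("WGD") >= n_clonal:
        order.remove("WGD")
        order.insert(n_clonal - 1, "WGD")
    clonal_part, subclonal_part = order[:n_clonal], order[n_clonal:]

    if wgd:
        wgd_pos = clonal_part.index("WGD")
        # a clonal LOH or HD in a duplicated genome is parsimony-timed
        # pre-WGD, so a loss drawn after the duplication cannot be realized
        # as a late-clonal state of its class: it becomes subclonal instead
        early = clonal_part[:wgd_pos]
        late = []
        demoted = []
        for event_id in clonal_part[wgd_pos + 1:]:
            if events_by_id[event_id].kind in ("LOH", "HD"):
                demoted.append(event_id)
            else:
                late.append(event_id)
        subclonal_part = demoted + subclonal_part
        clonal_part = early + ["WGD"] + late
        timing_of = {e: Timing.EARLY_CLONAL for e in early}
        timing_of.update({e: Timing.LATE_CLONAL for e in late})
        timing_of["WGD"] = Timing.WGD
    else:
        timing_of = {e: Timing.CLONAL for e in clonal_part}

    # subclones: consecutive subclonal events share a cluster
    n_sub = min(5, len(subclonal_part))
    clusters, parent = _build_clusters(
        n_sub, rng, m_truncal=archetype.burden["m_truncal"],
        m_sub=archetype.burden["m_sub"])
    ccfs = {c.cluster_id: c.ccf for c in clusters}
    cluster_of = {}
    if subclonal_part:
        chunks = np.array_split(np.arange(len(subclonal_part)), n_sub)
        for k, chunk in enumerate(chunks, start=1):
            for idx in chunk:
                cluster_of[subclonal_part[idx]] = f"sub{k}"

    carried_scnas, snvs = {}, []
    event_info = {}
    for event_id in order:
        event = events_by_id[event_id]
        if event_id in cluster_of:
            clonality, timing = "subclonal", Timing.SUBCLONAL
            cluster_id = cluster_of[event_id]
        else:
            clonality, timing = "clonal", timing_of[event_id]
            cluster_id = "clonal"
        event_info[event_id] = (clonality, timing, cluster_id)
        if event.kind == "WGD":
            continue
        if event.kind == "SNV":
            mult = 2 if (wgd and timing is Timing.EARLY_CLONAL) else 1
            snvs.append(SnvCall(event.gene, cluster_id, mult))
        else:
            carried_scnas[event] = (clonality, timing, cluster_id)

    segments = _realize_segments(carried_scnas, wgd, ccfs, genome)

    smoking = _choose(rng, archetype.demographic_bias["smoking"])
    ancestry = _choose(rng, archetype.demographic_bias["ancestry"])
    sex = _choose(rng, archetype.demographic_bias["sex"])
    sbs4 = bool(rng.random() < (0.90 if smoking == "ever" else 0.04))
    mutated = {s.gene for s in snvs}

    sample = TumourSample(
        sample_id=sample_id,
        purity=float(rng.uniform(0.35, 0.95)),
        nrpcc=float(rng.uniform(10.0, 40.0)),
        wgd=wgd, smoking=smoking, ancestry=ancestry, sex=sex,
        age_dx=float(np.clip(rng.normal(66, 9), 35, 90)),
        sbs4_positive=sbs4,
        segments=segments, snvs=snvs, clusters=clusters,
        sv_count=int(rng.poisson(archetype.burden["sv_mean"])),
        kataegis_count=int(rng.poisson(archetype.burden["kataegis_mean"])),
        snv_total=sum(c.n_mutations for c in clusters),
        survival_weeks=float(rng.uniform(30, 500)),
        signature_activities=_signature_activities(
            rng, archetype, wgd, sbs4, mutated),
    )
    truth = TruthRecord(sample_id=sample_id, label=archetype.label,
                        tree_parent=parent, event_info=event_info)
    return sample, truth


def simulate_cohort(archetypes=None, n_per_archetype: int = 100,
                    seed: int = 0, noise: float = 0.1,
                    genome: dict | None = None,
                    inject_unclassifiable: bool = False):
    """A full synthetic cohort: ``n_per_archetype`` samples drawn from each
    archetype, with truth records for every sample."""
    if n_per_archetype < 1:
        raise ValidationError("n_per_archetype must be >= 1")
    if not 0.0 <= noise <= 1.0:
        raise ValidationError("noise must lie in [0,1]")
    archetypes = archetypes or default_archetypes()
    genome = genome or miniature_genome()
    samples, truths = [], []
    for a_idx, archetype in enumerate(archetypes):
        for i in range(n_per_archetype):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(a_idx, i)))
            sid = f"{archetype.label}_{i:04d}"
            sample, truth = simulate_sample(archetype, sid, rng,
                                            noise=noise, genome=genome)
            samples.append(sample)
            truths.append(truth)
    if inject_unclassifiable:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
        baseline = [(c, 0, L, (CNState(1, 1, 1.0),))
                    for c, L in genome.items()]
        samples.append(TumourSample(
            sample_id="unclassifiable_0000",
            purity=float(rng.uniform(0.35, 0.95)),
            nrpcc=float(rng.uniform(10, 40)), wgd=False,
            segments=[CopyNumberSegment(*args) for args in baseline],
            clusters=[SubcloneCluster("clonal", 0.98, 5000)],
            snv_total=5000))
        truths.append(TruthRecord("unclassifiable_0000", "none", {}, {}))
    cohort = Cohort(samples=samples, driver_list=default_driver_list(),
                    provenance={"generator": "evotraj.synth", "seed": seed,
                                "noise": noise,
                                "n_per_archetype": n_per_archetype})
    return cohort, truths


def perturb_orderings(cohort: Cohort, swap_rate: float, seed: int = 0) -> Cohort:
    """Stress fixture: swap the event payloads of adjacent subclone depths
    at the given rate (CCFs, and hence pigeonhole feasibility, untouched)."""
    if not 0.0 <= swap_rate <= 1.0:
        raise ValidationError("swap_rate must lie in [0,1]")
    new_samples = []
    for s_idx, sample in enumerate(cohort.samples):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(s_idx,)))
        subclones = sorted((c for c in sample.clusters
                            if c.cluster_id != "clonal"),
                           key=lambda c: -c.ccf)
        swap_map = {}
        for a, b in zip(subclones, subclones[1:]):
            if rng.random() < swap_rate:
                swap_map[a.cluster_id] = b.cluster_id
                swap_map[b.cluster_id] = a.cluster_id
        if not swap_map:
            new_samples.append(sample)
            continue
        ccfs = {c.cluster_id: c.ccf for c in sample.clusters}
        new_snvs = [SnvCall(v.gene, swap_map.get(v.cluster_id, v.cluster_id),
                            v.multiplicity) for v in sample.snvs]
        new_segments = []
        for seg in sample.segments:
            if seg.clonal:
                new_segments.append(seg)
                continue
            altered, baseline_state = seg.states
            # remap the altered-state fraction to the swapped cluster's CCF
            old = min(ccfs, key=lambda c: abs(ccfs[c] - altered.fraction))
            target = swap_map.get(old, old)
            frac = ccfs[target]
            new_segments.append(CopyNumberSegment(
                seg.chrom, seg.start, seg.end,
                (CNState(altered.major, altered.minor, frac),
                 CNState(baseline_state.major, baseline_state.minor,
                         1.0 - frac))))
        new_samples.append(TumourSample(
            sample_id=sample.sample_id, purity=sample.purity,
            nrpcc=sample.nrpcc, wgd=sample.wgd, smoking=sample.smoking,
            ancestry=sample.ancestry, sex=sample.sex, age_dx=sample.age_dx,
            sbs4_positive=sample.sbs4_positive, segments=new_segments,
            snvs=new_snvs, clusters=list(sample.clusters),
            sv_count=sample.sv_count, kataegis_count=sample.kataegis_count,
            snv_total=sample.snv_total, survival_weeks=sample.survival_weeks,
            signature_activities=dict(sample.signature_activities)))
    return Cohort(samples=new_samples, driver_list=list(cohort.driver_list),
                  provenance=dict(cohort.provenance, swap_rate=swap_rate))


def match_planted_events(catalog, planted_events) -> dict:
    """Map discovered catalog event_ids to planted event_ids (same kind
    and overlapping region for SCNAs; gene identity for SNVs)."""
    from ._intervals import overlap_length

    mapping = {}
    for event in catalog:
        if event.kind == "WGD":
            mapping[event.event_id] = "WGD"
            continue
        for planted in planted_events:
            if planted.kind != event.kind:
                continue
            if event.kind == "SNV":
                if planted.gene == event.gene:
                    mapping[event.event_id] = planted.event_id
                    break
            else:
                c1, s1, e1 = event.region
                c2, s2, e2 = planted.region
                if c1 == c2 and overlap_length(s1, e1, s2, e2) > 0:
                    mapping[event.event_id] = planted.event_id
                    break
    return mapping
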