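# Methods

## Overview

`evotraj` discovers evolutionary trajectories in tumour cohorts de novo:
it builds a cohort-wide catalog of recurrent somatic events, draws
randomized within-tumour total orders of each sample's events under hard
biological constraints, clusters those orders with Plackett-Luce (PL)
mixture models, and summarizes each discovered subset with an aggregate
event ordering and a battery of contingency statistics. Because the
matched whole-genome data that motivates this design are access
controlled, the package ships a synthetic-cohort generator that plants
known trajectories with full CCF/WGD/demographic structure, so every
stage is testable end to end.

## Event catalog

Allele-specific copy-number segments (major + minor copies, up to two
cellular states per segment) are classed relative to the sample baseline
(1+1, or 2+2 after whole-genome duplication, WGD):

* **HD** — total copy number 0;
* **LOH** — minor allele 0 with total > 0 (LOH takes precedence over any
  total-based call);
* **GAIN** / **non-LOH loss** — total above / below the baseline total;
* **none** otherwise. A mixed state at the baseline total (e.g. 3+1 in a
  WGD sample) is "none": the five classes are mutually exclusive and LOH
  is the defining allele-level feature.

Recurrently altered loci are found per class (gains, LOH, HD — non-LOH
losses are classed but not scanned) by tiling the unmasked autosomes into
1 Mb bins and testing each bin's carrier count against an exact binomial
upper tail. The null rate is the cohort mean of each sample's genome
fraction carrying the class; Benjamini-Hochberg FDR < 0.05 is applied
across bins x classes; adjacent significant bins are merged and extended
to the union of the overlapping per-sample segments. The exact tail (not
a normal approximation) and the cohort-mean background are package
choices; the binomial null itself is the standard recurrence test in this
setting. The mask removes centromeres, 5 Mb telomeric pads, the HLA
region, acrocentric short arms (13/14/15/21/22) and the X/Y chromosomes
(sex-imbalanced cohorts would otherwise bias discovery); a default
GRCh38-like mask is built in and any mask can be supplied as BED.

Driver-gene SNVs from a configurable list (72 genes bundled) enter the
catalog when mutated in >= 3% of samples (inclusive), and WGD is one
catalog item of its own.

## Within-sample ordering

Each sample's present events are ordered subject to:

1. clonal events precede subclonal events;
2. in WGD samples, early-clonal events precede WGD, which precedes
   late-clonal events;
3. subclonal events follow a phylogenetic tree over the mutation
   clusters: ancestors precede descendants.

Clonal SCNAs in WGD samples are timed by maximum parsimony: the minimum
number of single-copy gain/loss steps from 1+1 to the observed state with
at least one step before the doubling is compared with the minimum with
every step after it; ties go to early (the minimal-event history). A
fully lost allele cannot be regained. This classification is exhaustively
checked against an independent breadth-first enumeration oracle in the
test suite. Driver SNVs are timed by mutant multiplicity (>= 2 copies
implies the mutation preceded the doubling).

Trees are enumerated over all parent maps rooted at the clonal cluster in
which each child's CCF does not exceed its parent's and sibling CCFs
respect the pigeonhole principle; one feasible tree is drawn uniformly
per ordering iteration (at most 8 subclones — beyond that the user is
asked to merge clusters upstream). Within every unordered stratum events
are shuffled uniformly; the subclonal tail is emitted by random
topological traversal (uniform choice among clusters whose ancestors are
exhausted). That traversal is not exactly uniform over linear extensions;
it is an O(n) scheme and the method requires random tie-breaking, not
uniformity over extensions. The whole ordering is repeated across
iterations (1000 by default; desk-scale runs here use 25) with RNG
streams keyed by (seed, sample, iteration) so runs are reproducible and
order-independent.

Subclonal SCNAs are linked to clusters by matching the altered state's
cell fraction to the nearest subclonal cluster CCF; SNV clonality uses a
clonal CCF band of >= 0.9 (both configurable).

## Plackett-Luce mixtures

Each ranking is treated as a total order over the sample's own item
subset: the PL likelihood of placing item *i* next is its worth divided
by the summed worths of the sample's remaining items. Worths are fitted
by Hunter's MM algorithm; with a pseudocount *c* (default 0.1) the update
is the MAP step under independent Gamma(1 + c, c·m) priors, which keeps
the comparison graph effectively connected (identical rankings otherwise
push worths to the boundary; with *c* = 0 a non-strongly-connected
comparison graph raises an error instead). The penalized objective is
monotone at every MM update and the tests assert this.

Mixtures over K trajectories are fitted by EM (responsibilities from
log-sum-exp-stabilized component likelihoods; weighted MM as the M-step),
best of several random starts. Because consecutive ordering iterations
differ only in random tie-breaking, each iteration's fit is warm-started
from its predecessor's solution, with a fresh random start retained as a
safeguard; this stabilizes the fits and keeps component labels aligned
across iterations. K = 1 reduces exactly to the single fit. K is chosen
by the lowest median BIC across iterations over K = 1..5 (ties to the
smaller K), with BIC = −2·loglik + p·log N and p = (K−1) + K(m−1).

One sample label is consolidated from the per-iteration fits by aligning
component labels to the first iteration (maximum-overlap Hungarian
matching of MAP assignments) and taking the per-sample modal MAP label,
ties broken by mean responsibility. Samples carrying no catalog events
are reported unclassifiable and excluded. After assignment, the catalog
is re-discovered within each subset (so subset-specific events can enter
its trajectory), samples are re-ordered, and the aggregate ordering is
collated: per iteration a single PL fit ranks events by worth, and the
per-event median rank with 2.5/97.5 percentile ranks across iterations is
reported alongside subset prevalence. Events carried by fewer than 2
subset samples are dropped from that subset's trajectory.

## Trajectory statistics

All group comparisons share one scheme: a 2x2 table, a two-tailed Fisher
exact p (probability-mass summation), odds ratio (Haldane-Anscombe +0.5
on every cell iff any cell is zero), risk ratio, and BH adjustment within
each family of tests. Event-level comparisons flag hits with odds ratio
> 3/2 or < 2/3 at FDR < 0.05. Pairwise event co-occurrence uses
hypergeometric tails with the positive and negative directions adjusted
separately. Clonality preference compares each event's clonal/subclonal
counts against all other events pooled within a subset. The pre-WGD
proportion per WGD sample (events ranked before the WGD marker over all
its other events) is compared between trajectories by a two-sided
Wilcoxon rank-sum (exact for small untied samples, normal approximation
with tie correction otherwise). The driver-count test compares, per
subset, the number of driver genes mutated in >= 3% of its samples
against the other subsets pooled as the union of their qualifying genes
over the same 72-gene universe (an additive-counts pooling over a doubled
universe is available behind a flag, as the pooling convention is
genuinely ambiguous).

## Genome-state metrics

Subclonal segments are summarized as CCF-weighted expected copy numbers.
Subset profiles are compared on the union segmentation (breakpoints
pooled across samples) per segment by Wilcoxon rank-sum with BH across
segments, masking segments covered in fewer than 25% of either subset's
samples. Locus amplification magnitude multiplies each gained segment's
weighted major copy number by the covered fraction of the gene
(overlap-restricted, so partial overlaps are prorated). Copy-number
deviation is the length-weighted mean of |major − b| + |minor − b| with
baseline b = 1 (non-WGD) or 2 (WGD); PGA keeps the diploid 1+1 baseline
for all samples, so WGD itself contributes to PGA. Latency is
L = age·m_post / (a·m_truncal + m_post) with acceleration a (default 1),
truncal mutations from the clonal cluster and m_post summed along the
greedy highest-CCF root-to-leaf subclonal path — a declared
simplification of mutation-clock timing. The aberrant
copy-number-signature proportion is 1 − baseline/total over CN-prefixed
activities (baseline CN1, or CN2 after WGD), and the genomic-instability
model is an OLS of that proportion on driver-gene/WGD indicators plus
purity, smoking, ancestry and sex, with per-predictor VIFs (auxiliary
regressions) and the predictor correlation matrix; rank-deficient designs
raise an error naming the collinear columns.

## Synthetic cohorts

The generator realizes three archetypes on a miniature genome (22
autosomes x 100 Mb, with a scaled mask) so full runs take seconds:

* **loss** — WGD in 87% of samples; a small TP53/EGFR/RBM10-style driver
  core; losses dominate the early order with gains later and at lower
  prevalence (0.25).
* **gain** — WGD rate 0.31 and placed late; early frequent gains from a
  near-diploid base.
* **smoking** — driver-rich (many SNVs at moderate prevalence — the
  driver-count asymmetry), a distinct KRAS/STK11-style core, the shared
  loss block traversed in reverse, the homozygous deletion pre-WGD, and
  WGD in 60% of samples.

Each sample Bernoulli-draws its archetype's events by prevalence, orders
them by a PL draw with geometrically decaying worths (ratio 0.7; a noise
parameter flattens worths toward uniform), and splits the order into
clonal and subclonal parts (clonal fraction Beta(3, 2)). Subclonal
events land in up to five stick-breaking clusters whose CCFs satisfy the
pigeonhole principle by construction (chains with occasional branching).
Copy-number states are chosen so classification and parsimony timing
round-trip exactly — e.g. pre-WGD LOH is 2+0, post-WGD gain 3+2 — and a
loss event drawn after WGD is realized as subclonal LOH, since a
late-clonal state of the LOH class does not exist under parsimony.
Driver SNVs carry multiplicity 2 iff pre-WGD in a WGD sample.
Demographics, SBS4 status, burden fields and signature activities follow
archetype-specific distributions (e.g. the smoking-like archetype is
mostly ever-smokers with an SV5-style signature, EGFR mutations raise and
KRAS mutations lower the aberrant CN proportion).

Because within-stratum order is deliberately randomized by the ordering
model, a planted canonical order is observable only through stratum
membership (pre/post-WGD, clonal/subclonal, subclonal tree depth) — not
through intra-stratum positions. The archetypes are therefore designed so
that trajectories share high-prevalence events but disagree on their
strata and depth order; archetypes differing only in which events they
carry would be unidentifiable under the rankings-of-subsets likelihood.
What passing recovery tests show is that the pipeline separates
trajectories that differ in this observable structure at realistic noise;
they do not certify performance on real data, where cluster CCF error,
segmentation noise and catalog misspecification add further blur. The
generator also does not emulate read-level noise, mutational spectra, or
signature extraction — signature activities are drawn directly.

## Problem sizes and defaults

Desk-scale runs in the tests and the reproduction script use 300 samples
(100 per archetype), 25 ordering iterations, K = 1..5, EM with 2-4
random restarts, convergence at relative tolerance 1e-6 (max 200 EM / 500
MM updates). These sizes were chosen so a full discovery run completes in
about a minute while keeping the planted structure comfortably
recoverable; production-scale cohorts simply raise `n_iterations` and
`n_restarts` in the `PipelineConfig`.

## Known limitations

* Non-uniform sampling over linear extensions (random topological
  traversal) slightly favours bushy subtrees; immaterial for the
  aggregate statistics used here.
* The per-bin binomial null ignores within-sample spatial correlation of
  segments; merged regions partially absorb this.
* SCNA-to-cluster matching by nearest CCF can mis-link events when two
  subclones have similar CCFs.
* The latency path choice (greedy highest-CCF) underestimates m_post in
  heavily branched tumours.
* Aggregate-ordering intervals reflect tie-breaking stochasticity only,
  not catalog or clonality-call uncertainty.
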