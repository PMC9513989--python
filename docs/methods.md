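# Methods

`cloneflow` reconstructs clonal evolution from longitudinal somatic variant
tables of a single patient progressing through disease stages (the motivating
setting is Fanconi anemia → myelodysplastic syndrome → acute myeloid
leukemia, with paired peripheral-blood and bone-marrow samples at each
stage).  This note documents the models, the parameters that matter, the
synthetic cohort the tests run on, and the design choices made where the
design was genuinely open.

## Cancer cell fractions

For a mutation at a locus of total copy number CN, present at multiplicity
m in tumor cells, in a sample of purity p, the expected variant allele
frequency is

    E[VAF] = p · m · CCF / (p · CN + (1 − p) · 2)

where CCF is the fraction of tumor cells carrying the mutation.  The point
estimate inverts this; multiplicity, when unknown, is the rounded
maximum-likelihood value `round(vaf · (p·CN + (1−p)·2) / p)` clamped to
1..CN.  At 40–50× whole-genome coverage the binomial noise of a clonal
heterozygous site routinely pushes the raw estimate a few percent above 1,
so estimates are clamped to 1 and flagged only when the raw value exceeds
1.05 (the same 0.05 tolerance reappears as the tree-consistency slack ε
below, for the same reason).  Homozygous deletions (CN = 0) leave nothing
to estimate and are rejected.  Defaults assume a diploid autosome (CN = 2,
m = 1); sex-chromosome loci in single-copy contexts should be passed CN = 1
explicitly.

## Clonal-group inference

Mutations are clustered on multi-sample read counts with a K-component
product-binomial mixture: variant i belongs to component c with likelihood
∏_s Binom(b_is | d_is, ξ_cs), where ξ_cs is the component's expected VAF in
sample s.  Working on counts rather than VAF point estimates weighs a 200×
observation more than a 12× one, which matters at the 40–50× coverage this
design targets.  Entries with zero depth are treated as missing — not VAF 0
— and contribute no likelihood term; this is what lets stage-specific
clones (absent early, dominant late) cluster correctly.

EM details: responsibilities by log-sum-exp; M-step ξ_cs = Σ r_ic b_is /
Σ r_ic d_is with centers clamped to [1e−4, 0.999]; initialization by
k-means++ on (missing-imputed) VAF vectors; 10 seeded restarts by default;
convergence when the log-likelihood improves by < 1e−6.  The log-likelihood
is non-decreasing across iterations (asserted in the tests).  Model
selection minimizes BIC = −2·loglik + q·ln N_obs with q = K·S + (K−1) and
N_obs the number of observed (variant, sample) cells, over K = 1..8 by
default.  Components that capture no variants are dropped (effective K);
after selection, clusters smaller than `min_cluster_size` (default 3 —
singleton "clones" at 40× are noise) merge into the nearest center by
Euclidean distance in ξ space.  Hard assignments take the maximum
responsibility, ties to the lower cluster id.

On simulated five-clone cohorts with per-sample center separations ≥ 0.08
and depth 300, BIC selects K = 5 and the partition matches truth with
ARI > 0.9 (median over seeds); at the ~45× depth the design actually
achieves, the same architecture is still recovered because three stages of
trajectory jointly separate the clusters.

## Clone tree under the sum rule

Cellular prevalences must obey two pigeonhole constraints in every sample:
an ancestor's prevalence is at least each descendant's (ancestry rule) and
at least the sum of its children's (sum rule).  `build_tree` attaches
clusters greedily in order of decreasing total prevalence, each to the
already-placed node of *smallest* prevalence that satisfies both rules
within ε (default 0.05, matching the CCF clamp tolerance); the root
(normal cells, prevalence 1) is the fallback.  When even the root cannot
legally adopt a cluster, the cluster is attached there anyway and the
violation recorded, so callers always receive a structured report rather
than a silently invalid tree or an exception.

The smallest-valid-parent convention deliberately prefers the most
constrained (deepest) placement.  When a cluster fits both under a sibling
and beside it the matrix genuinely cannot distinguish linear from branching
evolution; the convention picks the nesting reading, which is what recovers
rise-and-fall architectures where a late clone sits inside the rising
founder rather than beside it.  An exhaustive search over all parent maps
is provided for ≤ 7 clusters and serves as the test oracle: whenever the
greedy tree is consistent it lies in the exhaustive valid set, and whenever
no valid tree exists the greedy builder reports violations.

Timing classes per cluster use two thresholds, present ≥ 0.10 and absent
≤ 0.02 (the narrative labels "appeared"/"disappeared" need reproducible
cutoffs; these leave a deliberate dead zone in between that maps to
`unclassified` rather than forcing a label): `shared` (present at every
stage), `stage_specific:<s>` (present exactly once, absent elsewhere),
`emergent_at:<s>` (absent before, present from s onward), and
`vanished_after:<s>` (present through s, absent after).  The fishplot table
passes prevalences through unchanged and additionally emits a
`plot_prevalence` column in which children overflowing their parent (legal
within ε) are proportionally rescaled so drawing intervals always nest.

## Single-cell validation

Targeted single cells amplified by MDA are genotyped with the conventional
rule for this assay: a site is callable at total depth ≥ 5 and mutant when
VAF is strictly greater than 5%.  Cells are assigned to clone profiles
(binary carrier vectors along the root→clone path, plus an all-wildtype
normal profile) by maximum likelihood under a two-parameter miscall model:
allelic dropout α flips a truly mutant call to wildtype, false positives β
flip wildtype to mutant; the prior over profiles is uniform because the
stage-specific clone fractions are exactly what one wants to estimate, not
assume.  A cell is left unassigned when its top-two log-likelihood gap is
below 2 nats (so a single informative locus never yields a confident
assignment) or when it has no informative locus.  Doublets are out of
scope; a cell fitting two profiles equally stays unassigned.

Compartment comparison reports, per locus, the mutated-cell fraction in
sorted stem cells next to the bulk CCFs of PB and BM, and flags loci
present (≥ 0.10) in one compartment and absent (≤ 0.02) in another —
the pattern of a mutation detected at the stem-cell level years before it
is visible in whole bone marrow.  Both raw and purity-adjusted single-cell
fractions are available because published single-cell "CCFs" for such
designs are typically raw mutated-cell fractions.

## CNV cellular fractions

A segment of integer copy number CN carried by a fraction f of cells moves
the normalized depth ratio to R = (2(1−f) + CN·f)/2; inversion gives
f = 2(R−1)/(CN−2), clamped to [0, 1] and flagged beyond 0.05 outside.
CN = 2 carries no mixture signal and is rejected.  No B-allele frequency is
used, and purity is folded into f (f is the fraction of *sequenced* cells
carrying the CNV).  Cross-patient recurrence is a sweep-line intersection
of per-patient interval unions reporting maximal intervals with support ≥
`min_support`, equivalent to per-base support counting (the test oracle).

## The synthetic cohort

The simulator generates what the analysis assumes, with full ground truth:

- **Clone tree and prevalences.** The default is a scripted five-clone
  architecture over stages FA/MDS/AML: a founder (0.50/0.85/0.90), an early
  clone that fades (0.40/0.10/0), a rising clone that comes to dominate
  (0.05/0.60/0.85), an MDS-specific clone (0/0.45/0) and an AML-emergent
  clone (0/0.05/0.80) — the rise-and-fall dynamics longitudinal
  marrow-failure cohorts report.  Random mode draws a random topology and
  allocates cell mass down the tree by stick-breaking, so the sum rule
  holds by construction; scripted matrices are validated and an infeasible
  script raises naming the stage.  Exclusive clone fractions and clade
  prevalences (CCFs) are both carried: the former drive single-cell clone
  sampling, the latter the bulk VAF model and the sum-rule invariant.
- **Bulk counts.** 300 mutations per clone (≈ 1,500 per sample, the scale
  of whole-genome somatic calls in such patients), depth Poisson(45)
  (40–50× coverage), purity 1.0 by default (hematologic samples called
  against a germline control), binomial alt counts.  PB expected VAFs equal
  BM plus per-variant Gaussian jitter truncated to [0, 1]; the default
  s.d. 0.15 was calibrated (numerically, accounting for truncation —
  `calibrate_pb_noise`) so the paired-compartment correlation of expected
  VAFs at the MDS stage is ≈ 0.7, the concordance regime reported for this
  kind of paired design.
- **Single cells.** 96 cells per stage (one sorted plate), clone drawn from
  the stage's exclusive fractions with a normal-cell remainder, per-locus
  depth Poisson(50).  A carried allele drops out with probability α
  (default 0.2) and otherwise amplifies at a Beta(20, 20) allele fraction
  (MDA imbalance around 0.5); non-carried loci accrue alt reads at error
  rate β (default 0.005).  α and β are plausible MDA magnitudes, not
  measurements of any particular kit, and the tests vary them.
- **CNVs.** Default segments mimic a large chr1 gain and chr17 loss whose
  fractions grow over stages plus a trisomy-8-like event appearing at the
  leukemic stage, with Gaussian ratio noise (s.d. 0.01).

All randomness flows from one integer seed through spawned child
generators, one per component, so identical config + seed is bit-identical
and each stage is reproducible in isolation.

What the simulator does **not** emulate: sequencing-error substitution
context (spectra from simulated data are uniform over classes), indels,
mutation phasing onto CNV alleles (multiplicity is 1 unless configured),
regional annotation (simulated positions are intergenic by construction),
doublets, and amplicon-specific single-cell bias.  Passing tests therefore
demonstrate estimator correctness under the stated generative model, not
robustness to artifacts outside it.

## Problem sizes in the test and acceptance runs

The suites run at sizes chosen to make the statistical assertions sharp yet
quick: clustering recovery at 250 mutations × 3 samples × depth 300 (10
seeds), CCF recovery at 360 mutations × depth 500, concordance
unbiasedness at 1,000 replicates of 18 pairs drawn from a 9,000-mutation
population, single-cell accuracy at 5 × 200 cells × 8 loci, CNV recovery
at 600 noisy ratios.  The full pipeline run writes every stage output for a
downscaled cohort in a few seconds.

## Known limitations

- Purity and local copy number are inputs, not inferred; no ABSOLUTE-style
  joint fitting.
- The binomial mixture has no overdispersion term; strand bias or mapping
  artifacts that inflate VAF variance will fragment clusters.
- The greedy tree builder is sound but not complete: in principle it can
  report violations where some non-greedy attachment order would have
  succeeded (not observed on simulator output).
- Region classification depends entirely on the user-supplied BEDs; the
  "others" category is whatever the user provides (e.g. UTR/ncRNA), and
  overlap precedence is fixed to splicing > exonic > other > intronic >
  intergenic.
- Recurrent-CNV support counts patients, not breakpoint concordance;
  cytoband labels are annotation supplied by the caller, never computed.
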