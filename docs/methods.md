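# Methods

## Scope and data flow

`tailoseq` covers the dry-lab half of a tailocin-sensitivity study:
barcode counts → fitness → hits; annotated genomes → delineated loci →
OSA distance tree; spot tests → sensitivity matrix → concordance with the
tree; emPAI tables → molar fractions. Wet-lab steps (induction,
purification, spotting, TEM), genome assembly, orthology inference,
marker-gene phylogenetics, external prophage callers, and GWAS are out of
scope; their outputs (orthogroup tables, newick trees, sensitivity
records) are consumed as inputs where relevant.

## Fitness estimator

The estimator is deterministic and fully specified in `tailoseq.fitness`:
pseudocount 1 on both counts, inverse-Poisson-variance weights in log2
units, per-sample normalization by subtracting the median of preliminary
(unnormalized) gene fitness, a central-insertion window of [0.1, 0.9] of
gene length, a minimum Time0 count of 3, and a variance floor σ₀ = 0.1
inside the t denominator. One median is taken per sample (single-genome
pools are assumed; no per-scaffold normalization). Missing barcodes in a
sample are counted as 0, not dropped. Genes with no usable insertion are
absent from the output — "no data", not fitness 0.

Replicates are combined per gene by the arithmetic mean of fitness, with
the combined t = f̄ / sqrt(Σ_r (V_r + σ₀²) / R²); read summaries are
depth-normalized (counts per million over used strains) and summed across
replicates, because the hit-calling direction check must not conflate
sequencing depth with selection.

Known behavior under strong sweeps: when one gene's mutants amplify by
2^16, every other strain's post-selection counts drop to a few reads, and
the pseudocount biases the per-sample median upward by ~0.5 log2. The
estimate for a concurrently spiked φ = 8 gene therefore concentrates
around 7.1–7.5 rather than 8, and its *relative* read share may fall even
though its disruption is beneficial. This compression of weaker positive
effects under stringent selection is a property of pooled assays
themselves (strongly selected mutants outcompete weakly selected ones),
and it places a φ = 8 effect at the edge of the f ≥ 7.0 hit threshold.

## Hit calling

Inclusive comparisons at the printed thresholds (≥ 7.0 / ≥ 5.0 for
positive, ≤ −2.0 / ≤ −5.0 for negative), applied to replicate-averaged
fitness and combined t, plus a read-count direction check on the
replicate-pooled, depth-normalized sums (positive hits must gain reads
from Time0, negative hits must lose them). No multiple-testing
correction: the thresholds are intentionally stringent fixed cutoffs.
Direction is checked on pooled rather than per-replicate sums for
stability at low counts.

## Synthetic assay generator

The generator encodes the study conditions and is not meant to be tuned
per experiment:

- **Library**: 500 genes by default; strains per gene ~ 1 + Poisson(1)
  (sparse insertion coverage, so some genes legitimately lack data, as
  real libraries do); insertion positions place 80% of mass in the
  central [0.1, 0.9] window (equivalent to uniform positions along the
  gene); latent strain abundances are log-normal with σ = 1.
- **Sequencing**: one multinomial draw per sample at fixed depth
  (5 × 10⁵ reads by default), so totals are conserved exactly. An
  optional Dirichlet-multinomial overdispersion parameter exists and is
  off by default — plain multinomial is the simplest model consistent
  with barcode counting.
- **Selection**: post-treatment abundance a′ ∝ a · 2^φ with φ the true
  log2 effect; the buffer control ("Ctrl") sets φ = 0, the full-strength
  treatment ("Max") applies φ, and the tenfold dilution ("Dil")
  attenuates φ by 0.6 — a free modeling choice (no quantitative
  dose–response is available to emulate) picked so Max and Dil hit sets
  can differ.
- **Effects**: receptor-gene effects are assigned evenly spaced across
  [8, 16] (so the maximum, a full 2^16 sweep, is always represented, and
  the range endpoints are fixed features of the design rather than
  lottery draws); shield-gene effects likewise across [−4, −2].
- **Assays** run in duplicate, each replicate with its own Time0 sample.

What the generator does **not** emulate: PCR/amplification bias,
chromosomal-position effects, strain cross-feeding, partial killing
kinetics, or growth-phase dependence. Passing tests therefore demonstrate
correctness of the estimator and calling rules under clean multinomial
noise, not robustness to every artifact of real BarSeq data.

## Genome panel generator

Each simulated strain is a one-contig genome with the anchor genes
*mutS*, *cinA*, *ihfB* and *wbpM* placed correctly: a 12-gene tailocin
locus with phage-structural products (and no capsid/terminase/integrase)
between *mutS* and *cinA*, a clade-specific OSA locus between *ihfB* and
*wbpM*, and core/CPA loci carrying orthogroups mapped to the PAO1
reference ranges. Clades share an OSA orthogroup repertoire (12 of a pool
of 80 by default); within-clade divergence optionally swaps orthogroups.
Sensitivity truth is "sensitive iff the tailocin's receptor orthogroup is
present in the strain's OSA set"; each producer strain is chosen among
strains resistant to its own sample, so the generated killing matrix has
a self-kill count of zero. An optional "SM-like" clade keeps OSA content
identical but flips the phenotype of half its members for one tailocin —
the pattern of a real clade whose sensitivity split is unexplained by
gene content.

## Locus delineation

Anchor search is orientation-free (either anchor may come first; strands
ignored) and requires each anchor exactly once on a shared contig;
violations raise typed errors (absent, duplicated, split across contigs).
Anchors are excluded from region gene lists; an `include_3prime_anchor`
option adds *wbpM* to the OSA set for users who consider it part of the
cluster (off by default — both conventions appear in practice).
Coordinates are 1-based inclusive (GFF3); spans are computed on the
forward strand. The tailocin classifier replaces an external prophage
caller with a configurable keyword heuristic: ≥ 10 genes, ≥ 25% of
products matching phage-structural keywords, and no product matching
capsid/terminase/integrase/portal. Genes without an orthogroup become
`singleton:<locus_tag>` pseudo-orthogroups so private genes still count
in Jaccard unions.

## OSA comparison

Jaccard distance on presence/absence orthogroup sets; two empty sets are
defined as distance 0 (indistinguishable) with a warning, one empty set
as distance 1. Single linkage is the textbook O(n³) agglomeration with a
fixed tie-break (among equal-distance merges, the pair containing the
least original leaf index wins), making trees bit-reproducible; panels of
a few hundred strains cluster in milliseconds, so the cubic cost is
irrelevant. scipy's MST-based single linkage serves as an independent
cross-check of merge heights in the test suite. Trees serialize to
newick with branch lengths derived from merge heights; cutting at height
0 groups exactly the identical-content strains.

## Concordance statistic

C = (# clusters of size ≥ 2 whose members share an identical sensitivity
vector) / (# clusters of size ≥ 2); ambiguous entries (discordant spot
replicates) are excluded column-wise when comparing members. C and its
permutation null (uniform row shuffles; add-one p-value
p = (1 + #{C* ≥ C_obs}) / (M + 1), never 0) are this package's
formalization of a comparison usually made by eye on an annotated tree;
outputs are labeled accordingly. All-singleton partitions make C
undefined and raise an error.

## emPAI

Molar percentage is emPAI / Σ emPAI × 100 per sample over all rows
present in the input table; the tailocin fraction sums percentages over
flagged proteins. Non-positive emPAI values are rejected rather than
dropped silently. The `is_tailocin` flag is input metadata — mapping
proteins to tailocin-cluster genes happens upstream.

## Problem sizes and determinism

Tests and the acceptance script use 500-gene libraries at 5 × 10⁵ reads
(10 control seeds, 5 spiked seeds), 100 random 12-strain matrices for the
clustering cross-check, a 130-strain / 12-clade panel with 999
permutations, and 200-protein emPAI tables — sizes at which every stage's
statistical behavior is already asymptotic while the whole suite runs in
seconds. Every random draw flows through numpy `Generator` objects seeded
from a single integer plus a CRC-keyed stream label per sample, so
repeated runs are byte-identical and replicates get independent streams.

## Known limitations

- Weak positive effects (φ near the f ≥ 7 threshold) are compressed under
  concurrent strong sweeps (see the estimator section) and will be missed
  in a fraction of runs; this mirrors the real assay's blindness to
  mutants that are outcompeted before sequencing.
- Cofitness, chromosomal-bias correction, and essential-gene inference
  from the broader BarSeq method family are not implemented.
- Gene-order (synteny) and nucleotide-identity comparisons of OSA
  clusters are out of scope; comparison is purely set-based on
  orthogroups.
- The keyword tailocin classifier is a heuristic stand-in for dedicated
  prophage callers and is configurable for that reason.
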