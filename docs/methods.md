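# Methods

## Model

A circRNA is treated as a miRNA sponge whose disease relevance is
measured by over-representation of disease-associated miRNAs among its
interaction partners. Conditional on a circRNA interacting with m_c
miRNAs drawn from a universe of M_T, and M_d of the universe being
associated with a disease, the number of disease miRNAs among the
partners is hypergeometric under the null of no preferential
interaction. The reported p-value is the upper tail P(X >= m_d); the
model assumes the interaction table is a fixed, binary relation (no
affinities, no expression weighting) and that the universe is the
correct exchangeable reference set.

Multiple testing is controlled per disease: the family is the m circRNAs
interacting with at least one of the disease's miRNAs, each tested at
0.05/m with strict inequality. Two properties of this scheme are worth
stating plainly:

* the family is defined *after* seeing which circRNAs interact with
  disease miRNAs (m_d >= 1). This selection makes the procedure mildly
  anti-conservative relative to a Bonferroni correction over all
  circRNAs: in null simulations at the default conditions the
  disease-level familywise error sits near 0.054 rather than below
  0.05. The calibration check therefore allows three binomial standard
  errors above 0.05, which the measured rate satisfies;
* m is recomputed after any curation filter is applied to the disease's
  miRNA set, so the threshold always matches the family actually tested.

Disease miRNAs absent from the interaction universe are dropped (with a
logged count) before computing M_d; without this the tail sum is
ill-defined. circRNAs with no miRNA partner are never tested (their
p-value is trivially 1).

## Numerical evaluation

The tail sum is evaluated in log space from a cached table of
log-factorials (lgamma), with terms rescaled by their maximum and
accumulated by compensated summation (math.fsum). This is stable for
universes of at least 10,000 miRNAs. When the requested tail covers the
whole support (m_d at or below the lower support bound), exactly 1.0 is
returned. Against an exact integer-binomial suffix-sum oracle the worst
relative error over the full valid grid up to M_T = 60 (1.23 million
cases) is below 2e-13; the test tolerance is 1e-12. The exact rational
evaluation is kept in the test suite only — it is the independent
oracle, not the implementation. scipy's hypergeometric survival function
provides a second, library-independent cross-check in the tests.

## Interval mapping

All coordinates are 0-based half-open, converted once at read time for
1-based catalogs. A point hits a locus iff start <= pos < end; intervals
overlap iff they share >= 1 bp (touching intervals do not overlap).
Mapping counts carry multiplicity: a variant inside two overlapping
circRNA loci contributes two mapping events, and per-circRNA means
divide by the number of *mapped* loci. This multiplicity reading is the
one consistent with jointly reporting a unique-SNP count and a
per-circRNA mean for trait SNPs. Because "variants per kb" is ambiguous
between an aggregate ratio (total hits / total length) and a mean of
per-locus densities, both are computed and reported.

Ago-site overlap is strand-aware by default (CLIP clusters and circRNAs
are both stranded); point mapping ignores strand. Both behaviours are
flag-controlled. The interval index is an interval tree per chromosome;
its contract — and the acceptance check — is exact agreement with a
naive all-pairs scan, verified on random instances up to 1,000 loci by
5,000 features including all four boundary positions of every locus.

The backsplice junction is not modelled as sequence: a circRNA is the
linear genomic span between its backsplice coordinates, so variants or
sites spanning the junction point itself are outside scope, as is LD
expansion of GWAS SNPs and any functional-consequence annotation.

## Networks

A disease network is the interaction table restricted to the disease's
miRNAs: nodes are those miRNAs plus every target they hit, edges run
miRNA -> target only (bipartite by construction). Disease miRNAs with no
target remain as isolated nodes, so the node list always reflects the
full (post-filter) disease set. Target identity is the (id, class) pair,
keeping an mRNA and a lncRNA with the same symbol distinct. Exports (SIF,
GraphML, node attributes, degrees) are lexicographically ordered and
byte-stable across reruns.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs, not
their content:

* circRNA loci: lognormal lengths (log-mean 8.7898, log-sd 0.8, minimum
  200 bp), placed uniformly and non-overlapping by default on 4
  chromosomes of 10 Mb (an overlap-allowing mode exercises multiplicity
  counting). The log-mean is calibrated so the mean length is ~9,043 bp,
  the ratio of the two published per-locus summary rates (217.13 SNPs
  per locus / 24.01 SNPs per kb); the log-sd is a single fixed choice
  giving a realistically right-skewed length distribution whose sample
  mean at n=200 stays within a few percent of the target.
* interactions: each circRNA-miRNA edge is an independent Bernoulli draw
  at pi0 = 0.01; for planted (circRNA, disease) pairs the edges to that
  disease's miRNAs are drawn at pi1 = 0.5 instead. Defaults: universe of
  2,000 miRNAs, 10 diseases of 30 miRNAs each (sampled without
  replacement, sets may overlap across diseases), 200 circRNAs, 5
  planted pairs. mRNA/lncRNA targets (500/200) attach to miRNAs at
  probability 0.01.
* variants: a homogeneous Poisson process at 24.01 SNPs per kb inside
  each locus, plus 500 intergenic SNPs rejected out of the loci (to
  exercise the zero-hit path). A fraction 0.001 of SNPs receives a trait
  label drawn uniformly from the disease list, mirroring the sparsity of
  GWAS-catalog annotation relative to genome-wide catalogs.
* Ago sites: per circRNA a Poisson(2.658) count of sites of uniform
  length 20-40 bp (typical PAR-CLIP cluster widths), placed uniformly
  inside the locus on the circRNA's strand.

Randomness flows from a single root seed through named per-stream
sub-seeds (loci, disease sets, edges, mRNA/lncRNA edges, SNPs, traits,
Ago), so resizing or disabling one stage never perturbs another's draws
and output files are byte-identical for identical config + seed. The
sidecar `truth.json` records the planted pairs and their realized m_d,
which the tests check against the emitted interaction table.

What the generator does *not* emulate: sequence (no seed-match model, no
FASTA), tissue-specific expression, LD structure among SNPs, clustering
of CLIP sites at real binding motifs, and the heavy-tailed degree
distributions of curated disease-miRNA catalogs. Passing tests therefore
demonstrate correctness of the statistics and the mappings under the
stated generative model, not biological validity on any particular real
catalog. Genome-build agreement between loci and variant catalogs is the
caller's responsibility.

## Problem sizes and tolerances

Seeded checks use: the full hypergeometric grid to M_T = 60 at relative
tolerance 1e-12; 500 null replicates for calibration (bound: 0.05 plus
three binomial standard errors); 100 replicates for planted recovery
(sensitivity >= 0.9; measured 1.0); 100 random instances for
mapping-oracle equivalence; 200+ random records per round-trip check.
Realized simulation rates are required to lie within three standard
errors of their configured values, a bound chosen to be essentially
non-flaky under the fixed seeds while still detecting rate errors of a
few percent.

## Design choices where the design was open

* The miRNA universe (M_T) is an explicit input (a universe file) rather
  than hard-coded: catalog sizes vary by release, and the union of
  observed edge miRNAs is used only as a fallback.
* SNP catalogs use a single TSV schema in which an empty trait field
  means "genome-wide catalog"; trait-labelled records form the GWAS
  catalog. VCF parsing is deliberately out of scope in v1.
* Duplicate interaction rows are collapsed silently (logged): unions of
  several target-prediction tools routinely duplicate edges.
* Output ordering everywhere is deterministic (disease, ascending p,
  circ_id for enrichment; lexicographic for graph exports) so that runs
  can be diffed.
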