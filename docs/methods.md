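# Methods

## Overview

`commphen` analyses phylotype-resolution 16S profiles of cultured
communities in two layers: composition (QC, normalization, taxonomic
aggregation, α/β diversity, fold-change screening, two-group tests) and
predicted function (projection of reference-genome binary phenotypes
onto observed taxa, summarized as Community Phenotype Indices). A
synthetic-data module generates complete study bundles with known
planted structure; it is first-class, tested code, and every
quantitative guarantee of the package is stated against it.

## Composition layer

**QC.** Samples with fewer than `min_reads` total reads (default 5,000)
are excluded before any other step; the comparison is strict (`< 5000`
excluded, `== 5000` retained). QC requires raw counts and refuses
tables whose columns already sum to one.

**Normalization.** Default is total-sum scaling to relative abundances,
because every downstream formula (Shannon, UniFrac weights, fold
ratios, CPI) consumes relative abundances. Rarefaction (seeded
subsampling without replacement, via the multivariate hypergeometric
distribution) is available as an alternative; samples shallower than
the target depth are dropped with a warning rather than silently
upsampled. Pipeline order is QC → normalize → aggregate.

**Aggregation.** Abundances are summed within species, genus, or
family from the taxonomy map; phylotypes without an assignment at the
requested rank are pooled under `unassigned` so each sample's total is
conserved exactly.

**Shannon diversity** uses natural logarithm (nats) by default; the
base is configurable. Input compositions are renormalized if their sum
deviates from 1 by at most 1e-6 and rejected otherwise.

**Midpoint rooting.** The root is placed halfway along the longest
leaf-to-leaf path. Ties between equal-diameter leaf pairs are broken by
lexicographic order of the (sorted) leaf-name pair; if the midpoint
falls exactly on an existing node (within 1e-12 of the diameter), that
node becomes the root and no zero-length edge is introduced. Rooting
preserves all pairwise leaf distances; zero-diameter trees are
rejected.

**Weighted UniFrac.** A single postorder pass accumulates, per branch,
the fractions of each community descending through it; the raw distance
is Σ l·|A−B| and the normalized variant divides by Σ l·(A+B), lying in
[0, 1]. The normalized variant is the default (the metric is commonly
reported that way for compositional comparisons); both are exposed.
Tests verify the implementation against an independent per-branch
brute-force oracle and against scikit-bio's implementation.

**PCoA.** Classical metric MDS: Gower double-centring of the squared
distance matrix, symmetric eigendecomposition, axes ordered by
decreasing eigenvalue. Negative eigenvalues (non-Euclidean input) are
dropped from the embedding but reported with their magnitudes;
`correction="lingoes"` adds the Lingoes constant to squared
off-diagonal distances instead. Proportion explained is computed over
the retained positive eigenvalues.

**Fold screen.** Classification uses arithmetic means of relative
abundance across replicates with no pseudocount: taxa with control mean
zero and condition mean positive form a dedicated `herb_only` class
(and symmetrically `control_only`) rather than receiving an inflated
ratio. Up requires ratio ≥ k, down requires ratio ≤ 1/k (symmetric
threshold, default k = 5). "Detected" means mean abundance strictly
above `min_detect` (default 0); the classification is invariant to
common rescaling. Summary counts report `herb_only` both separately and
inside the `n_up_total` convention.

**Group tests.** The Mann–Whitney U test is exact (full enumeration of
the U null distribution via a rank-sum dynamic program) when the pooled
sample is ≤ 12 values with no ties — which covers the 3-vs-4–6
replicate designs this package targets — and otherwise uses the
tie-corrected normal approximation with continuity correction. The
two-sided exact p sums the probabilities of all outcomes at least as
far from n_x·n_y/2 as observed (symmetric-null convention; identical
multisets give p = 1). Welch's t-test flags the zero-variance
degenerate cases explicitly. Presence/absence frequencies use the 2×2
Pearson chi-squared without Yates correction by default (configurable);
a zero marginal is flagged undefined rather than reported as 0. Raw
p-values are reported throughout; a Benjamini–Hochberg post-processor
exists but is off by default. The batch driver requires an explicit
method choice rather than guessing per metric.

## Phenotype layer

**Mapping.** Species names are normalized (case and whitespace) and
matched between the taxonomy map and the binary phenotype matrix
(BPM). A taxon's phenotype value is the arithmetic mean of its species'
genomes' binary values — the fractional-representation reading that
makes CPI an estimate of the fraction of *cells* with the capability.
An `"any"` mode (max over genomes) is available. Taxa with no species
assignment or no matching genomes stay unmapped and are reported with
their abundance share; genus-level fallback is deliberately not applied
by default.

**CPI.** CPI = 100 · Σ p·a over mapped taxa. Two denominators are
supported: total abundance (default; unmapped abundance dilutes the
index toward 0) or mapped abundance only (`renormalize=True`). The
mapped fraction is reported per sample either way, and a sample with no
mappable abundance yields NaN (undefined), never 0.

**Pathway sets and media contexts.** A capability with several routes
(butyrate: two carbohydrate-derived routes via pyruvate or succinate
and two amino-acid routes via lysine or glutamate; propionate: four
routes) is evaluated genome-first: a genome is a producer if it encodes
ANY route in the context's active subset, and species averaging happens
afterwards. Evaluating the OR on averaged fractions instead would
understate producer frequency whenever different genomes of a species
carry different routes, so the genome-level order is the correct one
for a presence/absence pathway fact. The packaged context table admits
only the amino-acid routes in the sugar-free control medium and all
routes under supplementation. Panels (SCFA routes, 11
vitamins/cofactors, 20 amino acids, 10 sugars; GH families free-form)
are data — an editable JSON shipped with the package — not code.

**Sugar utilization** is the logical AND of catabolic-pathway and
uptake-transporter presence, applied per genome before any averaging.

**Deltas.** Per-phenotype condition-vs-control differences of mean CPI
are classified increased/decreased, and a panel's net effect is the
plain mean of the signed changes.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the pipeline targets:

- 3 control and 5 supplemented replicates (both configurable);
- a base composition drawn from a Gamma(2) profile, offset by a quarter
  of its mean so no taxon sits at the detection boundary, then
  normalized (40 taxa by default);
- planted effects on the probability simplex: by default 5 taxa scaled
  up 7-fold (planted on the low-abundance tail), 5 scaled down 7-fold
  (high-abundance tail, so planted mass roughly balances), and 2 taxa
  present only under supplementation. After renormalization the
  *realized* fold differs from the planted one by the common
  renormalization constant; ground truth stores both, and taxon classes
  are assigned from realized folds. The 7-fold default keeps realized
  folds near 6–7, safely past the k = 5 screen threshold — an effect
  planted exactly at the threshold would be recovered only about half
  the time under symmetric replicate noise, which would make
  "sensitivity" meaningless;
- Dirichlet-multinomial replicate noise. The concentration parameter
  (default 5,000, i.e. intraclass correlation ≈ 2·10⁻⁴) represents
  technical replicates of a well-mixed saturated culture, which vary
  far less than biological replicates; `dispersion=inf` gives pure
  multinomial sampling. Larger concentrations provably tighten
  replicate spread (tested);
- sequencing depths drawn uniformly from 4,000–150,000 reads, spanning
  the 5,000-read QC threshold so the QC gate is occasionally exercised;
- reference genomes: 25 species owning 1–3 genomes each, phenotypes
  drawn Bernoulli(0.5) per genome (default panel: the four butyrate
  routes, two vitamins, two sugars, four GH families, so the
  media-context machinery is exercised); 10% of phylotypes are left
  species-unassigned to exercise unmapped-taxon reporting;
- a uniform stepwise-addition random binary tree with Exp(0.1) branch
  lengths — only tree shape and lengths matter to UniFrac and rooting,
  so no evolutionary realism is attempted.

True per-condition CPI is computed analytically from the base
compositions and species-averaged phenotypes over mapped taxa
(consistent with the default no-renormalization CPI), so estimator
recovery can be measured without Monte-Carlo ground-truth error.

What the generator does **not** model: sequence-level error, chimeras,
donor structure of a pooled inoculum, cross-feeding dynamics,
compositional correlations between taxa beyond the simplex constraint,
and biological replicate variation. Passing tests therefore demonstrate
correctness of the estimators and the pipeline's bookkeeping under a
known sampling model — not robustness to real amplicon artefacts.

## Problem sizes

The test suite and the acceptance script use 40-taxon, 8-sample
datasets at 100,000 reads per sample, 20-seed ensembles for performance
measures, 2,000 draws for test-calibration checks, and 50–100 random
instances for oracle-equivalence checks; these sizes make the full
suite run in seconds while keeping Monte-Carlo standard errors small
relative to the margins being tested.

## Known limitations

- Exact Mann–Whitney enumeration is limited to pooled n ≤ 12 (beyond
  that the normal approximation is used; at n = 6 vs 6 the two agree to
  within 0.02 in tests).
- The screen is a fold-change classification, not an inferential
  procedure; it inherits the paper-trail of mean ratios (no variance
  weighting, no compositional correction).
- Genus-only phylotypes are left unmapped by default; where a study's
  taxonomy is largely genus-level the mapped fraction will be low and
  CPI correspondingly diluted (or renormalized, if requested).
- PCoA axes are sign-indeterminate; downstream comparisons should use
  distances or proportions, not raw coordinates.
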