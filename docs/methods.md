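# Methods

`crossqtl` implements a multi-omics QTL mapping pipeline for biparental
haploid segregant panels (the BYxRM-style yeast cross design): genotype
cleaning, residual molecular trait derivation, Random-Forest linkage
mapping with a permutation-based empirical FDR, broad-sense
heritability, QTL-effect characterisation with hotspot detection, and
integration with physiological traits.  This note records the models,
the numerical choices, and the places where the design was genuinely
open.

## Synthetic segregant panel

The generator (`crossqtl.simulate`) is first-class code: it defines the
conditions under which every downstream estimator is validated.

**Genotypes.** Haploid biallelic calls (0 = BY allele, 1 = RM allele)
are simulated per chromosome as a two-state Markov chain: the first
marker is Bernoulli(1/2) and the transition probability between
adjacent markers is the Haldane recombination fraction
c = ½(1 − e^(−2d/100)) for genetic distance d in cM, converted from
physical distance at 0.4 cM/kb (a yeast-like rate; configurable).  The
default panel is 110 recombinant strains — the study scale for such
crosses — on four 760-kb chromosomes with 10-kb marker spacing, which
collapses to roughly 300 unique mapping markers; the real cross has
~3,600 unique markers over sixteen chromosomes, and the scaled-down map
keeps the same strain-to-marker information structure while letting a
mapping run finish in seconds per trait on one CPU.

**Molecular layers.** Traits are built hierarchically on log2 scale:

    transcript  t  = Σ β·x            + ε_t
    protein     p  = α·t + Σ β′·x     + ε_p
    phospho     ph = γ·p + Σ β″·x     + ε_ph

with transmission coefficients α (transcript→protein) and γ
(protein→phospho) defaulting to 0.7, causal effects β drawn
±Uniform(0.5, 1.5), and per-layer Gaussian noise (σ = 0.5/0.4/0.5).
Protein-layer coefficients β′ implement the transmission classes:
*buffered* proteins cancel the transmitted effect (β′ = −αβ),
*enhanced* proteins add a same-signed increment, and *protein-only*
traits carry an effect at a locus their transcript ignores.  Each
phosphoprotein contributes 1–3 peptides so multiple-site analyses have
structure, and a configurable fraction of peptides carries a direct
genetic effect independent of protein abundance.  Master-regulator
hotspot loci add effects from one marker to a configurable fraction of
a layer's traits.

**Replicates and batches.** A shared sample design gives six strains
three replicates each (emulating the replicate structure used for
heritability estimation in this kind of study) and every other strain
one sample; samples receive additive per-batch trait shifts
(σ_batch = 0.3 across 3 batches) and replicate noise (σ_rep = 0.4).
The recorded true broad-sense heritability of a trait is
Var(strain values)/(Var(strain values) + σ_rep²) on the realized strain
values — batch shifts are excluded because the pipeline removes them
before estimating H².

**What the generator does not emulate.** Counts-level measurement
models (library size, mass-spec intensity dependence), missingness that
correlates with abundance, genuine linkage disequilibrium decay over
sixteen chromosomes, epistasis, and correlated residuals between
layers beyond the explicit α/γ paths.  Passing tests therefore
demonstrate correctness of the estimators under additive Gaussian
conditions, not robustness to every artefact of real data.

All randomness derives from one integer seed through
`numpy.random.SeedSequence` spawning, so each sub-step has an
independent, reproducible stream.

## Genotype processing

Markers callable in < 70% of strains or with minor-allele frequency
< 20% (strict thresholds, computed on non-missing calls) are removed.
A marker whose call differs from both immediate flanking markers in
more than one strain is treated as a genotyping error and excluded;
a single such strain is tolerated.  Missing calls are imputed from the
nearest non-missing neighbours on the same chromosome when both lie
within 20 kb and carry the same parental allele.  Runs of adjacent
markers with identical segregation patterns (missingness counts as its
own symbol) collapse into unique mapping markers; the representative
position is the midpoint of the spanned interval, and coordinates are
1-based inclusive throughout.  The pipeline order is
filter → flag → impute → collapse; markers still incomplete after
imputation are dropped before collapsing so the mapper sees an NA-free
matrix.

Population-structure covariates are the top-k (default 7) strain-side
singular vectors of the normalised genotype matrix, each marker centred
by its allele frequency p and scaled by √(p(1−p)) — the haploid variant
of the usual eigenanalysis normalisation, since segregants carry one
allele copy.

## Residual traits (pt and phRes)

For each child/parent trait pair (protein/transcript, or
phosphopeptide/protein-of-origin), both sample-level vectors are
standardised using moments computed **only on samples where both are
measured**, then applied to all non-missing entries (the handling of
entries outside the shared set is our interpretation; the alternative
— leaving them unstandardised — would mix scales).  The child is then
regressed on the parent with an MM estimator and the residuals averaged
per strain, in that order (regress first, average second).  Pairs with
fewer than 10 shared samples (configurable) or zero spread are skipped
and logged.

**MM details.** The S stage minimises a high-breakdown M-scale of the
residuals: mean ρ(r/s) = 0.5 with the Tukey bisquare ρ at tuning
1.5476 (50% breakdown, consistent at the normal).  The scale *must* use
a bounded ρ: an unbounded (classical Huber) ρ gives the scale a
breakdown point of zero, and in experiments with 20% gross outliers the
scale inflated several-fold and dragged the fit — this is why the
implementation departs from a literal "Huber-type" S stage and matches
what standard MM implementations actually do.  Candidate fits are exact
two-point lines from a seeded subsample (50 draws) plus the OLS line;
the best candidate is refined by reweighted least squares with scale
updates.  The M stage is IRWLS with bisquare ρ at 4.685 (95% Gaussian
efficiency), scale held fixed, tolerance 1e-8, at most 50 iterations;
non-convergence is flagged and the last iterate used.  A perfect linear
fit short-circuits with zero residuals.

Batch correction is per-trait, per-batch mean centring (grand mean
restored).  The batch structure in the synthetic data is additive, so
an empirical-Bayes method would add machinery without changing the
estimand; this is a deliberate simplification of the pipeline stage.

## Random-Forest QTL mapping

Each strain-level trait (replicates averaged first; strains with a
missing value dropped for that trait) is modelled by a regression
forest over all collapsed markers plus the structure covariates.
Defaults: 500 trees (200 in the self-calibration experiments), p/3
candidate predictors per split, minimum node size 5 — standard
regression-forest settings.  Two importances are combined per
predictor:

* **RSS** — mean over trees of the total decrease in node sum of
  squared residuals from splits on the predictor;
* **PI** — mean over trees of the increase in out-of-bag mean squared
  error after permuting the predictor within the tree's out-of-bag
  samples.  The raw difference is used, not the ratio to the per-tree
  base error: the ratio form explodes whenever a strong covariate
  drives the base error toward zero, which manifested as spurious
  significance in structured-trait experiments.

The combined score is S = max(0, RSS) · max(0, PI).  Covariate scores
are computed but never reported as QTLs.

**Permutation null and FDR.** The trait vector is permuted across
strains (covariates stay attached to the genotypes, being functions of
them) and the forest rerun; permutation b is seeded from (seed, b), so
the null matrix is bitwise reproducible.  Two estimators are provided:

* `estimate_fdr` — per trait, at marker level:
  FDR(s) = mean over permutations of #{null S ≥ s} / #{observed S ≥ s},
  q_i = min over thresholds s ≤ S_i, clipped to [0, 1].
* `pooled_linkage_fdr` (the `map_traits` default) — pooled across
  traits and counted at the **linkage** level: for each threshold the
  observed count sums, over traits, the merged groups of significant
  markers (transitive closure of map adjacency and LD r > 0.8), and the
  null count averages the same quantity over every trait's permutation
  forests.

The pooled linkage estimator is the package's reconstruction of
permutation-based FDR control for this caller, validated by calibration
simulation rather than by matching published QTL counts.  The per-trait
marker-level estimator cannot control the false-discovery proportion of
the *reported calls* in a realistic mixture: whatever the number of
permutations, a fully null trait's top marker exceeds the 0.9 quantile
of its own null maxima with probability ≈ 0.1, so with 80% null traits
the realized FDP plateaus near 0.3.  Pooling gives the estimator
resolution proportional to the number of traits, and counting linkages
instead of markers matches the unit in which calls are reported, so the
nominal 10% threshold controls the FDP of the calls themselves
(measured ≈ 0–11% across calibration seeds, power ≥ 0.9 for loci
explaining ~30% of variance at 110 strains).

**Merging.** Significant markers merge into one QTL when adjacent on
the unique-marker map or correlated at r > 0.8 (the LD rule may join
markers across chromosomes).  The peak is the member with maximal S,
ties toward the smaller genomic coordinate; the effect size attached to
a QTL is the allele log2 fold change at the peak, mean(BY) − mean(RM).

## Heritability

One-way random-effects method of moments on strains with ≥ 2
replicates: σ_E² is the pooled within-strain variance; σ_G² =
max(0, (MS_between − MS_within)/n₀) with the unbalanced effective
replicate count n₀ = (N − Σn_i²/N)/(k−1); H² = σ_G²/(σ_G² + σ_E²)
clipped to [0, 1].  On balanced designs this is exactly the classical
ANOVA estimator, and it is equivalent in expectation to a mixed-model
fit for this one-way layout, which is why no mixed-model dependency is
used.  Standard errors use a delete-one jackknife over replicated
strains (strain-level deletion; the replicate-level alternative would
break the grouping that defines the estimand); significance comes from
permuting strain labels among samples, p = (1 + #{null ≥ obs})/(1 + B).

## Characterisation

Transmission classes use Δep = sign(E_e)·(E_e − E_p) with threshold
0.15: above +0.15 buffered, below −0.15 enhanced, otherwise similar
(the boundary value itself is similar, matching the strict
inequalities); E_e = 0 is reported unclassified.  A protein-layer QTL
is *protein_only* when no transcript-layer QTL of the same gene shares
a marker with it or is linked at r > 0.8.  Local/distant calls use
r ≥ 0.8 between any QTL member and the unique markers directly flanking
the gene midpoint (single flank at chromosome ends).

Hotspots: the genome is divided into 40-kb bins per chromosome, the
final partial bin merged into its predecessor (terminal bins can be
bigger).  Per layer, λ = total linkages / total bins, and the count
threshold is the smallest k with Poisson CDF ≥ 1 − α (α = 0.01),
computed by exact term summation; bins with count > k are hotspot
candidates and consecutive candidates merge.  This quantile convention
is declared rather than fitted: the five printed thresholds in the
source study are not all consistent with any single convention we
could reconstruct, so they are not used as numeric targets.

Sequence context: up/downstream windows span 2 kb from the outer UTR
borders; SNP counts are by 1-based inclusive interval membership;
amino-acid changes collapse multiple SNPs in one codon to one event;
genes with indels are excluded; phosphosite-to-variant distance is the
minimum absolute residue difference.

## Integration

Peptides aggregate to protein-level phospho traits as the mean of
z-scored peptides.  Top-correlator extraction uses pairwise-complete
Pearson correlation, restricted (when gene maps are supplied) to genes
measured on every layer, ranking by |r| by default — the choice between
signed and absolute ranking is genuinely open, so a flag switches it.
Mediation is the linear product-of-coefficients method: a from m ~ x,
(c′, b) from y ~ x + m; ACME = a·b, ADE = c′, total = a·b + c′, with
two-sided percentile-bootstrap p-values over strains (999 draws by
default, add-one correction so p ∈ (0, 1]).  Under linear models with
no exposure–mediator interaction this coincides with the
counterfactual ACME.  When the mediator is an exact function of the
genotype the outcome model is rank-deficient and the decomposition
unidentified; the implementation then attributes the whole effect to
the mediated path (b from y ~ m, c′ = 0), which reproduces the
noiseless full-mediation limit.  Enrichment machinery is the one-sided
(greater) Fisher exact test with the sample odds ratio (∞ when an
off-diagonal margin is empty).

## Problem sizes used by the self-checks

The calibration experiments run mixed panels of 110 strains and ~300
collapsed markers.  `scripts/acceptance.py` uses 3 seeds × 40 traits
(32 null + 8 with one ~30%-variance locus), 200 trees and 25
permutations per forest (~15 minutes on one CPU); the test suite uses
2 seeds × 30 traits at 150 trees / 20 permutations, and 15 peptides for
the residual-specificity check.  These sizes are the package's choice
for routine verification; the estimators themselves are size-agnostic,
and the permutation count only sets the resolution of the pooled null
(≥ 20 enforced).

## Known limitations

* The forest-based caller localises QTLs only to linkage resolution;
  no interval mapping, kinship mixed models, or epistasis scans.
* Structure covariates included as forest predictors dilute but cannot
  remove structure-driven signal when the structure axis lies in the
  span of the markers (as in a clonal or family design): whenever a
  split's candidate subset excludes the covariate, a correlated marker
  substitutes and earns genuine importance.  In a biparental cross
  panel this is moot — there is no external structure axis — but users
  mapping structured panels should not expect the covariates to act
  like fixed-effect adjustment.
* The per-trait marker-level FDR estimator is provided for
  completeness but is conservative in resolution and anti-conservative
  at the call level (see above); the pooled linkage estimator is the
  supported default.
* Mediation assumes linearity and no exposure–mediator interaction;
  bootstrap p-values inherit the usual percentile-interval small-sample
  behaviour.
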