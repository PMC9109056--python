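# crossqtl

Multi-omics QTL mapping for biparental haploid segregant panels.

Genetic crosses between two yeast strains (BY × RM and its relatives)
are a workhorse for dissecting how genomic variation propagates through
molecular layers: from transcript abundance (eQTL) to protein abundance
(pQTL) to protein phosphorylation state (phQTL), and on to physiology.
`crossqtl` provides the full analysis chain for such panels, plus a
synthetic-panel generator with known ground truth so every stage is
testable without any external data:

* **Genotype processing** — call-rate/MAF filtering, double-recombinant
  flagging, 20-kb neighbour imputation, collapsing of identically
  segregating adjacent markers into unique mapping markers, and
  population-structure eigenvectors from the √(p(1−p))-normalised
  genotype matrix.
* **Trait processing** — gene-length correction
  c′ = log₂(2ᶜ·1000/l), per-batch centring, replicate averaging, and
  residual trait layers: post-transcriptional (**pt**, protein
  regressed on transcript) and phospho-residual (**phRes**,
  phosphopeptide regressed on its protein of origin) via robust MM
  regression (50%-breakdown S-scale, bisquare M stage at 4.685).
* **QTL mapping** — per-trait regression forests over markers +
  structure covariates, scored with the combined variable importance
  S = max(0, RSS) · max(0, PI), significance from permutation nulls with
  an empirical FDR pooled across traits at the linkage level, and
  merging of adjacent / LD-linked (r > 0.8) significant markers into
  single QTL calls.
* **Heritability** — broad-sense H² = σ_G²/(σ_G² + σ_E²) from
  replicated strains (one-way method of moments, delete-one jackknife
  SEs, permutation p-values).
* **Characterisation** — allele effects E = mean(BY) − mean(RM),
  transmission classes via Δep = sign(E_e)(E_e − E_p) with a 0.15
  threshold (similar / buffered / enhanced / protein-only),
  local–distant calls against the gene's flanking markers, Poisson
  40-kb-bin hotspot detection, and SNP context counts around genes.
* **Integration** — top molecular correlators of physiological traits,
  ACME mediation (product method, 999-draw percentile bootstrap), and
  one-sided Fisher enrichment machinery.

See `docs/methods.md` for the models, estimators and numerical choices.

## Worked example

Simulate a small panel, map the transcript layer, and look at the calls:

```python
import crossqtl as cq
from crossqtl.mapping import ForestConfig

mm   = cq.make_marker_map({"chrI": 760_000, "chrII": 760_000}, 10_000)
geno = cq.simulate_genotypes(mm, n_strains=110, seed=3)
cfg  = cq.SimulationConfig(n_strains=110, n_transcripts=12,
                           chrom_lengths={"chrI": 760_000, "chrII": 760_000})
layers, annot, truth = cq.simulate_trait_layers(geno, cfg, seed=3)

uset = cq.process_genotypes(geno)                      # unique mapping markers
cov  = cq.structure_eigenvectors(uset.calls, k=7).vectors
qtls = cq.map_traits(layers["transcript"], uset, cov,
                     ForestConfig(n_trees=200, n_permutations=25, seed=0),
                     layer="transcript")
print(len(uset.markers), "unique markers")
print(qtls[["trait", "chrom", "peak_marker", "q_value", "effect", "n_markers"]])
```

Output (about a minute on one CPU):

```
150 unique markers
      trait  chrom  peak_marker  q_value    effect  n_markers
0  gene0000  chrII  chrII_u0020     0.00 -1.524498          5
1  gene0002  chrII  chrII_u0004     0.00  1.112192          5
2  gene0003  chrII  chrII_u0042     0.00  0.867132          3
3  gene0004   chrI   chrI_u0018     0.06  0.468204          1
4  gene0005  chrII  chrII_u0002     0.00  1.637095          5
5  gene0006   chrI   chrI_u0057     0.00 -1.094286          4
6  gene0008   chrI   chrI_u0028     0.00  1.059996          4
7  gene0009  chrII  chrII_u0055     0.00 -1.145043          5
8  gene0010  chrII  chrII_u0072     0.00 -0.950921          5
9  gene0011  chrII  chrII_u0064     0.00 -0.931422          4
```

Ten calls for the ten simulated causal transcripts (the two null traits
produce none), each row one merged linkage: the peak unique marker, its
empirical q-value from the permutation null, the allele log2 fold
change at the peak (BY minus RM, so a simulated effect of +1.41 on the
RM allele appears as E ≈ −1.5), and how many significant markers were
merged.  Comparing
`qtls` with `truth.links` shows which calls hit the planted loci; the
bundled experiments (`crossqtl.evaluation`) automate exactly that
comparison to measure false-discovery proportion and power.

A thin CLI mirrors the library (`crossqtl simulate / residuals / map /
heritability / integrate`); run `crossqtl --help`.

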