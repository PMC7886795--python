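# commphen

Community profiling and genome-reconstruction phenotype prediction for
cultured gut microbiomes.

## The problem

*In vitro* fecal cultivation is a common way to test whether a substrate
(a prebiotic, a medicinal herb, a purified fiber) reshapes a gut
microbial community: a pooled fecal inoculum is grown in a chemically
defined medium with and without the supplement, and the resulting
communities are profiled by 16S rRNA amplicon sequencing at phylotype
resolution (unique sequence variants approximating strains/species).
Composition alone does not say what the restructured community can *do*,
so the profile is combined with curated reference genomes: each genome
carries binary phenotypes (1 iff it encodes a complete metabolic pathway
or CAZyme family), and these are projected onto the observed taxa to
predict the community's metabolic capacity — short-chain fatty acid
synthesis, vitamin biosynthesis, amino acid biosynthesis, glycoside
hydrolase repertoires, and sugar utilization.

`commphen` implements that full analysis as a tested, reusable library
with a CLI, exercised end to end on synthetic communities with known
planted structure (no sequencing data or proprietary genome collection
required).

## The core quantities

**Community Phenotype Index (CPI).** Let a taxon *t* observed at
relative abundance *a_t* map to the reference genomes of its species,
and let *p_{t,φ}* ∈ [0,1] be the mean of those genomes' binary values
for phenotype *φ* (the fraction of the species' genomes encoding it).
Then

    CPI(φ) = 100 · Σ_t p_{t,φ} · a_t        (scale 0–100 %)

estimates the percentage of cells in the community carrying capability
*φ*. Unmapped abundance dilutes the index toward 0 by default; an
optional mode renormalizes over mapped taxa, and the mapped fraction is
always reported. Capabilities reachable by several routes (e.g.
butyrate synthesis via carbohydrate-derived or amino-acid-derived
pathways) are handled as *pathway sets*: a genome counts as a producer
if it encodes **any** route active in the given medium — in a
sugar-free control medium only the amino-acid fermentation routes count,
while supplemented cultures admit all routes. Sugar utilization is the
AND of catabolic pathway and uptake transporter presence.

**Diversity.** Shannon entropy H = −Σ *p_i* ln *p_i* per sample;
weighted UniFrac between samples on a midpoint-rooted phylogeny,
d(A,B) = Σ_i l_i |A_i − B_i| over branches *i* (normalized variant
divides by Σ_i l_i (A_i + B_i)); classical PCoA (metric MDS of the
double-centred squared distance matrix) for ordination.

**Differential screen.** Taxa are classified by the ratio of mean
relative abundances (condition / control): up at ≥ k, down at ≤ 1/k
(default k = 5), with dedicated classes for taxa detected in only one
condition. Group comparisons use a double-tailed Mann–Whitney U test —
exact by enumeration for the tiny replicate counts typical of culture
experiments — or Welch's t-test, and a 2×2 chi-squared for
presence/absence frequencies. Samples with fewer than 5,000 reads are
excluded before any comparison.

## Worked example

```python
import commphen as cp

ds  = cp.simulate_dataset(cp.SimulationConfig(seed=1, depth_range=(100_000, 100_000)))
rel = cp.normalize(ds.counts)

print(cp.shannon_table(rel).round(3).to_string())
res = cp.fold_screen(rel, ds.metadata, "herb")
print(cp.screen_summary(res))

prof = cp.CommunityPhenotypeProfiler(ds.bpm, ds.taxonomy).fit()
_, psets = cp.load_panels()
ctrl = list(ds.metadata.index[ds.metadata.condition == "control"])
herb = list(ds.metadata.index[ds.metadata.condition == "herb"])
bc = prof.pathway_set_profile(rel[ctrl], psets["butyrate"], "control")["cpi"].mean()
bh = prof.pathway_set_profile(rel[herb], psets["butyrate"], "herb")["cpi"].mean()
print(f"Butyrate producer CPI: control medium {bc:.1f}%  herb medium {bh:.1f}%")

sh = cp.shannon_table(rel)
mw = cp.mann_whitney(sh[herb].to_numpy(), sh[ctrl].to_numpy())
print(f"Shannon herb vs control: U={mw.statistic:.1f}, p={mw.pvalue:.4f} ({mw.method})")
```

Output:

```
control_r1    3.428
control_r2    3.406
control_r3    3.395
herb_r1       3.524
herb_r2       3.521
herb_r3       3.536
herb_r4       3.538
herb_r5       3.529
{'n_up': 5, 'n_down': 5, 'n_herb_only': 2, 'n_control_only': 0, 'n_null': 28, 'n_up_total': 7}
Butyrate producer CPI: control medium 64.6%  herb medium 83.5%
Shannon herb vs control: U=15.0, p=0.0357 (mann_whitney_exact)
```

The screen recovers exactly the planted structure of this simulation
(5 six-to-seven-fold increases, 5 decreases, 2 supplement-only taxa out
of 40). The butyrate CPI rises under supplementation both because
producer taxa expand and because the supplemented medium activates the
carbohydrate-derived routes. The Shannon comparison at n = 5 vs 3 uses
the exact U distribution; p = 0.0357 is the smallest two-sided p that
design can produce.

## Command line

```bash
commphen simulate --out sim/ --seed 1          # synthetic study bundle
commphen run --config run.json --out run/      # full pipeline
commphen report --rundir run/                  # figures (PCoA, Shannon,
                                               # family bars, CPI, GH deltas)
```

`run.json` points at the count table, sample metadata, taxonomy map,
binary phenotype matrix TSV and Newick tree; single stages are also
exposed (`commphen qc|diversity|screen|cpi|stats`).

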