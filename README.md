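# hotcomp

Comparative recombination-hotspot analysis for multi-population LD-based
recombination maps. The package stitches per-window rate estimates into
chromosome-wide maps, detects locally defined hotspots against a simulation
null, quantifies hotspot sharing across populations against genetic
differentiation and a drift tree, tests feature/repeat enrichment with
size/count-matched resampling nulls, and fits a recessive-model GLM linking
missense-mutation homozygosity to population-level recombination rate. A
first-class synthetic-data generator produces every input format so the
whole pipeline runs and is tested without external data.

## Modules

| module            | role |
|-------------------|------|
| `io_formats`      | readers/writers: LDhat-style rates text, BED, GFF3, newick, TSV matrices, genome layout, population metadata |
| `synthetic_data`  | seeded generators: drift tree, tree-structured hotspot gain/loss, autocorrelated rate landscapes with intensity spikes, MCMC-trace emulation, gene/repeat annotations, F_ST proxy, genotype tables with injected effects |
| `ratemap`         | window planning/stitching, rho -> r conversion, genome summaries with bootstrap CIs, trace-uncertainty report, Kruskal-Wallis + pairwise Wilcoxon with Bonferroni, confound regressions |
| `hotspot_calling` | 1 kb window scan vs a gamma background null (nsims simulations, empirical p, alpha refinement, merging), hotspot/genome and hotspot/flank rate contrasts |
| `comparison`      | consensus hotspots, Boolean sharing matrix, upset-style subset counts, ubiquitous hotspots, pairwise Fisher overlap tests (bedtools:fisher contingency semantics), Jaccard distances, Mantel test |
| `phylo_trait`     | MCA of the sharing matrix; Brownian-motion vs Ornstein-Uhlenbeck fits along the drift tree compared by AIC |
| `enrichment`      | strand-aware TSS/TTS flanks; size/count-matched uniform placement nulls for feature overlap and repeat bp content |
| `suppressor_glm`  | homozygous-alternative frequencies, r^2 = 1 pruning, Gaussian identity-link GLM (OLS with t-tests) |

## Command line

```bash
# generate a complete synthetic dataset (rates, hotspots, tree, F_ST,
# annotations, genotypes) under out/
hotcomp simulate --out out --seed 1            # optionally --config sim.yaml

# stitch per-window LDhat rate files into one chromosome map
hotcomp stitch w0.txt w1.txt w2.txt --out stitched.txt

# per-population mean/median r with bootstrap CI
hotcomp summarize --rates-dir out --meta out/meta.tsv --out summary.tsv

# Kruskal-Wallis + pairwise Wilcoxon + Bonferroni cutoff
hotcomp compare-rates --rates-dir out --meta out/meta.tsv --out-prefix cmp

# hotspot calling on one rate map (BED6 output, p in the score column)
hotcomp call-hotspots --rates out/rates_pop1_chr1.txt --out hs.bed \
    --nsims 1000 --alpha 0.001 --seed 1

# consensus/sharing/Jaccard/Mantel (+ pairwise Fisher with --genome)
hotcomp compare --hotspots out --fst out/fst.tsv --out cmpdir \
    --genome out/layout.tsv

# MCA + BM vs OU along the drift tree
hotcomp phylo --sharing cmpdir/sharing_matrix.tsv --tree out/tree.nwk \
    --dims 9 --out phylo.tsv

# feature-overlap and repeat-content enrichment
hotcomp enrich --hotspots out/hotspots_pop1.bed --genes out/genes.gff3 \
    --repeats out/repeats.bed --genome out/layout.tsv --nsims 1000 \
    --seed 1 --out enrich.tsv

# recessive homozygosity GLM
hotcomp glm --genotypes out/genotypes.tsv --rates out/median_r.tsv \
    --out coeffs.tsv
```

## Rates text dialect

LDhat-`stats`-style whitespace-separated text with one header line. Each
subsequent row holds a SNP position (kb with 3 decimals by default) and the
mean rho of the interval to its right (per kb by default; zero on the final
row). `io_formats.LdhatDialect` switches positions/rates to bp units.
Internally positions are integer bp and rho is Morgans/bp everywhere.

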