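# admixscan

Windowed population-genomic statistics and selection scans for admixed
cohorts, plus a synthetic-data generator that makes every stage testable
without external downloads.

The package implements, as a reusable pipeline:

- **core_io** — VCF reading (biallelic SNPs, phased haplotypes) into a
  haplotype matrix, vcftools-style hard filters (call-rate ≥ 0.5, minor
  allele count ≥ 2), population maps, coordinate- and SNP-count-based
  windows, and TSV table I/O. Internal coordinates are 0-based half-open.
- **sexlink** — coverage-based scaffold classification
  (X / autosome / Y / repeat / too-small) from normalized per-sample read
  depth, using threshold rules with ceil-of-fraction vote counts.
- **popstats** — per-window nucleotide diversity, Hudson F_ST
  (ratio-of-averages with finite-sample corrections), the population branch
  statistic (PBS), and an unfolded joint SFS polarized by a fixed outgroup
  allele.
- **topoweights** — neighbour-joining window trees from pairwise Hamming
  distances, quartet topology weighting over (outgroup, west, east, focal)
  groups with exhaustive enumeration or seeded subtree sampling, the >50%
  window classification rule, the per-window ancestry score (w1 − w2), and
  Spearman score correlations between focal populations.
- **allele_sharing** — f4 statistics for quartets ([A,B],[C,D]) with
  block-jackknife standard errors (500-SNP blocks that never span
  scaffolds) and Z-scores.
- **selection_scan** — top-1% PBS outlier calling split by chromosome
  class, overlap categories across comparisons (shared-two / shared-three /
  plus-native / plus-introduced / unique), a without-replacement overlap
  randomization null with empirical p-values, and a chi-squared
  ancestry-composition enrichment test.
- **simulate** — a hierarchical Balding–Nichols generator with two source
  lineages, shared or independent per-window admixture in introduced
  populations, X-linked drift inflation, planted directional selection, and
  matching depth tables; emits VCF / popmap / lengths / truth / depth files
  deterministically under a seed.
- **pipeline** — YAML-configured orchestration of all stages with stable
  per-stage sub-seeding and a JSON run manifest.

## Command line

The `admixscan` entry point exposes one subcommand per stage plus a full
run:

```bash
# generate a synthetic dataset
admixscan simulate --seed 1 --out-dir out/sim

# individual stages
admixscan filter --vcf out/sim/sim.vcf --out out/filtered.vcf
admixscan sexlink --depths out/sim/depth.tsv \
    --lengths out/sim/scaffold_lengths.tsv \
    --popmap out/sim/popmap.tsv --out out/assignment.tsv
admixscan popstats --vcf out/filtered.vcf --popmap out/sim/popmap.tsv \
    --pi-pop I1 --fst-pair I1,W1 \
    --pbs-triplet I1_btw,I1,W1,E1 --out out/window_stats.tsv
admixscan topoweights --vcf out/filtered.vcf --popmap out/sim/popmap.tsv \
    --outgroup OUT --west W1 --east E1 --focal I1 \
    --snps-per-window 25 --out out/weights.tsv
admixscan f4 --vcf out/filtered.vcf --popmap out/sim/popmap.tsv \
    --quartet OUT,E1,I1,W1 --out out/f4.tsv
admixscan scan --window-stats out/window_stats.tsv \
    --comparison I1_btw=between_range ... --out out/outliers.tsv

# everything from one config
admixscan run --config config.yaml --seed 1 --out-dir out/run
```

A self-contained example config is produced by
`admixscan.pipeline.default_config()`.

## Notes on estimator choices

- F_ST uses the Hudson ratio-of-averages estimator on called genotypes
  (negative window values reported raw, clamped to [0, 1) before the PBS
  log transform).
- Window trees use neighbour joining on Hamming distances; tree inference
  sits behind a single function (`topoweights.nj_tree`) and can be swapped.
- Randomization p-values are reported both raw (can be 0) and with the
  (count+1)/(reps+1) correction.
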