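# acetclust

Cluster core promoters by the spatial distribution of the surrounding
histone-acetylation ChIP-chip signal, and associate the resulting
**upstream / centered / downstream** promoter classes with promoter
architecture and genomic context.

The pipeline:

1. **Filter** promoters: discard every promoter with another promoter within
   ±2,200 bp (either strand; both members of each proximal pair go), then keep
   only promoters with ≥ 1 tiling-array probe in each of the eleven 400 bp
   bins spanning [rep − 2,200, rep + 2,200) around the representative TSS.
2. **Profile**: per-probe score = −10·log10(p-value), averaged over biological
   replicates on the score scale (equivalently, the geometric mean of the
   replicate p-values); mean score per bin, ordered 5'→3' in promoter
   orientation; cumulative sum normalized to [0, 1].
3. **Cluster**: all-pairs Kolmogorov distance (max absolute difference of the
   cumulative profiles) fed to a deterministic PAM k-medoids (greedy BUILD +
   best-improvement SWAP), k = 3 by default; clusters are named by the rank of
   the center of mass of their mean binned profile.
4. **Annotate** each promoter: single-peak vs broad architecture (≥ 50% of
   tags in a 4-nt window), CpG-island and repeat overlap of the core promoter,
   gene / lincRNA start in the strand-relative [−300, +1,000] window, and a
   TATA PWM scan of the strand-relative [−50, −15] window (relative score
   strictly > 0.75; the JASPAR TBP count matrix ships with the package).
5. **Test** associations: per-cluster feature contingency tables with Pearson
   chi-square, Fisher's exact (2×2), Bonferroni correction, Kruskal-Wallis and
   Wilcoxon rank-sum on expression, plus bottom/top-10% expression tiers and
   per-tier repeat fractions.

A first-class **synthetic data module** (`acetclust.synth`) generates promoter
tables, probe tracks (25 bp probes at 35 bp spacing, masked "repetitive" gap
runs, p = 10^(−score/10)), annotation intervals, and genome sequence with
planted ground truth (profile shapes, SP/BR architectures, feature flags,
expression tiers, proximal pairs), so every stage is testable without any
download.

## CLI

```sh
acetclust synth    --out data/ --n-promoters 300 --seed 1      # synthetic dataset
acetclust filter   --promoters data/promoters.tsv --probes data/probes_rep*.bedgraph \
                   --radius 2200 --bins 11 --bin-size 400 --out filtered.tsv
acetclust profile  --promoters filtered.tsv --probes data/probes_rep*.bedgraph --out profiles.tsv
acetclust cluster  --profiles profiles.tsv --k 3 --out assignments.tsv
acetclust annotate --promoters filtered.tsv --cpg data/cpg.bed --repeats data/repeats.bed \
                   --genes data/genes.tsv --lincrna data/lincrna.bed --fasta data/genome.fa \
                   --out annotations.tsv
acetclust stats    --assignments assignments.tsv --annotations annotations.tsv --out stats.json
acetclust run      --seed 7 --out report.json                  # end-to-end on synthetic data
acetclust run      --config pipeline.yaml --out report.json    # YAML config + overrides
acetclust compare  report_0h.json report_96h.json              # concordance between two runs
```

`run` is deterministic under a fixed seed and records a config hash in the
report. Every analysis constant (radius, bin count/size, k, windows,
thresholds, tier fraction) is a named parameter of `PipelineConfig`.

## Layout

| module | role |
| --- | --- |
| `acetclust.synth` | synthetic promoters / probe tracks / annotations with planted truth |
| `acetclust.io` | readers & writers, core record types (0-based half-open throughout) |
| `acetclust.preprocess` | proximal-promoter and bin-coverage filters |
| `acetclust.profiles` | scoring, replicate averaging, binning, cumulative normalization, metagene histograms |
| `acetclust.clustering` | Kolmogorov distance matrix, PAM k-medoids, semantic labels, cross-tabulation |
| `acetclust.features` | SP/BR classifier, overlap/window flags, TATA PWM scan |
| `acetclust.stats` | contingency tables, chi-square/Fisher/KW/rank-sum, expression tiers |
| `acetclust.pipeline` / `acetclust.cli` | orchestration, reports, CLI |
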