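# superbarcode

Whole-organellar-genome DNA barcoding ("super-barcoding") and molecular
species delimitation for small multi-specimen datasets — the situation of a
bryophyte or other plant genus sampled with 2–3 specimens per species and a
complete mitogenome or plastome alignment per specimen.

The package covers the full analysis chain that such studies run:

* **Variation profiling** — nucleotide diversity π (mean pairwise per-site
  difference under pairwise deletion), SNP and indel-event counts, globally,
  per annotated region (CDS / spacer / intron / pseudogene / rRNA / tRNA) and
  in sliding windows (500 bp every 50 bp by default), including hotspot
  ranking.
* **Barcoding diagnostics** — Kimura 2-parameter distances
  `d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)` with transitions *P* and transversions
  *Q*, per-species barcoding gaps (min inter − max intra) with a
  label-permutation significance test, molecular diagnostic characters
  (columns fixed within a species and absent elsewhere), and the classic
  six-panel sliding-window suite (mean K2P, zero non-conspecific distances,
  zero cells, clade congruence, diagnostic sums, species monophyly on
  per-window neighbor-joining trees).
* **Species delimitation** — three engines exposed as model/results pairs:
  `AsapModel` (ASAP-style ranked candidate partitions from single-linkage
  clustering, scored by a panmixia permutation p-value and barcoding-gap
  width), `GmycModel` (single-threshold generalized mixed Yule-coalescent on
  ultrametric trees, with mean-path-length ultrametrization and midpoint
  rooting helpers), and `PtpModel` (Poisson tree processes on
  substitutions-scaled trees, exhaustive/greedy ML plus a Metropolis sampler
  for Bayesian support values).
* **Synthetic data** — a generator (`make_dataset`, preset
  `calypogeia_like`) producing organelle-like alignments with known truth:
  Yule species tree, within-species coalescents, K2P site evolution with
  per-region rate multipliers, indel blocks confined to noncoding regions.

Coordinates are 0-based half-open throughout. Species labels come from a
specimen→species TSV, never from FASTA headers.

## Worked example

```python
import superbarcode as sb

ds = sb.make_dataset(sb.calypogeia_like(seed=1))     # 26 specimens, 11 species
aln = ds.alignment
stat = sb.nucleotide_diversity(aln)
print(f"global pi = {stat.pi:.5f}, SNPs = {stat.snps}, indels = {stat.indel_events}")

dm = sb.k2p_matrix(aln)
res = sb.AsapModel(dm).fit(n_perm=999, seed=1)
print(res.summary().head(3))
print("ARI vs truth:", sb.partition_compare(res.best.groups, ds.true_partition))

fit = sb.gmyc_fit(ds.gene_tree)                      # true ultrametric gene tree
print(fit.summary())
```

prints

```
global pi = 0.01717, SNPs = 1754, indels = 78

 rank  n_groups  threshold  p_panmixia  gap_width  asap_score flags
    1        11   0.003016       0.001   0.489954         6.5
    2        10   0.011593       0.001   0.057112         7.0
    3         9   0.012641       0.001   0.055535         7.5
ARI vs truth: 1.0

Generalized mixed Yule-coalescent (single threshold)
  threshold time T      : 1.71075
  entities              : 10
  Yule    lambda, p     : 1.34152, 1
  Coal    lambda, p     : 3.29731, 1
  logL alt / null       : 46.3323 / 33.4470
  LR = 2*dlogL          : 25.7707  (chi2 df=3, p = 1.065e-05, significant)
```

The best-scored ASAP partition (lowest asap-score, the mean of the two
component ranks) recovers the 11 true species exactly; GMYC places its
threshold between the species divergences and the shallow within-species
coalescents and finds 10 entities here (one recent species pair merged — the
typical lumping behaviour of single-threshold GMYC), with a strongly
significant likelihood-ratio test against the one-process null.

The same analyses run from the shell:

```
superbarcode simulate --seed 1 --out data/
superbarcode pi-windows   --alignment data/alignment.fasta --species-map data/species.tsv
superbarcode gap          --alignment data/alignment.fasta --species-map data/species.tsv
superbarcode asap         --alignment data/alignment.fasta --species-map data/species.tsv
superbarcode gmyc         --tree data/tree.nwk
superbarcode ptp          --tree data/tree.nwk --bayes --seed 123
superbarcode run          --config run.json        # whole pipeline + manifest
```

`--exclude 10000-18000`-style intervals drop columns (e.g. the second
inverted-repeat copy of a plastome) before any statistic is computed.

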