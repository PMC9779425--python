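# Methods

This note documents the models implemented in `superbarcode`, the choices
made where the methodology is genuinely open, and what the synthetic-data
generator does and does not emulate.

## Sequence statistics

**Nucleotide diversity.** π is the mean over all unordered specimen pairs of
the per-site difference proportion. Sites where either sequence of a pair
carries `-` or `N` are excluded *for that pair* (pairwise deletion); pairs
with zero comparable sites are dropped from the mean and counted. Pairwise
deletion is the default because whole-organelle alignments concentrate
indels in spacers, and complete deletion would discard a large share of the
noncoding columns whose variation is precisely the object of interest.
Undefined windows are reported as missing, never as 0.

**SNPs and indels.** A SNP is a column with ≥ 2 distinct states from
{A,C,G,T}; gaps and Ns are ignored. An indel *event* is a maximal run of
consecutive columns sharing one identical gap pattern (the exact set of
gapped specimens) — an event count, matching how indel totals are usually
reported for organellar alignments. Counting gapped columns instead is
available via `count_mode="columns"`.

**Sliding windows.** Windows are `[k·step, k·step+width)` for every k with
the window fully inside the alignment (defaults 500/50). Trailing partial
windows are dropped so per-window values stay comparable; an alignment
shorter than one window yields the single window `[0, length)`.

**K2P distances.** `d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)` with transition and
transversion proportions P, Q computed under the same pairwise deletion.
When an argument of a logarithm is non-positive (saturation) or no site is
comparable, the entry is flagged undefined rather than raised; undefined
entries are excluded from window means and zero-proportion denominators, and
windows with more than half of their cells undefined are missing-marked.
"Zero distance" in the window diagnostics means exactly 0.0 — the shared-
haplotype reading — with no epsilon.

**Diagnostic characters.** A column is diagnostic for species S iff all
members of S share one state in {A,C,G,T} there and no non-member carries
that state; a gap/N inside S disqualifies the column, gaps/Ns among
non-members neither match nor disqualify.

**Barcoding gap.** Per species: largest intraspecific distance, smallest
distance to a non-conspecific, and their difference. Significance is a
label-permutation test (species labels shuffled over specimens, group sizes
fixed; `p = (1+#{gap* ≥ gap})/(1+n_perm)`). The permutation design is this
package's choice of test; its type-I error is verified against the nominal
5% level in the test suite. Singleton species report intra = 0 with a flag.

**Per-window trees.** Neighbor joining (scikit-bio) with negative branch
lengths clamped to zero. Clade congruence between a window tree and the
full-data tree compares non-trivial unrooted bipartitions, since NJ trees
carry no meaningful root. A species is monophyletic in a window when some
edge isolates exactly its members; singletons count as monophyletic.

## ASAP-style partitioning

Single-linkage agglomeration over the pairwise distances yields one nested
candidate partition per distinct merge height (plus the all-singleton
partition). Two scores per candidate:

* **Panmixia p-value** — the permutation probability that random labels with
  the same group sizes separate intra from inter distances as cleanly at the
  candidate's threshold (statistic: inter-group pairs at distance ≤
  threshold; lower is cleaner).
* **Gap width** — the candidate's observed barcoding gap, (smallest
  inter-group distance − largest intra-group pairwise distance) / mean
  distance. Under single linkage the smallest inter-group distance equals
  the next merge height. Using the *actual* largest intra-group distance —
  not the merge threshold — matters: partitions that bury large distances
  inside their groups (e.g. two species fused, or deep substructure hidden)
  score poorly, which is what makes the species-level cut win against both
  coarser and finer cuts.

The asap-score is the mean of the two rank columns (lower is better); ties
break toward fewer groups, then lower threshold. This is a
faithful-in-spirit reimplementation of the published scoring scheme
(ranked panmixia probability and gap width averaged into one score), not a
bit-compatible port of the original program, whose analytic panmixia model
is not public in comparable detail; `AsapResults.all_candidates` records
every component so runs can be set against original-ASAP output.

## GMYC (single threshold)

An ultrametric tree is split at a time threshold T: branching older than T
follows a Yule process with rate `λ_y·k^{p_y}` (k lineages), branching
younger than T follows independent per-cluster coalescents with combined
rate `λ_c·Σ_j C(m_j,2)^{p_c}`, the clusters being the subtrees hanging
below the branches crossing T. Intervals between node ages contribute
survival terms and each node the total rate of its regime, evaluated with
the lineage counts of the interval on its recent side. A fully coalesced
cluster contributes zero rate, so eventless stretches between the species
radiation and the shallow coalescents are cheap for the threshold model and
expensive for the null — that is the source of the method's power. The rate
parameters profile out analytically; the exponents, when free, are
optimized in one dimension per candidate threshold (candidates: midpoints
between consecutive distinct node ages plus the two degenerate ends).

Decisions on the points the literature leaves open:

* **Null model** — one branching process over the whole tree, identical to
  the degenerate all-coalescent candidate, which guarantees
  `logL_alt ≥ logL_null`.
* **Exponents** — fixed at 1 by default (`free_exponents=True` enables the
  generalized scaling). In simulation the free exponents let the null
  absorb genuine multi-species structure and inflate the LR under the null,
  degrading both recovery and calibration, so the strict processes are the
  default.
* **LR reference** — χ² with df = 3 by default. The threshold parameter is
  not identified under the null, so no textbook df applies; df = 3 puts the
  empirical type-I error on 20-tip single-population coalescent trees at
  ≈ 5% (df = 2 measured ≈ 18%). `df` is a parameter.
* Trees must be rooted, binary, ultrametric; `ultrametrize()` provides
  mean-path-length smoothing (each node's age = mean node-to-tip path
  length, children clamped below parents), the uncalibrated special case of
  rate-smoothing dating, and `midpoint_root()` a deterministic midpoint
  rooting (diameter ties broken by tip-label order).

## PTP (ML and Bayesian)

A delimitation is an antichain of "species root" nodes covering all tips;
edges inside species subtrees and the remaining (speciation) edges form two
iid Exponential classes. For a fixed delimitation the profile
log-likelihood is `Σ_class n·log(n/S) − n`; an empty class contributes 0 and
a zero-length class sum is rate-capped (1e10) with a flag. The ML search is
exhaustive for ≤ 12 tips (the admissible-delimitation count is small) and
greedy hill-climbing over split/merge moves with 25 seeded restarts
otherwise; single-species and all-singleton states are always evaluated and
likelihood ties break toward fewer species. The Bayesian variant is a
Metropolis sampler over the same state space (uniform prior, split/merge
proposals with a Hastings correction for the move-count asymmetry,
defaults 500,000 generations / thinning 100 / seed 123 / 10% burn-in);
support of a species is the fraction of retained samples containing exactly
that tip set, and a split-half support correlation is reported as a
convergence diagnostic. Unrooted input trees are midpoint-rooted first,
since the edge classification needs a root.

## Synthetic data generator

Three layers, one root seed (sub-streams by fixed offsets, so bundles are
byte-stable):

1. **Yule species tree** — waiting time to the next speciation
   ~ Exponential(birth_rate·k). `min_species_sep` lengthens every pendant
   species branch, imposing a floor of `2·min_species_sep·subs_rate` on
   interspecific divergence without touching the topology.
2. **Within-species coalescents** grafted on each species tip, timescale
   `Ne = theta/(2·subs_rate)` so the expected pairwise intraspecific
   divergence is θ. Event times are truncated at `coal_depth_cap·Ne`
   (default 3, shifting E[divergence] by about −5%): organellar genomes
   have small effective sizes and the emulated datasets show clean
   within-species clusters, so the deep exponential tail is cut off.
   Incomplete lineage sorting across species is deliberately ignored (one
   non-recombining organellar locus, strongly diverged species); a
   coalescent deeper than 90% of its pendant branch is compressed onto it.
3. **K2P site evolution** along the gene tree with per-region rate
   multipliers (and optional hotspot factors), root sequence uniform;
   indels are Poisson block events in noncoding regions only, geometric
   lengths, each gapping the whole descendant clade — the generator emits a
   true alignment and needs no re-alignment.

The `calypogeia_like` preset fixes the study-like conditions: 11 species,
26 specimens (four species with three specimens, seven with two),
θ = 0.001 substitutions/site, substitution rate 0.003 per unit time,
κ = 2, minimum species separation 1.7 time units (so interspecific
divergence ≥ 0.010, an order of magnitude above θ, with most pairwise K2P
below ~0.03), noncoding regions (spacers, introns, one pseudogene) at 1.5×
the coding rate, ~70/30 coding/noncoding template of ~18.7 kb by default
(scaled down from full organelle size for tractability; the template
repeats an organelle-like CDS/spacer/intron unit), indel rate 5×10⁻⁴ per
noncoding column per unit time with geometric mean length ≈ 3.3. The
hotspot variant multiplies the pseudogene region by a further 10×.

What passing tests on these data do *not* show: robustness to alignment
error (the generator emits true alignments), to rate heterogeneity beyond
region multipliers (no gamma variation, no codon structure, no base
composition skew), to recombination or ILS, or to the base-frequency
asymmetries of real organellar genomes. Conclusions about real data should
lean on the oracle-equivalence and calibration results, not on the recovery
rates alone.

## Numerical choices and degenerate inputs

Exponent optimization is bounded to [−3, 3]; profile weights are floored at
1e-300 to keep logs finite on zero-length intervals. Ultrametricity is
checked at 1e-8 relative tolerance; ultrametrization clamps children 1e-12
of the root age below their parents. NJ tie-breaks follow input order and
negative branch lengths clamp to 0. Polytomies (including basal
trifurcations of unrooted input) are resolved deterministically by smallest
descendant label with zero-length branches. All-identical distance matrices
yield a single flagged candidate partition. Alignment columns containing
only gaps/N make pairs undefined, and an alignment where every pair is
undefined raises rather than returning a silent 0.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the preset at ~18.7 kb ×
26 specimens with 100-seed recovery loops, 400-replicate gap-test
calibration (199 permutations each) and 100-replicate GMYC null
calibration — sizes chosen so the whole suite completes in a few minutes on
one CPU while keeping every rate estimate's binomial error a few percent.
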