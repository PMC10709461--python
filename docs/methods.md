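# Methods

`lxeflow` asks whether suppressed recombination limits interspecific gene
flow, using three coordinated analyses over four gene categories — autosomal
and X-linked genes in frequently- vs rarely-recombining regions (freqA,
rareA, freqX, rareX): per-gene polymorphism statistics, joint-SFS demographic
inference under isolation-with-migration (IM) models, and gene-expression
divergence. A synthetic-data generator reproduces the statistical structure
of the study design so every stage runs, and is tested, without external
data.

## Polymorphism statistics

All statistics are computed on haplotype rows (two per diploid sample, after
pseudo-phasing) with complete deletion: within each gene and site class,
alignment columns with any N or gap are dropped and the retained count
reported. Site classes come from codon structure: fourfold-degenerate third
positions (most neutral), first two codon positions (least neutral), and all
sites. Degeneracy requires unanimity — a codon whose first two positions are
polymorphic in a way that changes the degeneracy family contributes no
fourfold site. This is a deliberate choice (the alternative, per-row
classification, lets a site change class between species); it only discards
sites, never misclassifies them.

Definitions: π is the mean per-site pairwise mismatch fraction within a
species (all unordered row pairs, the unbiased n/(n−1) form); D_xy the same
over between-species pairs; F_ST = 1 − π̄_w / D_xy (Hudson/Nei family; the
estimator family is configurable because more than one is in common use);
Tajima's D uses the standard constants and is undefined at S = 0; Z_nS is the
mean r² over all pairs of biallelic segregating sites, computed on
haplotypes. Undefined values (monomorphic genes, zero between-species
diversity) propagate as NaN and are excluded listwise from group tests, with
counts retained in the per-gene table. For X-vs-autosome comparisons,
autosomal π can be multiplied by 0.75 (the X has 3/4 of the autosomal
effective size); adjusted and raw values are both kept.

Group comparisons use Kruskal–Wallis (tie-corrected, χ² reference) plus
pairwise Mann–Whitney U tests (normal approximation with tie correction)
summarized as a compact letter display built by insert-and-absorb: two
groups share a letter iff their pairwise test is not significant at α = 0.05.
No multiple-testing correction is applied to the pairwise matrix by default
(a Holm option exists); the letters are descriptive, mirroring standard
boxplot annotation practice.

## Joint SFS

Spectra are (n1+1)×(n2+1) matrices over variant-allele counts, corners
masked. Sites with missing rows are projected down by hypergeometric
expectation; sites with more than two alleles are skipped. Observed spectra
are folded by default (no outgroup): each cell is combined with its point
reflection, mass stored on or below the folding diagonal, self-conjugate
cells counted once. Gene-level bootstrap resamples genes with replacement
(per-gene spectra cached, so replicates are exact).

## Demographic models and likelihood

Five two-population models, all with an ancestral population of relative
size 1: `split_mig` (constant sizes N1, N2, symmetric migration M),
`IM` (split at sizes (s, 1−s), exponential change to (N1, N2), symmetric M),
`IM2` (directional M1, M2), and the two-class mixtures `IM_2M` / `IM2_2M`
in which a latent fraction P of sites carries class-A migration rates and
1−P class-B rates, sharing one θ. Units: sizes in N_A, time T in 2·N_A
generations, migration M = 2·N_A·m. Free-parameter counts: 4, 5, 6, 7, 9.

Expected spectra come from a Monte-Carlo structured coalescent (numba):
backward in time, deme sizes follow the exponential trajectories, events are
sampled exactly by thinning against an upper-bound hazard (the trajectories
are monotone, so the minimum deme size on the remaining interval is at an
endpoint), and each lineage adds its length to the cell indexed by its
present-day descendants in each species. The engine is the package's own;
`msprime` appears only in the test suite as an independent oracle (the two
agree to ~1.5% mean relative cell difference on a split-migration model).

The data likelihood is the Poisson random field composite likelihood with θ
profiled out analytically (θ̂ = ΣS/ΣE). Two numerical points matter:

* **Floor.** Cells the simulation missed are floored at 0.5/n_reps —
  "below half a replicate", not impossible. A hard zero makes the
  likelihood discontinuous in the parameters.
* **Debiasing.** With a Monte-Carlo Ê, E[S·ln Ê] is depressed by
  S·δ²/2 (δ = relative MC standard error), which is parameter-dependent:
  deep-genealogy regions (large sizes, small migration) have noisier
  estimators and the raw composite likelihood misranks them by up to
  ~100 units at a few hundred replicates. After θ-profiling only noise in
  the spectrum *shape* matters, so the correction has two terms:
  +Σ S·δ²_cell/2 − S_tot·δ²_mass/2, with per-cell and total-mass variances
  tracked by the engine. Pure scale noise cancels exactly. Mixture
  components get distinct (deterministic) seeds so their variances are
  independent and the correction exact.

Optimization is two-stage multi-start Nelder–Mead on log-transformed
parameters (logit for s and P), defaults 10 + 30 runs as in the standard
protocol: stage 1 starts are the best of a cheap screened set of log-uniform
candidates in the wide ranges (T ∈ [0.01, 5], M ∈ [0.01, 10], N ∈ [0.01,
100]); stage 2 tightens ranges by a factor 3 around the stage-1 best; a
final polish restart is added. Local searches use a wide initial simplex
(0.8 log-units) — the default 5% simplex is far too small for a search space
spanning four orders of magnitude. All likelihood evaluations within a fit
share one random-number seed (common random numbers: the surface is
deterministic), and the reported log-likelihood is re-evaluated at a higher
replicate count with a separate seed, so model comparisons are not inflated
by the optimizer exploiting one noise realization.

Model selection: AIC = 2k − 2lnL, ΔAIC, relative likelihood exp(−ΔAIC/2).
Nested pairs (IM vs IM_2M, IM2 vs IM2_2M) are compared by likelihood-ratio
tests, χ² with df = Δk; a negative statistic is clamped to zero with a
warning. `nested_lrt` symmetrizes optimization effort: the collapsed
alternative optimum (class rates → weighted mean) is offered to the null and
the exactly-embedded null to the alternative; without this the statistic
measures which model got the luckier search. Bootstrap CIs are M ± 1.96·SD
over replicate refits (single-stage, starts perturbed around M).

## Synthetic data

The generator emulates the study design: 12 diploid females per species (24
haplotypes each), four gene categories, per-gene independent structured-
coalescent genealogies, codon-structured mutations, and lognormal FPKM.

* **Demography per category**: the published best-fit two-class IM2 point
  estimates for that category (e.g. rareA: s=0.27, N1=1.82, N2=2.48,
  T=4.84, M_A=(0.10, 0.11), M_B=(2.52, 0.75), P=0.55). Rare categories
  carry a larger low-migration fraction (P ≈ 0.5–0.56) than freq categories
  (P ≈ 0.26–0.31). In the generator a whole gene draws its migration class
  with probability P.
* **θ per site**: freqA 0.032, rareA 0.011 (rare ≪ freq, matching the
  observed fourfold diversity contrast), X categories at 0.75× the
  corresponding autosomal values.
* **Coding structure**: ancestral genes are random stop-free codons;
  mutation weights thin first/second codon positions to 0.15 of third
  positions, so fourfold sites are the most variable class.
* **Gene counts** default to the real category sizes (2009 freqA, 1909
  rareA, 209 freqX, 398 rareX); gene length defaults to 300 codons.
* **Expression**: per-gene lognormal FPKM (between-gene SD 1.0, within-
  species SD 0.35 on the log scale); a configured fraction per category
  (7.2–10%, freqA lowest) receives a ±1.0 log-e species shift. With 12 vs
  12 samples the Welch test at P < 10⁻⁴ detects roughly 60% of shifted
  genes — the configured fractions are fractions of *shifted means*, not of
  detections.

What the generator does **not** emulate: linkage within genes (sites are
exchangeable given the genealogy; there is one genealogy per gene, so
within-gene LD is maximal rather than distance-decaying), recombination-rate
variation within categories, selection (the diversity contrast is imposed
through θ, not through linked selection), read-level noise in FPKM, or
orthology/mapping error. Passing tests therefore show the estimators and the
inference machinery are correct under the model's assumptions, not that the
biological conclusions would survive real-data complications.

A consequence of taking the published mixture parameters at face value: the
per-gene F_ST distribution in rareX is a ~50/50 two-class mixture, so its
median sits at the class boundary and is unstable; the mean (and upper
quantiles) are the stable location summaries and are highest in rareX, as in
the real data. End-to-end checks assert on the mean.

## Problem sizes used by the test and acceptance runs

Chosen to keep a full run on one CPU within minutes while leaving the
conclusions stable:

* Engine calibration: Kingman marginal at n=10, 20 000 replicates; neutral
  Tajima's D over 2 000 genes (n=10, 500 sites, θ=0.01/site).
* Parameter recovery: IM2 truth (s=0.4, N1=1.5, N2=2.5, T=1.0, M1=0.5,
  M2=0.1), folded 8+8 spectrum, ~20 000 sites; 10+30 fit at 800 replicates
  per evaluation; 25 parametric-bootstrap refits. Coverage check:
  ≥ 5 of 6 true values inside M ± 1.96·SD.
* Likelihood-ratio experiments (IM2 vs IM2_2M, 6+6 spectra, 20 replicates
  each): the null-calibration experiment uses ~1 000 sites — the
  winner's-curse error of optimizing against a Monte-Carlo surface scales
  with data mass while the χ² threshold does not, so a small mass is the
  regime where the calibration question is answerable at desk scale — and
  the power experiment (10-fold class contrast, P=0.5) ~3 000 sites.
  Replicate fits are locally optimized from truth-derived anchors (the
  collapsed/embedded counterpart for the other model), which tests the
  statistic rather than the global search; the global search protocol is
  exercised separately by the recovery test.
* End-to-end orderings: default gene counts, 150-codon genes, one seed.

## Known limitations

* The Monte-Carlo likelihood has residual bias of a few units at a few
  hundred replicates; fits for model *selection* should use ≥ 500
  replicates per evaluation and the nested-test helper rather than raw
  differences of independently optimized likelihoods.
* The two-class mixture likelihood treats sites, not genes, as the latent
  class unit (composite likelihood); the generator assigns classes per
  gene. This mismatch is the standard one in SFS-based scans and is
  invisible to the SFS itself.
* F_ST is undefined for genes with zero between-species diversity and is
  excluded listwise; at very low θ this removes real genes preferentially.
* The compact-letter display reports unadjusted pairwise tests by default.
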