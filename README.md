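# lxeflow

Evolutionary-genetic analysis of whether pericentromeric recombination
suppression explains the "large X effect" — the disproportionate role of the
X chromosome in isolation between hybridising species. In many plants and
animals a massive rarely-recombining pericentromeric region covers most of
each chromosome (on the X, ~90% of its length). If incompatibility loci sit
anywhere in such a region, linkage opposes interspecific gene flow for every
gene in it, which would produce a large-X signal without any X-specific
mechanism. `lxeflow` implements the three analyses that test this on
transcriptome data from two hybridising dioecious plant species, and a
synthetic-data generator so the whole pipeline runs and is tested without
any external data.

The analyses, over four gene categories (freqA/rareA = autosomal genes in
frequently/rarely recombining regions; freqX/rareX = X-linked genes in the
recombining terminal region vs the pericentromeric region):

1. **Per-gene polymorphism statistics** on haplotype alignments — π,
   Tajima's D, F_ST, D_xy and Kelly's Z_nS, per site class (all sites,
   fourfold-degenerate sites, first two codon positions), compared across
   categories with Kruskal–Wallis and pairwise Wilcoxon rank-sum tests
   summarised as compact letter displays. Autosomal π can be ploidy-adjusted
   (×0.75) for X-vs-autosome comparisons.
2. **Joint-SFS demographic inference** under five isolation-with-migration
   models (`split_mig`, `IM`, `IM2` with directional migration, and the
   two-class mixtures `IM_2M`, `IM2_2M` in which a fraction *P* of sites
   carries distinct migration rates), fitted by Poisson random field
   composite likelihood over a Monte-Carlo structured-coalescent expected
   SFS, with AIC model selection, nested likelihood-ratio tests and
   bootstrap confidence intervals (M ± 1.96·SD).
3. **Expression divergence** — per-gene Welch t-tests on FPKM at
   P < 10⁻⁴, tabulated per category, with r² of species-mean expression.

The core model: two populations split T (units of 2·N_A generations) ago at
relative sizes (s, 1−s), grow exponentially to (N1, N2) (units of N_A), and
exchange migrants at rates M = 2·N_A·m. Heterogeneous gene flow — the
signature of linked barriers — is detected when the two-class models beat
their homogeneous counterparts by likelihood-ratio test, and the low-flow
class fraction P is larger in rarely-recombining gene sets.

## Worked example

The numbered drivers under `analysis/` run the pipeline on a synthetic
dataset (250 genes per autosomal category, 120 per X category, 150 codons,
12 diploids per species):

```bash
python analysis/01_simulate.py 1
python analysis/02_polymorphism.py
python analysis/03_demography.py 1
python analysis/04_expression.py
```

`02_polymorphism.py` prints (seed 1):

```
median fourfold pi per category (species1 / species2):
  freqA: 0.0337 / 0.0329 (ploidy-adjusted sp1: 0.0253)
  freqX: 0.0376 / 0.0374 (ploidy-adjusted sp1: 0.0376)
  rareA: 0.0190 / 0.0222 (ploidy-adjusted sp1: 0.0142)
  rareX: 0.0104 / 0.0108 (ploidy-adjusted sp1: 0.0104)
median F_ST (all sites): {'freqA': 0.046, 'freqX': 0.079, 'rareA': 0.181, 'rareX': 0.148}
```

Diversity is depressed and differentiation elevated in the rarely-
recombining categories — the configured barrier-to-gene-flow signal.
`04_expression.py` prints the diverged-expression tabulation and the r²
grid:

```
diverged-expression genes per category (Welch t-test, P < 1e-4):
  freqX: 6.0/120.0 = 5.00%
  freqA: 10.0/250.0 = 4.00%
  rareX: 6.0/120.0 = 5.00%
  rareA: 14.0/250.0 = 5.60%
freqA vs rareA diverged-count contrast: chi2 = 0.700, P = 0.4027
```

(the generator shifts 7.2–10% of gene means per category; the t-test at this
stringent threshold detects about 60% of them). `03_demography.py` fits the
five demographic models per recombination class and prints the AIC ranking,
the heterogeneity likelihood-ratio tests and the estimated low-migration
site-class fraction P.

The same machinery is scriptable: `lxeflow simulate|import-vcf|fit|run`
(see `lxeflow --help`) covers dataset generation, VCF → pseudo-haplotype
conversion, single-model SFS fits and the end-to-end pipeline with a JSON
config and a reproducibility manifest.

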