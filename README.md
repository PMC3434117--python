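# twostage-rp

Two-stage rank-product analysis of dye-swap two-color spotted microarrays,
built around an inflammation pharmacology design: peripheral blood
mononuclear cells stimulated with LPS, with and without an
anti-inflammatory drug (thalidomide), hybridized as Cy5/Cy3 pairs against
non-stimulated controls.  The package is for analysts who want a tested,
reproducible implementation of this classic small-replicate workflow —
spot-level preprocessing, lowess + ANOVA normalization, rank-product
permutation testing, two-stage gene selection, hypergeometric gene-set
enrichment and 2^−ΔΔCt qPCR confirmation — together with a synthetic-data
generator that emulates the array design with known ground truth.

## The method

Each slide carries ~10⁴ genes spotted in duplicate; two RNA samples
compete on every slide (dye swap on the third array).  Preprocessing
subtracts each spot's mean local background, rescues a nonpositive value
from its same-slide duplicate (eliminating the gene entirely when both
duplicates are nonpositive), averages duplicates and takes log2, giving
the expression level *y*₍ᵢⱼₖg₎ for array *i*, dye *j*, condition *k*,
gene *g*.

Within each array, the intensity-dependent dye bias visible in the MA
plot (M = log₂R − log₂G vs A = (log₂R + log₂G)/2) is removed by
subtracting a robust lowess fit of M on A.  Between arrays, the
fixed-effects normalization model

    y_ijkg = μ + A_i + D_j + AD_ij + r_ijkg

is fitted jointly over all genes with sum-to-zero constraints; the
residual *r* — which retains the condition signal, since no condition
effect is estimated — is the input of the test.

For each array the per-gene log2 fold change (treated channel minus
control channel of the residuals) is ranked twice, ascending and
descending; the **rank product** of gene *g* in direction *d* over *k*
arrays is

    RP_d(g) = ( ∏_i rank_d(g, i) )^(1/k),

and its significance comes from permutations that shuffle each array's
fold changes independently, pooling the null RPs over genes:

    p(g) = (1 + #{null RP ≤ RP(g)}) / (1 + n_genes · n_perm),

with the proportion of false prediction pfp(g) = p(g)·n_genes/rank(g)
reported alongside.  The **two-stage screen** first selects stimulus-
responsive genes at a permissive nominal p < 0.05, then re-runs the rank
product on the stimulus+drug contrast restricted to those genes (ranks
recomputed on the reduced set) at a stringent p < 0.001.  Selected lists
are tested for category over-representation with the upper-tail
hypergeometric probability, and confirmation qPCR is quantified as
2^−ΔΔCt with one-way ANOVA + Bonferroni post-tests across culture groups.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (outputs under `results/`):

```sh
python analysis/01_simulate.py          # two experiments, truth, GMT, qPCR Ct
python analysis/02_preprocess.py        # background, rescue, log2, QC
python analysis/03_normalize.py         # lowess + ANOVA residuals, MA plots
python analysis/04_rank_product.py      # two-stage selection
python analysis/05_enrichment.py        # hypergeometric over-representation
python analysis/06_qpcr.py              # ddCt confirmation
```

A run with the default seed prints, at the selection step:

```
{
  "stage1_count": 1262,
  "stage2_count": 9,
  "stage2_up": 7,
  "stage2_down": 2,
  "median_fold_change": 0.993,
  "stage1_recall": 0.91,
  "stage2_empirical_fdr": 0.0
}
```

meaning: of 9984 assayed genes (998 planted as differentially expressed),
the permissive LPS screen kept 1262 at p < 0.05, recovering 91% of the
planted genes; the stringent drug-contrast re-test kept 9 genes at
p < 0.001, all of them truly planted (empirical FDR 0); and the median
gene's fold change was 0.993 — essentially 1, as expected when most genes
do not change.  The preprocessing step reports within-array duplicate
correlations of 0.81–0.85, and the enrichment step flags exactly the four
annotation categories constructed to be enriched in planted genes.  The
qPCR step shows the drug suppressing an induced gene ~4-fold
(Bonferroni p < 0.01 vs stimulus alone).

The same workflow is scriptable through the `twostage-rp` command
(`simulate`, `preprocess`, `normalize`, `rankprod`, `enrich`, `qpcr`, and
`run --config run.yaml` for the YAML-driven end-to-end pipeline).

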