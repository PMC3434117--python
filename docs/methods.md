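# Methods

## Preprocessing model

A spot's corrected intensity is foreground minus mean local background per
channel; no global background model is used.  Corrected values in (0, 1)
are legal and yield negative log2 expression — no flooring is applied, to
avoid compressing the low-intensity range.  The duplicate-rescue rule is
applied per (array, channel): a nonpositive corrected value is replaced by
its same-slide duplicate when that one is positive; when both duplicates
are nonpositive the gene is eliminated from the *entire dataset*, not just
that array.  Dataset-wide elimination is deliberate: the rank-product test
needs a rank for every gene in every array, so the expression matrix must
stay rectangular.  The rescue threshold compares the *background-corrected*
value to zero (the alternative reading — raw foreground equal to zero —
would almost never trigger and would pass meaningless nonpositive values
to the log).

## Normalization

Within-array normalization subtracts a robust lowess fit of M on A, one
global fit per array (no print-tip stratification; the generator does not
model spatial artifacts and real print-tip effects are out of scope).
Defaults: span 0.3 — the conventional span for global intensity loess on
~10⁴ genes (e.g. the default in limma's within-array normalization) and
small enough to track curvature in the intensity tails — with 3
robustifying iterations so strongly regulated genes do not lever the
trend.  Fit points are ordered by A with ties broken by gene id, making
the fit reproducible under input reordering.

Between-array normalization fits y = μ + array + dye + array:dye jointly
over genes by least squares with sum-to-zero constraints.  With the
balanced dye-swap layout (each array × dye cell observed once per gene)
this is identical to subtracting each (array, dye) cell's mean over genes,
which is how it is computed; a generic normal-equations solve is used as
an oracle in the tests, never in the implementation.  No per-gene model is
fitted — with one measurement per cell per gene it would zero every
residual — and no condition effect is estimated, on purpose: the condition
signal must remain in the residuals, which are the test's input.

## Rank product and significance

Down-ranks order fold changes ascending (most negative = rank 1),
up-ranks descending; ties get midranks (unbiased under the null).  The
null distribution shuffles values within each array's column — the
original rank-product scheme — which on ranks is just a uniform
permutation of each column's rank vector, so the null is sampled directly
on precomputed ranks.  Nominal p-values pool the null RPs over genes and
permutations with a +1 pseudocount (p is never 0); pfp = p·n/rank is
reported even though selection thresholds the nominal p only, matching
the two-stage design's intent (the first stage deliberately tolerates
false positives).  Default 10,000 permutations, mandatory seed; one
value-shuffle per (permutation, array) drives both directions, which
makes the up/down results exactly antisymmetric under fold-change
negation.

A structural property worth knowing: because the pooled null p of a gene
at rank r among n genes over k arrays behaves like (r/n)^k times a
log factor, a threshold of p < 0.001 on a restricted set of a few hundred
to a few thousand genes admits roughly the top 2–4% per direction *no
matter how strong the effects are*.  The stringent second stage is
therefore an extreme-tail filter, not an exhaustive detector — the
permissive first stage (p < 0.05) is what bounds how many true genes the
procedure can recover, and the recovery guarantees in the tests are
stated accordingly (screen recall ≥ 80%; stage-2 selection judged by its
empirical FDR).

Stage-2 ranks and p-values are recomputed on the restricted gene set
rather than inherited from the full set, reflecting that the second
experiment is re-analyzed only over first-stage genes.

## Enrichment and qPCR

Enrichment is the plain (unconditional) upper-tail hypergeometric test
per category, with the universe restricted to assayed genes carrying at
least one annotation and category sizes recomputed inside the universe.
No multiple-testing correction is applied to enrichment p-values (the
output header says so); annotation comes from user-supplied GMT files —
term memberships are annotation-release-dependent, so no live download is
attempted.  Printed tables show p at 3 decimals ("0.000" means < 0.0005);
the TSV keeps full precision.

qPCR quantification assumes doubling efficiency (the 2^−ΔΔCt model;
efficiency-corrected variants are out of scope).  Technical duplicates
are averaged on the Ct scale before the delta steps; SEM is computed
across donors.  ANOVA and the Bonferroni-adjusted pairwise t-tests run on
log2 fold (= −ΔΔCt), where the equal-variance assumption is far more
plausible than on the ratio scale.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the array design the analysis assumes: 9984
genes in duplicate (19,968 spots per slide), three slides per comparison
with the third dye-swapped, Gaussian log2 baselines (mean 8, sd 1.5),
per-array offsets (sd 0.3), and an intensity-dependent bias added to the
Cy5 channel as a quadratic in the average log intensity (defaults
c = (3.6, −0.96, 0.06), i.e. a ±0.2–0.7 bow across the intensity range).
Planted genes (default 10%, signed |log2FC| = 1.5) shift the treated
condition's channel.

`noise_sd` (default 0.5) is the *gene-level* per-channel measurement
noise, i.e. the noise of the duplicate-averaged value — the quantity all
power statements refer to.  It is realized as a duplicate-shared plus a
per-spot independent component, with the split chosen to hit the target
duplicate correlation (`replicate_corr`, default 0.8) when the two
targets are compatible; at the defaults they are not quite (a correlation
of 0.8 with a baseline spread of 1.5 already forces an averaged noise of
≥ 0.53), so the shared part collapses to zero and the realized
correlation emerges from the signal spread at ~0.82 — inside the 0.75–0.88
band typical of duplicate-spot QC.  Foreground intensities carry the
spot's reported local background additively, so background subtraction is
exact on clean spots; a configurable 0.5% of spots is forced to
nonpositive corrected intensity to exercise the rescue/elimination paths.

In the two-stage scenario the second experiment keeps the planted effects
by default (the drug contrast is stimulus+drug vs non-stimulated control,
so stimulus effects persist); `stage2_de_fraction` reverts a chosen
fraction of planted genes to null, modelling drug suppression.

Not emulated: spatial/print-tip artifacts, probe-specific affinity
differences, scanner saturation and cross-hybridization.  One visible
consequence: between-array gene-level correlations come out high
(~0.85–0.9) because probe effects are absent, whereas real arrays of this
type show 0.25–0.65.  Passing tests therefore demonstrate the statistical
machinery under the assumed noise model, not robustness to every artifact
of real slides.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study-scale design
(9984 genes × 2 experiments) with 100–200 permutations — ample for the
pooled p-value, whose resolution is 1/(n_genes·n_perm) ≈ 10⁻⁶ — and the
planted-recovery simulation at 2000 genes, keeping every run seeded and
in the tens of seconds.  The exhaustive rank-product check compares
50,000 Monte-Carlo permutations against all 576 orderings of a 4 × 2
matrix on integer rank products, which avoids float tie-breaking
altogether.  Zero-variance correlation inputs are reported as undefined
and flagged rather than propagated as NaN; degenerate selections (empty
stage-1 list, single-gene restricted set) return empty selections with a
warning instead of failing.
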