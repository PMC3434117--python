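"""Rank-product test and two-stage gene selection.

For each array the genes' per-array log2 fold changes (treated channel minus
control channel of the ANOVA residuals, so the dye-swap array contributes
with consistent sign) are rank-ordered twice: ascending for down-regulation
(most negative fold change = rank 1) and descending for up-regulation.  The
rank product of a gene is the geometric mean of its ranks across the k
arrays,

    RP_dir(g) = (prod_arrays rank_dir(g, array)) ** (1/k),

small values flagging consistently extreme genes.  Significance comes from a
permutation null: each permutation shuffles the fold changes independently
within every array, the RPs of all genes are recomputed, and the nominal
p-value pools the null RPs over genes and permutations,

    p(g) = (1 + #{null RP <= RP(g)}) / (1 + n_genes * n_perm),

with a +1 pseudocount so p is never 0.  The proportion of false prediction
pfp(g) = p(g) * n_genes / rank_of(g) is the method's FDR-like estimate at
each position of the ranked list.

The two-stage selection runs the test twice: a permissive screen (alpha1,
e.g. 0.05, stimulus vs control), then a stringent screen (alpha2, e.g.
0.001) on the stimulus+drug contrast restricted to the first-stage genes,
with ranks recomputed over the restricted set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .array_io import DesignTable
from .normalization import AnovaFit

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeMatrix:
    """Per-array log2 fold changes (genes x arrays), treated minus control."""

    log2fc: pd.DataFrame
    treated: str
    control: str

    @property
    def n_genes(self) -> int:
        return self.log2fc.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.log2fc.shape[1]

    def restrict(self, genes) -> "FoldChangeMatrix":
        """Restrict to a gene subset (order follows the existing index)."""
        keep = self.log2fc.index.intersection(pd.Index(genes))
        missing = pd.Index(genes).difference(self.log2fc.index)
        if len(missing):
            raise KeyError(f"genes absent from fold-change matrix: {list(missing[:5])}")
        return FoldChangeMatrix(
            log2fc=self.log2fc.loc[keep], treated=self.treated, control=self.control
        )


@dataclass
class RankProductResult:
    """Per-gene rank-product statistics and permutation significance.

    ``table`` columns: rp_up, rp_down (geometric-mean ranks, in
    [1, n_genes]); avg_fc (2**mean log2FC, natural ratio scale); after
    :func:`permutation_pvalues` additionally p_up, p_down, pfp_up, pfp_down.
    """

    table: pd.DataFrame
    n_arrays: int
    n_perm: int | None = None
    seed: int | None = None


@dataclass
class StageSelection:
    """Outcome of the two-stage screen; stage2 genes are a subset of stage1."""

    stage1_genes: list[str]
    stage2_genes: list[str]
    direction: pd.Series  # 'up'/'down' per stage-2 gene
    alpha1: float
    alpha2: float
    stage1_result: RankProductResult = field(repr=False, default=None)
    stage2_result: RankProductResult = field(repr=False, default=None)

    @property
    def up_genes(self) -> list[str]:
        return [g for g in self.stage2_genes if self.direction[g] == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g in self.stage2_genes if self.direction[g] == "down"]


def fold_changes(
    fit: AnovaFit, design: DesignTable, treated: str, control: str
) -> FoldChangeMatrix:
    """Per-array log2FC from ANOVA residuals, oriented treated minus control.

    Each array hybridizes both conditions, so the contrast is within-array:
    the residual of the channel carrying *treated* minus the residual of the
    channel carrying *control*, regardless of which dye that is (dye-swap
    arrays therefore contribute with the same sign as forward arrays).
    """
    if treated == control:
        raise ValueError("treated and control labels must differ")
    res = fit.residuals
    arrays = list(res.columns.get_level_values(0).unique())
    cols = {}
    for a in arrays:
        ch_t = design.channel_of(a, treated)
        ch_c = design.channel_of(a, control)
        cols[a] = res[(a, ch_t)] - res[(a, ch_c)]
    fc = pd.DataFrame(cols, index=res.index)
    fc.columns.name = "array_id"
    return FoldChangeMatrix(log2fc=fc, treated=treated, control=control)


def _ranks(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Down- and up-ranks per column, midranks for ties."""
    down = np.apply_along_axis(rankdata, 0, fc)
    up = np.apply_along_axis(rankdata, 0, -fc)
    return down, up


def _geomean(ranks: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.exp(np.mean(np.log(ranks), axis=axis))


def rank_product(fc: FoldChangeMatrix) -> RankProductResult:
    """Rank-product statistics (no significance) for a fold-change matrix."""
    mat = fc.log2fc.to_numpy(float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if np.isnan(mat).any():
        raise ValueError("fold-change matrix contains missing values")
    down, up = _ranks(mat)
    table = pd.DataFrame(
        {
            "rp_up": _geomean(up, axis=1),
            "rp_down": _geomean(down, axis=1),
            "avg_fc": np.exp2(mat.mean(axis=1)),
        },
        index=fc.log2fc.index,
    )
    return RankProductResult(table=table, n_arrays=fc.n_arrays)


def permutation_pvalues(
    fc: FoldChangeMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    batch_size: int = 256,
) -> RankProductResult:
    """Permutation p-values and pfp for the rank-product statistics.

    Each of the ``n_perm`` permutations independently shuffles the fold
    changes within every array's column and recomputes the RPs of all genes;
    the observed RP of each gene is referred to the pooled null.  Because a
    within-column shuffle of values induces the same shuffle of that
    column's rank vector, the null is sampled directly on the precomputed
    rank matrices.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable null tail")
    result = rank_product(fc)
    n_genes = fc.n_genes
    down, up = _ranks(fc.log2fc.to_numpy(float))
    rng = np.random.default_rng(seed)

    obs = {
        "up": result.table["rp_up"].to_numpy(),
        "down": result.table["rp_down"].to_numpy(),
    }
    log_ranks = {"up": np.log(up), "down": np.log(down)}
    counts = {
        "up": np.zeros(n_genes, dtype=np.int64),
        "down": np.zeros(n_genes, dtype=np.int64),
    }

    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        # one value-shuffle per (perm, array), shared by both directions
        keys = rng.random((b, n_genes, fc.n_arrays))
        idx = np.argsort(keys, axis=1)
        for direction in ("up", "down"):
            null_log = np.zeros((b, n_genes))
            for j in range(fc.n_arrays):
                null_log += np.take(log_ranks[direction][:, j], idx[:, :, j])
            null_rp = np.exp(null_log / fc.n_arrays)
            null_sorted = np.sort(null_rp, axis=None)
            counts[direction] += np.searchsorted(
                null_sorted, obs[direction], side="right"
            )
        done += b

    denom = 1 + n_genes * n_perm
    table = result.table
    for direction in ("up", "down"):
        p = (1 + counts[direction]) / denom
        order_rank = rankdata(obs[direction], method="average")
        table[f"p_{direction}"] = p
        table[f"pfp_{direction}"] = p * n_genes / order_rank
    return RankProductResult(
        table=table, n_arrays=fc.n_arrays, n_perm=n_perm, seed=seed
    )


def select(result: RankProductResult, alpha: float) -> pd.DataFrame:
    """Genes with min(p_up, p_down) < alpha, with direction and best p."""
    t = result.table
    pmin = t[["p_up", "p_down"]].min(axis=1)
    direction = np.where(t["p_up"] <= t["p_down"], "up", "down")
    out = pd.DataFrame({"p": pmin, "direction": direction}, index=t.index)
    return out[pmin < alpha].sort_values("p")


def two_stage_select(
    stage1: RankProductResult,
    alpha1: float,
    stage2_fc: FoldChangeMatrix,
    alpha2: float,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> StageSelection:
    """Two-stage screen: permissive stage-1 list, stringent stage-2 re-test.

    ``stage2_fc`` is the second experiment's fold-change matrix; it is
    restricted to the stage-1 genes and the rank product, permutation null
    and p-values are recomputed on that reduced set before thresholding at
    ``alpha2``.
    """
    if alpha2 > alpha1:
        warnings.warn(
            f"stage-2 threshold {alpha2} is laxer than stage-1 {alpha1}",
            stacklevel=2,
        )
    stage1_sel = select(stage1, alpha1)
    stage1_genes = list(stage1_sel.index)
    if not stage1_genes:
        warnings.warn("stage 1 selected no genes; returning empty selection",
                      stacklevel=2)
        return StageSelection([], [], pd.Series(dtype=object), alpha1, alpha2,
                              stage1, None)
    if len(stage1_genes) < 2:
        warnings.warn(
            "stage 1 selected fewer than 2 genes; rank products are undefined "
            "on the restricted set, returning empty stage-2 selection",
            stacklevel=2,
        )
        return StageSelection(stage1_genes, [], pd.Series(dtype=object),
                              alpha1, alpha2, stage1, None)
    wanted = pd.Index(stage1_genes)
    missing = wanted.difference(stage2_fc.log2fc.index)
    if len(missing):
        logger.warning(
            "%d stage-1 genes absent from the stage-2 matrix were dropped",
            len(missing),
        )
        wanted = wanted.difference(missing)
    restricted = stage2_fc.restrict(wanted)
    stage2 = permutation_pvalues(restricted, n_perm=n_perm, seed=seed)
    stage2_sel = select(stage2, alpha2)
    return StageSelection(
        stage1_genes=stage1_genes,
        stage2_genes=list(stage2_sel.index),
        direction=stage2_sel["direction"],
        alpha1=alpha1,
        alpha2=alpha2,
        stage1_result=stage1,
        stage2_result=stage2,
    )


def result_table(result: RankProductResult) -> pd.DataFrame:
    """Reporting view: per-gene fold change on the ratio scale, best p, direction."""
    t = result.table
    direction = np.where(t["p_up"] <= t["p_down"], "up", "down")
    return pd.DataFrame(
        {
            "FC": t["avg_fc"],
            "p_value": t[["p_up", "p_down"]].min(axis=1),
            "pfp": np.where(direction == "up", t["pfp_up"], t["pfp_down"]),
            "direction": direction,
        },
        index=t.index,
    ).sort_values("p_value")
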