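"""Within-array lowess and between-array ANOVA normalization.

Two-color arrays show intensity-dependent dye bias: the log-ratio
M = log2(R) - log2(G) drifts with the average intensity
A = (log2(R) + log2(G)) / 2.  Within each slide this is removed by
subtracting a robust lowess fit of M on A (global, not per print-tip).
Between slides, systematic array and dye effects are removed by fitting,
jointly over all genes, the fixed-effects model

    y_ijkg = mu + A_i + D_j + AD_ij + r_ijkg

with sum-to-zero constraints on the array effects A_i, dye effects D_j and
their interaction.  For the balanced dye-swap layout (every array measures
both dyes once per gene) the least-squares residual is simply the
measurement minus its (array, dye) cell mean over genes; the condition index
k carries no estimated effect so that the condition signal stays in the
residual r, which is the input of the rank-product test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .array_io import CHANNELS, DesignTable, GeneExpressionTable

logger = logging.getLogger(__name__)

# channel j is the dye factor of the ANOVA model
DYES = CHANNELS


@dataclass
class MAData:
    """Per-array MA coordinates: M = log2R - log2G, A = (log2R + log2G)/2.

    Both attributes are genes x arrays DataFrames.  The transform is
    invertible: log2R = A + M/2, log2G = A - M/2
    (:meth:`to_expression`).
    """

    M: pd.DataFrame
    A: pd.DataFrame

    def to_expression(self) -> GeneExpressionTable:
        """Invert the MA transform back to per-channel log2 intensities."""
        cols = pd.MultiIndex.from_product(
            [self.M.columns, CHANNELS], names=["array_id", "channel"]
        )
        out = pd.DataFrame(index=self.M.index, columns=cols, dtype=float)
        for a in self.M.columns:
            out[(a, "cy5")] = self.A[a] + self.M[a] / 2.0
            out[(a, "cy3")] = self.A[a] - self.M[a] / 2.0
        return GeneExpressionTable(values=out)


@dataclass
class AnovaFit:
    """Decomposition y = mu + A_i + D_j + AD_ij + r under sum-to-zero coding.

    ``residuals`` is a genes x (array, dye) DataFrame; the condition carried
    by each (array, dye) cell is kept as metadata in ``conditions``.
    Reconstruction ``fitted + residuals`` equals the input exactly.
    """

    mu: float
    array_effects: pd.Series
    dye_effects: pd.Series
    interaction: pd.DataFrame  # arrays x dyes
    residuals: pd.DataFrame  # genes x (array, dye)
    conditions: dict[tuple[str, str], str]

    def fitted(self, array_id: str, dye: str) -> float:
        return (
            self.mu
            + self.array_effects[array_id]
            + self.dye_effects[dye]
            + self.interaction.loc[array_id, dye]
        )


@dataclass
class QCReport:
    """Pearson reproducibility correlations.

    ``within`` has one row per (array, channel): correlation between the two
    duplicate spots' log2 corrected intensities.  ``between`` has one row per
    (array pair, channel): correlation of gene-level log2 values.  Undefined
    correlations (zero-variance series) are flagged, not NaN-propagated.
    """

    within: pd.DataFrame
    between: pd.DataFrame


def ma_transform(expr: GeneExpressionTable) -> MAData:
    """MA coordinates per gene per array from per-channel log2 values."""
    vals = expr.values
    arrays = expr.arrays
    M = pd.DataFrame(index=vals.index, columns=arrays, dtype=float)
    A = pd.DataFrame(index=vals.index, columns=arrays, dtype=float)
    for a in arrays:
        for ch in CHANNELS:
            if (a, ch) not in vals.columns:
                raise ValueError(f"array {a!r} lacks channel {ch!r}")
        r, g = vals[(a, "cy5")], vals[(a, "cy3")]
        M[a] = r - g
        A[a] = (r + g) / 2.0
    M.columns.name = A.columns.name = "array_id"
    return MAData(M=M, A=A)


def lowess_within(ma: MAData, span: float = 0.3, iterations: int = 3) -> MAData:
    """Subtract a robust per-array lowess fit of M on A (dye-bias removal).

    Parameters
    ----------
    span
        Lowess smoothing fraction in (0, 1]; the window covers this fraction
        of the genes at each fit point.
    iterations
        Robustifying reweighting iterations, which keep strongly regulated
        genes from pulling the trend.

    Returns a new :class:`MAData` with M replaced by M - fhat(A); A is
    untouched, so corrected channel values follow from
    :meth:`MAData.to_expression`.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(ma.M.index) < 50:
        raise ValueError("need >= 50 genes per array for lowess support")
    Mout = ma.M.copy()
    for a in ma.M.columns:
        # stable order: sort by A, ties broken by gene id, for reproducibility
        order = np.lexsort((ma.M.index.to_numpy(), ma.A[a].to_numpy()))
        x = ma.A[a].to_numpy()[order]
        y = ma.M[a].to_numpy()[order]
        fit = sm.nonparametric.lowess(
            y, x, frac=span, it=iterations, return_sorted=False
        )
        corrected = np.empty_like(fit)
        corrected[order] = y - fit
        Mout[a] = corrected
    return MAData(M=Mout, A=ma.A.copy())


def anova_normalize(
    expr: GeneExpressionTable, design: DesignTable | None = None
) -> AnovaFit:
    """Fit the array/dye normalization ANOVA and return effects + residuals.

    Effects are estimated jointly over all genes by least squares with
    sum-to-zero constraints; for the balanced design required here this
    reduces to cell-mean centering, so each residual is the log2 value minus
    the mean over genes of its (array, dye) cell.
    """
    vals = expr.values
    arrays = list(vals.columns.get_level_values(0).unique())
    for a, d in itertools.product(arrays, DYES):
        if (a, d) not in vals.columns:
            raise ValueError(f"unbalanced design: missing (array, dye) cell ({a!r}, {d!r})")
        if vals[(a, d)].isna().any():
            raise ValueError(f"missing values in (array, dye) cell ({a!r}, {d!r})")

    cell_means = pd.DataFrame(
        {d: [vals[(a, d)].mean() for a in arrays] for d in DYES},
        index=pd.Index(arrays, name="array_id"),
    )
    mu = float(cell_means.to_numpy().mean())
    array_eff = cell_means.mean(axis=1) - mu
    dye_eff = cell_means.mean(axis=0) - mu
    interaction = cell_means.sub(array_eff, axis=0).sub(dye_eff, axis=1) - mu

    residuals = vals.copy()
    for a, d in itertools.product(arrays, DYES):
        residuals[(a, d)] = vals[(a, d)] - cell_means.loc[a, d]

    conditions: dict[tuple[str, str], str] = {}
    if design is not None:
        for a in arrays:
            c5, c3 = design.assignments[a]
            conditions[(a, "cy5")] = c5
            conditions[(a, "cy3")] = c3
    return AnovaFit(
        mu=mu,
        array_effects=array_eff,
        dye_effects=dye_eff,
        interaction=interaction,
        residuals=residuals,
        conditions=conditions,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r and a defined-ness flag (False for zero-variance input)."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, False
    return float(np.corrcoef(x, y)[0, 1]), True


def qc_correlations(
    corrected_spots: pd.DataFrame, expr: GeneExpressionTable
) -> QCReport:
    """Replicate reproducibility within arrays and concordance between arrays.

    Within-array correlations compare the two duplicate spots' log2
    background-corrected intensities (spots with a nonpositive value are
    dropped from that series).  Between-array correlations compare
    gene-level log2 values channel by channel.
    """
    within_rows = []
    for (array_id, channel), grp in _iter_spot_channels(corrected_spots):
        wide = grp.pivot_table(
            index="gene_id", columns="replicate", values=f"corr_{channel}",
            aggfunc="first",
        )
        if wide.shape[1] < 2:
            continue
        pair = wide.iloc[:, :2].to_numpy(float)
        pair[pair <= 0] = np.nan
        r, defined = _pearson(np.log2(pair[:, 0]), np.log2(pair[:, 1]))
        within_rows.append((array_id, channel, r, defined))
    within = pd.DataFrame(
        within_rows, columns=["array_id", "channel", "r", "defined"]
    )

    between_rows = []
    arrays = expr.arrays
    for (a1, a2), ch in itertools.product(itertools.combinations(arrays, 2), CHANNELS):
        r, defined = _pearson(
            expr.values[(a1, ch)].to_numpy(float),
            expr.values[(a2, ch)].to_numpy(float),
        )
        between_rows.append((a1, a2, ch, r, defined))
    between = pd.DataFrame(
        between_rows, columns=["array_a", "array_b", "channel", "r", "defined"]
    )
    rs = [s["r"].dropna() for s in (within, between) if len(s)]
    if rs:
        bad = pd.concat(rs)
        assert ((bad >= -1 - 1e-12) & (bad <= 1 + 1e-12)).all()
    return QCReport(within=within, between=between)


def _iter_spot_channels(corrected_spots: pd.DataFrame):
    for array_id, grp in corrected_spots.groupby("array_id"):
        for channel in CHANNELS:
            yield (array_id, channel), grp


def ma_plot(
    ma: MAData, array_id: str, path, title: str | None = None
) -> None:  # pragma: no cover - plotting
    """Save an MA scatter for one array (diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ma.A[array_id], ma.M[array_id], s=2, alpha=0.3, rasterized=True)
    ax.axhline(0.0, color="red", lw=1)
    ax.set_xlabel("A = (log2 R + log2 G) / 2")
    ax.set_ylabel("M = log2 R - log2 G")
    ax.set_title(title or f"MA plot, array {array_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
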