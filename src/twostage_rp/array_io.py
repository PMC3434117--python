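"""Spot-level I/O and gene-level summarization for two-color arrays.

A spot table is a tab-delimited file with one row per spot and columns
``array_id, gene_id, replicate, fg_cy5, bg_cy5, fg_cy3, bg_cy3`` (foreground
and mean local background per channel, arbitrary fluorescence units).  Genes
are spotted in duplicate, so each (array, gene) pair normally contributes two
rows with ``replicate`` 1 and 2.

Gene-level expression is obtained by background subtraction (fg - bg per
channel), a duplicate-spot rescue rule for nonpositive corrected values, and
log2 of the replicate mean:

* both replicates positive  -> log2 of their mean;
* one replicate nonpositive -> the positive replicate stands in for both;
* both nonpositive          -> the gene is eliminated from the whole dataset
  (every array), keeping the expression matrix complete for rank-based
  testing downstream.

Values in (0, 1) after correction are legal and give negative log2
expression; no flooring is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPOT_COLUMNS = [
    "array_id",
    "gene_id",
    "replicate",
    "fg_cy5",
    "bg_cy5",
    "fg_cy3",
    "bg_cy3",
]

CHANNELS = ("cy5", "cy3")


class SpotTableFormatError(ValueError):
    """Raised when a spot table does not conform to the expected schema."""


class DesignError(ValueError):
    """Raised when data refer to arrays or conditions absent from the design."""


@dataclass(frozen=True)
class DesignTable:
    """Dye-to-condition assignment of every array in one experiment.

    Parameters
    ----------
    assignments
        Mapping ``array_id -> (cy5_condition, cy3_condition)``.  The two
        conditions on one array must differ, and every array must carry the
        same unordered condition pair (the dye-swap design: the swapped array
        reverses the pair, it does not introduce a new one).
    """

    assignments: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise DesignError("design table is empty")
        pairs = set()
        for array_id, (c5, c3) in self.assignments.items():
            if c5 == c3:
                raise DesignError(
                    f"array {array_id!r} assigns condition {c5!r} to both dyes"
                )
            pairs.add(frozenset((c5, c3)))
        if len(pairs) > 1:
            raise DesignError(
                f"arrays do not share one condition pair: {sorted(map(sorted, pairs))}"
            )

    @property
    def arrays(self) -> list[str]:
        return list(self.assignments)

    @property
    def conditions(self) -> frozenset[str]:
        c5, c3 = next(iter(self.assignments.values()))
        return frozenset((c5, c3))

    def channel_of(self, array_id: str, condition: str) -> str:
        """Return the channel ('cy5'/'cy3') carrying *condition* on *array_id*."""
        c5, c3 = self.assignments[array_id]
        if condition == c5:
            return "cy5"
        if condition == c3:
            return "cy3"
        raise DesignError(f"condition {condition!r} not hybridized on array {array_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, c5, c3) for a, (c5, c3) in self.assignments.items()],
            columns=["array_id", "cy5_condition", "cy3_condition"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignTable":
        required = {"array_id", "cy5_condition", "cy3_condition"}
        missing = required - set(df.columns)
        if missing:
            raise SpotTableFormatError(f"design table missing columns: {sorted(missing)}")
        return cls(
            {
                str(r.array_id): (str(r.cy5_condition), str(r.cy3_condition))
                for r in df.itertuples()
            }
        )


def read_design(path: str | Path) -> DesignTable:
    """Read a tab-delimited design table (array_id, cy5_condition, cy3_condition)."""
    return DesignTable.from_frame(pd.read_csv(path, sep="\t", comment="#"))


def write_design(design: DesignTable, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GeneExpressionTable:
    """Gene-level log2 expression with preprocessing provenance.

    Attributes
    ----------
    values
        DataFrame indexed by gene_id with a (array_id, channel) column
        MultiIndex of log2 intensities; rectangular over retained genes.
    eliminated
        Gene ids removed because some (array, channel) had both duplicate
        spots nonpositive after background correction.
    rescued
        Boolean DataFrame aligned with ``values`` flagging cells whose value
        came from a single surviving duplicate spot.
    """

    values: pd.DataFrame
    eliminated: list[str] = field(default_factory=list)
    rescued: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())


def read_spot_table(path: str | Path, design: DesignTable) -> pd.DataFrame:
    """Read a tab-delimited spot-intensity table.

    Returns one row per spot with the :data:`SPOT_COLUMNS` schema.  Raises
    :class:`SpotTableFormatError` for a malformed header and
    :class:`DesignError` when the file mentions an array absent from the
    design.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise SpotTableFormatError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    df = df[SPOT_COLUMNS].copy()
    df["array_id"] = df["array_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    if df.empty:
        logger.warning("%s: spot table has no data rows", path)
        return df
    unknown = set(df["array_id"]) - set(design.arrays)
    if unknown:
        raise DesignError(f"{path}: arrays not in design: {sorted(unknown)}")
    intens = df[["fg_cy5", "bg_cy5", "fg_cy3", "bg_cy3"]].to_numpy(float)
    if not np.isfinite(intens).all() or (intens < 0).any():
        raise SpotTableFormatError(f"{path}: intensities must be finite and >= 0")
    return df


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def background_correct(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract each spot's mean local background from its mean foreground.

    Adds ``corr_cy5``/``corr_cy3`` columns; results may be <= 0, which the
    replicate-collapse step resolves.
    """
    out = spots.copy()
    out["corr_cy5"] = out["fg_cy5"] - out["bg_cy5"]
    out["corr_cy3"] = out["fg_cy3"] - out["bg_cy3"]
    return out


def collapse_replicates(
    corrected: pd.DataFrame, design: DesignTable
) -> GeneExpressionTable:
    """Collapse duplicate spots to one log2 value per (gene, array, channel).

    Applies the rescue rule per (array, channel): a nonpositive corrected
    value is replaced by its internal (same-slide) duplicate when that one is
    positive; when both duplicates are nonpositive the gene is eliminated
    from the entire dataset so the retained matrix stays rectangular.
    """
    if corrected.empty:
        raise ValueError("no spots to collapse")
    arrays = [a for a in design.arrays if a in set(corrected["array_id"])]

    rep_counts = corrected.groupby(["array_id", "gene_id"])["replicate"].agg(
        ["size", "nunique"]
    )
    if (rep_counts["size"] != rep_counts["nunique"]).any():
        bad = rep_counts[rep_counts["size"] != rep_counts["nunique"]].index[:3]
        raise SpotTableFormatError(
            f"duplicate replicate indices for (array, gene) pairs, e.g. {list(bad)}"
        )
    if (rep_counts["size"] == 1).any():
        n_single = int((rep_counts["size"] == 1).sum())
        logger.warning(
            "%d (array, gene) pairs have a single spotted replicate", n_single
        )

    # gene x (array, channel, replicate) wide layout; NaN marks absent spots
    wide = corrected.pivot_table(
        index="gene_id",
        columns=["array_id", "replicate"],
        values=["corr_cy5", "corr_cy3"],
        aggfunc="first",
    )
    genes = wide.index

    values: dict[tuple[str, str], np.ndarray] = {}
    rescued: dict[tuple[str, str], np.ndarray] = {}
    dead = np.zeros(len(genes), dtype=bool)
    for array_id in arrays:
        for channel in CHANNELS:
            sub = wide[f"corr_{channel}"][array_id]
            mat = sub.to_numpy(float)  # genes x replicates (1 or 2 columns)
            if mat.shape[1] == 1:
                mat = np.hstack([mat, np.full_like(mat, np.nan)])
            r1, r2 = mat[:, 0], mat[:, 1]
            pos1 = np.nan_to_num(r1, nan=-np.inf) > 0
            pos2 = np.nan_to_num(r2, nan=-np.inf) > 0
            both = pos1 & pos2
            only1 = pos1 & ~pos2
            only2 = pos2 & ~pos1
            val = np.full(len(genes), np.nan)
            val[both] = (r1[both] + r2[both]) / 2.0
            val[only1] = r1[only1]
            val[only2] = r2[only2]
            dead |= ~(pos1 | pos2)
            values[(array_id, channel)] = val
            rescued[(array_id, channel)] = only1 | only2

    eliminated = sorted(genes[dead])
    if eliminated:
        logger.info("eliminated %d genes with no positive duplicate", len(eliminated))
    keep = ~dead
    cols = pd.MultiIndex.from_product([arrays, CHANNELS], names=["array_id", "channel"])
    vals = pd.DataFrame(
        {c: np.log2(values[c][keep]) for c in cols}, index=genes[keep], columns=cols
    )
    vals.index.name = "gene_id"
    resc = pd.DataFrame(
        {c: rescued[c][keep] for c in cols}, index=genes[keep], columns=cols
    )
    return GeneExpressionTable(values=vals, eliminated=eliminated, rescued=resc)


def preprocess(spots: pd.DataFrame, design: DesignTable) -> GeneExpressionTable:
    """Background-correct and collapse a spot table to gene-level log2 values."""
    return collapse_replicates(background_correct(spots), design)


def write_expression(expr: GeneExpressionTable, path: str | Path) -> None:
    """Write gene-level log2 values as TSV with ``array:channel`` columns."""
    flat = expr.values.copy()
    flat.columns = [f"{a}:{c}" for a, c in flat.columns]
    flat.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> GeneExpressionTable:
    """Re-read a TSV written by :func:`write_expression` (values round-trip)."""
    flat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in flat.columns], names=["array_id", "channel"]
    )
    flat.columns = cols
    flat.index = flat.index.astype(str)
    return GeneExpressionTable(values=flat)
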