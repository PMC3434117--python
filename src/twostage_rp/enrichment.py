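"""Hypergeometric over-representation analysis against GMT gene sets.

Given a selected gene list and a gene universe (the assayed genes that carry
at least one annotation), each category of size K in a universe of N genes
is scored by the upper-tail hypergeometric probability of observing at least
the seen overlap k among n selected genes:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

This is the plain (unconditional) per-category test; no multiple-testing
correction is applied to the enrichment p-values, and the output flags that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


class GMTFormatError(ValueError):
    """Raised for malformed GMT lines."""


@dataclass
class GeneSetCollection:
    """Named gene categories: id -> member set, id -> human-readable term."""

    members: dict[str, set[str]]
    terms: dict[str, str]

    def __len__(self) -> int:
        return len(self.members)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every category with *universe*; drop emptied categories."""
        members = {}
        for cid, genes in self.members.items():
            inside = genes & universe
            if inside:
                members[cid] = inside
        return GeneSetCollection(
            members=members, terms={c: self.terms[c] for c in members}
        )

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (category id, description/term, members...)."""
    members: dict[str, set[str]] = {}
    terms: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            cid, term, *genes = fields
            members[cid] = {g for g in genes if g}
            terms[cid] = term
    if not members:
        logger.warning("%s: GMT file contains no categories", path)
    return GeneSetCollection(members=members, terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, genes in collection.members.items():
            fh.write("\t".join([cid, collection.terms[cid], *sorted(genes)]) + "\n")


def build_universe(assayed_genes, collection: GeneSetCollection) -> set[str]:
    """Universe = assayed genes annotated to at least one category."""
    assayed = set(assayed_genes)
    if not assayed:
        raise ValueError("assayed gene set is empty")
    universe = assayed & collection.annotated_genes()
    if not universe:
        raise ValueError("no assayed gene carries an annotation; empty universe")
    return universe


def hypergeometric_enrichment(
    selected,
    universe,
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every category; return (significant rows, full table).

    Rows follow the ``category_id, pvalue, count, size, term`` schema, with
    category sizes recomputed inside the universe; the significant table
    keeps rows with p < alpha sorted ascending by p.
    """
    selected, universe = set(selected), set(universe)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:5]}")
    restricted = collection.restrict(universe)
    n = len(selected)
    N = len(universe)
    rows = []
    for cid, genes in restricted.members.items():
        size = len(genes)
        count = len(genes & selected)
        # P(X >= count) = sf(count - 1)
        p = float(hypergeom.sf(count - 1, N, size, n))
        rows.append((cid, p, count, size, restricted.terms[cid]))
    full = pd.DataFrame(
        rows, columns=["category_id", "pvalue", "count", "size", "term"]
    ).sort_values(["pvalue", "category_id"], ignore_index=True)
    hits = full[full["pvalue"] < alpha].reset_index(drop=True)
    return hits, full


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    """Write an enrichment table; p shown at 3 decimals, full precision kept."""
    out = table.copy()
    out.insert(1, "Pvalue", out.pop("pvalue").round(3))
    out["pvalue_full"] = table["pvalue"]
    with open(path, "w") as fh:
        fh.write("# raw hypergeometric p-values; no multiple-testing correction\n")
        out.to_csv(fh, sep="\t", index=False)
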