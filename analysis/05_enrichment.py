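"""Gene-set over-representation of the selected lists.

Tests the stage-1 and stage-2 gene lists against the toy annotation with
the upper-tail hypergeometric probability, using as universe the assayed
genes that carry at least one annotation.  Categories constructed to be
enriched in planted genes should surface at p < 0.05; uniformly drawn
categories should not.
"""

import argparse
from pathlib import Path

import pandas as pd

from twostage_rp import enrichment

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

collection = enrichment.read_gmt(args.data / "toy_annotation.gmt")
assayed = pd.read_csv(
    args.out / "stage1_expression.tsv", sep="\t", index_col=0
).index.astype(str)
universe = enrichment.build_universe(assayed, collection)

for stage in ("stage1", "stage2"):
    selected = set((args.out / f"{stage}_genes.txt").read_text().split())
    hits, full = enrichment.hypergeometric_enrichment(
        selected & universe, universe, collection, alpha=args.alpha
    )
    enrichment.write_enrichment(full, args.out / f"{stage}_enrichment.tsv")
    print(f"{stage}: {len(hits)} of {len(full)} categories at p < {args.alpha}")
    if len(hits):
        print(hits.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
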