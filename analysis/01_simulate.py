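"""Simulate the two-stage dye-swap study.

Generates both experiments of the screen — stimulus (LPS) vs non-stimulated
(NS), and stimulus+drug (LPS+thalidomide) vs NS — at the study's array
design: 9984 genes spotted in duplicate, three arrays per comparison with
the third dye-swapped, intensity-dependent Cy5 bias, per-array offsets and
10% planted differentially expressed genes at |log2FC| = 1.5.  Also writes
the ground truth, a toy gene-set annotation (four categories enriched in
planted genes) and a confirmation qPCR Ct table for one suppressed and one
induced gene.

Outputs under results/data/.
"""

import argparse
from pathlib import Path

from twostage_rp import array_io, enrichment, synthetic

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-genes", type=int, default=9984)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = synthetic.SimulationConfig(n_genes=args.n_genes, seed=args.seed)
data = synthetic.simulate_two_stage(cfg)

args.out.mkdir(parents=True, exist_ok=True)
array_io.write_spot_table(data.stage1_spots, args.out / "stage1_spots.tsv")
array_io.write_spot_table(data.stage2_spots, args.out / "stage2_spots.tsv")
array_io.write_design(data.stage1_design, args.out / "stage1_design.tsv")
array_io.write_design(data.stage2_design, args.out / "stage2_design.tsv")
data.stage1_truth.to_csv(args.out / "stage1_truth.tsv", sep="\t")
data.stage2_truth.to_csv(args.out / "stage2_truth.tsv", sep="\t")

gmt = synthetic.make_gene_sets(data.stage1_truth, seed=args.seed)
enrichment.write_gmt(gmt, args.out / "toy_annotation.gmt")

# confirmation qPCR: one LPS-induced gene suppressed by the drug, one induced
planted = data.stage1_truth
up = planted.index[(planted["direction"] == "up")][:2]
ct = synthetic.simulate_qpcr(
    {
        up[0]: {"LPS": 3.0, "LPS+thalidomide": 1.0},   # suppressed 4-fold
        up[1]: {"LPS": 1.0, "LPS+thalidomide": 2.0},   # further induced
    },
    seed=args.seed,
)
ct.to_csv(args.out / "qpcr_ct.tsv", sep="\t", index=False)

n_de = int(data.stage1_truth["is_de"].sum())
print(f"simulated {args.n_genes} genes x 2 experiments x 3 dye-swap arrays")
print(f"planted DE genes: {n_de} ({100 * n_de / args.n_genes:.1f}%)")
print(f"outputs in {args.out}/")
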