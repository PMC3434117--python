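"""Confirmation qPCR analysis by 2^-ddCt.

Quantifies the simulated confirmation genes relative to the housekeeping
reference and the non-stimulated calibrator group, then compares culture
groups by one-way ANOVA with Bonferroni post-tests against the LPS-alone
group — the same readout used to confirm array hits (stars mark p<0.05 /
p<0.01 vs LPS).
"""

import argparse
from pathlib import Path

import pandas as pd

from twostage_rp.qpcr import ddct, group_compare

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

records = pd.read_csv(args.data / "qpcr_ct.tsv", sep="\t")
rel = ddct(records, calibrator_group="NS")
report = group_compare(rel, reference_group="LPS")

rel.groups.to_csv(args.out / "qpcr_folds.tsv", sep="\t", index=False)
report.to_csv(args.out / "qpcr_tests.tsv", sep="\t", index=False)

print("group mean fold (2^-ddCt, NS = 1):")
print(
    rel.groups.pivot(index="gene", columns="group", values="mean_fold")
    .round(2)
    .to_string()
)
print()
print(report[["gene", "comparison", "p_bonferroni", "stars"]].round(4).to_string(index=False))
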