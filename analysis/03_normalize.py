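"""Within-array lowess and between-array ANOVA normalization.

Transforms each array to MA coordinates, removes the intensity-dependent
dye bias with a robust lowess fit of M on A (span 0.3), then removes array
and dye effects by the joint ANOVA normalization model; its residuals are
the input of the rank-product test.  Saves MA plots before/after lowess for
the first array of each experiment.
"""

import argparse
from pathlib import Path

from twostage_rp import array_io
from twostage_rp.normalization import (
    anova_normalize,
    lowess_within,
    ma_plot,
    ma_transform,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--span", type=float, default=0.3)
args = parser.parse_args()
(args.out / "figures").mkdir(parents=True, exist_ok=True)

for stage in ("stage1", "stage2"):
    design = array_io.read_design(args.data / f"{stage}_design.tsv")
    expr = array_io.read_expression(args.out / f"{stage}_expression.tsv")
    ma_raw = ma_transform(expr)
    ma_norm = lowess_within(ma_raw, span=args.span)
    first = ma_raw.M.columns[0]
    ma_plot(ma_raw, first, args.out / "figures" / f"{stage}_{first}_raw.png",
            title=f"{stage} {first} before lowess")
    ma_plot(ma_norm, first, args.out / "figures" / f"{stage}_{first}_lowess.png",
            title=f"{stage} {first} after lowess")
    fit = anova_normalize(ma_norm.to_expression(), design)
    res = fit.residuals.copy()
    res.columns = [f"{a}:{c}" for a, c in res.columns]
    res.to_csv(args.out / f"{stage}_residuals.tsv", sep="\t")
    print(
        f"{stage}: array effects "
        + ", ".join(f"{a}={v:+.3f}" for a, v in fit.array_effects.items())
        + f"; dye effect cy5-cy3 = {fit.dye_effects['cy5'] - fit.dye_effects['cy3']:+.3f}"
    )
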