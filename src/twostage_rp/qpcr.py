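"""Relative quantification of confirmation qPCR by the 2^-ddCt method.

Each sample's target-gene cycle threshold is normalized to a reference
(housekeeping) gene, dCt = Ct_target - Ct_reference, then to the mean dCt of
a calibrator group, ddCt = dCt - mean dCt(calibrator); relative expression
is fold = 2^-ddCt, assuming doubling amplification efficiency.  Group
differences are assessed by one-way ANOVA on log2 fold (= -ddCt, where the
equal-variance assumption is more plausible than on the ratio scale)
followed by pairwise t-tests against a reference group with Bonferroni
multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["donor_id", "group", "gene", "ct_target", "ct_reference"]


@dataclass
class RelativeExpression:
    """Per-sample fold changes and per-group summaries.

    ``samples``: one row per (donor, group, gene) with dct, ddct and fold
    (technical duplicates averaged on the Ct scale first).
    ``groups``: per (group, gene) mean fold, SEM across donors and n.
    """

    samples: pd.DataFrame
    groups: pd.DataFrame
    calibrator_group: str


def ddct(records: pd.DataFrame, calibrator_group: str) -> RelativeExpression:
    """Apply 2^-ddCt per gene with *calibrator_group* as the calibrator.

    ``records`` needs the columns donor_id, group, gene, ct_target,
    ct_reference; repeated rows per (donor, group, gene) are treated as
    technical duplicates and averaged before the delta steps.
    """
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        bad = records[records[["ct_target", "ct_reference"]].isna().any(axis=1)]
        sample = bad[["donor_id", "group", "gene"]].iloc[0].tolist()
        raise ValueError(f"missing Ct value for sample {sample}")
    if calibrator_group not in set(records["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")

    per_sample = (
        records.groupby(["donor_id", "group", "gene"], as_index=False)[
            ["ct_target", "ct_reference"]
        ].mean()
    )
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    calib = (
        per_sample[per_sample["group"] == calibrator_group]
        .groupby("gene")["dct"]
        .mean()
    )
    absent = set(per_sample["gene"]) - set(calib.index)
    if absent:
        raise ValueError(f"genes without calibrator-group samples: {sorted(absent)}")
    per_sample["ddct"] = per_sample["dct"] - per_sample["gene"].map(calib)
    per_sample["fold"] = np.exp2(-per_sample["ddct"])

    groups = (
        per_sample.groupby(["group", "gene"])["fold"]
        .agg(mean_fold="mean", sem=lambda s: s.sem(), n="size")
        .reset_index()
    )
    return RelativeExpression(
        samples=per_sample, groups=groups, calibrator_group=calibrator_group
    )


def group_compare(rel: RelativeExpression, reference_group: str) -> pd.DataFrame:
    """One-way ANOVA across groups plus Bonferroni post-tests per gene.

    Tests run on log2 fold (= -ddCt).  Groups with fewer than 2 donors are
    excluded with a warning row.  Returns one row per gene with the ANOVA F
    and p, plus per-comparison Bonferroni-adjusted p-values and star codes
    (* p<0.05, ** p<0.01) for every group against *reference_group*.
    """
    rows = []
    for gene, sub in rel.samples.groupby("gene"):
        sizes = sub.groupby("group")["ddct"].size()
        keep = sizes[sizes >= 2].index
        dropped = sorted(set(sizes.index) - set(keep))
        if dropped:
            import warnings

            warnings.warn(
                f"{gene}: groups with n<2 excluded from testing: {dropped}",
                stacklevel=2,
            )
        sub = sub[sub["group"].isin(keep)]
        if reference_group not in set(sub["group"]) or len(keep) < 2:
            raise ValueError(
                f"{gene}: need reference group {reference_group!r} and >= 2 groups"
            )
        log2fold = {g: -grp["ddct"].to_numpy() for g, grp in sub.groupby("group")}
        F, p = stats.f_oneway(*log2fold.values())
        others = [g for g in log2fold if g != reference_group]
        m = len(others)
        for other in others:
            t, praw = stats.ttest_ind(
                log2fold[other], log2fold[reference_group], equal_var=True
            )
            padj = min(1.0, m * praw)
            stars = "**" if padj < 0.01 else ("*" if padj < 0.05 else "")
            rows.append(
                {
                    "gene": gene,
                    "anova_F": float(F),
                    "anova_p": float(p),
                    "comparison": f"{other} vs {reference_group}",
                    "t": float(t),
                    "p_raw": float(praw),
                    "p_bonferroni": float(padj),
                    "stars": stars,
                }
            )
    return pd.DataFrame(rows)
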