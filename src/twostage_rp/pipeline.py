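"""End-to-end orchestration of the two-stage analysis.

``run_pipeline`` chains spot-table ingestion, lowess + ANOVA normalization,
the stage-1 rank-product screen (stimulus vs control), the stage-2 re-test
of the stage-1 genes (stimulus+drug vs control), gene-set enrichment of both
lists and, when a Ct table is supplied, the ddCt confirmation analysis.
Every output TSV carries a provenance header (seed, parameters, package
version) and a summary JSON records the gene counts at each stage, so a
rerun with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, array_io, enrichment, normalization, qpcr, rankprod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of a full two-stage run."""

    stage1_spots: str
    stage1_design: str
    stage2_spots: str
    stage2_design: str
    out_dir: str
    stage1_treated: str = "LPS"
    stage2_treated: str = "LPS+thalidomide"
    control: str = "NS"
    gmt_files: dict[str, str] = field(default_factory=dict)  # label -> path
    qpcr_table: str | None = None
    qpcr_calibrator: str = "NS"
    qpcr_reference_group: str = "LPS"
    span: float = 0.3
    n_perm: int = 10_000
    seed: int = 0
    alpha1: float = 0.05
    alpha2: float = 0.001
    enrich_alpha: float = 0.05
    make_plots: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha1, self.alpha2, self.enrich_alpha):
            if not 0 < a <= 1:
                raise ValueError(f"alpha values must be in (0, 1], got {a}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _provenance_header(config: PipelineConfig, stage: str) -> str:
    return (
        f"# twostage-rp {__version__} | stage: {stage} | seed: {config.seed} | "
        f"span: {config.span} | n_perm: {config.n_perm} | "
        f"alpha1: {config.alpha1} | alpha2: {config.alpha2}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, stage))
        df.to_csv(fh, sep="\t", index=index)


def _normalize_experiment(
    spots: pd.DataFrame,
    design: array_io.DesignTable,
    config: PipelineConfig,
    tag: str,
    out: Path,
):
    corrected = array_io.background_correct(spots)
    expr = array_io.collapse_replicates(corrected, design)
    logger.info(
        "%s: %d genes retained, %d eliminated", tag, len(expr.genes), len(expr.eliminated)
    )
    ma = normalization.ma_transform(expr)
    ma_norm = normalization.lowess_within(ma, span=config.span)
    if config.make_plots:  # pragma: no cover - plotting
        for a in ma.M.columns:
            normalization.ma_plot(ma, a, out / f"ma_{tag}_{a}_raw.png")
            normalization.ma_plot(ma_norm, a, out / f"ma_{tag}_{a}_lowess.png")
    fit = normalization.anova_normalize(ma_norm.to_expression(), design)
    qc = normalization.qc_correlations(corrected, expr)
    _write_tsv(qc.within, out / f"qc_within_{tag}.tsv", config, tag, index=False)
    _write_tsv(qc.between, out / f"qc_between_{tag}.tsv", config, tag, index=False)
    res = fit.residuals.copy()
    res.columns = [f"{a}:{d}" for a, d in res.columns]
    _write_tsv(res, out / f"residuals_{tag}.tsv", config, tag)
    return expr, fit, qc


def _run_enrichment(
    selection_genes,
    universe_source,
    config: PipelineConfig,
    tag: str,
    out: Path,
) -> dict:
    summary = {}
    for label, path in config.gmt_files.items():
        collection = enrichment.read_gmt(path)
        try:
            universe = enrichment.build_universe(universe_source, collection)
        except ValueError as exc:
            logger.warning("%s/%s: %s", tag, label, exc)
            continue
        selected = set(selection_genes) & universe
        hits, full = enrichment.hypergeometric_enrichment(
            selected, universe, collection, alpha=config.enrich_alpha
        )
        enrichment.write_enrichment(full, out / f"enrichment_{tag}_{label}_full.tsv")
        enrichment.write_enrichment(hits, out / f"enrichment_{tag}_{label}.tsv")
        summary[label] = {
            "universe": len(universe),
            "selected_in_universe": len(selected),
            "significant_categories": int(len(hits)),
        }
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full two-stage analysis; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    analysis_params = (
        "stage1_treated stage2_treated control span n_perm seed alpha1 alpha2 "
        "enrich_alpha"
    ).split()
    cfg_dict = asdict(config)
    summary: dict = {"parameters": {k: cfg_dict[k] for k in analysis_params}}

    stage = "ingest"
    try:
        design1 = array_io.read_design(config.stage1_design)
        design2 = array_io.read_design(config.stage2_design)
        spots1 = array_io.read_spot_table(config.stage1_spots, design1)
        spots2 = array_io.read_spot_table(config.stage2_spots, design2)

        stage = "normalize"
        expr1, fit1, _ = _normalize_experiment(spots1, design1, config, "stage1", out)
        expr2, fit2, _ = _normalize_experiment(spots2, design2, config, "stage2", out)

        stage = "rankprod"
        fc1 = rankprod.fold_changes(
            fit1, design1, treated=config.stage1_treated, control=config.control
        )
        stage1 = rankprod.permutation_pvalues(
            fc1, n_perm=config.n_perm, seed=config.seed
        )
        _write_tsv(
            rankprod.result_table(stage1), out / "rankprod_stage1.tsv", config, "stage1"
        )

        stage = "twostage"
        fc2 = rankprod.fold_changes(
            fit2, design2, treated=config.stage2_treated, control=config.control
        )
        selection = rankprod.two_stage_select(
            stage1,
            config.alpha1,
            fc2,
            config.alpha2,
            n_perm=config.n_perm,
            seed=config.seed + 1,
        )
        if selection.stage2_result is not None:
            _write_tsv(
                rankprod.result_table(selection.stage2_result),
                out / "rankprod_stage2.tsv",
                config,
                "stage2",
            )
        (out / "stage1_genes.txt").write_text(
            "\n".join(selection.stage1_genes) + "\n" if selection.stage1_genes else ""
        )
        (out / "stage2_genes.txt").write_text(
            "\n".join(selection.stage2_genes) + "\n" if selection.stage2_genes else ""
        )
        summary["stage1_count"] = len(selection.stage1_genes)
        summary["stage2_count"] = len(selection.stage2_genes)
        summary["stage2_up"] = len(selection.up_genes)
        summary["stage2_down"] = len(selection.down_genes)
        assert set(selection.stage2_genes) <= set(selection.stage1_genes)

        stage = "enrichment"
        if config.gmt_files:
            summary["enrichment"] = {
                "stage1": _run_enrichment(
                    selection.stage1_genes, expr1.genes, config, "stage1", out
                ),
                "stage2": _run_enrichment(
                    selection.stage2_genes, expr1.genes, config, "stage2", out
                ),
            }

        stage = "qpcr"
        if config.qpcr_table:
            records = pd.read_csv(config.qpcr_table, sep="\t", comment="#")
            rel = qpcr.ddct(records, calibrator_group=config.qpcr_calibrator)
            report = qpcr.group_compare(rel, reference_group=config.qpcr_reference_group)
            _write_tsv(rel.groups, out / "qpcr_folds.tsv", config, "qpcr", index=False)
            _write_tsv(report, out / "qpcr_tests.tsv", config, "qpcr", index=False)
            summary["qpcr_genes"] = sorted(rel.samples["gene"].unique())
    except Exception as exc:
        logger.error("pipeline aborted during stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
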