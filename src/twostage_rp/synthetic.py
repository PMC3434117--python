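"""Synthetic two-color spotted-array experiments with known ground truth.

The generator reproduces the statistical structure the analysis chain
assumes: ~10k genes spotted in duplicate on each slide, three slides per
condition pair in a dye-swap layout (two forward, one reversed), Gaussian
gene baselines and measurement noise on the log2 scale (multiplicative on
intensities), per-array offsets, an intensity-dependent dye bias applied to
the Cy5 channel as a quadratic in the average log intensity (which makes the
swap array informative, as in real dye-swap designs), duplicate spots that
share the gene/channel signal plus independent spot noise tuned to a target
within-array correlation, and a planted set of differentially expressed
genes with signed log2 effects.  Foreground intensities carry the spot's
local background additively, so background subtraction is exact on clean
spots; a small fraction of spots is forced to nonpositive corrected
intensity to exercise the duplicate-rescue and elimination rules.

Ground truth (which genes are differentially expressed, in which direction,
by how much) is returned alongside the data, and helpers generate matching
toy GMT annotation files and qPCR Ct tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_io import DesignTable
from .enrichment import GeneSetCollection


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the array simulator (defaults emulate the study design).

    Intensities live on the log2 scale unless stated otherwise.
    """

    n_genes: int = 9984
    n_arrays: int = 3  # per condition pair; the last one is dye-swapped
    de_fraction: float = 0.1
    de_log2fc: float = 1.5  # magnitude of planted effects; sign drawn per gene
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5  # per-channel measurement noise
    dye_bias: tuple[float, float, float] = (3.6, -0.96, 0.06)  # c0 + c1*A + c2*A^2
    array_effect_sd: float = 0.3
    replicate_corr: float = 0.8  # target duplicate-spot correlation
    background_level: float = 50.0
    background_sd: float = 10.0
    nonpositive_fraction: float = 0.005  # spots forced to fg - bg <= 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "noise_sd", "array_effect_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if not 0 < self.replicate_corr <= 1:
            raise ValueError(
                f"replicate_corr must be in (0, 1], got {self.replicate_corr}"
            )
        if not 0 <= self.nonpositive_fraction < 1:
            raise ValueError("nonpositive_fraction must be in [0, 1)")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def make_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the planted-gene table: gene_id, is_de, direction, true_log2fc."""
    genes = _gene_ids(config.n_genes)
    n_de = round(config.de_fraction * config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    effects = np.zeros(config.n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects[de_idx] = signs * config.de_log2fc
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de": effects != 0,
            "direction": np.where(
                effects > 0, "up", np.where(effects < 0, "down", "none")
            ),
            "true_log2fc": effects,
        }
    ).set_index("gene_id")
    return truth


def simulate_experiment(
    config: SimulationConfig,
    treated: str = "LPS",
    control: str = "NS",
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, DesignTable, pd.DataFrame]:
    """Simulate one dye-swap experiment comparing *treated* vs *control*.

    Returns (spot table, design table, truth table).  Pass a pre-built
    ``truth`` to share or modify the planted genes between experiments of a
    multi-stage study; pass an ``rng`` to chain experiments off one stream
    (by default a fresh generator is seeded from ``config.seed``, making the
    output bit-reproducible).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = make_truth(config, rng)
    effects = truth["true_log2fc"].to_numpy(float)
    genes = truth.index.to_numpy()
    n = config.n_genes
    if len(genes) != n:
        raise ValueError("truth table size does not match config.n_genes")

    arrays = [f"A{i}" for i in range(1, config.n_arrays + 1)]
    assignments = {}
    for i, a in enumerate(arrays):
        swapped = i == config.n_arrays - 1  # last array reverses the dyes
        assignments[a] = (control, treated) if swapped else (treated, control)
    design = DesignTable(assignments)

    c0, c1, c2 = config.dye_bias
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
    rows = []
    for a in arrays:
        array_effect = rng.normal(0.0, config.array_effect_sd)
        chan_val = {}
        for channel in ("cy5", "cy3"):
            cond = design.assignments[a][0 if channel == "cy5" else 1]
            signal = baseline + (effects if cond == treated else 0.0)
            chan_val[channel] = signal + array_effect
        a_latent = (chan_val["cy5"] + chan_val["cy3"]) / 2.0
        chan_val["cy5"] = chan_val["cy5"] + (c0 + c1 * a_latent + c2 * a_latent**2)

        spot = {}
        for channel in ("cy5", "cy3"):
            v = chan_val[channel]
            # Measurement noise with total gene-level (duplicate-averaged)
            # variance noise_sd**2, split into a component shared by the two
            # duplicates and an independent per-spot component:
            #   shared + indep/2 = noise_sd**2
            #   corr(duplicates) = (var_v + shared) / (var_v + shared + indep)
            # When the correlation target is not reachable at this noise
            # level the shared part collapses to zero (pure spot noise) and
            # the realized correlation follows from the signal spread.
            rho = config.replicate_corr
            c_ratio = (1.0 - rho) / rho
            var_v = float(np.var(v))
            var_total = config.noise_sd**2
            var_shared = max(
                0.0, (var_total - c_ratio * var_v / 2.0) / (1.0 + c_ratio / 2.0)
            )
            var_indep = (
                c_ratio * (var_v + var_shared)
                if var_shared > 0
                else 2.0 * var_total
            )
            shared = v + rng.normal(0.0, np.sqrt(var_shared), n)
            spot_sd = np.sqrt(var_indep)
            spot[channel] = np.column_stack(
                [
                    shared + rng.normal(0.0, spot_sd, n),
                    shared + rng.normal(0.0, spot_sd, n),
                ]
            )

        for rep in (1, 2):
            bg5 = np.clip(rng.normal(config.background_level, config.background_sd, n), 0, None)
            bg3 = np.clip(rng.normal(config.background_level, config.background_sd, n), 0, None)
            fg5 = np.exp2(spot["cy5"][:, rep - 1]) + bg5
            fg3 = np.exp2(spot["cy3"][:, rep - 1]) + bg3
            if config.nonpositive_fraction > 0:
                kill = rng.random(n) < config.nonpositive_fraction
                u = rng.random(n)
                fg5 = np.where(kill, bg5 * u, fg5)
                kill3 = rng.random(n) < config.nonpositive_fraction
                fg3 = np.where(kill3, bg3 * rng.random(n), fg3)
            rows.append(
                pd.DataFrame(
                    {
                        "array_id": a,
                        "gene_id": genes,
                        "replicate": rep,
                        "fg_cy5": fg5,
                        "bg_cy5": bg5,
                        "fg_cy3": fg3,
                        "bg_cy3": bg3,
                    }
                )
            )
    spots = pd.concat(rows, ignore_index=True)
    return spots, design, truth


@dataclass
class TwoStageData:
    """Paired experiments for a two-stage screen, with per-stage truth."""

    stage1_spots: pd.DataFrame
    stage1_design: DesignTable
    stage1_truth: pd.DataFrame
    stage2_spots: pd.DataFrame
    stage2_design: DesignTable
    stage2_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def simulate_two_stage(
    config: SimulationConfig,
    stage2_de_fraction: float = 1.0,
    control: str = "NS",
    stage1_treated: str = "LPS",
    stage2_treated: str = "LPS+thalidomide",
) -> TwoStageData:
    """Simulate both experiments of a two-stage study.

    Stage 1 plants ``config.de_fraction`` of genes as responsive to the
    stimulus.  In stage 2 a fraction ``stage2_de_fraction`` of those same
    genes (default: all of them) remains differentially expressed in the
    treated-vs-control contrast; the rest revert to null.  Both experiments
    draw from one seeded stream, so the whole study is reproducible from
    ``config.seed``.
    """
    if not 0 <= stage2_de_fraction <= 1:
        raise ValueError("stage2_de_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    truth1 = make_truth(config, rng)
    s1_spots, s1_design, _ = simulate_experiment(
        config, treated=stage1_treated, control=control, truth=truth1, rng=rng
    )
    truth2 = truth1.copy()
    de_genes = truth1.index[truth1["is_de"]]
    n_keep = round(stage2_de_fraction * len(de_genes))
    kept = rng.choice(len(de_genes), size=n_keep, replace=False)
    reverted = de_genes.difference(de_genes[kept])
    truth2.loc[reverted, ["is_de", "direction", "true_log2fc"]] = [False, "none", 0.0]
    s2_spots, s2_design, _ = simulate_experiment(
        config, treated=stage2_treated, control=control, truth=truth2, rng=rng
    )
    return TwoStageData(
        stage1_spots=s1_spots,
        stage1_design=s1_design,
        stage1_truth=truth1,
        stage2_spots=s2_spots,
        stage2_design=s2_design,
        stage2_truth=truth2,
        config=config,
    )


def evaluate_truth(selection, truth: pd.DataFrame, threshold: float | None = None):
    """Confusion metrics of a selection against the planted truth.

    ``selection`` may be a list of gene ids, a
    :class:`~twostage_rp.rankprod.StageSelection` (stage-2 list used), or a
    :class:`~twostage_rp.rankprod.RankProductResult` (thresholded at
    ``threshold`` on min(p_up, p_down)).  Returns a dict with recall,
    precision, empirical FDR and per-direction confusion counts; precision
    and FDR are None for an empty selection.
    """
    from .rankprod import RankProductResult, StageSelection, select

    directions = None
    if isinstance(selection, StageSelection):
        genes = pd.Index(selection.stage2_genes)
        directions = selection.direction
    elif isinstance(selection, RankProductResult):
        if threshold is None:
            raise ValueError("threshold required to select from a RankProductResult")
        sel = select(selection, threshold)
        genes = sel.index
        directions = sel["direction"]
    else:
        genes = pd.Index(list(selection))

    if len(genes) and not genes.isin(truth.index).all():
        raise ValueError("selection contains gene ids absent from the truth table")

    de = set(truth.index[truth["is_de"]])
    picked = set(genes)
    tp = len(picked & de)
    metrics = {
        "n_selected": len(picked),
        "n_de": len(de),
        "recall": tp / len(de) if de else None,
        "precision": tp / len(picked) if picked else None,
        "fdr": (len(picked) - tp) / len(picked) if picked else None,
    }
    if directions is not None:
        conf = {"up": {"correct": 0, "wrong": 0}, "down": {"correct": 0, "wrong": 0}}
        for g in genes:
            d = directions[g]
            if g in de:
                key = "correct" if truth.loc[g, "direction"] == d else "wrong"
                conf[d][key] += 1
        metrics["direction_confusion"] = conf
    return metrics


def make_gene_sets(
    truth: pd.DataFrame,
    n_categories: int = 20,
    category_size: int = 40,
    n_enriched: int = 4,
    enriched_de_share: float = 0.6,
    seed: int = 0,
) -> GeneSetCollection:
    """Toy GMT-style annotation with some categories enriched in planted genes.

    The first ``n_enriched`` categories draw ``enriched_de_share`` of their
    members from the planted set; the rest sample uniformly, so enrichment
    analysis of a good selection should flag the former and not the latter.
    """
    rng = np.random.default_rng(seed)
    de = truth.index[truth["is_de"]].to_numpy()
    null = truth.index[~truth["is_de"]].to_numpy()
    members: dict[str, set[str]] = {}
    terms: dict[str, str] = {}
    for i in range(n_categories):
        cid = f"SYN:{i + 1:04d}"
        if i < n_enriched and len(de):
            n_from_de = min(round(enriched_de_share * category_size), len(de))
            chosen = np.concatenate(
                [
                    rng.choice(de, size=n_from_de, replace=False),
                    rng.choice(null, size=category_size - n_from_de, replace=False),
                ]
            )
            terms[cid] = f"synthetic process {i + 1} (planted-enriched)"
        else:
            chosen = rng.choice(truth.index.to_numpy(), size=category_size, replace=False)
            terms[cid] = f"synthetic process {i + 1}"
        members[cid] = set(chosen)
    return GeneSetCollection(members=members, terms=terms)


def simulate_qpcr(
    gene_effects: dict[str, dict[str, float]],
    groups: tuple[str, ...] = ("NS", "LPS", "LPS+thalidomide"),
    calibrator_group: str = "NS",
    n_donors: int = 4,
    n_duplicates: int = 2,
    ct_reference_mean: float = 20.0,
    ct_target_mean: float = 26.0,
    donor_sd: float = 0.4,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table for a confirmation qPCR of a few genes across culture groups.

    ``gene_effects`` maps gene -> {group: true log2 expression relative to
    the calibrator group}; a gene expressed 2-fold higher in a group has its
    target Ct lowered by 1 cycle there.  Technical duplicates appear as
    repeated rows.  Donor-to-donor offsets shift target and reference Ct
    together, which the ddCt normalization removes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for donor in range(1, n_donors + 1):
        donor_shift = rng.normal(0.0, donor_sd)
        for group in groups:
            for gene, per_group in gene_effects.items():
                log2_level = per_group.get(group, 0.0)
                ct_t = ct_target_mean - log2_level + donor_shift
                ct_r = ct_reference_mean + donor_shift
                for _ in range(n_duplicates):
                    rows.append(
                        {
                            "donor_id": f"D{donor}",
                            "group": group,
                            "gene": gene,
                            "ct_target": ct_t + rng.normal(0.0, ct_noise_sd),
                            "ct_reference": ct_r + rng.normal(0.0, ct_noise_sd),
                        }
                    )
    if calibrator_group not in groups:
        raise ValueError("calibrator group must be one of the simulated groups")
    return pd.DataFrame(rows)
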