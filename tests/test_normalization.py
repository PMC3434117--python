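import itertools

import numpy as np
import pandas as pd
import pytest

from twostage_rp import array_io, normalization
from twostage_rp.array_io import GeneExpressionTable
from twostage_rp.normalization import (
    MAData,
    anova_normalize,
    lowess_within,
    ma_transform,
    qc_correlations,
)


def expr_from_channels(log2r: np.ndarray, log2g: np.ndarray, arrays=("A1",)):
    cols = pd.MultiIndex.from_product([arrays, ("cy5", "cy3")])
    genes = [f"g{i}" for i in range(len(log2r))]
    df = pd.DataFrame(index=genes, columns=cols, dtype=float)
    for a in arrays:
        df[(a, "cy5")] = log2r
        df[(a, "cy3")] = log2g
    return GeneExpressionTable(values=df)


class TestMATransform:
    def test_arithmetic(self):
        ma = ma_transform(expr_from_channels(np.array([4.0]), np.array([2.0])))
        assert ma.M.iloc[0, 0] == 2.0
        assert ma.A.iloc[0, 0] == 3.0

    def test_equal_channels_give_zero_M(self):
        x = np.linspace(4, 12, 20)
        ma = ma_transform(expr_from_channels(x, x))
        assert np.allclose(ma.M, 0.0)

    def test_round_trip_bit_exact(self):
        rng = np.random.default_rng(0)
        r, g = rng.normal(8, 2, 50), rng.normal(8, 2, 50)
        expr = expr_from_channels(r, g)
        back = ma_transform(expr).to_expression()
        pd.testing.assert_frame_equal(
            back.values.astype(float), expr.values.astype(float),
            check_names=False,
        )


class TestLowessWithin:
    def make_ma(self, A, M):
        genes = [f"g{i}" for i in range(len(A))]
        return MAData(
            M=pd.DataFrame({"A1": M}, index=genes),
            A=pd.DataFrame({"A1": A}, index=genes),
        )

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        A = rng.normal(8, 1.5, 500)
        ma = lowess_within(self.make_ma(A, np.full(500, 0.7)))
        assert np.abs(ma.M.to_numpy()).max() < 1e-6

    def test_linear_trend_flattened(self):
        # oracle: OLS slope of the corrected M on A
        rng = np.random.default_rng(2)
        A = rng.normal(8, 1.5, 1000)
        M = 0.5 * A + rng.normal(0, 0.01, 1000)
        out = lowess_within(self.make_ma(A, M))
        slope = np.polyfit(A, out.M["A1"].to_numpy(), 1)[0]
        assert abs(slope) < 0.02

    def test_quadratic_trend_amplitude_reduced_90pct(self):
        rng = np.random.default_rng(3)
        A = rng.normal(8, 1.5, 2000)
        M = 0.3 * (A - 8) ** 2 + rng.normal(0, 0.05, 2000)
        out = lowess_within(self.make_ma(A, M))
        bins = np.quantile(A, np.linspace(0, 1, 21))
        idx = np.clip(np.digitize(A, bins[1:-1]), 0, 19)
        amp_before = max(abs(M[idx == b].mean()) for b in range(20))
        amp_after = max(abs(out.M["A1"].to_numpy()[idx == b].mean()) for b in range(20))
        assert amp_after <= 0.1 * amp_before

    def test_idempotent_on_noise_free_input(self):
        # a linear trend is reproduced exactly by the local-linear smoother,
        # so a second pass must leave the corrected M unchanged
        rng = np.random.default_rng(4)
        A = rng.normal(8, 1.5, 500)
        M = 0.4 * A - 1.0
        once = lowess_within(self.make_ma(A, M))
        twice = lowess_within(once)
        assert np.abs(twice.M.to_numpy() - once.M.to_numpy()).max() < 1e-6

    def test_parameter_validation(self):
        ma = self.make_ma(np.linspace(4, 12, 100), np.zeros(100))
        with pytest.raises(ValueError, match="span"):
            lowess_within(ma, span=1.5)
        tiny = self.make_ma(np.linspace(4, 12, 10), np.zeros(10))
        with pytest.raises(ValueError, match="50 genes"):
            lowess_within(tiny)


def lstsq_oracle(values: pd.DataFrame) -> np.ndarray:
    """Generic least-squares fit of y ~ mu + array + dye + array:dye with
    sum-to-zero constraints, via an explicit design matrix; returns residuals."""
    arrays = list(values.columns.get_level_values(0).unique())
    dyes = ["cy5", "cy3"]
    rows, y = [], []
    # effect (sum-to-zero) coding: n_arrays-1 array columns, 1 dye column,
    # (n_arrays-1) interaction columns
    na = len(arrays)
    for g in values.index:
        for i, a in enumerate(arrays):
            for j, d in enumerate(dyes):
                arr = np.zeros(na - 1)
                if i < na - 1:
                    arr[i] = 1.0
                else:
                    arr[:] = -1.0
                dye = 1.0 if j == 0 else -1.0
                row = np.concatenate([[1.0], arr, [dye], arr * dye])
                rows.append(row)
                y.append(values.loc[g, (a, d)])
    X = np.asarray(rows)
    y = np.asarray(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


class TestAnovaNormalize:
    def toy_expr(self, n_genes=4, n_arrays=3, seed=0):
        rng = np.random.default_rng(seed)
        cols = pd.MultiIndex.from_product(
            [[f"A{i}" for i in range(1, n_arrays + 1)], ("cy5", "cy3")]
        )
        df = pd.DataFrame(
            rng.normal(8, 1, (n_genes, 2 * n_arrays)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=cols,
        )
        return GeneExpressionTable(values=df)

    def test_saturated_input_gives_zero_residuals(self):
        expr = self.toy_expr()
        for c in expr.values.columns:
            expr.values[c] = 5.0 + hash(c) % 7  # constant within each cell
        fit = anova_normalize(expr)
        assert np.allclose(fit.residuals.to_numpy(), 0.0)

    def test_matches_generic_least_squares(self):
        expr = self.toy_expr(n_genes=4, n_arrays=3, seed=5)
        fit = anova_normalize(expr)
        oracle = lstsq_oracle(expr.values)
        ours = np.concatenate(
            [
                [fit.residuals.loc[g, (a, d)] for a in expr.arrays for d in ("cy5", "cy3")]
                for g in expr.values.index
            ]
        )
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_location_equivariance_per_array(self):
        expr = self.toy_expr(seed=6)
        fit0 = anova_normalize(expr)
        shifted = GeneExpressionTable(values=expr.values.copy())
        for d in ("cy5", "cy3"):
            shifted.values[("A2", d)] += 3.0
        fit1 = anova_normalize(shifted)
        assert fit1.array_effects["A2"] - fit0.array_effects["A2"] == pytest.approx(
            3.0 * (1 - 1 / 3)
        )
        pd.testing.assert_frame_equal(fit0.residuals, fit1.residuals)

    def test_residuals_center_within_cells_and_reconstruct(self):
        expr = self.toy_expr(n_genes=50, seed=7)
        fit = anova_normalize(expr)
        for a, d in itertools.product(expr.arrays, ("cy5", "cy3")):
            assert abs(fit.residuals[(a, d)].mean()) < 1e-9
            recon = fit.fitted(a, d) + fit.residuals[(a, d)]
            assert np.allclose(recon, expr.values[(a, d)])

    def test_relabeling_arrays_permutes_residuals(self):
        expr = self.toy_expr(seed=8)
        fit = anova_normalize(expr)
        relabeled = expr.values.rename(
            columns={"A1": "A2", "A2": "A3", "A3": "A1"}, level=0
        ).sort_index(axis=1)
        fit2 = anova_normalize(GeneExpressionTable(values=relabeled))
        assert np.allclose(
            fit.residuals[("A1", "cy5")], fit2.residuals[("A2", "cy5")]
        )

    def test_missing_cell_is_an_error(self):
        expr = self.toy_expr()
        vals = expr.values.drop(columns=[("A2", "cy3")])
        with pytest.raises(ValueError, match="A2"):
            anova_normalize(GeneExpressionTable(values=vals))


class TestQCCorrelations:
    def spots_from_pairs(self, pairs, array_id="A1"):
        rows = []
        for i, (v1, v2) in enumerate(pairs):
            for rep, v in ((1, v1), (2, v2)):
                rows.append(
                    {
                        "array_id": array_id,
                        "gene_id": f"g{i}",
                        "replicate": rep,
                        "corr_cy5": v,
                        "corr_cy3": v,
                    }
                )
        return pd.DataFrame(rows)

    def expr_of(self, arrays, values):
        cols = pd.MultiIndex.from_product([arrays, ("cy5", "cy3")])
        df = pd.DataFrame(index=[f"g{i}" for i in range(len(values))],
                          columns=cols, dtype=float)
        for a in arrays:
            for d in ("cy5", "cy3"):
                df[(a, d)] = values
        return GeneExpressionTable(values=df)

    def test_identical_duplicates_give_r_one(self):
        vals = 2.0 ** np.arange(3, 9)
        spots = self.spots_from_pairs(list(zip(vals, vals)))
        qc = qc_correlations(spots, self.expr_of(["A1"], np.log2(vals)))
        assert np.allclose(qc.within["r"], 1.0)

    def test_anticorrelated_pair_gives_r_minus_one(self):
        x = np.array([3.0, 4.0, 5.0, 6.0])
        cols = pd.MultiIndex.from_product([["A1", "A2"], ("cy5", "cy3")])
        df = pd.DataFrame(index=[f"g{i}" for i in range(4)], columns=cols, dtype=float)
        for d in ("cy5", "cy3"):
            df[("A1", d)] = x
            df[("A2", d)] = -x
        spots = self.spots_from_pairs(list(zip(2.0**x, 2.0**x)))
        qc = qc_correlations(spots, GeneExpressionTable(values=df))
        assert np.allclose(qc.between["r"], -1.0)

    def test_independent_noise_arrays_weakly_correlated(self):
        rng = np.random.default_rng(9)
        n = 1000
        cols = pd.MultiIndex.from_product([["A1", "A2"], ("cy5", "cy3")])
        df = pd.DataFrame(
            rng.normal(8, 1, (n, 4)), index=[f"g{i}" for i in range(n)], columns=cols
        )
        spots = self.spots_from_pairs([(256.0, 300.0)] * 3)
        qc = qc_correlations(spots, GeneExpressionTable(values=df))
        # sampling bound ~3/sqrt(n)
        assert (qc.between["r"].abs() < 3 / np.sqrt(n)).all()

    def test_zero_variance_flagged_not_propagated(self):
        spots = self.spots_from_pairs([(8.0, 8.0)] * 5)
        qc = qc_correlations(spots, self.expr_of(["A1"], np.full(5, 3.0)))
        assert not qc.within["defined"].any()
        assert qc.within["r"].isna().all()


class TestFullNormalizationPipeline:
    def test_null_simulation_residual_means_centered(self):
        from twostage_rp import synthetic

        cfg = synthetic.SimulationConfig(
            n_genes=800, de_fraction=0.0, dye_bias=(0.0, 0.0, 0.0),
            nonpositive_fraction=0.0, seed=10,
        )
        spots, design, _ = synthetic.simulate_experiment(cfg)
        expr = array_io.preprocess(spots, design)
        ma = lowess_within(ma_transform(expr))
        fit = anova_normalize(ma.to_expression(), design)
        grand = fit.residuals.to_numpy().mean()
        sigma = fit.residuals.to_numpy().std()
        assert abs(grand) < 3 * sigma / np.sqrt(fit.residuals.size)
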