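"""Polychorics, one-factor fit indices, LID screen, and the prune loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from probank.bankio import ResponseMatrix
from probank.dimensionality import (PoolExhaustedError, ScreenConfig,
                                    bivariate_normal_cdf, fit_unidimensional,
                                    polychoric_corr, polychoric_matrix,
                                    prune_pool, residual_lid_screen)
from probank.simulate import SimulationDesign, make_bank, simulate_responses


class TestBivariateNormalCdf:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            h, k = rng.uniform(-3, 3, size=2)
            rho = rng.uniform(-0.95, 0.95)
            ref = stats.multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]])
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-12)

    def test_zero_arguments(self):
        ref = stats.multivariate_normal.cdf(
            [0, 0], mean=[0, 0], cov=[[1, 0.7], [0.7, 1]])
        assert bivariate_normal_cdf(0.0, 0.0, 0.7) == pytest.approx(ref, abs=1e-12)


class TestPolychoric:
    def test_recovers_generating_correlation(self, rng):
        """Five-category discretisation of a bivariate normal with rho=0.5."""
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000)
        cuts = [-1.2, -0.4, 0.4, 1.2]
        x = np.digitize(z[:, 0], cuts) + 1.0
        y = np.digitize(z[:, 1], cuts) + 1.0
        assert polychoric_corr(x, y) == pytest.approx(0.5, abs=0.05)

    def test_independent_items_near_zero(self, rng):
        n = 5000
        frame = pd.DataFrame({
            f"v{j}": rng.integers(1, 6, size=n).astype(float) for j in range(4)})
        R = polychoric_matrix(frame)
        off = R.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.04

    def test_symmetric_unit_diagonal(self, rng):
        frame = pd.DataFrame({
            "a": rng.integers(1, 5, 500).astype(float),
            "b": rng.integers(1, 5, 500).astype(float),
            "c": rng.integers(1, 5, 500).astype(float)})
        R = polychoric_matrix(frame).to_numpy()
        assert np.array_equal(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    def test_single_category_item_raises_with_name(self):
        frame = pd.DataFrame({"good": [1.0, 2, 3, 2, 1], "flat": [2.0] * 5})
        with pytest.raises(ValueError, match="flat"):
            polychoric_matrix(frame)


def one_factor_corr(loadings: np.ndarray) -> pd.DataFrame:
    R = np.outer(loadings, loadings)
    np.fill_diagonal(R, 1.0)
    cols = [f"v{j}" for j in range(len(loadings))]
    return pd.DataFrame(R, index=cols, columns=cols)


class TestFitUnidimensional:
    def test_exact_one_factor_matrix_fits_perfectly(self):
        corr = one_factor_corr(np.array([0.7, 0.6, 0.8, 0.5, 0.65, 0.75]))
        fit = fit_unidimensional(corr, n=500)
        assert fit.indices.cfi == pytest.approx(1.0, abs=1e-3)
        assert fit.indices.rmsea == pytest.approx(0.0, abs=1e-3)
        assert fit.indices.tli <= 1.0

    def test_recovers_loadings_from_sampled_data(self):
        """Loadings recovered within +-0.05 on one-factor data at n=2000."""
        bank = make_bank(10, seed=14)
        design = SimulationDesign(bank=bank, n_persons=2000, seed=5)
        data = simulate_responses(design)
        fit = fit_unidimensional(polychoric_matrix(data), n=2000)
        # generating loading of a logistic GRM item on the latent response
        # scale: a / sqrt(a^2 + pi^2/3)
        for it in bank:
            lam_true = it.slope / np.sqrt(it.slope**2 + np.pi**2 / 3)
            assert fit.loadings[it.item_id] == pytest.approx(lam_true, abs=0.05)

    def test_two_factor_data_shows_misfit(self, rng):
        """Two weakly correlated factors -> RMSEA above the acceptable gate."""
        n = 1500
        f1 = rng.normal(size=n)
        f2 = 0.2 * f1 + np.sqrt(1 - 0.04) * rng.normal(size=n)
        cols = {}
        for j in range(10):
            f = f1 if j < 5 else f2
            latent = 0.85 * f + np.sqrt(1 - 0.85**2) * rng.normal(size=n)
            cols[f"v{j}"] = np.digitize(latent, [-1.0, 0.0, 1.0]) + 1.0
        fit = fit_unidimensional(polychoric_matrix(pd.DataFrame(cols)), n=n)
        assert fit.indices.rmsea > 0.08
        assert fit.indices.cfi < 0.95

    def test_heywood_case_clamped_and_flagged(self):
        corr = one_factor_corr(np.array([0.99, 0.99, 0.99, 0.4]))
        corr.iloc[0, 1] = corr.iloc[1, 0] = 0.999  # force loading past 1
        fit = fit_unidimensional(corr, n=200)
        assert np.all(np.abs(fit.loadings) <= 0.999)


class TestResidualLidScreen:
    def test_threshold_is_strict_at_point_two(self):
        """A residual of 0.21 is flagged; 0.19 is not."""
        lam = np.array([0.6, 0.6, 0.6, 0.6])
        corr = one_factor_corr(lam)
        corr.iloc[0, 1] = corr.iloc[1, 0] = 0.36 + 0.21
        corr.iloc[2, 3] = corr.iloc[3, 2] = 0.36 + 0.19
        flagged = residual_lid_screen(corr, pd.Series(lam, index=corr.columns))
        assert [f[:2] for f in flagged] == [("v0", "v1")]
        assert flagged[0][2] == pytest.approx(0.21, abs=1e-9)

    def test_clean_one_factor_data_rarely_flags(self):
        flags = 0
        for rep in range(5):
            design = SimulationDesign(bank=make_bank(15, seed=30 + rep),
                                      n_persons=2000, seed=rep)
            data = simulate_responses(design)
            R = polychoric_matrix(data)
            fit = fit_unidimensional(R, n=2000)
            flags += len(residual_lid_screen(R, fit.loadings))
        assert flags == 0


class TestPrunePool:
    def test_clean_pool_zero_removals(self):
        design = SimulationDesign(bank=make_bank(15, seed=40), n_persons=1000,
                                  seed=8)
        report = prune_pool(simulate_responses(design))
        assert report.removals == []
        assert report.retained == list(design.bank.item_ids)
        assert report.fit_acceptable

    def test_low_loading_item_removed_in_wave_one(self, rng):
        """An item nearly unrelated to the trait is dropped first."""
        bank = make_bank(11, seed=41, slope_logmean=np.log(1.8), slope_logsd=0.1)
        design = SimulationDesign(bank=bank, n_persons=1500, seed=9)
        data = simulate_responses(design)
        # replace one item with near-noise (loading ~ 0.1)
        theta = data.covariates["true_theta"].to_numpy()
        latent = 0.1 * theta + rng.normal(size=len(theta))
        data.responses["item011"] = (np.digitize(latent, [-1, 0, 1]) + 1).astype(float)
        report = prune_pool(data)
        removed = [(r.item_id, r.wave, r.reason) for r in report.removals]
        assert ("item011", 1, "low_loading") in removed

    def test_reasons_limited_to_enumerated_set(self):
        design = SimulationDesign(bank=make_bank(12, seed=42), n_persons=800,
                                  seed=10)
        from probank.simulate import inject_lid
        data = inject_lid(design, ("item004", "item011"), 0.6)
        report = prune_pool(data)
        assert {r.reason for r in report.removals} <= {"low_loading", "lid", "misfit"}
        # conservation: retained + removed = input pool
        assert sorted(report.retained + [r.item_id for r in report.removals]) \
            == sorted(design.bank.item_ids)

    def test_pool_floor_raises_with_partial_report(self, rng):
        """A pool of pure noise collapses and raises, carrying the audit."""
        n = 600
        frame = pd.DataFrame({
            f"v{j}": rng.integers(1, 5, size=n).astype(float) for j in range(5)})
        data = ResponseMatrix(frame)
        with pytest.raises(PoolExhaustedError) as exc:
            prune_pool(data, ScreenConfig(pool_floor=4))
        assert exc.value.partial.removals is not None
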