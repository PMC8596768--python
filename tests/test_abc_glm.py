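"""Reference table, PLS transform, retention, GLM fit and grid posteriors."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, kstest, norm

from lsd import (
    ParameterPrior,
    ReferenceTable,
    build_reference_table,
    fit_glm,
    fit_transform,
    locus_posterior,
    posterior_grid,
    retain_closest,
    retention_size,
    simulate_locus,
    stats_vector,
)
from lsd.abc_glm import GLMFit, StatTransform, _param_column
from tests.conftest import TOY_L, TOY_POPS


def synthetic_table(n=400, n_noise=4, seed=0, slope=2.0):
    """Focal parameter 'a' on log10 scale; stat x0 = slope*a + small noise."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-2, 2, n)
    stats = {"x0": slope * a + 0.01 * rng.normal(size=n)}
    for j in range(1, 1 + n_noise):
        stats[f"x{j}"] = rng.normal(size=n)
    priors = [ParameterPrior("a", "log10", -2.0, 2.0)]
    return ReferenceTable(
        pd.DataFrame({"log10_a": a}),
        pd.DataFrame(stats),
        priors,
        ["a"],
    )


class TestBuildReferenceTable:
    def test_row_count_and_seed_reproducibility(self, toy_model, toy_priors, toy_sample_config):
        t1 = build_reference_table(
            toy_model, toy_priors, 150, toy_sample_config, TOY_L, 99
        )
        t2 = build_reference_table(
            toy_model, toy_priors, 150, toy_sample_config, TOY_L, 99
        )
        assert len(t1.params) == 150
        pd.testing.assert_frame_equal(t1.params, t2.params)
        pd.testing.assert_frame_equal(t1.stats, t2.stats)

    def test_focal_columns_are_prior_uniform_on_log_scale(self, toy_table):
        for col in toy_table.focal_columns:
            u = (toy_table.params[col] + 4.0) / 7.0
            assert kstest(u, "uniform").pvalue > 0.001

    def test_round_trip_through_tsv(self, toy_table, tmp_path):
        path = tmp_path / "ref.tsv"
        toy_table.to_tsv(path)
        back = ReferenceTable.from_tsv(path)
        assert back.focal == toy_table.focal
        assert [p.name for p in back.priors] == [p.name for p in toy_table.priors]
        pd.testing.assert_frame_equal(back.params, toy_table.params, atol=1e-9)
        pd.testing.assert_frame_equal(back.stats, toy_table.stats, atol=1e-9)

    def test_tiny_tables_rejected(self, toy_model, toy_priors, toy_sample_config):
        with pytest.raises(ValueError):
            build_reference_table(toy_model, toy_priors, 50, toy_sample_config, TOY_L, 0)


class TestFitTransform:
    def test_informative_statistic_dominates_first_component(self):
        table = synthetic_table()
        tr = fit_transform(table, 1)
        loadings = tr.pls.x_weights_[:, 0]
        loadings = loadings / np.linalg.norm(loadings)
        assert abs(loadings[tr.names.index("x0")]) > 0.9

    def test_duplicated_column_is_tolerated(self):
        table = synthetic_table()
        table.stats["x_dup"] = table.stats["x0"]
        tr = fit_transform(table, 2)
        assert np.all(np.isfinite(tr.transform(table.stats)))

    def test_zero_components_rejected(self):
        with pytest.raises(ValueError):
            fit_transform(synthetic_table(), 0)

    def test_constant_statistic_dropped_with_warning(self):
        table = synthetic_table()
        table.stats["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            tr = fit_transform(table, 2)
        assert "flat" not in tr.names

    def test_distances_invariant_to_affine_rescaling_of_linear_stats(self):
        # bounded statistics enter linearly; affine changes are absorbed by
        # standardization, so retained sets agree
        table = synthetic_table()
        obs = table.stats.iloc[7]
        tr = fit_transform(table, 2)
        kept = retain_closest(table, tr, obs, 50)

        scaled = ReferenceTable(
            table.params.copy(),
            table.stats * 3.0 + 1.0,
            table.priors,
            table.focal,
        )
        tr2 = fit_transform(scaled, 2)
        kept2 = retain_closest(scaled, tr2, obs * 3.0 + 1.0, 50)
        assert set(kept) == set(kept2)


class TestRetainClosest:
    def test_retaining_everything_returns_all_rows(self):
        table = synthetic_table(n=120)
        tr = fit_transform(table, 2)
        idx = retain_closest(table, tr, table.stats.iloc[0], 120)
        assert len(idx) == 120

    def test_exact_match_has_distance_zero_and_is_retained(self):
        table = synthetic_table(n=100)
        tr = fit_transform(table, 2)
        idx = retain_closest(table, tr, table.stats.iloc[42], 1)
        assert idx[0] == 42

    def test_matches_brute_force_sorted_head(self):
        table = synthetic_table(n=100, seed=3)
        tr = fit_transform(table, 3)
        obs = table.stats.iloc[10]
        scores = tr.transform(table.stats)
        target = tr.transform(obs)[0]
        d2 = np.sum((scores - target) ** 2, axis=1)
        expected = np.argsort(d2, kind="stable")[:20]
        got = retain_closest(table, tr, obs, 20)
        assert list(got) == list(expected)

    def test_missing_observed_statistic_is_named(self):
        table = synthetic_table()
        tr = fit_transform(table, 2)
        obs = table.stats.iloc[0].copy()
        obs["x1"] = np.nan
        with pytest.raises(ValueError, match="x1"):
            retain_closest(table, tr, obs, 10)

    def test_retention_size_rule(self):
        assert retention_size(250_000) == 2500
        assert retention_size(50_000) == 1000  # floor of 1000
        assert retention_size(500) == 500  # capped at table size


class TestFitGlm:
    def test_noiseless_linear_model_recovered(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(-1, 1, size=(200, 2))
        b_true = np.array([[1.0, -2.0], [0.5, 3.0], [2.0, 0.0]])
        c_true = np.array([0.3, -0.1, 1.0])
        scores = c_true + theta @ b_true.T
        glm = fit_glm(theta, scores, ["a", "b"])
        assert np.allclose(glm.B, b_true, atol=1e-6)
        assert np.allclose(glm.c0, c_true, atol=1e-6)

    def test_null_model_has_near_zero_coefficients(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(-1, 1, size=(2000, 2))
        scores = rng.normal(size=(2000, 3))
        glm = fit_glm(theta, scores, ["a", "b"])
        assert np.max(np.abs(glm.B)) < 0.1

    def test_sigma_symmetric_positive_definite(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(-1, 1, size=(50, 2))
        scores = rng.normal(size=(50, 4))
        glm = fit_glm(theta, scores, ["a", "b"])
        assert np.allclose(glm.sigma, glm.sigma.T)
        assert np.all(np.linalg.eigvalsh(glm.sigma) > 0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_glm(np.zeros((3, 2)), np.zeros((3, 2)), ["a", "b"])


def identity_transform(names):
    """A StatTransform passing (standardized) stats straight through."""
    k = len(names)
    return StatTransform(list(names), np.zeros(k, dtype=bool), np.zeros(k), np.ones(k), None, k)


class TestPosteriorGrid:
    def test_zero_coefficients_give_uniform_posterior(self):
        glm = GLMFit(np.zeros(1), np.zeros((1, 1)), np.eye(1), ["log10_a"])
        priors = [ParameterPrior("a", "log10", -2.0, 2.0)]
        tr = identity_transform(["x"])
        grid = posterior_grid(glm, priors, tr, pd.Series({"x": 0.0}), focal=["a"], shape=(41,))
        assert np.allclose(grid.mass, 1.0 / 41)

    def test_mass_sums_to_one(self):
        glm = GLMFit(np.zeros(1), np.array([[1.0]]), np.eye(1) * 0.5, ["log10_a"])
        priors = [ParameterPrior("a", "log10", -2.0, 2.0)]
        tr = identity_transform(["x"])
        grid = posterior_grid(glm, priors, tr, pd.Series({"x": 0.3}), focal=["a"], shape=(33,))
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_conjugate_normal_closed_form(self):
        # s = b*theta + eps, eps ~ N(0, sig2); uniform prior on theta:
        # posterior theta | s ~ N(s/b, sig2/b^2) truncated to the prior box
        b, sig2, s_obs = 1.3, 0.4, 0.55
        glm = GLMFit(np.zeros(1), np.array([[b]]), np.eye(1) * sig2, ["log10_a"])
        priors = [ParameterPrior("a", "log10", -2.0, 2.0)]
        tr = identity_transform(["x"])
        grid = posterior_grid(glm, priors, tr, pd.Series({"x": s_obs}), focal=["a"], shape=(201,))
        centers = grid.axes[0]
        expected = norm.pdf(centers, loc=s_obs / b, scale=np.sqrt(sig2) / b)
        expected = expected / expected.sum()
        assert 0.5 * np.abs(grid.mass - expected).sum() < 0.01

    def test_extreme_underflow_still_normalizes(self):
        glm = GLMFit(np.zeros(1), np.array([[100.0]]), np.eye(1) * 1e-6, ["log10_a"])
        priors = [ParameterPrior("a", "log10", -2.0, 2.0)]
        tr = identity_transform(["x"])
        grid = posterior_grid(glm, priors, tr, pd.Series({"x": 150.0}), focal=["a"], shape=(33,))
        assert np.isfinite(grid.mass).all()
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-10)

    def test_shrinking_sigma_concentrates_the_posterior(self):
        priors = [ParameterPrior("a", "log10", -2.0, 2.0)]
        tr = identity_transform(["x"])
        entropies = []
        for sig2 in (1.0, 0.1, 0.01):
            glm = GLMFit(np.zeros(1), np.array([[1.0]]), np.eye(1) * sig2, ["log10_a"])
            grid = posterior_grid(glm, priors, tr, pd.Series({"x": 0.0}), focal=["a"], shape=(101,))
            entropies.append(grid.entropy())
        assert entropies[0] > entropies[1] > entropies[2]


class TestCalibration:
    def test_posterior_rank_of_truth_is_uniform(self, toy_model, toy_table, toy_transform,
                                                toy_sample_config):
        # simulation-based calibration of the marginal posterior of log10 M12
        rng = np.random.default_rng(1234)
        ranks = []
        for _ in range(500):
            m12, m21 = 10 ** rng.uniform(-4, 3, size=2)
            locus = simulate_locus(
                toy_model, {"M12": m12, "M21": m21}, toy_sample_config, TOY_L, rng
            )
            sv = stats_vector(locus, TOY_POPS, sfs_bins=4)
            if sv.isna().any():
                continue
            grid = locus_posterior(toy_table, toy_transform, sv, n_retain=400)
            marg = grid.mass.sum(axis=1)
            centers = grid.axes[0]
            below = marg[centers < np.log10(m12)].sum()
            at = marg[np.abs(centers - np.log10(m12)) < 1e-12].sum()
            ranks.append(below + rng.uniform() * at)
        hist, _ = np.histogram(ranks, bins=10, range=(0, 1))
        assert chisquare(hist).pvalue > 0.001
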