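import numpy as np
import pandas as pd
import pytest

from reefscape.behavior import (
    ModelSpec,
    filter_records,
    fit_escape_model,
    percent_of_body_size,
    site_contrasts,
    standardize_covariates,
    structure_regression,
)
from reefscape.bayes_linear import sample_lmm
from reefscape.simulate import example_effect_spec, make_behavior_table

FAST = dict(chains=4, iterations=1500, warmup=500)


@pytest.fixture(scope="module")
def damsel_table():
    spec = example_effect_spec(
        site_effect_cm=10.0, effect_species="Stegastes adustus", seed=11,
        n_per_cell=20,
    )
    return spec, make_behavior_table(spec)


@pytest.fixture(scope="module")
def damsel_fit(damsel_table):
    _, table = damsel_table
    return fit_escape_model(
        table, ModelSpec(response="fid", taxon="damselfish", **FAST), seed=5
    )


class TestFilters:
    def test_oversized_individuals_dropped(self):
        t = pd.DataFrame(
            {
                "body_length_cm": [5, 10, 26, 24, 30],
                "escape_category": ["fled_open"] * 5,
                "fid_cm": [10.0] * 5,
            }
        )
        out = filter_records(t)
        assert len(out) == 3
        assert (out["body_length_cm"] < 25).all()

    def test_response_specific_rows_kept(self):
        t = pd.DataFrame(
            {
                "body_length_cm": [5.0] * 4,
                "escape_category": ["fled_open", "fled_refuge", "evade", "none"],
                "fid_cm": [10.0] * 4,
                "distance_open_cm": [30.0, np.nan, np.nan, np.nan],
                "distance_refuge_cm": [np.nan, 12.0, np.nan, np.nan],
            }
        )
        assert len(filter_records(t, "fid")) == 4
        assert len(filter_records(t, "distance_open")) == 1
        assert len(filter_records(t, "distance_refuge")) == 1

    def test_filter_idempotent(self, damsel_table):
        _, table = damsel_table
        once = filter_records(table, "fid")
        twice = filter_records(once, "fid")
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_raises(self):
        t = pd.DataFrame(
            {
                "body_length_cm": [5.0, 6.0],
                "escape_category": ["evade", "none"],
                "fid_cm": [1.0, 2.0],
                "distance_open_cm": [np.nan, np.nan],
            }
        )
        with pytest.raises(ValueError, match="no records"):
            filter_records(t, "distance_open")


class TestStandardize:
    def test_z_columns_have_unit_moments(self, damsel_table):
        _, table = damsel_table
        out, scaling = standardize_covariates(table)
        for col in ("body_length_cm", "group_size"):
            z = out[f"z_{col}"]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_back_transform_roundtrip(self, damsel_table):
        _, table = damsel_table
        out, scaling = standardize_covariates(table)
        mu, sd = scaling["body_length_cm"]
        back = out["z_body_length_cm"] * sd + mu
        assert np.allclose(back, table["body_length_cm"])

    def test_zero_spread_rejected(self):
        t = pd.DataFrame({"body_length_cm": [5.0, 5.0], "group_size": [1, 2]})
        with pytest.raises(ValueError, match="zero spread"):
            standardize_covariates(t)


class TestEscapeModel:
    def test_convergence_gate_passes(self, damsel_fit):
        assert damsel_fit.converged
        assert (damsel_fit.summary["rhat"] <= 1.01).all()
        assert (damsel_fit.summary["ess"] > 1000).all()

    def test_deterministic_under_seed(self, damsel_table):
        _, table = damsel_table
        spec = ModelSpec(response="fid", taxon="damselfish",
                         chains=2, iterations=300, warmup=100)
        a = fit_escape_model(table, spec, seed=3)
        b = fit_escape_model(table, spec, seed=3)
        assert np.array_equal(a.draws.beta, b.draws.beta)
        assert np.array_equal(a.draws.sigma, b.draws.sigma)

    def test_recovers_generating_coefficients(self, damsel_table, damsel_fit):
        spec, _ = damsel_table
        s = damsel_fit.summary.set_index("parameter")
        truth = {f"b_cell[{sp}:{site}]": m for (sp, site), m in spec.cell_means.items()}
        truth["b_z_body_length_cm"] = spec.body_length_slope
        truth["b_z_start_distance_cm"] = spec.start_distance_slope
        for par, tv in truth.items():
            row = s.loc[par]
            assert abs(row["mean"] - tv) < 2.5 * row["sd"], par

    def test_site_contrast_recovers_built_in_offset(self, damsel_fit):
        cons = site_contrasts(damsel_fit, "Stegastes adustus")
        con = next(
            c for c in cons
            if c.site_pair == ("Coral View", "Sturch Bank")
        )
        # generating offset: Sturch Bank +10 cm for this species
        assert con.hpdi_89[0] <= -10.0 <= con.hpdi_89[1]
        assert con.significant

    def test_contrast_antisymmetry_on_draws(self, damsel_fit):
        beta = damsel_fit.draws.flat_beta()
        ia = damsel_fit.cells.index(("Stegastes adustus", "Coral View"))
        ib = damsel_fit.cells.index(("Stegastes adustus", "Sturch Bank"))
        assert np.array_equal(beta[:, ia] - beta[:, ib], -(beta[:, ib] - beta[:, ia]))

    def test_contrasts_refused_without_convergence(self, damsel_fit):
        import dataclasses

        bad = dataclasses.replace(damsel_fit, converged=False)
        with pytest.raises(RuntimeError, match="convergence"):
            site_contrasts(bad, "Stegastes adustus")

    def test_unknown_species_rejected(self, damsel_fit):
        with pytest.raises(ValueError, match="absent"):
            site_contrasts(damsel_fit, "Scarus iseri")

    def test_binned_start_distance_variant_runs(self, damsel_table):
        _, table = damsel_table
        spec = ModelSpec(response="fid", taxon="damselfish",
                         start_distance="binned", **FAST)
        fit = fit_escape_model(table, spec, seed=7)
        assert "start_bin" in fit.draws.group_sds
        assert fit.summary["rhat"].max() <= 1.02


class TestOlsAgreement:
    def test_posterior_matches_ols_with_wide_priors(self):
        # no grouping terms, wide priors: posterior mean -> OLS estimate
        rng = np.random.default_rng(21)
        n = 120
        x = rng.uniform(-2, 2, n)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.7, n)
        X = np.column_stack([np.ones(n), x])
        draws = sample_lmm(y, X, None, coef_sd=100.0, chains=4,
                           iterations=1500, warmup=500, seed=0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        post = draws.flat_beta().mean(axis=0)
        mc_err = draws.flat_beta().std(axis=0) / 10
        assert np.all(np.abs(post - ols) < 5 * mc_err + 0.02)


class TestPercentOfBodySize:
    def test_simple_ratio(self, damsel_fit):
        con = site_contrasts(damsel_fit, "Stegastes adustus")[0]
        pct = percent_of_body_size(con, 10.0)
        assert pct == pytest.approx(100.0 * con.estimate_cm / 10.0)

    def test_nonpositive_length_rejected(self, damsel_fit):
        con = site_contrasts(damsel_fit, "Stegastes adustus")[0]
        with pytest.raises(ValueError):
            percent_of_body_size(con, 0.0)


class TestStructureRegression:
    def test_recovers_negative_slope(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0.4, 0.7, 36)
        y = 0.9 - 0.5 * x + rng.normal(0, 0.05, 36)
        s = structure_regression(x, y, seed=2,
                                 spec=ModelSpec(**FAST)).set_index("parameter")
        lo, hi = s.loc["b_slope", "cri_89_lo"], s.loc["b_slope", "cri_89_hi"]
        assert lo <= -0.5 <= hi

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            structure_regression(np.ones(10), np.arange(10.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            structure_regression(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
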