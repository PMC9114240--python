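import numpy as np
import pytest
from scipy import stats
from scipy.optimize import check_grad

from tdsmc import (
    AttributeScheme,
    EmptyGroupError,
    ModelSpec,
    TDSSequence,
    aic,
    extract_durations,
    fit,
    mean_link,
    nb_pmf,
    param_count,
    preprocess_covariates,
    ranking_config,
    recovery_config,
    select_covariates,
    simulate_panel,
)
from tdsmc.models import _nll_grad
from tdsmc.simulate import CovariateSpec, SimulationConfig, chocolate_scheme
from conftest import random_sequences


class TestNBPmf:
    def test_point_values(self):
        assert nb_pmf(0, 2.0, 2.0) == pytest.approx(0.25)
        assert nb_pmf(2, 1.0, 1.0) == pytest.approx(0.125)  # geometric 0.5**3

    def test_poisson_limit_point(self):
        assert nb_pmf(3, 2.0, 1e6) == pytest.approx(stats.poisson.pmf(3, 2.0), abs=1e-6)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 5.0, 20.0])
    @pytest.mark.parametrize("kappa", [0.5, 1.0, 5.0, 20.0])
    def test_normalizes_to_one(self, mu, kappa):
        y = np.arange(0, 3000)
        assert nb_pmf(y, mu, kappa).sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 5.0])
    def test_kappa_one_is_geometric(self, mu):
        y = np.arange(0, 51)
        p = 1.0 / (1.0 + mu)
        np.testing.assert_allclose(
            nb_pmf(y, mu, 1.0), stats.geom.pmf(y + 1, p), atol=1e-12
        )

    @pytest.mark.parametrize("mu", [0.5, 5.0, 20.0])
    def test_large_kappa_converges_to_poisson(self, mu):
        y = np.arange(0, 51)
        np.testing.assert_allclose(
            nb_pmf(y, mu, 1e6), stats.poisson.pmf(y, mu), atol=1e-6
        )

    def test_invalid_arguments_rejected(self):
        for y, mu, k in [(-1, 1, 1), (0.5, 1, 1), (0, -1, 1), (0, 1, 0)]:
            with pytest.raises(ValueError):
                nb_pmf(y, mu, k)


class TestMeanLink:
    def test_zero_coefficients_give_unit_mean(self):
        assert mean_link([1.3, -2.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert mean_link([2.0], [0.7, 0.3]) == pytest.approx(np.exp(1.3))

    def test_intercept_multiplies_mean(self):
        base = mean_link([1.0, 2.0], [0.5, 0.1, 0.2])
        assert mean_link([1.0, 2.0], [1.0, 0.1, 0.2]) == pytest.approx(
            base * np.exp(0.5)
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_link([1.0, 2.0], [0.5, 0.1])


class TestParamCountAndAIC:
    @pytest.mark.parametrize("M", range(12))
    @pytest.mark.parametrize("G", range(1, 10))
    def test_family_formulas(self, M, G):
        assert param_count("G", M, G) == 1
        assert param_count("N", M, G) == 2
        assert param_count("Ng", M, G) == 2 * G
        assert param_count("R", M, G) == M + 2
        assert param_count("Rg", M, G) == (M + 2) * G

    def test_aic_arithmetic(self):
        assert aic(-100.0, 3) == 206.0
        assert aic(0.0, 1) == 2.0

    def test_aic_back_solves_published_value(self):
        # a two-parameter fit with AIC 2436.36 must have loglik -1216.18
        assert aic(-1216.18, 2) == pytest.approx(2436.36)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            param_count("X", 0, 1)
        with pytest.raises(ValueError):
            aic(0.0, 0)


class TestLikelihoodInternals:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5, 40).astype(float)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        for params in ([1.0, 0.2, -0.3, 0.5], [0.5, -0.1, 0.1, -1.0]):
            err = check_grad(
                lambda p: _nll_grad(p, y, X, None)[0],
                lambda p: _nll_grad(p, y, X, None)[1],
                np.array(params),
            )
            assert err < 1e-4


class TestFitting:
    def test_model_n_mean_equals_sample_mean(self, scheme_small):
        rng = np.random.default_rng(1)
        seqs = random_sequences(rng, scheme_small, n_panelists=8)
        durations = extract_durations(seqs, scheme_small)
        result = fit(ModelSpec("N"), durations, scheme_small)
        shifted = durations.frame["duration"].to_numpy() - 1.0
        assert np.exp(result.beta[0, 0]) == pytest.approx(shifted.mean(), abs=1e-6)
        assert result.converged

    def test_model_n_beats_dense_grid_oracle(self, scheme_small):
        rng = np.random.default_rng(2)
        seqs = random_sequences(rng, scheme_small, n_panelists=5, mean_runs=2)
        durations = extract_durations(seqs, scheme_small)
        y = durations.frame["duration"].to_numpy() - 1.0
        assert len(y) <= 30
        mus = np.linspace(0.05, 15, 200)
        kappas = np.exp(np.linspace(np.log(0.05), np.log(100), 200))
        grid_ll = max(
            stats.nbinom.logpmf(y, k, k / (k + m)).sum() for m in mus for k in kappas
        )
        result = fit(ModelSpec("N"), durations, scheme_small)
        assert result.loglik >= grid_ll - 1e-6

    def test_degenerate_geometric_all_ones(self, scheme_small):
        seqs = [TDSSequence.from_runs(f"p{i}", [(0, 1), (1, 1)]) for i in range(6)]
        durations = extract_durations(seqs, scheme_small)
        result = fit(ModelSpec("G"), durations, scheme_small)
        assert result.loglik == pytest.approx(0.0, abs=1e-6)

    def test_aic_identity_and_param_counts(self, choc_durations, scheme9, choc_panel):
        _, covariates, _, _ = choc_panel
        pre, _ = preprocess_covariates(covariates, variables=["V01", "V04", "V05"])
        specs = [
            ModelSpec("G"),
            ModelSpec("N"),
            ModelSpec("Ng"),
            ModelSpec("R", covariates=("V01", "V04", "V05")),
            ModelSpec("Rg", covariates=("V01", "V04", "V05")),
        ]
        expected = [1, 2, 8, 5, 20]
        for spec, k in zip(specs, expected):
            result = fit(spec, choc_durations, scheme9, pre)
            assert result.n_params == k
            assert result.aic == -2.0 * result.loglik + 2.0 * result.n_params

    def test_nesting_of_maximized_logliks(self, choc_durations, scheme9, choc_panel):
        _, covariates, _, _ = choc_panel
        names = ("V01", "V04", "V05")
        pre, _ = preprocess_covariates(covariates, variables=list(names))
        ll = {
            fam: fit(
                ModelSpec(fam, covariates=names if fam in ("R", "Rg") else ()),
                choc_durations,
                scheme9,
                pre if fam in ("R", "Rg") else None,
            ).loglik
            for fam in ("G", "N", "Ng", "R", "Rg")
        }
        assert ll["Rg"] >= ll["R"] - 1e-8
        assert ll["R"] >= ll["N"] - 1e-8
        assert ll["Ng"] >= ll["N"] - 1e-8
        assert ll["N"] >= ll["G"] - 1e-8

    def test_statsmodels_agrees_on_model_r(self):
        sm = pytest.importorskip("statsmodels.api")
        config = recovery_config(seed=5, n_panelists=100)
        covariates, seqs, _ = simulate_panel(config)
        durations = extract_durations(seqs, config.scheme)
        pre, _ = preprocess_covariates(covariates)
        result = fit(
            ModelSpec("R", covariates=pre.variables), durations, config.scheme, pre
        )
        y = durations.frame["duration"].to_numpy() - 1.0
        X = np.column_stack(
            [
                np.ones(len(y)),
                pre.frame.loc[durations.frame["panelist"]].to_numpy(),
            ]
        )
        ref = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0)
        assert result.loglik == pytest.approx(ref.llf, abs=1e-4)
        np.testing.assert_allclose(result.beta[0], ref.params[:-1], atol=1e-3)
        assert result.kappa[0] == pytest.approx(1.0 / ref.params[-1], rel=1e-3)

    def test_empty_group_rejected_for_grouped_families(self, scheme_small):
        seqs = [TDSSequence.from_runs("p1", [(0, 2), (1, 3)])]  # group Y unobserved
        durations = extract_durations(seqs, scheme_small)
        with pytest.raises(EmptyGroupError, match="Y"):
            fit(ModelSpec("Ng"), durations, scheme_small)

    def test_underdispersed_data_flags_poisson_boundary(self, scheme_small):
        seqs = [TDSSequence.from_runs(f"p{i}", [(0, 3), (1, 3)]) for i in range(10)]
        durations = extract_durations(seqs, scheme_small)
        result = fit(ModelSpec("N"), durations, scheme_small)
        assert result.boundary[0]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("N", covariates=("V01",))
        with pytest.raises(ValueError):
            ModelSpec("Q")


def _null_effect_config(seed, n_panelists=120):
    scheme = chocolate_scheme()
    J = scheme.n_attributes
    trans = np.full((J, J + 1), 0.87 / (J - 1))
    np.fill_diagonal(trans[:, :J], 0.0)
    trans[:, J] = 0.13
    covs = tuple(CovariateSpec(f"Z{m}", "continuous") for m in range(1, 4))
    beta = np.zeros((4, 4))
    beta[:, 0] = 2.1  # intercept only; no covariate affects durations
    return SimulationConfig(
        scheme=scheme,
        n_panelists=n_panelists,
        initial=np.full(J, 1 / J),
        trans=trans,
        beta=beta,
        kappa=np.array([2.0, 2.0, 2.0, 2.0]),
        covariate_specs=covs,
        seed=seed,
    )


class TestSelection:
    def test_strong_effect_is_selected(self):
        config = ranking_config(seed=3, n_panelists=100)
        covariates, seqs, _ = simulate_panel(config)
        durations = extract_durations(seqs, config.scheme)
        pre, _ = preprocess_covariates(covariates)
        result = select_covariates(
            "R", pre.variables, durations, config.scheme, pre, strategy="exhaustive"
        )
        assert "Z1" in result.best.spec.covariates
        assert len(result.ranking) == 8  # all subsets of 3 candidates

    def test_zero_candidates_intercept_only(self, choc_durations, scheme9, choc_panel):
        _, covariates, _, _ = choc_panel
        pre, _ = preprocess_covariates(covariates)
        result = select_covariates("R", [], choc_durations, scheme9, pre)
        assert result.best.spec.covariates == ()
        assert result.best.n_params == 2

    def test_null_effects_mostly_select_empty_subset(self):
        wins = 0
        for seed in range(1, 8):
            config = _null_effect_config(seed)
            covariates, seqs, _ = simulate_panel(config)
            durations = extract_durations(seqs, config.scheme)
            pre, _ = preprocess_covariates(covariates)
            result = select_covariates(
                "R", pre.variables, durations, config.scheme, pre
            )
            wins += result.best.spec.covariates == ()
        assert wins >= 4

    def test_forward_matches_exhaustive_here(self):
        config = ranking_config(seed=9, n_panelists=80)
        covariates, seqs, _ = simulate_panel(config)
        durations = extract_durations(seqs, config.scheme)
        pre, _ = preprocess_covariates(covariates)
        ex = select_covariates("R", pre.variables, durations, config.scheme, pre)
        fw = select_covariates(
            "R", pre.variables, durations, config.scheme, pre, strategy="forward"
        )
        assert fw.best.spec.covariates == ex.best.spec.covariates

    def test_too_many_candidates_for_exhaustive(self, choc_durations, scheme9, choc_panel):
        _, covariates, _, _ = choc_panel
        pre, _ = preprocess_covariates(covariates)
        with pytest.raises(ValueError, match="forward"):
            select_covariates(
                "R",
                [f"V{i:02d}" for i in range(1, 12)],
                choc_durations,
                scheme9,
                pre,
                max_exhaustive=5,
            )
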