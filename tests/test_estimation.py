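import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from teicopk import reference
from teicopk.data import PKDataset
from teicopk.estimation import (
    CovariateEffect,
    FoceEngine,
    ModelSpec,
    backward_keep,
    base_model,
    eps_shrinkage,
    eta_shrinkage,
    evaluate,
    final_model,
    fit,
    forward_accept,
    information_criteria,
    ofv_foce,
)
from teicopk.pk_core import DoseEvent, IndividualParams, simulate_profile
from teicopk.synthetic_data import CohortSpec, StudyDesign, generate_cohort, generate_dataset


def toy_dataset(y, times, dose=(0.0, 100.0, 1.0)):
    """One-subject dataset with a single infusion."""
    cov = pd.DataFrame(
        [{"ID": 0, "AGE": 1.25, "SEX": "M", "WT": 10.0, "HT": 80.0, "SCR": 25.9, "EGFR": 118.99}]
    )
    doses = pd.DataFrame({"ISUB": [0], "TIME": [dose[0]], "AMT": [dose[1]], "DUR": [dose[2]]})
    obs = pd.DataFrame({"ISUB": 0, "TIME": times, "DV": y})
    return PKDataset(covariates=cov, doses=doses, obs=obs)


def agq_ofv_cl_eta(y, times, theta4, omega_cl, sigma, power=0.5, dose=(0.0, 100.0, 1.0), n_nodes=41):
    """Oracle: -2 log marginal likelihood by adaptive Gauss-Hermite
    quadrature for a one-subject model with a single eta on CL."""
    y = np.asarray(y, float)
    times = np.asarray(times, float)
    v1, v2, cl, q = theta4

    def loglik(eta):
        p = IndividualParams(V1=v1, V2=v2, Q=q, CL=cl * np.exp(eta))
        f = simulate_profile(p, [DoseEvent(*dose)], times)
        g = np.maximum(sigma * f**power, 1e-6)
        return float(
            -0.5 * np.sum((y - f) ** 2 / g**2 + np.log(2.0 * np.pi * g**2))
        )

    def neg_log_post(eta):
        return -loglik(eta) + 0.5 * eta**2 / omega_cl**2 + 0.5 * np.log(2 * np.pi * omega_cl**2)

    mode = minimize_scalar(neg_log_post, bounds=(-6.0, 6.0), method="bounded", options={"xatol": 1e-10}).x
    h = 1e-4
    hess = (neg_log_post(mode + h) - 2 * neg_log_post(mode) + neg_log_post(mode - h)) / h**2
    scale = 1.0 / np.sqrt(max(hess, 1e-8))
    nodes, weights = hermgauss(n_nodes)
    etas = mode + np.sqrt(2.0) * scale * nodes
    logvals = np.array([-neg_log_post(e) for e in etas])
    log_integral = logsumexp(np.log(weights) + nodes**2 + logvals) + 0.5 * np.log(2.0) + np.log(scale)
    return -2.0 * log_integral


CL_ETA_MODEL = ModelSpec(effects=(), eta_on=("CL",))


class TestOfvFoce:
    def test_degenerate_omega_limit_closed_form(self):
        times = np.array([2.0, 6.0, 24.0])
        p = IndividualParams(V1=2.31, V2=16.19, Q=0.23, CL=0.13)
        f = simulate_profile(p, [DoseEvent(0.0, 100.0, 1.0)], times)
        y = f * np.array([1.1, 0.9, 1.05])
        ds = toy_dataset(y, times)
        model_no_eta = ModelSpec(effects=(), eta_on=())
        sigma = 0.46
        value = ofv_foce(ds, model_no_eta, [2.31, 16.19, 0.13, 0.23], [], sigma)
        g = sigma * np.sqrt(f)
        expected = float(np.sum((y - f) ** 2 / g**2 + np.log(2 * np.pi * g**2)))
        assert value == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("omega_cl,sigma,bump", [
        (0.2, 0.3, 1.15),
        (0.4467, 0.46, 0.8),
        (0.8, 0.2, 1.3),
        (0.1, 0.6, 1.0),
    ])
    def test_matches_quadrature_oracle(self, omega_cl, sigma, bump):
        times = np.array([1.5, 4.0, 12.0, 24.0])
        theta4 = (2.31, 16.19, 0.13, 0.23)
        p = IndividualParams(V1=2.31, V2=16.19, Q=0.23, CL=0.13)
        f = simulate_profile(p, [DoseEvent(0.0, 100.0, 1.0)], times)
        y = f * bump
        ds = toy_dataset(y, times)
        foce = ofv_foce(ds, CL_ETA_MODEL, theta4, [omega_cl], sigma)
        oracle = agq_ofv_cl_eta(y, times, theta4, omega_cl, sigma)
        assert foce == pytest.approx(oracle, abs=0.5)

    def test_uninformative_covariate_leaves_ofv_unchanged(self, sparse_dataset):
        theta4 = [2.31, 16.19, 0.13, 0.23]
        base_value = ofv_foce(sparse_dataset, base_model(), theta4, reference.REFERENCE_OMEGA_SD, 0.46)
        padded = ModelSpec(effects=(CovariateEffect("CL", "WT", form=13, reference=10.0),))
        padded_value = ofv_foce(
            sparse_dataset, padded, theta4 + [0.0], reference.REFERENCE_OMEGA_SD, 0.46
        )
        assert padded_value == pytest.approx(base_value, abs=1e-6)

    def test_subject_order_invariance(self, sparse_dataset):
        value = ofv_foce(
            sparse_dataset, final_model(), reference.REFERENCE_THETA,
            reference.REFERENCE_OMEGA_SD, reference.REFERENCE_SIGMA,
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(sparse_dataset.n_subjects)
        shuffled = sparse_dataset.subset(perm)
        value_perm = ofv_foce(
            shuffled, final_model(), reference.REFERENCE_THETA,
            reference.REFERENCE_OMEGA_SD, reference.REFERENCE_SIGMA,
        )
        assert value_perm == pytest.approx(value, abs=1e-5)


class TestInformationCriteria:
    def test_direct_formula(self):
        aic, bic = information_criteria(100.0, 5, 155)
        assert aic == pytest.approx(110.0)
        assert bic == pytest.approx(100.0 + 5 * np.log(155), abs=1e-9)
        assert bic == pytest.approx(125.2, abs=0.05)

    def test_reported_bic_consistency(self):
        # published candidate-model table: BIC - OFV = 1109.78 - 1044.19 = 65.59
        # matches k = 13 parameters at n = 155 observations
        assert 13 * np.log(155) == pytest.approx(65.59, abs=0.05)

    def test_zero_params(self):
        aic, bic = information_criteria(42.0, 0, 10)
        assert aic == bic == 42.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            information_criteria(1.0, 1, 0)


class TestShrinkage:
    def test_all_zero_ebes(self):
        shr = eta_shrinkage(np.zeros((50, 2)), np.array([0.3, 0.5]))
        np.testing.assert_allclose(shr, [100.0, 100.0])

    def test_sd_equal_omega(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(5000)
        draws = (draws - draws.mean()) / draws.std(ddof=1) * 0.3
        shr = eta_shrinkage(draws[:, None], np.array([0.3]))
        assert shr[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_omega_undefined(self):
        shr = eta_shrinkage(np.zeros((10, 1)), np.array([0.0]))
        assert np.isnan(shr[0])

    def test_eps_shrinkage(self):
        rng = np.random.default_rng(2)
        iwres = rng.standard_normal(2000)
        iwres = (iwres - iwres.mean()) / iwres.std(ddof=1)
        assert eps_shrinkage(iwres) == pytest.approx(0.0, abs=1e-9)
        assert eps_shrinkage(0.5 * iwres) == pytest.approx(50.0, abs=1e-9)


class TestFit:
    def test_near_noiseless_recovery(self):
        # rich design, no IIV, tiny noise: thetas recovered to < 1%
        cohort = generate_cohort(CohortSpec(n_subjects=24), seed=21)
        times = [np.array([0.5 + 48.1, 50.0, 52.0, 56.0, 64.0, 71.9, 120.0, 160.0]) for _ in range(24)]
        from teicopk.popmodel import ResidualSpec

        ds = generate_dataset(
            cohort,
            StudyDesign(),
            omega_sd=np.zeros(4),
            residual=ResidualSpec(form="power", sigma=0.01),
            seed=31,
            sample_times=times,
        )
        model_no_eta = ModelSpec(effects=final_model().effects, eta_on=())
        res = fit(ds, model_no_eta)
        assert res.converged
        for est, true in zip(res.theta[:4], reference.REFERENCE_THETA[:4]):
            assert est == pytest.approx(true, rel=0.01)

    def test_adding_free_parameter_never_raises_ofv(self):
        cohort = generate_cohort(CohortSpec(n_subjects=40), seed=22)
        ds = generate_dataset(cohort, StudyDesign(), seed=32)
        small = ModelSpec(effects=(), eta_on=("CL",))
        bigger = ModelSpec(
            effects=(CovariateEffect("CL", "WT", form=13, reference=10.0),), eta_on=("CL",)
        )
        fit_small = fit(ds, small)
        fit_big = fit(
            ds,
            bigger,
            init={"theta": np.append(fit_small.theta, 0.0), "omega_sd": fit_small.omega_sd, "sigma": fit_small.sigma},
            eta_start=fit_small.eta,
        )
        assert fit_big.ofv <= fit_small.ofv + 0.1

    def test_evaluate_matches_ofv(self, sparse_dataset, model):
        res = evaluate(
            sparse_dataset, model, reference.REFERENCE_THETA,
            reference.REFERENCE_OMEGA_SD, reference.REFERENCE_SIGMA,
        )
        direct = ofv_foce(
            sparse_dataset, model, reference.REFERENCE_THETA,
            reference.REFERENCE_OMEGA_SD, reference.REFERENCE_SIGMA,
        )
        assert res.ofv == pytest.approx(direct, abs=1e-8)
        assert res.eta.shape == (sparse_dataset.n_subjects, 4)
        assert np.all(res.eta_shrinkage_pct <= 100.0)

    def test_se_estimation_smoke(self):
        cohort = generate_cohort(CohortSpec(n_subjects=30), seed=23)
        ds = generate_dataset(cohort, StudyDesign(), seed=33)
        small = ModelSpec(effects=(), eta_on=("CL",))
        res = fit(ds, small, estimate_se=True)
        assert res.theta_se_pct is not None
        assert np.all(np.isfinite(res.theta_se_pct))
        assert res.omega_se_pct is not None and res.sigma_se_pct is not None


class TestSelectionDecisions:
    def test_forward_boundary_strict(self):
        assert not forward_accept(-3.84)  # exactly at the threshold: rejected
        assert forward_accept(-3.8401)
        assert not forward_accept(-1.0)

    def test_backward_boundary(self):
        assert backward_keep(6.64)  # removal raising OFV by the threshold: kept
        assert not backward_keep(6.6399)
        assert backward_keep(50.0)
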