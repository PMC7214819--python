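import numpy as np
import pandas as pd
import pytest

from teicopk import reference
from teicopk.data import PKDataset
from teicopk.diagnostics import (
    bootstrap,
    npde,
    plot_gof,
    plot_npde,
    plot_vpc,
    residual_table,
    simulate_dv,
    vpc,
)
from teicopk.estimation import ModelSpec, evaluate, final_model, fit
from teicopk.popmodel import ResidualSpec
from teicopk.synthetic_data import CohortSpec, StudyDesign, generate_cohort, generate_dataset

REF = dict(
    theta=reference.REFERENCE_THETA,
    omega_sd=reference.REFERENCE_OMEGA_SD,
    sigma=reference.REFERENCE_SIGMA,
)


def calibration_dataset(n_subjects=200, seed=51):
    """Dataset simulated from the reference model with 3 fixed samples per
    subject (>= 500 observations for residual calibration checks)."""
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects), seed=seed)
    times = [np.array([49.5, 60.0, 80.0]) for _ in range(n_subjects)]
    return generate_dataset(cohort, StudyDesign(), seed=seed + 1, sample_times=times)


class TestResidualTable:
    def test_cwres_calibration_on_self_simulated_data(self, model):
        # moderate IIV keeps the FOCE linearization accurate: sharp calibration
        omega = 0.6 * reference.REFERENCE_OMEGA_SD
        cohort = generate_cohort(CohortSpec(n_subjects=200), seed=51)
        times = [np.array([49.5, 60.0, 80.0]) for _ in range(200)]
        ds = generate_dataset(cohort, StudyDesign(), omega_sd=omega, seed=52, sample_times=times)
        fit_result = evaluate(ds, model, REF["theta"], omega, REF["sigma"])
        table = residual_table(ds, fit_result)
        assert len(table) == ds.n_obs >= 500
        assert abs(table["CWRES"].mean()) < 0.1
        assert abs(table["CWRES"].std() - 1.0) < 0.1

    def test_cwres_calibration_at_reference_omegas(self, model):
        # the 105% V1 omega skews the linearized residuals slightly negative;
        # the distribution must still be near standard normal
        ds = calibration_dataset()
        table = residual_table(ds, evaluate(ds, model, **REF))
        assert abs(table["CWRES"].mean()) < 0.2
        assert abs(table["CWRES"].std() - 1.0) < 0.1

    def test_zero_noise_limit(self, model):
        cohort = generate_cohort(CohortSpec(n_subjects=12), seed=52)
        times = [np.array([50.0, 70.0]) for _ in range(12)]
        ds = generate_dataset(
            cohort, StudyDesign(), omega_sd=np.zeros(4),
            residual=ResidualSpec(sigma=0.0), seed=53, sample_times=times,
        )
        no_eta = ModelSpec(effects=model.effects, eta_on=())
        fit_result = evaluate(ds, no_eta, REF["theta"], [], 1e-4)
        table = residual_table(ds, fit_result)
        np.testing.assert_allclose(table["CWRES"], 0.0, atol=1e-6)

    def test_single_observation_closed_form(self, model):
        cov = pd.DataFrame(
            [{"ID": 0, "AGE": 1.25, "SEX": "M", "WT": 10.0, "HT": 80.0, "SCR": 25.9, "EGFR": 118.99}]
        )
        doses = pd.DataFrame({"ISUB": [0], "TIME": [0.0], "AMT": [100.0], "DUR": [1.0]})
        obs = pd.DataFrame({"ISUB": [0], "TIME": [24.0], "DV": [4.0]})
        ds = PKDataset(covariates=cov, doses=doses, obs=obs)
        no_eta = ModelSpec(effects=model.effects, eta_on=())
        fit_result = evaluate(ds, no_eta, REF["theta"], [], REF["sigma"])
        table = residual_table(ds, fit_result)
        pred = table["PRED"].iloc[0]
        expected = (4.0 - pred) / (REF["sigma"] * np.sqrt(pred))
        assert table["CWRES"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert table["TAD"].iloc[0] == pytest.approx(24.0)

    def test_plot_smoke(self, tmp_path, model):
        ds = calibration_dataset(40, seed=54)
        table = residual_table(ds, evaluate(ds, model, **REF))
        plot_gof(table, tmp_path / "gof.png")
        assert (tmp_path / "gof.png").stat().st_size > 0


@pytest.fixture(scope="module")
def small_fit():
    cohort = generate_cohort(CohortSpec(n_subjects=40), seed=55)
    ds = generate_dataset(cohort, StudyDesign(), seed=56)
    model = ModelSpec(effects=final_model().effects, eta_on=("CL",))
    return ds, model, fit(ds, model)


class TestBootstrap:

    def test_identity_resample(self):
        # rich design and a correctly-specified simple model: the likelihood
        # is sharp, so the refit reproduces the point estimates
        cohort = generate_cohort(CohortSpec(n_subjects=30), seed=65)
        times = [np.array([361.0, 362.0, 364.0, 368.0, 372.0, 383.9]) for _ in range(30)]
        ds = generate_dataset(
            cohort, StudyDesign(), omega_sd=np.array([0.0, 0.0, 0.4467, 0.0]),
            seed=66, sample_times=times,
        )
        model = ModelSpec(effects=(), eta_on=("CL",))
        fit_result = fit(ds, model)
        result = bootstrap(
            ds, model, fit_result, n_rep=1, seed=0,
            resample_indices=lambda rng, rep: np.arange(ds.n_subjects),
        )
        assert np.all(np.abs(result.table["bias_pct"]) < 0.5)
        np.testing.assert_allclose(result.table["p2.5"], result.table["p97.5"])

    def test_seed_reproducibility(self, small_fit):
        ds, model, fit_result = small_fit
        a = bootstrap(ds, model, fit_result, n_rep=3, seed=11, maxiter=15)
        b = bootstrap(ds, model, fit_result, n_rep=3, seed=11, maxiter=15)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.n_success == b.n_success

    def test_percentiles_bracket_median(self, small_fit):
        ds, model, fit_result = small_fit
        result = bootstrap(ds, model, fit_result, n_rep=8, seed=12, maxiter=15)
        t = result.table
        assert (t["p2.5"] <= t["median"] + 1e-12).all()
        assert (t["median"] <= t["p97.5"] + 1e-12).all()


class TestNpde:
    def test_observation_at_simulated_median(self, model):
        ds = calibration_dataset(60, seed=57)
        n_sim, seed = 300, 99
        sims = simulate_dv(ds, model, REF["theta"], REF["omega_sd"], REF["sigma"],
                           n_sim, np.random.default_rng(seed))
        # plant one observation exactly at its simulated median
        ds.obs.loc[0, "DV"] = float(np.median(sims[:, 0]))
        fit_result = evaluate(ds, model, **REF)
        result = npde(ds, fit_result, n_sim=n_sim, seed=seed)
        assert abs(result.npde[0]) < 0.2

    def test_pvalues_in_unit_interval(self, model):
        ds = calibration_dataset(60, seed=58)
        result = npde(ds, evaluate(ds, model, **REF), n_sim=200, seed=1)
        for p in (result.p_ttest, result.p_fisher, result.p_shapiro, result.p_global):
            assert 0.0 <= p <= 1.0
        assert np.all(np.isfinite(result.npde))

    def test_power_against_doubled_concentrations(self, model):
        rejections = 0
        n_rep = 10
        for rep in range(n_rep):
            ds = calibration_dataset(60, seed=600 + rep)
            ds.obs["DV"] *= 2.0
            result = npde(ds, evaluate(ds, model, **REF), n_sim=300, seed=rep)
            rejections += result.p_ttest < 0.05
        assert rejections >= 0.9 * n_rep

    def test_n_sim_floor(self, model):
        ds = calibration_dataset(10, seed=59)
        with pytest.raises(ValueError):
            npde(ds, evaluate(ds, model, **REF), n_sim=50)

    def test_plot_smoke(self, tmp_path, model):
        ds = calibration_dataset(30, seed=60)
        result = npde(ds, evaluate(ds, model, **REF), n_sim=150, seed=3)
        plot_npde(result, tmp_path / "npde.png")
        assert (tmp_path / "npde.png").stat().st_size > 0


class TestVpc:
    def test_single_simulation_collapses_ci(self, model, sparse_dataset):
        result = vpc(sparse_dataset, evaluate(sparse_dataset, model, **REF), n_sim=1, seed=4)
        t = result.table
        np.testing.assert_allclose(t["sim_p50_lo"], t["sim_p50_hi"])

    def test_dose_doubling_scales_bands(self, model):
        cohort = generate_cohort(CohortSpec(n_subjects=50), seed=61)
        times = [np.array([49.5, 60.0, 80.0]) for _ in range(50)]
        ds = generate_dataset(cohort, StudyDesign(), seed=62, sample_times=times, lloq=None)
        doubled = PKDataset(
            covariates=ds.covariates.copy(),
            doses=ds.doses.assign(AMT=2.0 * ds.doses["AMT"]),
            obs=ds.obs.assign(DV=2.0 * ds.obs["DV"]),
        )
        a = vpc(ds, evaluate(ds, model, **REF), n_sim=80, seed=5)
        b = vpc(doubled, evaluate(doubled, model, **REF), n_sim=80, seed=5)
        # structural model is linear in dose: observed percentiles double
        # exactly; simulated bands only approximately (the power residual SD
        # grows with sqrt(concentration), not linearly)
        np.testing.assert_allclose(
            b.table["obs_p50"], 2.0 * a.table["obs_p50"], rtol=1e-9
        )
        np.testing.assert_allclose(
            b.table["sim_p50_lo"], 2.0 * a.table["sim_p50_lo"], rtol=0.05
        )
        np.testing.assert_allclose(
            b.table["sim_p50_hi"], 2.0 * a.table["sim_p50_hi"], rtol=0.05
        )

    def test_stratified_counts_pool(self, model, sparse_dataset):
        fit_result = evaluate(sparse_dataset, model, **REF)
        pooled = vpc(sparse_dataset, fit_result, n_sim=40, seed=6)
        strat = vpc(sparse_dataset, fit_result, n_sim=40, seed=6, stratify_by_renal=True)
        assert strat.table["n_obs"].sum() == pooled.table["n_obs"].sum() == sparse_dataset.n_obs

    def test_small_bins_merged(self, model):
        cohort = generate_cohort(CohortSpec(n_subjects=4), seed=63)
        ds = generate_dataset(cohort, StudyDesign(), seed=64)
        result = vpc(ds, evaluate(ds, model, **REF), n_sim=20, n_bins=6, seed=7)
        assert (result.table["n_obs"] >= 3).all() or len(result.table) == 1

    def test_plot_smoke(self, tmp_path, model, sparse_dataset):
        result = vpc(sparse_dataset, evaluate(sparse_dataset, model, **REF), n_sim=30, seed=8)
        plot_vpc(result, tmp_path / "vpc.png")
        assert (tmp_path / "vpc.png").stat().st_size > 0
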