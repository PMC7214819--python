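"""Model validation instruments: residual tables, nonparametric bootstrap,
normalized prediction distribution errors (NPDE) and visual predictive
checks (VPC).

All four accept an explicit seed.  CWRES uses the FOCE linearization at the
conditional eta modes (matching the estimator variant); the bootstrap
resamples subjects stratified by renal group to protect the sparse
moderate-insufficiency stratum; the NPDE global test is the Bonferroni
combination of its three component tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import RENAL_GROUPS
from .data import PKDataset
from .estimation import FitResult, FoceEngine, ModelSpec, fit as fit_model

logger = logging.getLogger("teicopk")

__all__ = [
    "residual_table",
    "simulate_dv",
    "bootstrap",
    "BootstrapResult",
    "npde",
    "NpdeResult",
    "vpc",
    "VpcResult",
    "plot_gof",
    "plot_npde",
    "plot_vpc",
]


def _time_after_last_dose(dataset: PKDataset) -> np.ndarray:
    """Hours between each observation and the subject's latest prior dose."""
    out = np.empty(dataset.n_obs)
    doses = dataset.doses
    for j, row in dataset.obs.iterrows():
        d = doses[(doses["ISUB"] == row["ISUB"]) & (doses["TIME"] < row["TIME"])]
        out[j] = row["TIME"] - d["TIME"].max() if len(d) else np.nan
    return out


def residual_table(dataset: PKDataset, fit: FitResult) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    PRED is the population prediction (eta = 0), IPRED the prediction at the
    conditional eta modes, IWRES the residual standardized by the residual
    SD at IPRED, and CWRES the FOCE-linearized standardized residual (the
    population residual whitened by the per-subject linearized covariance).
    """
    engine = FoceEngine(dataset, fit.model)
    tv = fit.model.typical(fit.theta, engine.cov)
    pred = engine.conc(tv)
    eta = fit.eta
    ipred = engine.conc(engine._with_eta(tv, eta))
    g = engine.resid_sd(ipred, fit.sigma)
    iwres = (engine.y - ipred) / g

    cwres = np.empty(engine.n_obs)
    if engine.k:
        G = engine._jac(tv, eta, ipred)
        rs = (engine.y - ipred) + np.einsum("jk,jk->j", G, eta[engine.obs_sub])
        omega2 = fit.omega_sd**2
        for i in range(engine.n_sub):
            idx = np.flatnonzero(engine.obs_sub == i)
            Gi = G[idx]
            C = Gi @ (omega2[:, None] * Gi.T) + np.diag(g[idx] ** 2)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                logger.warning("singular linearized covariance for subject %d", i)
                cwres[idx] = np.nan
                continue
            cwres[idx] = np.linalg.solve(L, rs[idx])
    else:
        cwres = (engine.y - pred) / engine.resid_sd(pred, fit.sigma)

    return pd.DataFrame(
        {
            "ISUB": engine.obs_sub,
            "TIME": engine.t_obs,
            "TAD": _time_after_last_dose(dataset),
            "DV": engine.y,
            "PRED": pred,
            "IPRED": ipred,
            "IWRES": iwres,
            "CWRES": cwres,
        }
    )


def simulate_dv(
    dataset: PKDataset,
    model: ModelSpec,
    theta,
    omega_sd,
    sigma,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n_sim`` replicates of the dataset's observations under the
    model (full IIV + residual noise, design preserved).  Negative draws are
    truncated at zero.  Returns an (n_sim, n_obs) matrix."""
    engine = FoceEngine(dataset, model)
    theta = np.asarray(theta, float)
    omega_sd = np.asarray(omega_sd, float)
    sigma = np.atleast_1d(np.asarray(sigma, float))
    tv = model.typical(theta, engine.cov)
    out = np.empty((n_sim, engine.n_obs))
    for s in range(n_sim):
        eta = rng.standard_normal((engine.n_sub, engine.k)) * omega_sd
        f = engine.conc(engine._with_eta(tv, eta))
        g = engine.resid_sd(f, sigma)
        out[s] = np.maximum(f + g * rng.standard_normal(engine.n_obs), 0.0)
    return out


# -- bootstrap ---------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Percentile summary of bootstrap re-estimates.

    ``table`` rows: parameter, point estimate, 2.5th/50th/97.5th percentiles
    and bias% = 100 * (median - estimate) / estimate."""

    table: pd.DataFrame
    n_success: int
    n_requested: int
    warning: str = ""


def _renal_bins(egfr: np.ndarray) -> np.ndarray:
    """Stratification bins for resampling (eGFR below 30 joins the lowest)."""
    edges = [g.lower for g in RENAL_GROUPS[1:]]
    return np.digitize(egfr, edges)


def bootstrap(
    dataset: PKDataset,
    model: ModelSpec,
    fit_result: FitResult,
    n_rep: int = 1000,
    seed: int = 0,
    stratified: bool = True,
    resample_indices=None,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric bootstrap: subjects resampled with replacement
    (stratified by renal group), the model refit per replicate, percentile
    CIs and bias versus the point estimates reported.

    ``resample_indices(rng, rep) -> indices`` overrides the resampler (used
    to force the identity resample in tests).  Non-converged replicates are
    dropped and counted; >20% failures sets a warning.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    egfr = dataset.covariates["EGFR"].to_numpy(float)
    bins = _renal_bins(egfr)
    groups = [np.flatnonzero(bins == b) for b in np.unique(bins)]

    names = list(model.theta_names) + [f"omega_{p}" for p in model.eta_on] + [
        "sigma" if i == 0 else f"sigma{i + 1}" for i in range(len(fit_result.sigma))
    ]
    point = np.concatenate([fit_result.theta, fit_result.omega_sd, fit_result.sigma])
    draws = []
    for rep in range(n_rep):
        if resample_indices is not None:
            idx = np.asarray(resample_indices(rng, rep), dtype=int)
        elif stratified:
            idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        else:
            idx = rng.choice(dataset.n_subjects, size=dataset.n_subjects, replace=True)
        sub = dataset.subset(idx)
        warm = {
            "theta": fit_result.theta,
            "omega_sd": fit_result.omega_sd,
            "sigma": fit_result.sigma,
        }
        try:
            res = fit_model(sub, model, init=warm, eta_start=fit_result.eta[idx], **fit_kwargs)
        except Exception:  # noqa: BLE001 -- a failed replicate is dropped, not fatal
            continue
        if np.isfinite(res.ofv):
            draws.append(np.concatenate([res.theta, res.omega_sd, res.sigma]))
    n_success = len(draws)
    if n_success == 0:
        raise RuntimeError("all bootstrap replicates failed")
    draws = np.asarray(draws)
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "parameter": names,
            "estimate": point,
            "p2.5": lo,
            "median": med,
            "p97.5": hi,
            "bias_pct": 100.0 * (med - point) / point,
        }
    )
    warning = ""
    if n_success < 0.8 * n_rep:
        warning = f"only {n_success}/{n_rep} bootstrap replicates converged"
        logger.warning(warning)
    return BootstrapResult(table=table, n_success=n_success, n_requested=n_rep, warning=warning)


# -- NPDE --------------------------------------------------------------------


@dataclass
class NpdeResult:
    """Per-observation NPDE values and the four test p-values."""

    npde: np.ndarray
    p_ttest: float
    p_fisher: float
    p_shapiro: float
    p_global: float


def npde(
    dataset: PKDataset,
    fit_result: FitResult,
    n_sim: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors.

    Per subject, observations and simulations are decorrelated with the
    empirical simulated mean and the Cholesky factor of the simulated
    covariance; the pde is the rank of the decorrelated observation among
    the decorrelated simulations (with a 1/(2 n_sim) continuity adjustment)
    and the NPDE its standard-normal quantile.  Tests: one-sample t-test on
    the mean, Fisher's variance test against 1, Shapiro-Wilk normality and
    their Bonferroni combination as the global test.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    sims = simulate_dv(
        dataset, fit_result.model, fit_result.theta, fit_result.omega_sd,
        fit_result.sigma, n_sim, rng,
    )
    obs_sub = dataset.obs["ISUB"].to_numpy(int)
    y = dataset.obs["DV"].to_numpy(float)
    values = np.empty(y.size)
    for i in range(dataset.n_subjects):
        idx = np.flatnonzero(obs_sub == i)
        S = sims[:, idx]
        mu = S.mean(axis=0)
        E = S - mu
        C = E.T @ E / (n_sim - 1)
        lam = 0.0
        diag = np.diag(np.diag(C))
        for _ in range(8):
            try:
                L = np.linalg.cholesky((1.0 - lam) * C + lam * diag)
                break
            except np.linalg.LinAlgError:
                lam = 0.1 if lam == 0.0 else min(1.0, lam * 2.0)
                logger.warning("shrinking simulated covariance toward diagonal (subject %d)", i)
        ystar = np.linalg.solve(L, y[idx] - mu)
        sstar = np.linalg.solve(L, E.T)  # (n_i, n_sim)
        count = (sstar < ystar[:, None]).sum(axis=1)
        pde = np.clip(count / n_sim, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        values[idx] = stats.norm.ppf(pde)

    p_t = float(stats.ttest_1samp(values, 0.0).pvalue)
    n = values.size
    chi2 = (n - 1) * values.var(ddof=1)
    p_f = float(2.0 * min(stats.chi2.cdf(chi2, n - 1), stats.chi2.sf(chi2, n - 1)))
    p_s = float(stats.shapiro(values).pvalue)
    p_global = float(min(1.0, 3.0 * min(p_t, p_f, p_s)))
    return NpdeResult(npde=values, p_ttest=p_t, p_fisher=p_f, p_shapiro=p_s, p_global=p_global)


# -- VPC ---------------------------------------------------------------------


@dataclass
class VpcResult:
    """Binned observed percentiles with simulated confidence bands.

    ``table`` rows per (stratum, bin): bin midpoint/edges, observed
    2.5/50/97.5 percentiles, and the simulated 95% CI of each percentile."""

    table: pd.DataFrame
    n_sim: int


_PCTS = (2.5, 50.0, 97.5)


def _bin_edges(tad: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin edges over time-after-last-dose; bins with fewer than 3
    observations are merged into their left neighbour."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(tad, qs))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    while len(edges) > 2:
        counts, _ = np.histogram(tad, bins=edges)
        small = np.flatnonzero(counts < 3)
        if small.size == 0:
            break
        j = small[0]
        drop = j if j > 0 else 1  # merge with the left neighbour (or right for the first bin)
        edges = np.delete(edges, drop)
        logger.info("merged VPC bin %d (fewer than 3 observations)", j)
    return edges


def vpc(
    dataset: PKDataset,
    fit_result: FitResult,
    n_sim: int = 1000,
    n_bins: int = 6,
    stratify_by_renal: bool = False,
    seed: int = 0,
) -> VpcResult:
    """Visual predictive check.

    Each simulation preserves every subject's design (doses, times,
    covariates).  Observed 2.5/50/97.5 percentiles per time-after-last-dose
    bin are compared with the 95% CI of the same percentiles across
    simulations, optionally stratified by the four renal groups.
    """
    if n_bins < 1:
        raise ValueError("bins must be non-empty")
    rng = np.random.default_rng(seed)
    sims = simulate_dv(
        dataset, fit_result.model, fit_result.theta, fit_result.omega_sd,
        fit_result.sigma, n_sim, rng,
    )
    tad = _time_after_last_dose(dataset)
    y = dataset.obs["DV"].to_numpy(float)
    obs_sub = dataset.obs["ISUB"].to_numpy(int)

    if stratify_by_renal:
        egfr = dataset.covariates["EGFR"].to_numpy(float)
        labels = np.array([g.label for g in RENAL_GROUPS])[_renal_bins(egfr)]
        strata = [(lab, np.flatnonzero(labels[obs_sub] == lab)) for lab in np.unique(labels)]
    else:
        strata = [("all", np.arange(y.size))]

    rows = []
    for label, idx in strata:
        if idx.size == 0:
            continue
        edges = _bin_edges(tad[idx], n_bins)
        which = np.digitize(tad[idx], edges) - 1
        for b in range(len(edges) - 1):
            sel = idx[which == b]
            if sel.size == 0:
                continue
            obs_p = np.percentile(y[sel], _PCTS)
            sim_p = np.percentile(sims[:, sel], _PCTS, axis=1)  # (3, n_sim)
            ci_lo = np.percentile(sim_p, 2.5, axis=1)
            ci_hi = np.percentile(sim_p, 97.5, axis=1)
            rows.append(
                {
                    "stratum": label,
                    "bin": b,
                    "t_lo": edges[b],
                    "t_hi": edges[b + 1],
                    "t_mid": float(np.median(tad[sel])),
                    "n_obs": int(sel.size),
                    "obs_p2.5": obs_p[0],
                    "obs_p50": obs_p[1],
                    "obs_p97.5": obs_p[2],
                    "sim_p2.5_lo": ci_lo[0],
                    "sim_p2.5_hi": ci_hi[0],
                    "sim_p50_lo": ci_lo[1],
                    "sim_p50_hi": ci_hi[1],
                    "sim_p97.5_lo": ci_lo[2],
                    "sim_p97.5_hi": ci_hi[2],
                }
            )
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim)


# -- plots -------------------------------------------------------------------


def _get_axes(n):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5))
    return fig, np.atleast_1d(axes)


def plot_gof(table: pd.DataFrame, path) -> None:
    """Observed vs predicted and CWRES panels, written to ``path``."""
    fig, axes = _get_axes(4)
    for ax, x, ylab in (
        (axes[0], "PRED", "DV"),
        (axes[1], "IPRED", "DV"),
    ):
        ax.plot(table[x], table["DV"], "o", ms=3, alpha=0.6)
        lim = max(table[x].max(), table["DV"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(x)
        ax.set_ylabel(ylab)
    for ax, x in ((axes[2], "PRED"), (axes[3], "TAD")):
        ax.plot(table[x], table["CWRES"], "o", ms=3, alpha=0.6)
        ax.axhline(0.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel(x)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_npde(result: NpdeResult, path) -> None:
    """QQ plot and histogram of the NPDE values."""
    from scipy.stats import norm

    fig, axes = _get_axes(2)
    v = np.sort(result.npde)
    q = norm.ppf((np.arange(v.size) + 0.5) / v.size)
    axes[0].plot(q, v, "o", ms=3)
    axes[0].plot(q, q, "k--", lw=0.8)
    axes[0].set_xlabel("theoretical quantile")
    axes[0].set_ylabel("NPDE")
    axes[1].hist(v, bins=20, density=True, alpha=0.7)
    grid = np.linspace(-3.5, 3.5, 200)
    axes[1].plot(grid, norm.pdf(grid), "k-")
    axes[1].set_xlabel("NPDE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_vpc(result: VpcResult, path) -> None:
    """Percentile bands per stratum."""
    strata = result.table["stratum"].unique()
    fig, axes = _get_axes(len(strata))
    for ax, label in zip(axes, strata):
        t = result.table[result.table["stratum"] == label]
        ax.fill_between(t["t_mid"], t["sim_p2.5_lo"], t["sim_p2.5_hi"], alpha=0.25)
        ax.fill_between(t["t_mid"], t["sim_p50_lo"], t["sim_p50_hi"], alpha=0.25)
        ax.fill_between(t["t_mid"], t["sim_p97.5_lo"], t["sim_p97.5_hi"], alpha=0.25)
        for col, style in (("obs_p2.5", "--"), ("obs_p50", "-"), ("obs_p97.5", "--")):
            ax.plot(t["t_mid"], t[col], "r" + style, lw=1)
        ax.set_title(label)
        ax.set_xlabel("time after last dose (h)")
        ax.set_ylabel("concentration (mg/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
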