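"""FOCE-type marginal-likelihood estimation of the population model.

The objective is -2 log marginal likelihood approximated per subject by
first-order conditional estimation with interaction: the random effects are
optimized to their conditional mode, the structural model is linearized
about that mode, and the resulting Gaussian integral is evaluated in closed
form.  The inner eta search runs vectorized across all subjects (damped
Gauss-Newton); the outer search is bounded quasi-Newton on log-transformed
scale parameters.

Covariate structure is expressed as a base four-parameter model (V1, V2, Q,
CL typical values) plus a list of :class:`CovariateEffect` terms, each
contributing one theta.  Forward/backward stepwise selection operates on
that representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .covariates import InvalidParameterError
from .data import PKDataset
from .pk_core import PARAM_ORDER, _macro

logger = logging.getLogger("teicopk")

__all__ = [
    "CovariateEffect",
    "ModelSpec",
    "FitResult",
    "SelectionStep",
    "base_model",
    "final_model",
    "ofv_foce",
    "evaluate",
    "fit",
    "information_criteria",
    "eta_shrinkage",
    "eps_shrinkage",
    "forward_accept",
    "backward_keep",
    "stepwise_select",
]

_BASE_THETA_NAMES = ("tv_V1", "tv_V2", "tv_CL", "tv_Q")
# map from base-theta position to column of the (V1, V2, Q, CL) matrix
_BASE_COLUMN = (0, 1, 3, 2)


class _InvalidProposal(Exception):
    """Parameter proposal outside the model domain; outer search rejects it."""


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate term on one structural parameter.

    ``form`` follows the generic inclusion forms: 11 additive on the
    covariate ratio, 12 additive on the centred covariate, 13 power of the
    covariate ratio, 14 categorical exponential shift.  ``log_covariate``
    applies the term to ``ln(cov)`` (used for the log-weight V1 term, whose
    reference is the literal 2.3)."""

    param: str
    covariate: str
    form: int = 13
    reference: float = 1.0
    log_covariate: bool = False
    theta_init: float = 0.1

    def __post_init__(self) -> None:
        if self.param not in PARAM_ORDER:
            raise ValueError(f"param must be one of {PARAM_ORDER}")
        if self.form not in (11, 12, 13, 14):
            raise ValueError(f"unknown covariate form {self.form}")

    @property
    def name(self) -> str:
        prefix = "ln" if self.log_covariate else ""
        return f"{self.param}-{prefix}{self.covariate}"


@dataclass(frozen=True)
class ModelSpec:
    """Population model structure: covariate effects, which parameters carry
    IIV, and the residual-error form."""

    effects: tuple[CovariateEffect, ...] = ()
    eta_on: tuple[str, ...] = ("V1", "V2", "CL", "Q")
    residual_form: str = "power"
    power: float = 0.5

    @property
    def theta_names(self) -> tuple[str, ...]:
        return _BASE_THETA_NAMES + tuple(e.name for e in self.effects)

    @property
    def n_theta(self) -> int:
        return 4 + len(self.effects)

    @property
    def n_sigma(self) -> int:
        return 2 if self.residual_form == "combined" else 1

    def typical(self, theta: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        """Typical parameter matrix (n, 4) in (V1, V2, Q, CL) order.

        Raises :class:`_InvalidProposal` if any parameter becomes
        non-positive (possible under the additive covariate forms).
        """
        theta = np.asarray(theta, dtype=float)
        n = len(cov)
        tv = np.empty((n, 4))
        for j, col in enumerate(_BASE_COLUMN):
            tv[:, col] = theta[j]
        for i, eff in enumerate(self.effects):
            th = theta[4 + i]
            col = PARAM_ORDER.index(eff.param)
            x = cov[eff.covariate].to_numpy(float)
            if eff.log_covariate:
                if np.any(x <= 1.0):
                    raise _InvalidProposal(f"ln({eff.covariate}) <= 0 in covariate data")
                x = np.log(x)
            if eff.form == 11:
                tv[:, col] = tv[:, col] + th * (x / eff.reference)
            elif eff.form == 12:
                tv[:, col] = tv[:, col] + th * (x - eff.reference)
            elif eff.form == 13:
                if np.any(x <= 0.0):
                    raise _InvalidProposal(f"{eff.covariate} must be > 0 for power form")
                tv[:, col] = tv[:, col] * (x / eff.reference) ** th
            else:  # 14
                tv[:, col] = tv[:, col] * np.exp(th * x)
        if not np.all(np.isfinite(tv)) or np.any(tv <= 0.0):
            raise _InvalidProposal("non-positive typical parameter value proposed")
        return tv


def base_model(
    eta_on: tuple[str, ...] = ("V1", "V2", "CL", "Q"),
    residual_form: str = "power",
    power: float = 0.5,
) -> ModelSpec:
    """Structural model without covariates."""
    return ModelSpec(effects=(), eta_on=eta_on, residual_form=residual_form, power=power)


def final_model() -> ModelSpec:
    """The final covariate model: lnWT on V1, WT on V2, WT and eGFR on CL."""
    return ModelSpec(
        effects=(
            CovariateEffect("V1", "WT", form=13, reference=reference.LNWT_REF, log_covariate=True),
            CovariateEffect("V2", "WT", form=13, reference=reference.WT_MEDIAN),
            CovariateEffect("CL", "WT", form=13, reference=reference.WT_MEDIAN),
            CovariateEffect("CL", "EGFR", form=13, reference=reference.EGFR_MEDIAN),
        )
    )


class FoceEngine:
    """Vectorized FOCE objective for one dataset/model pair.

    Precomputes the observation-by-dose pairing so each concentration
    evaluation is a handful of array operations over all subjects at once.
    """

    def __init__(self, dataset: PKDataset, model: ModelSpec):
        self.model = model
        self.cov = dataset.covariates.reset_index(drop=True)
        self.n_sub = len(self.cov)

        obs = dataset.obs
        self.y = obs["DV"].to_numpy(float)
        self.t_obs = obs["TIME"].to_numpy(float)
        self.obs_sub = obs["ISUB"].to_numpy(int)
        self.n_obs = len(self.y)
        counts = np.bincount(self.obs_sub, minlength=self.n_sub)
        if (counts == 0).any():
            raise ValueError("every subject needs at least one observation for estimation")

        doses = dataset.doses
        d_sub = doses["ISUB"].to_numpy(int)
        d_time = doses["TIME"].to_numpy(float)
        d_amt = doses["AMT"].to_numpy(float)
        d_dur = doses["DUR"].to_numpy(float)
        # observation x dose pairs within subject, keeping only doses started
        # before the observation (others contribute exactly zero)
        by_sub = [np.flatnonzero(d_sub == i) for i in range(self.n_sub)]
        p_obs, p_dose = [], []
        for j in range(self.n_obs):
            for di in by_sub[self.obs_sub[j]]:
                if self.t_obs[j] > d_time[di]:
                    p_obs.append(j)
                    p_dose.append(di)
        p_obs = np.asarray(p_obs, dtype=int)
        p_dose = np.asarray(p_dose, dtype=int)
        t_rel = self.t_obs[p_obs] - d_time[p_dose]
        self.p_obs = p_obs
        self.p_sub = self.obs_sub[p_obs]
        self.p_t1 = np.minimum(t_rel, d_dur[p_dose])
        self.p_t2 = t_rel - self.p_t1
        self.p_rate = d_amt[p_dose] / d_dur[p_dose]

        self.eta_idx = np.array([PARAM_ORDER.index(p) for p in model.eta_on], dtype=int)
        self.k = len(self.eta_idx)
        # tiled pair arrays for evaluating k perturbed parameter sets at once
        if self.k:
            reps = self.k
            self._m_sub = np.concatenate(
                [self.p_sub + d * self.n_sub for d in range(reps)]
            )
            self._m_obs = np.concatenate(
                [self.p_obs + d * self.n_obs for d in range(reps)]
            )
            self._m_t1 = np.tile(self.p_t1, reps)
            self._m_t2 = np.tile(self.p_t2, reps)
            self._m_rate = np.tile(self.p_rate, reps)

    # -- structural model ---------------------------------------------------

    def conc(self, params: np.ndarray) -> np.ndarray:
        """Predicted concentrations at the observation times for per-subject
        parameter rows (n_sub, 4)."""
        alpha, beta, A, B = _macro(params[:, 0], params[:, 1], params[:, 2], params[:, 3])
        s = self.p_sub
        a = alpha[s]
        b = beta[s]
        ca = (A[s] / a) * (-np.expm1(-a * self.p_t1)) * np.exp(-a * self.p_t2)
        cb = (B[s] / b) * (-np.expm1(-b * self.p_t1)) * np.exp(-b * self.p_t2)
        c = (self.p_rate / params[s, 0]) * (ca + cb)
        return np.bincount(self.p_obs, weights=c, minlength=self.n_obs)

    def _with_eta(self, tv: np.ndarray, eta: np.ndarray) -> np.ndarray:
        params = tv.copy()
        if self.k:
            params[:, self.eta_idx] *= np.exp(eta)
        return params

    def resid_sd(self, f: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        form = self.model.residual_form
        if form == "additive":
            g = np.full_like(f, sigma[0])
        elif form == "proportional":
            g = sigma[0] * f
        elif form == "combined":
            g = np.sqrt(sigma[0] ** 2 * f**2 + sigma[1] ** 2)
        else:  # power
            g = sigma[0] * np.maximum(f, 0.0) ** self.model.power
        return np.maximum(g, 1e-6)

    def _dg_df(self, f: np.ndarray, g: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """d residual-SD / d prediction, for the interaction term of the
        inner gradient."""
        form = self.model.residual_form
        if form == "additive":
            out = np.zeros_like(f)
        elif form == "proportional":
            out = np.full_like(f, sigma[0])
        elif form == "combined":
            out = sigma[0] ** 2 * f / g
        else:  # power
            out = self.model.power * g / np.maximum(f, 1e-12)
        # where the SD floor is active g is constant, so its derivative is 0
        return np.where(g <= 1e-6, 0.0, out)

    # -- segment reductions -------------------------------------------------

    def _segs(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.obs_sub, weights=values, minlength=self.n_sub)

    def _segv(self, mat: np.ndarray) -> np.ndarray:
        out = np.empty((self.n_sub, self.k))
        for d in range(self.k):
            out[:, d] = self._segs(mat[:, d])
        return out

    def _segm(self, G: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Per-subject G' W G, shape (n_sub, k, k)."""
        out = np.empty((self.n_sub, self.k, self.k))
        for a in range(self.k):
            for b in range(a, self.k):
                s = self._segs(w * G[:, a] * G[:, b])
                out[:, a, b] = s
                out[:, b, a] = s
        return out

    # -- inner eta optimization --------------------------------------------

    def _h(self, tv, eta, sigma, om2inv) -> np.ndarray:
        """Per-subject conditional objective (extended least squares + prior)."""
        f = self.conc(self._with_eta(tv, eta))
        g = self.resid_sd(f, sigma)
        ll = (self.y - f) ** 2 / g**2 + np.log(2.0 * np.pi * g * g)
        return self._segs(ll) + np.sum(eta * eta * om2inv, axis=1)

    def _jac(self, tv, eta, f0) -> np.ndarray:
        """Forward-difference d f / d eta, shape (n_obs, k).

        All k perturbed parameter sets are evaluated in a single stacked
        concentration call.
        """
        h = 1e-4
        stacked = np.empty((self.k * self.n_sub, 4))
        for d in range(self.k):
            ep = eta.copy()
            ep[:, d] += h
            stacked[d * self.n_sub : (d + 1) * self.n_sub] = self._with_eta(tv, ep)
        alpha, beta, A, B = _macro(stacked[:, 0], stacked[:, 1], stacked[:, 2], stacked[:, 3])
        s = self._m_sub
        a = alpha[s]
        b = beta[s]
        ca = (A[s] / a) * (-np.expm1(-a * self._m_t1)) * np.exp(-a * self._m_t2)
        cb = (B[s] / b) * (-np.expm1(-b * self._m_t1)) * np.exp(-b * self._m_t2)
        c = (self._m_rate / stacked[s, 0]) * (ca + cb)
        f = np.bincount(self._m_obs, weights=c, minlength=self.k * self.n_obs)
        return (f.reshape(self.k, self.n_obs).T - f0[:, None]) / h

    def _sub_view(self, sub_ids: np.ndarray) -> dict:
        """Pair/observation arrays restricted to a subject subset, with
        subjects and observations renumbered contiguously."""
        mask = np.zeros(self.n_sub, dtype=bool)
        mask[sub_ids] = True
        psel = mask[self.p_sub]
        osel = mask[self.obs_sub]
        obs_ids = np.flatnonzero(osel)
        sub_map = np.full(self.n_sub, -1)
        sub_map[sub_ids] = np.arange(sub_ids.size)
        obs_map = np.full(self.n_obs, -1)
        obs_map[obs_ids] = np.arange(obs_ids.size)
        return {
            "m": sub_ids.size,
            "n_obs": obs_ids.size,
            "sub_ids": sub_ids,
            "y": self.y[obs_ids],
            "os": sub_map[self.obs_sub[osel]],
            "ps": sub_map[self.p_sub[psel]],
            "po": obs_map[self.p_obs[psel]],
            "t1": self.p_t1[psel],
            "t2": self.p_t2[psel],
            "rate": self.p_rate[psel],
        }

    @staticmethod
    def _nest_view(view: dict, keep: np.ndarray) -> dict:
        """Restrict an existing view to a relative subject mask."""
        sub_rel = np.flatnonzero(keep)
        psel = keep[view["ps"]]
        osel = keep[view["os"]]
        obs_rel = np.flatnonzero(osel)
        sub_map = np.full(view["m"], -1)
        sub_map[sub_rel] = np.arange(sub_rel.size)
        obs_map = np.full(view["n_obs"], -1)
        obs_map[obs_rel] = np.arange(obs_rel.size)
        return {
            "m": sub_rel.size,
            "n_obs": obs_rel.size,
            "sub_ids": view["sub_ids"][sub_rel],
            "y": view["y"][obs_rel],
            "os": sub_map[view["os"][osel]],
            "ps": sub_map[view["ps"][psel]],
            "po": obs_map[view["po"][psel]],
            "t1": view["t1"][psel],
            "t2": view["t2"][psel],
            "rate": view["rate"][psel],
        }

    @staticmethod
    def _conc_view(view: dict, params: np.ndarray) -> np.ndarray:
        alpha, beta, A, B = _macro(params[:, 0], params[:, 1], params[:, 2], params[:, 3])
        s = view["ps"]
        a = alpha[s]
        b = beta[s]
        ca = (A[s] / a) * (-np.expm1(-a * view["t1"])) * np.exp(-a * view["t2"])
        cb = (B[s] / b) * (-np.expm1(-b * view["t1"])) * np.exp(-b * view["t2"])
        c = (view["rate"] / params[s, 0]) * (ca + cb)
        return np.bincount(view["po"], weights=c, minlength=view["n_obs"])

    def _h_view(self, view, tv_m, eta_m, sigma, om2inv) -> np.ndarray:
        f = self._conc_view(view, self._apply_eta(tv_m, eta_m))
        g = self.resid_sd(f, sigma)
        ll = (view["y"] - f) ** 2 / g**2 + np.log(2.0 * np.pi * g * g)
        return (
            np.bincount(view["os"], weights=ll, minlength=view["m"])
            + np.sum(eta_m * eta_m * om2inv, axis=1)
        )

    def _apply_eta(self, tv_m: np.ndarray, eta_m: np.ndarray) -> np.ndarray:
        params = tv_m.copy()
        if self.k:
            params[:, self.eta_idx] *= np.exp(eta_m)
        return params

    def _jac_view(self, view, tv_m, eta_m, f0) -> np.ndarray:
        h = 1e-4
        m = view["m"]
        stacked = np.empty((self.k * m, 4))
        for d in range(self.k):
            ep = eta_m.copy()
            ep[:, d] += h
            stacked[d * m : (d + 1) * m] = self._apply_eta(tv_m, ep)
        big = {
            "ps": np.concatenate([view["ps"] + d * m for d in range(self.k)]),
            "po": np.concatenate([view["po"] + d * view["n_obs"] for d in range(self.k)]),
            "t1": np.tile(view["t1"], self.k),
            "t2": np.tile(view["t2"], self.k),
            "rate": np.tile(view["rate"], self.k),
            "n_obs": self.k * view["n_obs"],
        }
        f = self._conc_view(big, stacked)
        return (f.reshape(self.k, view["n_obs"]).T - f0[:, None]) / h

    def inner_eta(self, tv, omega_sd, sigma, eta0) -> np.ndarray:
        """Conditional modes of eta for all subjects.

        Damped Newton with the exact gradient of the conditional objective
        (including the d log g / d eta interaction term) and a Gauss-Newton
        Hessian, which is always positive definite, so the step is a descent
        direction and the fixed point is path-independent -- the outer
        finite-difference gradient needs that smoothness.  Subjects are
        dropped from the working set as they converge, so the slow-linear
        tail of the search only touches the few stragglers.
        """
        om2inv = 1.0 / omega_sd**2
        prior_hess = np.diag(2.0 * om2inv)
        eta = np.clip(eta0, -8.0, 8.0)
        active = np.arange(self.n_sub)
        for _ in range(100):
            view = self._sub_view(active)
            tv_m = tv[active]
            eta_m = eta[active]
            f = self._conc_view(view, self._apply_eta(tv_m, eta_m))
            g = self.resid_sd(f, sigma)
            w = 1.0 / (g * g)
            r = view["y"] - f
            dg = self._dg_df(f, g, sigma)
            G = self._jac_view(view, tv_m, eta_m, f)
            # d h / d eta = sum_j G_jk [ -2 r/g^2 + (2 dg/g)(1 - r^2/g^2) ] + 2 eta/omega^2
            coef = -2.0 * r * w + (2.0 * dg / g) * (1.0 - r * r * w)
            os = view["os"]
            m = view["m"]
            grad = np.empty((m, self.k))
            H = np.empty((m, self.k, self.k))
            cg = coef[:, None] * G
            wG = w[:, None] * G
            for a in range(self.k):
                grad[:, a] = np.bincount(os, weights=cg[:, a], minlength=m)
                for b in range(a, self.k):
                    s = np.bincount(os, weights=wG[:, a] * G[:, b], minlength=m)
                    H[:, a, b] = 2.0 * s
                    H[:, b, a] = 2.0 * s
            grad += 2.0 * eta_m * om2inv
            H += prior_hess
            step = -np.linalg.solve(H, grad[..., None])[..., 0]
            # eta error enters the objective only at second order; 1e-6 on the
            # step keeps the OFV smooth to ~1e-12 at a fraction of the cost
            live = np.abs(step).max(axis=1) >= 1e-6
            if not live.any():
                break
            hval = (
                np.bincount(os, weights=r * r * w + np.log(2.0 * np.pi * g * g), minlength=m)
                + np.sum(eta_m * eta_m * om2inv, axis=1)
            )
            # backtracking: all unaccepted subjects share the same halving
            # count, so each successive trial only evaluates the shrinking
            # set that has rejected every larger step
            moved = np.zeros(m, dtype=bool)
            pending = live.copy()
            tfac = 1.0
            cur_view, cur_idx = view, np.arange(m)
            for _ls in range(10):
                if pending[cur_idx].sum() < cur_idx.size:
                    keep = pending[cur_idx]
                    cur_view = self._nest_view(cur_view, keep)
                    cur_idx = cur_idx[keep]
                trial = np.clip(eta_m[cur_idx] + tfac * step[cur_idx], -8.0, 8.0)
                ht = self._h_view(cur_view, tv_m[cur_idx], trial, sigma, om2inv)
                better = ht < hval[cur_idx] - 1e-10
                if better.any():
                    rows = cur_idx[better]
                    eta_m[rows] = trial[better]
                    hval[rows] = ht[better]
                    moved[rows] = True
                    pending[rows] = False
                if not pending.any():
                    break
                tfac *= 0.5
            eta[active] = eta_m
            if not moved.any():
                break
            active = active[moved]
        return eta

    # -- FOCE objective -----------------------------------------------------

    def ofv(self, theta, omega_sd, sigma, eta0=None):
        """FOCE(-interaction) objective and the conditional eta modes."""
        tv = self.model.typical(theta, self.cov)
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if self.k == 0:
            f = self.conc(tv)
            g = self.resid_sd(f, sigma)
            r = self.y - f
            value = float(np.sum(r * r / (g * g) + np.log(2.0 * np.pi * g * g)))
            return value, np.zeros((self.n_sub, 0))
        omega_sd = np.asarray(omega_sd, dtype=float)
        if eta0 is None:
            eta0 = np.zeros((self.n_sub, self.k))
        eta = self.inner_eta(tv, omega_sd, sigma, eta0)
        if np.abs(eta).max() >= 8.0 and np.abs(eta0).max() > 0.0:
            # stale warm start drove the inner search to the wall; restart cold
            eta = self.inner_eta(tv, omega_sd, sigma, np.zeros_like(eta0))
        f = self.conc(self._with_eta(tv, eta))
        g = self.resid_sd(f, sigma)
        w = 1.0 / (g * g)
        G = self._jac(tv, eta, f)
        # linearized population residual: y - f(eta_hat) + G eta_hat
        rs = (self.y - f) + np.einsum("jk,jk->j", G, eta[self.obs_sub])
        M = self._segm(G, w)
        bvec = self._segv((w * rs)[:, None] * G)
        omega2 = omega_sd**2
        om2inv = 1.0 / omega2
        eye = np.eye(self.k)
        iom = eye[None, :, :] + omega2[None, :, None] * M
        sign, logdet = np.linalg.slogdet(iom)
        if np.any(sign <= 0.0):
            raise _InvalidProposal("non-positive-definite marginal covariance")
        S = np.diag(om2inv)[None, :, :] + M
        x = np.linalg.solve(S, bvec[..., None])[..., 0]
        quad = self._segs(w * rs * rs) - np.einsum("ik,ik->i", bvec, x)
        lobs = self._segs(np.log(2.0 * np.pi * g * g))
        value = float(np.sum(lobs + logdet + quad))
        return value, eta


# -- results ----------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and diagnostics from one model fit."""

    model: ModelSpec
    theta: np.ndarray
    omega_sd: np.ndarray
    sigma: np.ndarray
    ofv: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    eta: np.ndarray
    eta_shrinkage_pct: np.ndarray
    eps_shrinkage_pct: float
    converged: bool
    message: str = ""
    theta_se_pct: Optional[np.ndarray] = None
    omega_se_pct: Optional[np.ndarray] = None
    sigma_se_pct: Optional[np.ndarray] = None
    n_fun_evals: int = 0

    @property
    def omega_pct(self) -> np.ndarray:
        """IIV on the reporting scale, 100 * sqrt(omega^2)."""
        return 100.0 * self.omega_sd

    def summary(self) -> pd.DataFrame:
        names = list(self.model.theta_names)
        values = list(self.theta)
        ses = list(self.theta_se_pct) if self.theta_se_pct is not None else [np.nan] * len(values)
        for i, p in enumerate(self.model.eta_on):
            names.append(f"omega_{p}(%)")
            values.append(self.omega_pct[i])
            ses.append(self.omega_se_pct[i] if self.omega_se_pct is not None else np.nan)
        for i in range(len(self.sigma)):
            names.append("sigma" if i == 0 else f"sigma{i + 1}")
            values.append(self.sigma[i])
            ses.append(self.sigma_se_pct[i] if self.sigma_se_pct is not None else np.nan)
        return pd.DataFrame({"parameter": names, "estimate": values, "se_pct": ses})


def information_criteria(ofv: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = OFV + 2k, BIC = OFV + k ln(n_obs)."""
    if n_params < 0 or n_obs < 1:
        raise ValueError("need n_params >= 0 and n_obs >= 1")
    return ofv + 2.0 * n_params, ofv + n_params * np.log(n_obs)


def eta_shrinkage(ebes: np.ndarray, omega_sd: np.ndarray) -> np.ndarray:
    """Per-dimension shrinkage 100 * (1 - SD(eta_hat) / omega); NaN where
    omega is zero."""
    ebes = np.asarray(ebes, dtype=float)
    omega_sd = np.asarray(omega_sd, dtype=float)
    if ebes.shape[0] < 2:
        raise ValueError("need at least two subjects")
    sd = ebes.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (1.0 - sd / omega_sd)
    return np.where(omega_sd > 0.0, out, np.nan)


def eps_shrinkage(iwres: np.ndarray) -> float:
    """100 * (1 - SD(IWRES))."""
    iwres = np.asarray(iwres, dtype=float)
    if iwres.size < 2:
        raise ValueError("need at least two residuals")
    return float(100.0 * (1.0 - iwres.std(ddof=1)))


# -- outer estimation --------------------------------------------------------


def _default_init(model: ModelSpec) -> dict:
    theta = [3.0, 12.0, 0.1, 0.2] + [e.theta_init for e in model.effects]
    return {
        "theta": np.array(theta, dtype=float),
        "omega_sd": np.full(len(model.eta_on), 0.3),
        "sigma": np.full(model.n_sigma, 0.3),
    }


class _Layout:
    """Packing of free parameters into the optimizer vector: log for the base
    typical values, omegas and sigmas; identity for covariate thetas."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.k = len(model.eta_on)
        self.n_theta = model.n_theta
        self.n_sigma = model.n_sigma
        self.n = self.n_theta + self.k + self.n_sigma

    def pack(self, theta, omega_sd, sigma) -> np.ndarray:
        x = np.empty(self.n)
        x[:4] = np.log(theta[:4])
        x[4 : self.n_theta] = theta[4:]
        x[self.n_theta : self.n_theta + self.k] = np.log(omega_sd)
        x[self.n_theta + self.k :] = np.log(sigma)
        return x

    def unpack(self, x: np.ndarray):
        theta = np.empty(self.n_theta)
        theta[:4] = np.exp(x[:4])
        theta[4:] = x[4 : self.n_theta]
        omega_sd = np.exp(x[self.n_theta : self.n_theta + self.k])
        sigma = np.exp(x[self.n_theta + self.k :])
        return theta, omega_sd, sigma

    def bounds(self) -> list[tuple[float, float]]:
        lo_tv, hi_tv = np.log(1e-4), np.log(1e4)
        b = [(lo_tv, hi_tv)] * 4
        b += [(-10.0, 10.0)] * (self.n_theta - 4)
        b += [(np.log(5e-3), np.log(5.0))] * self.k
        b += [(np.log(1e-4), np.log(10.0))] * self.n_sigma
        return b


def ofv_foce(dataset: PKDataset, model: ModelSpec, theta, omega_sd, sigma) -> float:
    """FOCE objective value at fixed parameters (no optimization)."""
    engine = FoceEngine(dataset, model)
    try:
        value, _ = engine.ofv(np.asarray(theta, float), np.asarray(omega_sd, float), sigma)
    except _InvalidProposal as exc:
        raise InvalidParameterError(str(exc)) from exc
    return value


def _make_result(engine, model, theta, omega_sd, sigma, value, eta, n_params, converged, message, n_fun):
    aic, bic = information_criteria(value, n_params, engine.n_obs)
    tv = model.typical(theta, engine.cov)
    ipred = engine.conc(engine._with_eta(tv, eta))
    g = engine.resid_sd(ipred, np.atleast_1d(sigma))
    iwres = (engine.y - ipred) / g
    shr = (
        eta_shrinkage(eta, omega_sd)
        if engine.k and engine.n_sub >= 2
        else np.full(engine.k, np.nan)
    )
    return FitResult(
        model=model,
        theta=np.asarray(theta, float),
        omega_sd=np.asarray(omega_sd, float),
        sigma=np.atleast_1d(np.asarray(sigma, float)),
        ofv=value,
        aic=aic,
        bic=bic,
        n_obs=engine.n_obs,
        n_params=n_params,
        eta=eta,
        eta_shrinkage_pct=shr,
        eps_shrinkage_pct=eps_shrinkage(iwres) if engine.n_obs >= 2 else np.nan,
        converged=converged,
        message=message,
        n_fun_evals=n_fun,
    )


def evaluate(dataset: PKDataset, model: ModelSpec, theta, omega_sd, sigma) -> FitResult:
    """Build a :class:`FitResult` at fixed parameters (EBEs computed, no
    outer optimization); used for diagnostics at known parameters."""
    engine = FoceEngine(dataset, model)
    theta = np.asarray(theta, float)
    omega_sd = np.asarray(omega_sd, float)
    value, eta = engine.ofv(theta, omega_sd, sigma)
    layout = _Layout(model)
    return _make_result(
        engine, model, theta, omega_sd, np.atleast_1d(sigma), value, eta,
        layout.n, True, "evaluated at fixed parameters", 1,
    )


def fit(
    dataset: PKDataset,
    model: ModelSpec,
    init: dict | None = None,
    estimate_se: bool = False,
    eta_start: np.ndarray | None = None,
    maxiter: int = 150,
    ftol: float = 1e-9,
    eps: float = 1e-5,
) -> FitResult:
    """Maximum-likelihood fit by FOCE.

    ``init`` may supply ``theta``, ``omega_sd`` and ``sigma`` starting
    values; warm starts (e.g. bootstrap replicates) pass the original
    estimates here and optionally ``eta_start`` for the inner modes.
    Convergence requires the OFV decrease per outer iteration to stay below
    ``max(ftol * |OFV|, 1e-4)`` on two consecutive iterations.
    """
    engine = FoceEngine(dataset, model)
    layout = _Layout(model)
    start = dict(_default_init(model))
    if init:
        for key in ("theta", "omega_sd", "sigma"):
            if key in init and init[key] is not None:
                start[key] = np.atleast_1d(np.asarray(init[key], dtype=float))
    x = layout.pack(start["theta"], start["omega_sd"], start["sigma"])

    eta0 = (
        eta_start.copy()
        if eta_start is not None
        else np.zeros((engine.n_sub, engine.k))
    )
    x, value, eta, n_evals, converged, message = _bfgs_outer(
        engine, layout, x, eta0, maxiter=maxiter, ftol=ftol, eps=eps
    )
    theta, omega_sd, sigma = layout.unpack(x)
    result = _make_result(
        engine, model, theta, omega_sd, sigma, value, eta, layout.n,
        converged, message, n_evals,
    )
    if estimate_se:
        _attach_se(result, engine, layout)
    return result


def _bfgs_outer(engine, layout, x0, eta_start, maxiter, ftol, eps):
    """Damped BFGS on the transformed parameter vector.

    The inner eta start is held fixed within each outer iteration (so the
    finite-difference gradient sees a smooth, deterministic objective) and
    refreshed from the current iterate between iterations, which keeps the
    inner search warm without introducing path dependence.
    """
    lo, hi = map(np.array, zip(*layout.bounds()))
    counter = {"n": 0}

    def value_and_eta(xv, eta_fixed):
        counter["n"] += 1
        theta, omega_sd, sigma = layout.unpack(xv)
        try:
            v, eta = engine.ofv(theta, omega_sd, sigma, eta0=eta_fixed)
        except (_InvalidProposal, np.linalg.LinAlgError):
            return 1e10, eta_fixed
        if not np.isfinite(v):
            return 1e10, eta_fixed
        return v, eta

    n = x0.size
    x = np.clip(x0, lo, hi)
    eta_cur = eta_start
    f0, eta_cur = value_and_eta(x, eta_cur)
    if f0 >= 1e10:
        # invalid starting point: fall back to a cold eta start
        eta_cur = np.zeros_like(eta_start)
        f0, eta_cur = value_and_eta(x, eta_cur)
    hinv = np.eye(n)
    g_prev = None
    s_prev = None
    flat_count = 0
    converged = False
    message = "maximum iterations reached"
    central = False
    for _it in range(maxiter):
        g = np.empty(n)
        for i in range(n):
            xp = x.copy()
            xp[i] += eps
            fp, _ = value_and_eta(xp, eta_cur)
            if central:
                xm = x.copy()
                xm[i] -= eps
                fm, _ = value_and_eta(xm, eta_cur)
                g[i] = (fp - fm) / (2.0 * eps)
            else:
                g[i] = (fp - f0) / eps
        if g_prev is not None and s_prev is not None:
            yk = g - g_prev
            sy = s_prev @ yk
            if sy > 1e-10:
                rho = 1.0 / sy
                v = np.eye(n) - rho * np.outer(s_prev, yk)
                hinv = v @ hinv @ v.T + rho * np.outer(s_prev, s_prev)
        d = -hinv @ g
        if d @ g >= 0.0:  # safeguard: reset to steepest descent
            hinv = np.eye(n)
            d = -g
        dmax = np.abs(d).max()
        if dmax > 1.0:  # trust-region style cap on the transformed scale
            d = d / dmax
        step = 1.0
        xn, fn, eta_n = x, f0, eta_cur
        ok = False
        for _ls in range(25):
            xt = np.clip(x + step * d, lo, hi)
            ft, eta_t = value_and_eta(xt, eta_cur)
            if ft < f0 - 1e-4 * step * abs(d @ g):
                xn, fn, eta_n, ok = xt, ft, eta_t, True
                break
            step *= 0.5
        if not ok:
            if not central:
                # forward-difference bias can stall the search just short of
                # the optimum; finish with central differences
                central = True
                g_prev = None
                s_prev = None
                continue
            converged = True
            message = "no further improvement along the search direction"
            break
        g_prev = g
        s_prev = xn - x
        drop = f0 - fn
        x, f0, eta_cur = xn, fn, eta_n
        flat_count = flat_count + 1 if drop < max(ftol * abs(f0), 1e-4) else 0
        if flat_count >= 2:
            converged = True
            message = "objective decrease below tolerance"
            break
    return x, f0, eta_cur, counter["n"], converged, message


def _attach_se(result: FitResult, engine: FoceEngine, layout: _Layout) -> None:
    """SE% from the numerical Hessian of OFV/2 in the natural parameter
    scale (R-matrix only)."""
    est = np.concatenate([result.theta, result.omega_sd, result.sigma])
    eta_cache = {"eta": result.eta.copy()}

    def half_ofv(v: np.ndarray) -> float:
        theta = v[: layout.n_theta]
        omega_sd = v[layout.n_theta : layout.n_theta + layout.k]
        sigma = v[layout.n_theta + layout.k :]
        if np.any(omega_sd <= 0.0) or np.any(sigma <= 0.0) or np.any(theta[:4] <= 0.0):
            return np.inf
        try:
            value, eta = engine.ofv(theta, omega_sd, sigma, eta0=eta_cache["eta"])
        except (_InvalidProposal, np.linalg.LinAlgError):
            return np.inf
        return 0.5 * value

    n = est.size
    steps = np.maximum(np.abs(est) * 1e-3, 1e-6)
    hess = np.empty((n, n))
    f0 = half_ofv(est)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        fp[i] = half_ofv(est + ei)
        fm[i] = half_ofv(est - ei)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / steps[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = half_ofv(est + ei + ej)
            fmm = half_ofv(est - ei - ej)
            hij = (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm) / (
                2.0 * steps[i] * steps[j]
            )
            hess[i, j] = hij
            hess[j, i] = hij
    try:
        cov = np.linalg.inv(hess)
        var = np.diag(cov)
        if np.any(var <= 0.0):
            raise np.linalg.LinAlgError("negative variance")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        var = np.abs(np.diag(cov))
        result.message += "; SE from pseudo-inverse Hessian"
    se_pct = 100.0 * np.sqrt(var) / np.abs(est)
    result.theta_se_pct = se_pct[: layout.n_theta]
    result.omega_se_pct = se_pct[layout.n_theta : layout.n_theta + layout.k]
    result.sigma_se_pct = se_pct[layout.n_theta + layout.k :]


# -- stepwise covariate selection -------------------------------------------


@dataclass(frozen=True)
class SelectionStep:
    """One decision in the forward/backward covariate search."""

    label: str
    phase: str  # 'forward' | 'backward'
    ofv: float
    delta_ofv: float
    decision: str  # 'include' | 'exclude' | 'keep' | 'remove'


def forward_accept(delta_ofv: float, threshold: float = 3.84) -> bool:
    """Forward inclusion requires an OFV drop strictly greater than the
    threshold (a drop of exactly 3.84 is not enough)."""
    return delta_ofv < -threshold


def backward_keep(increase: float, threshold: float = 6.64) -> bool:
    """Backward elimination keeps a covariate only if removing it raises the
    OFV by at least the threshold."""
    return increase >= threshold


def _with_effect(model: ModelSpec, effect: CovariateEffect) -> ModelSpec:
    return replace(model, effects=model.effects + (effect,))


def _without_effect(model: ModelSpec, index: int) -> ModelSpec:
    effects = model.effects[:index] + model.effects[index + 1 :]
    return replace(model, effects=effects)


def stepwise_select(
    dataset: PKDataset,
    base: ModelSpec,
    candidates: Sequence[CovariateEffect],
    include_threshold: float = 3.84,
    exclude_threshold: float = 6.64,
    init: dict | None = None,
    **fit_kwargs,
) -> tuple[ModelSpec, FitResult, list[SelectionStep]]:
    """Forward inclusion / backward elimination over candidate covariate
    effects.

    Ties in the forward phase break on larger OFV drop, then fewer added
    parameters, then the candidate label.  Returns the selected model, its
    fit and the decision trace.
    """
    steps: list[SelectionStep] = []
    current_model = base
    current_fit = fit(dataset, base, init=init, **fit_kwargs)
    remaining = list(candidates)

    while remaining:
        trials = []
        for cand in remaining:
            trial_model = _with_effect(current_model, cand)
            warm = {
                "theta": np.append(current_fit.theta, cand.theta_init),
                "omega_sd": current_fit.omega_sd,
                "sigma": current_fit.sigma,
            }
            trial_fit = fit(dataset, trial_model, init=warm, eta_start=current_fit.eta, **fit_kwargs)
            delta = trial_fit.ofv - current_fit.ofv
            trials.append((delta, 1, cand.name, cand, trial_model, trial_fit))
        trials.sort(key=lambda t: (t[0], t[1], t[2]))
        best = trials[0]
        if forward_accept(best[0], include_threshold):
            steps.append(
                SelectionStep(best[2], "forward", best[5].ofv, best[0], "include")
            )
            current_model, current_fit = best[4], best[5]
            remaining = [c for c in remaining if c is not best[3]]
        else:
            steps.append(SelectionStep(best[2], "forward", best[5].ofv, best[0], "exclude"))
            break

    removed = True
    while removed and current_model.effects:
        removed = False
        selected = [e for e in current_model.effects if e in tuple(candidates)]
        for eff in selected:
            index = current_model.effects.index(eff)
            reduced_model = _without_effect(current_model, index)
            warm = {
                "theta": np.delete(current_fit.theta, 4 + index),
                "omega_sd": current_fit.omega_sd,
                "sigma": current_fit.sigma,
            }
            reduced_fit = fit(dataset, reduced_model, init=warm, eta_start=current_fit.eta, **fit_kwargs)
            increase = reduced_fit.ofv - current_fit.ofv
            if backward_keep(increase, exclude_threshold):
                steps.append(SelectionStep(eff.name, "backward", reduced_fit.ofv, increase, "keep"))
            else:
                steps.append(SelectionStep(eff.name, "backward", reduced_fit.ofv, increase, "remove"))
                current_model, current_fit = reduced_model, reduced_fit
                removed = True
                break

    return current_model, current_fit, steps
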