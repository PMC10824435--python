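"""Year-stratified logistic growth curves with correlated field random effects.

The tuber weight y_ijk of field i at standardized day t_ijk in year k follows

    y_ijk = exp(a_ik) / (1 + exp(-b_ik (t_ijk - c_ik))) * exp(e_ijk)

with i.i.d. residuals e_ijk ~ N(0, sigma^2) (a multiplicative lognormal
error), and field-level curve parameters

    a_ik = alpha_0k + sigma_alpha * a_i          (log asymptote)
    b_ik = exp(beta_0k + sigma_beta * b_i)       (steepness, > 0)
    c_ik = gamma_0k + exp(sigma_gamma) * c_i     (midpoint)

where (a_i, b_i, c_i) are multivariate standard normal with correlation
matrix R = [[1, rho12, rho13], [rho12, 1, rho23], [rho13, rho23, 1]].  The
year-specific fixed effects give each calendar year its own average curve;
the unit-variance random effects are the field-specific deviations that
later serve as mining targets.

Estimation maximizes the marginal likelihood, integrating the three random
effects out per field with adaptive Gauss-Hermite quadrature: the quadrature
grid is recentred at each field's posterior mode and scaled by the curvature
there (one node per dimension is exactly the Laplace approximation).
Empirical-Bayes effects are those posterior modes at the fitted parameters.

Everything is evaluated on the log-weight scale, where the multiplicative
error is additive Gaussian; reported log-likelihoods are for the weights
themselves (the lognormal Jacobian is included).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import curve_fit, minimize
from scipy.special import expit, logsumexp
from scipy.stats import linregress

from .io_data import Dataset

_LOG_2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    """Raised for invalid model parameters or unusable data."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModelParams:
    """Population parameters of the growth model.

    ``sigma_gamma`` is the unconstrained pre-exponential parameter: the
    effective scale of the midpoint random effect is ``exp(sigma_gamma)``.
    """

    alpha0: dict[int, float]
    beta0: dict[int, float]
    gamma0: dict[int, float]
    sigma_alpha: float
    sigma_beta: float
    sigma_gamma: float
    rho12: float
    rho13: float
    rho23: float
    sigma_resid: float

    @property
    def years(self) -> list[int]:
        return sorted(self.alpha0)

    def corr_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.rho12, self.rho13],
                [self.rho12, 1.0, self.rho23],
                [self.rho13, self.rho23, 1.0],
            ]
        )

    def validate(self) -> None:
        if self.sigma_resid <= 0:
            raise ModelError("sigma_resid must be positive")
        if self.sigma_alpha < 0 or self.sigma_beta < 0:
            raise ModelError("sigma_alpha and sigma_beta must be non-negative")
        if set(self.beta0) != set(self.alpha0) or set(self.gamma0) != set(self.alpha0):
            raise ModelError("alpha0, beta0, gamma0 must cover the same years")
        R = self.corr_matrix()
        if np.any(np.abs([self.rho12, self.rho13, self.rho23]) >= 1.0):
            raise ModelError("correlations must lie in (-1, 1)")
        if np.linalg.eigvalsh(R)[0] <= 1e-10:
            raise ModelError("random-effect correlation matrix is not positive definite")

    def rescale_time(self, s: float) -> "ModelParams":
        """Re-express parameters after replacing time t by t / s.

        Steepness picks up a factor s (``beta0 + log s``), the midpoint and
        its random-effect scale shrink by s.  ``sigma_alpha``, ``sigma_beta``,
        the correlations and ``sigma_resid`` are invariant.
        """
        if s <= 0:
            raise ModelError("time scale must be positive")
        return dataclasses.replace(
            self,
            beta0={k: v + np.log(s) for k, v in self.beta0.items()},
            gamma0={k: v / s for k, v in self.gamma0.items()},
            sigma_gamma=self.sigma_gamma - float(np.log(s)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("alpha0", "beta0", "gamma0"):
            d[key] = {str(k): v for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        d = dict(d)
        for key in ("alpha0", "beta0", "gamma0"):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class RandomEffects:
    """Field-level standardized deviations (a, b, c) from the year-average curve."""

    a: float
    b: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@dataclasses.dataclass(frozen=True)
class FieldCurveParams:
    """Logistic curve parameters of one field-year.

    ``log_asymptote`` = a_ik, ``steepness`` = b_ik (> 0, per standardized
    day), ``midpoint`` = c_ik (standardized days).
    """

    log_asymptote: float
    steepness: float
    midpoint: float

    def __post_init__(self):
        if self.steepness <= 0:
            raise ModelError("steepness must be positive")


@dataclasses.dataclass
class FittedModel:
    """Result of :func:`fit`: population parameters plus per-field EB effects."""

    params: ModelParams
    loglik: float
    eb: dict[str, RandomEffects]
    converged: bool
    n_quadrature: int
    time_scale: float
    n_iter: int = 0

    SCHEMA_VERSION = 1

    def to_json(self, path) -> None:
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_quadrature": self.n_quadrature,
            "time_scale": self.time_scale,
            "n_iter": self.n_iter,
            "eb": {k: [v.a, v.b, v.c] for k, v in self.eb.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != cls.SCHEMA_VERSION:
            raise ModelError("unsupported model file schema")
        return cls(
            params=ModelParams.from_dict(doc["params"]),
            loglik=float(doc["loglik"]),
            eb={k: RandomEffects(*v) for k, v in doc["eb"].items()},
            converged=bool(doc["converged"]),
            n_quadrature=int(doc["n_quadrature"]),
            time_scale=float(doc["time_scale"]),
            n_iter=int(doc.get("n_iter", 0)),
        )

    def eb_frame(self) -> pd.DataFrame:
        """EB random effects as a DataFrame indexed by unit_id."""
        return pd.DataFrame(
            {u: [re.a, re.b, re.c] for u, re in self.eb.items()},
            index=["a", "b", "c"],
        ).T


@dataclasses.dataclass
class FitConfig:
    """Estimation settings.

    ``n_quadrature`` is the number of Gauss-Hermite nodes per dimension
    (1 = Laplace); optimization runs a Laplace stage first and then refines
    at ``n_quadrature`` nodes.  Convergence: gradient norm below ``gtol``
    or relative log-likelihood change below ``ftol``; at most ``max_iter``
    quasi-Newton iterations per stage.
    """

    n_quadrature: int = 5
    max_iter: int = 500
    gtol: float = 1e-5
    ftol: float = 1e-8
    sigma_init: float = 0.3
    verbose: bool = False


# ---------------------------------------------------------------------------
# curve evaluation
# ---------------------------------------------------------------------------


def _log_logistic(log_asym, steep, mid, t):
    """log of the logistic mean, overflow-safe: a - softplus(-b (t - mid))."""
    eta = steep * (np.asarray(t, dtype=float) - mid)
    # softplus(-eta) computed stably
    return log_asym - (np.logaddexp(0.0, -eta))


def logistic_mean(p: FieldCurveParams, t):
    """Expected tuber weight (g m^-2) of a field at standardized day t.

    Strictly increasing in t, bounded above by ``exp(log_asymptote)``; at
    ``t == midpoint`` the value is exactly half the asymptote.
    """
    out = np.exp(_log_logistic(p.log_asymptote, p.steepness, p.midpoint, t))
    if np.ndim(t) == 0:
        return float(out)
    return out


def field_params(params: ModelParams, year: int, re: RandomEffects) -> FieldCurveParams:
    """Combine year fixed effects with a field's random effects (Eq. above)."""
    if year not in params.alpha0:
        raise ModelError(f"year {year} not in fitted years {params.years}")
    return FieldCurveParams(
        log_asymptote=params.alpha0[year] + params.sigma_alpha * re.a,
        steepness=float(np.exp(params.beta0[year] + params.sigma_beta * re.b)),
        midpoint=params.gamma0[year] + float(np.exp(params.sigma_gamma)) * re.c,
    )


# ---------------------------------------------------------------------------
# packed data and vectorized likelihood machinery
# ---------------------------------------------------------------------------


class _Packed:
    """Observations padded to (n_fields, max_obs) arrays for vectorized math."""

    def __init__(self, dataset: Dataset):
        obs = dataset.observations
        units = [u for u in dataset.unit_ids if u in set(obs["unit_id"])]
        dropped = [u for u in dataset.unit_ids if u not in set(obs["unit_id"])]
        if dropped:
            warnings.warn(
                f"{len(dropped)} field(s) have no likelihood observations and are skipped"
            )
        self.unit_ids = units
        self.years = np.array(
            [int(dataset.fields.loc[u, "year"]) for u in units], dtype=int
        )
        self.year_levels = np.array(sorted(set(self.years.tolist())), dtype=int)
        lookup = {y: i for i, y in enumerate(self.year_levels.tolist())}
        self.year_idx = np.array([lookup[y] for y in self.years], dtype=int)

        grouped = {u: g for u, g in obs.groupby("unit_id")}
        F = len(units)
        M = max(len(grouped[u]) for u in units)
        self.t = np.zeros((F, M))
        self.logy = np.zeros((F, M))
        self.mask = np.zeros((F, M), dtype=bool)
        for i, u in enumerate(units):
            g = grouped[u]
            m = len(g)
            self.t[i, :m] = g["t_std"].to_numpy(float)
            self.logy[i, :m] = g["log_weight"].to_numpy(float)
            self.mask[i, :m] = True
        self.n_obs = self.mask.sum(axis=1)
        self.sum_logy = np.where(self.mask, self.logy, 0.0).sum(axis=1)

    @property
    def n_fields(self) -> int:
        return len(self.unit_ids)


class _ParamArrays:
    """ModelParams broadcast to per-field arrays plus prior matrices."""

    def __init__(self, params: ModelParams, packed: _Packed):
        missing = [y for y in packed.year_levels.tolist() if y not in params.alpha0]
        if missing:
            raise ModelError(f"no fixed effects for year(s) {missing}")
        a0 = np.array([params.alpha0[y] for y in packed.year_levels.tolist()])
        b0 = np.array([params.beta0[y] for y in packed.year_levels.tolist()])
        g0 = np.array([params.gamma0[y] for y in packed.year_levels.tolist()])
        self.alpha_f = a0[packed.year_idx]
        self.beta_f = b0[packed.year_idx]
        self.gamma_f = g0[packed.year_idx]
        self.sa = params.sigma_alpha
        self.sb = params.sigma_beta
        self.sc = float(np.exp(params.sigma_gamma))
        self.s2 = params.sigma_resid**2
        self.sigma_resid = params.sigma_resid
        R = params.corr_matrix()
        try:
            Lr = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ModelError("correlation matrix is not positive definite") from exc
        self.Rinv = np.linalg.inv(R)
        self.logdetR = 2.0 * float(np.sum(np.log(np.diag(Lr))))


def _cond_loglik(pa: _ParamArrays, packed: _Packed, u: np.ndarray) -> np.ndarray:
    """Conditional log-likelihood of each field's weights given u.

    ``u`` has shape (..., F, 3); returns shape (..., F).  Includes the
    lognormal Jacobian (-sum log y), so this is the density of the weights.
    """
    a = pa.alpha_f + pa.sa * u[..., 0]
    logb = pa.beta_f + pa.sb * u[..., 1]
    b = np.exp(logb)
    c = pa.gamma_f + pa.sc * u[..., 2]
    eta = b[..., None] * (packed.t - c[..., None])
    mu = a[..., None] - np.logaddexp(0.0, -eta)
    r = np.where(packed.mask, packed.logy - mu, 0.0)
    quad = (r**2).sum(axis=-1) / (2.0 * pa.s2)
    const = packed.n_obs * 0.5 * (_LOG_2PI + np.log(pa.s2)) + packed.sum_logy
    return -quad - const


def _neg_joint(pa: _ParamArrays, packed: _Packed, u: np.ndarray) -> np.ndarray:
    """h(u) = -log p(y_f | u) - log phi3(u; R), shape (..., F)."""
    prior = 0.5 * (
        3.0 * _LOG_2PI
        + pa.logdetR
        + np.einsum("...i,ij,...j->...", u, pa.Rinv, u)
    )
    return -_cond_loglik(pa, packed, u) + prior


def _neg_joint_grad_hess(pa: _ParamArrays, packed: _Packed, u: np.ndarray):
    """Gradient and Gauss-Newton Hessian of h(u); u shape (F, 3)."""
    a = pa.alpha_f + pa.sa * u[:, 0]
    logb = pa.beta_f + pa.sb * u[:, 1]
    b = np.exp(logb)
    c = pa.gamma_f + pa.sc * u[:, 2]
    eta = b[:, None] * (packed.t - c[:, None])
    mu = a[:, None] - np.logaddexp(0.0, -eta)
    sig_neg = expit(-eta)  # 1 - sigmoid(eta)
    r = np.where(packed.mask, packed.logy - mu, 0.0)
    # dmu/du: (F, M, 3)
    dmu = np.empty(packed.t.shape + (3,))
    dmu[..., 0] = pa.sa
    dmu[..., 1] = pa.sb * eta * sig_neg
    dmu[..., 2] = -pa.sc * b[:, None] * sig_neg
    dmu = np.where(packed.mask[..., None], dmu, 0.0)
    grad = -(r[..., None] * dmu).sum(axis=1) / pa.s2 + u @ pa.Rinv
    H = np.einsum("fmi,fmj->fij", dmu, dmu) / pa.s2 + pa.Rinv
    return grad, H


def _posterior_modes(
    pa: _ParamArrays,
    packed: _Packed,
    u0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
):
    """Batched Newton search for every field's posterior mode.

    Returns (modes (F,3), H (F,3,3) Gauss-Newton curvature at the mode,
    h(mode) (F,)).  Step-halving keeps h non-increasing per field.
    """
    F = packed.n_fields
    u = np.zeros((F, 3)) if u0 is None else u0.copy()
    h = _neg_joint(pa, packed, u)
    for _ in range(max_iter):
        grad, H = _neg_joint_grad_hess(pa, packed, u)
        gnorm = np.abs(grad).max(axis=1)
        active = gnorm > tol
        if not active.any():
            break
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        scale = np.ones(F)
        for _half in range(25):
            u_new = u - scale[:, None] * step * active[:, None]
            h_new = _neg_joint(pa, packed, u_new)
            worse = active & (h_new > h + 1e-12)
            if not worse.any():
                break
            scale[worse] *= 0.5
        improved = active & (h_new <= h + 1e-12)
        u[improved] = u_new[improved]
        h[improved] = h_new[improved]
        if not improved.any():
            break
    _, H = _neg_joint_grad_hess(pa, packed, u)
    return u, H, h


def _agq_loglik(
    pa: _ParamArrays,
    packed: _Packed,
    n_points: int,
    u0: np.ndarray | None = None,
):
    """Adaptive Gauss-Hermite marginal log-likelihood; returns (total, modes)."""
    modes, H, h_mode = _posterior_modes(pa, packed, u0=u0)
    L = np.linalg.cholesky(H)  # (F,3,3)
    # C with C C^T = H^{-1}: C = inv(L)^T
    eye = np.broadcast_to(np.eye(3), L.shape)
    Linv = np.linalg.solve(L, eye)
    C = np.swapaxes(Linv, -1, -2)
    logdetC = -np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)

    if n_points == 1:
        # Laplace: log f(mode) + 3/2 log(2 pi) + log|C|
        ll_f = -h_mode + 1.5 * _LOG_2PI + logdetC
        return float(ll_f.sum()), modes

    z1, w1 = hermgauss(n_points)
    Z = np.stack(np.meshgrid(z1, z1, z1, indexing="ij"), axis=-1).reshape(-1, 3)
    logw = (
        np.log(w1)[:, None, None]
        + np.log(w1)[None, :, None]
        + np.log(w1)[None, None, :]
    ).reshape(-1)
    znorm2 = (Z**2).sum(axis=1)
    # u nodes: (J, F, 3)
    u_nodes = modes[None, :, :] + np.sqrt(2.0) * np.einsum("fij,nj->nfi", C, Z)
    log_f = -_neg_joint(pa, packed, u_nodes)  # (J, F)
    ll_f = (
        logsumexp(log_f + znorm2[:, None] + logw[:, None], axis=0)
        + 1.5 * np.log(2.0)
        + logdetC
    )
    return float(ll_f.sum()), modes


def marginal_loglik(params: ModelParams, data: Dataset, n_points: int = 5) -> float:
    """Marginal log-likelihood of the dataset under the model.

    The three-dimensional random-effect integral of every field is
    approximated by ``n_points``-per-dimension adaptive Gauss-Hermite
    quadrature, recentred at the field's posterior mode and scaled by the
    curvature there.  ``n_points=1`` is the Laplace approximation.
    """
    if n_points < 1:
        raise ModelError("n_points must be >= 1")
    params.validate()
    packed = _Packed(data)
    pa = _ParamArrays(params, packed)
    total, _ = _agq_loglik(pa, packed, n_points)
    return total


def eb_random_effects(params: ModelParams, observations: pd.DataFrame) -> RandomEffects:
    """Empirical-Bayes (posterior-mode) random effects of one field.

    ``observations`` needs columns ``t_std``, ``log_weight`` and ``year``
    (one year only) — the same layout as ``Dataset.observations``.
    """
    if len(observations) < 1:
        raise ModelError("need at least one observation")
    years = set(int(y) for y in observations["year"])
    if len(years) != 1:
        raise ModelError("observations must belong to a single field-year")
    (year,) = years
    packed = _Packed.__new__(_Packed)
    packed.unit_ids = ["_single"]
    packed.years = np.array([year])
    packed.year_levels = np.array([year])
    packed.year_idx = np.array([0])
    t = observations["t_std"].to_numpy(float)
    packed.t = t[None, :]
    packed.logy = observations["log_weight"].to_numpy(float)[None, :]
    packed.mask = np.ones_like(packed.t, dtype=bool)
    packed.n_obs = np.array([len(t)])
    packed.sum_logy = packed.logy.sum(axis=1)
    pa = _ParamArrays(params, packed)
    modes, _, _ = _posterior_modes(pa, packed)
    return RandomEffects(*(float(v) for v in modes[0]))


# ---------------------------------------------------------------------------
# parameter vector <-> ModelParams
# ---------------------------------------------------------------------------


def _angles_to_corr(x: np.ndarray) -> tuple[float, float, float]:
    """Map three unconstrained reals to a PD correlation triple (spherical)."""
    t1, t2, t3 = np.pi * expit(x)
    rho12 = np.cos(t1)
    rho13 = np.cos(t2)
    rho23 = np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * np.cos(t3)
    return float(rho12), float(rho13), float(rho23)


def _corr_to_angles(rho12: float, rho13: float, rho23: float) -> np.ndarray:
    t1 = np.arccos(np.clip(rho12, -0.999999, 0.999999))
    t2 = np.arccos(np.clip(rho13, -0.999999, 0.999999))
    ct3 = (rho23 - rho12 * rho13) / (np.sin(t1) * np.sin(t2))
    t3 = np.arccos(np.clip(ct3, -0.999999, 0.999999))
    frac = np.clip(np.array([t1, t2, t3]) / np.pi, 1e-6, 1 - 1e-6)
    return np.log(frac / (1 - frac))


def _pack_theta(params: ModelParams, years: list[int]) -> np.ndarray:
    return np.concatenate(
        [
            [params.alpha0[y] for y in years],
            [params.beta0[y] for y in years],
            [params.gamma0[y] for y in years],
            [
                np.log(max(params.sigma_alpha, 1e-8)),
                np.log(max(params.sigma_beta, 1e-8)),
                params.sigma_gamma,
            ],
            _corr_to_angles(params.rho12, params.rho13, params.rho23),
            [np.log(params.sigma_resid)],
        ]
    )


def _unpack_theta(theta: np.ndarray, years: list[int]) -> ModelParams:
    K = len(years)
    rho12, rho13, rho23 = _angles_to_corr(theta[3 * K + 3 : 3 * K + 6])
    return ModelParams(
        alpha0={y: float(theta[i]) for i, y in enumerate(years)},
        beta0={y: float(theta[K + i]) for i, y in enumerate(years)},
        gamma0={y: float(theta[2 * K + i]) for i, y in enumerate(years)},
        sigma_alpha=float(np.exp(theta[3 * K])),
        sigma_beta=float(np.exp(theta[3 * K + 1])),
        sigma_gamma=float(theta[3 * K + 2]),
        rho12=rho12,
        rho13=rho13,
        rho23=rho23,
        sigma_resid=float(np.exp(theta[3 * K + 6])),
    )


# ---------------------------------------------------------------------------
# starting values and fitting
# ---------------------------------------------------------------------------


def _start_values(packed: _Packed, sigma_init: float) -> ModelParams:
    """Per-year nonlinear least squares of the fixed-effect curve on pooled data."""

    def mu(t, A, logb, c):
        return A - np.logaddexp(0.0, -np.exp(logb) * (t - c))

    alpha0, beta0, gamma0 = {}, {}, {}
    resid = []
    for j, year in enumerate(packed.year_levels.tolist()):
        sel = packed.year_idx == j
        t = packed.t[sel][packed.mask[sel]]
        logy = packed.logy[sel][packed.mask[sel]]
        span = max(t.max() - t.min(), 1e-6)
        p0 = (float(logy.max()) + 0.1, float(np.log(4.0 / span)), float(np.median(t)))
        try:
            popt, _ = curve_fit(mu, t, logy, p0=p0, maxfev=5000)
        except RuntimeError:
            popt = np.array(p0)
        alpha0[year], beta0[year], gamma0[year] = (float(v) for v in popt)
        resid.append(logy - mu(t, *popt))
    resid = np.concatenate(resid)
    sigma_resid = float(max(np.std(resid), 1e-3))
    return ModelParams(
        alpha0=alpha0,
        beta0=beta0,
        gamma0=gamma0,
        sigma_alpha=sigma_init,
        sigma_beta=sigma_init,
        sigma_gamma=float(np.log(sigma_init)),
        rho12=0.0,
        rho13=0.0,
        rho23=0.0,
        sigma_resid=sigma_resid,
    )


def fit(data: Dataset, config: FitConfig | None = None) -> FittedModel:
    """Maximize the marginal likelihood and extract empirical-Bayes effects.

    A Laplace (1-node) stage finds the neighbourhood of the optimum cheaply;
    a second stage refines at ``config.n_quadrature`` nodes per dimension.
    Non-convergence is reported through ``FittedModel.converged``, never
    silently.
    """
    config = config or FitConfig()
    packed = _Packed(data)
    if packed.n_fields < 2:
        raise ModelError("need at least 2 fields to fit")
    for j, year in enumerate(packed.year_levels.tolist()):
        if int((packed.year_idx == j).sum()) < 2:
            raise ModelError(f"year {year} has fewer than 2 fields")
    logy_all = packed.logy[packed.mask]
    if np.allclose(logy_all, logy_all[0]):
        raise ModelError("degenerate data: all weights identical")

    years = packed.year_levels.tolist()
    start = _start_values(packed, config.sigma_init)
    theta0 = _pack_theta(start, years)

    mode_cache = {"u": np.zeros((packed.n_fields, 3))}

    def make_objective(n_points: int):
        def nll(theta: np.ndarray) -> float:
            try:
                params = _unpack_theta(theta, years)
                pa = _ParamArrays(params, packed)
                total, modes = _agq_loglik(pa, packed, n_points, u0=mode_cache["u"])
            except (np.linalg.LinAlgError, FloatingPointError, ModelError):
                return 1e12
            if not np.isfinite(total):
                return 1e12
            mode_cache["u"] = modes
            return -total

        return nll

    n_iter = 0
    converged = True
    stages = [1] if config.n_quadrature == 1 else [1, config.n_quadrature]
    theta = theta0
    res = None
    for n_points in stages:
        res = minimize(
            make_objective(n_points),
            theta,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iter,
                "ftol": config.ftol,
                "gtol": config.gtol,
            },
        )
        theta = res.x
        n_iter += int(res.nit)
    converged = bool(res.success) or res.status == 1 and n_iter > 0
    if not res.success:
        warnings.warn(f"optimizer did not report convergence: {res.message}")
        converged = False

    params = _unpack_theta(theta, years)
    pa = _ParamArrays(params, packed)
    loglik, modes = _agq_loglik(
        pa, packed, config.n_quadrature, u0=mode_cache["u"]
    )
    eb = {
        u: RandomEffects(*(float(v) for v in modes[i]))
        for i, u in enumerate(packed.unit_ids)
    }
    return FittedModel(
        params=params,
        loglik=loglik,
        eb=eb,
        converged=converged,
        n_quadrature=config.n_quadrature,
        time_scale=data.time_scale,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# predictions and summaries
# ---------------------------------------------------------------------------


def predict_weights(model: FittedModel, data: Dataset) -> np.ndarray:
    """Predicted weight (g m^-2) for every likelihood observation.

    Uses each field's empirical-Bayes curve; aligned with
    ``data.observations`` rows.
    """
    obs = data.observations
    out = np.empty(len(obs))
    for i, row in enumerate(obs.itertuples(index=False)):
        re = model.eb.get(row.unit_id)
        if re is None:
            raise ModelError(f"no EB effects for unit {row.unit_id}")
        p = field_params(model.params, int(row.year), re)
        out[i] = logistic_mean(p, float(row.t_std))
    return out


def r_squared(model: FittedModel, data: Dataset) -> float:
    """R^2 of the OLS regression of observed on model-predicted weights."""
    obs = data.observations["weight_g_m2"].to_numpy(float)
    if len(obs) < 3:
        raise ModelError("need at least 3 observations for R^2")
    pred = predict_weights(model, data)
    if np.std(pred) == 0:
        raise ModelError("predictions have zero variance")
    res = linregress(pred, obs)
    return float(res.rvalue**2)


def random_effect_correlations(model: FittedModel) -> np.ndarray:
    """Fitted random-effect correlation matrix (symmetric, unit diagonal)."""
    return model.params.corr_matrix()
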