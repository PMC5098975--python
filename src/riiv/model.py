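"""The doubly hierarchical Gaussian model: likelihood, priors, fitting.

The mean model gives every assay an expected value built from fixed
effects (batch, Z-mass, centred week, Z-temperature, time of day) plus
an individual intercept and an individual-by-burst intercept.  The
residual model gives every assay a residual SD through a log link:
fixed effects of Z-mass and centred week plus an individual intercept
(the rIIV effect).  The two individual intercepts are jointly
multivariate normal with correlation ``rho``.  The reduced model drops
the individual effect (and hence the correlation) from the residual
model, leaving a single homogeneous residual-SD curve.

Fitting is by NUTS over a non-centred, unconstrained parameterization
(SDs on the log scale, the correlation through ``tanh``); convergence
is a contract checked with split R-hat and bulk/tail effective sample
sizes after sampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import betaln

from .data import PreparedData
from .errors import ConvergenceError, DegenerateDataError, ParameterDomainError
from .sampler import sample_nuts

_LOG_2PI = math.log(2.0 * math.pi)
_LOG_SD_BOUND = 40.0  # |log sigma_e| beyond this is treated as out of support

try:  # jit-compiled likelihood kernel; plain numpy works identically
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


@_njit(cache=True)
def _loglik_grad_kernel(y, xm, xr, j, k, beta, gamma, u_mu, u_sigma, v, het,
                        g_beta, g_gamma, g_umu, g_usig, g_v):
    """Gaussian log likelihood and its gradient w.r.t. the constrained
    per-observation building blocks, accumulated in one pass."""
    n = y.shape[0]
    loglik = -0.5 * n * _LOG_2PI
    for i in range(n):
        ji = j[i]
        mu = beta[0] + u_mu[ji] + v[k[i]]
        for q in range(5):
            mu += xm[i, q] * beta[q + 1]
        log_sd = gamma[0] + xr[i, 0] * gamma[1] + xr[i, 1] * gamma[2]
        if het:
            log_sd += u_sigma[ji]
        if log_sd > _LOG_SD_BOUND or log_sd < -_LOG_SD_BOUND:
            return np.inf  # caller maps to -inf log density
        inv_sd = math.exp(-log_sd)
        r = (y[i] - mu) * inv_sd
        loglik += -log_sd - 0.5 * r * r
        a = r * inv_sd
        b = r * r - 1.0
        g_beta[0] += a
        for q in range(5):
            g_beta[q + 1] += xm[i, q] * a
        g_gamma[0] += b
        g_gamma[1] += xr[i, 0] * b
        g_gamma[2] += xr[i, 1] * b
        g_umu[ji] += a
        g_v[k[i]] += a
        if het:
            g_usig[ji] += b
    return loglik

#: names of the scalar parameters reported in summaries, full model
SCALAR_PARAMS_FULL = (
    "beta0", "beta1", "beta2", "beta3", "beta4", "beta5",
    "gamma0", "gamma1", "gamma2",
    "sigma_id_mu", "omega", "sigma_id_burst", "rho",
)
SCALAR_PARAMS_REDUCED = (
    "beta0", "beta1", "beta2", "beta3", "beta4", "beta5",
    "gamma0", "gamma1", "gamma2",
    "sigma_id_mu", "sigma_id_burst",
)


@dataclass
class PriorConfig:
    """Weakly informative priors on the standardized response scale.

    Fixed effects get Normal(0, ``beta_scale``); the three SD
    parameters get half-Student-t(``sd_df``, 0, ``sd_scale``); the
    among-individual correlation gets LKJ(``lkj_eta``), whose 2x2 case
    has density proportional to ``(1 - rho^2)^(eta - 1)`` — ``eta`` = 2
    puts a mild peak on independence.
    """

    beta_scale: float = 5.0
    sd_df: float = 3.0
    sd_scale: float = 2.5
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        if self.lkj_eta < 1.0:
            raise ParameterDomainError("lkj_eta must be >= 1")
        if min(self.beta_scale, self.sd_df, self.sd_scale) <= 0:
            raise ParameterDomainError("prior scales must be positive")


@dataclass
class ModelParams:
    """One complete parameter point of the full model.

    ``u_mu`` / ``u_sigma`` are the individual intercepts of the mean
    and log-residual-SD models; ``v_burst`` the individual-by-burst
    mean deviations.  For the reduced model ``omega``, ``rho`` and
    ``u_sigma`` are zero.
    """

    beta: np.ndarray                  # (6,) incl. intercept
    gamma: np.ndarray                 # (3,) incl. intercept
    sigma_id_mu: float
    omega: float
    rho: float
    sigma_id_burst: float
    u_mu: np.ndarray
    u_sigma: np.ndarray
    v_burst: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != (6,) or self.gamma.shape != (3,):
            raise ParameterDomainError("beta must have 6 and gamma 3 entries")
        for name in ("sigma_id_mu", "omega", "sigma_id_burst"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ParameterDomainError("rho must lie in [-1, 1]")
        self.u_mu = np.asarray(self.u_mu, dtype=float)
        self.u_sigma = np.asarray(self.u_sigma, dtype=float)
        self.v_burst = np.asarray(self.v_burst, dtype=float)
        if self.u_mu.shape != self.u_sigma.shape:
            raise ParameterDomainError("u_mu and u_sigma lengths differ")

    @property
    def cov_id(self) -> np.ndarray:
        """The implied 2x2 among-individual covariance matrix."""
        cov = self.rho * self.sigma_id_mu * self.omega
        return np.array(
            [[self.sigma_id_mu ** 2, cov], [cov, self.omega ** 2]]
        )


@dataclass
class MCMCSettings:
    """Sampler settings; ``desk()`` is the documented default profile."""

    chains: int = 3
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.85
    max_depth: int = 10
    init_jitter: float = 0.5
    rhat_max: float = 1.01
    ess_min: float = 400.0

    @classmethod
    def desk(cls) -> "MCMCSettings":
        return cls()

    @classmethod
    def reduced(cls) -> "MCMCSettings":
        """Short-chain profile for replicated simulation studies."""
        return cls(chains=2, warmup=500, draws=500)


@dataclass
class Posterior:
    """MCMC draws with convergence summaries and pointwise likelihoods."""

    draws: dict                      # name -> (chain, draw, ...) arrays
    pointwise_loglik: np.ndarray     # (chain, draw, n_obs)
    convergence: pd.DataFrame
    converged: bool
    sampler_stats: list
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.pointwise_loglik.shape[0]

    @property
    def n_draws(self) -> int:
        return self.pointwise_loglik.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All post-warmup draws of a parameter, chains concatenated."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={k: v for k, v in self.draws.items()},
            log_likelihood={"y": self.pointwise_loglik},
        )

    # -- serialization (chain x draw x parameter, self-describing) -------
    def save(self, path) -> None:
        import json

        payload = {f"draw_{k}": v for k, v in self.draws.items()}
        meta = {
            "meta": self.meta,
            "converged": bool(self.converged),
            "convergence": self.convergence.reset_index().to_dict("list"),
            "format_version": 1,
        }
        np.savez(
            path,
            pointwise_loglik=self.pointwise_loglik,
            meta_json=np.frombuffer(json.dumps(meta).encode(),
                                    dtype=np.uint8),
            **payload,
        )

    @classmethod
    def load(cls, path) -> "Posterior":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            draws = {
                k[5:]: z[k] for k in z.files if k.startswith("draw_")
            }
            conv = pd.DataFrame(meta["convergence"]).set_index("parameter")
            return cls(
                draws=draws,
                pointwise_loglik=z["pointwise_loglik"],
                convergence=conv,
                converged=meta["converged"],
                sampler_stats=[],
                meta=meta["meta"],
            )


# ---------------------------------------------------------------------------
# model definition
# ---------------------------------------------------------------------------

class DHGLM:
    """Joint density of the doubly hierarchical model on prepared data.

    ``heterogeneous=False`` gives the reduced model: no individual
    effect in the residual model, hence no among-individual correlation.
    """

    def __init__(self, prepared: PreparedData, heterogeneous: bool = True,
                 priors: Optional[PriorConfig] = None):
        self.prepared = prepared
        self.heterogeneous = heterogeneous
        self.priors = priors or PriorConfig()
        self.y = prepared.y
        self.xm = prepared.x_mean
        self.xr = prepared.x_resid
        self.j = prepared.j_index
        self.k = prepared.k_index
        self.n_obs = prepared.n_obs
        self.n_id = prepared.n_id
        self.n_cell = prepared.n_cell
        # unconstrained layout: beta(6) gamma(3) log-sds(2 or 3) [z_rho]
        #   zu0(n_id) [zu1(n_id)] zv(n_cell)
        self._n_sds = 3 if heterogeneous else 2
        self._head = 9 + self._n_sds + (1 if heterogeneous else 0)
        self.dim = self._head + (2 if heterogeneous else 1) * self.n_id \
            + self.n_cell

    # -- likelihood ------------------------------------------------------
    def predicted_moments(self, params: ModelParams):
        """Per-observation expected value and residual SD."""
        mu = (
            params.beta[0]
            + self.xm @ params.beta[1:]
            + params.u_mu[self.j]
            + params.v_burst[self.k]
        )
        log_sd = (
            params.gamma[0]
            + self.xr @ params.gamma[1:]
            + params.u_sigma[self.j]
        )
        return mu, np.exp(log_sd)

    def log_likelihood(self, params: ModelParams) -> float:
        """Gaussian log likelihood summed over observations."""
        mu, sd = self.predicted_moments(params)
        r = (self.y - mu) / sd
        out = float(
            -0.5 * self.n_obs * _LOG_2PI - np.sum(np.log(sd))
            - 0.5 * np.sum(r * r)
        )
        if not np.isfinite(out):
            raise ParameterDomainError(
                "non-finite log likelihood at the supplied parameters"
            )
        return out

    def log_prior(self, params: ModelParams) -> float:
        """Normalized log prior density, including the random effects."""
        pr = self.priors
        lp = float(np.sum(sps.norm.logpdf(params.beta, 0, pr.beta_scale)))
        lp += float(np.sum(sps.norm.logpdf(params.gamma, 0, pr.beta_scale)))
        sds = [params.sigma_id_mu, params.sigma_id_burst]
        if self.heterogeneous:
            sds.append(params.omega)
        for s in sds:
            lp += math.log(2.0) + float(
                sps.t.logpdf(s, pr.sd_df, scale=pr.sd_scale)
            )
        if self.heterogeneous:
            if not -1.0 < params.rho < 1.0:
                raise ParameterDomainError("rho must lie strictly in (-1, 1)")
            eta = pr.lkj_eta
            # 2x2 LKJ: (rho+1)/2 ~ Beta(eta, eta)
            lp += (
                (eta - 1.0) * math.log1p(-params.rho ** 2)
                - (2.0 * eta - 1.0) * math.log(2.0)
                - float(betaln(eta, eta))
            )
            cov = params.cov_id
            lp += float(
                sps.multivariate_normal.logpdf(
                    np.column_stack([params.u_mu, params.u_sigma]),
                    mean=np.zeros(2), cov=cov, allow_singular=True,
                ).sum()
            )
        else:
            lp += float(
                np.sum(sps.norm.logpdf(params.u_mu, 0, params.sigma_id_mu))
            )
        lp += float(
            np.sum(sps.norm.logpdf(params.v_burst, 0, params.sigma_id_burst))
        )
        return lp

    # -- unconstrained parameterization ---------------------------------
    def params_from_unconstrained(self, theta: np.ndarray) -> ModelParams:
        beta = theta[0:6]
        gamma = theta[6:9]
        sigma_mu = math.exp(theta[9])
        if self.heterogeneous:
            omega = math.exp(theta[10])
            sigma_b = math.exp(theta[11])
            rho = math.tanh(theta[12])
            z0 = theta[self._head:self._head + self.n_id]
            z1 = theta[self._head + self.n_id:self._head + 2 * self.n_id]
            zv = theta[self._head + 2 * self.n_id:]
            u_mu = sigma_mu * z0
            u_sigma = omega * (rho * z0 + math.sqrt(1 - rho ** 2) * z1)
        else:
            omega, rho = 0.0, 0.0
            sigma_b = math.exp(theta[10])
            z0 = theta[self._head:self._head + self.n_id]
            zv = theta[self._head + self.n_id:]
            u_mu = sigma_mu * z0
            u_sigma = np.zeros(self.n_id)
        return ModelParams(
            beta=beta, gamma=gamma, sigma_id_mu=sigma_mu, omega=omega,
            rho=rho, sigma_id_burst=sigma_b, u_mu=u_mu, u_sigma=u_sigma,
            v_burst=sigma_b * zv,
        )

    def logp_grad(self, theta: np.ndarray):
        """Log joint density and gradient on the unconstrained scale.

        The random effects are non-centred (standard-normal raw
        vectors), SDs live on the log scale with the Jacobian included,
        and ``rho = tanh(z)``; normalizing constants independent of the
        parameters are dropped except the Gaussian -n/2 log(2 pi).
        """
        pr = self.priors
        het = self.heterogeneous
        beta = theta[0:6]
        gamma = theta[6:9]
        ls_mu = theta[9]
        if het:
            lo, lsb, z_rho = theta[10], theta[11], theta[12]
        else:
            lsb = theta[10]
        head = self._head
        z0 = theta[head:head + self.n_id]
        if het:
            z1 = theta[head + self.n_id:head + 2 * self.n_id]
            zv = theta[head + 2 * self.n_id:]
        else:
            zv = theta[head + self.n_id:]

        grad = np.zeros_like(theta)
        if het and abs(z_rho) > 18.0:
            # tanh saturates to +/-1 in float precision; the LKJ density
            # is effectively zero there
            return -np.inf, grad
        if abs(ls_mu) > _LOG_SD_BOUND or abs(lsb) > _LOG_SD_BOUND or (
            het and abs(lo) > _LOG_SD_BOUND
        ):
            return -np.inf, grad
        sigma_mu = math.exp(ls_mu)
        sigma_b = math.exp(lsb)
        if het:
            omega = math.exp(lo)
            rho = math.tanh(z_rho)
            c = math.sqrt(max(1.0 - rho * rho, 1e-300))
            u_sigma = omega * (rho * z0 + c * z1)
        else:
            omega, rho, c = 0.0, 0.0, 1.0
            u_sigma = None
        u_mu = sigma_mu * z0
        v = sigma_b * zv

        g_beta = np.zeros(6)
        g_gamma = np.zeros(3)
        g_umu = np.zeros(self.n_id)
        g_usig = np.zeros(self.n_id)
        g_v = np.zeros(self.n_cell)
        logp = _loglik_grad_kernel(
            self.y, self.xm, self.xr, self.j, self.k, beta, gamma, u_mu,
            u_sigma if het else g_usig, v, het,
            g_beta, g_gamma, g_umu, g_usig, g_v,
        )
        if not np.isfinite(logp):
            return -np.inf, grad
        grad[0:6] = g_beta
        grad[6:9] = g_gamma

        # chain rule into the non-centred raws and log-SDs
        g_z0 = sigma_mu * g_umu
        if het:
            g_z0 = g_z0 + omega * rho * g_usig
            g_z1 = omega * c * g_usig
            grad[10] = float(np.dot(u_sigma, g_usig))
            grad[12] = omega * float(
                np.dot(z0 - (rho / c) * z1, g_usig)
            ) * (c * c)
        grad[9] = float(np.dot(u_mu, g_umu))
        grad[11 if het else 10] = float(np.dot(v, g_v))

        # priors -----------------------------------------------------
        s2 = pr.beta_scale ** 2
        logp += -0.5 * (float(np.dot(beta, beta))
                        + float(np.dot(gamma, gamma))) / s2
        grad[0:6] -= beta / s2
        grad[6:9] -= gamma / s2

        nu, A = pr.sd_df, pr.sd_scale
        sds = [(9, sigma_mu), (11 if het else 10, sigma_b)]
        if het:
            sds.append((10, omega))
        for idx, s in sds:
            logp += -(nu + 1.0) / 2.0 * math.log1p(s * s / (nu * A * A)) \
                + math.log(s)
            grad[idx] += -(nu + 1.0) * s * s / (nu * A * A + s * s) + 1.0

        if het:
            # LKJ(eta) with the tanh Jacobian folded in
            logp += pr.lkj_eta * math.log1p(-rho * rho)
            grad[12] += -2.0 * pr.lkj_eta * rho

        logp += -0.5 * float(np.dot(z0, z0)) - 0.5 * float(np.dot(zv, zv))
        grad[head:head + self.n_id] = g_z0 - z0
        if het:
            logp += -0.5 * float(np.dot(z1, z1))
            grad[head + self.n_id:head + 2 * self.n_id] = g_z1 - z1
            grad[head + 2 * self.n_id:] = sigma_b * g_v - zv
        else:
            grad[head + self.n_id:] = sigma_b * g_v - zv
        return logp, grad

    # -- pointwise likelihood for draws ----------------------------------
    def pointwise_loglik(self, draws: dict, block: int = 256) -> np.ndarray:
        """Per-draw, per-observation Gaussian log density, conditioning on
        the individual-level random effects (within-individual focus)."""
        beta = draws["beta"]
        chains, ndraw = beta.shape[:2]
        out = np.empty((chains, ndraw, self.n_obs))
        het = "u_sigma" in draws
        for cidx in range(chains):
            for start in range(0, ndraw, block):
                sl = slice(start, min(start + block, ndraw))
                b = draws["beta"][cidx, sl]
                g = draws["gamma"][cidx, sl]
                um = draws["u_mu"][cidx, sl]
                vb = draws["v_burst"][cidx, sl]
                mu = (
                    b[:, [0]] + b[:, 1:] @ self.xm.T
                    + um[:, self.j] + vb[:, self.k]
                )
                log_sd = g[:, [0]] + g[:, 1:] @ self.xr.T
                if het:
                    log_sd = log_sd + draws["u_sigma"][cidx, sl][:, self.j]
                r = (self.y[None, :] - mu) * np.exp(-log_sd)
                out[cidx, sl] = -0.5 * _LOG_2PI - log_sd - 0.5 * r * r
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_data(prepared: PreparedData) -> None:
    if prepared.n_id < 2:
        raise DegenerateDataError(
            "at least two individuals are required to separate "
            "among-individual from residual variation"
        )


def _collect_draws(model: DHGLM, chains_theta: np.ndarray) -> dict:
    """Map raw chains (chain, draw, dim) onto named constrained arrays."""
    het = model.heterogeneous
    n_id, head = model.n_id, model._head
    th = chains_theta
    draws = {
        "beta": th[..., 0:6],
        "gamma": th[..., 6:9],
        "sigma_id_mu": np.exp(th[..., 9]),
        "sigma_id_burst": np.exp(th[..., 11 if het else 10]),
    }
    z0 = th[..., head:head + n_id]
    draws["u_mu"] = draws["sigma_id_mu"][..., None] * z0
    if het:
        draws["omega"] = np.exp(th[..., 10])
        draws["rho"] = np.tanh(th[..., 12])
        z1 = th[..., head + n_id:head + 2 * n_id]
        c = np.sqrt(1.0 - draws["rho"] ** 2)
        draws["u_sigma"] = draws["omega"][..., None] * (
            draws["rho"][..., None] * z0 + c[..., None] * z1
        )
        zv = th[..., head + 2 * n_id:]
    else:
        zv = th[..., head + n_id:]
    draws["v_burst"] = draws["sigma_id_burst"][..., None] * zv
    return draws


def _convergence_table(draws: dict, names: tuple) -> pd.DataFrame:
    import arviz as az

    rows = []
    for name in names:
        if name.startswith("beta"):
            arr = draws["beta"][..., int(name[4:])]
        elif name.startswith("gamma"):
            arr = draws["gamma"][..., int(name[5:])]
        else:
            arr = draws[name]
        data = az.convert_to_dataset({name: arr})
        rhat = float(az.rhat(data)[name]) if arr.shape[0] > 1 else np.nan
        ess_b = float(az.ess(data, method="bulk")[name])
        ess_t = float(az.ess(data, method="tail")[name])
        rows.append({"parameter": name, "rhat": rhat,
                     "ess_bulk": ess_b, "ess_tail": ess_t})
    return pd.DataFrame(rows).set_index("parameter")


def _fit(prepared: PreparedData, heterogeneous: bool,
         priors: Optional[PriorConfig], mcmc: Optional[MCMCSettings],
         seed: int) -> Posterior:
    _check_data(prepared)
    mcmc = mcmc or MCMCSettings.desk()
    model = DHGLM(prepared, heterogeneous=heterogeneous, priors=priors)
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(mcmc.chains)
    all_draws = np.empty((mcmc.chains, mcmc.draws, model.dim))
    stats = []
    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        theta0 = mcmc.init_jitter * rng.standard_normal(model.dim)
        draws_c, st = sample_nuts(
            model.logp_grad, theta0, mcmc.warmup, mcmc.draws, rng,
            target_accept=mcmc.target_accept, max_depth=mcmc.max_depth,
        )
        all_draws[c] = draws_c
        stats.append(st)

    named = _collect_draws(model, all_draws)
    names = SCALAR_PARAMS_FULL if heterogeneous else SCALAR_PARAMS_REDUCED
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conv = _convergence_table(named, names)
    bad = conv[
        (conv["rhat"].fillna(1.0) > mcmc.rhat_max)
        | (conv["ess_bulk"] < mcmc.ess_min)
        | (conv["ess_tail"] < mcmc.ess_min)
    ]
    converged = bad.empty and all(s.divergences == 0 for s in stats)
    if not converged:
        offenders = ", ".join(bad.index) if not bad.empty else "divergences"
        warnings.warn(
            f"MCMC convergence diagnostics flagged: {offenders} "
            f"(rhat > {mcmc.rhat_max} or ESS < {mcmc.ess_min}); "
            "inspect Posterior.convergence before trusting summaries",
            RuntimeWarning,
        )

    pointwise = model.pointwise_loglik(named)
    meta = {
        "model": "full" if heterogeneous else "reduced",
        "seed": seed,
        "mcmc": vars(mcmc).copy(),
        "priors": vars(model.priors).copy(),
        "transform_record": dict(prepared.transform_record),
        "divergences": [s.divergences for s in stats],
    }
    return Posterior(
        draws=named, pointwise_loglik=pointwise, convergence=conv,
        converged=converged, sampler_stats=stats, meta=meta,
    )


def fit_full(prepared: PreparedData, priors: Optional[PriorConfig] = None,
             mcmc: Optional[MCMCSettings] = None, seed: int = 0) -> Posterior:
    """Fit the full model (heterogeneous residual SDs with individual
    rIIV effects correlated with the mean intercepts)."""
    return _fit(prepared, True, priors, mcmc, seed)


def fit_reduced(prepared: PreparedData, priors: Optional[PriorConfig] = None,
                mcmc: Optional[MCMCSettings] = None, seed: int = 0
                ) -> Posterior:
    """Fit the reduced model: residual model without the individual
    effect, i.e. homogeneous predictability."""
    return _fit(prepared, False, priors, mcmc, seed)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_draws(draws: np.ndarray, level: float = 0.95):
    """Posterior mean, median and equal-tailed interval of a 1-D sample."""
    draws = np.asarray(draws, dtype=float).ravel()
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return {
        "mean": float(np.mean(draws)),
        "median": float(np.median(draws)),
        "sd": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
        "lower": float(lo),
        "upper": float(hi),
    }


def summarize(posterior: Posterior, level: float = 0.95) -> pd.DataFrame:
    """Point estimates and equal-tailed credible intervals per parameter."""
    het = "omega" in posterior.draws
    names = SCALAR_PARAMS_FULL if het else SCALAR_PARAMS_REDUCED
    rows = {}
    for name in names:
        if name.startswith("beta"):
            arr = posterior.draws["beta"][..., int(name[4:])]
        elif name.startswith("gamma"):
            arr = posterior.draws["gamma"][..., int(name[5:])]
        else:
            arr = posterior.draws[name]
        rows[name] = summarize_draws(arr, level)
    table = pd.DataFrame(rows).T
    table.index.name = "parameter"
    return table.join(posterior.convergence, how="left")


def require_converged(posterior: Posterior) -> Posterior:
    """Raise :class:`ConvergenceError` unless the fit met its thresholds."""
    if not posterior.converged:
        bad = posterior.convergence
        raise ConvergenceError(
            "fit did not meet convergence thresholds:\n" + bad.to_string()
        )
    return posterior
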