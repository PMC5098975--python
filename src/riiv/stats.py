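"""Derived quantities: repeatabilities, predictability CV, fold ratios.

All statistics are closed forms in the variance components of the
fitted model and are offered both as plug-in evaluations and per
posterior draw with equal-tailed interval summaries.

Notation: ``sigma_id_mu`` is the among-individual SD of mean
intercepts, ``sigma_id_burst`` the SD of individual-by-burst
deviations, ``exp(gamma0)`` the average residual SD, and ``omega`` the
among-individual SD of the log residual SD (the rIIV effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterDomainError
from .model import Posterior, summarize_draws

__all__ = [
    "repeatability_int", "repeatability_short", "repeatability_long",
    "cv_p", "fold_ratio", "corr_from_cov", "derive_posterior",
    "DerivedStats",
]


def repeatability_int(sigma_id_mu, sigma_id_burst):
    """Repeatability of individual intercepts across bursts.

    ``sigma_id_mu**2 / (sigma_id_mu**2 + sigma_id_burst**2)`` — the
    proportion of the among-plus-between-burst variance in individual
    mean values that is stable across bursts.
    """
    s2, b2 = np.square(sigma_id_mu), np.square(sigma_id_burst)
    denom = s2 + b2
    if np.any(np.asarray(denom) == 0):
        raise ParameterDomainError(
            "repeatability of intercepts is undefined when both variance "
            "components are zero"
        )
    return s2 / denom


def repeatability_short(sigma_id_mu, sigma_id_burst, gamma0):
    """Short-term (conditional) repeatability: within-burst consistency.

    ``(sigma_id_mu**2 + sigma_id_burst**2) / (sigma_id_mu**2 +
    sigma_id_burst**2 + exp(gamma0)**2)``.
    """
    s2, b2 = np.square(sigma_id_mu), np.square(sigma_id_burst)
    e2 = np.exp(np.asarray(gamma0, dtype=float)) ** 2
    return (s2 + b2) / (s2 + b2 + e2)


def repeatability_long(sigma_id_mu, sigma_id_burst, gamma0):
    """Long-term (unconditional) repeatability across the whole study.

    ``sigma_id_mu**2 / (sigma_id_mu**2 + sigma_id_burst**2 +
    exp(gamma0)**2)`` — never exceeds the short-term value.
    """
    s2, b2 = np.square(sigma_id_mu), np.square(sigma_id_burst)
    e2 = np.exp(np.asarray(gamma0, dtype=float)) ** 2
    return s2 / (s2 + b2 + e2)


def cv_p(omega):
    """Coefficient of variation in predictability.

    The individual residual SDs are log-normal with log-scale SD
    ``omega``, so their coefficient of variation is
    ``sqrt(exp(omega**2) - 1)``; for small ``omega`` this approaches
    ``omega`` itself.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ParameterDomainError("omega must be non-negative")
    return np.sqrt(np.expm1(np.square(omega)))


def fold_ratio(omega, k: float = 2.0, scale: str = "variance"):
    """Residual-variation ratio between individuals ``k`` SDs above and
    below the average rIIV.

    The log residual SD differs by ``2*k*omega`` between the two
    hypothetical individuals, so their residual SDs differ by
    ``exp(2*k*omega)``-fold and their residual variances by
    ``exp(2 * 2*k*omega)``-fold.
    """
    if k <= 0:
        raise ParameterDomainError("k must be positive")
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ParameterDomainError("omega must be non-negative")
    if scale == "variance":
        return np.exp(2.0 * (2.0 * k * omega))
    if scale == "sd":
        return np.exp(2.0 * k * omega)
    raise ParameterDomainError(f"scale must be 'variance' or 'sd', got {scale!r}")


def corr_from_cov(cov, sigma_id_mu, omega, tol: float = 1e-8):
    """Correlation between individual mean and log-residual-SD effects."""
    sigma_id_mu = np.asarray(sigma_id_mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(sigma_id_mu <= 0) or np.any(omega <= 0):
        raise ParameterDomainError(
            "correlation undefined when either SD is zero"
        )
    r = np.asarray(cov, dtype=float) / (sigma_id_mu * omega)
    if np.any(np.abs(r) > 1 + tol):
        raise ParameterDomainError(
            f"implied correlation {r} exceeds 1 beyond tolerance"
        )
    return np.clip(r, -1.0, 1.0)


@dataclass
class DerivedStats:
    """Per-draw derived statistics plus their summary table."""

    per_draw: pd.DataFrame       # one row per posterior draw
    summary: pd.DataFrame        # mean/median/interval per statistic
    plug_in: pd.Series           # closed forms at the posterior means

    def round_table(self, decimals: int = 2) -> pd.DataFrame:
        """Summary rounded for reporting; full precision stays inside."""
        return self.summary.round(decimals)


def derive_posterior(posterior: Posterior, level: float = 0.95,
                     fold_k: float = 2.0) -> DerivedStats:
    """Compute every derived statistic per posterior draw and summarize.

    Each statistic is evaluated draw by draw (so the intervals are
    genuine posterior intervals of the statistic), and additionally as
    a plug-in at the posterior means of the components, labelled
    separately since the two need not agree for nonlinear maps.
    """
    s_mu = posterior.stacked("sigma_id_mu")
    s_b = posterior.stacked("sigma_id_burst")
    g0 = posterior.stacked("gamma")[:, 0]
    cols = {
        "R_int": repeatability_int(s_mu, s_b),
        "R_short": repeatability_short(s_mu, s_b, g0),
        "R_long": repeatability_long(s_mu, s_b, g0),
    }
    if "omega" in posterior.draws:
        om = posterior.stacked("omega")
        cols["CV_P"] = cv_p(om)
        cols["fold_ratio"] = fold_ratio(om, k=fold_k)
        cols["rho_mean_riiv"] = posterior.stacked("rho")
    per_draw = pd.DataFrame(cols)
    summary = pd.DataFrame(
        {name: summarize_draws(vals, level) for name, vals in cols.items()}
    ).T
    summary.index.name = "statistic"

    plug = {
        "R_int": float(repeatability_int(s_mu.mean(), s_b.mean())),
        "R_short": float(
            repeatability_short(s_mu.mean(), s_b.mean(), g0.mean())
        ),
        "R_long": float(
            repeatability_long(s_mu.mean(), s_b.mean(), g0.mean())
        ),
    }
    if "omega" in posterior.draws:
        plug["CV_P"] = float(cv_p(om.mean()))
        plug["fold_ratio"] = float(fold_ratio(om.mean(), k=fold_k))
        plug["rho_mean_riiv"] = float(posterior.stacked("rho").mean())
    plug_in = pd.Series(plug, name="plug_in")
    return DerivedStats(per_draw=per_draw, summary=summary, plug_in=plug_in)
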