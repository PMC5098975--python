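"""Goodness-of-fit checks at every level of the hierarchy.

The model assumes normality at three levels: the individual effects,
the individual-by-burst deviations, and the observation-level
residuals (after scaling each by its own predicted SD).  ``diagnose``
evaluates all three with Shapiro–Wilk statistics at the posterior
means, tabulates the per-individual spread of standardized residuals
(the numerical counterpart of plotting residuals individual by
individual), and summarizes fitted-versus-residual structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import PreparedData
from .model import DHGLM, ModelParams, Posterior

__all__ = ["DiagnosticsReport", "diagnose", "posterior_mean_params"]


def posterior_mean_params(posterior: Posterior) -> ModelParams:
    """Posterior means of every parameter, as one parameter point."""
    d = posterior.draws
    het = "omega" in d

    def m(name):
        return d[name].mean(axis=(0, 1))

    n_id = d["u_mu"].shape[-1]
    return ModelParams(
        beta=m("beta"),
        gamma=m("gamma"),
        sigma_id_mu=float(m("sigma_id_mu")),
        omega=float(m("omega")) if het else 0.0,
        rho=float(m("rho")) if het else 0.0,
        sigma_id_burst=float(m("sigma_id_burst")),
        u_mu=m("u_mu"),
        u_sigma=m("u_sigma") if het else np.zeros(n_id),
        v_burst=m("v_burst"),
    )


@dataclass
class DiagnosticsReport:
    """Residuals, level-wise normality checks, and per-ID spread."""

    fitted: np.ndarray           # posterior-mean expected values
    std_resid: np.ndarray        # (y - fitted) / predicted residual SD
    normality: pd.DataFrame      # Shapiro-Wilk stat & p per level
    per_id: pd.DataFrame         # residual spread per individual
    fitted_vs_resid: dict        # simple association summaries
    convergence: pd.DataFrame

    @property
    def spread_ratio(self) -> float:
        """Ratio of largest to smallest per-individual residual SD."""
        sds = self.per_id["resid_sd"]
        return float(sds.max() / sds.min())

    def normality_ok(self, alpha: float = 0.05) -> bool:
        return bool((self.normality["pvalue"] > alpha).all())


def diagnose(posterior: Posterior, prepared: PreparedData,
             min_obs_per_id: int = 3) -> DiagnosticsReport:
    """Model checking at the posterior means.

    Standardized residuals use each observation's own predicted
    residual SD, so under the full model they should be standard
    normal regardless of how much individuals differ in rIIV; under
    the reduced model fitted to heterogeneous data the per-individual
    residual SDs in ``per_id`` spread far apart instead.
    """
    params = posterior_mean_params(posterior)
    model = DHGLM(prepared, heterogeneous="omega" in posterior.draws)
    mu, sd = model.predicted_moments(params)
    std_resid = (prepared.y - mu) / sd

    levels = {
        "id_effects": params.u_mu,
        "id_burst_effects": params.v_burst,
        "residuals": std_resid,
    }
    rows = []
    for name, values in levels.items():
        values = np.asarray(values, dtype=float)
        if values.size >= 3:
            stat, p = sps.shapiro(values)
        else:
            stat, p = np.nan, np.nan
        rows.append({"level": name, "statistic": float(stat),
                     "pvalue": float(p), "n": int(values.size)})
    normality = pd.DataFrame(rows).set_index("level")

    per_id_rows = []
    for j in range(prepared.n_id):
        mask = prepared.j_index == j
        if mask.sum() < min_obs_per_id:
            continue
        per_id_rows.append(
            {
                "individual": prepared.indices.id_labels[j],
                "n_obs": int(mask.sum()),
                "resid_sd": float(np.std(std_resid[mask], ddof=1)),
                "mean_fitted": float(np.mean(mu[mask])),
                "u_mu": float(params.u_mu[j]),
                "u_sigma": float(params.u_sigma[j]),
            }
        )
    per_id = pd.DataFrame(per_id_rows).set_index("individual")

    fitted_vs_resid = {
        "corr_fitted_resid": float(np.corrcoef(mu, std_resid)[0, 1]),
        "corr_fitted_absresid": float(
            np.corrcoef(mu, np.abs(std_resid))[0, 1]
        ),
        "resid_mean": float(np.mean(std_resid)),
        "resid_sd": float(np.std(std_resid, ddof=1)),
    }
    return DiagnosticsReport(
        fitted=mu,
        std_resid=std_resid,
        normality=normality,
        per_id=per_id,
        fitted_vs_resid=fitted_vs_resid,
        convergence=posterior.convergence,
    )
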