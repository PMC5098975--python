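"""Model comparison by the Watanabe–Akaike information criterion.

WAIC is computed from the matrix of pointwise posterior log
likelihoods: the log pointwise predictive density (lppd) via a
log-sum-exp over draws, and the effective parameter count as the sum
over observations of the per-observation variance of the log
likelihood across draws.  The pointwise terms here condition on the
individual-level random effects, so the criterion targets
within-individual prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DataValidationError

__all__ = ["WaicResult", "waic", "compare", "ComparisonResult"]


@dataclass
class WaicResult:
    """WAIC and its components; pointwise arrays kept for differencing."""

    lppd: float
    p_waic: float
    waic: float
    se_waic: float
    pointwise: np.ndarray        # per-observation -2*(lppd_i - p_i)
    n_obs: int
    n_draws: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WAIC = {self.waic:.1f} (SE {self.se_waic:.1f}); "
            f"lppd = {self.lppd:.1f}, p_waic = {self.p_waic:.1f}, "
            f"n = {self.n_obs}"
        )


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a draws-by-observations log-likelihood matrix.

    Accepts either ``(draws, obs)`` or ``(chain, draw, obs)``; chains
    are pooled.  Uses log-sum-exp stabilization for the lppd and the
    sample variance (ddof=1) across draws for the penalty.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise DataValidationError(
            "pointwise log-likelihood must be 2-D (draws x obs) or 3-D "
            "(chain x draw x obs)"
        )
    if not np.isfinite(ll).all():
        bad = np.argwhere(~np.isfinite(ll))
        raise DataValidationError(
            f"non-finite log-likelihood at (draw, obs) = {bad[0].tolist()}"
        )
    s, n = ll.shape
    if s < 2 or n < 1:
        raise DataValidationError("need at least 2 draws and 1 observation")

    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = np.var(ll, axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    waic_i = -2.0 * elpd_i
    total = float(np.sum(waic_i))
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(
        lppd=float(np.sum(lppd_i)),
        p_waic=float(np.sum(p_i)),
        waic=total,
        se_waic=se,
        pointwise=waic_i,
        n_obs=n,
        n_draws=s,
    )


@dataclass
class ComparisonResult:
    """Difference in WAIC between a reduced and a full model."""

    waic_full: float
    waic_reduced: float
    delta_waic: float            # reduced - full; positive favours full
    se_delta: float
    favours: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WAIC full = {self.waic_full:.1f}, "
            f"reduced = {self.waic_reduced:.1f}; "
            f"delta = {self.delta_waic:.1f} (SE {self.se_delta:.1f}), "
            f"favours {self.favours}"
        )


def compare(full: WaicResult, reduced: WaicResult) -> ComparisonResult:
    """Compare two WAIC results computed on identical observations.

    ``delta_waic = reduced - full`` so a positive difference favours
    the full (heterogeneous-residual) model; the SE comes from the
    pointwise differences, as for any paired comparison.
    """
    if full.n_obs != reduced.n_obs:
        raise DataValidationError(
            f"observation counts differ: {full.n_obs} vs {reduced.n_obs}"
        )
    diff_i = reduced.pointwise - full.pointwise
    delta = float(np.sum(diff_i))
    se = (
        float(np.sqrt(full.n_obs * np.var(diff_i, ddof=1)))
        if full.n_obs > 1 else 0.0
    )
    favours = "full" if delta > 0 else ("reduced" if delta < 0 else "neither")
    return ComparisonResult(
        waic_full=full.waic,
        waic_reduced=reduced.waic,
        delta_waic=delta,
        se_delta=se,
        favours=favours,
    )
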