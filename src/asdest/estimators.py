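"""Naive and conditionally unbiased (UMVUE) estimators after selection.

When S is selected the estimand is ``theta_S``; when F is selected it is
``theta_F = p_S * theta_S + (1 - p_S) * theta_Sc``.  The naive estimators
are ordinary two-stage pooled mean differences and are biased conditional
on the data-driven selection.  The UMVUEs arise by Rao-Blackwellisation:
the stage-2 mean (unbiased given the selection event) is conditioned on a
complete sufficient statistic, which yields closed forms built from the
normal Mills ratio phi/Phi evaluated at a standardised distance between
the naive estimate and the selection threshold.

All closed forms substitute the observed stratum fraction ``s_X / n1``
for the prevalence inside the selection margin, so one code path serves
both the known- and the estimated-prevalence analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .trial_model import (
    DerivedQuantities,
    DesignConfig,
    Selection,
    SelectionDecision,
    StageSummaries,
    decide,
    derive_quantities,
)

__all__ = [
    "mills_ratio",
    "truncated_mills_ratio",
    "naive_selected_s",
    "naive_selected_f",
    "umvue_selected_s",
    "umvue_selected_f",
    "umvue_selected_s_futility",
    "umvue_selected_f_futility",
    "EstimateSet",
    "estimate",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _log_phi(f):
    return -0.5 * np.square(f) - _LOG_SQRT_2PI


def mills_ratio(f):
    """Stable normal Mills ratio ``phi(f) / Phi(f)``.

    Computed as ``exp(log phi(f) - log Phi(f))`` so that it neither
    underflows nor returns 0/0 for arguments far in the left tail, where
    the ratio grows like ``-f``.
    """
    f = np.asarray(f, dtype=float)
    out = np.exp(_log_phi(f) - special.log_ndtr(f))
    return out if out.ndim else float(out)


def truncated_mills_ratio(f, f_B):
    """Two-sided ratio ``(phi(f) - phi(f_B)) / (Phi(f) - Phi(f_B))``.

    Requires ``f_B < f`` (a non-empty truncation interval).  The
    denominator is evaluated as ``Phi(f) * (1 - exp(logPhi(f_B) -
    logPhi(f)))`` to stay accurate when both arguments sit in the left
    tail.
    """
    f = np.asarray(f, dtype=float)
    f_B = np.asarray(f_B, dtype=float)
    if np.any(f_B >= f):
        raise ValueError(
            "empty truncation interval: the futility cut-off argument must lie "
            "strictly below the selection argument (observed data outside the "
            "continuation region?)"
        )
    log_cdf_f = special.log_ndtr(f)
    denom = np.exp(log_cdf_f) * (-np.expm1(special.log_ndtr(f_B) - log_cdf_f))
    num = np.exp(_log_phi(f)) - np.exp(_log_phi(f_B))
    out = num / denom
    return out if out.ndim else float(out)


def _margin(b, n1, s_X):
    """Selection margin ``b / (1 - s_X / n1)`` on the x-vs-y scale."""
    return b / (1.0 - np.asarray(s_X, dtype=float) / n1)


# ---------------------------------------------------------------------------
# naive estimators

def naive_selected_s(x, u, t_S):
    """Two-stage pooled mean for theta_S when S is selected."""
    if np.any(np.asarray(t_S) <= 0) or np.any(np.asarray(t_S) >= 1):
        raise ValueError(f"stage-1 weight t_S must lie in (0, 1), got {t_S}")
    return t_S * x + (1.0 - t_S) * u


def naive_selected_f(x, y, v, w, q: DerivedQuantities, p_combine):
    """Two-stage pooled means when F is selected.

    Returns ``(d_S_N_F, d_Sc_N_F, d_F_N)`` where the full-population
    estimate combines the stratum components with weight ``p_combine``
    (the known prevalence, or the pooled two-stage estimate
    ``(s_X + s_V) / (n1 + n2)`` when the prevalence is unknown).
    """
    if q.t_S_F is None:
        raise ValueError("F-branch weights require s_V in the derived quantities")
    p = np.asarray(p_combine, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError(f"combination weight must lie in (0, 1), got {p_combine}")
    d_s = q.t_S_F * x + (1.0 - q.t_S_F) * v
    d_sc = q.t_Sc_F * y + (1.0 - q.t_Sc_F) * w
    return d_s, d_sc, p * d_s + (1.0 - p) * d_sc


# ---------------------------------------------------------------------------
# UMVUEs, known or estimated prevalence

def umvue_selected_s(x, y, u, q: DerivedQuantities, b: float, n1: int, s_X=None):
    """Rao-Blackwell UMVUE for theta_S when S is selected.

    Returns ``(d_S_U, f_U)``.  The correction subtracts
    ``tau_U^2 / sqrt(sigma_X^2 + tau_U^2)`` times the Mills ratio at
    ``f_U``, the standardised gap between the naive estimate and the
    selection threshold ``y + b / (1 - s_X/n1)``.
    """
    s_X = q.s_X if s_X is None else s_X
    d_n = naive_selected_s(x, u, q.t_S)
    root = np.sqrt(q.sigma2_X + q.tau2_U)
    f_U = root / q.sigma2_X * (d_n - (y + _margin(b, n1, s_X)))
    d_u = d_n - q.tau2_U / root * mills_ratio(f_U)
    return d_u, f_U


def umvue_selected_f(
    x, y, v, w, q: DerivedQuantities, b: float, n1: int, p_combine, s_X=None
):
    """Rao-Blackwell UMVUEs for theta_S, theta_Sc and theta_F when F is selected.

    Returns ``(d_S_U_F, d_Sc_U_F, d_F_U, f_V, f_W)``.  The S component is
    corrected upward (selection of F means X looked unpromising) and the
    S^c component downward.  ``p_combine`` is p_S when known or
    ``s_X / n1`` when estimated.
    """
    if q.tau2_V is None or q.tau2_W is None:
        raise ValueError("F-branch UMVUEs require s_V in the derived quantities")
    s_X = q.s_X if s_X is None else s_X
    d_s_n, d_sc_n, _ = naive_selected_f(x, y, v, w, q, p_combine)
    margin = _margin(b, n1, s_X)

    root_v = np.sqrt(q.sigma2_X + q.tau2_V)
    f_V = root_v / q.sigma2_X * ((y + margin) - d_s_n)
    d_s_u = d_s_n + q.tau2_V / root_v * mills_ratio(f_V)

    # Q_F is X <= Y + b/(1-p), i.e. Y >= X - b/(1-p): the S^c threshold.
    root_w = np.sqrt(q.sigma2_Y + q.tau2_W)
    f_W = root_w / q.sigma2_Y * (d_sc_n - (x - margin))
    d_sc_u = d_sc_n - q.tau2_W / root_w * mills_ratio(f_W)

    p = np.asarray(p_combine, dtype=float)
    d_f_u = p * d_s_u + (1.0 - p) * d_sc_u
    return d_s_u, d_sc_u, d_f_u, f_V, f_W


# ---------------------------------------------------------------------------
# futility-adjusted variants (known prevalence only)

def umvue_selected_s_futility(
    x, y, u, q: DerivedQuantities, b: float, n1: int, B: float, s_X=None
):
    """UMVUE for theta_S under the futility rule ``max(x, z) >= B``.

    The selection threshold inside ``f_U`` becomes
    ``max(B, y + b / (1 - p_S))``; with ``B`` below the selection
    threshold this reduces exactly to :func:`umvue_selected_s`.
    """
    s_X = q.s_X if s_X is None else s_X
    d_n = naive_selected_s(x, u, q.t_S)
    root = np.sqrt(q.sigma2_X + q.tau2_U)
    threshold = np.maximum(B, y + _margin(b, n1, s_X))
    f_U = root / q.sigma2_X * (d_n - threshold)
    d_u = d_n - q.tau2_U / root * mills_ratio(f_U)
    return d_u, f_U


def umvue_selected_f_futility(
    x, y, v, w, q: DerivedQuantities, b: float, n1: int, B: float, p_S: float, s_X=None
):
    """UMVUEs when F is selected and a futility bound ``B`` was passed.

    Continuation requires ``max(x, z) >= B``, which truncates X to the
    interval ``((B - (1 - p_S) y) / p_S,  y + b/(1-p_S))`` given Y: the S
    component becomes a doubly-truncated-normal mean with arguments
    ``f_V`` and ``f_V_B``.  The S^c single-truncation threshold becomes
    ``max(x - b/(1-p_S), (B - p_S x) / (1 - p_S))``.

    Returns ``(d_S_U_F, d_Sc_U_F, d_F_U, f_V, f_V_B, f_W)``.  The
    combination ``d_F_U`` is reported for completeness but is not claimed
    unbiased under futility (the naive combination provably is not).
    """
    if q.tau2_V is None or q.tau2_W is None:
        raise ValueError("F-branch UMVUEs require s_V in the derived quantities")
    s_X = q.s_X if s_X is None else s_X
    d_s_n, d_sc_n, _ = naive_selected_f(x, y, v, w, q, p_S)
    margin = _margin(b, n1, s_X)

    root_v = np.sqrt(q.sigma2_X + q.tau2_V)
    f_V = root_v / q.sigma2_X * ((y + margin) - d_s_n)
    f_V_B = root_v / q.sigma2_X * ((B - (1.0 - p_S) * y) / p_S - d_s_n)
    d_s_u = d_s_n + q.tau2_V / root_v * truncated_mills_ratio(f_V, f_V_B)

    root_w = np.sqrt(q.sigma2_Y + q.tau2_W)
    threshold = np.maximum(x - margin, (B - p_S * x) / (1.0 - p_S))
    f_W = root_w / q.sigma2_Y * (d_sc_n - threshold)
    d_sc_u = d_sc_n - q.tau2_W / root_w * mills_ratio(f_W)

    d_f_u = p_S * d_s_u + (1.0 - p_S) * d_sc_u
    return d_s_u, d_sc_u, d_f_u, f_V, f_V_B, f_W


# ---------------------------------------------------------------------------
# orchestration

@dataclass(frozen=True)
class EstimateSet:
    """All estimates for one completed trial, on the selected branch."""

    selected: Selection
    decision: SelectionDecision
    prevalence_used: dict
    futility_adjusted: bool = False
    # S branch
    d_S_N: float | None = None
    d_S_U: float | None = None
    f_U: float | None = None
    # F branch
    d_S_N_F: float | None = None
    d_Sc_N_F: float | None = None
    d_F_N: float | None = None
    d_S_U_F: float | None = None
    d_Sc_U_F: float | None = None
    d_F_U: float | None = None
    f_V: float | None = None
    f_V_B: float | None = None
    f_W: float | None = None

    def to_dict(self, precision: str = "full") -> dict:
        """Serialisable view; ``precision='paper'`` rounds estimates to 2 dp
        and f-arguments to the display precision used in reports (f_U 1 dp,
        f_V/f_W 2 dp)."""
        out = {
            "selected": self.selected.value,
            "futility_adjusted": self.futility_adjusted,
            "prevalence_used": dict(self.prevalence_used),
        }
        rounding = {"f_U": 1} if precision == "paper" else {}
        for name in (
            "d_S_N", "d_S_U", "f_U",
            "d_S_N_F", "d_Sc_N_F", "d_F_N",
            "d_S_U_F", "d_Sc_U_F", "d_F_U", "f_V", "f_V_B", "f_W",
        ):
            value = getattr(self, name)
            if value is None:
                continue
            if precision == "paper":
                value = round(float(value), rounding.get(name, 2))
            out[name] = float(value)
        return out


def estimate(config: DesignConfig, summaries: StageSummaries) -> EstimateSet:
    """Compute naive and unbiased estimates for one observed trial.

    The branch is taken from the populated stage-2 summaries and checked
    for consistency with the interim rule applied to the stage-1 data.
    In known-prevalence mode the stratum counts must match ``p_S * n``;
    in unknown-prevalence mode the observed counts drive everything, with
    ``p_hat = s_X / n1`` combining the F-branch UMVUEs and
    ``p_hat_star = (s_X + s_V) / (n1 + n2)`` combining the naive ones.
    """
    n1, n2 = config.n1, config.n2
    s_X = summaries.s_X
    decision = decide(config, summaries.x, summaries.y, s_X)
    if decision.outcome is Selection.STOP_FUTILITY:
        raise ValueError(
            "stage-1 data fall below the futility bound; no stage-2 estimate exists"
        )
    branch = summaries.stage2_branch
    if branch is None:
        raise ValueError("stage-2 summaries are required to form estimates")
    if branch is not decision.outcome:
        raise ValueError(
            f"stage-2 summaries are for branch {branch.value!r} but the interim "
            f"rule selects {decision.outcome.value!r} on these stage-1 data"
        )
    futility = config.has_futility_rule
    if futility and not config.prevalence_known:
        raise ValueError(
            "unsupported: futility-adjusted estimation with unknown prevalence"
        )

    prev: dict[str, float] = {"p_hat_S": s_X / n1}
    if config.prevalence_known:
        prev["p_S"] = config.p_S

    q = derive_quantities(config, s_X, summaries.s_V)

    if branch is Selection.SELECT_S:
        d_n = naive_selected_s(summaries.x, summaries.u, q.t_S)
        if futility:
            d_u, f_U = umvue_selected_s_futility(
                summaries.x, summaries.y, summaries.u, q, config.b, n1, config.B
            )
        else:
            d_u, f_U = umvue_selected_s(
                summaries.x, summaries.y, summaries.u, q, config.b, n1
            )
        return EstimateSet(
            selected=branch,
            decision=decision,
            prevalence_used=prev,
            futility_adjusted=futility,
            d_S_N=float(d_n),
            d_S_U=float(d_u),
            f_U=float(f_U),
        )

    # F branch
    p_hat_star = (s_X + summaries.s_V) / (n1 + n2)
    if config.prevalence_known:
        p_naive = p_umvue = config.p_S
    else:
        prev["p_hat_S_star"] = p_hat_star
        p_naive = p_hat_star
        p_umvue = s_X / n1
    d_s_n, d_sc_n, d_f_n = naive_selected_f(
        summaries.x, summaries.y, summaries.v, summaries.w, q, p_naive
    )
    f_V_B = None
    if futility:
        d_s_u, d_sc_u, d_f_u, f_V, f_V_B, f_W = umvue_selected_f_futility(
            summaries.x, summaries.y, summaries.v, summaries.w,
            q, config.b, n1, config.B, config.p_S,
        )
        warnings.warn(
            "with a futility rule the naive full-population estimate is biased "
            "and the combined adjusted estimate d_F_U carries no unbiasedness "
            "guarantee",
            stacklevel=2,
        )
    else:
        d_s_u, d_sc_u, d_f_u, f_V, f_W = umvue_selected_f(
            summaries.x, summaries.y, summaries.v, summaries.w,
            q, config.b, n1, p_umvue,
        )
    return EstimateSet(
        selected=branch,
        decision=decision,
        prevalence_used=prev,
        futility_adjusted=futility,
        d_S_N_F=float(d_s_n),
        d_Sc_N_F=float(d_sc_n),
        d_F_N=float(d_f_n),
        d_S_U_F=float(d_s_u),
        d_Sc_U_F=float(d_sc_u),
        d_F_U=float(d_f_u),
        f_V=float(f_V),
        f_V_B=None if f_V_B is None else float(f_V_B),
        f_W=float(f_W),
    )
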