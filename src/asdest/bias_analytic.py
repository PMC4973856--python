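"""Exact conditional bias of the naive estimators, by numerical quadrature.

Conditional on selecting S, the naive two-stage mean for theta_S inherits
the selection event ``X > Y + b/(1-p_S)`` through its stage-1 component,
so its bias is ``t_S * (E[X | X > Y*] - theta_S)``.  The required
quantities ``Pr(X > Y*)`` and ``E[X 1(X > Y*)]`` are one-dimensional
integrals of a normal density times a normal CDF and are evaluated with
adaptive quadrature; the complementary event gives the component biases
when F is selected.  Everything depends on ``(theta_S, theta_Sc)`` only
through their difference, and a margin ``b`` rigidly shifts the curves by
``b / (1 - p_S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr

from .trial_model import DesignConfig, derive_quantities

__all__ = [
    "prob_select_s",
    "trunc_moment_x_select_s",
    "trunc_moment_y_select_f",
    "bias_naive_s",
    "bias_components_f",
    "bias_point",
    "bias_curve",
    "se_selected_s",
    "se_selected_f",
    "BiasResult",
]

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-12, limit=400)
#: integration window in standard deviations of the outer density; the
#: integrand is bounded by the normal density, so the truncation error is
#: far below the quadrature tolerance.
_WINDOW = 13.0
_ABS_TOL = 1e-10
_MIN_PROB = 1e-12


def _phi(s):
    return math.exp(-0.5 * s * s) / math.sqrt(2.0 * math.pi)


def _quad(f, lo=-_WINDOW, hi=_WINDOW):
    value, abserr = integrate.quad(f, lo, hi, **_QUAD_OPTS)
    if abserr > _ABS_TOL:
        raise RuntimeError(
            f"bias quadrature did not converge: estimated error {abserr:.3e} "
            f"exceeds {_ABS_TOL:.0e}"
        )
    return value


def prob_select_s(theta_S, theta_Sc, sigma_X, sigma_Y, b=0.0, p_S=0.5):
    """``Pr(X > Y*)`` with ``Y* = Y + b/(1-p_S)`` for independent normal
    stage-1 means."""
    if sigma_X <= 0 or sigma_Y <= 0:
        raise ValueError("sigma_X and sigma_Y must be positive")
    theta_Sc_star = theta_Sc + b / (1.0 - p_S)

    def integrand(s):
        return _phi(s) * ndtr((theta_S + sigma_X * s - theta_Sc_star) / sigma_Y)

    return _quad(integrand)


def trunc_moment_x_select_s(theta_S, theta_Sc, sigma_X, sigma_Y, b=0.0, p_S=0.5):
    """``E[X 1(X > Y*)]``; the complementary moment is ``theta_S`` minus
    this value."""
    if sigma_X <= 0 or sigma_Y <= 0:
        raise ValueError("sigma_X and sigma_Y must be positive")
    theta_Sc_star = theta_Sc + b / (1.0 - p_S)

    def integrand(s):
        return (theta_S + sigma_X * s) * _phi(s) * ndtr(
            (theta_S + sigma_X * s - theta_Sc_star) / sigma_Y
        )

    return _quad(integrand)


def trunc_moment_y_select_f(theta_S, theta_Sc, sigma_X, sigma_Y, b=0.0, p_S=0.5):
    """``E[Y 1(X <= Y*)]``, the stage-1 moment of the S^c mean on the
    F-selection event."""
    if sigma_X <= 0 or sigma_Y <= 0:
        raise ValueError("sigma_X and sigma_Y must be positive")
    theta_S_star = theta_S - b / (1.0 - p_S)

    def integrand(s):
        return (theta_Sc + sigma_Y * s) * _phi(s) * ndtr(
            (theta_Sc + sigma_Y * s - theta_S_star) / sigma_X
        )

    return _quad(integrand)


def _stratum_sds(design: DesignConfig):
    if not design.prevalence_known:
        raise ValueError("analytic bias requires a known prevalence p_S")
    s_X, s_V = design.expected_counts()
    q = derive_quantities(design, s_X, s_V)
    return q, math.sqrt(q.sigma2_X), math.sqrt(q.sigma2_Y)


def bias_naive_s(design: DesignConfig, theta_S: float, theta_Sc: float) -> float:
    """Conditional bias of the naive estimator for theta_S given S selected."""
    q, sd_x, sd_y = _stratum_sds(design)
    prob = prob_select_s(theta_S, theta_Sc, sd_x, sd_y, design.b, design.p_S)
    if prob < _MIN_PROB:
        raise ValueError(
            f"Pr(select S) = {prob:.3e} is numerically negligible; the "
            "conditional bias is undefined"
        )
    moment = trunc_moment_x_select_s(theta_S, theta_Sc, sd_x, sd_y, design.b, design.p_S)
    return q.t_S * (moment / prob - theta_S)


def bias_components_f(design: DesignConfig, theta_S: float, theta_Sc: float):
    """Conditional biases of the naive component and combined estimators
    given F selected: ``(bias_d_S_N_F, bias_d_Sc_N_F, bias_d_F_N)``.

    Under proportional allocation the prevalence-weighted component
    biases cancel exactly, so the combined naive estimator is unbiased.
    """
    q, sd_x, sd_y = _stratum_sds(design)
    prob_f = 1.0 - prob_select_s(theta_S, theta_Sc, sd_x, sd_y, design.b, design.p_S)
    if prob_f < _MIN_PROB:
        raise ValueError(
            f"Pr(select F) = {prob_f:.3e} is numerically negligible; the "
            "conditional bias is undefined"
        )
    moment_x = theta_S - trunc_moment_x_select_s(
        theta_S, theta_Sc, sd_x, sd_y, design.b, design.p_S
    )
    moment_y = trunc_moment_y_select_f(theta_S, theta_Sc, sd_x, sd_y, design.b, design.p_S)
    bias_s = q.t_S_F * (moment_x / prob_f - theta_S)
    bias_sc = q.t_Sc_F * (moment_y / prob_f - theta_Sc)
    bias_f = design.p_S * bias_s + (1.0 - design.p_S) * bias_sc
    return bias_s, bias_sc, bias_f


def se_selected_s(design: DesignConfig, se_mode: Literal["pooled", "printed"] = "pooled"):
    """Normalising SE for S-branch estimators.

    ``pooled`` (default) is the exact standard error of the two-stage
    pooled mean difference in S, ``sqrt(4 sigma^2 / (p_S n1 + n2))``;
    ``printed`` is the alternative reading ``sqrt(4 sigma^2 /
    (p_S (n1 + n2)))``.
    """
    four_s2 = 4.0 * design.sigma**2
    if se_mode == "pooled":
        return math.sqrt(four_s2 / (design.p_S * design.n1 + design.n2))
    if se_mode == "printed":
        return math.sqrt(four_s2 / (design.p_S * (design.n1 + design.n2)))
    raise ValueError(f"unknown se_mode {se_mode!r}")


def se_selected_f(design: DesignConfig):
    """Normalising SE for F-branch estimators, ``sqrt(4 sigma^2 / (n1 + n2))``."""
    return math.sqrt(4.0 * design.sigma**2 / (design.n1 + design.n2))


@dataclass(frozen=True)
class BiasResult:
    """Exact conditional biases of the naive estimators at one truth."""

    theta_S: float
    theta_Sc: float
    prob_S: float
    prob_F: float
    bias_d_S_N: float
    bias_d_S_N_F: float
    bias_d_Sc_N_F: float
    bias_d_F_N: float
    bias_d_S_N_norm: float
    bias_d_S_N_F_norm: float
    bias_d_Sc_N_F_norm: float
    bias_d_F_N_norm: float


def bias_point(
    design: DesignConfig,
    theta_S: float,
    theta_Sc: float,
    se_mode: Literal["pooled", "printed"] = "pooled",
) -> BiasResult:
    """All naive-estimator conditional biases, raw and SE-normalised."""
    q, sd_x, sd_y = _stratum_sds(design)
    prob_s = prob_select_s(theta_S, theta_Sc, sd_x, sd_y, design.b, design.p_S)
    bias_s = bias_naive_s(design, theta_S, theta_Sc)
    bias_s_f, bias_sc_f, bias_f = bias_components_f(design, theta_S, theta_Sc)
    se_s = se_selected_s(design, se_mode)
    se_f = se_selected_f(design)
    return BiasResult(
        theta_S=theta_S,
        theta_Sc=theta_Sc,
        prob_S=prob_s,
        prob_F=1.0 - prob_s,
        bias_d_S_N=bias_s,
        bias_d_S_N_F=bias_s_f,
        bias_d_Sc_N_F=bias_sc_f,
        bias_d_F_N=bias_f,
        bias_d_S_N_norm=bias_s / se_s,
        bias_d_S_N_F_norm=bias_s_f / se_f,
        bias_d_Sc_N_F_norm=bias_sc_f / se_f,
        bias_d_F_N_norm=bias_f / se_f,
    )


def bias_curve(
    design: DesignConfig,
    theta_S_grid: Iterable[float],
    theta_Sc: float = 0.0,
    se_mode: Literal["pooled", "printed"] = "pooled",
) -> pd.DataFrame:
    """Normalised bias curves over a grid of theta_S values.

    One row per grid point with the raw and normalised biases of all four
    naive estimators, mirroring a bias-versus-effect-difference plot.
    """
    grid = np.asarray(list(theta_S_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("theta_S grid must be non-empty")
    rows = [bias_point(design, t, theta_Sc, se_mode).__dict__ for t in grid]
    frame = pd.DataFrame(rows)
    return frame.rename(
        columns={
            "theta_S": "theta_s",
            "theta_Sc": "theta_sc",
            "prob_S": "prob_S",
            "bias_d_S_N": "bias_s_n",
            "bias_d_S_N_F": "bias_s_n_f",
            "bias_d_Sc_N_F": "bias_sc_n_f",
            "bias_d_F_N": "bias_f_n",
            "bias_d_S_N_norm": "bias_s_n_norm",
            "bias_d_S_N_F_norm": "bias_s_n_f_norm",
            "bias_d_Sc_N_F_norm": "bias_sc_n_f_norm",
            "bias_d_F_N_norm": "bias_f_n_norm",
        }
    )
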