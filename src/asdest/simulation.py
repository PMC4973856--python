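"""Monte Carlo engine, patient-level data generation and brute-force oracles.

The simulator draws trials at the summary-statistic level, exactly as the
sampling model specifies: stage-1 mean differences X ~ N(theta_S,
4 sigma^2 / s_X) and Y ~ N(theta_Sc, 4 sigma^2 / (n1 - s_X)), interim
selection (optionally after a futility check), then the appropriate
stage-2 means.  In unknown-prevalence mode the stratum counts are drawn
Binomial(n, p_S) first, with degenerate draws (an empty stratum)
resampled and counted.  Patient-level generation produces individual
normal outcomes whose stratum summaries reproduce the same model and is
used for fixture and round-trip validation.

The quadrature oracles recompute the Rao-Blackwell conditional
expectations E[stage-2 mean | complement observation, sufficient
statistic, selection event] by direct 1-D integration, independently of
the closed forms they are used to check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import integrate

from . import estimators as est
from .bias_analytic import se_selected_f, se_selected_s
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
    "SimulationConfig",
    "SimulationResult",
    "simulate_trial",
    "run_mc_study",
    "generate_patient_data",
    "summarize_patient_data",
    "rb_oracle_selected_s",
    "rb_oracle_selected_f_s",
    "rb_oracle_selected_f_sc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """One Monte Carlo configuration: a design plus the simulation truth."""

    design: DesignConfig
    theta_S: float
    theta_Sc: float
    n_reps: int = 1
    seed: int | None = None
    prevalence_mode: Literal["known", "unknown"] = "known"
    level: Literal["summary", "patient"] = "summary"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.design.p_S is None:
            raise ValueError(
                "simulation requires the true prevalence p_S in the design "
                "(prevalence_mode controls whether the analysis treats it as known)"
            )
        if self.prevalence_mode not in ("known", "unknown"):
            raise ValueError(f"unknown prevalence_mode {self.prevalence_mode!r}")

    @property
    def theta_F(self) -> float:
        return self.design.p_S * self.theta_S + (1.0 - self.design.p_S) * self.theta_Sc


def _draw_counts(rng, n, p, size):
    """Binomial stratum counts with degenerate draws resampled.

    Returns ``(counts, n_resampled)``; a count of 0 or n would leave an
    empty stratum and no defined mean, so such draws are redrawn (they
    are vanishingly rare at realistic n and p).
    """
    counts = rng.binomial(n, p, size)
    resampled = 0
    bad = (counts == 0) | (counts == n)
    while np.any(bad):
        resampled += int(bad.sum())
        counts[bad] = rng.binomial(n, p, int(bad.sum()))
        bad = (counts == 0) | (counts == n)
    if resampled:
        logger.warning("resampled %d degenerate binomial stratum draws", resampled)
    return counts.astype(float), resampled


def simulate_trial(cfg: SimulationConfig, rng=None) -> tuple[StageSummaries, SelectionDecision]:
    """Draw a single trial (stage-1 means, interim decision, stage-2 means)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    design = cfg.design
    n1, n2, sigma = design.n1, design.n2, design.sigma
    four_s2 = 4.0 * sigma**2

    if cfg.prevalence_mode == "known":
        s_X = design.p_S * n1
    else:
        counts, _ = _draw_counts(rng, n1, design.p_S, 1)
        s_X = float(counts[0])
    x = cfg.theta_S + math.sqrt(four_s2 / s_X) * rng.standard_normal()
    y = cfg.theta_Sc + math.sqrt(four_s2 / (n1 - s_X)) * rng.standard_normal()

    decision = decide(design, x, y, s_X)
    if decision.outcome is Selection.STOP_FUTILITY:
        return StageSummaries(x=x, y=y, s_X=s_X), decision
    if decision.outcome is Selection.SELECT_S:
        u = cfg.theta_S + math.sqrt(four_s2 / n2) * rng.standard_normal()
        return StageSummaries(x=x, y=y, s_X=s_X, u=u), decision
    if cfg.prevalence_mode == "known":
        s_V = design.p_S * n2
    else:
        counts, _ = _draw_counts(rng, n2, design.p_S, 1)
        s_V = float(counts[0])
    v = cfg.theta_S + math.sqrt(four_s2 / s_V) * rng.standard_normal()
    w = cfg.theta_Sc + math.sqrt(four_s2 / (n2 - s_V)) * rng.standard_normal()
    return StageSummaries(x=x, y=y, s_X=s_X, v=v, w=w, s_V=s_V), decision


@dataclass
class SimulationResult:
    """Branch-conditional performance of every estimator for one truth.

    ``table`` has one row per (branch, estimator) with the conditional
    mean, bias, MSE, root-MSE over the approximate SE, and Monte Carlo
    standard errors for each.
    """

    config: SimulationConfig
    table: pd.DataFrame
    n_select_s: int
    n_select_f: int
    n_futility: int
    n_resampled: int
    seed: int | None

    @property
    def select_s_freq(self) -> float:
        return self.n_select_s / self.config.n_reps

    @property
    def select_f_freq(self) -> float:
        return self.n_select_f / self.config.n_reps

    @property
    def futility_freq(self) -> float:
        return self.n_futility / self.config.n_reps

    def metric(self, branch: str, estimator: str, name: str) -> float:
        rows = self.table[
            (self.table["branch"] == branch) & (self.table["estimator"] == estimator)
        ]
        if rows.empty:
            raise KeyError(f"no rows for branch={branch!r}, estimator={estimator!r}")
        return float(rows.iloc[0][name])


def _branch_rows(values: dict, estimands: dict, se: float, branch: str) -> list[dict]:
    rows = []
    for name, draws in values.items():
        err = draws - estimands[name]
        n = err.size
        mse = float(np.mean(err**2))
        mse_se = float(np.std(err**2, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rmse = math.sqrt(mse)
        rows.append(
            {
                "branch": branch,
                "estimator": name,
                "estimand": estimands[name],
                "n": n,
                "mean": float(np.mean(draws)),
                "bias": float(np.mean(err)),
                "bias_mc_se": float(np.std(err, ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
                "mse": mse,
                "mse_mc_se": mse_se,
                "rmse_over_se": rmse / se,
                "rmse_over_se_mc_se": (mse_se / (2.0 * rmse)) / se if rmse > 0 else float("nan"),
            }
        )
    return rows


def run_mc_study(cfg: SimulationConfig, se_mode: str = "pooled") -> SimulationResult:
    """Vectorised Monte Carlo study of conditional bias and MSE.

    All random draws for every replicate are generated up front from a
    single seeded generator, so results are bitwise reproducible and
    branch-conditional summaries do not depend on evaluation order.
    """
    design = cfg.design
    n1, n2, sigma, b, B = design.n1, design.n2, design.sigma, design.b, design.B
    p_S = design.p_S
    n_reps = cfg.n_reps
    four_s2 = 4.0 * sigma**2
    if B is not None and cfg.prevalence_mode == "unknown":
        raise ValueError("unsupported: futility rule with unknown prevalence")
    rng = np.random.default_rng(cfg.seed)

    n_resampled = 0
    if cfg.prevalence_mode == "known":
        s_X = np.full(n_reps, p_S * n1)
        s_V = np.full(n_reps, p_S * n2)
    else:
        s_X, r1 = _draw_counts(rng, n1, p_S, n_reps)
        s_V, r2 = _draw_counts(rng, n2, p_S, n_reps)
        n_resampled = r1 + r2

    x = cfg.theta_S + np.sqrt(four_s2 / s_X) * rng.standard_normal(n_reps)
    y = cfg.theta_Sc + np.sqrt(four_s2 / (n1 - s_X)) * rng.standard_normal(n_reps)
    # stage-2 noise is drawn for every replicate regardless of branch so
    # that the stream layout is fixed
    u = cfg.theta_S + np.sqrt(four_s2 / n2) * rng.standard_normal(n_reps)
    v = cfg.theta_S + np.sqrt(four_s2 / s_V) * rng.standard_normal(n_reps)
    w = cfg.theta_Sc + np.sqrt(four_s2 / (n2 - s_V)) * rng.standard_normal(n_reps)

    p_hat = s_X / n1
    margin = b / (1.0 - p_hat)
    z = p_hat * x + (1.0 - p_hat) * y
    continued = np.ones(n_reps, dtype=bool) if B is None else (np.maximum(x, z) >= B)
    pick_s = x > y + margin
    mask_s = continued & pick_s
    mask_f = continued & ~pick_s

    rows: list[dict] = []
    se_s = se_selected_s(design, se_mode)
    se_f = se_selected_f(design)

    if np.any(mask_s):
        qs = DerivedQuantities(
            s_X=s_X[mask_s], s_V=None,
            sigma2_X=four_s2 / s_X[mask_s], sigma2_Y=four_s2 / (n1 - s_X[mask_s]),
            tau2_U=four_s2 / n2, tau2_V=None, tau2_W=None,
            t_S=s_X[mask_s] / (s_X[mask_s] + n2), t_S_F=None, t_Sc_F=None,
            t_F=n1 / (n1 + n2),
        )
        d_s_n = est.naive_selected_s(x[mask_s], u[mask_s], qs.t_S)
        if B is None:
            d_s_u, _ = est.umvue_selected_s(x[mask_s], y[mask_s], u[mask_s], qs, b, n1)
        else:
            d_s_u, _ = est.umvue_selected_s_futility(
                x[mask_s], y[mask_s], u[mask_s], qs, b, n1, B
            )
        rows += _branch_rows(
            {"d_S_N": d_s_n, "d_S_U": d_s_u},
            {"d_S_N": cfg.theta_S, "d_S_U": cfg.theta_S},
            se_s,
            "S",
        )

    if np.any(mask_f):
        m = mask_f
        qf = DerivedQuantities(
            s_X=s_X[m], s_V=s_V[m],
            sigma2_X=four_s2 / s_X[m], sigma2_Y=four_s2 / (n1 - s_X[m]),
            tau2_U=four_s2 / n2, tau2_V=four_s2 / s_V[m], tau2_W=four_s2 / (n2 - s_V[m]),
            t_S=s_X[m] / (s_X[m] + n2),
            t_S_F=s_X[m] / (s_X[m] + s_V[m]),
            t_Sc_F=(n1 - s_X[m]) / (n1 + n2 - s_X[m] - s_V[m]),
            t_F=n1 / (n1 + n2),
        )
        if cfg.prevalence_mode == "known":
            p_naive = p_umvue = p_S
        else:
            p_naive = (s_X[m] + s_V[m]) / (n1 + n2)  # pooled two-stage estimate
            p_umvue = s_X[m] / n1
        d_s_n, d_sc_n, d_f_n = est.naive_selected_f(
            x[m], y[m], v[m], w[m], qf, p_naive
        )
        if B is None:
            d_s_u, d_sc_u, d_f_u, _, _ = est.umvue_selected_f(
                x[m], y[m], v[m], w[m], qf, b, n1, p_umvue
            )
        else:
            d_s_u, d_sc_u, d_f_u, _, _, _ = est.umvue_selected_f_futility(
                x[m], y[m], v[m], w[m], qf, b, n1, B, p_S
            )
        theta_F = cfg.theta_F
        rows += _branch_rows(
            {
                "d_S_N_F": d_s_n, "d_Sc_N_F": d_sc_n, "d_F_N": d_f_n,
                "d_S_U_F": d_s_u, "d_Sc_U_F": d_sc_u, "d_F_U": d_f_u,
            },
            {
                "d_S_N_F": cfg.theta_S, "d_Sc_N_F": cfg.theta_Sc, "d_F_N": theta_F,
                "d_S_U_F": cfg.theta_S, "d_Sc_U_F": cfg.theta_Sc, "d_F_U": theta_F,
            },
            se_f,
            "F",
        )

    return SimulationResult(
        config=cfg,
        table=pd.DataFrame(rows),
        n_select_s=int(mask_s.sum()),
        n_select_f=int(mask_f.sum()),
        n_futility=int((~continued).sum()),
        n_resampled=n_resampled,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# patient-level generation

def generate_patient_data(
    design: DesignConfig,
    theta_S: float,
    theta_Sc: float,
    stage: int,
    selection: Selection | None = None,
    rng=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Individual patient records for one trial stage.

    Outcomes are normal with standard deviation sigma; within each
    stratum the experimental-arm mean exceeds the control-arm mean by the
    stratum's true treatment difference.  Randomisation is stratified
    1:1, so every per-stratum arm count must be an integer; stratum means
    of (experimental - control) reproduce the summary-level model
    exactly.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    if not design.prevalence_known:
        raise ValueError("patient-level generation requires a known prevalence")
    if stage == 1:
        counts = {"S": design.p_S * design.n1, "Sc": (1 - design.p_S) * design.n1}
    elif stage == 2:
        if selection is Selection.SELECT_S:
            counts = {"S": float(design.n2)}
        elif selection is Selection.SELECT_F:
            counts = {"S": design.p_S * design.n2, "Sc": (1 - design.p_S) * design.n2}
        else:
            raise ValueError("stage 2 requires selection SELECT_S or SELECT_F")
    else:
        raise ValueError(f"stage must be 1 or 2, got {stage}")

    theta = {"S": theta_S, "Sc": theta_Sc}
    records = []
    pid = 0
    for stratum, n_strat in counts.items():
        if abs(n_strat - round(n_strat)) > 1e-9 or round(n_strat) % 2:
            raise ValueError(
                f"stratum {stratum!r} needs an even integer patient count for 1:1 "
                f"randomisation, got {n_strat}"
            )
        half = int(round(n_strat)) // 2
        for arm, mean in (("control", 0.0), ("experimental", theta[stratum])):
            outcomes = mean + design.sigma * rng.standard_normal(half)
            for val in outcomes:
                records.append(
                    {
                        "patient_id": pid,
                        "stage": stage,
                        "stratum": stratum,
                        "arm": arm,
                        "outcome": float(val),
                    }
                )
                pid += 1
    return pd.DataFrame.from_records(records)


def summarize_patient_data(frames: pd.DataFrame | list[pd.DataFrame]) -> StageSummaries:
    """Reduce patient records (both stages) to the observed mean differences."""
    df = pd.concat(frames, ignore_index=True) if isinstance(frames, list) else frames

    def diff(sub: pd.DataFrame) -> float:
        means = sub.groupby("arm")["outcome"].mean()
        return float(means["experimental"] - means["control"])

    s1 = df[df["stage"] == 1]
    s2 = df[df["stage"] == 2]
    if s1.empty:
        raise ValueError("no stage-1 records")
    x = diff(s1[s1["stratum"] == "S"])
    y = diff(s1[s1["stratum"] == "Sc"])
    s_X = float((s1["stratum"] == "S").sum())
    if s2.empty:
        return StageSummaries(x=x, y=y, s_X=s_X)
    if (s2["stratum"] == "Sc").any():
        s_V = float((s2["stratum"] == "S").sum())
        return StageSummaries(
            x=x, y=y, s_X=s_X,
            v=diff(s2[s2["stratum"] == "S"]),
            w=diff(s2[s2["stratum"] == "Sc"]),
            s_V=s_V,
        )
    return StageSummaries(x=x, y=y, s_X=s_X, u=diff(s2))


# ---------------------------------------------------------------------------
# quadrature Rao-Blackwell oracles

def _rb_conditional_mean(
    z: float,
    var1: float,
    var2: float,
    lower: float,
    upper: float,
    theta_probe: float,
) -> float:
    """Brute-force ``E[M | Z = z, A in (lower, upper)]``.

    ``A ~ N(theta, var1)`` is the stage-1 mean, ``M ~ N(theta, var2)`` the
    stage-2 mean and ``Z = (sd2/sd1) A + (sd1/sd2) M`` the sufficient
    combination.  Along the Z = z slice, ``A = (sd1/sd2) z -
    (sd1^2/var2) M``, so the truncation of A maps to an interval of M and
    the expectation is a ratio of two 1-D integrals of the joint normal
    weight evaluated at ``theta_probe`` (the result is theta-free by
    sufficiency, which callers verify).
    """
    sd1, sd2 = math.sqrt(var1), math.sqrt(var2)
    if not lower < upper:
        raise ValueError(f"empty truncation region ({lower}, {upper})")

    def a_of_m(m):
        return (sd1 / sd2) * z - (var1 / var2) * m

    def m_of_a(a):
        return (var2 / var1) * ((sd1 / sd2) * z - a)

    # a_of_m is decreasing, so the A-interval maps to (m_of_a(upper), m_of_a(lower))
    m_lo = m_of_a(upper) if math.isfinite(upper) else -math.inf
    m_hi = m_of_a(lower) if math.isfinite(lower) else math.inf

    def neg_log_weight(m):
        return 0.5 * ((a_of_m(m) - theta_probe) ** 2 / var1 + (m - theta_probe) ** 2 / var2)

    # quadratic in m: locate the mode and curvature to centre the quadrature
    curv = (var1 / var2) ** 2 / var1 + 1.0 / var2
    d0 = (a_of_m(0.0) - theta_probe) * (-(var1 / var2)) / var1 - theta_probe / var2
    m_star = -d0 / curv
    scale = 1.0 / math.sqrt(curv)
    shift = neg_log_weight(m_star)

    lo = max(m_lo, m_star - 15.0 * scale)
    hi = min(m_hi, m_star + 15.0 * scale)
    if not lo < hi:
        # the truncation interval lies entirely in one tail of the weight
        lo, hi = (m_lo, min(m_hi, m_lo + 30.0 * scale)) if m_lo > m_star else (
            max(m_lo, m_hi - 30.0 * scale), m_hi)

    def weight(m):
        return math.exp(-(neg_log_weight(m) - shift))

    opts = dict(epsabs=1e-13, epsrel=1e-13, limit=400)
    den, _ = integrate.quad(weight, lo, hi, **opts)
    num, _ = integrate.quad(lambda m: m * weight(m), lo, hi, **opts)
    if den <= 0.0:
        raise ValueError("truncation region carries no probability mass")
    return num / den


def rb_oracle_selected_s(
    y: float,
    z_S: float,
    q: DerivedQuantities,
    b: float,
    n1: int,
    theta_probe: float = 0.0,
    B: float | None = None,
) -> float:
    """Quadrature value of E[U | Y=y, Z_S=z_S, selection of S].

    The selection event truncates X to ``X > max(B, y + b/(1 - s_X/n1))``.
    This is the independent check of the S-branch closed form.
    """
    lower = y + b / (1.0 - q.s_X / n1)
    if B is not None:
        lower = max(B, lower)
    return _rb_conditional_mean(z_S, q.sigma2_X, q.tau2_U, lower, math.inf, theta_probe)


def rb_oracle_selected_f_s(
    y: float,
    z_S_F: float,
    q: DerivedQuantities,
    b: float,
    n1: int,
    theta_probe: float = 0.0,
    B: float | None = None,
    p_S: float | None = None,
) -> float:
    """Quadrature value of E[V | Y=y, Z_S^F, selection of F (and continuation)].

    Selection of F truncates X above at ``y + b/(1 - s_X/n1)``; an active
    futility bound additionally truncates it below at
    ``(B - (1 - p_S) y) / p_S``.
    """
    upper = y + b / (1.0 - q.s_X / n1)
    lower = -math.inf
    if B is not None:
        if p_S is None:
            raise ValueError("futility oracle requires p_S")
        lower = (B - (1.0 - p_S) * y) / p_S
    return _rb_conditional_mean(z_S_F, q.sigma2_X, q.tau2_V, lower, upper, theta_probe)


def rb_oracle_selected_f_sc(
    x: float,
    z_Sc_F: float,
    q: DerivedQuantities,
    b: float,
    n1: int,
    theta_probe: float = 0.0,
    B: float | None = None,
    p_S: float | None = None,
) -> float:
    """Quadrature value of E[W | X=x, Z_Sc^F, selection of F (and continuation)].

    Selection of F truncates Y below at ``x - b/(1 - s_X/n1)``; an active
    futility bound raises the threshold to ``max(that, (B - p_S x) /
    (1 - p_S))``.
    """
    lower = x - b / (1.0 - q.s_X / n1)
    if B is not None:
        if p_S is None:
            raise ValueError("futility oracle requires p_S")
        lower = max(lower, (B - p_S * x) / (1.0 - p_S))
    return _rb_conditional_mean(z_Sc_F, q.sigma2_Y, q.tau2_W, lower, math.inf, theta_probe)
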