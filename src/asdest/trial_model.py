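"""Trial design constants, observed summaries and interim decision rules.

The design under study is a two-stage adaptive seamless trial in which a
control and an experimental treatment are compared in a full population F
that contains a pre-specified subpopulation S of prevalence ``p_S`` (the
remainder is S^c).  Stage 1 recruits from F with stratified 1:1
randomisation; at the interim, the observed stage-1 mean treatment
differences ``x`` (in S) and ``y`` (in S^c) decide whether stage 2 enrols
from S only or from all of F.  Outcomes are normal with known common
standard deviation ``sigma``, so each observed mean difference based on
``m`` patients (m/2 per arm) has variance ``4 * sigma**2 / m``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "DesignConfig",
    "StageSummaries",
    "DerivedQuantities",
    "Selection",
    "SelectionDecision",
    "derive_quantities",
    "pooled_stage1",
    "select_population",
    "apply_futility",
    "decide",
]

#: Marker accepted for an unknown subpopulation prevalence.
UNKNOWN = "unknown"


class Selection(enum.Enum):
    """Outcome of the interim analysis."""

    SELECT_S = "S"
    SELECT_F = "F"
    STOP_FUTILITY = "futility"


@dataclass(frozen=True)
class DesignConfig:
    """Fixed constants of a two-stage subpopulation-selection design.

    Parameters
    ----------
    n1, n2
        Total patients recruited in stage 1 and stage 2 (each split 1:1
        between arms within every stratum).
    sigma
        Known outcome standard deviation (common to both arms and strata).
    p_S
        Prevalence of the subpopulation S in (0, 1), or ``None`` /
        ``"unknown"`` when the prevalence must be estimated from the
        observed stratum counts.
    b
        Selection margin: S continues to stage 2 iff ``x > z + b``,
        equivalently ``x > y + b / (1 - p_S)``.
    B
        Optional futility bound: the trial stops after stage 1 when
        ``max(x, z) < B``.  ``None`` disables the rule.
    seed
        Optional RNG seed recorded with the design for reproducibility.
    """

    n1: int
    n2: int
    sigma: float
    p_S: float | None = None
    b: float = 0.0
    B: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.p_S, str):
            if self.p_S.lower() != UNKNOWN:
                raise ValueError(f"p_S must be a number in (0,1) or 'unknown', got {self.p_S!r}")
            object.__setattr__(self, "p_S", None)
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(f"n1 and n2 must both be >= 2, got n1={self.n1}, n2={self.n2}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.p_S is not None and not 0.0 < self.p_S < 1.0:
            raise ValueError(f"p_S must lie strictly in (0, 1), got {self.p_S}")
        if self.B is not None and not math.isfinite(self.B):
            raise ValueError("futility bound B must be finite (omit it for no rule)")

    @property
    def prevalence_known(self) -> bool:
        return self.p_S is not None

    @property
    def has_futility_rule(self) -> bool:
        return self.B is not None

    def expected_counts(self) -> tuple[float, float]:
        """Expected stratum-S patient counts ``(p_S*n1, p_S*n2)``.

        Only available in known-prevalence mode; the values may be
        non-integral and are then usable for summary-level analytic work
        but not for patient-level generation.
        """
        if self.p_S is None:
            raise ValueError("expected counts require a known prevalence p_S")
        return self.p_S * self.n1, self.p_S * self.n2


@dataclass(frozen=True)
class StageSummaries:
    """Observed stage-wise mean treatment differences.

    ``x``/``y`` are the stage-1 differences in S and S^c based on ``s_X``
    and ``n1 - s_X`` patients.  After stage 2 exactly one of ``u`` (S
    selected) or ``(v, w, s_V)`` (F selected) is populated.
    """

    x: float
    y: float
    s_X: float
    u: float | None = None
    v: float | None = None
    w: float | None = None
    s_V: float | None = None

    def __post_init__(self) -> None:
        has_u = self.u is not None
        has_f = self.v is not None or self.w is not None or self.s_V is not None
        if has_u and has_f:
            raise ValueError("provide either u (S selected) or v/w/s_V (F selected), not both")
        if has_f and (self.v is None or self.w is None or self.s_V is None):
            raise ValueError("F-selected summaries require all of v, w and s_V")

    @property
    def stage2_branch(self) -> Selection | None:
        if self.u is not None:
            return Selection.SELECT_S
        if self.v is not None:
            return Selection.SELECT_F
        return None

    def p_hat(self, n1: int) -> float:
        """Stage-1 prevalence estimate ``s_X / n1``."""
        return self.s_X / n1

    def pooled(self, n1: int) -> float:
        """Pooled stage-1 difference ``z`` at the observed stratum split."""
        return pooled_stage1(self.x, self.y, self.p_hat(n1))


@dataclass(frozen=True)
class DerivedQuantities:
    """Variances of the observed means and the two-stage pooling weights.

    With ``m`` patients contributing to a mean difference, its variance is
    ``4 sigma^2 / m``; the weights are the stage-1 share of the pooled
    per-stratum sample.
    """

    s_X: float
    s_V: float | None
    sigma2_X: float
    sigma2_Y: float
    tau2_U: float
    tau2_V: float | None
    tau2_W: float | None
    t_S: float
    t_S_F: float | None
    t_Sc_F: float | None
    t_F: float

    def z_S(self, x: float, u: float):
        """Sufficient-statistic component when S is selected."""
        su, sx = math.sqrt(self.tau2_U), math.sqrt(self.sigma2_X)
        return (su / sx) * x + (sx / su) * u

    def z_S_F(self, x: float, v: float):
        sv, sx = math.sqrt(self.tau2_V), math.sqrt(self.sigma2_X)
        return (sv / sx) * x + (sx / sv) * v

    def z_Sc_F(self, y: float, w: float):
        sw, sy = math.sqrt(self.tau2_W), math.sqrt(self.sigma2_Y)
        return (sw / sy) * y + (sy / sw) * w


def derive_quantities(
    config: DesignConfig, s_X: float, s_V: float | None = None
) -> DerivedQuantities:
    """Compute sampling variances and pooling weights for given stratum counts.

    ``s_X`` (stage-1 patients from S) and optionally ``s_V`` (stage-2
    patients from S when F is selected) may be real-valued expected counts
    in summary-level work.
    """
    n1, n2 = config.n1, config.n2
    four_s2 = 4.0 * config.sigma**2
    if not 0 < s_X < n1:
        raise ValueError(
            f"s_X={s_X} leaves an empty stratum in stage 1: the variance "
            f"{'sigma2_X' if s_X <= 0 else 'sigma2_Y'} is undefined"
        )
    if s_V is not None and not 0 < s_V < n2:
        raise ValueError(
            f"s_V={s_V} leaves an empty stratum in stage 2: the variance "
            f"{'tau2_V' if s_V <= 0 else 'tau2_W'} is undefined"
        )
    tau2_V = four_s2 / s_V if s_V is not None else None
    tau2_W = four_s2 / (n2 - s_V) if s_V is not None else None
    return DerivedQuantities(
        s_X=s_X,
        s_V=s_V,
        sigma2_X=four_s2 / s_X,
        sigma2_Y=four_s2 / (n1 - s_X),
        tau2_U=four_s2 / n2,
        tau2_V=tau2_V,
        tau2_W=tau2_W,
        t_S=s_X / (s_X + n2),
        t_S_F=s_X / (s_X + s_V) if s_V is not None else None,
        t_Sc_F=(n1 - s_X) / (n1 + n2 - s_X - s_V) if s_V is not None else None,
        t_F=n1 / (n1 + n2),
    )


def pooled_stage1(x: float, y: float, p_hat: float) -> float:
    """Pooled full-population stage-1 difference ``z = p x + (1 - p) y``."""
    if not 0.0 < p_hat < 1.0:
        raise ValueError(f"p_hat must lie strictly in (0, 1), got {p_hat}")
    return p_hat * x + (1.0 - p_hat) * y


@dataclass(frozen=True)
class SelectionDecision:
    """Interim decision with the threshold and futility statistic used."""

    outcome: Selection
    threshold_used: float
    futility_stat: float | None = None


def select_population(x: float, y: float, p_hat: float, b: float = 0.0) -> SelectionDecision:
    """Apply the interim selection rule.

    S continues iff ``x > y + b / (1 - p_hat)``; equality goes to F (the
    rule for F is stated with ``<=``).
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError(f"p_hat must lie strictly in (0, 1), got {p_hat}")
    threshold = y + b / (1.0 - p_hat)
    outcome = Selection.SELECT_S if x > threshold else Selection.SELECT_F
    return SelectionDecision(outcome=outcome, threshold_used=threshold)


def apply_futility(x: float, z: float, B: float | None) -> bool:
    """Return True when the trial continues past the futility check.

    The trial stops iff ``max(x, z) < B``; a missing bound always
    continues.
    """
    if B is None:
        return True
    return max(x, z) >= B


def decide(config: DesignConfig, x: float, y: float, s_X: float) -> SelectionDecision:
    """Full interim decision: futility first, then population selection."""
    p_hat = s_X / config.n1
    z = pooled_stage1(x, y, p_hat)
    if not apply_futility(x, z, config.B):
        threshold = y + config.b / (1.0 - p_hat)
        return SelectionDecision(
            outcome=Selection.STOP_FUTILITY,
            threshold_used=threshold,
            futility_stat=max(x, z),
        )
    decision = select_population(x, y, p_hat, config.b)
    if config.B is not None:
        decision = SelectionDecision(
            outcome=decision.outcome,
            threshold_used=decision.threshold_used,
            futility_stat=max(x, z),
        )
    return decision
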