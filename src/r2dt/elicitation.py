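"""Solvers turning stated lottery indifference points into utility parameters.

The elicitation protocol asks a decision maker (DM) for certainty
equivalents of simple two-outcome lotteries.  Indifference between the
lottery ``(x1 with probability w, x3 otherwise)`` and the sure level ``x2``
pins down one equation ``w*u(x1) + (1-w)*u(x3) = u(x2)``.  Lotteries held on
one side of the reference identify a risk exponent; a lottery straddling the
reference identifies the loss-aversion multiplier (which enters linearly);
two equivalences in the bivariate outcome space identify the joint corner
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .errors import ElicitationInconsistencyError, SingularSystemError
from .utility import (
    JointUtilitySpec,
    MarginalUtilitySpec,
    UtilityFunction,
    joint_utility,
    marginal_utility,
    marginal_utility_inverse,
)

__all__ = [
    "Lottery",
    "certainty_equivalent",
    "solve_risk_exponent",
    "risk_exponent_band",
    "solve_loss_aversion",
    "solve_joint_weights",
    "joint_weights_from_corners",
    "stopping_contour_reference",
    "consistency_check",
]

_RISK_NEUTRAL_TOL = 1e-9
_EXP_LO, _EXP_HI = 1e-3, 1e3


@dataclass(frozen=True)
class Lottery:
    """Two-outcome lottery ``(x1 with probability mix_w, x3 otherwise)`` and,
    optionally, the DM's stated certainty equivalent ``indiff``."""

    x1: float
    x3: float
    mix_w: float = 0.5
    indiff: float | None = None

    def __post_init__(self) -> None:
        for nm, v in (("x1", self.x1), ("x3", self.x3)):
            if not 0.0 <= v <= 1.0:
                raise ElicitationInconsistencyError(f"{nm} must lie in [0, 1], got {v}")
        if not 0.0 < self.mix_w < 1.0:
            raise ElicitationInconsistencyError(
                f"mix_w must lie strictly in (0, 1), got {self.mix_w}"
            )
        if self.indiff is not None and not 0.0 <= self.indiff <= 1.0:
            raise ElicitationInconsistencyError(
                f"indiff must lie in [0, 1], got {self.indiff}"
            )

    @property
    def mean(self) -> float:
        return self.mix_w * self.x1 + (1.0 - self.mix_w) * self.x3


def certainty_equivalent(spec: MarginalUtilitySpec, lottery: Lottery) -> float:
    """Forward direction: the sure level whose utility equals the lottery's
    expected utility, inverted through the exact utility branch."""
    u_target = lottery.mix_w * marginal_utility(spec, lottery.x1) + (
        1.0 - lottery.mix_w
    ) * marginal_utility(spec, lottery.x3)
    return float(marginal_utility_inverse(spec, u_target))


def _gain_coords(values, reference: float, orientation: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v - reference if orientation == "efficacy" else reference - v


def solve_risk_exponent(
    lottery: Lottery,
    reference: float,
    branch: str,
    orientation: str = "efficacy",
) -> float:
    """Recover a power-branch risk exponent from a one-sided lottery.

    Both lottery levels and the stated indifference must sit on the stated
    side of the reference (``branch`` in {"gain", "loss"}).  Within a single
    branch the loss-aversion multiplier and the [0, 1] normalization cancel,
    leaving the weighted power-mean equation

        (w*t1^a + (1-w)*t3^a)^(1/a) = t2,

    with t the distance from the reference.  The power mean is increasing in
    ``a``, so the root is unique and bracketed on a log grid.  An indifference
    at the risk-neutral mean returns exactly 1.
    """
    if branch not in ("gain", "loss"):
        raise ValueError(f"branch must be 'gain' or 'loss', got {branch!r}")
    if lottery.indiff is None:
        raise ElicitationInconsistencyError("lottery has no stated indifference point")
    sign = 1.0 if branch == "gain" else -1.0
    t = sign * _gain_coords([lottery.x1, lottery.x3, lottery.indiff], reference, orientation)
    t1, t3, t2 = float(t[0]), float(t[1]), float(t[2])
    if t1 < 0 or t3 < 0:
        raise ElicitationInconsistencyError(
            f"lottery levels must lie on the {branch} side of reference {reference}"
        )
    if t2 < 0:
        raise ElicitationInconsistencyError(
            f"indifference point must lie on the {branch} side of reference {reference}"
        )
    lo_sup, hi_sup = min(t1, t3), max(t1, t3)
    if not lo_sup < t2 < hi_sup:
        if abs(t2 - lo_sup) < _RISK_NEUTRAL_TOL or abs(t2 - hi_sup) < _RISK_NEUTRAL_TOL:
            raise ElicitationInconsistencyError(
                "indifference at a lottery endpoint does not identify an exponent"
            )
        raise ElicitationInconsistencyError(
            f"indifference {lottery.indiff} lies outside the lottery support"
        )
    w = lottery.mix_w
    if abs(t2 - (w * t1 + (1 - w) * t3)) < _RISK_NEUTRAL_TOL:
        return 1.0

    def gap(log_a: float) -> float:
        # Weighted power mean evaluated in log space so extreme exponents do
        # not underflow: log M_a = logsumexp(log w + a log t) / a.
        a = np.exp(log_a)
        with np.errstate(divide="ignore"):
            terms = np.array([np.log(w) + a * np.log(t1), np.log1p(-w) + a * np.log(t3)])
        return np.exp(logsumexp(terms) / a) - t2

    lo, hi = np.log(_EXP_LO), np.log(_EXP_HI)
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ElicitationInconsistencyError(
            f"indifference {lottery.indiff} is not representable by a power "
            f"exponent in [{_EXP_LO}, {_EXP_HI}] "
            "(e.g. below the weighted geometric mean of the lottery)"
        )
    root = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return float(np.exp(root))


def risk_exponent_band(
    lottery: Lottery,
    reference: float,
    branch: str,
    orientation: str = "efficacy",
    granularity: float = 0.005,
) -> tuple:
    """Exponent interval implied by rounding of the stated indifference.

    Clinician answers are realistically given to 2 decimal places; the band
    re-solves at ``indiff +/- granularity`` (half a rounding unit by default).
    """
    vals = []
    for d in (-granularity, granularity):
        try:
            vals.append(
                solve_risk_exponent(
                    Lottery(lottery.x1, lottery.x3, lottery.mix_w, lottery.indiff + d),
                    reference,
                    branch,
                    orientation,
                )
            )
        except ElicitationInconsistencyError:
            vals.append(np.inf if branch == "gain" else np.inf)
    return (min(vals), max(vals))


def solve_loss_aversion(
    lottery: Lottery,
    exp_gain: float,
    exp_loss: float,
    reference: float,
    orientation: str = "efficacy",
) -> float:
    """Recover the loss-aversion multiplier from a reference-straddling lottery.

    Requires one lottery level on each side of the reference and previously
    solved exponents.  Within the unnormalized two-branch value the multiplier
    enters linearly, so the solution is a closed-form ratio.
    """
    if lottery.indiff is None:
        raise ElicitationInconsistencyError("lottery has no stated indifference point")
    t = _gain_coords([lottery.x1, lottery.x3, lottery.indiff], reference, orientation)
    t1, t3, t2 = float(t[0]), float(t[1]), float(t[2])
    if not (min(t1, t3) < 0 < max(t1, t3)):
        raise ElicitationInconsistencyError(
            "loss-aversion lottery must straddle the reference point"
        )

    def phi_gain(x):
        return x**exp_gain if x >= 0 else 0.0

    def phi_loss(x):
        return (-x) ** exp_loss if x < 0 else 0.0

    w = lottery.mix_w
    num = w * phi_gain(t1) + (1 - w) * phi_gain(t3) - phi_gain(t2)
    den = w * phi_loss(t1) + (1 - w) * phi_loss(t3) - phi_loss(t2)
    if abs(den) < 1e-14:
        raise ElicitationInconsistencyError(
            "stated indifference leaves the loss-aversion multiplier unidentified"
        )
    lam = num / den
    if lam < 0:
        raise ElicitationInconsistencyError(
            f"stated indifference implies negative loss aversion ({lam:.4g})"
        )
    return float(lam)


def solve_joint_weights(
    equivalences,
    eff_spec: MarginalUtilitySpec,
    tox_spec: MarginalUtilitySpec,
) -> tuple:
    """Solve for (k_eff, k_tox) from two stated outcome equivalences.

    Each equivalence is a pair of outcome points ``((pe_a, pt_a), (pe_b, pt_b))``
    the DM regards as equally desirable.  Substituting
    ``k_int = 1 - k_eff - k_tox`` into the equal-utility condition gives one
    linear equation per equivalence.
    """
    if len(equivalences) != 2:
        raise SingularSystemError("exactly two equivalences are required")
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for i, (pt_a, pt_b) in enumerate(equivalences):
        ue_a = marginal_utility(eff_spec, pt_a[0])
        ut_a = marginal_utility(tox_spec, pt_a[1])
        ue_b = marginal_utility(eff_spec, pt_b[0])
        ut_b = marginal_utility(tox_spec, pt_b[1])
        d_ue, d_ut = ue_a - ue_b, ut_a - ut_b
        d_p = ue_a * ut_a - ue_b * ut_b
        A[i] = (d_ue - d_p, d_ut - d_p)
        b[i] = -d_p
    if np.linalg.cond(A) > 1e10:
        raise SingularSystemError(
            f"equivalences {equivalences[0]} and {equivalences[1]} are colinear; "
            "the 2x2 system is singular"
        )
    k_eff, k_tox = np.linalg.solve(A, b)
    for nm, v in (("k_eff", k_eff), ("k_tox", k_tox)):
        if not -1e-9 <= v <= 1 + 1e-9:
            raise ElicitationInconsistencyError(
                f"equivalences imply {nm} = {v:.4g} outside [0, 1]"
            )
    if k_eff + k_tox >= 1:
        warnings.warn(
            f"k_eff + k_tox = {k_eff + k_tox:.4g} >= 1: no positive interaction",
            UserWarning,
            stacklevel=2,
        )
    return float(np.clip(k_eff, 0, 1)), float(np.clip(k_tox, 0, 1))


def joint_weights_from_corners(u11: float, u00: float) -> tuple:
    """Shortcut: stated corner utilities u(1,1) and u(0,0) are the weights."""
    JointUtilitySpec(k_eff=u11, k_tox=u00)  # validates bounds
    return float(u11), float(u00)


def stopping_contour_reference(point: tuple, utility: UtilityFunction) -> float:
    """Reference utility of the stopping contour through the elicited point."""
    x, y = point
    if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
        raise ElicitationInconsistencyError(
            f"contour point must lie in (0, 1)^2, got {point}"
        )
    return float(utility(x, y))


def consistency_check(spec: MarginalUtilitySpec, lotteries) -> list:
    """Compare stated indifference points with model-implied certainty
    equivalents for each extra lottery; reporting only, never raises."""
    report = []
    for lot in lotteries:
        implied = certainty_equivalent(spec, lot)
        stated = lot.indiff
        report.append(
            {
                "x1": lot.x1,
                "x3": lot.x3,
                "mix_w": lot.mix_w,
                "stated": stated,
                "implied": implied,
                "discrepancy": None if stated is None else float(stated - implied),
            }
        )
    return report
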