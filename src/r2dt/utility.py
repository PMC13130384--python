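"""Reference-dependent von Neumann-Morgenstern utilities for efficacy and toxicity.

Each attribute (probability of an efficacy event, probability of a toxicity
event) carries a marginal utility that is a two-branch power function around a
clinical reference point: outcomes better than the reference are "gains",
outcomes worse are "losses", with separate risk exponents per branch and a
loss-aversion multiplier on the loss branch.  The marginal utilities are
normalized to [0, 1] and combined multiplicatively under mutual utility
independence,

    u(pi_E, pi_T) = kE * uE + kT * uT + kET * uE * uT,    kET = 1 - kE - kT.

The patient-outcome utility used by EffToxU-style designs is the degenerate
case with linear marginals (loss aversion 1, both exponents 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UtilityConfigError

__all__ = [
    "MarginalUtilitySpec",
    "JointUtilitySpec",
    "UtilityFunction",
    "marginal_utility",
    "marginal_utility_inverse",
    "joint_utility",
    "efftoxu_utility",
    "contour_grid",
]

_ORIENTATIONS = ("efficacy", "toxicity")


@dataclass(frozen=True)
class MarginalUtilitySpec:
    """Parameters of one reference-dependent marginal utility.

    Parameters
    ----------
    reference : float
        Reference probability in (0, 1) splitting gains from losses.  For
        efficacy this is the standard-of-care response rate; for toxicity a
        target toxicity level.
    loss_aversion : float
        Multiplier (lambda >= 0) applied to losses.  Values above 1 weight
        losses more heavily than equal-sized gains.
    exp_gain, exp_loss : float
        Risk exponents (> 0) of the power branches for gains and losses.
    orientation : {"efficacy", "toxicity"}
        Efficacy utilities increase in the probability, toxicity utilities
        decrease.
    """

    reference: float
    loss_aversion: float
    exp_gain: float
    exp_loss: float
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS:
            raise UtilityConfigError(
                f"orientation must be one of {_ORIENTATIONS}, got {self.orientation!r}"
            )
        if not 0.0 < self.reference < 1.0:
            raise UtilityConfigError(
                f"reference must lie strictly inside (0, 1), got {self.reference}"
            )
        if self.exp_gain <= 0 or self.exp_loss <= 0:
            # The exponent->0 limit is a step function; 0**0 is ambiguous so it
            # is not representable here.
            raise UtilityConfigError(
                "risk exponents must be strictly positive "
                f"(got exp_gain={self.exp_gain}, exp_loss={self.exp_loss}); "
                "the exponent-zero step-function limit is not representable"
            )
        if self.loss_aversion < 0:
            raise UtilityConfigError(
                f"loss_aversion must be nonnegative, got {self.loss_aversion}"
            )
        if self.loss_aversion == 0:
            warnings.warn(
                "loss_aversion = 0 collapses the loss branch to the reference "
                "value; loss aversion above 1 is the intended regime",
                UserWarning,
                stacklevel=2,
            )
        if self._v_best() - self._v_worst() <= 0:
            raise UtilityConfigError("normalizer denominator must be positive")

    # Internal gain-coordinate helpers.  t = p - reference for efficacy and
    # reference - p for toxicity, so t > 0 is always a gain.
    def _gain_coord(self, p: np.ndarray) -> np.ndarray:
        if self.orientation == "efficacy":
            return p - self.reference
        return self.reference - p

    def _from_gain_coord(self, t: np.ndarray) -> np.ndarray:
        if self.orientation == "efficacy":
            return self.reference + t
        return self.reference - t

    def _v(self, t: np.ndarray) -> np.ndarray:
        """Unnormalized two-branch power value at gain coordinate t."""
        t = np.asarray(t, dtype=float)
        gain = np.where(t >= 0, t, 0.0) ** self.exp_gain
        loss = -self.loss_aversion * np.where(t < 0, -t, 0.0) ** self.exp_loss
        return np.where(t >= 0, gain, loss)

    def _v_best(self) -> float:
        # Best outcome: p = 1 (efficacy) or p = 0 (toxicity); t_best is the
        # full gain range.
        t_best = 1.0 - self.reference if self.orientation == "efficacy" else self.reference
        return float(t_best**self.exp_gain)

    def _v_worst(self) -> float:
        t_worst = self.reference if self.orientation == "efficacy" else 1.0 - self.reference
        return float(-self.loss_aversion * t_worst**self.exp_loss)


@dataclass(frozen=True)
class JointUtilitySpec:
    """Corner weights of the multiplicative joint utility.

    ``k_eff`` is the utility of the corner (pi_E, pi_T) = (1, 1) (full efficacy
    despite certain toxicity) and ``k_tox`` that of (0, 0) (no efficacy but no
    toxicity).  The interaction weight ``k_int = 1 - k_eff - k_tox`` is derived;
    a positive value means the two attributes reinforce each other.
    """

    k_eff: float
    k_tox: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_eff <= 1.0:
            raise UtilityConfigError(f"k_eff must lie in [0, 1], got {self.k_eff}")
        if not 0.0 <= self.k_tox <= 1.0:
            raise UtilityConfigError(f"k_tox must lie in [0, 1], got {self.k_tox}")

    @property
    def k_int(self) -> float:
        return 1.0 - self.k_eff - self.k_tox


def marginal_utility(spec: MarginalUtilitySpec, p):
    """Evaluate the normalized marginal utility at probability ``p``.

    Efficacy utilities run from 0 at p=0 to 1 at p=1 (nondecreasing); toxicity
    utilities from 1 at p=0 to 0 at p=1 (nonincreasing).  Accepts scalars or
    arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise DomainError(f"probability outside [0, 1]: {p}")
    v = spec._v(spec._gain_coord(p_arr))
    lo, hi = spec._v_worst(), spec._v_best()
    u = (v - lo) / (hi - lo)
    return u if u.ndim else float(u)


def marginal_utility_inverse(spec: MarginalUtilitySpec, u):
    """Probability at which the marginal utility equals ``u`` (branch-exact).

    With ``loss_aversion == 0`` the loss branch is flat at the reference value
    and utilities below it are unattainable.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr > 1):
        raise DomainError(f"utility outside [0, 1]: {u}")
    lo, hi = spec._v_worst(), spec._v_best()
    v = u_arr * (hi - lo) + lo
    with np.errstate(invalid="ignore", divide="ignore"):
        t_gain = np.where(v >= 0, v, 0.0) ** (1.0 / spec.exp_gain)
        if spec.loss_aversion > 0:
            t_loss = -(np.where(v < 0, -v, 0.0) / spec.loss_aversion) ** (
                1.0 / spec.exp_loss
            )
        else:
            t_loss = np.zeros_like(v)
            if np.any(v < 0):
                raise DomainError(
                    "utility below the reference value is unattainable when "
                    "loss_aversion is 0"
                )
    t = np.where(v >= 0, t_gain, t_loss)
    p = np.clip(spec._from_gain_coord(t), 0.0, 1.0)
    return p if p.ndim else float(p)


def joint_utility(jspec: JointUtilitySpec, u_eff, u_tox):
    """Combine two marginal utilities: kE*uE + kT*uT + kET*uE*uT."""
    u_eff = np.asarray(u_eff, dtype=float)
    u_tox = np.asarray(u_tox, dtype=float)
    out = jspec.k_eff * u_eff + jspec.k_tox * u_tox + jspec.k_int * u_eff * u_tox
    return out if out.ndim else float(out)


def efftoxu_utility(k11: float, k00: float, p_eff, p_tox):
    """Patient-outcome utility with linear marginals uE = pi_E, uT = 1 - pi_T.

    ``k11`` is the utility of experiencing both events, ``k00`` of neither.
    """
    jspec = JointUtilitySpec(k_eff=k11, k_tox=k00)
    return joint_utility(jspec, np.asarray(p_eff, dtype=float), 1.0 - np.asarray(p_tox, dtype=float))


@dataclass(frozen=True)
class UtilityFunction:
    """Full bivariate utility: two marginal specs plus joint corner weights."""

    efficacy: MarginalUtilitySpec
    toxicity: MarginalUtilitySpec
    joint: JointUtilitySpec

    def __call__(self, p_eff, p_tox):
        return joint_utility(
            self.joint,
            marginal_utility(self.efficacy, p_eff),
            marginal_utility(self.toxicity, p_tox),
        )

    @classmethod
    def reference_dependent(
        cls,
        ref_eff: float,
        ref_tox: float,
        loss_aversion_eff: float,
        loss_aversion_tox: float,
        exp_gain_eff: float,
        exp_loss_eff: float,
        exp_gain_tox: float,
        exp_loss_tox: float,
        k_eff: float,
        k_tox: float,
    ) -> "UtilityFunction":
        return cls(
            efficacy=MarginalUtilitySpec(
                ref_eff, loss_aversion_eff, exp_gain_eff, exp_loss_eff, "efficacy"
            ),
            toxicity=MarginalUtilitySpec(
                ref_tox, loss_aversion_tox, exp_gain_tox, exp_loss_tox, "toxicity"
            ),
            joint=JointUtilitySpec(k_eff=k_eff, k_tox=k_tox),
        )

    @classmethod
    def efftoxu(cls, k11: float, k00: float) -> "UtilityFunction":
        """Linear-marginal (degenerate) stack; the references are value-irrelevant."""
        return cls.reference_dependent(
            ref_eff=0.5,
            ref_tox=0.5,
            loss_aversion_eff=1.0,
            loss_aversion_tox=1.0,
            exp_gain_eff=1.0,
            exp_loss_eff=1.0,
            exp_gain_tox=1.0,
            exp_loss_tox=1.0,
            k_eff=k11,
            k_tox=k00,
        )


def contour_grid(utility: UtilityFunction, n: int = 101):
    """Evaluate the joint utility on an n-by-n probability grid.

    Returns ``(p_eff, p_tox, u)`` where ``u[i, j] = utility(p_eff[j], p_tox[i])``,
    suitable for contour plotting or CSV export.
    """
    p = np.linspace(0.0, 1.0, n)
    pe, pt = np.meshgrid(p, p)
    return p, p, np.asarray(utility(pe, pt))
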