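"""Dose decisions from posterior summaries: admissibility, utility-based
stopping, posterior-expected-utility argmax, and the no-skip escalation cap.

Three rule variants are supported:

* ``conventional_admissibility`` - separate evidence floors on efficacy and
  toxicity exclude doses before the utility argmax; an empty admissible set
  stops the trial.
* ``utility_admissibility`` - a single rule excludes any dose whose posterior
  probability of falling below a reference utility contour is too high; an
  empty admissible set stops the trial.
* ``utility_trial_stop`` - the argmax runs over all doses; the trial stops
  only when every dose violates the utility contour rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .utility import UtilityFunction

__all__ = [
    "RULE_VARIANTS",
    "DesignConfig",
    "InterimDecision",
    "conventional_admissible",
    "utility_admissible",
    "select_dose",
    "final_selection",
]

RULE_VARIANTS = (
    "conventional_admissibility",
    "utility_admissibility",
    "utility_trial_stop",
)


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters of one trial variant.

    ``adm_eff = (threshold, evidence_floor)`` keeps a dose only if
    Pr(pi_E > threshold | y) exceeds the floor; ``adm_tox`` analogously for
    Pr(pi_T < threshold | y).  ``stop_contour = (pi_E*, pi_T*, pu)`` defines
    the reference utility u_ref = u(pi_E*, pi_T*): a dose violates the rule
    when Pr(u < u_ref | y) > 1 - pu.
    """

    utility: UtilityFunction
    cohort_size: int = 3
    max_n: int = 45
    start_dose_index: int = 0
    rule_variant: str = "conventional_admissibility"
    adm_eff: tuple = (0.5, 0.075)
    adm_tox: tuple = (0.4, 0.075)
    stop_contour: tuple | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.rule_variant not in RULE_VARIANTS:
            raise ConfigError(
                f"rule_variant must be one of {RULE_VARIANTS}, got {self.rule_variant!r}"
            )
        if self.cohort_size < 1:
            raise ConfigError(f"cohort_size must be >= 1, got {self.cohort_size}")
        if self.max_n < self.cohort_size or self.max_n % self.cohort_size:
            raise ConfigError(
                f"max_n ({self.max_n}) must be a positive multiple of "
                f"cohort_size ({self.cohort_size})"
            )
        if self.start_dose_index < 0:
            raise ConfigError("start_dose_index must be >= 0")
        for nm, pair in (("adm_eff", self.adm_eff), ("adm_tox", self.adm_tox)):
            thr, floor = pair
            if not (0 < thr < 1 and 0 < floor < 1):
                raise ConfigError(f"{nm}: threshold and evidence floor must lie in (0, 1)")
        if self.rule_variant != "conventional_admissibility" and self.stop_contour is None:
            raise ConfigError(
                f"rule_variant {self.rule_variant!r} requires stop_contour"
            )
        if self.stop_contour is not None:
            x, y, pu = self.stop_contour
            if not (0 < x < 1 and 0 < y < 1):
                raise ConfigError("stop_contour: contour point must lie in (0, 1)^2")
            if not 0 < pu < 1:
                raise ConfigError(f"stop_contour: pu must lie in (0, 1), got {pu}")

    @property
    def n_cohorts(self) -> int:
        return self.max_n // self.cohort_size

    def contour_reference_utility(self) -> float:
        """Joint utility at the elicited contour point (the stopping reference)."""
        if self.stop_contour is None:
            raise ConfigError("design has no stop_contour")
        x, y, _ = self.stop_contour
        return float(self.utility(x, y))


@dataclass(frozen=True)
class InterimDecision:
    """Outcome of one decision point."""

    action: str  # "treat_at_dose" | "stop_no_dose"
    dose_index: int | None
    expected_utilities: np.ndarray = field(default_factory=lambda: np.zeros(0))
    admissible: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    capped_by_no_skip: bool = False


def conventional_admissible(tail_probs: dict, config: DesignConfig) -> np.ndarray:
    """Boolean admissibility per dose under the separate efficacy/toxicity rules.

    A dose is admissible iff Pr(pi_E > threshold_E | y) > p_E and
    Pr(pi_T < threshold_T | y) > p_T.
    """
    _, floor_e = config.adm_eff
    _, floor_t = config.adm_tox
    return (np.asarray(tail_probs["pr_eff_above"]) > floor_e) & (
        np.asarray(tail_probs["pr_tox_below"]) > floor_t
    )


def utility_admissible(pr_utility_below: np.ndarray, config: DesignConfig) -> np.ndarray:
    """Boolean per-dose flags under the utility contour rule.

    A dose is excluded iff Pr(u < u_ref | y) > 1 - pu.
    """
    if config.stop_contour is None:
        raise ConfigError("utility rule requires stop_contour")
    pu = config.stop_contour[2]
    return np.asarray(pr_utility_below) <= 1.0 - pu


def _constrained_argmax(expected_utilities: np.ndarray, admissible: np.ndarray):
    eu = np.asarray(expected_utilities, dtype=float)
    adm = np.asarray(admissible, dtype=bool)
    if not adm.any():
        return None
    masked = np.where(adm, eu, -np.inf)
    # np.argmax takes the first maximum, so ties break to the lowest dose.
    return int(np.argmax(masked))


def select_dose(
    expected_utilities: np.ndarray,
    admissible: np.ndarray,
    highest_tried: int,
    config: DesignConfig,
) -> InterimDecision:
    """Interim decision: constrained argmax with the no-skip escalation cap.

    Under ``utility_trial_stop`` the argmax runs over all doses and
    ``admissible`` carries the per-dose contour flags used only for the
    all-doses-violate stopping check.  Ties break to the lowest dose index.
    """
    eu = np.asarray(expected_utilities, dtype=float)
    adm = np.asarray(admissible, dtype=bool)
    if config.rule_variant == "utility_trial_stop":
        if not adm.any():
            return InterimDecision("stop_no_dose", None, eu, adm)
        best = int(np.argmax(eu))
    else:
        best = _constrained_argmax(eu, adm)
        if best is None:
            return InterimDecision("stop_no_dose", None, eu, adm)
    capped = best > highest_tried + 1
    if capped:
        best = highest_tried + 1
    return InterimDecision("treat_at_dose", best, eu, adm, capped_by_no_skip=capped)


def final_selection(
    expected_utilities: np.ndarray,
    admissible: np.ndarray,
    config: DesignConfig,
) -> InterimDecision:
    """Final recommendation: same rules as the interim decision, without the
    no-skip cap (no further patients are treated).  ``stop_no_dose`` maps to
    "no dose selected"."""
    eu = np.asarray(expected_utilities, dtype=float)
    adm = np.asarray(admissible, dtype=bool)
    if config.rule_variant == "utility_trial_stop":
        if not adm.any():
            return InterimDecision("stop_no_dose", None, eu, adm)
        return InterimDecision("treat_at_dose", int(np.argmax(eu)), eu, adm)
    best = _constrained_argmax(eu, adm)
    if best is None:
        return InterimDecision("stop_no_dose", None, eu, adm)
    return InterimDecision("treat_at_dose", best, eu, adm)
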