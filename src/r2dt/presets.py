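"""Built-in design presets, the default dose grid and default priors.

The presets cover the study variants of the multiple-myeloma worked example:
a reference-dependent utility with efficacy reference 0.5, toxicity reference
0.35, loss aversion 2 and risk exponents 0.7 on every branch, joint corner
weights (0.25, 0.15); a linear-marginal (EffToxU-style) comparator with the
same corner weights; utility-contour admissibility and trial-stopping
variants at three contour points; and linear-marginal sensitivity variants.
"""

from __future__ import annotations

from .errors import ConfigError
from .model import DoseGrid, PriorSpec, center_log_dose
from .policy import DesignConfig
from .utility import UtilityFunction

__all__ = [
    "DEFAULT_DOSES",
    "default_grid",
    "default_prior",
    "r2dt_utility",
    "efftoxu_utility_stack",
    "preset_names",
    "get_preset",
]

DEFAULT_DOSES = (20.0, 30.0, 40.0, 50.0)

# Default normal priors for (mu_eff, beta_eff1, beta_eff2, mu_tox, beta_tox).
# Means are a least-squares fit of the two logistic curves to the average
# dose-response of the first six built-in scenarios on the default grid; the
# common sd of 2 on the logit scale is a weakly informative package default.
# These are package defaults, not published trial hyperparameters.
DEFAULT_PRIOR_MEAN = (0.4238, 1.4094, -0.2328, -1.2437, 1.2580)
DEFAULT_PRIOR_SD = (2.0, 2.0, 2.0, 2.0, 2.0)

_CONTOURS = {"i": (0.5, 0.35), "ii": (0.7, 0.4), "iii": (0.9, 0.4)}
_PU = 0.1


def default_grid() -> DoseGrid:
    return center_log_dose(DEFAULT_DOSES)


def default_prior() -> PriorSpec:
    return PriorSpec(mean=DEFAULT_PRIOR_MEAN, sd=DEFAULT_PRIOR_SD)


def r2dt_utility() -> UtilityFunction:
    """Reference-dependent utility stack of the primary design."""
    return UtilityFunction.reference_dependent(
        ref_eff=0.5,
        ref_tox=0.35,
        loss_aversion_eff=2.0,
        loss_aversion_tox=2.0,
        exp_gain_eff=0.7,
        exp_loss_eff=0.7,
        exp_gain_tox=0.7,
        exp_loss_tox=0.7,
        k_eff=0.25,
        k_tox=0.15,
    )


def efftoxu_utility_stack(k11: float = 0.25, k00: float = 0.15) -> UtilityFunction:
    return UtilityFunction.efftoxu(k11, k00)


def _design(utility, variant, contour=None, name="") -> DesignConfig:
    return DesignConfig(
        utility=utility,
        cohort_size=3,
        max_n=45,
        start_dose_index=0,
        rule_variant=variant,
        adm_eff=(0.5, 0.075),
        adm_tox=(0.4, 0.075),
        stop_contour=None if contour is None else (*contour, _PU),
        name=name,
    )


def _build_presets() -> dict:
    presets = {
        "R2DT1": lambda: _design(r2dt_utility(), "conventional_admissibility", name="R2DT1"),
        "EffToxU2": lambda: _design(
            efftoxu_utility_stack(), "conventional_admissibility", name="EffToxU2"
        ),
        "EffToxU5": lambda: _design(
            efftoxu_utility_stack(),
            "utility_admissibility",
            contour=_CONTOURS["i"],
            name="EffToxU5",
        ),
        "EffToxU7": lambda: _design(
            efftoxu_utility_stack(0.5, 0.3), "conventional_admissibility", name="EffToxU7"
        ),
    }
    for roman, contour in _CONTOURS.items():
        presets[f"R2DT3{roman}"] = (
            lambda c=contour, r=roman: _design(
                r2dt_utility(), "utility_admissibility", contour=c, name=f"R2DT3{r}"
            )
        )
        presets[f"R2DT4{roman}"] = (
            lambda c=contour, r=roman: _design(
                r2dt_utility(), "utility_trial_stop", contour=c, name=f"R2DT4{r}"
            )
        )
    return presets


_PRESETS = _build_presets()


def preset_names() -> tuple:
    return tuple(sorted(_PRESETS))


def get_preset(name: str) -> DesignConfig:
    """Expand a preset label into a fully parameterized :class:`DesignConfig`."""
    key = name.replace(" ", "").replace("(", "").replace(")", "")
    if key not in _PRESETS:
        raise ConfigError(f"unknown design preset {name!r}; known: {preset_names()}")
    return _PRESETS[key]()
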