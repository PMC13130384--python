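"""Whole-trial simulation and operating characteristics.

A simulated trial recruits cohorts of patients at the currently assigned
dose, draws independent Bernoulli efficacy and toxicity outcomes from fixed
scenario probabilities, refits the posterior after each cohort and applies
the design's decision rules until the maximum sample size is reached or the
trial stops.  Replicate studies aggregate per-dose selection percentages,
mean numbers of patients treated, and the percentage of trials ending with
no dose selected (NDS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .model import (
    DoseGrid,
    PriorSpec,
    TrialData,
    expected_utilities,
    posterior_tail_probs,
    sample_posterior,
)
from .policy import (
    DesignConfig,
    InterimDecision,
    conventional_admissible,
    final_selection,
    select_dose,
    utility_admissible,
)
from .utility import UtilityFunction

__all__ = [
    "Scenario",
    "TrialResult",
    "OperatingCharacteristics",
    "simulate_outcomes",
    "run_trial",
    "run_study",
    "builtin_scenarios",
    "optimal_dose_oracle",
]


@dataclass(frozen=True)
class Scenario:
    """Fixed true dose-response probabilities for one simulation scenario."""

    name: str
    true_eff: tuple
    true_tox: tuple
    optimal_dose: int | None = None  # 0-based; None means no dose should be selected

    def __post_init__(self) -> None:
        e = np.asarray(self.true_eff, dtype=float)
        t = np.asarray(self.true_tox, dtype=float)
        if e.shape != t.shape or e.ndim != 1:
            raise ConfigError("true_eff and true_tox must be equal-length vectors")
        if np.any((e <= 0) | (e >= 1)) or np.any((t <= 0) | (t >= 1)):
            raise ConfigError("scenario probabilities must lie strictly in (0, 1)")
        object.__setattr__(self, "true_eff", tuple(float(x) for x in e))
        object.__setattr__(self, "true_tox", tuple(float(x) for x in t))

    @property
    def k(self) -> int:
        return len(self.true_eff)


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    selected: int | None
    patients_per_dose: np.ndarray
    total_n: int
    stopped_early: bool
    trace: list = field(default_factory=list)
    failed: bool = False

    def __post_init__(self) -> None:
        if int(self.patients_per_dose.sum()) != self.total_n:
            raise ConfigError("patients_per_dose must sum to total_n")


@dataclass
class OperatingCharacteristics:
    """Aggregated study results over replicate trials."""

    pct_selection: np.ndarray
    pct_nds: float
    mean_patients: np.ndarray
    n_reps: int
    n_failed: int = 0

    @classmethod
    def from_results(cls, results, k: int) -> "OperatingCharacteristics":
        ok = [r for r in results if not r.failed]
        n_failed = len(results) - len(ok)
        if not ok:
            raise ConfigError("no successful replicates to aggregate")
        sel = np.zeros(k)
        nds = 0
        patients = np.zeros(k)
        for r in ok:
            if r.selected is None:
                nds += 1
            else:
                sel[r.selected] += 1
            patients += r.patients_per_dose
        n = len(ok)
        return cls(
            pct_selection=100.0 * sel / n,
            pct_nds=100.0 * nds / n,
            mean_patients=patients / n,
            n_reps=n,
            n_failed=n_failed,
        )

    def pool(self, other: "OperatingCharacteristics") -> "OperatingCharacteristics":
        """Exact pooling of two disjoint replicate batches."""
        n1, n2 = self.n_reps, other.n_reps
        n = n1 + n2
        return OperatingCharacteristics(
            pct_selection=(self.pct_selection * n1 + other.pct_selection * n2) / n,
            pct_nds=(self.pct_nds * n1 + other.pct_nds * n2) / n,
            mean_patients=(self.mean_patients * n1 + other.mean_patients * n2) / n,
            n_reps=n,
            n_failed=self.n_failed + other.n_failed,
        )


def simulate_outcomes(scenario: Scenario, dose_index: int, n: int, rng) -> tuple:
    """Independent Bernoulli efficacy and toxicity outcomes for ``n`` patients."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    y_eff = (rng.random(n) < scenario.true_eff[dose_index]).astype(int)
    y_tox = (rng.random(n) < scenario.true_tox[dose_index]).astype(int)
    return y_eff, y_tox


def _decision_inputs(draws, grid, design: DesignConfig):
    eu = expected_utilities(draws, grid, design.utility)
    if design.rule_variant == "conventional_admissibility":
        tails = posterior_tail_probs(
            draws, grid, eff_threshold=design.adm_eff[0], tox_threshold=design.adm_tox[0]
        )
        adm = conventional_admissible(tails, design)
    else:
        u_ref = design.contour_reference_utility()
        tails = posterior_tail_probs(
            draws, grid, utility=design.utility, u_ref=u_ref
        )
        adm = utility_admissible(tails["pr_utility_below"], design)
    return eu, adm, tails


def run_trial(
    scenario: Scenario,
    design: DesignConfig,
    prior: PriorSpec,
    grid: DoseGrid,
    seed=0,
    sampler_options: dict | None = None,
) -> TrialResult:
    """Simulate one trial of the design under the scenario.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; all outcome and
    sampler randomness derives from it.  If a posterior fit reports
    non-convergence it is retried once with a perturbed substream; a second
    failure marks the trial as failed (excluded from aggregation but counted).
    """
    if scenario.k != grid.k:
        raise ConfigError("scenario and dose grid have different numbers of doses")
    opts = dict(sampler_options or {})
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_out, child_mcmc = ss.spawn(2)
    rng = np.random.default_rng(child_out)
    mcmc_seeds = child_mcmc.spawn(2 * design.n_cohorts)

    data = TrialData()
    current = design.start_dose_index
    highest = -1
    trace: list = []
    selected: int | None = None
    stopped_early = False
    failed = False

    for cohort in range(design.n_cohorts):
        y_eff, y_tox = simulate_outcomes(scenario, current, design.cohort_size, rng)
        data.add_cohort(current, y_eff, y_tox)
        highest = max(highest, current)

        draws = sample_posterior(data, prior, grid, seed=mcmc_seeds[2 * cohort], **opts)
        if not draws.provenance.get("converged", True):
            draws = sample_posterior(
                data, prior, grid, seed=mcmc_seeds[2 * cohort + 1], **opts
            )
            if not draws.provenance.get("converged", True):
                failed = True

        eu, adm, _ = _decision_inputs(draws, grid, design)
        last = cohort == design.n_cohorts - 1
        if last:
            decision = final_selection(eu, adm, design)
        else:
            decision = select_dose(eu, adm, highest, design)
        trace.append(
            {
                "cohort": cohort + 1,
                "assigned_dose": current + 1,
                "n_total": data.n,
                "expected_utilities": decision.expected_utilities.tolist(),
                "admissible": decision.admissible.tolist(),
                "action": decision.action,
                "next_dose": None if decision.dose_index is None else decision.dose_index + 1,
            }
        )
        if failed:
            break
        if decision.action == "stop_no_dose":
            stopped_early = not last
            selected = None
            break
        if last:
            selected = decision.dose_index
        else:
            current = decision.dose_index

    return TrialResult(
        selected=None if failed else selected,
        patients_per_dose=data.patients_per_dose(grid),
        total_n=data.n,
        stopped_early=stopped_early,
        trace=trace,
        failed=failed,
    )


def run_study(
    scenario: Scenario,
    design: DesignConfig,
    prior: PriorSpec,
    grid: DoseGrid,
    n_reps: int,
    seed=0,
    sampler_options: dict | None = None,
    rep_seeds=None,
    return_results: bool = False,
):
    """Replicate ``run_trial`` and aggregate operating characteristics.

    The master seed spawns one independent substream per replicate, so a study
    split across two calls (via ``rep_seeds``) pools to the same result as a
    single run.  Mean patients per dose averages over all replicates,
    including early-stopped trials.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if rep_seeds is None:
        rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    elif len(rep_seeds) != n_reps:
        raise ConfigError("rep_seeds must have length n_reps")
    results = [
        run_trial(scenario, design, prior, grid, seed=s, sampler_options=sampler_options)
        for s in rep_seeds
    ]
    oc = OperatingCharacteristics.from_results(results, grid.k)
    return (oc, results) if return_results else oc


_SCENARIO_TABLE = [
    # (true_eff, true_tox, optimal 0-based or None)
    ((0.30, 0.57, 0.75, 0.85), (0.05, 0.08, 0.12, 0.15), 3),
    ((0.37, 0.45, 0.51, 0.55), (0.05, 0.08, 0.12, 0.15), 3),
    ((0.30, 0.57, 0.75, 0.85), (0.05, 0.13, 0.23, 0.35), 2),
    ((0.37, 0.45, 0.51, 0.55), (0.05, 0.13, 0.23, 0.35), 2),
    ((0.55, 0.75, 0.85, 0.90), (0.35, 0.42, 0.47, 0.51), 0),
    ((0.60, 0.62, 0.63, 0.64), (0.26, 0.35, 0.42, 0.48), 0),
    ((0.26, 0.60, 0.70, 0.70), (0.05, 0.13, 0.23, 0.35), 2),
    ((0.26, 0.60, 0.70, 0.70), (0.18, 0.35, 0.50, 0.62), 1),
    ((0.55, 0.75, 0.85, 0.90), (0.45, 0.57, 0.64, 0.70), None),
    ((0.20, 0.30, 0.38, 0.45), (0.05, 0.08, 0.12, 0.15), None),
]


def builtin_scenarios() -> list:
    """The ten built-in dose-response scenarios for the default 4-dose grid.

    ``optimal_dose`` records the scenario's target answer: the best dose under
    the reference-dependent utility after excluding doses with true toxicity
    above 0.4 or true efficacy below 0.5, or ``None`` when every dose is
    excluded (the trial should select no dose).
    """
    return [
        Scenario(name=f"scenario{i + 1}", true_eff=e, true_tox=t, optimal_dose=o)
        for i, (e, t, o) in enumerate(_SCENARIO_TABLE)
    ]


def optimal_dose_oracle(
    scenario: Scenario,
    design: DesignConfig,
    tox_cap: float = 0.4,
    eff_floor: float = 0.5,
) -> int | None:
    """True-optimum oracle: exclude doses with toxicity above ``tox_cap`` or
    efficacy below ``eff_floor``, then maximize the design's utility at the
    true probabilities.  Returns ``None`` when every dose is excluded."""
    e = np.asarray(scenario.true_eff)
    t = np.asarray(scenario.true_tox)
    ok = (t <= tox_cap) & (e >= eff_floor)
    if not ok.any():
        return None
    u = np.asarray(design.utility(e, t))
    return int(np.argmax(np.where(ok, u, -np.inf)))
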