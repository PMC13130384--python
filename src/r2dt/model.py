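"""Bayesian dose-response model: logistic efficacy/toxicity curves, normal
priors, posterior sampling, and the posterior functionals used by decisions.

Doses are transformed by centering the log dose at its mean (equivalently,
scaling by the geometric mean of the grid).  Efficacy follows a quadratic
logistic model in the transformed dose, allowing non-monotone dose-response;
toxicity follows a linear logistic model and is monotone in dose for a fixed
parameter vector.  The five regression coefficients carry independent normal
priors and efficacy and toxicity outcomes are modeled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .errors import ConfigError
from .utility import UtilityFunction

__all__ = [
    "PARAM_NAMES",
    "DoseGrid",
    "ModelParams",
    "PriorSpec",
    "TrialData",
    "PosteriorDraws",
    "center_log_dose",
    "prob_efficacy",
    "prob_toxicity",
    "dose_response_probs",
    "log_posterior",
    "sample_posterior",
    "posterior_expected_utility",
    "expected_utilities",
    "posterior_tail_probs",
]

PARAM_NAMES = ("mu_eff", "beta_eff1", "beta_eff2", "mu_tox", "beta_tox")


@dataclass(frozen=True)
class DoseGrid:
    """Strictly increasing dose grid with centered-log-dose covariates."""

    doses: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ConfigError("doses: need at least two dose levels")
        if np.any(d <= 0):
            raise ConfigError(f"doses must be positive, got {self.doses}")
        if np.any(np.diff(d) <= 0):
            raise ConfigError(f"doses must be strictly increasing, got {self.doses}")
        object.__setattr__(self, "doses", tuple(float(x) for x in d))

    @property
    def k(self) -> int:
        return len(self.doses)

    @property
    def centered_log(self) -> np.ndarray:
        logd = np.log(np.asarray(self.doses))
        return logd - logd.mean()


def center_log_dose(doses: Sequence[float]) -> DoseGrid:
    """Build a :class:`DoseGrid`; the covariate is log(d) minus its grid mean."""
    return DoseGrid(tuple(doses))


@dataclass(frozen=True)
class ModelParams:
    """One parameter vector theta = (mu_eff, beta_eff1, beta_eff2, mu_tox, beta_tox)."""

    mu_eff: float
    beta_eff1: float
    beta_eff2: float
    mu_tox: float
    beta_tox: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mu_eff, self.beta_eff1, self.beta_eff2, self.mu_tox, self.beta_tox]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelParams":
        return cls(*(float(x) for x in np.asarray(arr, dtype=float)))


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors, one (mean, sd) pair per model coefficient."""

    mean: tuple
    sd: tuple

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if m.shape != (5,) or s.shape != (5,):
            raise ConfigError(
                f"prior mean and sd must each have 5 entries ({', '.join(PARAM_NAMES)})"
            )
        if np.any(s <= 0):
            raise ConfigError(f"prior sd must be positive, got {self.sd}")
        object.__setattr__(self, "mean", tuple(float(x) for x in m))
        object.__setattr__(self, "sd", tuple(float(x) for x in s))

    @property
    def mean_arr(self) -> np.ndarray:
        return np.asarray(self.mean)

    @property
    def sd_arr(self) -> np.ndarray:
        return np.asarray(self.sd)


@dataclass
class TrialData:
    """Accumulated per-patient records (0-based dose index, binary outcomes)."""

    dose_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    y_eff: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    y_tox: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.dose_index = np.asarray(self.dose_index, dtype=int)
        self.y_eff = np.asarray(self.y_eff, dtype=int)
        self.y_tox = np.asarray(self.y_tox, dtype=int)
        if not (len(self.dose_index) == len(self.y_eff) == len(self.y_tox)):
            raise ConfigError("dose_index, y_eff, y_tox must have equal length")
        for name, y in (("y_eff", self.y_eff), ("y_tox", self.y_tox)):
            if y.size and not np.isin(y, (0, 1)).all():
                raise ConfigError(f"{name} must be binary")

    @property
    def n(self) -> int:
        return len(self.dose_index)

    def validate_indices(self, grid: DoseGrid) -> None:
        if self.n and (self.dose_index.min() < 0 or self.dose_index.max() >= grid.k):
            raise ConfigError(
                f"dose_index out of range 0..{grid.k - 1}: {sorted(set(self.dose_index))}"
            )

    def add_cohort(self, dose_index: int, y_eff: np.ndarray, y_tox: np.ndarray) -> None:
        m = len(np.atleast_1d(y_eff))
        self.dose_index = np.concatenate([self.dose_index, np.full(m, dose_index, dtype=int)])
        self.y_eff = np.concatenate([self.y_eff, np.atleast_1d(y_eff).astype(int)])
        self.y_tox = np.concatenate([self.y_tox, np.atleast_1d(y_tox).astype(int)])

    def counts(self, grid: DoseGrid) -> dict:
        """Per-dose sufficient statistics of the independent Bernoulli likelihood."""
        self.validate_indices(grid)
        k = grid.k
        n = np.bincount(self.dose_index, minlength=k)
        e1 = np.bincount(self.dose_index, weights=self.y_eff, minlength=k)
        t1 = np.bincount(self.dose_index, weights=self.y_tox, minlength=k)
        return {"n": n.astype(float), "eff": e1, "tox": t1}

    def patients_per_dose(self, grid: DoseGrid) -> np.ndarray:
        return np.bincount(self.dose_index, minlength=grid.k)


@dataclass(frozen=True)
class PosteriorDraws:
    """Sampled parameter vectors (S, 5) with sampling provenance."""

    params: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 5 or p.shape[0] < 1:
            raise ConfigError("params must be a (S, 5) array with S >= 1")
        if not np.isfinite(p).all():
            raise ConfigError("posterior draws contain non-finite values")
        object.__setattr__(self, "params", p)

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    def probs(self, grid: DoseGrid) -> tuple:
        """Per-draw dose-response probabilities, each of shape (S, k)."""
        return dose_response_probs(self.params, grid)


def prob_efficacy(theta, fd):
    """Inverse-logit quadratic efficacy curve at centered log dose ``fd``."""
    arr = theta.as_array() if isinstance(theta, ModelParams) else np.asarray(theta, float)
    fd = np.asarray(fd, dtype=float)
    eta = arr[..., 0, None] + arr[..., 1, None] * fd + arr[..., 2, None] * fd**2
    out = expit(np.squeeze(eta))
    return out if out.ndim else float(out)


def prob_toxicity(theta, fd):
    """Inverse-logit linear toxicity curve at centered log dose ``fd``."""
    arr = theta.as_array() if isinstance(theta, ModelParams) else np.asarray(theta, float)
    fd = np.asarray(fd, dtype=float)
    eta = arr[..., 3, None] + arr[..., 4, None] * fd
    out = expit(np.squeeze(eta))
    return out if out.ndim else float(out)


def dose_response_probs(params: np.ndarray, grid: DoseGrid) -> tuple:
    """Vectorized (S, k) efficacy/toxicity probabilities over a draw matrix."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    fd = grid.centered_log
    eta_e = params[:, [0]] + params[:, [1]] * fd + params[:, [2]] * fd**2
    eta_t = params[:, [3]] + params[:, [4]] * fd
    return expit(eta_e), expit(eta_t)


def _log_lik(params: np.ndarray, counts: dict, grid: DoseGrid) -> np.ndarray:
    params = np.atleast_2d(params)
    fd = grid.centered_log
    eta_e = params[:, [0]] + params[:, [1]] * fd + params[:, [2]] * fd**2
    eta_t = params[:, [3]] + params[:, [4]] * fd
    # Bernoulli log-likelihood from per-dose counts, written with log-sigmoid
    # terms for numerical stability:  y*eta - n*log(1 + e^eta).
    def bern(eta, y1, n):
        return y1 * eta - n * np.logaddexp(0.0, eta)

    return bern(eta_e, counts["eff"], counts["n"]).sum(axis=1) + bern(
        eta_t, counts["tox"], counts["n"]
    ).sum(axis=1)


def log_posterior(theta, data: TrialData, prior: PriorSpec, grid: DoseGrid):
    """Unnormalized log posterior density at ``theta`` (vectorized over rows)."""
    arr = theta.as_array() if isinstance(theta, ModelParams) else np.asarray(theta, float)
    params = np.atleast_2d(arr)
    counts = data.counts(grid)
    z = (params - prior.mean_arr) / prior.sd_arr
    log_prior = -0.5 * (z**2).sum(axis=1) - np.log(prior.sd_arr).sum() - 2.5 * np.log(2 * np.pi)
    out = log_prior + _log_lik(params, counts, grid)
    return float(out[0]) if arr.ndim == 1 else out


def _neg_log_post(x, counts, prior, grid):
    params = x[None, :]
    z = (x - prior.mean_arr) / prior.sd_arr
    return 0.5 * float((z**2).sum()) - float(_log_lik(params, counts, grid)[0])


def _laplace_draws(counts, prior, grid, n_draws, rng):
    res = optimize.minimize(
        _neg_log_post, prior.mean_arr, args=(counts, prior, grid), method="BFGS"
    )
    mode = res.x
    # Numerical Hessian by central differences.
    h = 1e-4
    H = np.zeros((5, 5))
    for i in range(5):
        for j in range(i, 5):
            xpp = mode.copy(); xpp[i] += h; xpp[j] += h
            xpm = mode.copy(); xpm[i] += h; xpm[j] -= h
            xmp = mode.copy(); xmp[i] -= h; xmp[j] += h
            xmm = mode.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (
                _neg_log_post(xpp, counts, prior, grid)
                - _neg_log_post(xpm, counts, prior, grid)
                - _neg_log_post(xmp, counts, prior, grid)
                + _neg_log_post(xmm, counts, prior, grid)
            ) / (4 * h * h)
    cov = np.linalg.inv(H + 1e-10 * np.eye(5))
    draws = rng.multivariate_normal(mode, cov, size=n_draws, method="cholesky")
    return draws, {"converged": bool(res.success), "map": mode.tolist()}


def _mcmc_draws(counts, prior, grid, n_draws, rng, n_chains, warmup, thin):
    """Adaptive random-walk Metropolis, vectorized across parallel chains.

    Warmup adapts a global proposal scale toward ~30% acceptance on a
    diagonal (prior-sd shaped) proposal, then re-estimates the proposal
    covariance from the warmup states and adapts the scale once more.
    """
    dim = 5
    x = prior.mean_arr + 0.1 * prior.sd_arr * rng.standard_normal((n_chains, dim))
    lp = _log_lik(x, counts, grid) + _log_prior_vec(x, prior)

    half = warmup // 2
    log_scale = np.log(2.38 / np.sqrt(dim))
    chol = np.diag(prior.sd_arr)
    kept_warm = []
    accepts = 0
    total = 0

    def step(x, lp, chol, scale):
        prop = x + scale * rng.standard_normal((n_chains, dim)) @ chol.T
        lp_prop = _log_lik(prop, counts, grid) + _log_prior_vec(prop, prior)
        accept = np.log(rng.random(n_chains)) < lp_prop - lp
        x = np.where(accept[:, None], prop, x)
        lp = np.where(accept, lp_prop, lp)
        return x, lp, accept

    for it in range(warmup):
        x, lp, accept = step(x, lp, chol, np.exp(log_scale))
        log_scale += 0.05 * (accept.mean() - 0.3)
        if it >= half // 2:
            kept_warm.append(x.copy())
        if it == half:
            states = np.concatenate(kept_warm, axis=0)
            cov = np.cov(states.T) + 1e-8 * np.eye(dim)
            chol = np.linalg.cholesky(cov)
            log_scale = np.log(2.38 / np.sqrt(dim))

    keep_per_chain = int(np.ceil(n_draws / n_chains))
    out = np.empty((keep_per_chain, n_chains, dim))
    for it in range(keep_per_chain * thin):
        x, lp, accept = step(x, lp, chol, np.exp(log_scale))
        accepts += int(accept.sum())
        total += n_chains
        if (it + 1) % thin == 0:
            out[(it + 1) // thin - 1] = x
    draws = out.reshape(-1, dim)[:n_draws]
    acc_rate = accepts / total
    return draws, {"acceptance_rate": acc_rate, "converged": bool(0.1 <= acc_rate <= 0.7)}


def _log_prior_vec(params, prior):
    z = (params - prior.mean_arr) / prior.sd_arr
    return -0.5 * (z**2).sum(axis=1)


def sample_posterior(
    data: TrialData,
    prior: PriorSpec,
    grid: DoseGrid,
    n_draws: int = 2000,
    seed=0,
    method: str = "mcmc",
    n_chains: int = 8,
    warmup: int = 500,
    thin: int = 3,
) -> PosteriorDraws:
    """Draw from the posterior of the five dose-response coefficients.

    ``method="mcmc"`` (reference implementation) runs the adaptive random-walk
    sampler; ``method="laplace"`` is a fast deterministic Gaussian
    approximation around the posterior mode intended for large simulation
    sweeps.  ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``Generator``; identical seeds give identical draws.
    """
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    data.validate_indices(grid)
    counts = data.counts(grid)
    rng = np.random.default_rng(seed)
    if method == "mcmc":
        draws, diag = _mcmc_draws(counts, prior, grid, n_draws, rng, n_chains, warmup, thin)
    elif method == "laplace":
        draws, diag = _laplace_draws(counts, prior, grid, n_draws, rng)
    else:
        raise ConfigError(f"unknown sampler method {method!r}")
    provenance = {
        "method": method,
        "n_draws": int(n_draws),
        "n_data": int(data.n),
        "seed": repr(seed),
        **diag,
    }
    return PosteriorDraws(params=draws, provenance=provenance)


def posterior_expected_utility(
    draws: PosteriorDraws, grid: DoseGrid, dose_index: int, utility: UtilityFunction
) -> float:
    """Monte-Carlo posterior mean of u(pi_E(theta, d), pi_T(theta, d))."""
    pe, pt = draws.probs(grid)
    return float(np.mean(utility(pe[:, dose_index], pt[:, dose_index])))


def expected_utilities(
    draws: PosteriorDraws, grid: DoseGrid, utility: UtilityFunction
) -> np.ndarray:
    """Posterior expected utility at every dose, shape (k,)."""
    pe, pt = draws.probs(grid)
    return np.asarray(utility(pe, pt)).mean(axis=0)


def posterior_tail_probs(
    draws: PosteriorDraws,
    grid: DoseGrid,
    dose_index=None,
    eff_threshold: float = 0.5,
    tox_threshold: float = 0.4,
    utility: UtilityFunction | None = None,
    u_ref: float | None = None,
) -> dict:
    """Monte-Carlo tail probabilities used by admissibility and stopping rules.

    Returns ``pr_eff_above`` = Pr(pi_E > eff_threshold | y), ``pr_tox_below``
    = Pr(pi_T < tox_threshold | y) and, when a utility stack and reference
    utility are supplied, ``pr_utility_below`` = Pr(u(pi_E, pi_T) < u_ref | y).
    With ``dose_index=None`` each entry is a vector over all doses.
    """
    for name, thr in (("eff_threshold", eff_threshold), ("tox_threshold", tox_threshold)):
        if not 0.0 < thr < 1.0:
            raise ConfigError(f"{name} must lie in (0, 1), got {thr}")
    pe, pt = draws.probs(grid)
    if dose_index is not None:
        pe, pt = pe[:, [dose_index]], pt[:, [dose_index]]
    out = {
        "pr_eff_above": (pe > eff_threshold).mean(axis=0),
        "pr_tox_below": (pt < tox_threshold).mean(axis=0),
    }
    if utility is not None and u_ref is not None:
        if not 0.0 <= u_ref <= 1.0:
            raise ConfigError(f"u_ref must lie in [0, 1], got {u_ref}")
        out["pr_utility_below"] = (np.asarray(utility(pe, pt)) < u_ref).mean(axis=0)
    if dose_index is not None:
        out = {k: float(v[0]) for k, v in out.items()}
    return out
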