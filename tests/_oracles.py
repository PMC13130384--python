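"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (per-patient
loops, dense-grid numerical integration) and never calls the code paths it
checks.
"""

import math

import numpy as np


def brute_log_posterior(theta, dose_index, y_eff, y_tox, fd, prior_mean, prior_sd):
    """Per-patient log posterior: normal log prior plus Bernoulli log likelihoods."""
    mu_e, b1, b2, mu_t, bt = theta
    total = 0.0
    for m, s, x in zip(prior_mean, prior_sd, theta):
        total += -0.5 * math.log(2 * math.pi) - math.log(s) - 0.5 * ((x - m) / s) ** 2
    for j, ye, yt in zip(dose_index, y_eff, y_tox):
        f = fd[j]
        pe = 1.0 / (1.0 + math.exp(-(mu_e + b1 * f + b2 * f * f)))
        pt = 1.0 / (1.0 + math.exp(-(mu_t + bt * f)))
        total += math.log(pe if ye else 1.0 - pe)
        total += math.log(pt if yt else 1.0 - pt)
    return total


def quadrature_posterior_mean_eff(
    dose_index, y_eff, fd, prior_mean, prior_sd, n_grid=301, half_width=6.0
):
    """Posterior mean of the efficacy probability at each dose, for the
    restricted two-parameter efficacy model (intercept and linear slope, no
    quadratic term), by dense-grid quadrature over the parameter plane."""
    m0, m1 = prior_mean
    s0, s1 = prior_sd
    a = np.linspace(m0 - half_width * s0, m0 + half_width * s0, n_grid)
    b = np.linspace(m1 - half_width * s1, m1 + half_width * s1, n_grid)
    A, B = np.meshgrid(a, b, indexing="ij")
    log_p = -0.5 * (((A - m0) / s0) ** 2 + ((B - m1) / s1) ** 2)
    for j, y in zip(dose_index, y_eff):
        eta = A + B * fd[j]
        # log Bernoulli(y; expit(eta)) = y*eta - log(1 + e^eta)
        log_p += y * eta - np.logaddexp(0.0, eta)
    w = np.exp(log_p - log_p.max())
    w /= w.sum()
    means = []
    for f in fd:
        pe = 1.0 / (1.0 + np.exp(-(A + B * f)))
        means.append(float((w * pe).sum()))
    return np.array(means)


def quadrature_tail_prob_eff(
    dose_index, y_eff, fd, prior_mean, prior_sd, threshold, n_grid=301, half_width=6.0
):
    """Pr(pi_E(d) > threshold | data) per dose, same restricted model."""
    m0, m1 = prior_mean
    s0, s1 = prior_sd
    a = np.linspace(m0 - half_width * s0, m0 + half_width * s0, n_grid)
    b = np.linspace(m1 - half_width * s1, m1 + half_width * s1, n_grid)
    A, B = np.meshgrid(a, b, indexing="ij")
    log_p = -0.5 * (((A - m0) / s0) ** 2 + ((B - m1) / s1) ** 2)
    for j, y in zip(dose_index, y_eff):
        eta = A + B * fd[j]
        log_p += y * eta - np.logaddexp(0.0, eta)
    w = np.exp(log_p - log_p.max())
    w /= w.sum()
    out = []
    for f in fd:
        pe = 1.0 / (1.0 + np.exp(-(A + B * f)))
        out.append(float(w[pe > threshold].sum()))
    return np.array(out)
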