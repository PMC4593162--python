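"""Adaptive Metropolis sampler and convergence diagnostics.

Random-walk Metropolis with the Haario adaptive proposal: after an initial
adaptation delay the proposal covariance is s_d * (empirical covariance of
the past chain + eps * I) with s_d = 2.4^2 / d, times a global scale factor
tuned by Robbins-Monro toward a 0.234 acceptance rate. A single seeded chain
is bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain schedule; defaults give 1000 retained draws from 160k iterations."""

    n_iter: int = 160000
    burn_in: int = 32000
    thin: int = 128
    adapt_start: int = 500
    target_draws: int = 1000
    rng_seed: int = 0
    initial_scale: float = 0.1  # pre-adaptation isotropic proposal SD (per sqrt(d))
    epsilon: float = 1e-6
    target_acceptance: float = 0.234
    scale_decay: float = 0.7    # Robbins-Monro step exponent for the global scale

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if (self.n_iter - self.burn_in) // self.thin < self.target_draws:
            raise ValueError(
                f"chain of {self.n_iter} iterations with burn_in {self.burn_in} and "
                f"thin {self.thin} cannot yield {self.target_draws} draws")


@dataclass
class ChainResult:
    chain: np.ndarray          # n_iter x d (post-init states)
    log_posts: np.ndarray
    acceptance_rate: float

    def retained(self, settings: MCMCSettings) -> np.ndarray:
        """Exactly ``target_draws`` evenly thinned post-burn-in states."""
        post = self.chain[settings.burn_in:]
        idx = np.arange(0, len(post), settings.thin)[: settings.target_draws]
        if len(idx) < settings.target_draws:
            raise ValueError(
                f"chain too short: need {settings.target_draws} draws, have {len(idx)}; "
                f"increase n_iter to >= {settings.burn_in + settings.target_draws * settings.thin}")
        return post[idx]


def adaptive_metropolis(log_posterior, init, settings: MCMCSettings,
                        initial_cov: np.ndarray | None = None) -> ChainResult:
    """Run one adaptive Metropolis chain from ``init``.

    ``log_posterior`` maps a parameter vector to a float; it must be finite at
    ``init``. Proposal covariance is updated from the running empirical
    moments of the chain once ``adapt_start`` states have accumulated;
    ``initial_cov`` (e.g. a Laplace approximation at the mode) seeds the
    pre-adaptation proposal.
    """
    x = np.asarray(init, dtype=float).copy()
    d = x.size
    lp = float(log_posterior(x))
    if not np.isfinite(lp):
        raise ValueError("log-posterior is not finite at the initial state")

    rng = np.random.default_rng(settings.rng_seed)
    s_d = 2.4 ** 2 / d
    chain = np.empty((settings.n_iter, d))
    lps = np.empty(settings.n_iter)

    # running moments for the adaptive covariance
    mean = x.copy()
    m2 = np.zeros((d, d))  # sum of outer products of deviations
    count = 1

    if initial_cov is not None:
        chol = np.linalg.cholesky(s_d * (initial_cov + settings.epsilon * np.eye(d)))
    else:
        chol = settings.initial_scale / np.sqrt(d) * np.eye(d)
    log_scale = 0.0
    accepted = 0
    for t in range(settings.n_iter):
        prop = x + np.exp(0.5 * log_scale) * (chol @ rng.standard_normal(d))
        lp_prop = float(log_posterior(prop))
        alpha = min(1.0, np.exp(min(lp_prop - lp, 0.0))) if np.isfinite(lp_prop) else 0.0
        if rng.random() < alpha:
            x, lp = prop, lp_prop
            accepted += 1
        chain[t] = x
        lps[t] = lp

        delta = x - mean
        mean += delta / (count + 1)
        m2 += np.outer(delta, x - mean)
        count += 1

        log_scale += (t + 1) ** -settings.scale_decay * (alpha - settings.target_acceptance)
        if t >= settings.adapt_start and (t % 50 == 0 or t == settings.adapt_start):
            cov = m2 / (count - 1)
            prop_cov = s_d * (cov + settings.epsilon * np.eye(d))
            chol = np.linalg.cholesky(prop_cov)

    rate = accepted / settings.n_iter
    if not 0.05 <= rate <= 0.7:
        warnings.warn(f"Metropolis acceptance rate {rate:.3f} outside [0.05, 0.7]; "
                      "check scaling or chain length", stacklevel=2)
    return ChainResult(chain=chain, log_posts=lps, acceptance_rate=rate)


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter for a single chain (n_draws x d)."""
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    n = (draws.shape[0] // 2) * 2
    halves = draws[:n].reshape(2, n // 2, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(halves))
    return np.asarray(r["x"])
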