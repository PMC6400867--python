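"""Self-contained MCMC for the hierarchical model.

Conjugate Gibbs updates for every location block (fixed-effect
coefficients jointly, random intercepts, the ridge hyperparameter) and
univariate slice updates on the log scale for the two standard
deviations.  Chains are initialized overdispersed and are fully
reproducible under a seed: chain c of seed s always sees the same stream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List

import numpy as np

from ..errors import ConfigurationError, InitializationError
from .design import Design
from .model import ParamState, log_posterior
from .priors import PriorSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 25_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ConfigurationError("need at least one chain")
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ConfigurationError("thinning must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning

    @property
    def total_retained(self) -> int:
        return self.chains * self.retained_per_chain


@dataclass
class Chains:
    """Retained draws: array of shape (chains, draws, parameters)."""

    param_names: List[str]
    draws: np.ndarray
    n_beta: int
    n_cmp: int
    n_alpha: int

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws of one parameter, shape (chains, draws)."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def beta_draws(self) -> np.ndarray:
        """(total_draws, n_beta) pooled fixed-effect draws."""
        return self.draws[:, :, : self.n_beta].reshape(-1, self.n_beta)

    def alpha_draws(self) -> np.ndarray:
        a0 = self.n_beta
        return self.draws[:, :, a0 : a0 + self.n_alpha].reshape(-1, self.n_alpha)

    def scalar_draws(self, name: str) -> np.ndarray:
        return self.pooled(name)

    def state_at(self, flat_index: int) -> ParamState:
        """Reconstruct the parameter state of one pooled draw."""
        flat = self.draws.reshape(-1, self.draws.shape[2])[flat_index]
        return self._state_from_row(flat)

    def mean_state(self) -> ParamState:
        flat = self.draws.reshape(-1, self.draws.shape[2]).mean(axis=0)
        return self._state_from_row(flat)

    def _state_from_row(self, row: np.ndarray) -> ParamState:
        a0 = self.n_beta
        return ParamState(
            beta=row[:a0].copy(),
            alpha=row[a0 : a0 + self.n_alpha].copy(),
            mu_alpha=float(row[self.index("mu_alpha")]),
            sigma_y=float(row[self.index("sigma_y")]),
            sigma_alpha=float(row[self.index("sigma_alpha")]),
        )


def slice_sample(
    logf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampler (stepping out + shrinkage, Neal 2003)."""
    fx0 = logf(x0)
    if not np.isfinite(fx0):
        raise ValueError("slice_sample started outside the support")
    log_u = fx0 + math.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logf(left) > log_u:
        left -= w
        j -= 1
    while k > 0 and logf(right) > log_u:
        right += w
        k -= 1
    for _ in range(1000):
        x1 = left + (right - left) * rng.random()
        if logf(x1) > log_u:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological shrinkage; keep current value


def _sigma_log_conditional(
    n_terms: int, sum_sq: float, scale: float, on_variance: bool
) -> Callable[[float], float]:
    """Log conditional of log(sigma) given its quadratic-form statistics."""

    def logf(u: float) -> float:
        sigma = math.exp(u)
        val = -n_terms * u - sum_sq / (2.0 * sigma * sigma)
        x = sigma * sigma if on_variance else sigma
        # half-Cauchy density plus the log-scale Jacobian
        val += math.log(2.0 / (math.pi * scale * (1.0 + (x / scale) ** 2)))
        return val + u

    return logf


def _initial_state(
    design: Design, priors: PriorSet, rng: np.random.Generator
) -> ParamState:
    """Overdispersed start drawn from (capped) priors."""
    p, J = len(design.columns), design.n_ids
    mu_sd = min(1.0 / math.sqrt(priors.mu_alpha_precision), 10.0)
    beta_sd = min(1.0 / math.sqrt(priors.beta_precision), 10.0)
    cmp_sd = min(1.0 / math.sqrt(priors.cmp_precision), 10.0)
    mu_alpha = rng.normal(0.0, mu_sd)
    beta = np.empty(p)
    beta[: design.n_cmp] = rng.normal(mu_alpha, cmp_sd, size=design.n_cmp)
    beta[design.n_cmp :] = rng.normal(0.0, beta_sd, size=p - design.n_cmp)
    sigma_y = (
        priors.sigma_y_fixed
        if priors.sigma_y_fixed is not None
        else float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
    )
    sigma_alpha = (
        priors.sigma_alpha_fixed
        if priors.sigma_alpha_fixed is not None
        else float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
    )
    alpha = rng.normal(0.0, sigma_alpha, size=J)
    return ParamState(beta=beta, alpha=alpha, mu_alpha=mu_alpha,
                      sigma_y=sigma_y, sigma_alpha=sigma_alpha)


def run_mcmc(design: Design, priors: PriorSet, config: McmcConfig) -> Chains:
    """Run all chains and return the retained, thinned draws.

    Parameter order: fixed-effect columns (composition block first, labeled
    as in the design), per-id intercepts ``alpha[<id>]``, then ``mu_alpha``,
    ``sigma_y``, ``sigma_alpha``.
    """
    p, J, n = len(design.columns), design.n_ids, design.n_obs
    param_names = (
        list(design.columns)
        + [f"alpha[{sid}]" for sid in design.id_labels]
        + ["mu_alpha", "sigma_y", "sigma_alpha"]
    )
    n_params = len(param_names)
    n_ret = config.retained_per_chain
    draws = np.empty((config.chains, n_ret, n_params))

    X, y, idx = design.X, design.y, design.id_index
    XtX = X.T @ X if n else np.zeros((p, p))
    n_per_id = (
        np.bincount(idx, minlength=J).astype(float) if n and J else np.zeros(J)
    )
    prior_prec = np.full(p, priors.beta_precision)
    prior_prec[: design.n_cmp] = priors.cmp_precision
    n_cmp = design.n_cmp

    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    for c, child in enumerate(chain_seeds):
        rng = np.random.default_rng(child)
        state = None
        for _ in range(20):
            candidate = _initial_state(design, priors, rng)
            if np.isfinite(log_posterior(candidate, design, priors)):
                state = candidate
                break
        if state is None:
            raise InitializationError(
                f"chain {c}: no finite starting state after 20 attempts"
            )
        beta, alpha = state.beta, state.alpha
        mu_alpha, sigma_y, sigma_alpha = (
            state.mu_alpha, state.sigma_y, state.sigma_alpha,
        )
        store = 0
        for it in range(config.iterations):
            inv_sy2 = 1.0 / (sigma_y * sigma_y)
            # --- fixed effects jointly (conjugate Normal) ---
            b0 = np.zeros(p)
            b0[:n_cmp] = mu_alpha
            if n:
                r = y - alpha[idx] if J else y
                Q = XtX * inv_sy2 + np.diag(prior_prec)
                lin = X.T @ r * inv_sy2 + prior_prec * b0
            else:
                Q = np.diag(prior_prec)
                lin = prior_prec * b0
            L = np.linalg.cholesky(Q)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, lin))
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            # --- random intercepts (conjugate Normal, vectorized per id) ---
            if J:
                resid = y - X @ beta if n else np.zeros(0)
                sums = np.bincount(idx, weights=resid, minlength=J) if n else np.zeros(J)
                prec_j = n_per_id * inv_sy2 + 1.0 / (sigma_alpha * sigma_alpha)
                alpha = sums * inv_sy2 / prec_j + rng.standard_normal(J) / np.sqrt(prec_j)
            # --- ridge hyperparameter (conjugate Normal) ---
            prec_mu = n_cmp * priors.cmp_precision + priors.mu_alpha_precision
            mean_mu = priors.cmp_precision * float(beta[:n_cmp].sum()) / prec_mu
            mu_alpha = mean_mu + rng.standard_normal() / math.sqrt(prec_mu)
            # --- scales (slice on log sigma) ---
            if priors.sigma_y_fixed is None:
                if n:
                    err = y - X @ beta - (alpha[idx] if J else 0.0)
                    ssr = float(err @ err)
                else:
                    ssr = 0.0
                logf = _sigma_log_conditional(
                    n, ssr, priors.sigma_y_scale, priors.half_cauchy_on == "variance"
                )
                sigma_y = math.exp(slice_sample(logf, math.log(sigma_y), rng))
            if priors.sigma_alpha_fixed is None:
                ssa = float(alpha @ alpha) if J else 0.0
                logf = _sigma_log_conditional(
                    J, ssa, priors.sigma_alpha_scale,
                    priors.half_cauchy_on == "variance",
                )
                sigma_alpha = math.exp(slice_sample(logf, math.log(sigma_alpha), rng))
            # --- retain ---
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                row = draws[c, store]
                row[:p] = beta
                row[p : p + J] = alpha
                row[p + J] = mu_alpha
                row[p + J + 1] = sigma_y
                row[p + J + 2] = sigma_alpha
                store += 1
        assert store == n_ret
        logger.info("chain %d finished: %d retained draws", c, store)

    return Chains(
        param_names=param_names, draws=draws, n_beta=p, n_cmp=n_cmp, n_alpha=J,
    )
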