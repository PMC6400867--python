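"""MCMC diagnostics and model assessment.

Split-chain potential scale reduction (Rhat), autocorrelation-based
effective sample size with Geyer initial-positive-sequence truncation,
the deviance information criterion with the classic pD penalty, posterior
predictive checks, and the credibility classification used for the
coefficient plot (does the 50% or the 95% interval exclude zero?).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .bhlm.design import Design
from .bhlm.model import deviance
from .bhlm.sampler import Chains
from .errors import DataError

logger = logging.getLogger(__name__)

STRONG = "strong"
MODERATE = "moderate"
NONE = "none"


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _split_chains(chains: np.ndarray) -> np.ndarray:
    """Halve each chain, doubling the chain count (drops one draw if odd)."""
    m, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); requires >= 2 chains with
    >= 4 draws each.  Degenerate (constant) draws yield 1.0 with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise DataError("gelman_rubin needs >= 2 chains of >= 4 draws")
    split = _split_chains(chains)
    m, n = split.shape
    within = split.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        warnings.warn("all chains constant; Rhat defined as 1", RuntimeWarning)
        return 1.0
    b = n * split.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance estimates at all lags via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    return acov


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS of pooled draws, Geyer initial-positive-sequence truncation.

    Averages per-chain autocovariances, converts to correlations using the
    pooled variance, sums successive lag pairs while they remain positive,
    and caps the result at the total number of draws.  Constant chains
    report the total draw count with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise DataError("effective_sample_size needs >= 2 chains of >= 4 draws")
    m, n = chains.shape
    total = m * n
    within = chains.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        warnings.warn("all chains constant; ESS reported as total draws", RuntimeWarning)
        return float(total)
    b = n * chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b / n
    acov = np.mean([_autocovariance(chains[c]) for c in range(m)], axis=0)
    rho = 1.0 - (w - acov) / var_plus  # rho[0] is slightly below 1 by construction
    tau = 0.0
    t = 1
    prev_pair = np.inf
    # Geyer: sum pairs (rho[2k-1] + rho[2k]) while positive; enforce monotone decrease
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        pair = min(pair, prev_pair)
        tau += pair
        prev_pair = pair
        t += 2
    tau_total = 1.0 + 2.0 * tau
    ess = total / max(tau_total, 1e-12)
    return float(min(ess, total))


# ---------------------------------------------------------------------------
# model assessment
# ---------------------------------------------------------------------------

def dic(chains: Chains, design: Design) -> Dict[str, float]:
    """Deviance information criterion with the classic pD penalty.

    D(theta) = -2 log-likelihood; DIC = mean deviance + pD where
    pD = mean deviance - deviance at the posterior mean.  A negative pD is
    reported as-is with a warning.
    """
    betas = chains.beta_draws()
    alphas = chains.alpha_draws()
    sigmas = chains.scalar_draws("sigma_y")
    n = design.n_obs
    mu = betas @ design.X.T  # (draws, n)
    if chains.n_alpha:
        mu = mu + alphas[:, design.id_index]
    resid = design.y[None, :] - mu
    loglik = (
        -0.5 * np.sum(resid * resid, axis=1) / (sigmas**2)
        - n * np.log(sigmas)
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    mean_dev = float(np.mean(-2.0 * loglik))
    dev_at_mean = deviance(chains.mean_state(), design)
    if not np.isfinite(dev_at_mean):
        raise DataError("deviance at the posterior mean is not finite")
    pd_ = mean_dev - dev_at_mean
    if pd_ < 0:
        warnings.warn(f"negative effective parameter count pD={pd_:.3f}", RuntimeWarning)
    return {"dic": mean_dev + pd_, "mean_deviance": mean_dev, "pd": pd_}


DEFAULT_PPC_STATS = ("mean", "sd", "min", "max")

_STAT_FUNCS = {
    "mean": lambda a: np.mean(a, axis=-1),
    "sd": lambda a: np.std(a, axis=-1, ddof=1),
    "min": lambda a: np.min(a, axis=-1),
    "max": lambda a: np.max(a, axis=-1),
}


def posterior_predictive_check(
    chains: Chains,
    design: Design,
    rng: np.random.Generator,
    stats: Sequence[str] = DEFAULT_PPC_STATS,
) -> Dict[str, float]:
    """Tail probabilities P(stat(y_rep) >= stat(y_obs)) per statistic.

    One replicated dataset is simulated from the likelihood at every
    retained draw.  Probabilities near 0 or 1 flag misfit of that
    statistic; a well-calibrated model keeps them away from the extremes.
    """
    betas = chains.beta_draws()
    alphas = chains.alpha_draws()
    sigmas = chains.scalar_draws("sigma_y")
    mu = betas @ design.X.T
    if chains.n_alpha:
        mu = mu + alphas[:, design.id_index]
    y_rep = mu + sigmas[:, None] * rng.standard_normal(mu.shape)
    out = {}
    for name in stats:
        func = _STAT_FUNCS[name]
        rep_stats = func(y_rep)
        obs_stat = float(func(design.y))
        out[name] = float(np.mean(rep_stats >= obs_stat))
    return out


def classify_credibility(summary_row: Mapping[str, float]) -> str:
    """Figure-style shading rule from the 50% and 95% credible intervals.

    strong   - 0 outside [2.5%, 97.5%]
    moderate - 0 outside [25%, 75%] but inside [2.5%, 97.5%]
    none     - 0 inside [25%, 75%]
    """
    lo95, hi95 = summary_row["cri_2.5%"], summary_row["cri_97.5%"]
    lo50, hi50 = summary_row["cri_25%"], summary_row["cri_75%"]
    if not (lo95 <= 0.0 <= hi95):
        return STRONG
    if not (lo50 <= 0.0 <= hi50):
        return MODERATE
    return NONE


@dataclass
class DiagnosticsReport:
    """Bundle of everything reported for one fitted model."""

    rhat: Dict[str, float]
    ess: Dict[str, float]
    dic: float
    mean_deviance: float
    pd: float
    ppc: Dict[str, float]
    credibility: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess": self.ess,
            "dic": self.dic,
            "mean_deviance": self.mean_deviance,
            "pd": self.pd,
            "ppc": self.ppc,
            "credibility": self.credibility,
        }

    def to_json(self, path, extra: Optional[dict] = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def diagnose(
    chains: Chains,
    design: Design,
    rng: np.random.Generator,
    summary=None,
) -> DiagnosticsReport:
    """Full diagnostics for one fitted model."""
    rhat = {name: gelman_rubin(chains.get(name)) for name in chains.param_names}
    ess = {name: effective_sample_size(chains.get(name)) for name in chains.param_names}
    dic_parts = dic(chains, design)
    ppc = posterior_predictive_check(chains, design, rng)
    credibility = {}
    if summary is not None:
        for _, row in summary.iterrows():
            credibility[row["parameter"]] = classify_credibility(row)
    return DiagnosticsReport(
        rhat=rhat, ess=ess, dic=dic_parts["dic"],
        mean_deviance=dic_parts["mean_deviance"], pd=dic_parts["pd"],
        ppc=ppc, credibility=credibility,
    )


def plot_composition_slopes(summary, path, title: str = "") -> None:
    """Coefficient plot of the six composition slopes with 50%/95% bars.

    Shading follows :func:`classify_credibility`: black marker for strong,
    gray closed circle for moderate, gray open circle for none.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = summary.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(rows) + 1.2))
    for k, row in rows.iterrows():
        label = classify_credibility(row)
        color = "black" if label == STRONG else "gray"
        open_face = label == NONE
        ax.plot([row["cri_2.5%"], row["cri_97.5%"]], [k, k], color=color, lw=1)
        ax.plot([row["cri_25%"], row["cri_75%"]], [k, k], color=color, lw=3)
        ax.plot(
            row["mean"], k, marker="o", color=color,
            markerfacecolor="white" if open_face else color, markersize=7,
        )
    ax.axvline(0.0, color="0.7", lw=0.8, zorder=0)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(rows["parameter"])
    ax.invert_yaxis()
    ax.set_xlabel("posterior mean and 50% / 95% credible intervals")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
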