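"""Posterior summaries in the published table shape.

One row per parameter: pooled posterior mean, sd, the 2.5/25/50/75/97.5%
quantiles, and the convergence diagnostics Rhat and ESS.  Quantiles use
the linear-interpolation rule (numpy's default), documented here as the
package's quantile convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import DataError
from .sampler import Chains

QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)
QUANTILE_COLUMNS = ("cri_2.5%", "cri_25%", "cri_50%", "cri_75%", "cri_97.5%")


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior summary (one published-table row)."""

    parameter: str
    mean: float
    sd: float
    quantiles: Sequence[float]  # at QUANTILES
    rhat: float
    ess: float

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles)
        if q.size != len(QUANTILES):
            raise DataError("expected five quantiles")
        if np.any(np.diff(q) < -1e-12):
            raise DataError("quantiles must be non-decreasing")


def summarize_posterior(
    chains: Chains,
    parameters: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Summarise pooled draws parameter by parameter.

    Requires at least two chains of at least 100 retained draws each.
    Rhat/ESS are delegated to the diagnostics module.  Returns a DataFrame
    with columns ``parameter, mean, sd, cri_2.5% ... cri_97.5%, rhat, ess``.
    """
    from ..diagnostics import effective_sample_size, gelman_rubin

    if chains.n_chains < 2:
        raise DataError("summaries require at least 2 chains")
    if chains.n_draws < 50 or chains.n_chains * chains.n_draws < 100:
        raise DataError(
            "summaries require >= 50 retained draws per chain and >= 100 pooled"
        )
    if parameters is None:
        parameters = chains.param_names
    rows = []
    for name in parameters:
        per_chain = chains.get(name)
        pooled = per_chain.reshape(-1)
        qs = np.quantile(pooled, QUANTILES)
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                **{col: float(q) for col, q in zip(QUANTILE_COLUMNS, qs)},
                "rhat": gelman_rubin(per_chain),
                "ess": effective_sample_size(per_chain),
            }
        )
    return pd.DataFrame(rows)


def composition_summary(chains: Chains) -> pd.DataFrame:
    """Summary restricted to the six group-specific composition slopes."""
    return summarize_posterior(chains, chains.param_names[: chains.n_cmp])
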