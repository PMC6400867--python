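"""Prior sets for the four hierarchical models.

Two published sets exist: a vaguely-informed one for the cortisol models
and a super-vague "reference" one for the cfDNA models.  The second
argument of every Normal prior is read as a PRECISION by default (the
JAGS convention implied by the original toolchain); ``normal_arg``
switches to a variance reading.  The half-Cauchy scale priors are placed
on the standard deviations by default; ``half_cauchy_on="variance"``
places them on the variances instead.  Both switches exist because the
published notation is ambiguous on these points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ..errors import ConfigurationError


@dataclass(frozen=True)
class PriorSet:
    #: second argument of mu_alpha's Normal hyperprior (precision by default)
    mu_alpha_arg: float
    #: second argument of the Normal priors on timepoint/gender/season slopes
    beta_arg: float
    #: second argument of the shared Normal prior tying the six composition
    #: slopes to mu_alpha (the ridge)
    cmp_arg: float
    #: half-Cauchy scale for the residual sd
    sigma_y_scale: float
    #: half-Cauchy scale for the random-intercept sd
    sigma_alpha_scale: float
    normal_arg: str = "precision"  # or "variance"
    half_cauchy_on: str = "sd"  # or "variance"
    #: test hooks: pin a scale instead of sampling it
    sigma_y_fixed: Optional[float] = None
    sigma_alpha_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mu_alpha_arg", "beta_arg", "cmp_arg",
                     "sigma_y_scale", "sigma_alpha_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.normal_arg not in ("precision", "variance"):
            raise ConfigurationError(f"normal_arg={self.normal_arg!r} invalid")
        if self.half_cauchy_on not in ("sd", "variance"):
            raise ConfigurationError(f"half_cauchy_on={self.half_cauchy_on!r} invalid")

    def _to_precision(self, arg: float) -> float:
        return arg if self.normal_arg == "precision" else 1.0 / arg

    @property
    def mu_alpha_precision(self) -> float:
        return self._to_precision(self.mu_alpha_arg)

    @property
    def beta_precision(self) -> float:
        return self._to_precision(self.beta_arg)

    @property
    def cmp_precision(self) -> float:
        return self._to_precision(self.cmp_arg)


#: Vaguely-informed set used for the cortisol models (1 and 2).
CORTISOL_PRIORS = PriorSet(
    mu_alpha_arg=5.0, beta_arg=5.0, cmp_arg=1.0,
    sigma_y_scale=5.0, sigma_alpha_scale=5.0,
)

#: Super-vague reference set used for the cfDNA models (3 and 4).
CFDNA_PRIORS = PriorSet(
    mu_alpha_arg=1e-6, beta_arg=1e-6, cmp_arg=1.0,
    sigma_y_scale=25.0, sigma_alpha_scale=25.0,
)
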