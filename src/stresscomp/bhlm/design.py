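"""Model specification and design construction.

The composition enters as raw closed proportions expanded into six
group-specific columns (SB/LPA/MVPA crossed with CG/IG), so each behavior
gets its own slope per group; collinearity is controlled by the shared
ridge prior, not by log-ratio transforms.  Season, gender and timepoint
enter as indicator contrasts with reference levels fall / female /
midmorning.  Observations are sorted canonically before the matrix is
assembled, so the design — and every seeded fit built on it — is invariant
to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, DataError
from .priors import CFDNA_PRIORS, CORTISOL_PRIORS, PriorSet

GROUPS = ("CG", "IG")
PART_NAMES = ("SB", "LPA", "MVPA")
REFERENCE_LEVELS = {"season": "fall", "gender": "female", "timepoint": "midmorning"}
KNOWN_GENDERS = ("female", "male")
KNOWN_TIMEPOINTS = ("midmorning", "noon")

#: Composition-slope labels in design-column order.
CMP_LABELS = tuple(f"{part} ({grp})" for grp in GROUPS for part in PART_NAMES)


@dataclass(frozen=True)
class Observation:
    """One modeling row: a response index value with its covariates."""

    y: float
    id: str
    group: str
    composition: Tuple[float, float, float]
    season: str
    gender: str
    timepoint: str = "NA"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}")
        if any(p < 0 for p in self.composition):
            raise DataError(f"negative composition part: {self.composition}")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise DataError(f"composition {self.composition} not closed")


def observations_to_frame(observations: Sequence[Observation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(y=o.y, id=o.id, group=o.group, gender=o.gender, season=o.season,
                 timepoint=o.timepoint, sb=o.composition[0], lpa=o.composition[1],
                 mvpa=o.composition[2])
            for o in observations
        ]
    )


_MODEL_TABLE = {
    "BHLM1": ("cortisol", "PR", True),
    "BHLM2": ("cortisol", "AUCi", False),
    "BHLM3": ("cfdna", "PR", True),
    "BHLM4": ("cfdna", "AUCi", False),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four models is being fitted, and with which priors."""

    model_id: str
    prior_set: PriorSet

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_TABLE:
            raise ConfigurationError(
                f"unknown model {self.model_id!r}; expected one of {sorted(_MODEL_TABLE)}"
            )

    @property
    def analyte(self) -> str:
        return _MODEL_TABLE[self.model_id][0]

    @property
    def index(self) -> str:
        return _MODEL_TABLE[self.model_id][1]

    @property
    def include_timepoint(self) -> bool:
        return _MODEL_TABLE[self.model_id][2]

    @classmethod
    def from_id(cls, model_id: str, prior_set: Optional[PriorSet] = None) -> "ModelSpec":
        model_id = model_id.upper()
        if model_id not in _MODEL_TABLE:
            raise ConfigurationError(
                f"unknown model {model_id!r}; expected one of {sorted(_MODEL_TABLE)}"
            )
        if prior_set is None:
            analyte = _MODEL_TABLE[model_id][0]
            prior_set = CORTISOL_PRIORS if analyte == "cortisol" else CFDNA_PRIORS
        return cls(model_id=model_id, prior_set=prior_set)


@dataclass
class Design:
    """Assembled regression structure handed to the sampler."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, p); first n_cmp columns are the composition block
    columns: List[str]
    n_cmp: int
    id_index: np.ndarray  # (n,) integer codes into id_labels
    id_labels: List[str]
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_ids(self) -> int:
        return len(self.id_labels)

    def drop_column(self, name: str) -> "Design":
        """A copy without one non-composition column (used in model comparison)."""
        k = self.columns.index(name)
        if k < self.n_cmp:
            raise ConfigurationError("cannot drop a composition column")
        keep = [j for j in range(len(self.columns)) if j != k]
        return Design(
            y=self.y, X=self.X[:, keep],
            columns=[self.columns[j] for j in keep],
            n_cmp=self.n_cmp, id_index=self.id_index,
            id_labels=self.id_labels, spec=self.spec,
        )


def build_design(observations, spec: ModelSpec) -> Design:
    """Build the response vector and covariate matrix for one model.

    ``observations`` is a DataFrame with columns
    ``y, id, group, gender, season, timepoint, sb, lpa, mvpa`` (or a
    sequence of :class:`Observation`).  Raises :class:`DataError` listing
    every offending row on unknown levels or missing values.
    """
    if not isinstance(observations, pd.DataFrame):
        observations = observations_to_frame(observations)
    df = observations.copy()

    required = ["y", "id", "group", "gender", "season", "timepoint",
                "sb", "lpa", "mvpa"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataError(f"observations table lacks columns {missing_cols}")

    problems = []
    for col in ["y", "sb", "lpa", "mvpa"]:
        bad = df.index[df[col].isna()].tolist()
        if bad:
            problems.append(f"NA in {col!r} at rows {bad}")
    bad = df.index[~df["group"].isin(GROUPS)].tolist()
    if bad:
        problems.append(f"unknown group at rows {bad}")
    bad = df.index[~df["gender"].isin(KNOWN_GENDERS)].tolist()
    if bad:
        problems.append(f"unknown gender at rows {bad}")
    if spec.include_timepoint:
        bad = df.index[~df["timepoint"].isin(KNOWN_TIMEPOINTS)].tolist()
        if bad:
            problems.append(
                f"PR model requires timepoint in {KNOWN_TIMEPOINTS}, bad rows {bad}"
            )
    else:
        bad = df.index[df["timepoint"].notna() & (df["timepoint"] != "NA")].tolist()
        if bad:
            problems.append(f"AUCi model forbids timepoints, bad rows {bad}")
    closure = (df[["sb", "lpa", "mvpa"]].sum(axis=1) - 1.0).abs()
    bad = df.index[closure > 1e-9].tolist()
    if bad:
        problems.append(f"composition not closed at rows {bad}")
    if problems:
        raise DataError("; ".join(problems))

    # canonical order => permutation-invariant design and fits
    sort_cols = ["id", "season", "timepoint"]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    n = len(df)
    blocks = []
    columns: List[str] = []
    comp = df[["sb", "lpa", "mvpa"]].to_numpy(dtype=float)
    for grp in GROUPS:
        in_grp = (df["group"] == grp).to_numpy()[:, None]
        blocks.append(comp * in_grp)
        columns.extend(f"{part} ({grp})" for part in PART_NAMES)
    n_cmp = len(columns)

    season_levels = sorted(set(df["season"]) - {REFERENCE_LEVELS["season"]})
    for lvl in season_levels:
        blocks.append((df["season"] == lvl).to_numpy(dtype=float)[:, None])
        columns.append(f"season[{lvl}]")
    blocks.append((df["gender"] == "male").to_numpy(dtype=float)[:, None])
    columns.append("gender[male]")
    if spec.include_timepoint:
        blocks.append((df["timepoint"] == "noon").to_numpy(dtype=float)[:, None])
        columns.append("timepoint[noon]")

    X = np.hstack(blocks) if n else np.empty((0, len(columns)))
    id_labels = sorted(df["id"].unique())
    id_map = {sid: k for k, sid in enumerate(id_labels)}
    id_index = df["id"].map(id_map).to_numpy(dtype=np.int64)

    return Design(
        y=df["y"].to_numpy(dtype=float), X=X, columns=columns, n_cmp=n_cmp,
        id_index=id_index, id_labels=id_labels, spec=spec,
    )
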