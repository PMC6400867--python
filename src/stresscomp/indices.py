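"""Log-scale trajectory indices: area under the curve w.r.t. increase and
peak reactivity.

Concentrations are log-transformed first; the indices are computed on the
log scale and may be negative (declining trajectories).  AUCi follows the
trapezoidal convention: ground area minus baseline level times elapsed
time.  Peak reactivity defaults to change-from-baseline at each
post-baseline timepoint, which is what makes the per-timepoint covariate in
the PR models well-defined; a max-minus-baseline variant is available via
``pr_definition="max"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

CORTISOL = "cortisol"
CFDNA = "cfdna"
ANALYTES = (CORTISOL, CFDNA)

AUCI = "AUCi"
PR = "PR"

#: Timepoint labels for the three-sample schedule, in clock order.
TIMEPOINT_LABELS = ("baseline", "midmorning", "noon")

#: Canonical clock hours of the three samples (08:30, 10:30, 12:30).
DEFAULT_SCHEDULE = (8.5, 10.5, 12.5)


def _timepoint_label(time_h: float, schedule: Sequence[float]) -> str:
    """Label a sample by the nearest slot of the clock schedule."""
    k = int(np.argmin(np.abs(np.asarray(schedule) - time_h)))
    return TIMEPOINT_LABELS[k]


@dataclass
class SalivaTrajectory:
    """One student-day of analyte concentrations at increasing clock times."""

    id: str
    season: str
    analyte: str
    times_h: Tuple[float, ...]
    concentrations: Tuple[float, ...]
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise DataError(f"unknown analyte {self.analyte!r}")
        if len(self.times_h) != len(self.concentrations):
            raise DataError(f"{self.id}/{self.season}: times/values length mismatch")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise DataError(f"{self.id}/{self.season}: times not strictly increasing")
        if not self.log_scale and any(c <= 0 for c in self.concentrations):
            raise DataError(
                f"{self.id}/{self.season}/{self.analyte}: non-positive concentration"
            )


@dataclass(frozen=True)
class IndexValue:
    """One computed response index (the modeling unit downstream)."""

    id: str
    season: str
    analyte: str
    index: str  # PR or AUCi
    timepoint: Optional[str]  # midmorning / noon for PR, None for AUCi
    value: float

    def __post_init__(self) -> None:
        if (self.timepoint is None) != (self.index == AUCI):
            raise DataError("timepoint must be None iff the index is AUCi")


def log_transform(
    trajectory: SalivaTrajectory,
    detection_floor: Optional[float] = 1e-3,
) -> SalivaTrajectory:
    """Replace concentrations by their natural logs; times unchanged.

    Non-positive values are floored to ``detection_floor`` (and logged) when
    a floor is configured, otherwise they raise :class:`DataError`.
    """
    if trajectory.log_scale:
        raise DataError(f"{trajectory.id}/{trajectory.season}: already log scale")
    values = []
    for t, c in zip(trajectory.times_h, trajectory.concentrations):
        if c <= 0:
            if detection_floor is None:
                raise DataError(
                    f"non-positive concentration {c} at t={t} for "
                    f"{trajectory.id}/{trajectory.season}/{trajectory.analyte} "
                    f"with flooring disabled"
                )
            logger.warning(
                "flooring non-positive concentration %s -> %s (%s/%s/%s, t=%s)",
                c, detection_floor, trajectory.id, trajectory.season,
                trajectory.analyte, t,
            )
            c = detection_floor
        values.append(float(np.log(c)))
    return replace(trajectory, concentrations=tuple(values), log_scale=True)


def auc_increase(trajectory: SalivaTrajectory) -> IndexValue:
    """AUCi = trapezoidal ground area minus baseline * total elapsed time."""
    _require_log(trajectory)
    if len(trajectory.times_h) < 2:
        raise DataError(
            f"{trajectory.id}/{trajectory.season}: AUCi needs >= 2 samples"
        )
    t = np.asarray(trajectory.times_h)
    m = np.asarray(trajectory.concentrations)
    ground = float(np.trapezoid(m, t))
    auci = ground - m[0] * (t[-1] - t[0])
    return IndexValue(
        id=trajectory.id, season=trajectory.season, analyte=trajectory.analyte,
        index=AUCI, timepoint=None, value=float(auci),
    )


def peak_reactivity(
    trajectory: SalivaTrajectory,
    definition: str = "per_timepoint",
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> List[IndexValue]:
    """Change from baseline, emitted once per post-baseline timepoint.

    With the default three-sample schedule this yields PR(midmorning) =
    m2 - m1 and PR(noon) = m3 - m1.  Timepoint labels are assigned from
    clock time against ``schedule``, so a missing middle sample still
    yields a correctly labeled noon PR.  ``definition="max"`` instead
    emits a single value, max(m) - m1, labeled by the maximising timepoint.
    """
    _require_log(trajectory)
    m = np.asarray(trajectory.concentrations)
    if m.size < 2:
        raise DataError(
            f"{trajectory.id}/{trajectory.season}: PR needs >= 2 samples"
        )
    if m.size > len(schedule):
        raise DataError("more samples than schedule slots")
    labels = [_timepoint_label(t, schedule) for t in trajectory.times_h]
    if labels[0] != TIMEPOINT_LABELS[0]:
        raise DataError(
            f"{trajectory.id}/{trajectory.season}: baseline sample missing"
        )
    if m.size < len(schedule):
        logger.warning(
            "only %d of %d samples present for %s/%s/%s; emitting computable PRs",
            m.size, len(schedule), trajectory.id, trajectory.season,
            trajectory.analyte,
        )
    if definition == "per_timepoint":
        ks = range(1, m.size)
    elif definition == "max":
        ks = [int(np.argmax(m[1:])) + 1]
    else:
        raise ConfigurationError(f"unknown PR definition {definition!r}")
    return [
        IndexValue(
            id=trajectory.id, season=trajectory.season,
            analyte=trajectory.analyte, index=PR,
            timepoint=labels[k], value=float(m[k] - m[0]),
        )
        for k in ks
    ]


def _require_log(trajectory: SalivaTrajectory) -> None:
    if not trajectory.log_scale:
        raise DataError(
            f"{trajectory.id}/{trajectory.season}: indices require a "
            f"log-transformed trajectory"
        )


def indices_from_saliva(
    saliva_df: pd.DataFrame,
    detection_floor: Optional[float] = 1e-3,
    pr_definition: str = "per_timepoint",
) -> pd.DataFrame:
    """Compute PR and AUCi for every (id, season, analyte) in a long table.

    Expects columns ``id, season, time_h, cortisol, cfdna``; returns the
    long index table ``id, season, analyte, index, timepoint, value``.
    Trajectories with fewer than two usable samples are skipped and logged.
    """
    records = []
    for (sid, season), grp in saliva_df.groupby(["id", "season"], sort=True):
        grp = grp.sort_values("time_h")
        for analyte in ANALYTES:
            sub = grp.dropna(subset=[analyte])
            if len(sub) < 2:
                logger.warning(
                    "skipping %s/%s/%s: %d usable sample(s)",
                    sid, season, analyte, len(sub),
                )
                continue
            values = sub[analyte].astype(float).to_numpy()
            if detection_floor is not None and (values <= 0).any():
                # the trajectory type requires positive concentrations;
                # apply the detection floor before construction
                logger.warning(
                    "flooring %d non-positive %s value(s) for %s/%s",
                    int((values <= 0).sum()), analyte, sid, season,
                )
                values = np.where(values <= 0, detection_floor, values)
            traj = SalivaTrajectory(
                id=str(sid), season=str(season), analyte=analyte,
                times_h=tuple(sub["time_h"].astype(float)),
                concentrations=tuple(values),
            )
            logged = log_transform(traj, detection_floor=detection_floor)
            results = [auc_increase(logged)]
            results.extend(peak_reactivity(logged, definition=pr_definition))
            records.extend(
                dict(id=r.id, season=r.season, analyte=r.analyte, index=r.index,
                     timepoint=r.timepoint if r.timepoint is not None else "NA",
                     value=r.value)
                for r in results
            )
    return pd.DataFrame(
        records, columns=["id", "season", "analyte", "index", "timepoint", "value"]
    )
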