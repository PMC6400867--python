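"""Synthetic cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes — diurnal log-scale analyte trajectories with subject random
intercepts, group-dependent activity mixtures, and optional missingness —
so every pipeline stage is testable without any external dataset.

All generation happens on the natural-log scale and is exponentiated to
concentration scale for output realism.  Every function is driven by an
explicit :class:`numpy.random.Generator`; the table-level entry point
derives independent named streams from the single configured seed, so
identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .accelerometry import BehaviorComposition, CountSeries, CutPoints
from .errors import ConfigurationError
from .indices import CFDNA, CORTISOL, SalivaTrajectory

IG = "IG"
CG = "CG"
GROUPS = (CG, IG)
GENDERS = ("female", "male")
DEFAULT_SEASONS = ("fall", "spring", "summer")
DEFAULT_SAMPLE_TIMES_H = (8.5, 10.5, 12.5)

#: Wear window 08:30-12:30 expressed in seconds.
WINDOW_SECONDS = 4 * 3600


def _default_mixtures() -> Dict[Tuple[str, str], Tuple[float, float, float]]:
    # CG: more sedentary, less vigorous; IG: the reverse.  Mild seasonal drift.
    base = {
        CG: (0.70, 0.24, 0.06),
        IG: (0.52, 0.33, 0.15),
    }
    drift = {"fall": 0.0, "spring": 0.02, "summer": 0.04}
    out = {}
    for grp, (sb, lpa, mvpa) in base.items():
        for season, d in drift.items():
            mix = np.array([sb - d, lpa, mvpa + d])
            out[(grp, season)] = tuple(mix / mix.sum())
    return out


@dataclass
class TrueParams:
    """Generative parameters: the synthetic counterparts of the model's
    random intercepts, composition/covariate slopes, and variance components."""

    cortisol_log_intercept: Dict[str, float] = field(
        default_factory=lambda: {CG: np.log(10.0), IG: np.log(10.0)}
    )
    #: per-hour diurnal slope of log-cortisol; more negative in IG.
    cortisol_slope_per_h: Dict[str, float] = field(
        default_factory=lambda: {CG: -0.08, IG: -0.25}
    )
    cfdna_log_mean: Dict[str, float] = field(
        default_factory=lambda: {CG: np.log(50.0), IG: np.log(50.0)}
    )
    #: per sample-slot offsets of log-cfDNA (no diurnal trend by default).
    cfdna_timepoint_effects: Tuple[float, ...] = (0.0, 0.05, -0.05)
    sigma_alpha: float = 0.30
    sigma_y: float = 0.25
    #: target (SB, LPA, MVPA) wear-time mixture per group x season.
    behavior_mixture: Dict[Tuple[str, str], Tuple[float, float, float]] = field(
        default_factory=_default_mixtures
    )
    #: Dirichlet concentration controlling day-to-day mixture variation.
    mixture_concentration: float = 150.0
    #: generative composition effects injected into the trajectories,
    #: per group, in (SB, LPA, MVPA) order.
    composition_effects: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {CG: (-0.2, 0.0, -0.5), IG: (0.0, -0.7, 0.0)}
    )
    #: season effects on log-cortisol only (cfDNA has no clear seasonal pattern).
    season_effects: Dict[str, float] = field(
        default_factory=lambda: {"fall": 0.0, "spring": 0.05, "summer": -0.05}
    )
    gender_effects: Dict[str, float] = field(
        default_factory=lambda: {"female": 0.0, "male": 0.05}
    )

    def validate(self) -> None:
        # zero is allowed for noise-free generative edge cases (closed-form tests)
        if self.sigma_alpha < 0 or self.sigma_y < 0:
            raise ConfigurationError("sigma_alpha and sigma_y must be >= 0")
        for key, mix in self.behavior_mixture.items():
            if abs(sum(mix) - 1.0) > 1e-9 or any(m < 0 for m in mix):
                raise ConfigurationError(f"behavior mixture {key} is not closed: {mix}")
        if self.mixture_concentration <= 0:
            raise ConfigurationError("mixture_concentration must be > 0")


@dataclass
class MissingnessConfig:
    """Per student-day saliva dropout and per student-season sensor loss."""

    saliva_day_dropout: float = 0.0
    sensor_loss: float = 0.0

    def validate(self) -> None:
        for name in ("saliva_day_dropout", "sensor_loss"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} outside [0, 1]")


@dataclass
class CohortConfig:
    n_ig: int = 37
    n_cg: int = 11
    seasons: Tuple[str, ...] = DEFAULT_SEASONS
    sample_times_h: Tuple[float, ...] = DEFAULT_SAMPLE_TIMES_H
    epoch_length_s: int = 15
    seed: int = 0
    true_params: TrueParams = field(default_factory=TrueParams)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def validate(self) -> None:
        if self.n_ig < 1 or self.n_cg < 1:
            raise ConfigurationError("n_ig and n_cg must each be >= 1")
        if any(b <= a for a, b in zip(self.sample_times_h, self.sample_times_h[1:])):
            raise ConfigurationError("sample_times_h must be strictly increasing")
        if self.epoch_length_s <= 0 or WINDOW_SECONDS % self.epoch_length_s != 0:
            raise ConfigurationError(
                f"epoch_length_s={self.epoch_length_s} must divide the "
                f"{WINDOW_SECONDS} s wear window"
            )
        if not self.seasons:
            raise ConfigurationError("at least one season required")
        self.true_params.validate()
        self.missingness.validate()


@dataclass(frozen=True)
class Student:
    id: str
    group: str
    gender: str


def generate_cohort(config: CohortConfig, rng: Optional[np.random.Generator] = None):
    """Enroll ``n_ig + n_cg`` students with unique ids and seeded genders."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_ig + config.n_cg
    width = max(2, len(str(n)))
    students = []
    for i in range(n):
        group = IG if i < config.n_ig else CG
        students.append(
            Student(
                id=f"S{i + 1:0{width}d}",
                group=group,
                gender=GENDERS[int(rng.integers(0, 2))],
            )
        )
    return students


def draw_day_mixture(
    student: Student, season: str, params: TrueParams, rng: np.random.Generator
) -> np.ndarray:
    """One day's activity mixture: Dirichlet around the group x season target."""
    target = np.asarray(params.behavior_mixture[(student.group, season)])
    return rng.dirichlet(params.mixture_concentration * target)


def _injected_effect(
    student: Student, params: TrueParams, composition
) -> float:
    if composition is None:
        return 0.0
    comp = (
        composition.as_array()
        if isinstance(composition, BehaviorComposition)
        else np.asarray(composition, dtype=float)
    )
    return float(np.dot(params.composition_effects[student.group], comp))


def simulate_saliva_day(
    student: Student,
    season: str,
    params: TrueParams,
    rng: np.random.Generator,
    sample_times_h: Sequence[float] = DEFAULT_SAMPLE_TIMES_H,
    subject_intercepts: Tuple[float, float] = (0.0, 0.0),
    composition=None,
) -> Tuple[SalivaTrajectory, SalivaTrajectory]:
    """Simulate one student-day of cortisol and cfDNA concentrations.

    Log-concentration = group diurnal mean + subject random intercept +
    season/gender effects + injected composition effect + Normal noise,
    then exponentiated.  The composition effect ramps linearly from zero
    at baseline to its full value at the last sample, so it moves the
    change-from-baseline indices rather than the overall level.

    ``subject_intercepts`` are the (cortisol, cfDNA) random intercepts,
    drawn once per student by the caller so they persist across seasons.
    """
    t = np.asarray(sample_times_h, dtype=float)
    ramp = (t - t[0]) / (t[-1] - t[0])
    inject = _injected_effect(student, params, composition)
    gdr = params.gender_effects[student.gender]

    log_cort = (
        params.cortisol_log_intercept[student.group]
        + params.cortisol_slope_per_h[student.group] * (t - t[0])
        + subject_intercepts[0]
        + params.season_effects[season]
        + gdr
        + inject * ramp
        + rng.normal(0.0, params.sigma_y, size=t.size)
    )
    tp_eff = np.asarray(params.cfdna_timepoint_effects[: t.size])
    log_cfdna = (
        params.cfdna_log_mean[student.group]
        + tp_eff
        + subject_intercepts[1]
        + gdr
        + inject * ramp
        + rng.normal(0.0, params.sigma_y, size=t.size)
    )
    make = lambda analyte, logs: SalivaTrajectory(
        id=student.id, season=season, analyte=analyte,
        times_h=tuple(t), concentrations=tuple(np.exp(logs)),
    )
    return make(CORTISOL, log_cort), make(CFDNA, log_cfdna)


def simulate_accelerometry(
    student: Student,
    season: str,
    params: TrueParams,
    rng: np.random.Generator,
    cuts: CutPoints,
    mixture: Optional[np.ndarray] = None,
    truncate_fraction: Optional[float] = None,
) -> CountSeries:
    """Per-epoch counts from a 3-state mixture straddling the cut-points.

    State-specific count distributions are uniform within the SB / LPA /
    MVPA count bands, so classification against the same cut-points
    recovers the state labels exactly.  ``truncate_fraction`` right-
    truncates the series (sensor fell off and was not re-attached).
    """
    if mixture is None:
        mixture = draw_day_mixture(student, season, params, rng)
    n_epochs = WINDOW_SECONDS // cuts.epoch_length_s
    states = rng.choice(3, size=n_epochs, p=np.asarray(mixture))
    sb_hi = int(cuts.sb_max)
    lpa_lo, lpa_hi = int(cuts.sb_max) + 1, int(cuts.mvpa_min) - 1
    mv_lo, mv_hi = int(cuts.mvpa_min), int(cuts.mvpa_min) * 3
    counts = np.empty(n_epochs, dtype=float)
    counts[states == 0] = rng.integers(0, sb_hi + 1, size=int((states == 0).sum()))
    counts[states == 1] = rng.integers(lpa_lo, lpa_hi + 1, size=int((states == 1).sum()))
    counts[states == 2] = rng.integers(mv_lo, mv_hi + 1, size=int((states == 2).sum()))
    starts = np.arange(n_epochs, dtype=float) * cuts.epoch_length_s
    if truncate_fraction is not None:
        keep = max(1, int(np.floor(truncate_fraction * n_epochs)))
        starts, counts = starts[:keep], counts[:keep]
    return CountSeries(
        id=student.id, season=season, epoch_length_s=cuts.epoch_length_s,
        epoch_starts_s=starts, counts=counts,
    )


def apply_missingness(
    tables: Dict[str, pd.DataFrame],
    missingness: MissingnessConfig,
    rng: np.random.Generator,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Drop saliva student-days and truncate lost-sensor count series.

    Each student-day is hit independently with the configured
    probabilities; surviving rows are unchanged.  Returns the thinned
    tables plus a manifest of every dropped/truncated unit.
    """
    missingness.validate()
    out = dict(tables)
    manifest = []

    saliva = tables["saliva"]
    keep_mask = np.ones(len(saliva), dtype=bool)
    for (sid, season), idx in saliva.groupby(["id", "season"], sort=True).groups.items():
        if rng.random() < missingness.saliva_day_dropout:
            keep_mask[saliva.index.get_indexer(idx)] = False
            manifest.append(dict(table="saliva", id=sid, season=season,
                                 action="dropped_day"))
    out["saliva"] = saliva.loc[keep_mask].reset_index(drop=True)

    counts = tables["counts"]
    keep_mask = np.ones(len(counts), dtype=bool)
    for (sid, season), idx in counts.groupby(["id", "season"], sort=True).groups.items():
        if rng.random() < missingness.sensor_loss:
            pos = counts.index.get_indexer(idx)
            cutoff = rng.uniform(0.1, 0.9)
            n_keep = max(1, int(np.floor(cutoff * len(pos))))
            keep_mask[pos[n_keep:]] = False
            manifest.append(dict(table="counts", id=sid, season=season,
                                 action=f"truncated_at_{cutoff:.3f}"))
    out["counts"] = counts.loc[keep_mask].reset_index(drop=True)

    manifest_df = pd.DataFrame(manifest, columns=["table", "id", "season", "action"])
    return out, manifest_df


def simulate_cohort_tables(
    config: CohortConfig, cuts: Optional[CutPoints] = None
) -> Dict[str, pd.DataFrame]:
    """Full synthetic dataset: students, saliva, and counts long tables.

    The same per-day activity mixture drives both the count series and the
    composition effect injected into that day's saliva trajectories, so
    the generative composition slopes are recoverable downstream.
    """
    config.validate()
    if cuts is None:
        cuts = CutPoints.from_preset("romanzini_vm")
        cuts = CutPoints(cuts.sb_max, cuts.mvpa_min, config.epoch_length_s)
    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_alpha, rng_day, rng_missing = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    students = generate_cohort(config, rng_cohort)
    students_df = pd.DataFrame(
        [dict(id=s.id, group=s.group, gender=s.gender) for s in students]
    )

    alphas = {
        s.id: (
            rng_alpha.normal(0.0, config.true_params.sigma_alpha),
            rng_alpha.normal(0.0, config.true_params.sigma_alpha),
        )
        for s in students
    }

    saliva_rows, count_rows = [], []
    for s in students:
        for season in config.seasons:
            mixture = draw_day_mixture(s, season, config.true_params, rng_day)
            series = simulate_accelerometry(
                s, season, config.true_params, rng_day, cuts, mixture=mixture
            )
            count_rows.append(
                pd.DataFrame(
                    dict(id=s.id, season=season,
                         epoch_start_s=series.epoch_starts_s,
                         vm_counts=series.counts)
                )
            )
            cort, cfdna = simulate_saliva_day(
                s, season, config.true_params, rng_day,
                sample_times_h=config.sample_times_h,
                subject_intercepts=alphas[s.id], composition=mixture,
            )
            for t, cc, dc in zip(
                cort.times_h, cort.concentrations, cfdna.concentrations
            ):
                saliva_rows.append(
                    dict(id=s.id, season=season, time_h=t, cortisol=cc, cfdna=dc)
                )

    tables = {
        "students": students_df,
        "saliva": pd.DataFrame(saliva_rows),
        "counts": pd.concat(count_rows, ignore_index=True),
    }
    tables, manifest = apply_missingness(tables, config.missingness, rng_missing)
    tables["missingness_manifest"] = manifest
    return tables


def simulate_observations(
    n_ig: int,
    n_cg: int,
    seasons: Sequence[str],
    composition_slopes: Dict[str, Tuple[float, float, float]],
    rng: np.random.Generator,
    sigma_alpha: float = 0.3,
    sigma_y: float = 0.5,
    season_effects: Optional[Dict[str, float]] = None,
    gender_effect: float = 0.15,
    timepoint_effect: Optional[float] = None,
    mixture_concentration: float = 25.0,
    behavior_mixture: Optional[Dict[str, Tuple[float, float, float]]] = None,
) -> pd.DataFrame:
    """Observations drawn exactly from the hierarchical model's likelihood.

    y = alpha_id + beta_cmp(group) . composition + season + gender
    (+ timepoint) + Normal(0, sigma_y) noise.  Used for parameter-recovery
    checks where the fitted model and the generator must coincide.
    Returns one row per observation with the true slopes known to the caller.
    """
    if season_effects is None:
        season_effects = {s: v for s, v in zip(seasons, (0.0, 0.2, -0.3))}
    if behavior_mixture is None:
        behavior_mixture = {CG: (0.70, 0.24, 0.06), IG: (0.52, 0.33, 0.15)}
    rows = []
    n = n_ig + n_cg
    width = max(2, len(str(n)))
    for i in range(n):
        group = IG if i < n_ig else CG
        sid = f"S{i + 1:0{width}d}"
        gender = GENDERS[int(rng.integers(0, 2))]
        alpha = rng.normal(0.0, sigma_alpha)
        for season in seasons:
            comp = rng.dirichlet(
                mixture_concentration * np.asarray(behavior_mixture[group])
            )
            timepoints = ["NA"] if timepoint_effect is None else ["midmorning", "noon"]
            for tp in timepoints:
                y = (
                    alpha
                    + float(np.dot(composition_slopes[group], comp))
                    + season_effects.get(season, 0.0)
                    + (gender_effect if gender == "male" else 0.0)
                    + (timepoint_effect if tp == "noon" else 0.0)
                    + rng.normal(0.0, sigma_y)
                )
                rows.append(
                    dict(y=y, id=sid, group=group, gender=gender, season=season,
                         timepoint=tp, sb=comp[0], lpa=comp[1], mvpa=comp[2])
                )
    return pd.DataFrame(rows)
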