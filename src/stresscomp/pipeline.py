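"""Pipeline orchestration: configuration, validation, staged execution.

Stages run in a fixed order — synthetic/ingest, accelerometry, indices,
model fitting, diagnostics — and every written artifact is stamped with
the config hash and global seed.  Reruns under an identical config are
byte-identical; a stage failure aborts the run, removes partial artifacts,
and names the failing stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import accelerometry as accel
from . import diagnostics as diag
from .accelerometry import CutPoints, compositions_from_counts
from .bhlm import (
    McmcConfig,
    ModelSpec,
    build_design,
    run_mcmc,
    summarize_posterior,
)
from .errors import ConfigurationError, DataError, StresscompError
from .indices import indices_from_saliva
from .io import config_hash, read_table, write_table
from .synthetic import CohortConfig, MissingnessConfig, TrueParams, simulate_cohort_tables

logger = logging.getLogger(__name__)

ALL_MODELS = ("BHLM1", "BHLM2", "BHLM3", "BHLM4")
STAGES = ("simulate", "compose", "indices", "fit", "diagnose")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("results")
    seed: int = 0
    synthetic: bool = True
    #: synthetic-mode generator settings (seed is overridden by the global seed)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    #: real-data mode input paths
    students_csv: Optional[Path] = None
    saliva_csv: Optional[Path] = None
    counts_csv: Optional[Path] = None
    cutpoint_preset: str = "romanzini_vm"
    epoch_length_s: int = 15
    min_wear_minutes: float = 120.0
    detection_floor: Optional[float] = 1e-3
    pr_definition: str = "per_timepoint"
    models: Tuple[str, ...] = ALL_MODELS
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    save_draws: bool = True
    make_plots: bool = True

    def validate(self) -> None:
        for m in self.models:
            if m.upper() not in ALL_MODELS:
                raise ConfigurationError(f"unknown model {m!r}")
        if self.synthetic:
            self.cohort.validate()
        else:
            for name in ("students_csv", "saliva_csv", "counts_csv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(
                        f"real-data mode requires existing {name}, got {path}"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    def hash(self) -> str:
        # artifact location does not change the science: exclude it, so
        # the same analysis run into two directories stays combinable
        d = self.to_dict()
        d.pop("out_dir")
        return config_hash(d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort = dict(raw["cohort"])
            if "true_params" in cohort and isinstance(cohort["true_params"], dict):
                cohort["true_params"] = TrueParams(**cohort["true_params"])
            if "missingness" in cohort and isinstance(cohort["missingness"], dict):
                cohort["missingness"] = MissingnessConfig(**cohort["missingness"])
            raw["cohort"] = CohortConfig(**cohort)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ValidationProblem:
    severity: str  # "warning" | "fatal"
    message: str


@dataclass
class ValidationReport:
    problems: List[ValidationProblem] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.problems.append(ValidationProblem(severity, message))

    @property
    def fatal(self) -> bool:
        return any(p.severity == "fatal" for p in self.problems)

    def __bool__(self) -> bool:  # truthy when clean
        return not self.problems


def validate_inputs(
    tables: Dict[str, pd.DataFrame], flooring_enabled: bool = True
) -> ValidationReport:
    """Schema, level, and key-join checks across the three input tables."""
    report = ValidationReport()
    schemas = {
        "students": ["id", "group", "gender"],
        "saliva": ["id", "season", "time_h", "cortisol", "cfdna"],
        "counts": ["id", "season", "epoch_start_s", "vm_counts"],
    }
    for name, cols in schemas.items():
        if name not in tables:
            report.add("fatal", f"missing table {name!r}")
            continue
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            report.add("fatal", f"table {name!r} lacks columns {missing}")
    if report.fatal:
        return report

    students = tables["students"]
    if students["id"].duplicated().any():
        dupes = students.loc[students["id"].duplicated(), "id"].tolist()
        report.add("fatal", f"duplicate student ids {dupes}")
    bad_grp = students.loc[~students["group"].isin(["CG", "IG"]), "id"].tolist()
    if bad_grp:
        report.add("fatal", f"unknown group for ids {bad_grp}")

    known_ids = set(students["id"])
    for name in ("saliva", "counts"):
        stray = sorted(set(tables[name]["id"]) - known_ids)
        if stray:
            report.add("fatal", f"table {name!r} references unknown ids {stray}")

    saliva = tables["saliva"]
    dup = saliva.duplicated(subset=["id", "season", "time_h"])
    if dup.any():
        report.add("fatal", f"duplicate saliva rows at {saliva.index[dup].tolist()}")
    for analyte in ("cortisol", "cfdna"):
        bad = saliva.index[(saliva[analyte] <= 0) & saliva[analyte].notna()].tolist()
        if bad:
            severity = "warning" if flooring_enabled else "fatal"
            report.add(
                severity,
                f"non-positive {analyte} at rows {bad}"
                + (" (will be floored)" if flooring_enabled else ""),
            )
    bad = tables["counts"].index[tables["counts"]["vm_counts"] < 0].tolist()
    if bad:
        report.add("fatal", f"negative counts at rows {bad}")
    return report


def _assemble_observations(
    indices_df: pd.DataFrame,
    compositions_df: pd.DataFrame,
    students_df: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Join index values with compositions and covariates for one model.

    Complete-case: rows missing a valid composition or covariates drop out.
    """
    sub = indices_df[
        (indices_df["analyte"] == spec.analyte) & (indices_df["index"] == spec.index)
    ].copy()
    if spec.include_timepoint:
        sub = sub[sub["timepoint"].isin(["midmorning", "noon"])]
    comps = compositions_df[compositions_df["valid"].astype(bool)]
    merged = sub.merge(comps, on=["id", "season"], how="inner")
    merged = merged.merge(students_df, on="id", how="inner")
    merged = merged.rename(columns={"value": "y"})
    return merged[
        ["y", "id", "group", "gender", "season", "timepoint", "sb", "lpa", "mvpa"]
    ].dropna()


def _mcmc_seed(base_seed: int, stream: str) -> int:
    """Stable per-stream seed (str hash() is process-salted, so digest instead)."""
    import hashlib

    digest = hashlib.sha256(f"{base_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


class PipelineRun:
    """Executes the staged pipeline for one config."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.hash = config.hash()
        self.out_dir = Path(config.out_dir)
        self.artifacts: List[Path] = []
        self._written: List[Path] = []

    # -- helpers ---------------------------------------------------------
    def _write(self, df: pd.DataFrame, name: str) -> Path:
        path = self.out_dir / name
        write_table(df, path, self.hash, self.config.seed)
        self._written.append(path)
        self.artifacts.append(path)
        return path

    def _cuts(self) -> CutPoints:
        preset = CutPoints.from_preset(self.config.cutpoint_preset)
        return CutPoints(preset.sb_max, preset.mvpa_min, self.config.epoch_length_s)

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> Dict[str, pd.DataFrame]:
        cfg = self.config
        if cfg.synthetic:
            # pipeline seed and epoch length are authoritative in synthetic mode
            cohort = dataclasses.replace(
                cfg.cohort, seed=cfg.seed, epoch_length_s=cfg.epoch_length_s
            )
            tables = simulate_cohort_tables(cohort, cuts=self._cuts())
            self._write(tables["students"], "students.csv")
            self._write(tables["saliva"], "saliva.csv")
            self._write(tables["counts"], "counts.csv")
            self._write(tables["missingness_manifest"], "missingness_manifest.csv")
        else:
            tables = {
                "students": read_table(cfg.students_csv),
                "saliva": read_table(cfg.saliva_csv),
                "counts": read_table(cfg.counts_csv),
            }
        report = validate_inputs(
            tables, flooring_enabled=cfg.detection_floor is not None
        )
        for p in report.problems:
            logger.log(
                logging.ERROR if p.severity == "fatal" else logging.WARNING,
                "input validation: %s", p.message,
            )
        if report.fatal:
            raise DataError(
                "input validation failed: "
                + "; ".join(p.message for p in report.problems if p.severity == "fatal")
            )
        return tables

    def stage_compose(self, tables: Dict[str, pd.DataFrame]) -> pd.DataFrame:
        logger.info("classifying epoch counts and closing wear-time compositions")
        comps = compositions_from_counts(
            tables["counts"], self._cuts(), self.config.min_wear_minutes
        )
        self._write(comps, "compositions.csv")
        return comps

    def stage_indices(self, tables: Dict[str, pd.DataFrame]) -> pd.DataFrame:
        logger.info("log-transforming trajectories and computing PR / AUCi")
        idx = indices_from_saliva(
            tables["saliva"],
            detection_floor=self.config.detection_floor,
            pr_definition=self.config.pr_definition,
        )
        self._write(idx, "indices.csv")
        return idx

    def stage_fit(
        self,
        tables: Dict[str, pd.DataFrame],
        compositions: pd.DataFrame,
        indices_df: pd.DataFrame,
    ) -> Dict[str, dict]:
        cfg = self.config
        results: Dict[str, dict] = {}
        summaries = []
        for model_id in cfg.models:
            model_id = model_id.upper()
            spec = ModelSpec.from_id(model_id)
            obs = _assemble_observations(
                indices_df, compositions, tables["students"], spec
            )
            if obs.empty:
                raise DataError(f"{model_id}: no complete-case observations")
            design = build_design(obs, spec)
            mcmc = dataclasses.replace(
                cfg.mcmc, seed=_mcmc_seed(cfg.seed, model_id)
            )
            logger.info(
                "fitting %s (%s %s): %d observations, %d ids, %d chains x %d iterations",
                model_id, spec.analyte, spec.index, design.n_obs, design.n_ids,
                mcmc.chains, mcmc.iterations,
            )
            chains = run_mcmc(design, spec.prior_set, mcmc)
            summary = summarize_posterior(chains)
            summary.insert(0, "model", model_id)
            summaries.append(summary)
            results[model_id] = dict(spec=spec, design=design, chains=chains,
                                     summary=summary)
            if cfg.save_draws:
                self._write_draws(model_id, chains)
        combined = pd.concat(summaries, ignore_index=True)
        self._write(combined, "posterior_summary.csv")
        return results

    def _write_draws(self, model_id: str, chains) -> None:
        # fixed effects + hyperparameters only; per-id intercepts stay in memory
        keep = (
            chains.param_names[: chains.n_beta]
            + ["mu_alpha", "sigma_y", "sigma_alpha"]
        )
        frames = []
        for name in keep:
            per_chain = chains.get(name)
            for c in range(chains.n_chains):
                frames.append(
                    pd.DataFrame(
                        dict(
                            chain=c,
                            iteration=np.arange(chains.n_draws),
                            parameter=name,
                            value=per_chain[c],
                        )
                    )
                )
        long_df = pd.concat(frames, ignore_index=True)
        path = self.out_dir / f"draws_{model_id.lower()}.csv.gz"
        path.parent.mkdir(parents=True, exist_ok=True)
        long_df.to_csv(path, index=False, compression="gzip")
        self._written.append(path)
        self.artifacts.append(path)

    def stage_diagnose(self, results: Dict[str, dict]) -> None:
        cfg = self.config
        for model_id, res in results.items():
            rng = np.random.default_rng(_mcmc_seed(cfg.seed, f"ppc:{model_id}"))
            report = diag.diagnose(
                res["chains"], res["design"], rng, summary=res["summary"]
            )
            path = self.out_dir / f"diagnostics_{model_id.lower()}.json"
            path.parent.mkdir(parents=True, exist_ok=True)
            report.to_json(
                path,
                extra={"model": model_id, "config_hash": self.hash, "seed": cfg.seed},
            )
            self._written.append(path)
            self.artifacts.append(path)
            if cfg.make_plots:
                cmp_summary = res["summary"].iloc[: res["chains"].n_cmp]
                plot_path = self.out_dir / f"slopes_{model_id.lower()}.svg"
                diag.plot_composition_slopes(
                    cmp_summary, plot_path,
                    title=f"{model_id}: {res['spec'].analyte} {res['spec'].index}",
                )
                self._written.append(plot_path)
                self.artifacts.append(plot_path)

    # -- entry point -----------------------------------------------------
    def run(self, through: str = "diagnose") -> Dict[str, object]:
        if through not in STAGES:
            raise ConfigurationError(f"unknown stage {through!r}")
        stage_idx = STAGES.index(through)
        outputs: Dict[str, object] = {}
        current = "simulate"
        try:
            tables = self.stage_simulate()
            outputs["tables"] = tables
            if stage_idx >= STAGES.index("compose"):
                current = "compose"
                outputs["compositions"] = self.stage_compose(tables)
            if stage_idx >= STAGES.index("indices"):
                current = "indices"
                outputs["indices"] = self.stage_indices(tables)
            if stage_idx >= STAGES.index("fit") and self.config.models:
                current = "fit"
                outputs["fits"] = self.stage_fit(
                    tables, outputs["compositions"], outputs["indices"]
                )
            if (
                stage_idx >= STAGES.index("diagnose")
                and self.config.models
                and "fits" in outputs
            ):
                current = "diagnose"
                self.stage_diagnose(outputs["fits"])
        except Exception as exc:
            for path in self._written:
                try:
                    Path(path).unlink(missing_ok=True)
                except OSError:
                    pass
            raise StresscompError(f"stage {current!r} failed: {exc}") from exc
        outputs["artifacts"] = list(self.artifacts)
        return outputs


def run_pipeline(config: PipelineConfig, through: str = "diagnose") -> Dict[str, object]:
    """Convenience wrapper: build a run and execute it."""
    return PipelineRun(config).run(through=through)
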