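import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stresscomp.accelerometry import CutPoints, classify_epochs, compute_composition
from stresscomp.errors import ConfigurationError
from stresscomp.indices import auc_increase, log_transform, peak_reactivity
from stresscomp.synthetic import (
    CohortConfig,
    MissingnessConfig,
    Student,
    TrueParams,
    apply_missingness,
    generate_cohort,
    simulate_accelerometry,
    simulate_cohort_tables,
    simulate_observations,
    simulate_saliva_day,
)


class TestGenerateCohort:
    def test_study_sized_enrollment(self):
        students = generate_cohort(CohortConfig(n_ig=37, n_cg=11, seed=1))
        assert len(students) == 48
        assert sum(s.group == "IG" for s in students) == 37
        assert sum(s.group == "CG" for s in students) == 11

    def test_minimal_cohort(self):
        students = generate_cohort(CohortConfig(n_ig=1, n_cg=1, seed=1))
        assert len(students) == 2
        assert students[0].id != students[1].id

    def test_unique_ids(self):
        students = generate_cohort(CohortConfig(n_ig=37, n_cg=11, seed=1))
        assert len({s.id for s in students}) == 48

    def test_determinism(self):
        a = generate_cohort(CohortConfig(n_ig=5, n_cg=3, seed=9))
        b = generate_cohort(CohortConfig(n_ig=5, n_cg=3, seed=9))
        assert a == b

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_ig=0, n_cg=1).validate()
        with pytest.raises(ConfigurationError):
            CohortConfig(sample_times_h=(10.5, 8.5)).validate()
        with pytest.raises(ConfigurationError):
            CohortConfig(epoch_length_s=7).validate()  # does not divide the window
        with pytest.raises(ConfigurationError):
            CohortConfig(missingness=MissingnessConfig(saliva_day_dropout=1.5)).validate()


class TestSimulateSalivaDay:
    def test_noise_free_closed_form(self, rng):
        params = TrueParams(
            cortisol_log_intercept={"CG": np.log(10.0), "IG": np.log(10.0)},
            cortisol_slope_per_h={"CG": -0.2, "IG": -0.2},
            sigma_y=0.0,
            season_effects={"fall": 0.0},
            gender_effects={"female": 0.0, "male": 0.0},
        )
        student = Student(id="S01", group="IG", gender="female")
        cort, _ = simulate_saliva_day(student, "fall", params, rng)
        t = np.array(cort.times_h)
        expected = 10.0 * np.exp(-0.2 * (t - 8.5))
        assert np.allclose(cort.concentrations, expected, rtol=1e-12)

    def test_flat_trajectory_zero_indices(self, rng):
        params = TrueParams(
            cortisol_slope_per_h={"CG": 0.0, "IG": 0.0},
            sigma_y=0.0,
            season_effects={"fall": 0.0},
            gender_effects={"female": 0.0, "male": 0.0},
        )
        student = Student(id="S01", group="CG", gender="female")
        cort, _ = simulate_saliva_day(student, "fall", params, rng)
        t = log_transform(cort)
        assert auc_increase(t).value == pytest.approx(0.0, abs=1e-12)
        assert all(p.value == pytest.approx(0.0, abs=1e-12) for p in peak_reactivity(t))

    def test_concentrations_positive(self, rng):
        params = TrueParams()
        student = Student(id="S01", group="IG", gender="male")
        for _ in range(50):
            cort, cfdna = simulate_saliva_day(student, "spring", params, rng)
            assert min(cort.concentrations) > 0
            assert min(cfdna.concentrations) > 0

    def test_group_contrast_monte_carlo(self, rng):
        # IG slope steeper than CG -> smaller mean noon/baseline ratio
        params = TrueParams()  # IG -0.25/h vs CG -0.08/h
        ratios = {"IG": [], "CG": []}
        for grp in ("IG", "CG"):
            student = Student(id="S01", group=grp, gender="female")
            for _ in range(1000):
                cort, _ = simulate_saliva_day(student, "fall", params, rng)
                ratios[grp].append(cort.concentrations[-1] / cort.concentrations[0])
        assert np.mean(ratios["IG"]) < np.mean(ratios["CG"])

    def test_log_normality_moment_check(self, rng):
        params = TrueParams()
        student = Student(id="S01", group="IG", gender="female")
        logs = []
        for _ in range(500):
            cort, _ = simulate_saliva_day(student, "fall", params, rng)
            logs.append(np.log(cort.concentrations[0]))
        # generated log-concentrations are Normal by construction
        assert stats.normaltest(logs).pvalue > 1e-3


class TestSimulateAccelerometry:
    def test_pure_sb_mixture(self, rng, cuts):
        params = TrueParams()
        student = Student(id="S01", group="CG", gender="female")
        series = simulate_accelerometry(
            student, "fall", params, rng, cuts, mixture=np.array([1.0, 0.0, 0.0])
        )
        labels = classify_epochs(series, cuts)
        comp = compute_composition(labels, cuts.epoch_length_s, min_wear_minutes=1)
        assert (comp.sb, comp.lpa, comp.mvpa) == (1.0, 0.0, 0.0)

    def test_label_counts_reproducible(self, cuts):
        params = TrueParams()
        student = Student(id="S01", group="IG", gender="male")
        mixture = np.array([0.5, 0.25, 0.25])
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(314)
            series = simulate_accelerometry(
                student, "fall", params, rng, cuts, mixture=mixture
            )
            labels = classify_epochs(series, cuts)
            runs.append([int((labels == part).sum()) for part in ("SB", "LPA", "MVPA")])
        assert runs[0] == runs[1]

    def test_law_of_large_numbers(self, rng):
        # 1 s epochs -> 14,400 epochs in the window
        cuts1 = CutPoints(sb_max=180, mvpa_min=757, epoch_length_s=1)
        params = TrueParams()
        student = Student(id="S01", group="IG", gender="female")
        mixture = np.array([0.5, 0.3, 0.2])
        series = simulate_accelerometry(
            student, "fall", params, rng, cuts1, mixture=mixture
        )
        labels = classify_epochs(series, cuts1)
        comp = compute_composition(labels, 1, min_wear_minutes=1)
        assert np.allclose(comp.as_array(), mixture, atol=0.02)

    def test_truncation(self, rng, cuts):
        params = TrueParams()
        student = Student(id="S01", group="CG", gender="male")
        series = simulate_accelerometry(
            student, "fall", params, rng, cuts, truncate_fraction=0.5
        )
        assert len(series) == 480  # half of the 960 15 s epochs


def _unit_tables(n_units):
    ids = [f"U{k}" for k in range(n_units)]
    saliva = pd.DataFrame(
        dict(id=ids, season=["fall"] * n_units, time_h=[8.5] * n_units,
             cortisol=[5.0] * n_units, cfdna=[50.0] * n_units)
    )
    counts = pd.DataFrame(
        dict(id=ids, season=["fall"] * n_units,
             epoch_start_s=[0.0] * n_units, vm_counts=[10.0] * n_units)
    )
    students = pd.DataFrame(dict(id=ids, group=["IG"] * n_units,
                                 gender=["female"] * n_units))
    return {"students": students, "saliva": saliva, "counts": counts}


class TestApplyMissingness:
    def test_zero_probability_identity(self, rng):
        tables = _unit_tables(20)
        out, manifest = apply_missingness(tables, MissingnessConfig(), rng)
        pd.testing.assert_frame_equal(out["saliva"], tables["saliva"])
        pd.testing.assert_frame_equal(out["counts"], tables["counts"])
        assert manifest.empty

    def test_certain_saliva_dropout(self, rng):
        tables = _unit_tables(20)
        out, manifest = apply_missingness(
            tables, MissingnessConfig(saliva_day_dropout=1.0), rng
        )
        assert out["saliva"].empty
        assert (manifest["table"] == "saliva").sum() == 20

    def test_binomial_interval(self, rng):
        # 99% binomial interval for p=0.2, n=1000 is about [0.17, 0.23]
        tables = _unit_tables(1000)
        out, _ = apply_missingness(
            tables, MissingnessConfig(saliva_day_dropout=0.2), rng
        )
        dropped = 1 - len(out["saliva"]) / 1000
        assert 0.17 <= dropped <= 0.23

    def test_surviving_rows_unchanged(self, rng):
        tables = _unit_tables(50)
        out, _ = apply_missingness(
            tables, MissingnessConfig(saliva_day_dropout=0.5), rng
        )
        kept = out["saliva"]
        merged = kept.merge(tables["saliva"], on=list(kept.columns), how="left",
                            indicator=True)
        assert (merged["_merge"] == "both").all()


class TestCohortTables:
    def test_seed_determinism_byte_identical(self):
        cfg = CohortConfig(n_ig=4, n_cg=2, seed=5, epoch_length_s=120)
        a = simulate_cohort_tables(cfg)
        b = simulate_cohort_tables(cfg)
        for key in ("students", "saliva", "counts"):
            assert a[key].to_csv() == b[key].to_csv()

    def test_schema(self, small_tables):
        assert list(small_tables["students"].columns) == ["id", "group", "gender"]
        assert list(small_tables["saliva"].columns) == [
            "id", "season", "time_h", "cortisol", "cfdna"]
        assert list(small_tables["counts"].columns) == [
            "id", "season", "epoch_start_s", "vm_counts"]

    def test_missingness_wired_through(self):
        cfg = CohortConfig(
            n_ig=4, n_cg=2, seed=5, epoch_length_s=120,
            missingness=MissingnessConfig(saliva_day_dropout=1.0),
        )
        tables = simulate_cohort_tables(cfg)
        assert tables["saliva"].empty
        assert len(tables["missingness_manifest"]) == 18  # 6 students x 3 seasons


class TestSimulateObservations:
    def test_model_structure(self, rng):
        obs = simulate_observations(
            n_ig=5, n_cg=3, seasons=("fall", "spring"),
            composition_slopes={"CG": (1.0, 0.0, 0.0), "IG": (0.0, 1.0, 0.0)},
            rng=rng,
        )
        assert len(obs) == 8 * 2
        assert set(obs["group"]) == {"CG", "IG"}
        assert np.allclose(obs[["sb", "lpa", "mvpa"]].sum(axis=1), 1.0)

    def test_timepoint_doubling(self, rng):
        obs = simulate_observations(
            n_ig=2, n_cg=2, seasons=("fall",),
            composition_slopes={"CG": (0, 0, 0), "IG": (0, 0, 0)},
            rng=rng, timepoint_effect=0.5,
        )
        assert len(obs) == 4 * 2
        assert set(obs["timepoint"]) == {"midmorning", "noon"}
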