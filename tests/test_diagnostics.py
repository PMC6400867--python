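import json

import numpy as np
import pytest

from stresscomp.bhlm import McmcConfig, ModelSpec, build_design, run_mcmc
from stresscomp.bhlm.model import deviance
from stresscomp.bhlm.sampler import Chains
from stresscomp.diagnostics import (
    DiagnosticsReport,
    classify_credibility,
    diagnose,
    dic,
    effective_sample_size,
    gelman_rubin,
    plot_composition_slopes,
    posterior_predictive_check,
)
from stresscomp.errors import DataError
from stresscomp.synthetic import simulate_observations


def rhat_formula_oracle(chains):
    """Direct split-chain PSRF recomputation for the test's own use."""
    m, n = chains.shape
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    sm, sn = split.shape
    w = split.var(axis=1, ddof=1).mean()
    b = sn * split.mean(axis=1).var(ddof=1)
    return np.sqrt(((sn - 1) / sn * w + b / sn) / w)


class TestGelmanRubin:
    def test_identical_white_noise_near_one(self, rng):
        draws = rng.normal(size=(4, 1000))
        assert gelman_rubin(draws) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_match_formula_oracle(self, rng):
        chains = np.vstack([rng.normal(0.0, 1.0, 1000), rng.normal(100.0, 1.0, 1000)])
        r = gelman_rubin(chains)
        assert r > 1.1  # B/W dominance
        assert r == pytest.approx(rhat_formula_oracle(chains), rel=1e-12)

    def test_constant_chains_warn_one(self):
        with pytest.warns(RuntimeWarning):
            assert gelman_rubin(np.full((3, 100), 7.0)) == 1.0

    def test_affine_invariance(self, rng):
        chains = rng.normal(size=(3, 500)) + np.array([[0.0], [0.5], [1.0]])
        a = gelman_rubin(chains)
        b = gelman_rubin(3.7 * chains - 11.0)
        assert a == pytest.approx(b, rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(DataError):
            gelman_rubin(np.zeros((1, 100)))
        with pytest.raises(DataError):
            gelman_rubin(np.zeros((2, 3)))


class TestEffectiveSampleSize:
    def test_iid_draws_near_total(self, rng):
        draws = rng.normal(size=(3, 2500))
        ess = effective_sample_size(draws)
        assert 6500 <= ess <= 7500

    def test_ar1_closed_form(self, rng):
        rho = 0.9
        m, n = 3, 5000
        chains = np.empty((m, n))
        for c in range(m):
            x = rng.normal()
            for t in range(n):
                x = rho * x + rng.normal() * np.sqrt(1 - rho**2)
                chains[c, t] = x
        ess = effective_sample_size(chains)
        expected = m * n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.25)

    def test_cap_at_total(self, rng):
        # antithetic draws are negatively correlated -> raw estimate exceeds total
        half = rng.normal(size=(3, 500))
        chains = np.concatenate([half, -half], axis=1)
        assert effective_sample_size(chains) <= 3000

    def test_constant_chains_warn_total(self):
        with pytest.warns(RuntimeWarning):
            assert effective_sample_size(np.full((3, 100), 2.0)) == 300.0

    def test_affine_invariance(self, rng):
        chains = rng.normal(size=(3, 1000))
        a = effective_sample_size(chains)
        b = effective_sample_size(-2.0 * chains + 5.0)
        assert a == pytest.approx(b, rel=1e-10)


class TestDic:
    def test_point_mass_chains(self, fitted_small_model):
        design, chains, _ = fitted_small_model
        # freeze every draw at one state: pD must vanish exactly
        frozen = Chains(
            param_names=chains.param_names,
            draws=np.tile(chains.draws[0, 0], (2, 100, 1)),
            n_beta=chains.n_beta, n_cmp=chains.n_cmp, n_alpha=chains.n_alpha,
        )
        parts = dic(frozen, design)
        state = frozen.state_at(0)
        assert parts["pd"] == pytest.approx(0.0, abs=1e-8)
        assert parts["dic"] == pytest.approx(deviance(state, design), rel=1e-10)

    def test_brute_force_reimplementation_oracle(self, fitted_small_model):
        design, chains, _ = fitted_small_model
        parts = dic(chains, design)
        # independent loop over every pooled draw
        total = chains.n_chains * chains.n_draws
        devs = np.array(
            [deviance(chains.state_at(k), design) for k in range(total)]
        )
        mean_dev = devs.mean()
        pd_ = mean_dev - deviance(chains.mean_state(), design)
        assert parts["mean_deviance"] == pytest.approx(mean_dev, rel=1e-9)
        assert parts["pd"] == pytest.approx(pd_, rel=1e-6, abs=1e-8)
        assert parts["dic"] == pytest.approx(mean_dev + pd_, rel=1e-9)

    def test_decomposition_identity(self, fitted_small_model):
        design, chains, _ = fitted_small_model
        parts = dic(chains, design)
        assert parts["dic"] == parts["mean_deviance"] + parts["pd"]

    def test_irrelevant_covariate_mean_deviance(self):
        # dropping a pure-noise covariate never helps mean deviance on average
        cfg = McmcConfig(chains=2, iterations=1200, burn_in=400, thinning=2, seed=0)
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            obs = simulate_observations(
                n_ig=8, n_cg=6, seasons=("fall", "spring"),
                composition_slopes={"CG": (0.5, -0.5, 0.5), "IG": (-0.5, 0.5, -0.5)},
                rng=rng, gender_effect=0.0,  # gender column is irrelevant
            )
            spec = ModelSpec.from_id("bhlm2")
            design = build_design(obs, spec)
            reduced = design.drop_column("gender[male]")
            import dataclasses

            full_chains = run_mcmc(design, spec.prior_set, cfg)
            red_chains = run_mcmc(reduced, spec.prior_set,
                                  dataclasses.replace(cfg, seed=cfg.seed + 1))
            diffs.append(
                dic(full_chains, design)["mean_deviance"]
                - dic(red_chains, reduced)["mean_deviance"]
            )
        assert np.mean(diffs) >= -0.5  # irrelevant covariate adds fit noise, never signal


class TestPosteriorPredictiveCheck:
    def test_probabilities_in_unit_interval(self, fitted_small_model, rng):
        design, chains, _ = fitted_small_model
        probs = posterior_predictive_check(chains, design, rng)
        assert set(probs) == {"mean", "sd", "min", "max"}
        assert all(0.0 <= p <= 1.0 for p in probs.values())

    def test_calibrated_under_true_model(self, fitted_small_model):
        # data were generated from the fitted model family: tail probabilities
        # should stay away from 0/1 in at least 9 of 10 seeded replications
        design, chains, _ = fitted_small_model
        ok = 0
        for seed in range(10):
            probs = posterior_predictive_check(
                chains, design, np.random.default_rng(seed)
            )
            ok += all(0.05 < probs[s] < 0.95 for s in ("mean", "sd"))
        assert ok >= 9

    def test_gross_misfit_detected(self, fitted_small_model, rng):
        import dataclasses as dc

        design, chains, _ = fitted_small_model
        sigma = chains.pooled("sigma_y").mean()
        shifted = dc.replace(design, y=design.y + 10.0 * sigma)
        probs = posterior_predictive_check(chains, shifted, rng)
        assert probs["mean"] <= 0.01


class TestClassifyCredibility:
    @staticmethod
    def row(q025, q25, q75, q975):
        return {"cri_2.5%": q025, "cri_25%": q25, "cri_75%": q75, "cri_97.5%": q975}

    def test_printed_strong_interval(self):
        # 95% interval [-1.268, -0.190] excludes zero
        assert classify_credibility(self.row(-1.268, -0.908, -0.551, -0.190)) == "strong"

    def test_printed_moderate_interval(self):
        assert classify_credibility(self.row(-0.512, -0.318, -0.112, 0.085)) == "moderate"

    def test_symmetric_none(self):
        assert classify_credibility(self.row(-1.0, -0.5, 0.5, 1.0)) == "none"

    def test_monotone_in_widening(self, rng):
        order = {"strong": 2, "moderate": 1, "none": 0}
        for _ in range(100):
            center = rng.normal()
            w50, w95e = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
            narrow = self.row(center - w50 - w95e, center - w50,
                              center + w50, center + w50 + w95e)
            grow = rng.uniform(0.0, 2.0, size=2)
            wide = self.row(narrow["cri_2.5%"] - grow[1], narrow["cri_25%"] - grow[0],
                            narrow["cri_75%"] + grow[0], narrow["cri_97.5%"] + grow[1])
            assert order[classify_credibility(wide)] <= order[classify_credibility(narrow)]


class TestReportAndPlot:
    def test_diagnose_bundle(self, fitted_small_model, rng, tmp_path):
        from stresscomp.bhlm import summarize_posterior

        design, chains, _ = fitted_small_model
        summary = summarize_posterior(chains)
        report = diagnose(chains, design, rng, summary=summary)
        assert report.dic == pytest.approx(report.mean_deviance + report.pd)
        assert set(report.credibility) == set(chains.param_names)
        out = tmp_path / "diag.json"
        report.to_json(out, extra={"model": "BHLM2"})
        payload = json.loads(out.read_text())
        assert payload["model"] == "BHLM2"
        assert "rhat" in payload and "ppc" in payload

    def test_plot_written(self, fitted_small_model, tmp_path):
        from stresscomp.bhlm import composition_summary

        _, chains, _ = fitted_small_model
        path = tmp_path / "slopes.svg"
        plot_composition_slopes(composition_summary(chains), path, title="test")
        assert path.exists() and path.stat().st_size > 0
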