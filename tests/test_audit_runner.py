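"""Config loading, six-step orchestration and the study-batch simulator."""

import math

import numpy as np
import pytest
import yaml

from bayes_audit import (
    BfMethodSpec,
    ConfigurationError,
    ContractError,
    DomainError,
    calibration_check,
    load_config,
    packaged_config_path,
    run_audit,
    simulate_studies,
)


class TestLoadConfig:
    def test_packaged_case_study_config(self, case_config):
        assert [p.value for p in case_config.priors] == [0.05, 0.10, 0.20]
        assert case_config.evidence.stipulated == [3.0]
        assert case_config.claim.strength.value == "strong_causal_general"

    def test_missing_priors_named_in_error(self, tmp_path):
        cfg = {"claim": {"text": "x", "strength": "tentative"},
               "evidence": {"stipulated": [3.0]}}
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigurationError, match="priors"):
            load_config(path)

    def test_all_failures_reported_at_once(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"claim": {"text": "x"}}))
        with pytest.raises(ConfigurationError) as exc:
            load_config(path)
        msg = str(exc.value)
        assert "priors" in msg and "evidence" in msg and "strength" in msg

    def test_stipulated_takes_precedence_over_studies(self, case_config):
        report = run_audit(case_config)
        assert report.effective_evidence.method.value == "stipulated"
        assert report.effective_evidence.bf10 == 3.0
        # the study row is still translated and retained
        assert any(e.method.value == "jzs" for e in report.evidence)

    def test_json_dialect_accepted(self, tmp_path):
        import json

        cfg = {
            "claim": {"text": "x", "strength": "tentative"},
            "priors": [{"value": 0.1}],
            "evidence": {"stipulated": [2.0]},
        }
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps(cfg))
        assert load_config(path).evidence.stipulated == [2.0]

    def test_missing_file(self, tmp_path):
        with pytest.raises(ConfigurationError, match="not found"):
            load_config(tmp_path / "absent.yaml")


class TestRunAudit:
    def test_case_study_posteriors(self, case_config):
        report = run_audit(case_config)
        assert [round(p.value, 2) for p in report.posteriors] == [0.14, 0.25, 0.43]
        assert report.verdict.value == "over_claimed"
        assert report.stability.breakeven_prior == pytest.approx(0.25)

    def test_appending_unit_bf_leaves_posteriors_identical(self, case_config):
        base = run_audit(case_config)
        cfg = case_config.model_copy(deep=True)
        cfg.evidence.stipulated = [3.0, 1.0]
        with_replication = run_audit(cfg)
        assert [p.value for p in with_replication.posteriors] == [
            p.value for p in base.posteriors
        ]

    def test_neutral_prior_yields_moderate_belief(self, case_config):
        cfg = case_config.model_copy(deep=True)
        cfg.priors = [p.model_copy(update={"value": 0.50}) for p in cfg.priors[:1]]
        report = run_audit(cfg)
        assert report.posteriors[0].value == pytest.approx(0.75, abs=1e-12)
        assert report.belief.band.value == "moderate"

    def test_combination_mode_multiplies_evidence(self, case_config):
        cfg = case_config.model_copy(deep=True)
        cfg.evidence.stipulated = [3.0, 3.0]
        cfg.evidence.combine = True
        report = run_audit(cfg)
        assert report.effective_evidence.bf10 == pytest.approx(9.0)
        assert "naive_independence_product" in report.effective_evidence.caveats

    def test_end_to_end_determinism(self, case_config):
        from bayes_audit import render_report

        assert render_report(run_audit(case_config), "json") == render_report(
            run_audit(case_config), "json"
        )


class TestSimulateStudies:
    def test_seed_reproducibility_bit_for_bit(self):
        a = simulate_studies(5, 0.4, 15, 15, seed=42)
        b = simulate_studies(5, 0.4, 15, 15, seed=42)
        assert a.summaries == b.summaries

    def test_null_batch_follows_central_t(self):
        from scipy import stats

        batch = simulate_studies(5000, 0.0, 15, 15, seed=7)
        t = np.array([s.t_value for s in batch.summaries])
        df = 28
        assert abs(t.mean()) < 0.1
        # sampling SD of the variance of n t(28) draws, from its kurtosis
        var_sd = math.sqrt(
            (df / (df - 2)) ** 2 * (2 / (len(t) - 1) + (6 / (df - 4)) / len(t))
        )
        assert abs(t.var(ddof=1) - df / (df - 2)) < 3 * var_sd
        assert stats.kstest(t, "t", args=(df,)).pvalue > 0.01

    def test_noncentral_mean_matches_oracle(self):
        batch = simulate_studies(1000, 0.75, 15, 15, seed=7)
        t = np.array([s.t_value for s in batch.summaries])
        df, ncp = 28, 0.75 * math.sqrt(7.5)
        # E[t] = ncp * sqrt(df/2) * gamma((df-1)/2) / gamma(df/2)
        exact_mean = ncp * math.sqrt(df / 2) * math.gamma((df - 1) / 2) / math.gamma(df / 2)
        se = t.std(ddof=1) / math.sqrt(len(t))
        assert abs(t.mean() - exact_mean) < 3 * se

    def test_one_sample_design(self):
        batch = simulate_studies(3, 0.0, 20, None, seed=1)
        assert batch.summaries[0].df == 19

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(DomainError):
            simulate_studies(0, 0.0, 15, 15, seed=1)
        with pytest.raises(DomainError):
            simulate_studies(10, 0.0, 0, 15, seed=1)


class TestCalibrationCheck:
    def test_null_exceedance_respects_markov_bound(self):
        batch = simulate_studies(1500, 0.0, 15, 15, seed=3)
        table = calibration_check(batch, BfMethodSpec(), c_values=(1.0, 3.0))
        for _, row in table.iterrows():
            assert row["rate"] <= row["markov_bound"] + 3 * max(row["se"], 1e-6)

    def test_nonnull_batch_rejected_for_bound_check(self):
        batch = simulate_studies(10, 0.75, 15, 15, seed=3)
        with pytest.raises(ContractError, match="null batch"):
            calibration_check(batch)

    def test_true_effect_raises_exceedance(self):
        null = simulate_studies(400, 0.0, 15, 15, seed=5)
        effect = simulate_studies(400, 0.75, 15, 15, seed=5)
        r_null = calibration_check(null, c_values=(3.0,)).loc[0, "rate"]
        r_eff = calibration_check(effect, c_values=(3.0,), require_null=False).loc[
            0, "rate"
        ]
        assert r_eff > r_null
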