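import numpy as np
import pandas as pd
import pytest

from deweight import (
    SimulationConfig,
    ValidationError,
    estimate_disparity,
    generate,
    oracle_truth,
    true_propensities,
    true_weight_set,
    unadjusted_difference,
)


class TestConfigValidation:
    def test_default_config_is_valid(self, default_config):
        assert default_config.n_ses == 2
        assert default_config.n_health == 6

    def test_tables_must_sum_to_one(self, default_config):
        bad = default_config.ses_joint_minority * 0.5
        with pytest.raises(ValidationError, match="sum to 1"):
            SimulationConfig(ses_joint_minority=bad)

    def test_zero_probability_cell_rejected(self, default_config):
        tab = default_config.ses_joint_minority.copy()
        tab[0, 0] += tab[1, 1]
        tab[1, 1] = 0.0
        with pytest.raises(ValidationError, match="positiv"):
            SimulationConfig(ses_joint_minority=tab)

    def test_non_spd_covariance_rejected(self):
        cov = -np.eye(6)
        with pytest.raises(ValidationError, match="positive definite"):
            SimulationConfig(health_cov=cov)

    def test_yaml_round_trip(self, tmp_path, default_config):
        import yaml

        cfg_dict = {
            "n": 100,
            "p_minority": 0.3,
            "ses_names": ["a", "b"],
            "ses_joint_minority": default_config.ses_joint_minority.tolist(),
            "ses_joint_majority": default_config.ses_joint_majority.tolist(),
            "race_shift": default_config.race_shift.tolist(),
            "ses_shifts": default_config.ses_shifts.tolist(),
            "health_cov": default_config.health_cov.tolist(),
            "outcome_ses": default_config.outcome_ses.tolist(),
            "outcome_health": default_config.outcome_health.tolist(),
        }
        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(cfg_dict))
        cfg = SimulationConfig.from_yaml(p)
        assert cfg.n == 100 and cfg.ses_names == ("a", "b")


class TestGenerate:
    def test_fixed_seed_reproducible(self, default_config):
        a = generate(default_config, seed=11, n=500).to_frame()
        b = generate(default_config, seed=11, n=500).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, default_config):
        a = generate(default_config, seed=1, n=500).to_frame()
        b = generate(default_config, seed=2, n=500).to_frame()
        assert not a.equals(b)

    def test_null_race_effect_gives_null_crude_difference(self):
        cfg = SimulationConfig(
            race_shift=np.zeros(6),
            outcome_race=0.0,
            ses_joint_minority=SimulationConfig().ses_joint_majority,
        )
        data = generate(cfg, seed=123, n=100_000)
        est = unadjusted_difference(data)
        binom_se = np.sqrt(
            0.25 / data.n_minority + 0.25 / data.n_majority
        )
        assert abs(est.tau_hat) < 3 * binom_se

    def test_marginals_track_config(self, default_config):
        data = generate(default_config, seed=8, n=200_000)
        assert abs(data.Z.mean() - default_config.p_minority) < 0.005
        minority_edu = data.X_s.loc[data.Z == 1, "educ_hs"].mean()
        expected = default_config.ses_joint_minority[1, :].sum()
        assert abs(minority_edu - expected) < 0.01


class TestTruePropensities:
    def test_ses_ps_matches_empirical_cell_proportions(self, default_config):
        data = generate(default_config, seed=21, n=200_000)
        _, e_ses = true_propensities(
            default_config, data.X_s.to_numpy(), data.X_h.to_numpy()
        )
        for r in range(1, data.n_subgroups + 1):
            cell = data.G == r
            emp = data.Z[cell].mean()
            assert abs(e_ses[cell][0] - emp) < 0.02

    def test_full_ps_calibration(self, default_config):
        # among subjects with similar true e(x), the minority share ≈ e(x)
        data = generate(default_config, seed=22, n=200_000)
        e_full, _ = true_propensities(
            default_config, data.X_s.to_numpy(), data.X_h.to_numpy()
        )
        bins = np.quantile(e_full, np.linspace(0, 1, 11))
        idx = np.clip(np.searchsorted(bins, e_full) - 1, 0, 9)
        for b in range(10):
            m = idx == b
            if m.sum() > 2000:
                assert abs(data.Z[m].mean() - e_full[m].mean()) < 0.02


class TestOracle:
    def test_null_outcome_model_gives_zero_truth(self):
        cfg = SimulationConfig(outcome_race=0.0, outcome_ses=np.zeros(2),
                               ses_shifts=np.zeros((2, 6)))
        # outcome independent of Z given covariates AND SES effect removed:
        # every estimand's truth is 0
        for estimand in ("ate", "att", "ato"):
            t = oracle_truth(cfg, estimand, n_oracle=200_000, seed=3)
            assert abs(t.tau) < 3 * t.mc_se + 1e-3

    def test_single_ses_cell_reduces_to_plain_weighting(self):
        # one (near-degenerate) SES cell: deweighting reduces to plain
        # balancing weights because e(x^s) is constant
        eps = 1e-9
        tab = np.array([[1 - 3 * eps, eps], [eps, eps]])
        cfg = SimulationConfig(
            ses_joint_minority=tab, ses_joint_majority=tab,
            outcome_ses=np.zeros(2), ses_shifts=np.zeros((2, 6)),
        )
        rng_t = oracle_truth(cfg, "ate", n_oracle=200_000, seed=9)
        # independent plain-IPW oracle on the same draw mechanism
        from deweight.synthetic import _draw

        rng = np.random.default_rng(9)
        Z, X_s, X_h, _, eta = _draw(cfg, 200_000, rng)
        from scipy.special import expit

        m = expit(eta)
        e_full, _ = true_propensities(cfg, X_s, X_h)
        w1 = 1 / e_full[Z == 1]
        w0 = 1 / (1 - e_full[Z == 0])
        ipw = (np.sum(w1 * m[Z == 1]) / w1.sum()
               - np.sum(w0 * m[Z == 0]) / w0.sum())
        assert abs(rng_t.tau - ipw) < 1e-10

    def test_mc_se_scales_with_oracle_size(self, default_config):
        t_small = oracle_truth(default_config, "att", n_oracle=20_000, seed=4)
        t_big = oracle_truth(default_config, "att", n_oracle=320_000, seed=4)
        ratio = t_small.mc_se / t_big.mc_se
        assert 2.5 < ratio < 6.5  # expect 4 = sqrt(16)

    def test_true_weight_set_att_preserves_ses_shares(self, default_config):
        data = generate(default_config, seed=31, n=50_000)
        w = true_weight_set(
            default_config, data.X_s.to_numpy(), data.X_h.to_numpy(), "att"
        )
        maj = data.Z == 0
        for col in data.X_s.columns:
            x = data.X_s[col].to_numpy(float)[maj]
            wv = w.omega0[maj]
            raw, weighted = x.mean(), np.sum(wv * x) / wv.sum()
            assert abs(raw - weighted) < 0.01


class TestIndependenceReduction:
    def test_health_ps_and_deweighting_agree_when_ses_indep_health(self):
        from deweight import (
            comparator_weights,
            deweighting_weights,
            fit_health_status_ps,
            fit_ses_ps_saturated,
            fit_stratified_full_ps,
        )

        cfg = SimulationConfig(ses_shifts=np.zeros((2, 6)))
        data = generate(cfg, seed=13, n=50_000)
        w_dw = deweighting_weights(
            fit_stratified_full_ps(data, "cbps", "att"),
            fit_ses_ps_saturated(data),
            "att",
        )
        w_h = comparator_weights(
            fit_health_status_ps(data, "cbps", "att"), "att", "health_ps"
        )
        d_dw = estimate_disparity(data, w_dw)
        d_h = estimate_disparity(data, w_h)
        combined = np.hypot(d_dw.se, d_h.se)
        assert abs(d_dw.tau_hat - d_h.tau_hat) < 3 * combined
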