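import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deweight import (
    WeightSet,
    asmd_between,
    build_weights,
    concordance_report,
    ses_alteration,
    subgroup_health_balance,
)

from conftest import make_dataset


def unit_weights(n):
    return WeightSet(np.ones(n), np.ones(n), "ate", "manual")


def brute_force_metrics(data, w):
    """Independent loop-based recomputation of D1, D0 and Dr."""
    d1, d0, dr = {}, {}, {}
    Z, G = data.Z, data.G
    for col in data.X_s.columns:
        x = data.X_s[col].to_numpy(float)
        for label, store, sel, wv in (
            ("min", d1, Z == 1, w.omega1),
            ("maj", d0, Z == 0, w.omega0),
        ):
            xs, ws = x[sel], wv[sel]
            sd = np.std(xs, ddof=1)
            val = abs(xs.mean() - np.sum(ws * xs) / ws.sum())
            store[col] = 0.0 if sd == 0 else val / sd
    for r in sorted(set(G)):
        for col in data.X_h.columns:
            x = data.X_h[col].to_numpy(float)
            m1 = (G == r) & (Z == 1)
            m0 = (G == r) & (Z == 0)
            s1, s0 = np.std(x[m1], ddof=1), np.std(x[m0], ddof=1)
            denom = np.sqrt((s1**2 + s0**2) / 2)
            num = abs(
                np.sum(w.omega1[m1] * x[m1]) / w.omega1[m1].sum()
                - np.sum(w.omega0[m0] * x[m0]) / w.omega0[m0].sum()
            )
            dr[(r, col)] = num / denom
    return d1, d0, dr


class TestAsmdBetween:
    def test_identical_weighted_means_give_zero(self):
        data = make_dataset(
            Z=[1, 1, 0, 0], Y=[0] * 4,
            ses={"s": [0, 1, 0, 1]}, health={"x": [0.0, 2, 1, 1]},
        )
        # minority (0,2) and majority (1,1): equal means, unequal variances
        D = asmd_between(data, unit_weights(4), covariates=["x"])
        assert D.loc["x", "D"] == 0.0

    def test_degenerate_covariate_flagged_not_fatal(self):
        data = make_dataset(
            Z=[1, 1, 0, 0], Y=[0] * 4,
            ses={"s": [0, 1, 0, 1]}, health={"x": [1.0, 1, 1, 1]},
        )
        D = asmd_between(data, unit_weights(4), covariates=["x"])
        assert D.loc["x", "D"] == 0.0
        assert bool(D.loc["x", "degenerate"])

    def test_pooled_cbps_ate_balances_modeled_covariates(self, medium_data):
        from deweight import comparator_weights, fit_health_status_ps

        e = fit_health_status_ps(medium_data, "cbps", "ate")
        w = comparator_weights(e, "ate", "health_ps")
        D = asmd_between(medium_data, w, covariates=list(medium_data.X_h.columns))
        assert D["D"].max() <= 1e-6


class TestSesAlteration:
    def test_constant_weights_give_zero(self, medium_data):
        w = unit_weights(medium_data.n_subjects)
        for group in ("minority", "majority"):
            assert (ses_alteration(medium_data, w, group)["D"] == 0.0).all()

    def test_hand_arithmetic(self):
        data = make_dataset(
            Z=[1, 1, 0, 0], Y=[0] * 4,
            ses={"s": [0, 1, 0, 1]}, health={"h": [0.0, 1, 2, 3]},
        )
        w = WeightSet(np.array([1.0, 3, 1, 1]), np.ones(4), "ate", "manual")
        d1 = ses_alteration(data, w, "minority")
        sd = np.std([0.0, 1.0], ddof=1)
        np.testing.assert_allclose(d1.loc["s", "D"], abs(0.5 - 0.75) / sd)

    def test_invalid_group_name(self, tiny_dataset):
        with pytest.raises(ValueError):
            ses_alteration(tiny_dataset, unit_weights(4), "both")


class TestSubgroupHealthBalance:
    def test_single_subgroup_reduces_to_between_group_asmd(self, medium_data):
        data = make_dataset(
            Z=medium_data.Z, Y=medium_data.Y,
            ses={"s": np.zeros(medium_data.n_subjects, dtype=int)},
            health={c: medium_data.X_h[c].to_numpy()
                    for c in medium_data.X_h.columns},
        )
        w = unit_weights(data.n_subjects)
        dr = subgroup_health_balance(data, w).set_index("covariate")
        D = asmd_between(data, w, covariates=list(data.X_h.columns))
        np.testing.assert_allclose(dr["D"], D["D"])

    def test_stratified_ml_ato_exact_balance(self, medium_data):
        from deweight import deweighting_weights, fit_ses_ps_saturated, \
            fit_stratified_full_ps

        e_full = fit_stratified_full_ps(medium_data, "ml", "ato")
        e_ses = fit_ses_ps_saturated(medium_data)
        w = deweighting_weights(e_full, e_ses, "ato")
        dr = subgroup_health_balance(medium_data, w)
        assert dr["D"].max() <= 1e-8

    def test_insufficient_stratum_flagged(self):
        data = make_dataset(
            Z=[1, 0, 0, 1, 1, 0, 0, 1, 1, 0],
            Y=[0] * 10,
            ses={"s": [0] * 9 + [1]},
            health={"h": np.arange(10.0)},
        )
        dr = subgroup_health_balance(data, unit_weights(10))
        flags = dr.set_index("subgroup")["flag"]
        assert flags.loc[2] == "insufficient_n"


class TestConcordanceReport:
    def test_unit_weights_identity(self, medium_data):
        w = unit_weights(medium_data.n_subjects)
        rep = concordance_report(medium_data, {"unit": w})
        assert (rep.d1["unit"]["D"] == 0).all()
        assert (rep.d0["unit"]["D"] == 0).all()
        raw = subgroup_health_balance(medium_data, w)
        np.testing.assert_allclose(rep.dr["unit"]["D"], raw["D"])

    def test_flags_match_brute_force_recomputation(self, medium_data):
        w = build_weights(medium_data, "ate", "sshs_ps")
        rep = concordance_report(medium_data, {"sshs": w}, threshold=0.1)
        d1, d0, dr = brute_force_metrics(medium_data, w)
        expected_flags = {
            ("D1", c) for c, v in d1.items() if v > 0.1
        } | {("D0", c) for c, v in d0.items() if v > 0.1} | {
            ("Dr", c) for (r, c), v in dr.items() if v > 0.1
        }
        got = {
            (row["metric"], row["covariate"])
            for _, row in rep.flags.iterrows()
        }
        assert got == expected_flags
        for c, v in d1.items():
            np.testing.assert_allclose(rep.d1["sshs"].loc[c, "D"], v)

    def test_long_format_covers_all_metrics(self, medium_data):
        w = build_weights(medium_data, "att", "deweighting")
        rep = concordance_report(medium_data, {"dw": w})
        long = rep.to_long()
        assert set(long["metric"]) == {"D1", "D0", "Dr"}
        n_ses = medium_data.X_s.shape[1]
        n_dr = medium_data.n_subgroups * medium_data.X_h.shape[1]
        assert len(long) == 2 * n_ses + n_dr


class TestMetricInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c1=st.floats(0.1, 50), c0=st.floats(0.1, 50))
    def test_rescaling_weights_leaves_metrics_unchanged(self, c1, c0, medium_data):
        w = build_weights(medium_data, "ate", "deweighting")
        ws = WeightSet(w.omega1 * c1, w.omega0 * c0, w.estimand, w.method)
        for grp in ("minority", "majority"):
            np.testing.assert_allclose(
                ses_alteration(medium_data, w, grp)["D"],
                ses_alteration(medium_data, ws, grp)["D"],
                rtol=1e-9, atol=1e-12,
            )
        np.testing.assert_allclose(
            subgroup_health_balance(medium_data, w)["D"],
            subgroup_health_balance(medium_data, ws)["D"],
            rtol=1e-9, atol=1e-12,
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.2, 5), b=st.floats(-10, 10))
    def test_affine_equivariance_of_asmd(self, a, b, medium_data):
        w = build_weights(medium_data, "att", "deweighting")
        col = medium_data.X_h.columns[0]
        base = asmd_between(medium_data, w, covariates=[col]).loc[col, "D"]
        shifted = make_dataset(
            Z=medium_data.Z, Y=medium_data.Y,
            ses={c: medium_data.X_s[c].to_numpy()
                 for c in medium_data.X_s.columns},
            health={col: a * medium_data.X_h[col].to_numpy() + b},
        )
        val = asmd_between(shifted, w, covariates=[col]).loc[col, "D"]
        np.testing.assert_allclose(val, base, rtol=1e-9, atol=1e-12)

    def test_subgroup_masses_partition_sample(self, medium_data):
        total = 0
        for r in range(1, medium_data.n_subgroups + 1):
            total += int((medium_data.G == r).sum())
        assert total == medium_data.n_subjects
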