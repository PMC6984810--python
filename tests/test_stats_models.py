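import numpy as np
import pandas as pd
import pytest

from meawell.stats_models import (
    AmplitudeMixedModel,
    FrequencyMixedModel,
    GammaFrequencyGLM,
    contrast_tests,
    persistent_amplitude_filter,
)


def amplitude_frame(shift=-0.074, noise=0.02, n_exp=3, n_elec=8, n_clu=2, seed=0):
    """Nested pre/post amplitude data with a known treated-group shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_exp):
        e_off = rng.normal(0, 0.05)
        for el in range(n_elec):
            el_off = rng.normal(0, 0.05)
            trt = "treated" if el < n_elec // 2 else "control"
            for c in range(n_clu):
                base = 1.7 + e_off + el_off + rng.normal(0, 0.1)
                for rec, s in [("r1", 0.0), ("r2", shift if trt == "treated" else 0.0)]:
                    rows.append(
                        {
                            "log10_uv": base + s + (rng.normal(0, noise) if noise else 0.0),
                            "treatment": trt,
                            "recording": rec,
                            "cluster": f"c{c}",
                            "electrode": f"el{el}",
                            "experiment": f"e{e}",
                        }
                    )
    return pd.DataFrame(rows)


class TestGammaGLM:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"hz": rng.gamma(2.0, 0.24 / 2.0, 500), "treatment": "media", "recording": "r1"}
        )
        res = GammaFrequencyGLM(df).fit()
        mu, se = res.mu_by_cell.loc[0, ["mu_hz", "se"]]
        assert abs(mu - 0.24) <= 3 * se

    def test_cell_means_match_sample_means(self):
        # saturated interaction design: fitted cell means are an algebraic
        # identity with the sample means
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "hz": rng.gamma(2.0, 0.5, 400),
                "treatment": rng.choice(["a", "b"], 400),
                "recording": rng.choice(["r1", "r2"], 400),
            }
        )
        res = GammaFrequencyGLM(df).fit()
        fitted = res.mu_by_cell.set_index(["treatment", "recording"])["mu_hz"]
        observed = df.groupby(["treatment", "recording"])["hz"].mean()
        for key in observed.index:
            assert fitted.loc[key] == pytest.approx(observed.loc[key], rel=1e-6)

    def test_identical_conditions_null_contrast(self):
        rng = np.random.default_rng(2)
        hz = rng.gamma(2.0, 0.3, 200)
        df = pd.DataFrame(
            {
                "hz": np.r_[hz, hz],
                "treatment": ["a"] * 200 + ["b"] * 200,
                "recording": "r1",
            }
        )
        res = GammaFrequencyGLM(df).fit()
        c = res.cell_contrast(("a", "r1"), ("b", "r1"))
        out = contrast_tests(res, {"a_vs_b": c})[0]
        assert out.estimate == pytest.approx(0.0, abs=1e-10)
        assert out.p_raw > 0.05

    def test_nonpositive_frequency_rejected(self):
        df = pd.DataFrame({"hz": [0.0, 1.0, 1.0], "treatment": "a", "recording": "r1"})
        with pytest.raises(ValueError, match="non-positive"):
            GammaFrequencyGLM(df)

    def test_zero_offset_mode_retains_silent_clusters(self):
        df = pd.DataFrame({"hz": [0.0, 1.0, 0.5, 0.2], "treatment": "a", "recording": "r1"})
        model = GammaFrequencyGLM(df, zero_offset_duration=1800.0)
        assert (model.data["hz"] > 0).all()

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"hz": [1.0] * 10, "treatment": "a", "recording": "r1"})
        with pytest.raises(ValueError, match="degenerate|constant"):
            GammaFrequencyGLM(df)


class TestAmplitudeLME:
    def test_zero_effect_recovered(self):
        res = AmplitudeMixedModel(amplitude_frame(shift=0.0, seed=3)).fit()
        row = res.treatment_changes.set_index("treatment").loc["treated"]
        assert abs(row["delta"]) <= 3 * row["se"]

    def test_toxin_scale_shift_recovered(self):
        res = AmplitudeMixedModel(amplitude_frame(shift=-0.074, seed=4)).fit()
        row = res.treatment_changes.set_index("treatment").loc["treated"]
        assert abs(row["delta"] - (-0.074)) <= 3 * row["se"]

    def test_noise_free_shift_exact(self):
        res = AmplitudeMixedModel(amplitude_frame(shift=-0.1, noise=0.0, seed=5)).fit()
        row = res.treatment_changes.set_index("treatment").loc["treated"]
        assert row["delta"] == pytest.approx(-0.1, abs=1e-6)

    def test_variance_components_nonnegative(self):
        res = AmplitudeMixedModel(amplitude_frame(seed=6)).fit()
        assert all(v >= 0 for v in res.variance_components.values())


class TestFrequencyLME:
    def _frame(self, shift, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for e in range(3):
            e_off = rng.normal(0, 0.2)
            for w in range(16):
                base = -0.8 + e_off + rng.normal(0, 0.4)
                trt = "ttx" if w < 8 else "control"
                for rec, s in [("r1", 0.0), ("r2", shift if trt == "ttx" else 0.0)]:
                    rows.append(
                        {
                            "log10_hz": base + s + rng.normal(0, 0.25),
                            "treatment": trt,
                            "recording": rec,
                            "experiment": f"e{e}",
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_effect(self):
        res = FrequencyMixedModel(self._frame(0.0, 7)).fit()
        row = res.treatment_changes.set_index("treatment").loc["ttx"]
        assert abs(row["delta"]) <= 3 * row["se"]

    def test_ttx_scale_shift_recovered(self):
        res = FrequencyMixedModel(self._frame(-1.14, 8)).fit()
        row = res.treatment_changes.set_index("treatment").loc["ttx"]
        assert abs(row["delta"] - (-1.14)) <= 3 * row["se"]

    def test_experiment_offsets_absorbed(self):
        rng = np.random.default_rng(9)
        rows = []
        for e in range(4):
            e_off = [-1.0, 0.0, 1.0, 2.0][e]  # large experiment intercepts
            for w in range(8):
                base = -0.8 + e_off + rng.normal(0, 0.1)
                trt = "t" if w < 4 else "control"
                for rec in ["r1", "r2"]:
                    rows.append(
                        {
                            "log10_hz": base + rng.normal(0, 0.1),
                            "treatment": trt,
                            "recording": rec,
                            "experiment": f"e{e}",
                        }
                    )
        res = FrequencyMixedModel(pd.DataFrame(rows)).fit()
        row = res.treatment_changes.set_index("treatment").loc["t"]
        assert abs(row["delta"]) <= 3 * row["se"]
        assert res.variance_components["experiment"] > 0

    def test_single_experiment_falls_back(self):
        df = self._frame(0.0, 10)
        df["experiment"] = "only"
        with pytest.warns(UserWarning, match="single experiment"):
            res = FrequencyMixedModel(df).fit()
        assert res.fixed_only


class TestPersistentFilter:
    def test_filters_amplitude_and_persistence(self):
        df = pd.DataFrame(
            [
                # persistent, bright: kept
                {"cluster": "a", "recording": "r1", "amplitude_uv": 50.0},
                {"cluster": "a", "recording": "r2", "amplitude_uv": 40.0},
                # persistent but dim pre-treatment: dropped
                {"cluster": "b", "recording": "r1", "amplitude_uv": 10.0},
                {"cluster": "b", "recording": "r2", "amplitude_uv": 45.0},
                # bright but lost: dropped
                {"cluster": "c", "recording": "r1", "amplitude_uv": 80.0},
            ]
        )
        out = persistent_amplitude_filter(df, min_amplitude_uv=30.0)
        assert set(out["cluster"]) == {"a"}


class TestContrasts:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "hz": rng.gamma(2.0, 0.3, 600),
                "treatment": rng.choice(["a", "b", "c"], 600),
                "recording": rng.choice(["r1", "r2"], 600),
            }
        )
        return GammaFrequencyGLM(df).fit()

    def test_single_contrast_unadjusted(self):
        res = self._fit()
        c = res.cell_contrast(("a", "r1"), ("b", "r1"))
        out = contrast_tests(res, {"ab": c}, method="single_step")[0]
        assert out.p_adjusted == pytest.approx(out.p_raw, abs=1e-4)

    def test_single_step_dominates_bonferroni(self):
        res = self._fit(1)
        cons = {
            "ab": res.cell_contrast(("a", "r1"), ("b", "r1")),
            "ac": res.cell_contrast(("a", "r1"), ("c", "r1")),
            "bc": res.cell_contrast(("b", "r2"), ("c", "r2")),
        }
        ss = contrast_tests(res, cons, method="single_step", seed=2)
        bf = contrast_tests(res, cons, method="bonferroni")
        for s, b in zip(ss, bf):
            assert s.p_adjusted <= b.p_adjusted + 1e-3

    def test_adjusted_at_least_raw(self):
        res = self._fit(2)
        cons = {
            "ab": res.cell_contrast(("a", "r1"), ("b", "r1")),
            "ac": res.cell_contrast(("a", "r2"), ("c", "r2")),
        }
        for out in contrast_tests(res, cons, method="single_step", seed=3):
            assert out.p_adjusted >= out.p_raw
            assert 0.0 <= out.p_adjusted <= 1.0

    def test_unknown_method_rejected(self):
        res = self._fit(3)
        with pytest.raises(ValueError):
            contrast_tests(res, {"x": res.cell_contrast(("a", "r1"), ("b", "r1"))}, method="fdr")
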