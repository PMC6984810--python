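import numpy as np
import pytest
from scipy import stats

from meawell.design import correlated_followup
from meawell.interchange import PlateLayout
from meawell.network import SpikeTrain, sttc
from meawell.preprocess import array_activities, filter_high_noise_spikes
from meawell.simulate import (
    CouplingSpec,
    SimConfig,
    apply_treatment,
    build_ground_truth,
    lsa_amplitude,
    point_source_amplitude,
    simulate_plate,
    simulate_trains,
)


class TestLSA:
    def test_linear_in_current(self):
        v1 = lsa_amplitude(1e-8, 0.3, 50e-6, 50e-6, 10e-6)
        v2 = lsa_amplitude(2e-8, 0.3, 50e-6, 50e-6, 10e-6)
        assert v2 == pytest.approx(2 * v1)

    def test_inverse_in_conductivity(self):
        v1 = lsa_amplitude(1e-8, 0.3, 50e-6, 50e-6, 10e-6)
        v2 = lsa_amplitude(1e-8, 0.15, 50e-6, 50e-6, 10e-6)
        assert v2 == pytest.approx(2 * v1)

    def test_point_source_limit(self):
        # short segment far away: LSA converges to Coulomb's law
        v_lsa = lsa_amplitude(1e-8, 0.3, 1e-6, 1e-3, 0.0)
        v_pt = point_source_amplitude(1e-8, 0.3, 1e-3)
        assert v_lsa == pytest.approx(v_pt, rel=0.05)

    def test_singular_geometry_rejected(self):
        with pytest.raises(ValueError):
            lsa_amplitude(1e-8, 0.3, 50e-6, 0.0, 0.0)

    def test_physiological_amplitude_range(self):
        # default geometry ranges put amplitudes in the tens of uV
        v = abs(lsa_amplitude(15e-9, 0.3, 50e-6, 50e-6, 20e-6)) * 1e6
        assert 5.0 < v < 500.0


class TestSimulateTrains:
    def test_zero_rate_neuron_silent(self):
        trains, _ = simulate_trains({"a": 0.0, "b": 1.0}, 100.0, seed=0)
        assert len(trains["a"]) == 0

    def test_rates_match_targets(self):
        rates = {f"n{k}": r for k, r in enumerate([0.5, 1.0, 2.0])}
        trains, _ = simulate_trains(rates, 2000.0, seed=1)
        for nid, r in rates.items():
            n = len(trains[nid])
            assert abs(n - r * 2000.0) <= 3 * np.sqrt(r * 2000.0)

    def test_uncoupled_trains_uncorrelated(self):
        vals = []
        for seed in range(20):
            trains, pairs = simulate_trains(
                {"a": 1.0, "b": 1.0}, 600.0, CouplingSpec(fraction=0.0), seed=seed
            )
            assert pairs == []
            vals.append(
                sttc(
                    SpikeTrain("a", "r", np.unique(trains["a"]), 600.0),
                    SpikeTrain("b", "r", np.unique(trains["b"]), 600.0),
                )
            )
        assert abs(np.mean(vals)) <= 3 * np.std(vals) / np.sqrt(len(vals))

    def test_full_sharing_gives_identical_trains(self):
        trains, pairs = simulate_trains(
            {"a": 1.0, "b": 1.0},
            600.0,
            CouplingSpec(fraction=1.0, parent_share=1.0, jitter_sd_ms=0.0),
            seed=2,
        )
        assert pairs == [("a", "b")] or pairs == [("b", "a")]
        s = sttc(
            SpikeTrain("a", "r", np.unique(trains["a"]), 600.0),
            SpikeTrain("b", "r", np.unique(trains["b"]), 600.0),
        )
        assert s == pytest.approx(1.0, abs=0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_trains({"a": -1.0}, 10.0)


class TestSimulatePlate:
    def test_default_layout_has_768_channels(self):
        assert SimConfig().layout.n_channels == 768

    def test_all_events_have_registered_truth(self, small_plate):
        table, truth = small_plate
        assert table.n_events > 0
        for e in table.events:
            assert e.truth_neuron in truth.neurons

    def test_deterministic_per_seed(self, small_layout):
        cfg = SimConfig(layout=small_layout, recording_durations=(120.0,),
                        recording_phases=("pre",), seed=21)
        t1, _ = simulate_plate(cfg)
        t2, _ = simulate_plate(cfg)
        assert t1.n_events == t2.n_events
        assert all(
            a.timestamp == b.timestamp and a.truth_neuron == b.truth_neuron
            for a, b in zip(t1.events, t2.events)
        )

    def test_log_mfr_approximately_normal(self):
        # right-skewed in Hz, symmetric in log10 Hz
        pvals, skews_hz, skews_log = [], [], []
        for seed in range(5):
            cfg = SimConfig(
                layout=PlateLayout(n_rows=4, n_cols=6),
                recording_durations=(900.0,),
                recording_phases=("pre",),
                seed=seed + 200,
            )
            table, _ = simulate_plate(cfg)
            acts = array_activities(table, "r1")
            log_mfr = np.array([a.log_mfr for a in acts])
            mfr = np.array([a.mfr for a in acts])
            pvals.append(stats.shapiro(log_mfr).pvalue)
            skews_hz.append(stats.skew(mfr))
            skews_log.append(stats.skew(log_mfr))
        assert np.median(pvals) > 0.01
        assert np.mean(skews_hz) > 0.5  # right-skewed on the Hz scale
        assert abs(np.mean(skews_log)) < 0.5

    def test_day_correlation_near_target(self):
        rhos = []
        for seed in range(10):
            cfg = SimConfig(
                layout=PlateLayout(n_rows=4, n_cols=6),
                recording_durations=(1800.0, 1800.0),
                recording_phases=("pre", "pre"),
                day_correlation=0.8,
                coupling=CouplingSpec(fraction=0.0),
                seed=seed + 400,
            )
            table, _ = simulate_plate(cfg)
            a1 = {a.well: a.log_mfr for a in array_activities(table, "r1")}
            a2 = {a.well: a.log_mfr for a in array_activities(table, "r2")}
            wells = sorted(a1)
            rhos.append(np.corrcoef([a1[w] for w in wells], [a2[w] for w in wells])[0, 1])
        assert np.mean(rhos) == pytest.approx(0.8, abs=0.1)

    def test_high_noise_electrodes_get_filtered(self, small_layout):
        cfg = SimConfig(
            layout=small_layout,
            recording_durations=(300.0,),
            recording_phases=("pre",),
            high_noise_electrode_frac=0.1,
            seed=31,
        )
        table, _ = simulate_plate(cfg)
        filtered, excluded = filter_high_noise_spikes(table)
        assert excluded > 0
        kept_thr = {e.crossing_threshold for e in filtered.events}
        assert max(kept_thr) < 5.5 * cfg.noise_sd * cfg.high_noise_multiplier

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(recording_durations=(600.0,), recording_phases=("pre", "post"))


class TestApplyTreatment:
    def _config(self, rate_mult, amp_mult, small_layout=None):
        layout = small_layout or PlateLayout(n_rows=2, n_cols=4)
        groups = {w: ("treated" if i < 4 else "control") for i, w in enumerate(layout.well_labels)}
        return SimConfig(
            layout=layout,
            recording_durations=(300.0, 300.0),
            recording_phases=("pre", "post"),
            groups=groups,
            treatment_effects={"treated": {"post": (rate_mult, amp_mult)}},
            seed=41,
        )

    def test_rate_multiplier_zero_silences_group(self):
        cfg = self._config(0.0, 1.0)
        table, truth = simulate_plate(cfg)
        treated_wells = {w for w, g in cfg.groups.items() if g == "treated"}
        post = [e for e in table.events if e.recording_id == "r2" and e.well in treated_wells]
        assert post == []
        pre = [e for e in table.events if e.recording_id == "r1" and e.well in treated_wells]
        assert len(pre) > 0

    def test_amplitude_multiplier_exact_in_scale_table(self):
        cfg = self._config(1.0, 10 ** -0.074)
        _, truth = simulate_plate(cfg)
        treated = [n for n in truth.neurons.values() if cfg.groups[n.well] == "treated"]
        for n in treated[:5]:
            scale = truth.amp_scale.loc[n.neuron_id, "r2"]
            assert np.log10(scale) == pytest.approx(-0.074, abs=1e-12)

    def test_identity_multiplier_changes_nothing(self, small_layout):
        cfg = self._config(1.0, 1.0)
        base = SimConfig(
            layout=cfg.layout,
            recording_durations=cfg.recording_durations,
            recording_phases=cfg.recording_phases,
            groups=cfg.groups,
            seed=41,
        )
        t1, _ = simulate_plate(cfg)
        t2, _ = simulate_plate(base)
        assert t1.n_events == t2.n_events

    def test_negative_multiplier_rejected(self):
        truth, recs = build_ground_truth(SimConfig(layout=PlateLayout(n_rows=1, n_cols=2),
                                                   recording_durations=(60.0,),
                                                   recording_phases=("post",),
                                                   groups={"A1": "g1"}))
        with pytest.raises(ValueError):
            apply_treatment(truth, {"g1": {"post": (-1.0, 1.0)}},
                            {r.recording_id: r.phase for r in recs})
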