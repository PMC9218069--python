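import math

import numpy as np
import pytest
from scipy import stats

from chronicsense.core_model import StimSetting, build_lead
from chronicsense.synthetic_cohort import (
    GeneratorParams,
    generate_cohort_timeline,
    generate_lfp,
    generate_stim_session,
)
from chronicsense import evoked, network, spectral


class TestParams:
    @pytest.mark.parametrize("kw", [
        {"theta_f0": 3.5}, {"theta_f0": 5.5},
        {"net_lag_ms": 20.0}, {"net_lag_ms": 50.0},
        {"theta_supp_v": 1.2, "theta_ad_v": 1.0},
        {"segment_gains": {"E1a": 0.0}},
        {"farfield_ratio": 1.5},
    ])
    def test_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorParams(seed=0, **kw)

    def test_round_trip(self):
        p = GeneratorParams(seed=3, theta_f0=4.2)
        assert GeneratorParams.from_dict(p.to_dict()) == p


class TestGenerateLfp:
    def test_determinism(self):
        p = GeneratorParams(seed=11)
        a = generate_lfp(p, 10.0)
        b = generate_lfp(GeneratorParams(seed=11), 10.0)
        assert np.array_equal(a.samples, b.samples)

    def test_seed_changes_samples(self):
        a = generate_lfp(GeneratorParams(seed=1), 10.0)
        b = generate_lfp(GeneratorParams(seed=2), 10.0)
        assert not np.array_equal(a.samples, b.samples)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_lfp(GeneratorParams(seed=0), -1.0)
        with pytest.raises(ValueError):
            generate_lfp(GeneratorParams(seed=0), 10.0, fs=0.0)

    def test_infinite_theta_dwell_peak_at_f0(self, theta_params):
        rec = generate_lfp(theta_params, 30.0)
        est = spectral.power_spectral_density(rec, "HC_E0-E3")
        peak = spectral.peak_frequency(est, (2.0, 12.0))
        assert abs(peak - theta_params.theta_f0) <= est.df

    def test_sharp_wave_count_poisson_interval(self):
        # 60 s of pure sharp-wave state at 0.5/s: event count must fall in
        # the central 99% Poisson interval around 30
        lo, hi = stats.poisson.interval(0.99, 30.0)
        p = GeneratorParams(seed=0, state_dwell={"sharp_wave": math.inf})
        rec = generate_lfp(p, 60.0)
        events = network.detect_spike_events(rec, "HC_E0-E3")
        assert lo <= len(events) <= hi

    def test_theta_peak_in_band_across_seeds(self):
        hits = 0
        for seed in range(20):
            p = GeneratorParams(seed=seed, state_dwell={"theta": math.inf},
                                theta_f0=4.1 + 0.8 * (seed % 10) / 9)
            est = spectral.power_spectral_density(
                generate_lfp(p, 30.0), "HC_E0-E3")
            if 4.0 <= spectral.peak_frequency(est, (2.0, 12.0)) <= 5.0:
                hits += 1
        assert hits == 20

    def test_directional_gain_monotonicity(self, directional_lead):
        gains = {"E1a": 1.0, "E1b": 0.3, "E1c": 0.3,
                 "E2a": 1.0, "E2b": 0.3, "E2c": 0.3}
        hits = 0
        for seed in range(10):
            p = GeneratorParams(seed=100 + seed, segment_gains=gains,
                                state_dwell={"theta": math.inf})
            rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
            est_hi = spectral.power_spectral_density(rec, "HC_E1a-E2a")
            est_lo = spectral.power_spectral_density(rec, "HC_E1b-E2b")
            if spectral.band_power(est_hi, (3, 8)) > spectral.band_power(est_lo, (3, 8)):
                hits += 1
        assert hits >= 10 * 0.95


class TestEpTrain:
    def test_event_count_5hz_30s(self, ep_session):
        _, events = ep_session
        assert len(events) == 150

    def test_determinism(self, ep_setting):
        p = GeneratorParams(seed=9)
        a, _ = generate_stim_session(p, ep_setting, "ep_train")
        b, _ = generate_stim_session(GeneratorParams(seed=9), ep_setting, "ep_train")
        assert np.array_equal(a.samples, b.samples)

    def test_zero_amplitude_is_sham(self, theta_params):
        setting = StimSetting("E1", "E2", 0.0, "V", 5.0, 120.0, 30.0)
        rec, events = generate_stim_session(theta_params, setting, "ep_train")
        assert events == []
        base = generate_lfp(theta_params, rec.duration_s)
        assert np.array_equal(rec.samples, base.samples)

    def test_unknown_protocol(self, theta_params, ep_setting):
        with pytest.raises(ValueError, match="protocol"):
            generate_stim_session(theta_params, ep_setting, "tetanus")

    def test_ep_amplitude_monotone_in_stim_amplitude(self):
        # averaged EP amplitude is sigmoidal, hence non-decreasing, over 1-7 V
        amps = []
        for v in (1.0, 3.0, 5.0, 7.0):
            p = GeneratorParams(seed=33, state_dwell={"theta": math.inf})
            setting = StimSetting("E1", "E2", v, "V", 5.0, 120.0, 30.0)
            rec, _ = generate_stim_session(p, setting, "ep_train")
            triggers = evoked.detect_stim_artifacts(rec, "HC_E0-E3")
            ep = evoked.average_epochs(rec, "HC_E0-E3", triggers)
            amps.append(ep.amplitude_uv)
        assert all(b >= a - 1.0 for a, b in zip(amps, amps[1:]))
        assert amps[-1] > 3 * amps[0]


class TestBurstRamp:
    def test_fig3_style_response_sequence(self):
        p = GeneratorParams(seed=13)
        setting = StimSetting("E1", "case", 1.0, "V", 50.0, 300.0, 10.0)
        rec, events = generate_stim_session(
            p, setting, "burst_ramp", amplitudes=[0.4, 0.6, 0.8, 1.0])
        assert [e.setting.amplitude for e in events] == [0.4, 0.6, 0.8, 1.0]
        responses, th_inh, th_ad = evoked.classify_burst_responses(rec, events)
        assert [r.label for r in responses] == [
            "none", "suppression", "suppression", "after_discharge"]
        assert th_inh == 0.6
        assert th_ad == 1.0


class TestDirectionalSweep:
    def test_randomized_order_and_coverage(self, directional_lead):
        p = GeneratorParams(seed=17)
        setting = StimSetting("E1a", "case", 1.0, "mA", 100.0, 300.0, 10.0)
        rec, events = generate_stim_session(
            p, setting, "directional_sweep", post_s=30.0,
            leads={"HC": directional_lead})
        stimmed = [e.setting.cathode_contact for e in events]
        assert sorted(stimmed) == sorted(directional_lead.segmented_contacts)
        # a different seed permutes the order but not the set
        rec2, events2 = generate_stim_session(
            GeneratorParams(seed=18), setting, "directional_sweep",
            post_s=30.0, leads={"HC": directional_lead})
        assert sorted(e.setting.cathode_contact for e in events2) == sorted(stimmed)

    def test_requires_directional_lead(self, ring_lead):
        setting = StimSetting("E1", "case", 1.0, "mA", 100.0, 300.0, 10.0)
        with pytest.raises(ValueError, match="directional"):
            generate_stim_session(GeneratorParams(seed=0), setting,
                                  "directional_sweep", leads={"HC": ring_lead})


class TestCohortTimeline:
    def test_breakage_invalidates_channels(self):
        p = GeneratorParams(seed=3, breakage_schedule=[("E1", 4)])
        sessions = generate_cohort_timeline(p, 6, session_s=4.0)
        before = sessions[2]
        after = sessions[3]
        assert before.invalid_channels == []
        assert sorted(after.invalid_channels) == [
            "HC_E0-E1", "HC_E1-E2", "HC_E1-E3"]
        assert after.impedance_ohm["HC:E1"] > 50_000
        # broken channels are flat amplifier noise
        i = after.recording.channel_index("HC_E1-E3")
        assert np.std(after.recording.samples[i]) < 10.0

    def test_no_breakage_all_valid(self):
        sessions = generate_cohort_timeline(GeneratorParams(seed=4), 3, session_s=4.0)
        assert all(s.invalid_channels == [] for s in sessions)

    def test_unknown_breakage_contact_rejected(self):
        p = GeneratorParams(seed=0, breakage_schedule=[("E9", 2)])
        with pytest.raises(ValueError, match="breakage"):
            generate_cohort_timeline(p, 3, session_s=4.0)

    def test_schedule_deterministic_across_seeds(self):
        a = generate_cohort_timeline(GeneratorParams(seed=1), 4, session_s=4.0)
        b = generate_cohort_timeline(GeneratorParams(seed=2), 4, session_s=4.0)
        assert [(s.month, s.condition) for s in a] == [(s.month, s.condition) for s in b]
        assert not np.array_equal(a[0].recording.samples, b[0].recording.samples)

    def test_months_validation(self):
        with pytest.raises(ValueError):
            generate_cohort_timeline(GeneratorParams(seed=0), 0)
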