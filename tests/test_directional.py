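import math

import numpy as np
import pytest
from scipy import stats

from chronicsense import directional
from chronicsense.core_model import StimEvent, StimSetting, build_lead
from chronicsense.directional import (
    SegmentRanking,
    enumerate_montage,
    montage_groups,
    radial_spectra,
    rank_concordance,
    rank_segments,
    suppression_response,
)
from chronicsense.spectral import band_power
from chronicsense.synthetic_cohort import GeneratorParams, generate_lfp, generate_stim_session

EXPECTED_15 = {
    "E0-E1a", "E0-E1b", "E0-E1c",
    "E1a-E1b", "E1a-E1c", "E1b-E1c",
    "E2a-E2b", "E2a-E2c", "E2b-E2c",
    "E1a-E2a", "E1b-E2b", "E1c-E2c",
    "E2a-E3", "E2b-E3", "E2c-E3",
}

# attributed order matches gain order for this set (rings pull toward 1.0)
TEST_GAINS = {"E2b": 1.0, "E2c": 0.85, "E2a": 0.71,
              "E1b": 0.54, "E1a": 0.41, "E1c": 0.29}


class TestMontage:
    def test_directional_15_distinct_pairs(self, directional_lead):
        pairs = enumerate_montage(directional_lead)
        assert len(pairs) == 15
        assert {p.label for p in pairs} == EXPECTED_15

    def test_ring_lead_6_pairs(self, ring_lead):
        pairs = enumerate_montage(ring_lead)
        assert len(pairs) == 6
        assert len({p.label for p in pairs}) == 6

    def test_three_groups_of_five_total_2min(self, directional_lead):
        groups, total_s = montage_groups(directional_lead)
        assert [len(g) for g in groups] == [5, 5, 5]
        assert total_s == 120.0

    def test_unsupported_geometry(self):
        from chronicsense.core_model import LeadGeometry
        odd = LeadGeometry("custom", ("E0", "E1"), {"E0": 0, "E1": 1},
                           {"E0": "ring", "E1": "ring"})
        with pytest.raises(ValueError):
            enumerate_montage(odd)


class TestRadialSpectra:
    def test_gain_ordering(self, directional_lead):
        gains = dict(TEST_GAINS, **{"E1a": 1.0, "E2a": 1.0, "E1b": 0.5,
                                    "E2b": 0.5, "E1c": 0.2, "E2c": 0.2})
        p = GeneratorParams(seed=1, segment_gains=gains,
                            state_dwell={"theta": math.inf})
        rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
        spectra = radial_spectra(rec, "HC", directional_lead)
        pw = {d: band_power(est, (3, 8)) for d, est in spectra.items()}
        assert pw["a"] > pw["b"] > pw["c"]

    def test_isotropic_gains_indistinguishable(self, directional_lead):
        per_dir = {d: [] for d in "abc"}
        for seed in range(6):
            p = GeneratorParams(seed=300 + seed, state_dwell={"theta": math.inf})
            rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
            for d, est in radial_spectra(rec, "HC", directional_lead).items():
                per_dir[d].append(band_power(est, (3, 8)))
        means = {d: np.mean(v) for d, v in per_dir.items()}
        sds = {d: np.std(v, ddof=1) for d, v in per_dir.items()}
        pooled = max(np.mean(list(sds.values())), 1e-9)
        vals = list(means.values())
        assert max(vals) - min(vals) <= 2.0 * pooled

    def test_broken_pair_omitted(self, directional_lead):
        p = GeneratorParams(seed=2, state_dwell={"theta": math.inf})
        rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
        i = rec.channel_index("HC_E1b-E2b")
        rec.channels[i].valid = False
        spectra = radial_spectra(rec, "HC", directional_lead)
        assert set(spectra) == {"a", "c"}


class TestRankSegments:
    def test_top_gain_contact_rank1(self, directional_lead):
        hits = 0
        for seed in range(12):
            p = GeneratorParams(seed=500 + seed, segment_gains=TEST_GAINS,
                                state_dwell={"theta": math.inf})
            rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
            rk = rank_segments([rec], "HC", directional_lead)[0]
            hits += rk.top_contact == "E2b"
        assert hits >= 12 * 0.95

    def test_noise_free_ranks_match_attributed_order(self, directional_lead):
        p = GeneratorParams(seed=4, segment_gains=TEST_GAINS, noise_sd=1e-6,
                            state_dwell={"theta": math.inf})
        rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
        rk = rank_segments([rec], "HC", directional_lead)[0]
        expected = sorted(TEST_GAINS, key=TEST_GAINS.get, reverse=True)
        assert [c for c, _ in sorted(rk.ranks.items(), key=lambda kv: kv[1])] == expected

    def test_equal_gains_top_contact_uniform(self, directional_lead):
        # with isotropic gains the top-ranked contact is uniform over the six
        # segments; chi-square goodness of fit must not reject
        counts = {c: 0 for c in directional_lead.segmented_contacts}
        n = 120
        for seed in range(n):
            p = GeneratorParams(seed=2000 + seed, state_dwell={"theta": math.inf})
            rec = generate_lfp(p, 12.0, leads={"HC": directional_lead})
            rk = rank_segments([rec], "HC", directional_lead)[0]
            counts[rk.top_contact] += 1
        chi2, pval = stats.chisquare(list(counts.values()))
        assert pval > 0.01

    def test_ranks_are_permutation(self, directional_lead):
        p = GeneratorParams(seed=5, state_dwell={"theta": math.inf})
        rec = generate_lfp(p, 30.0, leads={"HC": directional_lead})
        rk = rank_segments([rec], "HC", directional_lead)[0]
        assert sorted(rk.ranks.values()) == [1, 2, 3, 4, 5, 6]


@pytest.fixture(scope="module")
def sweep_session():
    lead = build_lead("1-3-3-1")
    p = GeneratorParams(seed=8, segment_gains=TEST_GAINS)
    setting = StimSetting("E1a", "case", 1.0, "mA", 100.0, 300.0, 10.0)
    rec, events = generate_stim_session(p, setting, "directional_sweep",
                                        post_s=60.0, leads={"HC": lead})
    return rec, events


class TestSuppressionResponse:
    def test_depth_tracks_gain(self, sweep_session):
        rec, events = sweep_session
        profiles = [suppression_response(rec, ev, channel="HC_E0-E1a")
                    for ev in events]
        depth = {p.stimulated_contact: p.depth for p in profiles}
        assert min(depth, key=depth.get) == "E2b"
        # deepest suppression near the generator floor 1 - 0.75*1.0 = 0.25
        assert depth["E2b"] == pytest.approx(0.25, abs=0.12)

    def test_long_follow_up_recovery(self):
        # suppression floor 0.25 holds ~3 min then recovers by minute 5
        lead = build_lead("1-3-3-1")
        gains = {c: 1.0 for c in lead.segmented_contacts}
        p = GeneratorParams(seed=9, segment_gains=gains)
        setting = StimSetting("E1a", "case", 1.0, "mA", 100.0, 300.0, 10.0)
        rec, events = generate_stim_session(p, setting, "directional_sweep",
                                            post_s=330.0, leads={"HC": lead})
        prof = suppression_response(rec, events[0], channel="HC_E0-E1a")
        assert prof.normalized[0] == pytest.approx(0.25, abs=0.10)
        assert prof.normalized[4] == pytest.approx(1.0, abs=0.15)

    def test_sham_event_flat(self):
        p = GeneratorParams(seed=10, state_dwell={"theta": math.inf})
        rec = generate_lfp(p, 120.0)
        setting = StimSetting("E1", "case", 0.0, "V", 100.0, 300.0, 10.0)
        ev = StimEvent(setting, 30.0, 30.04)
        prof = suppression_response(rec, ev, channel="HC_E0-E3")
        assert prof.normalized[0] == pytest.approx(1.0, abs=0.35)

    def test_short_baseline_rejected(self):
        p = GeneratorParams(seed=10, state_dwell={"theta": math.inf})
        rec = generate_lfp(p, 120.0)
        setting = StimSetting("E1", "case", 1.0, "V", 100.0, 300.0, 10.0)
        ev = StimEvent(setting, 10.0, 10.04)  # only 10 s of pre data
        with pytest.raises(ValueError, match="baseline"):
            suppression_response(rec, ev, channel="HC_E0-E3")

    def test_contaminated_baseline_rejected(self, sweep_session):
        rec, events = sweep_session
        setting = events[0].setting
        bad = StimEvent(setting, events[1].onset_s - 5.0, events[1].onset_s - 4.0)
        rec.events.append(bad)
        try:
            with pytest.raises(ValueError, match="contaminated"):
                suppression_response(rec, events[1], channel="HC_E0-E1a")
        finally:
            rec.events.remove(bad)


class TestRankConcordance:
    def test_identical_rankings(self):
        r = {"a": 1, "b": 2, "c": 3}
        r2, signed = rank_concordance(r, dict(r))
        assert r2 == pytest.approx(1.0)
        assert signed == pytest.approx(1.0)

    def test_hand_oracle_single_swap(self):
        # oracle: Pearson of (1,2,3) vs (1,3,2) = 0.5 -> R^2 = 0.25
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 3.0, 2.0])
        oracle_r = float(np.corrcoef(a, b)[0, 1])
        assert oracle_r == pytest.approx(0.5)
        r2, signed = rank_concordance(
            {"x": 1, "y": 2, "z": 3}, {"x": 1, "y": 3, "z": 2})
        assert r2 == pytest.approx(oracle_r**2) == pytest.approx(0.25)

    def test_reversed_is_direction_blind(self):
        r2, signed = rank_concordance(
            {"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1})
        assert r2 == pytest.approx(1.0)
        assert signed == pytest.approx(-1.0)

    def test_relabeling_invariance(self):
        a = {"a": 1, "b": 3, "c": 2, "d": 4}
        b = {"a": 2, "b": 4, "c": 1, "d": 3}
        ren = {"a": "w", "b": "x", "c": "y", "d": "z"}
        a2 = {ren[k]: v for k, v in a.items()}
        b2 = {ren[k]: v for k, v in b.items()}
        assert rank_concordance(a, b) == rank_concordance(a2, b2)

    def test_mismatched_contacts_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "d": 3})

    def test_too_few_contacts_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance({"a": 1, "b": 2}, {"a": 2, "b": 1})
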