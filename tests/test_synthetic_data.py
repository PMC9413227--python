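"""Generator fidelity: protocol arithmetic, rates, determinism, ground truth."""

import numpy as np
import pytest

from mea_evoked.burst_analysis import detect_bursts, mean_firing_rate
from mea_evoked.core_model import ValidationError
from mea_evoked.psth_analysis import area_map, compute_psth, filter_responsive
from mea_evoked.synthetic_data import (
    PopulationProfile,
    cortical_like_profile,
    generate_profile_dataset,
    generate_recording,
    hippocampal_like_profile,
    make_benchmark_suite,
)


def _silent_profile(**over):
    base = dict(
        label="silent",
        background_rate=0.0,
        burst_rate=0.0,
        burst_len=5,
        burst_isi=10.0,
        early_prob=0.0,
        early_latency0=10.0,
        latency_slope=0.0,
        early_jitter=0.0,
        late_prob=0.0,
        late_latency=0.0,
        late_spread=0.0,
        spatial_decay=10.0,
        baseline_fraction=1.0,
    )
    base.update(over)
    return PopulationProfile(**base)


class TestProtocol:
    def test_five_minute_session_at_02hz_yields_60_stimuli(self):
        rec, _ = generate_recording(_silent_profile(), seed=0)
        assert len(rec.sessions) == 3
        for s in rec.sessions:
            assert s.n_stimuli == 60
            assert np.allclose(np.diff(s.stimulus_times), 5.0)

    def test_silent_profile_produces_empty_trains(self):
        rec, _ = generate_recording(_silent_profile(), seed=0)
        assert all(len(t) == 0 for t in rec.trains.values())

    def test_sessions_stimulate_one_electrode_per_compartment(self):
        rec, truth = generate_recording(cortical_like_profile(), seed=0)
        comps = {
            rec.compartments.label(s.stimulated_electrode) for s in rec.sessions
        }
        assert comps == {"big", "small_left", "small_right"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            generate_recording(_silent_profile(), stim_freq=-1.0)


class TestStatisticalFidelity:
    def test_background_poisson_count_within_3_sigma(self):
        profile = _silent_profile(background_rate=5.0)
        rec, _ = generate_recording(
            profile, n_sessions=0, spont_len=600.0, seed=123
        )
        counts = np.array([len(t) for t in rec.trains.values()])
        expected = 5.0 * 600.0
        # per-electrode counts stay within 3 sigma of the Poisson mean
        within = np.abs(counts - expected) <= 3 * np.sqrt(expected)
        assert within.mean() > 0.95
        # and the grand mean much tighter
        assert abs(counts.mean() - expected) <= 3 * np.sqrt(expected / 120)

    def test_mfr_and_mbr_match_configured_rates(self):
        profile = _silent_profile(background_rate=2.0, burst_rate=12.0, burst_len=5)
        rec, _ = generate_recording(profile, n_sessions=0, spont_len=300.0, seed=7)
        train = rec.trains["r05c05"]
        mfr = mean_firing_rate(train)
        # expected: background + comb spikes (12/min * 5 spikes)
        expected_mfr = 2.0 + 12.0 / 60.0 * 5
        assert mfr == pytest.approx(expected_mfr, rel=0.25)
        bursts = detect_bursts(train)
        mbr = 60 * len(bursts) / 300.0
        assert mbr == pytest.approx(12.0, rel=0.35)

    def test_zero_noise_psth_peak_at_configured_latency(self):
        """Deterministic latency, certain response: PSTH mass in one bin."""
        profile = _silent_profile(
            early_prob=5.0, early_jitter=0.0, latency_slope=0.0, early_latency0=10.0
        )
        rec, _ = generate_recording(profile, n_sessions=1, spont_len=0.0, seed=1)
        sess = rec.sessions[0]
        p = compute_psth(rec.trains[sess.stimulated_electrode], sess)
        # all mass in bin [8,12); Poisson(5) truncated by 1 ms refractory -> 1 spike
        assert p.values[2] == pytest.approx(1.0)
        assert p.area == pytest.approx(1.0)

    def test_refractory_invariant_of_generated_trains(self):
        rec, _ = generate_recording(cortical_like_profile(), seed=5)
        for t in rec.trains.values():
            if len(t) > 1:
                assert np.diff(t.times).min() >= 1e-3 - 1e-12


class TestDeterminismAndTruth:
    def test_same_seed_identical_recordings(self):
        r1, t1 = generate_recording(cortical_like_profile(), seed=42)
        r2, t2 = generate_recording(cortical_like_profile(), seed=42)
        assert r1 == r2
        assert t1.stimulated_electrodes == t2.stimulated_electrodes

    def test_different_seed_differs(self):
        r1, _ = generate_recording(cortical_like_profile(), seed=1)
        r2, _ = generate_recording(cortical_like_profile(), seed=2)
        assert r1 != r2

    def test_inactive_electrodes_fall_below_both_filters(self):
        dead = ("r05c05", "r00c05", "r11c06")
        rec, truth = generate_recording(
            cortical_like_profile(), seed=3, inactive_electrodes=dead
        )
        for eid in dead:
            spont = rec.trains[eid].slice(0.0, 600.0)
            assert mean_firing_rate(spont) < 0.1
            for sess in rec.sessions:
                assert compute_psth(rec.trains[eid], sess).area < 1.0

    def test_ground_truth_latencies_increase_with_distance(self):
        rec, truth = generate_recording(cortical_like_profile(), seed=4)
        sess = rec.sessions[0]
        stim_pos = rec.layout.position_of(sess.stimulated_electrode)
        lats, dists = [], []
        for eid in rec.layout.electrode_ids:
            d = np.linalg.norm(rec.layout.position_of(eid) - stim_pos) / 200.0
            dists.append(d)
            lats.append(truth.early_latency[0][eid])
        slope = np.polyfit(dists, lats, 1)[0]
        assert slope == pytest.approx(cortical_like_profile().latency_slope, rel=1e-6)


class TestSpatialContrast:
    def test_cx_area_map_more_uniform_than_hp(self):
        cx, _ = generate_recording(cortical_like_profile(), seed=10)
        hp, _ = generate_recording(hippocampal_like_profile(), seed=10)
        cvs = {}
        for name, rec in (("cx", cx), ("hp", hp)):
            sess = rec.sessions[0]
            psths = [compute_psth(t, sess) for t in rec.trains.values()]
            areas = np.array([p.area for p in psths])
            cvs[name] = areas.std() / areas.mean()
        assert cvs["cx"] < cvs["hp"]

    def test_hp_responsive_electrodes_cluster_near_stimulation(self):
        hp, _ = generate_recording(hippocampal_like_profile(), seed=11)
        sess = hp.sessions[0]
        stim_pos = hp.layout.position_of(sess.stimulated_electrode)
        psths = [compute_psth(t, sess) for t in hp.trains.values()]
        kept, removed = filter_responsive(psths)
        # top-area electrodes are nearer the stimulation site than average
        top = sorted(kept, key=lambda p: -p.area)[:10]
        d_top = np.mean(
            [
                np.linalg.norm(hp.layout.position_of(p.electrode_id) - stim_pos)
                for p in top
            ]
        )
        d_all = np.mean(
            [
                np.linalg.norm(hp.layout.position_of(p.electrode_id) - stim_pos)
                for p in psths
            ]
        )
        assert d_top < 0.5 * d_all


class TestProfileDataset:
    def test_two_classes_with_known_labels(self):
        psths, labels = generate_profile_dataset(seed=0)
        assert len(psths) == 40
        assert labels.sum() == 20
        late_mass = [p.values[40:110].sum() for p in psths]
        assert np.mean([m for m, l in zip(late_mass, labels) if l]) > 5 * np.mean(
            [m for m, l in zip(late_mass, labels) if not l]
        )

    def test_deterministic(self):
        p1, l1 = generate_profile_dataset(seed=9)
        p2, l2 = generate_profile_dataset(seed=9)
        assert np.array_equal(l1, l2)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.values, b.values)


def test_benchmark_suite_structure():
    datasets, manifest = make_benchmark_suite(
        seed=0, n_per_population=1, session_len=50.0, spont_len=60.0
    )
    assert len(datasets) == 2
    labels = [rec.population_label for rec, _ in datasets]
    assert labels == ["Cx", "Hp"]
    assert len(manifest["recordings"]) == 2
    assert manifest["recordings"][0]["profile"]["label"] == "Cx-like"
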