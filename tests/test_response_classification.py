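"""k-means PSTH classification, peak analysis, and latency assignment."""

import numpy as np
import pytest

from mea_evoked.psth_analysis import Psth
from mea_evoked.response_classification import (
    LATE_SENTINEL_MS,
    ClassificationConfig,
    ResponseClass,
    assign_latencies,
    class_mean_and_smooth,
    classify_psths,
    classify_session,
    find_early_late_peaks,
    moving_average,
    separation_statistic,
)
from mea_evoked.synthetic_data import generate_profile_dataset

EDGES = np.arange(151) * 4.0
CENTERS = 0.5 * (EDGES[:-1] + EDGES[1:])


def _psth(values, eid="e0"):
    return Psth(eid, EDGES, np.asarray(values, dtype=float), n_stimuli=60)


def _bump(mu, sigma, amp):
    return amp * np.exp(-0.5 * ((CENTERS - mu) / sigma) ** 2)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        x = np.full(150, 0.7)
        assert np.allclose(moving_average(x, 13), x)

    def test_unit_impulse_spreads_one_thirteenth(self):
        x = np.zeros(150)
        x[75] = 1.0
        sm = moving_average(x, 13)
        assert np.allclose(sm[75 - 6 : 75 + 7], 1 / 13)
        assert sm[75 - 7] == 0.0 and sm[75 + 7] == 0.0

    def test_edges_use_shrunken_window(self):
        x = np.ones(150)
        sm = moving_average(x, 13)
        assert np.allclose(sm, 1.0)  # mean of a constant is exact at edges too

    def test_mean_of_identical_members_is_member(self):
        v = _bump(20, 8, 1.0)
        mean, _ = class_mean_and_smooth([_psth(v, "a"), _psth(v, "b")])
        assert np.allclose(mean, v)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), 12)


class TestPeakFinding:
    def test_two_bumps_located(self):
        profile = _bump(15, 6, 1.0) + _bump(200, 30, 0.5)
        x1, x2 = find_early_late_peaks(profile, CENTERS)
        assert abs(x1 - 15) <= 4
        assert abs(x2 - 200) <= 4

    def test_unimodal_no_late_peak(self):
        profile = _bump(10, 8, 1.0)
        x1, x2 = find_early_late_peaks(profile, CENTERS)
        assert abs(x1 - 10) <= 4
        assert x2 is None

    def test_prominence_gate_blocks_small_late_peak(self):
        profile = _bump(15, 6, 1.0) + _bump(200, 30, 0.05)
        x1, x2 = find_early_late_peaks(profile, CENTERS)
        assert x1 is not None and x2 is None

    def test_no_early_peak_reports_none(self):
        profile = _bump(300, 30, 1.0)
        x1, x2 = find_early_late_peaks(profile, CENTERS)
        assert x1 is None

    def test_brute_force_local_max_oracle(self):
        rng = np.random.default_rng(5)
        profile = moving_average(rng.uniform(0, 1, 150), 13)
        x1, _ = find_early_late_peaks(profile, CENTERS)
        # oracle: exhaustive scan for local maxima (zero-padded ends)
        padded = np.concatenate([[0], profile, [0]])
        maxima = [
            i - 1
            for i in range(1, 151)
            if padded[i] > padded[i - 1] and padded[i] >= padded[i + 1]
        ]
        early = [i for i in maxima if CENTERS[i] <= 52]
        expected = None if not early else CENTERS[max(early, key=lambda i: profile[i])]
        assert x1 == expected


class TestSeparation:
    def test_zero_valley_gives_s_one(self):
        profile = _bump(16, 4, 1.0) + _bump(200, 20, 0.8)
        s, x_min = separation_statistic(profile, CENTERS, 16.0, 200.0)
        assert s == pytest.approx(1.0, abs=1e-3)
        assert 16 < x_min < 200

    def test_flat_profile_gives_s_zero(self):
        profile = np.ones(150)
        s, _ = separation_statistic(profile, CENTERS, 16.0, 200.0)
        assert s == pytest.approx(0.0)

    def test_direct_formula_evaluation(self):
        """p1=1, p2=0.5, valley 0.35 -> s = 1 - 0.35/sqrt(0.5)."""
        profile = np.interp(
            CENTERS, [0, 14, 94, 106, 202, 600], [0, 1.0, 0.35, 0.35, 0.5, 0]
        )
        s, x_min = separation_statistic(profile, CENTERS, 14.0, 202.0)
        assert s == pytest.approx(1 - 0.35 / np.sqrt(0.5), abs=1e-9)
        assert abs(x_min - 100) <= 6

    def test_literal_ratio_form(self):
        profile = np.interp(
            CENTERS, [0, 14, 94, 106, 202, 600], [0, 1.0, 0.35, 0.35, 0.5, 0]
        )
        s, _ = separation_statistic(profile, CENTERS, 14.0, 202.0, form="literal_ratio")
        assert s == pytest.approx(0.35 / (1.0 * 0.5), abs=1e-9)

    def test_dip_depth_scale_invariant(self):
        profile = _bump(15, 6, 1.0) + _bump(200, 30, 0.5)
        s1, m1 = separation_statistic(profile, CENTERS, 16.0, 200.0)
        s2, m2 = separation_statistic(5 * profile, CENTERS, 16.0, 200.0)
        assert s1 == pytest.approx(s2)
        assert m1 == m2


class TestClustering:
    def test_two_well_separated_classes_recovered(self):
        psths, truth = generate_profile_dataset(seed=3)
        labels, k = classify_psths(psths, ClassificationConfig(seed=3))
        assert k == 2
        # label agreement up to permutation
        agree = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert agree == 1.0

    def test_identical_profiles_degenerate_to_one_class(self):
        v = _bump(20, 8, 1.0)
        psths = [_psth(v, f"e{i}") for i in range(10)]
        labels, k = classify_psths(psths)
        assert k == 1
        assert np.all(labels == 0)

    def test_three_clusters_selected_by_silhouette(self):
        rng = np.random.default_rng(9)
        psths = []
        for mu, n in ((12, 15), (200, 15), (420, 15)):
            for i in range(n):
                v = _bump(mu, 10, 2.0) + 0.01 * rng.random(150)
                psths.append(_psth(v, f"e{mu}_{i}"))
        labels, k = classify_psths(
            psths, ClassificationConfig(k_range=(2, 3, 4, 5, 6), seed=1)
        )
        assert k == 3

    def test_empty_input_rejected(self):
        from mea_evoked.core_model import ValidationError

        with pytest.raises(ValidationError):
            classify_psths([])

    def test_determinism_given_seed(self):
        psths, _ = generate_profile_dataset(seed=4)
        cfg = ClassificationConfig(seed=11)
        out1 = classify_session(psths, cfg)
        out2 = classify_session(psths, cfg)
        assert np.array_equal(out1[1], out2[1])
        for c1, c2 in zip(out1[0], out2[0]):
            assert c1.x1 == c2.x1 and c1.x2 == c2.x2 and c1.s == c2.s
        assert out1[2].early == out2[2].early
        assert out1[2].late == out2[2].late

    def test_scale_invariance_of_labels_and_separation(self):
        psths, _ = generate_profile_dataset(seed=6)
        scaled = [
            Psth(p.electrode_id, p.bin_edges, 3.0 * p.values, p.n_stimuli)
            for p in psths
        ]
        cfg = ClassificationConfig(seed=2)
        classes1, labels1, _ = classify_session(psths, cfg)
        classes2, labels2, _ = classify_session(scaled, cfg)
        assert np.array_equal(labels1, labels2)
        for c1, c2 in zip(classes1, classes2):
            assert c1.has_late == c2.has_late
            assert c1.x1 == c2.x1 and c1.x2 == c2.x2
            if c1.s is not None:
                assert c1.s == pytest.approx(c2.s)


class TestLatencyAssignment:
    def _class(self, has_late, x_min=60.0):
        profile = _bump(12, 6, 1.0) + (_bump(180, 30, 0.5) if has_late else 0)
        return ResponseClass(
            class_id=0,
            member_electrodes=("e0",),
            mean_psth=profile,
            psth_smooth=profile,
            bin_centers=CENTERS,
            x1=12.0,
            x2=180.0 if has_late else None,
            x_min=x_min if has_late else None,
            s=0.9 if has_late else None,
            has_late=has_late,
        )

    def test_early_only_class_gets_sentinel(self):
        p = _psth(_bump(20, 4, 1.0))
        lmap = assign_latencies([p], [self._class(False)], np.array([0]))
        e, l = lmap["e0"]
        assert abs(e - 20) <= 4
        assert l == LATE_SENTINEL_MS

    def test_has_late_class_splits_at_x_min(self):
        p = _psth(_bump(12, 4, 1.0) + _bump(180, 20, 0.6))
        lmap = assign_latencies([p], [self._class(True)], np.array([0]))
        e, l = lmap["e0"]
        assert abs(e - 12) <= 4
        assert abs(l - 180) <= 4

    def test_unlabelled_electrode_rejected(self):
        from mea_evoked.core_model import ValidationError

        p = _psth(_bump(12, 4, 1.0))
        with pytest.raises(ValidationError):
            assign_latencies([p], [self._class(False)], np.array([5]))

    def test_has_late_invariants_on_profile_dataset(self):
        psths, _ = generate_profile_dataset(seed=8)
        classes, labels, lmap = classify_session(psths, ClassificationConfig(seed=8))
        for c in classes:
            if c.has_late:
                assert c.x1 < c.x_min < c.x2
                assert c.s > 0.3
            else:
                for eid in c.member_electrodes:
                    assert lmap.late[eid] == LATE_SENTINEL_MS
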