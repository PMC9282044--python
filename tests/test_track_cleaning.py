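"""Identity relabelling, ghost flagging, ledger corrections, child selection."""

from itertools import permutations

import numpy as np
import pytest

from drumpose.pose_io import FramePose, PoseTimeSeries, TrialInfo
from drumpose.synth import CohortSpec, generate_trial
from drumpose.track_cleaning import (
    CorrectionLedger,
    Directive,
    DirectiveError,
    NoTracksError,
    apply_ledger,
    flag_ghosts,
    match_by_location,
    match_by_size,
    person_centroids,
    relabel_series,
    select_child,
)

from conftest import person_at


def frame_with_centroids(*centroids, conf=0.8):
    persons = [person_at(x, y, conf=conf) for x, y in centroids]
    return FramePose(np.stack(persons))


def brute_force_location(prev, curr):
    """Independent oracle: minimise summed centroid distance over injections."""
    pc = person_centroids(prev.keypoints)
    cc = person_centroids(curr.keypoints)
    n_prev, n_curr = len(pc), len(cc)
    best, best_cost = None, np.inf
    for rows in permutations(range(n_prev), min(n_prev, n_curr)):
        if n_prev >= n_curr:
            mapping = {j: r for j, r in enumerate(rows)}
        else:
            continue
        cost = sum(np.linalg.norm(pc[r] - cc[j]) for j, r in mapping.items())
        if cost < best_cost:
            best, best_cost = mapping, cost
    if n_prev < n_curr:
        for cols in permutations(range(n_curr), n_prev):
            mapping = {j: i for i, j in enumerate(cols)}
            cost = sum(np.linalg.norm(pc[i] - cc[j]) for j, i in mapping.items())
            if cost < best_cost:
                best, best_cost = mapping, cost
    return best


class TestMatchByLocation:
    def test_swapped_listing_recovered(self):
        prev = frame_with_centroids((100, 100), (300, 100))
        curr = frame_with_centroids((302, 101), (101, 99))
        a = match_by_location(prev, curr)
        assert a.mapping == {0: 1, 1: 0}
        assert a.mapping == brute_force_location(prev, curr)

    def test_identical_frames_identity(self):
        f = frame_with_centroids((50, 60), (200, 220))
        assert match_by_location(f, f).mapping == {0: 0, 1: 1}

    def test_extra_person_gets_fresh_label(self):
        prev = frame_with_centroids((100, 100), (300, 100))
        curr = frame_with_centroids((101, 101), (299, 99), (900, 500))
        a = match_by_location(prev, curr)
        assert a.mapping[0] == 0 and a.mapping[1] == 1
        assert a.mapping[2] == 2 and a.unmatched_new == [2]
        matched = brute_force_location(prev, curr)
        assert {j: l for j, l in a.mapping.items() if j in matched} == matched

    def test_no_prev_persons_all_fresh(self):
        prev = FramePose(np.zeros((0, 67, 3)))
        curr = frame_with_centroids((10, 10))
        a = match_by_location(prev, curr)
        assert a.mapping == {0: 0}
        assert a.unmatched_new == [0]


class TestMatchBySize:
    @staticmethod
    def frame_with_sizes(*sizes):
        persons = []
        for s in sizes:
            kp = person_at(100.0, 100.0)
            kp[:25, 1] = np.linspace(100.0, 100.0 + s, 25)
            persons.append(kp)
        return FramePose(np.stack(persons))

    def test_size_swap_recovered(self):
        prev = self.frame_with_sizes(200, 100)
        curr = self.frame_with_sizes(98, 205)
        assert match_by_size(prev, curr).mapping == {0: 1, 1: 0}

    def test_identical_frames_identity(self):
        f = self.frame_with_sizes(180, 90)
        assert match_by_size(f, f).mapping == {0: 0, 1: 1}

    def test_exact_tie_breaks_to_identity_order(self):
        prev = self.frame_with_sizes(150, 150)
        curr = self.frame_with_sizes(150, 150)
        assert match_by_size(prev, curr).mapping == {0: 0, 1: 1}


def truth_alignment(series, clean, truth):
    """Fraction of frames where relabelled persons equal the clean figures
    under one fixed global permutation (identity-switch-free labelling)."""
    n_clean = truth.n_persons_clean
    out = series.data[:, :n_clean]
    best = 0.0
    for sigma in permutations(range(n_clean)):
        ok = 0
        for f in range(series.n_frames):
            if np.array_equal(out[f, list(sigma)], clean[f]):
                ok += 1
        best = max(best, ok / series.n_frames)
    return best


class TestRelabelSeries:
    def test_recovers_ground_truth_under_swaps(self):
        spec = CohortSpec(swap_rate=0.1, pos_noise_px=0.5)
        td = generate_trial(spec, "c0", 2, "P500", 1, 550.0, seed=3)
        assert len(td.truth.swap_events) > 20
        clean_spec = CohortSpec(swap_rate=0.0, pos_noise_px=0.5)
        clean = generate_trial(clean_spec, "c0", 2, "P500", 1, 550.0, seed=3).frames
        relabelled = relabel_series(td.to_series(), method="location")
        assert truth_alignment(relabelled, clean, td.truth) == 1.0

    def test_consistent_series_unchanged(self, clean_trial):
        series = clean_trial.to_series()
        out = relabel_series(series, method="location")
        np.testing.assert_array_equal(out.data, series.data)

    def test_ghost_confined_to_fresh_label(self, clean_trial):
        series = clean_trial.to_series()
        data = np.concatenate([series.data, np.zeros_like(series.data[:, :1])], axis=1)
        ghost = person_at(600.0, 20.0, conf=0.1)
        data[100:103, 2] = ghost
        corrupted = PoseTimeSeries(trial_info=series.trial_info, data=data)
        out = relabel_series(corrupted, method="location")
        np.testing.assert_array_equal(out.data[:, :2], series.data)
        assert out.missing()[:, 2].all(axis=1).sum() == out.n_frames - 3

    def test_relabelling_conserves_keypoint_multiset(self):
        spec = CohortSpec(swap_rate=0.2)
        td = generate_trial(spec, "c0", 3, "P600", 1, 500.0, seed=11)
        series = td.to_series()
        out = relabel_series(series, method="location")
        for f in range(0, series.n_frames, 37):
            a = series.data[f].reshape(-1, 3)
            b = out.data[f].reshape(-1, 3)
            a = np.sort(a[np.any(a != 0, axis=1)], axis=0)
            b = np.sort(b[np.any(b != 0, axis=1)], axis=0)
            np.testing.assert_array_equal(a, b)


class TestFlagGhosts:
    def make_series(self, trial_info):
        data = np.zeros((600, 2, 67, 3))
        data[:, 0] = person_at(100, 100, conf=0.8)
        data[:3, 1] = person_at(500, 50, conf=0.1)
        return PoseTimeSeries(trial_info=trial_info, data=data)

    def test_sparse_low_conf_track_flagged(self, trial_info):
        flagged = flag_ghosts(self.make_series(trial_info), 0.2, 0.3)
        assert flagged == {1}

    def test_persistent_confident_track_not_flagged(self, trial_info):
        assert 0 not in flag_ghosts(self.make_series(trial_info), 0.2, 0.3)

    def test_vacuous_thresholds_flag_nothing(self, trial_info):
        assert flag_ghosts(self.make_series(trial_info), 0.0, 0.0) == set()


class TestLedger:
    def test_swap_directive_repairs_known_switch(self, trial_info):
        data = np.zeros((600, 2, 67, 3))
        data[:, 0] = person_at(100, 100)
        data[:, 1] = person_at(400, 100)
        truth = data.copy()
        data[250:600, [0, 1]] = data[250:600, [1, 0]]  # injected identity switch
        series = PoseTimeSeries(trial_info=trial_info, data=data)
        ledger = CorrectionLedger([Directive("swap", 250, 600, 0, 1)])
        fixed = apply_ledger(series, ledger)
        np.testing.assert_array_equal(fixed.data, truth)

    def test_empty_ledger_is_identity(self, clean_trial):
        series = clean_trial.to_series()
        out = apply_ledger(series, CorrectionLedger())
        np.testing.assert_array_equal(out.data, series.data)

    def test_delete_blanks_label(self, clean_trial):
        series = clean_trial.to_series()
        out = apply_ledger(
            series, CorrectionLedger([Directive("delete", 0, series.n_frames, 1)])
        )
        assert out.missing()[:, 1].all()

    def test_unknown_label_raises_naming_directive(self, clean_trial):
        series = clean_trial.to_series()
        with pytest.raises(DirectiveError, match="delete"):
            apply_ledger(series, CorrectionLedger([Directive("delete", 0, 10, 9)]))

    def test_out_of_range_frames_raise(self, clean_trial):
        series = clean_trial.to_series()
        with pytest.raises(DirectiveError):
            apply_ledger(series, CorrectionLedger([Directive("swap", 0, 10_000, 0, 1)]))

    def test_independent_directives_commute(self, trial_info):
        data = np.zeros((100, 3, 67, 3))
        for p in range(3):
            data[:, p] = person_at(100.0 * (p + 1), 100)
        series = PoseTimeSeries(trial_info=trial_info, data=data)
        d1 = Directive("delete", 0, 50, 0)
        d2 = Directive("delete", 50, 100, 2)
        a = apply_ledger(series, CorrectionLedger([d1, d2]))
        b = apply_ledger(series, CorrectionLedger([d2, d1]))
        np.testing.assert_array_equal(a.data, b.data)

    def test_csv_round_trip(self, tmp_path):
        ledger = CorrectionLedger(
            [Directive("swap", 10, 20, 0, 1), Directive("set_child", 0, 0, 1)]
        )
        path = tmp_path / "ledger.csv"
        ledger.to_csv(path)
        assert CorrectionLedger.from_csv(path) == ledger


class TestSelectChild:
    def test_ledger_directive_takes_precedence(self, clean_trial):
        series = clean_trial.to_series()
        ledger = CorrectionLedger([Directive("set_child", 0, 0, 0)])
        assert select_child(series, ledger) == 0

    def test_variance_fallback_picks_drummer(self, clean_trial):
        # caregiver (track 0) is static; the drumming child is track 1
        assert select_child(clean_trial.to_series()) == 1

    def test_single_track(self, trial_info):
        data = np.zeros((10, 1, 67, 3))
        data[:, 0] = person_at(5, 5)
        assert select_child(PoseTimeSeries(trial_info=trial_info, data=data)) == 0

    def test_no_tracks_raises(self, trial_info):
        series = PoseTimeSeries(trial_info=trial_info, data=np.zeros((10, 1, 67, 3)))
        with pytest.raises(NoTracksError):
            select_child(series)
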