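"""Neighbour-exchange canonicalisation, detection and angular measures."""

import numpy as np
import pytest

from germband.tracks import ScriptedT1, generate_scripted_t1_lattice
from germband.t1 import (
    MIN_BOUT_FRAMES,
    ConnectivityError,
    QuartetSeries,
    canonicalize_connectivity,
    corrected_lost_gained_angle,
    count_productive_t1s,
    detect_t1_events,
    events_from_series,
    fill_owner_series,
    gain_axis_class,
    immortal_length_series,
    resolution_phase_duration,
    shortening_to_centroid_angle,
    smooth_owner_series,
    t1_orientation,
)


def make_series(owner, frames=None):
    frames = frames if frames is not None else list(range(len(owner)))
    q = QuartetSeries(
        cells=frozenset((1, 2, 3, 4)),
        diag1=(1, 3),
        diag2=(2, 4),
        frames=frames,
        raw=list(owner),
    )
    q.owner = smooth_owner_series(fill_owner_series(q.raw))
    return q


class TestOwnerSeries:
    def test_fourway_frames_assigned_to_most_recent_owner(self):
        assert fill_owner_series([1, None, None, 2, None]) == [1, 1, 1, 2, 2]

    def test_leading_unknowns_take_first_known_owner(self):
        assert fill_owner_series([None, None, 2, 1]) == [2, 2, 2, 1]

    def test_short_bout_reversed(self):
        filled = [1] * 4 + [2] * 3 + [1] * 4
        assert smooth_owner_series(filled) == [1] * 11

    def test_long_bout_survives(self):
        filled = [1] * 6 + [2] * 5 + [1] * 6
        assert smooth_owner_series(filled) == filled

    def test_shortest_bout_reversed_first(self):
        # three bouts of lengths 4, 2, 2; the earliest 2-frame bout (the
        # brief return to owner 1) is reversed first, merging the two
        # 2-runs into one 8-frame run that then survives as a real swap
        filled = [1] * 5 + [2] * 4 + [1] * 2 + [2] * 2 + [1] * 5
        smoothed = smooth_owner_series(filled)
        assert smoothed == [1] * 5 + [2] * 8 + [1] * 5

    def test_bouts_of_two_and_four_frames_resolve_in_length_order(self):
        # the 2-frame bout is reversed first; the 4-frame run it flanked
        # merges with the tail and is re-evaluated as a stable swap
        filled = [1] * 6 + [2] * 4 + [1] * 2 + [2] * 6
        assert smooth_owner_series(filled) == [1] * 6 + [2] * 12

    def test_boundary_runs_are_never_bouts(self):
        filled = [2] * 3 + [1] * 10
        assert smooth_owner_series(filled) == filled

    def test_smoothing_is_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = list(rng.integers(1, 3, size=rng.integers(5, 40)))
            once = smooth_owner_series(raw)
            assert smooth_owner_series(once) == once

    def test_time_reversal_swaps_losing_and_gaining(self):
        owner = [1] * 10 + [2] * 12
        fwd = events_from_series(make_series(owner))
        rev = events_from_series(make_series(owner[::-1]))
        assert len(fwd) == len(rev) == 1
        assert fwd[0].losing_pair == rev[0].gaining_pair
        assert fwd[0].gaining_pair == rev[0].losing_pair


class TestDetection:
    def test_single_scripted_swap_gives_one_event_at_first_contact(self, ideal_t1_tracks):
        events = detect_t1_events(canonicalize_connectivity(ideal_t1_tracks))
        assert len(events) == 1
        assert events[0].gain_frame == 26
        assert set(events[0].losing_pair) == {12, 13}
        assert set(events[0].gaining_pair) == {7, 17}

    def test_fourway_plateau_times_event_at_new_contact(self):
        script = ScriptedT1(losing=(12, 13), shrink_start=5, swap_frame=15,
                            hold_frames=10, regrow_frames=10)
        tracks = generate_scripted_t1_lattice([script], n_frames=50)
        events = detect_t1_events(canonicalize_connectivity(tracks))
        assert len(events) == 1
        assert events[0].gain_frame == script.gain_frame == 26

    def test_reverted_swap_smoothed_to_nothing(self):
        script = ScriptedT1(losing=(12, 13), shrink_start=5, swap_frame=15,
                            hold_frames=0, regrow_frames=10, revert_frame=18)
        tracks = generate_scripted_t1_lattice([script], n_frames=40)
        assert detect_t1_events(canonicalize_connectivity(tracks)) == []

    def test_slow_reversion_counts_both_events(self):
        script = ScriptedT1(losing=(12, 13), shrink_start=5, swap_frame=15,
                            hold_frames=0, regrow_frames=8, revert_frame=28)
        tracks = generate_scripted_t1_lattice([script], n_frames=50)
        events = detect_t1_events(canonicalize_connectivity(tracks))
        assert len(events) == 2
        assert events[0].gaining_pair == events[1].losing_pair

    def test_impossible_connectivity_raises(self, ideal_t1_tracks):
        tracks = ideal_t1_tracks
        extra = tracks.interfaces.iloc[[0]].copy()
        extra["cell_a"], extra["cell_b"] = 12, 13
        extra["frame"] = 40  # both diagonals connected after the swap
        import pandas as pd

        tracks = type(tracks)(
            cells=tracks.cells,
            interfaces=pd.concat([tracks.interfaces, extra], ignore_index=True),
            frame_interval_s=tracks.frame_interval_s,
            axes=tracks.axes,
        )
        with pytest.raises(ConnectivityError):
            canonicalize_connectivity(tracks)


class TestAngles:
    def test_pre_swap_orientation_of_dv_junction(self, ideal_t1_tracks):
        (event,) = detect_t1_events(canonicalize_connectivity(ideal_t1_tracks))
        assert t1_orientation(event, ideal_t1_tracks) == pytest.approx(90.0)

    def test_event_too_close_to_track_start_excluded(self):
        script = ScriptedT1(losing=(12, 13), shrink_start=0, swap_frame=3,
                            hold_frames=0, regrow_frames=10)
        tracks = generate_scripted_t1_lattice([script], n_frames=30)
        (event,) = detect_t1_events(canonicalize_connectivity(tracks))
        assert t1_orientation(event, tracks) is None

    def test_gain_axis_is_dv_for_vertical_gaining_pair(self, ideal_t1_tracks):
        (event,) = detect_t1_events(canonicalize_connectivity(ideal_t1_tracks))
        assert gain_axis_class(event, ideal_t1_tracks) == "DV"

    def test_corrected_angle_is_90_for_ideal_t1(self, ideal_t1_tracks):
        (event,) = detect_t1_events(canonicalize_connectivity(ideal_t1_tracks))
        angle = corrected_lost_gained_angle(event, ideal_t1_tracks)
        assert angle == pytest.approx(90.0, abs=1e-9)

    def test_corrected_angle_unchanged_by_rigid_rotation_after_swap(self, ideal_t1_tracks):
        # rotate every frame after the gain by 30 degrees about the origin:
        # the raw angular difference changes but the centroid-line
        # correction removes the rigid part
        tracks = ideal_t1_tracks
        theta = np.deg2rad(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        cells = tracks.cells.copy()
        ifaces = tracks.interfaces.copy()
        post = cells["frame"] >= 30
        xy = cells.loc[post, ["x", "y"]].to_numpy() @ R.T
        cells.loc[post, ["x", "y"]] = xy
        posti = ifaces["frame"] >= 30
        for cols in (["x1", "y1"], ["x2", "y2"]):
            ifaces.loc[posti, cols] = ifaces.loc[posti, cols].to_numpy() @ R.T
        rotated = type(tracks)(
            cells=cells, interfaces=ifaces,
            frame_interval_s=tracks.frame_interval_s, axes=tracks.axes,
        )
        (event,) = detect_t1_events(canonicalize_connectivity(rotated))
        angle = corrected_lost_gained_angle(event, rotated)
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_shortening_to_centroid_angle_zero_for_ideal_t1(self, ideal_t1_tracks):
        (event,) = detect_t1_events(canonicalize_connectivity(ideal_t1_tracks))
        series = shortening_to_centroid_angle(event, ideal_t1_tracks)
        assert len(series) >= 20
        assert max(abs(a) for _, a in series) < 1e-9

    def test_global_rotation_leaves_relative_angle_unchanged(self, ideal_t1_tracks):
        tracks = ideal_t1_tracks
        theta = np.deg2rad(25.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        cells = tracks.cells.copy()
        ifaces = tracks.interfaces.copy()
        cells[["x", "y"]] = cells[["x", "y"]].to_numpy() @ R.T
        for cols in (["x1", "y1"], ["x2", "y2"]):
            ifaces[cols] = ifaces[cols].to_numpy() @ R.T
        rotated = type(tracks)(
            cells=cells, interfaces=ifaces,
            frame_interval_s=tracks.frame_interval_s, axes=tracks.axes,
        )
        (event,) = detect_t1_events(canonicalize_connectivity(rotated))
        series = shortening_to_centroid_angle(event, rotated)
        assert max(abs(a) for _, a in series) < 1e-6


class TestProductiveCounting:
    def test_dv_gains_accumulate_and_normalise(self, ideal_t1_tracks):
        events = detect_t1_events(canonicalize_connectivity(ideal_t1_tracks))
        table = count_productive_t1s(events, ideal_t1_tracks)
        before = table[table["frame"] < 26]
        after = table[table["frame"] >= 26]
        assert (before["net_gains"] == 0).all()
        assert (after["net_gains"] == 1).all()
        assert after["productive_per_dv_interface"].iloc[-1] == pytest.approx(
            1.0 / after["n_dv_interfaces"].iloc[-1]
        )

    def test_doubling_the_tissue_leaves_measure_unchanged(self):
        script = ScriptedT1(losing=(16, 17), shrink_start=5, swap_frame=15,
                            regrow_frames=10)
        single = generate_scripted_t1_lattice([script], n_frames=40, rows=7, cols=6)
        both = generate_scripted_t1_lattice(
            [script, ScriptedT1(losing=(30, 31), shrink_start=5, swap_frame=15,
                                regrow_frames=10)],
            n_frames=40, rows=7, cols=6,
        )
        # two disjoint copies of the same local event in a tissue with
        # twice the events: per-DV-interface normalisation is intensive
        t1 = count_productive_t1s(
            detect_t1_events(canonicalize_connectivity(single)), single
        )
        t2 = count_productive_t1s(
            detect_t1_events(canonicalize_connectivity(both)), both
        )
        assert t2["net_gains"].iloc[-1] == 2 * t1["net_gains"].iloc[-1]


class TestResolutionPhase:
    def test_eight_subthreshold_frames_is_four_minutes(self):
        lengths = np.concatenate([np.full(20, 3.0), np.full(8, 0.1), np.full(20, 3.0)])
        phase = resolution_phase_duration(lengths, smoothing_window=1, swap_index=24)
        assert phase.duration_min == 4.0

    def test_series_never_below_threshold_has_no_phase(self):
        assert resolution_phase_duration(np.full(40, 2.0)) is None

    def test_phase_touching_series_start_discarded(self):
        lengths = np.concatenate([np.full(6, 0.1), np.full(30, 3.0)])
        assert resolution_phase_duration(lengths, smoothing_window=1, swap_index=2) is None

    def test_phase_touching_series_end_discarded(self):
        lengths = np.concatenate([np.full(30, 3.0), np.full(6, 0.1)])
        assert resolution_phase_duration(lengths, smoothing_window=1, swap_index=33) is None

    def test_hanning_smoothing_bridges_transient_spikes(self):
        lengths = np.full(40, 0.2)
        lengths[:15] = 3.0
        lengths[-15:] = 3.0
        lengths[20] = 1.2  # one-frame tracking glitch
        phase = resolution_phase_duration(lengths, smoothing_window=5, swap_index=20)
        assert phase is not None
        assert phase.start_frame < 20 < phase.end_frame

    def test_scripted_swap_duration_from_immortal_series(self, ideal_t1_tracks):
        (quartet,) = canonicalize_connectivity(ideal_t1_tracks)
        series = immortal_length_series(quartet, ideal_t1_tracks)
        (event,) = events_from_series(quartet)
        phase = resolution_phase_duration(
            series, frame_interval_s=30.0,
            swap_index=quartet.frames.index(event.gain_frame),
        )
        assert phase is not None
        # shrink rate 0.1 um/frame towards the swap, regrow 0.1 um/frame:
        # the sub-threshold stretch spans roughly 15 frames
        assert 5.0 <= phase.duration_min <= 10.0
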