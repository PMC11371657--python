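"""Repolarization-event rules: stationarity, initial polarity, triggers,
veto, correctness, temporal change, summaries."""

import numpy as np
import pandas as pd
import pytest

from twitchtaxis.gradient_models import alternating_dualflow_field, \
    dual_flow_design
from twitchtaxis.polarity_profiler import (
    BIPOLAR,
    EXCLUDED_MIDCELL,
    NONPOLAR,
    UNIPOLAR_POLE1,
    UNIPOLAR_POLE2,
)
from twitchtaxis.repolarization_classifier import (
    ClassifierConfig,
    GradientTimeline,
    assign_temporal_change,
    classify_correctness,
    detect_event,
    detect_events,
    events_from_counts,
    initial_polarity,
    stationary_window_check,
    summarize_events,
)

RATE = 7.5          # cell-channel frames per minute
SWAP_T = 44.0       # min; swap frame = 330; fluorescence every 15 frames
SWAP_F = 330
FLUOR_EVERY = 15


def make_timeline(initial_sign=1, centre=40.0):
    field = alternating_dualflow_field(dual_flow_design(), centre=centre,
                                       swap_times=(SWAP_T,),
                                       initial_sign=initial_sign)
    return GradientTimeline.from_swap_times((SWAP_T,), 90.0, RATE, field,
                                            dead_zone_halfwidth=10.0)


def make_traj(g_series, frame0=0, x=20.0, theta=np.pi / 2, length=3.0,
              cell_id=0):
    """Trajectory along the gradient axis (+y); g_series are y positions."""
    n = len(g_series)
    frames = np.arange(frame0, frame0 + n)
    return pd.DataFrame({
        "cell_id": cell_id, "frame": frames, "t_min": frames / RATE,
        "x_um": x, "y_um": np.asarray(g_series, dtype=float),
        "orientation_rad": theta, "length_um": length, "width_um": 0.9})


def make_polarity(classes, first_fluor_frame=0, cell_id=0):
    ffs = np.arange(first_fluor_frame, first_fluor_frame + len(classes))
    return pd.DataFrame({
        "cell_id": cell_id, "fluor_frame": ffs,
        "frame": ffs * FLUOR_EVERY, "t_min": ffs * FLUOR_EVERY / RATE,
        "polarity_class": list(classes)})


def static_traj(n_frames=675, y=20.0, **kw):
    return make_traj(np.full(n_frames, y), **kw)


class TestStationaryWindow:
    timeline = make_timeline()

    def test_zero_displacement_passes(self):
        ok, reason = stationary_window_check(static_traj(), self.timeline,
                                             event_frame=400)
        assert ok and reason == ""

    def test_two_big_consecutive_steps_fail(self):
        y = np.full(675, 20.0)
        y[340:] += 0.5
        y[341:] += 0.5      # two +0.5 µm steps along the gradient
        ok, reason = stationary_window_check(make_traj(y), self.timeline,
                                             event_frame=400)
        assert not ok and reason == "consecutive_steps"

    def test_cumulative_excursion_fails(self):
        y = 20.0 + np.linspace(0, 5.0, 675)  # slow 5 µm drift
        ok, reason = stationary_window_check(make_traj(y), self.timeline,
                                             event_frame=600)
        assert not ok and reason == "excursion"

    def test_orthogonal_drift_passes(self):
        traj = static_traj()
        traj["x_um"] = 20.0 + np.linspace(0, 3.0, 675)  # across the gradient
        ok, _ = stationary_window_check(traj, self.timeline, event_frame=400)
        assert ok

    def test_empty_window_fails(self):
        traj = static_traj(n_frames=5)
        ok, reason = stationary_window_check(traj, self.timeline,
                                             event_frame=400)
        assert not ok and reason == "no_window"


class TestInitialPolarity:
    timeline = make_timeline()

    def _pol(self, last4):
        classes = [NONPOLAR] * 18 + list(last4) + [UNIPOLAR_POLE2] * 10
        return make_polarity(classes)

    def test_majority_wins(self):
        pol = self._pol([BIPOLAR, BIPOLAR, BIPOLAR, UNIPOLAR_POLE1])
        assert initial_polarity(pol, self.timeline)[0] == "bipolar"

    def test_tie_broken_by_immediately_preceding_frame(self):
        pol = self._pol([UNIPOLAR_POLE1, UNIPOLAR_POLE1, NONPOLAR, NONPOLAR])
        assert initial_polarity(pol, self.timeline)[0] == "nonpolar"

    def test_post_division_counts_after_division_only(self):
        pol = self._pol([UNIPOLAR_POLE1, EXCLUDED_MIDCELL, BIPOLAR, BIPOLAR])
        coarse, post_div = initial_polarity(pol, self.timeline)
        assert coarse == "bipolar" and post_div

    def test_no_preswap_frames_not_assignable(self):
        pol = make_polarity([UNIPOLAR_POLE1] * 5, first_fluor_frame=23)
        assert initial_polarity(pol, self.timeline)[0] == "not_assignable"


class TestDetectEvent:
    timeline = make_timeline()
    cfg = ClassifierConfig()

    def _pol_series(self, pre, post):
        """22 pre-swap fluorescence frames then the post-swap classes."""
        return make_polarity([pre] * 22 + list(post))

    def test_polarity_trigger_fires_on_new_pole(self):
        pol = self._pol_series(NONPOLAR, [NONPOLAR, NONPOLAR,
                                          UNIPOLAR_POLE2, UNIPOLAR_POLE2,
                                          UNIPOLAR_POLE2] + [UNIPOLAR_POLE2] * 10)
        ev = detect_event(pol, static_traj(y=60.0), self.timeline, self.cfg)
        assert ev is not None
        assert ev.trigger == "polarity_first"
        assert ev.new_leading_pole == 2
        assert ev.event_fluor_frame == 24
        assert ev.initial_polarity == "nonpolar"

    def test_veto_when_pole_already_unipolar_preswap(self):
        classes = [NONPOLAR] * 18 + [UNIPOLAR_POLE2, UNIPOLAR_POLE2,
                                     NONPOLAR, NONPOLAR]
        classes += [NONPOLAR, NONPOLAR] + [UNIPOLAR_POLE2] * 10
        ev = detect_event(make_polarity(classes), static_traj(y=60.0),
                          self.timeline, self.cfg)
        assert ev is None

    def test_movement_trigger_before_polarity_change(self):
        y = np.full(675, 60.0)
        y[361:] += 1.0
        y[362:] += 1.0      # two >= one-cell-width steps at frames 361-362
        pol = self._pol_series(NONPOLAR, [NONPOLAR] * 23)
        ev = detect_event(pol, make_traj(y), self.timeline, self.cfg)
        assert ev is not None
        assert ev.trigger == "movement_first"
        assert ev.event_frame == 361
        # +y movement under a post-swap sign of -1 means lower
        # concentration: an incorrect repolarization
        assert ev.direction_call == "incorrect"

    def test_no_event_for_constant_polarity(self):
        for cls in (NONPOLAR, UNIPOLAR_POLE1, UNIPOLAR_POLE2, BIPOLAR):
            pol = make_polarity([cls] * 45)
            ev = detect_event(pol, static_traj(y=60.0), self.timeline,
                              self.cfg)
            assert ev is None

    def test_nonstationary_candidate_rejected(self):
        y = np.full(675, 60.0)
        y[335:400] = 60.0 + np.linspace(0, 4.0, 65)  # drifts after the swap
        y[400:] = 64.0
        pol = self._pol_series(NONPOLAR, [NONPOLAR, NONPOLAR,
                                          UNIPOLAR_POLE2] + [UNIPOLAR_POLE2] * 12)
        ev = detect_event(pol, make_traj(y), self.timeline, self.cfg)
        assert ev is None

    def test_unstable_length_rejected(self):
        traj = static_traj(y=60.0)
        traj.loc[traj.frame.between(350, 360), "length_um"] = 6.0  # merge
        pol = self._pol_series(NONPOLAR, [NONPOLAR, NONPOLAR,
                                          UNIPOLAR_POLE2] + [UNIPOLAR_POLE2] * 12)
        assert detect_event(pol, traj, self.timeline, self.cfg) is None

    def test_detect_events_over_table(self):
        pol_a = self._pol_series(NONPOLAR, [NONPOLAR, NONPOLAR,
                                            UNIPOLAR_POLE2] + [UNIPOLAR_POLE2] * 12)
        pol_b = make_polarity([BIPOLAR] * 45, cell_id=1)
        traj_a = static_traj(y=60.0)
        traj_b = static_traj(y=25.0, cell_id=1)
        events = detect_events(pd.concat([traj_a, traj_b]),
                               pd.concat([pol_a, pol_b]), self.timeline,
                               self.cfg)
        assert len(events) == 1
        assert events.cell_id.iloc[0] == 0


class TestCorrectnessAndTemporalChange:
    def test_correct_pole_faces_higher_concentration(self):
        timeline = make_timeline()
        pose = {"cell_id": 0, "x_um": 20.0, "y_um": 60.0,
                "orientation_rad": np.pi / 2, "length_um": 3.0}
        # post-swap sign -1: concentration increases toward -y, so pole 2
        # (the -axis endpoint, lower y) is the correct new leading pole
        assert classify_correctness(2, pose, timeline, 50.0) == "correct"
        assert classify_correctness(1, pose, timeline, 50.0) == "incorrect"

    def test_flipping_epoch_sign_flips_every_call(self):
        pose = {"cell_id": 0, "x_um": 20.0, "y_um": 60.0,
                "orientation_rad": np.pi / 2, "length_um": 3.0}
        plus = make_timeline(initial_sign=1)
        minus = make_timeline(initial_sign=-1)
        for pole in (1, 2):
            a = classify_correctness(pole, pose, plus, 50.0)
            b = classify_correctness(pole, pose, minus, 50.0)
            assert {a, b} == {"correct", "incorrect"}

    def test_pole_orthogonal_to_gradient_unclassifiable(self):
        timeline = make_timeline()
        pose = {"cell_id": 0, "x_um": 20.0, "y_um": 60.0,
                "orientation_rad": 0.0, "length_um": 3.0}
        assert classify_correctness(1, pose, timeline, 50.0) is None

    def test_temporal_change_rules(self):
        timeline = make_timeline()  # centre 40, dead zone half-width 10
        assert assign_temporal_change(20.0, 70.0, timeline) == "step_down"
        assert assign_temporal_change(20.0, 12.0, timeline) == "step_up"
        assert assign_temporal_change(20.0, 43.0, timeline) == \
            "not_assignable"


class TestSummaries:
    def test_published_totals_round_to_sixfold(self):
        summary = summarize_events(events_from_counts(148, 23))
        assert round(summary["overall"]["ratio"]) == 6
        assert summary["overall"]["p_binomial"] < 1e-10

    def test_empty_events(self):
        summary = summarize_events(pd.DataFrame(
            columns=["direction_call", "initial_polarity",
                     "temporal_change"]))
        assert summary["overall"]["n_correct"] == 0
        assert summary["by_initial_polarity"].empty

    def test_scripted_counts_tabulated(self):
        ev = events_from_counts(10, 2)
        summary = summarize_events(ev)
        assert summary["overall"]["n_correct"] == 10
        assert summary["overall"]["n_incorrect"] == 2
        tab = summary["by_initial_polarity"]
        assert tab.n_correct.sum() == 10 and tab.n_incorrect.sum() == 2
        assert np.all((tab.ci_low >= 0) & (tab.ci_high <= 1))
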