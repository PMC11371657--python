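"""Detection and classification of repolarization events in stationary cells.

When the cross-channel chemoattractant gradient flips direction, a
stationary cell that senses the new orientation re-localizes its
retraction-motor fusion to the pole now facing higher concentration (a
"correct" event) or the opposite pole ("incorrect").  The rules
implemented here mirror the manual annotation protocol:

* an event fires when the cell either (A) develops a unipolar pattern at
  a pole different from its initial localization, sustained in at least
  2 of 4 consecutive fluorescence frames, or (B) moves off consistently
  at >= one cell width per frame (on the gradient axis) for two frames —
  whichever occurs first;
* the cell must have been stationary along the gradient axis from the
  frame after the last frame of the initial gradient until the event
  (and for at least 3 frames before it): no two consecutive same-sign
  steps each above half a cell width, and no net excursion above one
  cell width;
* the event is vetoed if the new leading pole was already unipolar in
  2 of the 4 pre-swap fluorescence frames or in the frame immediately
  preceding the swap;
* the initial polarity is the majority class of the 4 fluorescence
  frames preceding the new gradient (2-2 ties broken by the immediately
  preceding frame); frames flagged as mid-cell (pre-division)
  localization are never counted, and classes are only counted after a
  division;
* each event is called correct/incorrect from the concentration at the
  two pole positions, and step-up/step-down from the pre-swap
  concentration at the cell relative to half the source concentration,
  with cells near the gradient centreline not assignable.

Trigger A runs on the fluorescence clock, trigger B on the cell-channel
clock; event frames are reported on the cell-channel clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gradient_models import ConcentrationField
from .inference_stats import exact_binomial_test, proportion_ci
from .polarity_profiler import (
    BIPOLAR,
    EXCLUDED_MIDCELL,
    NONPOLAR,
    UNIPOLAR_POLE1,
    UNIPOLAR_POLE2,
)

logger = logging.getLogger(__name__)

CORRECT = "correct"
INCORRECT = "incorrect"
STEP_UP = "step_up"
STEP_DOWN = "step_down"
NOT_ASSIGNABLE = "not_assignable"
POLARITY_FIRST = "polarity_first"
MOVEMENT_FIRST = "movement_first"

_COARSE = {NONPOLAR: "nonpolar", UNIPOLAR_POLE1: "unipolar",
           UNIPOLAR_POLE2: "unipolar", BIPOLAR: "bipolar"}
_UNIPOLAR_OF = {1: UNIPOLAR_POLE1, 2: UNIPOLAR_POLE2}


@dataclass
class ClassifierConfig:
    """Rule parameters (frames are fluorescence frames unless noted)."""

    cell_width: float = 0.9        # µm, nominal
    min_preceding: int = 3         # cell-channel frames before the event
    init_window: int = 4           # fluorescence frames for initial polarity
    a_window: int = 4              # trigger A: window length
    a_min_count: int = 2           # trigger A: required occupancy
    b_steps: int = 2               # trigger B: consecutive cell-channel steps
    max_length_dev: float = 0.25   # relative length instability tolerated


@dataclass
class GradientTimeline:
    """Gradient epochs on the cell-channel frame clock.

    ``epochs`` are contiguous half-open (start_frame, end_frame, sign)
    triples; ``swap_frames`` the first frame of each new orientation.
    """

    epochs: Sequence[tuple]
    swap_frames: Sequence[int]
    c_max: float
    field: ConcentrationField
    frame_rate: float
    gradient_axis: tuple = (0.0, 1.0)
    dead_zone_halfwidth: float = 10.0

    def __post_init__(self) -> None:
        eps = list(self.epochs)
        for (s0, e0, _), (s1, _, _) in zip(eps, eps[1:]):
            if s1 != e0:
                raise ValueError("epochs must be contiguous, non-overlapping")

    @classmethod
    def from_swap_times(cls, swap_times: Sequence[float], duration: float,
                        frame_rate: float, field: ConcentrationField,
                        gradient_axis: tuple = (0.0, 1.0),
                        dead_zone_halfwidth: float = 10.0
                        ) -> "GradientTimeline":
        n_frames = int(round(duration * frame_rate))
        swap_frames = [int(np.ceil(ts * frame_rate - 1e-9))
                       for ts in sorted(swap_times)]
        bounds = [0] + swap_frames + [n_frames]
        epochs = [(bounds[i], bounds[i + 1],
                   field.initial_sign * (-1) ** i)
                  for i in range(len(bounds) - 1)]
        return cls(epochs, swap_frames, field.c_max, field, frame_rate,
                   gradient_axis, dead_zone_halfwidth)

    def time_of(self, frame: int) -> float:
        return frame / self.frame_rate

    def sign_at(self, frame: int) -> int:
        for s, e, sign in self.epochs:
            if s <= frame < e:
                return sign
        raise ValueError(f"frame {frame} outside the timeline")

    def gradient_coordinate(self, x, y):
        gx, gy = self.gradient_axis
        return np.asarray(x) * gx + np.asarray(y) * gy


@dataclass
class RepolarizationEvent:
    cell_id: int
    event_frame: int               # cell-channel clock
    t_min: float
    trigger: str                   # polarity_first | movement_first
    initial_polarity: str          # nonpolar | unipolar | bipolar | not_assignable
    new_leading_pole: int          # 1 | 2
    direction_call: Optional[str]  # correct | incorrect | None
    temporal_change: str           # step_up | step_down | not_assignable
    post_division: bool = False
    event_fluor_frame: Optional[int] = None

    def as_row(self) -> dict:
        return {
            "cell_id": self.cell_id, "event_frame": self.event_frame,
            "event_fluor_frame": self.event_fluor_frame, "t_min": self.t_min,
            "trigger": self.trigger, "initial_polarity": self.initial_polarity,
            "new_leading_pole": self.new_leading_pole,
            "direction_call": self.direction_call,
            "temporal_change": self.temporal_change,
            "post_division": self.post_division,
        }


# ---------------------------------------------------------------------------
# Rule implementations
# ---------------------------------------------------------------------------

def stationary_window_check(traj: pd.DataFrame, timeline: GradientTimeline,
                            event_frame: int, cell_width: float = 0.9,
                            min_preceding: int = 3) -> tuple:
    """Is the cell stationary along the gradient axis before the event?

    The monitored window runs from the first frame of the final gradient
    orientation to ``event_frame`` inclusive, extended backwards to at
    least ``min_preceding`` frames before the event.  Displacements are
    projected on the gradient axis.  Fails when (a) two consecutive
    same-sign steps each exceed half a cell width, or (b) the net
    excursion from the window start exceeds one cell width at any frame.
    Returns ``(passed, reason)`` with reason in {"", "no_window",
    "consecutive_steps", "excursion"}.
    """
    swap_start = timeline.swap_frames[-1] if timeline.swap_frames else 0
    start = min(swap_start, event_frame - min_preceding)
    win = traj[(traj.frame >= start) & (traj.frame <= event_frame)]
    if len(win) < 2:
        return False, "no_window"
    g = timeline.gradient_coordinate(win.x_um.to_numpy(),
                                     win.y_um.to_numpy())
    steps = np.diff(g)
    half = 0.5 * cell_width
    big = np.abs(steps) > half
    same = np.sign(steps[:-1]) == np.sign(steps[1:])
    if np.any(big[:-1] & big[1:] & same):
        return False, "consecutive_steps"
    if np.any(np.abs(g - g[0]) > cell_width):
        return False, "excursion"
    return True, ""


def _pre_swap_classes(polarity: pd.DataFrame, swap_start: int,
                      window: int) -> list:
    pre = polarity[polarity.frame < swap_start].sort_values("fluor_frame")
    return list(pre.polarity_class.to_numpy()[-window:])


def initial_polarity(polarity: pd.DataFrame, timeline: GradientTimeline,
                     window: int = 4) -> tuple:
    """Majority polarity mode over the fluorescence frames preceding the
    final gradient orientation.

    Returns ``(coarse_class, post_division)``.  Mid-cell (pre-division)
    frames are never counted; when present, only frames after the last
    such frame contribute and the record is flagged post-division.  A 2-2
    tie is broken by the frame immediately preceding the swap; an
    unresolvable window yields ``not_assignable``.
    """
    swap_start = timeline.swap_frames[-1] if timeline.swap_frames else 0
    classes = _pre_swap_classes(polarity, swap_start, window)
    if not classes:
        return NOT_ASSIGNABLE, False
    post_division = EXCLUDED_MIDCELL in classes
    if post_division:
        last_mid = max(i for i, c in enumerate(classes)
                       if c == EXCLUDED_MIDCELL)
        classes = classes[last_mid + 1:]
    coarse = [_COARSE[c] for c in classes if c in _COARSE]
    if not coarse:
        return NOT_ASSIGNABLE, post_division
    counts = pd.Series(coarse).value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) == 1:
        return top[0], post_division
    last = coarse[-1]
    if last in top:
        return last, post_division
    return NOT_ASSIGNABLE, post_division


def _veto_pole(polarity: pd.DataFrame, swap_start: int, pole: int,
               window: int, min_count: int) -> bool:
    """True when the candidate new pole was already unipolar pre-swap."""
    classes = _pre_swap_classes(polarity, swap_start, window)
    if not classes:
        return False
    target = _UNIPOLAR_OF[pole]
    if classes[-1] == target:
        return True
    return sum(c == target for c in classes) >= min_count


def classify_correctness(new_pole: int, pose, timeline: GradientTimeline,
                         t: float) -> Optional[str]:
    """Correct when the new leading pole sits at higher concentration than
    the opposite pole under the current epoch's field; None when the two
    poles see equal concentration (logged)."""
    theta = float(pose["orientation_rad"])
    axis = np.array([np.cos(theta), np.sin(theta)])
    half = 0.5 * float(pose["length_um"])
    centre = np.array([float(pose["x_um"]), float(pose["y_um"])])
    p1 = centre + half * axis
    p2 = centre - half * axis
    g1 = float(timeline.gradient_coordinate(*p1))
    g2 = float(timeline.gradient_coordinate(*p2))
    c1 = float(timeline.field.concentration(g1, t))
    c2 = float(timeline.field.concentration(g2, t))
    c_new, c_old = (c1, c2) if new_pole == 1 else (c2, c1)
    if c_new == c_old:
        logger.warning("cell %s: poles at equal concentration; direction "
                       "not classifiable", pose.get("cell_id"))
        return None
    return CORRECT if c_new > c_old else INCORRECT


def assign_temporal_change(x: float, y: float,
                           timeline: GradientTimeline) -> str:
    """Step-up/step-down from the pre-swap concentration at the cell.

    Concentration below half the source concentration before the swap
    means the swap raised the local concentration (step_up), above means
    step_down; cells within the centreline dead zone are not assignable.
    """
    if not timeline.swap_frames:
        return NOT_ASSIGNABLE
    g = float(timeline.gradient_coordinate(x, y))
    centre = timeline.field.centre
    if abs(g - centre) < timeline.dead_zone_halfwidth:
        return NOT_ASSIGNABLE
    t_pre = timeline.time_of(timeline.swap_frames[-1]) - 1e-6
    c_pre = float(timeline.field.concentration(g, t_pre))
    return STEP_UP if c_pre < 0.5 * timeline.c_max else STEP_DOWN


def detect_event(polarity: pd.DataFrame, traj: pd.DataFrame,
                 timeline: GradientTimeline,
                 cfg: ClassifierConfig | None = None
                 ) -> Optional[RepolarizationEvent]:
    """Scan one cell for a repolarization event after the final swap.

    ``polarity`` needs columns fluor_frame, frame, polarity_class (one
    cell); ``traj`` the cell-channel pose rows of the same cell.  The
    scan horizon runs from the first frame of the new gradient to the end
    of the track.  Returns the earliest qualifying event or None.

    Two admissibility guards reject records an annotator could not have
    verified: the cell must have fluorescence coverage before the swap
    (otherwise the pre-existing-localization veto cannot be assessed),
    and its measured length must stay within ``max_length_dev`` of the
    track median across the swap (large excursions are the signature of a
    transient merge with a neighbouring cell, whose fluorescence would
    contaminate the profile).
    """
    cfg = cfg or ClassifierConfig()
    if not timeline.swap_frames:
        return None
    swap_start = timeline.swap_frames[-1]
    polarity = polarity.sort_values("fluor_frame")
    traj = traj.sort_values("frame")
    if traj.empty:
        return None
    cell_id = int(traj.cell_id.iloc[0]) if "cell_id" in traj else -1
    if not (polarity.frame < swap_start).any():
        return None  # no pre-swap coverage: veto unassessable
    if "length_um" in traj:
        lengths = traj.length_um.to_numpy(dtype=float)
        med = np.median(lengths)
        if med > 0 and np.max(np.abs(lengths - med)) / med > \
                cfg.max_length_dev:
            logger.debug("cell %s: unstable length (neighbour contact); "
                         "not assignable", cell_id)
            return None

    init_class, post_division = initial_polarity(polarity, timeline,
                                                 cfg.init_window)
    init_pole = None
    pre = _pre_swap_classes(polarity, swap_start, cfg.init_window)
    if init_class == "unipolar":
        uni = [c for c in pre if c in (UNIPOLAR_POLE1, UNIPOLAR_POLE2)]
        if uni:
            init_pole = 1 if uni[-1] == UNIPOLAR_POLE1 else 2

    # --- trigger A: polarity on the fluorescence clock ---------------------
    post = polarity[polarity.frame >= swap_start].reset_index(drop=True)
    cand_a = None  # (cell_frame, pole, fluor_frame)
    classes = post.polarity_class.to_numpy()
    for i in range(len(post)):
        c = classes[i]
        if c not in (UNIPOLAR_POLE1, UNIPOLAR_POLE2):
            continue
        pole = 1 if c == UNIPOLAR_POLE1 else 2
        if init_pole is not None and pole == init_pole:
            continue
        if _veto_pole(polarity, swap_start, pole, cfg.init_window,
                      cfg.a_min_count):
            continue
        window = classes[i:i + cfg.a_window]
        if np.sum(window == c) >= cfg.a_min_count:
            cand_a = (int(post.frame.iloc[i]), pole,
                      int(post.fluor_frame.iloc[i]))
            break

    # --- trigger B: movement on the cell-channel clock ---------------------
    cand_b = None  # (cell_frame, pole)
    frames = traj.frame.to_numpy()
    g = timeline.gradient_coordinate(traj.x_um.to_numpy(),
                                     traj.y_um.to_numpy())
    steps = np.diff(g)
    for j in range(1, len(steps)):
        k = frames[j]  # frame at the end of step j-1 -> j
        if k < swap_start:
            continue
        window = steps[j - 1:j - 1 + cfg.b_steps]
        if len(window) < cfg.b_steps:
            break
        if np.all(np.abs(window) >= cfg.cell_width) and \
                len(set(np.sign(window))) == 1:
            m = float(np.sign(window[0]))
            row = traj.iloc[j]
            theta = float(row.orientation_rad)
            axis_g = float(timeline.gradient_coordinate(np.cos(theta),
                                                        np.sin(theta)))
            if axis_g == 0:
                continue  # body orthogonal to the gradient: pole undefined
            pole = 1 if m * axis_g > 0 else 2
            if _veto_pole(polarity, swap_start, pole, cfg.init_window,
                          cfg.a_min_count):
                continue
            cand_b = (int(k), pole)
            break

    if cand_a is None and cand_b is None:
        return None
    if cand_b is None or (cand_a is not None and cand_a[0] <= cand_b[0]):
        event_frame, pole, fluor_frame = cand_a
        trigger = POLARITY_FIRST
        window_end = event_frame
    else:
        event_frame, pole = cand_b
        fluor_frame = None
        trigger = MOVEMENT_FIRST
        window_end = event_frame - 1  # the scripted movement is the event

    ok, reason = stationary_window_check(traj, timeline, window_end,
                                         cfg.cell_width, cfg.min_preceding)
    if not ok:
        logger.debug("cell %s: candidate at frame %d rejected (%s)",
                     cell_id, event_frame, reason)
        return None

    pose_rows = traj[traj.frame <= event_frame]
    pose = pose_rows.iloc[-1]
    t_event = timeline.time_of(event_frame)
    direction = classify_correctness(pole, pose, timeline, t_event)
    # pre-swap position decides the temporal stimulus
    pre_rows = traj[traj.frame < swap_start]
    ref = pre_rows.iloc[-1] if len(pre_rows) else traj.iloc[0]
    temporal = assign_temporal_change(float(ref.x_um), float(ref.y_um),
                                      timeline)
    return RepolarizationEvent(
        cell_id=cell_id, event_frame=int(event_frame), t_min=t_event,
        trigger=trigger, initial_polarity=init_class, new_leading_pole=pole,
        direction_call=direction, temporal_change=temporal,
        post_division=post_division, event_fluor_frame=fluor_frame)


def detect_events(poses: pd.DataFrame, polarity: pd.DataFrame,
                  timeline: GradientTimeline,
                  cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """Run :func:`detect_event` over every cell present in both tables."""
    cfg = cfg or ClassifierConfig()
    rows = []
    pol_groups = dict(tuple(polarity.groupby("cell_id")))
    for cid, traj in poses.groupby("cell_id"):
        pol = pol_groups.get(cid)
        if pol is None or pol.empty:
            continue
        ev = detect_event(pol, traj, timeline, cfg)
        if ev is not None:
            rows.append(ev.as_row())
    cols = ["cell_id", "event_frame", "event_fluor_frame", "t_min", "trigger",
            "initial_polarity", "new_leading_pole", "direction_call",
            "temporal_change", "post_division"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _table(events: pd.DataFrame, by: str) -> pd.DataFrame:
    rows = []
    for key, grp in events.groupby(by):
        n_c = int((grp.direction_call == CORRECT).sum())
        n_i = int((grp.direction_call == INCORRECT).sum())
        n = n_c + n_i
        if n == 0:
            continue
        lo, hi = proportion_ci(n_c, n)
        rows.append({by: key, "n_correct": n_c, "n_incorrect": n_i,
                     "proportion_correct": n_c / n, "ci_low": lo,
                     "ci_high": hi,
                     "p_binomial": exact_binomial_test(n_c, n, 0.5)})
    return pd.DataFrame(rows)


def summarize_events(events: pd.DataFrame) -> dict:
    """Contingency summaries of classified events.

    Returns overall correct/incorrect counts and their ratio, plus
    breakdowns by initial polarity and by temporal change, each with
    Wilson 95 % intervals on the proportion correct and an exact
    two-sided binomial test against equal abundance.  An empty event
    table yields empty tables and no test.
    """
    if events.empty:
        return {"overall": {"n_correct": 0, "n_incorrect": 0, "ratio": np.nan},
                "by_initial_polarity": pd.DataFrame(),
                "by_temporal_change": pd.DataFrame()}
    n_c = int((events.direction_call == CORRECT).sum())
    n_i = int((events.direction_call == INCORRECT).sum())
    overall = {"n_correct": n_c, "n_incorrect": n_i,
               "ratio": (n_c / n_i) if n_i else np.inf}
    if n_c + n_i:
        lo, hi = proportion_ci(n_c, n_c + n_i)
        overall.update({"proportion_correct": n_c / (n_c + n_i),
                        "ci_low": lo, "ci_high": hi,
                        "p_binomial": exact_binomial_test(n_c, n_c + n_i, 0.5)})
    return {"overall": overall,
            "by_initial_polarity": _table(events, "initial_polarity"),
            "by_temporal_change": _table(events, "temporal_change")}


def events_from_counts(n_correct: int, n_incorrect: int,
                       initial_polarity: str = "unipolar") -> pd.DataFrame:
    """Build a minimal event table from summary counts (for re-analysing
    published totals)."""
    rows = [{"cell_id": i, "event_frame": 0, "event_fluor_frame": 0,
             "t_min": 0.0, "trigger": POLARITY_FIRST,
             "initial_polarity": initial_polarity, "new_leading_pole": 1,
             "direction_call": CORRECT if i < n_correct else INCORRECT,
             "temporal_change": NOT_ASSIGNABLE, "post_division": False}
            for i in range(n_correct + n_incorrect)]
    return pd.DataFrame(rows)
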