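"""Synthetic time-lapse microscopy of surface-attached twitching bacteria.

Generates dual-channel (plus dye) image stacks and complete ground-truth
tables emulating microfluidic chemotaxis experiments on rod-shaped cells:

* rod cells (~0.9 µm wide, lengths 2-3.5 µm) rendered as blurred
  spherocylinders, creeping along their body axis at ~0.2 µm/min with rare
  ~20x single-frame jumps and Poisson-distributed reversals;
* a stationary subpopulation (~5-10 %) with sub-pixel jitter;
* polar fluorescent foci with nonpolar / unipolar / bipolar states, and
  scripted repolarization events (polarity-first or movement-first);
* asynchronous channels: the cell channel at 7.5 frames/min and the
  fluorescence/dye channels at an integer subsampling of it (default
  0.5 frames/min), sharing one clock;
* an analytic concentration field (alternating cross-channel gradient,
  advected front, or uniform switching) sampled into the dye channel.

Every output is a deterministic function of (config, seed).  The scripted
polarity timeline is intentionally static for non-event cells: spontaneous
repolarization only enters through explicit event scripts, so an
event-free run is a true negative control for the event classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

from .gradient_models import (
    ConcentrationField,
    GradientDesign,
    advected_front_field,
    alternating_dualflow_field,
    concentration_to_intensity,
    dual_flow_design,
    switching_field,
    switching_design,
    taylor_aris_design,
)
from .polarity_profiler import BIPOLAR, NONPOLAR, UNIPOLAR_POLE1, UNIPOLAR_POLE2

logger = logging.getLogger(__name__)

CORRECT = "correct"
INCORRECT = "incorrect"
STEP_UP = "step_up"
STEP_DOWN = "step_down"
NOT_ASSIGNABLE = "not_assignable"


@dataclass
class EventSpec:
    """One scripted repolarization event.

    ``event_fluor_frame`` is the fluorescence-frame index at which the new
    unipolar localization appears (polarity trigger) or at which the cell
    moves off (movement trigger).  ``correct`` selects whether the new
    leading pole faces higher concentration after the swap.
    ``initial_class`` is the coarse pre-swap polarity (nonpolar / unipolar /
    bipolar); drawn at random when omitted.
    """

    cell_id: int
    event_fluor_frame: int
    correct: bool = True
    trigger: str = "polarity"  # "polarity" | "movement"
    initial_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trigger not in ("polarity", "movement"):
            raise ValueError("trigger must be 'polarity' or 'movement'")
        if self.initial_class not in (None, "nonpolar", "unipolar", "bipolar"):
            raise ValueError("initial_class must be nonpolar/unipolar/bipolar")


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic experiment.

    Defaults encode the experimental conditions the package analyses: cell
    channel at 7.5 frames/min, fluorescence at 0.5 frames/min, mean
    twitching speed 0.2 µm/min with ~20x pili-release jumps, a 5-10 %
    stationary fraction, 0.9 µm cell width and 0.1 µm/px optics.
    """

    scenario_kind: str = "alternating_gradient"
    n_cells: int = 200
    field_size: tuple = (800, 800)        # (rows, cols) px
    pixel_size: float = 0.1               # µm / px
    frame_rate_cell_channel: float = 7.5  # frames / min
    frame_rate_fluor_channel: float = 0.5
    duration: float = 90.0                # min
    stationary_fraction: float = 0.075
    mean_speed: float = 0.2               # µm / min
    jump_speed_factor: float = 20.0
    jump_probability_per_frame: float = 0.002
    reversal_rate_baseline: float = 0.005  # events / min
    cell_width: float = 0.9               # µm
    cell_length_range: tuple = (2.0, 3.5)  # µm
    focus_sigma: float = 0.15             # µm
    noise_model: str = "gaussian"         # none | gaussian | poisson
    noise_sigma: Optional[float] = None   # default 2 % of focus amplitude
    gradient_params: GradientDesign = dc_field(default_factory=dual_flow_design)
    swap_times: tuple = ()
    repolarization_spec: tuple = ()
    rng_seed: int = 0
    # rendering / secondary knobs
    gradient_axis: tuple = (0.0, 1.0)
    stationary_jitter: float = 0.02       # µm per frame, isotropic
    cell_level: float = 120.0             # cell-channel amplitude (a.u.)
    cyto_level: float = 20.0              # cytoplasmic fluorescence (a.u.)
    focus_amplitude: float = 4.0          # focus peak / cyto_level
    blur_sigma: float = 0.1               # µm, optical blur of both channels
    dye_gain: float = 50.0                # a.u. per mM
    dye_offset: float = 10.0              # a.u.
    class_proportions: tuple = (0.15, 0.55, 0.30)  # nonpolar/unipolar/bipolar
    border_margin: float = 5.0            # µm keep-out at the field edge

    def __post_init__(self) -> None:
        if not 0.0 <= self.stationary_fraction <= 1.0:
            raise ValueError("stationary_fraction must be in [0, 1]")
        if self.frame_rate_fluor_channel > self.frame_rate_cell_channel:
            raise ValueError("fluorescence frame rate must not exceed the "
                             "cell-channel frame rate")
        for name in ("pixel_size", "duration", "cell_width", "focus_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mean_speed", "jump_speed_factor",
                     "jump_probability_per_frame", "reversal_rate_baseline",
                     "stationary_jitter"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.cell_length_range[0] <= 0 or \
                self.cell_length_range[1] < self.cell_length_range[0]:
            raise ValueError("invalid cell_length_range")
        ratio = self.frame_rate_cell_channel / self.frame_rate_fluor_channel
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("cell/fluorescence frame-rate ratio must be an "
                             "integer (shared acquisition clock)")
        if any(t < 0 or t >= self.duration for t in self.swap_times):
            raise ValueError("swap_times must lie within [0, duration)")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none/gaussian/poisson")
        self.repolarization_spec = tuple(
            e if isinstance(e, EventSpec) else EventSpec(**e)
            for e in self.repolarization_spec)

    # --- derived quantities -------------------------------------------------
    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_cell_channel

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate_cell_channel))

    @property
    def fluor_every(self) -> int:
        return int(round(self.frame_rate_cell_channel /
                         self.frame_rate_fluor_channel))

    @property
    def fluor_frames(self) -> np.ndarray:
        """Cell-channel frame indices at which fluorescence is acquired."""
        return np.arange(0, self.n_frames, self.fluor_every)

    @property
    def extent(self) -> tuple:
        """Field size in µm, (width_x, height_y)."""
        return (self.field_size[1] * self.pixel_size,
                self.field_size[0] * self.pixel_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gradient_params"] = self.gradient_params.to_dict()
        d["repolarization_spec"] = [asdict(e) for e in self.repolarization_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if isinstance(d.get("gradient_params"), dict):
            d["gradient_params"] = GradientDesign.from_dict(d["gradient_params"])
        for key in ("field_size", "cell_length_range", "gradient_axis",
                    "swap_times", "class_proportions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "repolarization_spec" in d:
            d["repolarization_spec"] = tuple(
                EventSpec(**e) if isinstance(e, dict) else e
                for e in d["repolarization_spec"])
        return cls(**d)


def default_event_script(n_correct: int = 9, n_incorrect: int = 3,
                         first_fluor_frame: int = 24,
                         n_movement: int = 3) -> tuple:
    """A mixed script of repolarization events for closure testing.

    Events are assigned to cell ids 0..n-1, staggered over consecutive
    fluorescence frames, cycling through nonpolar/unipolar/bipolar initial
    polarities; the last ``n_movement`` events use the movement trigger
    (the cell moves off before its polarity change becomes visible).
    """
    initials = ["nonpolar", "unipolar", "bipolar"]
    n = n_correct + n_incorrect
    specs = []
    for i in range(n):
        trigger = "movement" if i >= n - n_movement else "polarity"
        specs.append(EventSpec(
            cell_id=i, event_fluor_frame=first_fluor_frame + (i % 5),
            correct=i < n_correct, trigger=trigger,
            initial_class=initials[i % 3] if trigger == "polarity" else None))
    return tuple(specs)


def alternating_gradient_scenario(n_cells: int = 200, duration: float = 90.0,
                                  swap_times: Sequence[float] = (44.0,),
                                  events: Sequence[EventSpec] = (),
                                  rng_seed: int = 0,
                                  noise_model: str = "none",
                                  **overrides) -> ScenarioConfig:
    """Alternating cross-channel gradient (2 mM source, 100 µm length
    scale) whose orientation flips at each swap time."""
    return ScenarioConfig(
        scenario_kind="alternating_gradient", n_cells=n_cells,
        duration=duration, swap_times=tuple(swap_times),
        repolarization_spec=tuple(events), rng_seed=rng_seed,
        gradient_params=dual_flow_design(), noise_model=noise_model,
        **overrides)


def taylor_aris_scenario(n_cells: int = 100, duration: float = 180.0,
                         rng_seed: int = 0, **overrides) -> ScenarioConfig:
    """Dispersion-front scenario: a metre-scale gradient sweeps past the
    cells mid-run; cell channel only matters (1.16 -> 0.84 mM)."""
    return ScenarioConfig(
        scenario_kind="taylor_aris", n_cells=n_cells, duration=duration,
        gradient_params=taylor_aris_design(), rng_seed=rng_seed, **overrides)


def switching_scenario(n_cells: int = 100, duration: float = 180.0,
                       interval: float = 15.0, rng_seed: int = 0,
                       **overrides) -> ScenarioConfig:
    """Sharp-switch scenario: uniform concentration alternating between
    1.16 and 0.84 mM every ``interval`` min over timescale tau = 1.5 min."""
    swaps = tuple(np.arange(interval, duration, interval))
    return ScenarioConfig(
        scenario_kind="switching", n_cells=n_cells, duration=duration,
        swap_times=swaps, gradient_params=switching_design(),
        rng_seed=rng_seed, **overrides)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Scripted truth behind one simulation.

    ``poses``: per (cell, cell frame) positions and true motility class.
    ``polarity``: per (cell, fluorescence frame) true polarity class.
    ``events``: scripted repolarization events with their true labels.
    ``cells``: static per-cell attributes (orientation, length, ...).
    """

    poses: pd.DataFrame
    polarity: pd.DataFrame
    events: pd.DataFrame
    cells: pd.DataFrame
    field: ConcentrationField

    def validate(self) -> None:
        pose_keys = set(zip(self.poses.cell_id, self.poses.frame))
        for _, ev in self.events.iterrows():
            if (ev.cell_id, ev.event_frame) not in pose_keys:
                raise AssertionError("event refers to a missing pose")
        allowed = {NONPOLAR, UNIPOLAR_POLE1, UNIPOLAR_POLE2, BIPOLAR}
        if not set(self.polarity.polarity_class).issubset(allowed):
            raise AssertionError("unknown polarity class in ground truth")


@dataclass
class SimulationResult:
    config: ScenarioConfig
    cell_stack: np.ndarray   # (n_frames, H, W) float32
    fluor_stack: np.ndarray  # (n_fluor, H, W) float32
    dye_stack: np.ndarray    # (n_fluor, H, W) float32
    fluor_frames: np.ndarray
    truth: GroundTruth

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.config.n_frames) * self.config.dt


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------

def _track_arrays(rng: np.random.Generator, config: ScenarioConfig,
                  start: np.ndarray, theta: float, length: float,
                  stationary: bool,
                  move_script: Optional[tuple] = None) -> dict:
    """Simulate one cell's centroid series over all cell-channel frames.

    ``move_script`` (frame0, n_steps, step_vec) forces an initially
    stationary cell to step deterministically (scripted movement-first
    repolarization); outside the scripted window the cell is stationary.
    """
    n = config.n_frames
    dt = config.dt
    axis = np.array([np.cos(theta), np.sin(theta)])
    pos = np.empty((n, 2))
    is_jump = np.zeros(n, dtype=bool)
    is_reversal = np.zeros(n, dtype=bool)
    is_reflection = np.zeros(n, dtype=bool)

    if stationary or move_script is not None:
        jitter = (rng.normal(0.0, config.stationary_jitter, size=(n, 2))
                  if config.stationary_jitter > 0 else np.zeros((n, 2)))
        anchor = np.tile(start, (n, 1))
        if move_script is not None:
            f0, n_steps, step_vec = move_script
            for k in range(n_steps):
                anchor[f0 + 1 + k:] += step_vec
        pos[:] = anchor + jitter
    else:
        p_rev = -np.expm1(-config.reversal_rate_baseline * dt)
        direction = 1 if rng.random() < 0.5 else -1
        w, h = config.extent
        lo = config.border_margin
        pos[0] = start
        for k in range(1, n):
            if rng.random() < p_rev:
                direction = -direction
                is_reversal[k] = True
            jump = rng.random() < config.jump_probability_per_frame
            is_jump[k] = jump
            speed = config.mean_speed * (config.jump_speed_factor if jump
                                         else 1.0)
            step = direction * speed * dt * axis
            nxt = pos[k - 1] + step
            if not (lo <= nxt[0] <= w - lo and lo <= nxt[1] <= h - lo):
                # reflect at the border keep-out; flips the travel
                # direction but is not a stochastic reversal
                direction = -direction
                is_reflection[k] = True
                nxt = pos[k - 1] + direction * speed * dt * axis
            pos[k] = nxt
    return {"pos": pos, "is_jump": is_jump, "is_reversal": is_reversal,
            "is_reflection": is_reflection,
            "orientation": np.full(n, theta % np.pi)}


def simulate_twitching_track(config: ScenarioConfig,
                             cell_seed: int) -> pd.DataFrame:
    """Simulate one ground-truth trajectory from the scenario parameters.

    The cell's attributes (start position, orientation, length, stationary
    vs motile) are drawn from the config distributions using a stream
    derived from ``(config.rng_seed, cell_seed)``, so identical arguments
    reproduce the identical track.  Motile cells creep at ``mean_speed``
    along the body axis, jump ``jump_speed_factor`` times faster in rare
    single frames, and reverse as a Poisson process at
    ``reversal_rate_baseline``; stationary cells receive only isotropic
    sub-pixel jitter.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.rng_seed), 101, int(cell_seed)]))
    w, h = config.extent
    m = config.border_margin
    start = np.array([rng.uniform(m, w - m), rng.uniform(m, h - m)])
    theta = rng.uniform(0.15, np.pi - 0.15)
    length = rng.uniform(*config.cell_length_range)
    stationary = rng.random() < config.stationary_fraction
    arrays = _track_arrays(rng, config, start, theta, length, stationary)
    n = config.n_frames
    return pd.DataFrame({
        "frame": np.arange(n),
        "t_min": np.arange(n) * config.dt,
        "x_um": arrays["pos"][:, 0],
        "y_um": arrays["pos"][:, 1],
        "orientation_rad": arrays["orientation"],
        "length_um": np.full(n, length),
        "width_um": np.full(n, config.cell_width),
        "motility_class": "stationary" if stationary else "motile",
        "is_jump": arrays["is_jump"],
        "is_reversal": arrays["is_reversal"],
        "is_reflection": arrays["is_reflection"],
    })


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_capsule(img: np.ndarray, x: float, y: float, length: float,
                 width: float, theta: float, level: float,
                 pixel_size: float) -> None:
    """Add a constant-intensity spherocylinder footprint (in place)."""
    s = pixel_size
    half_seg = max(0.0, 0.5 * (length - width))
    axis = np.array([np.cos(theta), np.sin(theta)])
    pad = 0.5 * width + 2.0 * s
    reach = half_seg + pad
    r0 = max(0, int((y - reach) / s))
    r1 = min(img.shape[0], int((y + reach) / s) + 2)
    c0 = max(0, int((x - reach) / s))
    c1 = min(img.shape[1], int((x + reach) / s) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    px = (cols + 0.5) * s - x
    py = (rows + 0.5) * s - y
    proj = np.clip(px * axis[0] + py * axis[1], -half_seg, half_seg)
    dx = px - proj * axis[0]
    dy = py - proj * axis[1]
    inside = dx * dx + dy * dy <= (0.5 * width) ** 2
    img[rows[inside], cols[inside]] += level


def _add_gaussian(img: np.ndarray, x: float, y: float, amp: float,
                  sigma: float, pixel_size: float) -> None:
    """Add an isotropic 2-D Gaussian focus (in place)."""
    s = pixel_size
    reach = 4.0 * sigma
    r0 = max(0, int((y - reach) / s))
    r1 = min(img.shape[0], int((y + reach) / s) + 2)
    c0 = max(0, int((x - reach) / s))
    c1 = min(img.shape[1], int((x + reach) / s) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    px = (cols + 0.5) * s - x
    py = (rows + 0.5) * s - y
    img[rows, cols] += amp * np.exp(-(px * px + py * py) / (2.0 * sigma ** 2))


def _pole_positions(x: float, y: float, length: float, width: float,
                    theta: float) -> dict:
    """Focus anchor of each pole: inset width/4 from the pole tip, since
    polar accumulations peak near (not at) the very tip of the pole."""
    axis = np.array([np.cos(theta), np.sin(theta)])
    off = 0.5 * length - 0.25 * width
    return {1: np.array([x, y]) + off * axis,
            2: np.array([x, y]) - off * axis}


def _bright_poles(polarity_class: str, amp_factor: float) -> list:
    """Map a polarity class to (pole, relative amplitude) focus list."""
    if polarity_class == NONPOLAR:
        return []
    if polarity_class == UNIPOLAR_POLE1:
        return [(1, amp_factor)]
    if polarity_class == UNIPOLAR_POLE2:
        return [(2, amp_factor)]
    if polarity_class == BIPOLAR:
        return [(1, amp_factor), (2, amp_factor)]
    raise ValueError(f"unknown polarity class {polarity_class!r}")


def render_frame(poses, polarity_states, field: Optional[ConcentrationField],
                 config: ScenarioConfig, t: float = 0.0,
                 noise_rng: Optional[np.random.Generator] = None) -> tuple:
    """Render one (cell, fluorescence, dye) image triplet.

    ``poses`` is an iterable of mappings with keys x_um, y_um, length_um,
    width_um, orientation_rad (and cell_id).  ``polarity_states`` maps
    cell_id to (polarity_class, amplitude_factor, lateral_offset_um); cells
    missing from it render without foci.  The dye channel is the affine map
    of the concentration field at each pixel (None field -> zeros).
    Overlapping cells are permitted; overlaps are logged, not resolved.
    """
    h_px, w_px = config.field_size
    s = config.pixel_size
    cell_img = np.zeros((h_px, w_px), dtype=np.float32)
    fluor_img = np.zeros((h_px, w_px), dtype=np.float32)

    poses = list(poses)
    w_um, h_um = config.extent
    for p in poses:
        if not (0 <= p["x_um"] <= w_um and 0 <= p["y_um"] <= h_um):
            raise ValueError("pose outside the field of view")

    for p in poses:
        _add_capsule(cell_img, p["x_um"], p["y_um"], p["length_um"],
                     p["width_um"], p["orientation_rad"], config.cell_level, s)
        _add_capsule(fluor_img, p["x_um"], p["y_um"], p["length_um"],
                     p["width_um"], p["orientation_rad"], config.cyto_level, s)
    n_overlap = int(np.sum(cell_img > 1.5 * config.cell_level))
    if n_overlap:
        logger.debug("render_frame t=%.2f: %d overlapping pixels", t, n_overlap)

    perp = None
    for p in poses:
        state = polarity_states.get(p.get("cell_id"), None) \
            if polarity_states else None
        if state is None:
            continue
        pclass, amp_factor, lateral = state
        theta = p["orientation_rad"]
        perp = np.array([-np.sin(theta), np.cos(theta)])
        anchors = _pole_positions(p["x_um"], p["y_um"], p["length_um"],
                                  p["width_um"], theta)
        for pole, rel_amp in _bright_poles(pclass, amp_factor):
            cx, cy = anchors[pole] + lateral * perp
            _add_gaussian(fluor_img, cx, cy,
                          rel_amp * config.focus_amplitude * config.cyto_level,
                          config.focus_sigma, s)

    blur_px = config.blur_sigma / s
    if blur_px > 0:
        cell_img = gaussian_filter(cell_img, blur_px)
        fluor_img = gaussian_filter(fluor_img, blur_px)

    if field is not None:
        g = (np.arange(h_px) + 0.5) * s  # gradient axis = +y (rows)
        conc = np.asarray(field.concentration(g, t), dtype=np.float32)
        dye_img = np.broadcast_to(
            concentration_to_intensity(conc, (config.dye_gain,
                                              config.dye_offset))[:, None],
            (h_px, w_px)).astype(np.float32)
    else:
        dye_img = np.zeros((h_px, w_px), dtype=np.float32)

    if config.noise_model != "none" and noise_rng is not None:
        sigma = config.noise_sigma
        if sigma is None:
            sigma = 0.02 * config.focus_amplitude * config.cyto_level
        if config.noise_model == "gaussian":
            cell_img = cell_img + noise_rng.normal(
                0.0, sigma, cell_img.shape).astype(np.float32)
            fluor_img = fluor_img + noise_rng.normal(
                0.0, sigma, fluor_img.shape).astype(np.float32)
        elif config.noise_model == "poisson":
            scale = max(sigma, 1e-6)
            fluor_img = (noise_rng.poisson(
                np.maximum(fluor_img, 0.0) / scale) * scale).astype(np.float32)
            cell_img = (noise_rng.poisson(
                np.maximum(cell_img, 0.0) / scale) * scale).astype(np.float32)
    return cell_img, fluor_img, dye_img


# ---------------------------------------------------------------------------
# Experiment assembly
# ---------------------------------------------------------------------------

def _build_field(config: ScenarioConfig) -> ConcentrationField:
    centre = 0.5 * config.extent[1]  # gradient axis = +y
    if config.scenario_kind == "alternating_gradient":
        return alternating_dualflow_field(config.gradient_params, centre,
                                          config.swap_times)
    if config.scenario_kind == "taylor_aris":
        return advected_front_field(config.gradient_params,
                                    arrival_time=0.5 * config.duration,
                                    position=centre)
    if config.scenario_kind == "switching":
        return switching_field(config.gradient_params, config.swap_times)
    raise ValueError(f"unknown scenario_kind {config.scenario_kind!r}")


def _grid_positions(config: ScenarioConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of candidate centroids inside the border keep-out."""
    w, h = config.extent
    m = config.border_margin
    n_side = int(np.ceil(np.sqrt(1.3 * config.n_cells)))
    xs = np.linspace(m, w - m, n_side)
    ys = np.linspace(m, h - m, n_side)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    spacing = min(xs[1] - xs[0], ys[1] - ys[0]) if n_side > 1 else m
    if spacing < 4.0:
        logger.warning("cell spacing %.2f µm; overlaps likely", spacing)
    pts = pts + rng.uniform(-0.15 * spacing, 0.15 * spacing, pts.shape)
    rng.shuffle(pts)
    return pts


def _post_swap_sign(field: ConcentrationField, swap_time: float) -> int:
    return field.epoch_sign(swap_time + 1e-9)


def simulate_experiment(config: ScenarioConfig) -> SimulationResult:
    """Run the full generator: tracks, polarity timeline, scripted events,
    rendered stacks, and ground-truth tables.

    Scripted events are realized so that they satisfy the event definition
    used downstream: the cell is stationary through the monitoring window,
    its pre-swap polarity is held constant, and from the event frame onward
    it is unipolar at the scripted new pole (polarity trigger) or it steps
    >= 1.1 cell widths per frame along the gradient for two frames
    (movement trigger, with the polarity change following two fluorescence
    frames later).
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.rng_seed), 1]))
    n_frames = config.n_frames
    fluor_frames = config.fluor_frames
    n_fluor = len(fluor_frames)
    field = _build_field(config)
    centre = field.centre
    dead_zone = 0.1 * config.gradient_params.width_scale

    events = list(config.repolarization_spec)
    event_by_cell = {}
    for ev in events:
        if ev.cell_id in event_by_cell:
            raise ValueError("at most one scripted event per cell")
        if ev.cell_id >= config.n_cells:
            raise ValueError("event cell_id beyond n_cells")
        if ev.event_fluor_frame >= n_fluor:
            raise ValueError("event beyond the last fluorescence frame")
        if config.swap_times:
            swap_frame = config.swap_times[-1] * config.frame_rate_cell_channel
            if fluor_frames[ev.event_fluor_frame] <= swap_frame:
                raise ValueError("scripted events must follow the last swap")
        elif config.scenario_kind == "alternating_gradient":
            raise ValueError("scripted events need at least one swap")
        event_by_cell[ev.cell_id] = ev

    # --- per-cell attributes ------------------------------------------------
    candidates = _grid_positions(config, rng)
    positions = np.empty((config.n_cells, 2))
    thetas = np.empty(config.n_cells)
    lengths = rng.uniform(*config.cell_length_range, size=config.n_cells)
    stationary = rng.random(config.n_cells) < config.stationary_fraction

    event_ids = sorted(event_by_cell)
    # Event cells: stationary, off the centreline dead zone, with body axes
    # well away from gradient-orthogonal so the up-gradient pole is defined.
    ok = np.abs(candidates[:, 1] - centre) >= dead_zone + 3.0
    ev_slots = np.flatnonzero(ok)
    if len(ev_slots) < len(event_ids):
        raise ValueError("field too small to place all scripted events")
    other_slots = [i for i in range(len(candidates)) if i not in
                   set(ev_slots[:len(event_ids)])]
    for j, cid in enumerate(event_ids):
        positions[cid] = candidates[ev_slots[j]]
        thetas[cid] = rng.uniform(0.65, np.pi - 0.65)
        stationary[cid] = True
    rest = [c for c in range(config.n_cells) if c not in event_by_cell]
    if len(other_slots) < len(rest):
        raise ValueError("not enough grid positions for n_cells")
    # keep non-event cells clear of scripted movement paths
    keep = []
    move_clear = [positions[ev.cell_id] for ev in events
                  if ev.trigger == "movement"]
    for slot in other_slots:
        p = candidates[slot]
        if any(np.linalg.norm(p - q) < 7.0 for q in move_clear):
            continue
        keep.append(slot)
    if len(keep) < len(rest):
        keep = other_slots  # fall back: allow proximity, log it
        logger.warning("movement-path clearance relaxed; overlaps possible")
    for j, cid in enumerate(rest):
        positions[cid] = candidates[keep[j]]
        thetas[cid] = rng.uniform(0.15, np.pi - 0.15)

    # Motile cells translate along their fixed body axis, so each sweeps a
    # known line segment.  Steer those corridors clear of scripted-event
    # cells: a merge with a passing neighbour would break the event cell's
    # track and contaminate its fluorescence profile.
    if event_ids:
        ev_pos = positions[event_ids]
        reach = config.mean_speed * config.duration + 5.0
        clearance = 0.5 * max(config.cell_length_range) + config.cell_width \
            + 1.5

        def _corridor_clear(p, th):
            a = np.array([np.cos(th), np.sin(th)])
            rel = ev_pos - p
            proj = np.clip(rel @ a, -reach, reach)
            d = np.linalg.norm(rel - proj[:, None] * a[None, :], axis=1)
            return np.all(d >= clearance)

        for cid in rest:
            if stationary[cid]:
                continue
            for _ in range(20):
                if _corridor_clear(positions[cid], thetas[cid]):
                    break
                thetas[cid] = rng.uniform(0.15, np.pi - 0.15)
            else:
                stationary[cid] = True  # no clear heading: park the cell

    # --- polarity scripting -------------------------------------------------
    base_class = rng.choice(
        [NONPOLAR, "unipolar", BIPOLAR], size=config.n_cells,
        p=config.class_proportions)
    uni_pole = rng.choice([1, 2], size=config.n_cells)
    amp_factor = rng.uniform(0.8, 1.2, size=config.n_cells)
    lateral = rng.uniform(-0.3, 0.3, size=config.n_cells)

    s2 = _post_swap_sign(field, config.swap_times[-1]) if config.swap_times \
        else 1
    new_pole = np.zeros(config.n_cells, dtype=int)
    for cid, ev in event_by_cell.items():
        axis_g = np.sin(thetas[cid])  # gradient axis = +y
        pole1_up = s2 * axis_g > 0
        new_pole[cid] = 1 if (ev.correct == pole1_up) else 2
        if ev.initial_class is None:
            ev.initial_class = ["nonpolar", "unipolar",
                                "bipolar"][int(rng.integers(3))]
        base_class[cid] = ev.initial_class if ev.initial_class != "unipolar" \
            else "unipolar"
        if ev.initial_class == "unipolar":
            uni_pole[cid] = 3 - new_pole[cid]  # veto-safe: other pole

    def coarse_to_class(cid: int) -> str:
        c = base_class[cid]
        if c == "unipolar":
            return UNIPOLAR_POLE1 if uni_pole[cid] == 1 else UNIPOLAR_POLE2
        return c

    polarity_classes = np.empty((config.n_cells, n_fluor), dtype=object)
    for cid in range(config.n_cells):
        polarity_classes[cid, :] = coarse_to_class(cid)
    for cid, ev in event_by_cell.items():
        onset = ev.event_fluor_frame + (2 if ev.trigger == "movement" else 0)
        newc = UNIPOLAR_POLE1 if new_pole[cid] == 1 else UNIPOLAR_POLE2
        polarity_classes[cid, onset:] = newc

    # --- trajectories -------------------------------------------------------
    tracks = []
    for cid in range(config.n_cells):
        crng = np.random.default_rng(np.random.SeedSequence(
            [int(config.rng_seed), 101, cid]))
        move_script = None
        ev = event_by_cell.get(cid)
        if ev is not None and ev.trigger == "movement":
            axis = np.array([np.cos(thetas[cid]), np.sin(thetas[cid])])
            axis_g = axis[1]
            m_dir = s2 if ev.correct else -s2
            step_g = 1.1 * config.cell_width
            step_vec = axis * (m_dir * np.sign(axis_g)) * (step_g /
                                                           abs(axis_g))
            f0 = int(fluor_frames[ev.event_fluor_frame])
            move_script = (f0 - 1, 2, step_vec)
        arr = _track_arrays(crng, config, positions[cid], thetas[cid],
                            lengths[cid], bool(stationary[cid]), move_script)
        n = n_frames
        tracks.append(pd.DataFrame({
            "cell_id": cid, "frame": np.arange(n),
            "t_min": np.arange(n) * config.dt,
            "x_um": arr["pos"][:, 0], "y_um": arr["pos"][:, 1],
            "orientation_rad": arr["orientation"],
            "length_um": lengths[cid], "width_um": config.cell_width,
            "motility_class": "stationary" if stationary[cid] else "motile",
            "is_jump": arr["is_jump"], "is_reversal": arr["is_reversal"],
            "is_reflection": arr["is_reflection"],
        }))
    poses = pd.concat(tracks, ignore_index=True)

    # --- ground-truth tables ------------------------------------------------
    pol_rows = []
    for cid in range(config.n_cells):
        for j, f in enumerate(fluor_frames):
            pol_rows.append((cid, j, int(f), f * config.dt,
                             polarity_classes[cid, j]))
    polarity = pd.DataFrame(pol_rows, columns=[
        "cell_id", "fluor_frame", "frame", "t_min", "polarity_class"])

    ev_rows = []
    for cid in event_ids:
        ev = event_by_cell[cid]
        f_cell = int(fluor_frames[ev.event_fluor_frame])
        g = positions[cid][1]
        if abs(g - centre) < dead_zone:
            temporal = NOT_ASSIGNABLE
        else:
            c_pre = float(field.concentration(
                g, config.swap_times[-1] - 1e-6)) if config.swap_times else \
                float(field.concentration(g, 0.0))
            temporal = STEP_UP if c_pre < 0.5 * field.c_max else STEP_DOWN
        ev_rows.append({
            "cell_id": cid, "event_fluor_frame": ev.event_fluor_frame,
            "event_frame": f_cell, "t_min": f_cell * config.dt,
            "trigger": ("polarity_first" if ev.trigger == "polarity"
                        else "movement_first"),
            "initial_polarity": ev.initial_class,
            "new_leading_pole": int(new_pole[cid]),
            "direction_call": CORRECT if ev.correct else INCORRECT,
            "temporal_change": temporal,
        })
    events_df = pd.DataFrame(ev_rows, columns=[
        "cell_id", "event_fluor_frame", "event_frame", "t_min", "trigger",
        "initial_polarity", "new_leading_pole", "direction_call",
        "temporal_change"])

    cells_df = pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "x0_um": positions[:, 0], "y0_um": positions[:, 1],
        "orientation_rad": thetas % np.pi, "length_um": lengths,
        "stationary": stationary, "base_class": base_class,
        "amp_factor": amp_factor, "lateral_offset_um": lateral,
    })

    truth = GroundTruth(poses, polarity, events_df, cells_df, field)
    truth.validate()

    # --- rendering ----------------------------------------------------------
    h_px, w_px = config.field_size
    # cell channel quantized to 8 bit (levels span 0..255): keeps the
    # full stack small; segmentation accuracy is blur-limited, not
    # quantization-limited
    cell_stack = np.zeros((n_frames, h_px, w_px), dtype=np.uint8)
    fluor_stack = np.zeros((n_fluor, h_px, w_px), dtype=np.float32)
    dye_stack = np.zeros((n_fluor, h_px, w_px), dtype=np.float32)
    by_frame = dict(tuple(poses.groupby("frame", sort=True)))
    fluor_index = {int(f): j for j, f in enumerate(fluor_frames)}
    for f in range(n_frames):
        t = f * config.dt
        frame_poses = by_frame[f].to_dict("records")
        noise_rng = np.random.default_rng(np.random.SeedSequence(
            [int(config.rng_seed), 777, f]))
        if f in fluor_index:
            j = fluor_index[f]
            states = {cid: (polarity_classes[cid, j], amp_factor[cid],
                            lateral[cid]) for cid in range(config.n_cells)}
            cimg, fimg, dimg = render_frame(frame_poses, states, field,
                                            config, t, noise_rng)
            fluor_stack[j] = fimg
            dye_stack[j] = dimg
        else:
            cimg, _, _ = render_frame(frame_poses, None, None, config, t,
                                      noise_rng)
        cell_stack[f] = np.clip(cimg, 0, 255).astype(np.uint8)
    return SimulationResult(config, cell_stack, fluor_stack, dye_stack,
                            np.asarray(fluor_frames), truth)


# ---------------------------------------------------------------------------
# I/O and validation helpers
# ---------------------------------------------------------------------------

def write_simulation(result: SimulationResult, outdir) -> dict:
    """Write TIFF stacks, ground-truth tables, config and metadata sidecar.

    Returns a dict of written paths.  One multi-page TIFF per channel
    (page = frame); tables as CSV with documented headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, stack in (("cell", result.cell_stack),
                        ("fluor", result.fluor_stack),
                        ("dye", result.dye_stack)):
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, stack, photometric="minisblack")
        paths[name] = p
    for name, df in (("poses", result.truth.poses),
                     ("polarity", result.truth.polarity),
                     ("events", result.truth.events),
                     ("cells", result.truth.cells)):
        p = outdir / f"truth_{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    cfg_path = outdir / "scenario.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=False)
    paths["config"] = cfg_path
    meta = {
        "seed": result.config.rng_seed,
        "units": {"length": "um", "time": "min", "concentration": "mM",
                  "angle": "rad from +x axis"},
        "frame_rate_cell_channel_per_min":
            result.config.frame_rate_cell_channel,
        "frame_rate_fluor_channel_per_min":
            result.config.frame_rate_fluor_channel,
        "pixel_size_um": result.config.pixel_size,
        "fluor_frames": [int(f) for f in result.fluor_frames],
    }
    meta_path = outdir / "metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    paths["metadata"] = meta_path
    return paths


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def match_poses_to_truth(detected: pd.DataFrame, truth_poses: pd.DataFrame,
                         max_dist: float = 1.0) -> pd.DataFrame:
    """Per-frame association of detected poses with ground-truth cells.

    For every frame, each detection is matched to the nearest true cell
    within ``max_dist`` (µm), one-to-one, closest pairs first.  Returns the
    detected table with added columns ``truth_cell`` (NaN when unmatched)
    and ``match_dist``.  Track identity plays no role, so linking errors do
    not propagate into per-frame evaluations.
    """
    from scipy.spatial import cKDTree

    out = detected.copy()
    out["truth_cell"] = np.nan
    out["match_dist"] = np.nan
    for f, det in detected.groupby("frame"):
        tru = truth_poses[truth_poses.frame == f]
        if det.empty or tru.empty:
            continue
        tree = cKDTree(tru[["x_um", "y_um"]].to_numpy())
        d, idx = tree.query(det[["x_um", "y_um"]].to_numpy())
        used = set()
        tru_ids = tru.cell_id.to_numpy()
        for k in np.argsort(d):
            if d[k] > max_dist or idx[k] in used:
                continue
            out.loc[det.index[k], "truth_cell"] = tru_ids[idx[k]]
            out.loc[det.index[k], "match_dist"] = d[k]
            used.add(idx[k])
    return out


def match_tracks_to_truth(detected: pd.DataFrame, truth_poses: pd.DataFrame,
                          frame: int = 0, max_dist: float = 1.5) -> dict:
    """Map detected track ids to ground-truth cell ids by centroid proximity
    at one frame.  Unmatched tracks are omitted."""
    from scipy.spatial import cKDTree

    det = detected[detected.frame == frame]
    tru = truth_poses[truth_poses.frame == frame]
    if det.empty or tru.empty:
        return {}
    tree = cKDTree(tru[["x_um", "y_um"]].to_numpy())
    d, idx = tree.query(det[["x_um", "y_um"]].to_numpy())
    mapping = {}
    used = set()
    order = np.argsort(d)
    det_ids = det.cell_id.to_numpy()
    tru_ids = tru.cell_id.to_numpy()
    for k in order:
        if d[k] > max_dist or tru_ids[idx[k]] in used:
            continue
        mapping[int(det_ids[k])] = int(tru_ids[idx[k]])
        used.add(tru_ids[idx[k]])
    return mapping
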