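"""Microfluidic concentration fields and gradient-design arithmetic.

Three stimulus geometries are modelled:

* an advected longitudinal front produced by shear dispersion in a long
  feed tube (a metre-scale gradient that sweeps past surface-attached
  cells, exposing them to a slow temporal ramp);
* a steady cross-channel (dual-flow) gradient formed by molecular
  diffusion between two co-flowing streams, with a ~100 µm length scale;
* an abrupt but smooth switch between two uniform concentrations on a
  timescale of ~1.5 min.

Units follow the package conventions: lengths in µm, time in minutes,
concentration in mM.  ``design_report`` reproduces the desk arithmetic
that relates the three scenarios (mean temporal gradient dC/dt, spatial
gradient dC/dx, gradient length scale L and the fold ratios between
scenarios).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import erf

logger = logging.getLogger(__name__)

#: Argument scaling of the erf front shape.  With S(z) = (1 + erf(kz))/2 and
#: k = sqrt(pi), S'(0) = 1 exactly, so the mid-front gradient of
#: C = C_MIN + (C_MAX - C_MIN) * S(x/L) equals (C_MAX - C_MIN)/L.  This makes
#: the nominal length scale L and the characteristic spatial gradient
#: mutually consistent by construction.
FRONT_SHAPE_CONST = math.sqrt(math.pi)


def _ramp(z):
    """Smooth monotone ramp S with S(-inf)=0, S(0)=1/2, S(inf)=1, S'(0)=1."""
    return 0.5 * (1.0 + erf(FRONT_SHAPE_CONST * np.asarray(z, dtype=float)))


@dataclass
class GradientDesign:
    """Parameters of one microfluidic gradient scenario.

    Attributes
    ----------
    c_max, c_min:
        Endpoint concentrations (mM), ``c_max > c_min >= 0``.
    tau:
        Transition timescale (min): time for the front/switch to pass.
    u:
        Mean flow (front advection) speed, µm/min.
    v_c:
        Reference cell speed, µm/min (sets the temporal stimulus a moving
        cell experiences in a static spatial gradient).
    length_scale:
        Longitudinal gradient length scale L (µm).  Derived as ``u * tau``
        when not supplied.
    dcdx_ref:
        Reference spatial gradient of the dual-flow assay (mM/µm).
    width_scale:
        Cross-channel gradient length scale (µm) of the dual-flow device.
    """

    c_max: float
    c_min: float
    tau: Optional[float] = None
    u: Optional[float] = None
    v_c: Optional[float] = None
    length_scale: Optional[float] = None
    dcdx_ref: Optional[float] = None
    width_scale: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.c_max) or not np.isfinite(self.c_min):
            raise ValueError("endpoint concentrations must be finite")
        if not (self.c_max > self.c_min >= 0.0):
            raise ValueError("require c_max > c_min >= 0")
        for name in ("tau", "u", "v_c", "length_scale", "dcdx_ref"):
            val = getattr(self, name)
            if val is not None and (not np.isfinite(val)):
                raise ValueError(f"{name} must be finite")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.u is not None and self.u <= 0:
            raise ValueError("u must be positive")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        if self.length_scale is None and self.tau is not None and self.u is not None:
            self.length_scale = self.u * self.tau

    @property
    def delta_c(self) -> float:
        return self.c_max - self.c_min

    @property
    def mean_c(self) -> float:
        return 0.5 * (self.c_max + self.c_min)

    def to_dict(self) -> dict:
        return {
            "c_max": self.c_max, "c_min": self.c_min, "tau": self.tau,
            "u": self.u, "v_c": self.v_c, "length_scale": self.length_scale,
            "dcdx_ref": self.dcdx_ref, "width_scale": self.width_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GradientDesign":
        return cls(**{k: d.get(k) for k in (
            "c_max", "c_min", "tau", "u", "v_c", "length_scale", "dcdx_ref")},
            width_scale=d.get("width_scale", 100.0))


# ---------------------------------------------------------------------------
# Study-condition presets.  These are the parameter sets of the three
# gradient scenarios the package is built to analyse.
# ---------------------------------------------------------------------------

def taylor_aris_design() -> GradientDesign:
    """Dispersion-front scenario: 1.16/0.84 mM endpoints, 60 min passage,
    27 mm/min front speed (hence a 1.6 m gradient length scale)."""
    return GradientDesign(c_max=1.16, c_min=0.84, tau=60.0, u=27_000.0,
                          v_c=0.2, dcdx_ref=0.02)


def switching_design() -> GradientDesign:
    """Concentration-switch scenario: same endpoints, 1.5 min transition,
    2.5 mm/min mean flow in the test section."""
    return GradientDesign(c_max=1.16, c_min=0.84, tau=1.5, u=2_500.0,
                          v_c=0.2, dcdx_ref=0.02)


def dual_flow_design(c_source: float = 2.0) -> GradientDesign:
    """Dual-flow (Y-channel) scenario: one stream carries ``c_source`` mM,
    the other none; diffusion forms a steady cross-channel gradient with a
    100 µm length scale (mid-channel slope ~0.02 mM/µm at 2 mM)."""
    return GradientDesign(c_max=c_source, c_min=0.0, v_c=0.2,
                          dcdx_ref=c_source / 100.0, width_scale=100.0)


# ---------------------------------------------------------------------------
# Field evaluators
# ---------------------------------------------------------------------------

def temporal_gradient_from_motion(v_c: float, dcdx: float) -> float:
    """Temporal stimulus dC/dt = V_C * dC/dx experienced by a cell moving at
    speed ``v_c`` through a static spatial gradient ``dcdx``.  Signs are
    preserved (moving down-gradient gives a negative dC/dt)."""
    if not (np.isfinite(v_c) and np.isfinite(dcdx)):
        raise ValueError("v_c and dcdx must be finite")
    return v_c * dcdx


def taylor_aris_front(design: GradientDesign, x, t):
    """Concentration of a dispersed front advected at speed ``design.u``.

    C(x, t) = C_MIN + (C_MAX - C_MIN) * S((x - U t)/L) with S the erf ramp,
    so fluid ahead of the front (x >> U t) is still at C_MAX and fluid behind
    is at C_MIN.  Accepts scalars or arrays for ``x`` and ``t``.
    """
    L = design.length_scale
    if L is None or L <= 0:
        raise ValueError("front requires a positive length scale L")
    u = design.u if design.u is not None else 0.0
    z = (np.asarray(x, dtype=float) - u * np.asarray(t, dtype=float)) / L
    return design.c_min + design.delta_c * _ramp(z)


def dualflow_profile(c_source: float, y, width_scale: float = 100.0,
                     epoch_sign: int = 1):
    """Steady cross-channel diffusion profile of the dual-flow device.

    Monotone erf profile between 0 and ``c_source`` across the channel,
    centred on the interface at y = 0: the centreline concentration is
    c_source/2 and the mid-channel slope magnitude is c_source/width_scale.
    ``epoch_sign`` (+1/-1) selects which side of the channel carries the
    source stream; -1 mirrors the profile about the centreline.
    """
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")
    if epoch_sign not in (1, -1):
        raise ValueError("epoch_sign must be +1 or -1")
    z = epoch_sign * np.asarray(y, dtype=float) / width_scale
    return 0.5 * c_source * (1.0 + erf(FRONT_SHAPE_CONST * z))


def switching_profile(design: GradientDesign, t, t_switch: float,
                      direction: str = "up"):
    """Uniform concentration during a smooth switch between two media.

    Ramps monotonically from the pre-switch to the post-switch concentration
    over timescale ``design.tau`` centred on ``t_switch``; far from the
    switch the concentration is constant at the plateau values.
    """
    if design.tau is None or design.tau <= 0:
        raise ValueError("switching profile requires tau > 0")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    s = _ramp((np.asarray(t, dtype=float) - t_switch) / design.tau)
    if direction == "up":
        return design.c_min + design.delta_c * s
    return design.c_max - design.delta_c * s


def dye_to_concentration(intensity, calibration, c_max: Optional[float] = None):
    """Invert the affine dye calibration intensity = gain * C + offset.

    ``calibration`` is ``(gain, offset)``; values outside [0, c_max] are
    clipped with a logged warning (camera noise can push the affine inverse
    slightly out of range).
    """
    gain, offset = calibration
    if gain == 0:
        raise ValueError("calibration gain must be nonzero")
    intensity = np.asarray(intensity, dtype=float)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("intensity values must be finite")
    conc = (intensity - offset) / gain
    lo, hi = 0.0, (np.inf if c_max is None else c_max)
    if np.any(conc < lo) or np.any(conc > hi):
        logger.warning("dye_to_concentration: clipping %d of %d values "
                       "outside [%g, %g] mM",
                       int(np.sum((conc < lo) | (conc > hi))), conc.size, lo, hi)
        conc = np.clip(conc, lo, hi)
    return conc if conc.ndim else float(conc)


def concentration_to_intensity(conc, calibration):
    """Forward affine dye map (gain, offset): intensity = gain * C + offset."""
    gain, offset = calibration
    return gain * np.asarray(conc, dtype=float) + offset


# ---------------------------------------------------------------------------
# ConcentrationField: a space-time evaluator with gradient epochs
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationField:
    """Concentration as a function of gradient-axis coordinate and time.

    ``evaluator(g, t)`` maps a coordinate along the gradient axis (µm) and a
    time (min) to concentration (mM).  ``swap_times`` mark the instants at
    which the gradient orientation alternates; the epoch sign is
    ``initial_sign`` before the first swap and flips at every swap.
    """

    evaluator: Callable
    c_min: float
    c_max: float
    swap_times: Sequence[float] = field(default_factory=tuple)
    initial_sign: int = 1
    centre: float = 0.0

    def concentration(self, g, t):
        return self.evaluator(g, t)

    def epoch_sign(self, t: float) -> int:
        n = int(np.searchsorted(np.asarray(self.swap_times, dtype=float), t,
                                side="right"))
        return self.initial_sign * (-1) ** n


def alternating_dualflow_field(design: GradientDesign, centre: float,
                               swap_times: Sequence[float],
                               initial_sign: int = 1) -> ConcentrationField:
    """Dual-flow cross-channel gradient whose orientation flips at each swap.

    The profile runs between 0 and ``design.c_max`` (source concentration)
    across the gradient axis, centred at ``centre``; within each epoch the
    field is steady.
    """
    swap_arr = np.asarray(sorted(swap_times), dtype=float)

    def _eval(g, t):
        n = np.searchsorted(swap_arr, np.asarray(t, dtype=float), side="right")
        sign = initial_sign * (-1.0) ** n
        z = sign * (np.asarray(g, dtype=float) - centre) / design.width_scale
        return 0.5 * design.c_max * (1.0 + erf(FRONT_SHAPE_CONST * z))

    return ConcentrationField(_eval, 0.0, design.c_max, tuple(swap_arr),
                              initial_sign, centre)


def advected_front_field(design: GradientDesign, arrival_time: float,
                         position: float = 0.0) -> ConcentrationField:
    """Front field for the dispersion scenario: the front midpoint passes the
    observation coordinate ``position`` at ``arrival_time``."""
    def _eval(g, t):
        return taylor_aris_front(
            design, np.asarray(g, dtype=float) - position,
            np.asarray(t, dtype=float) - arrival_time)

    return ConcentrationField(_eval, design.c_min, design.c_max, (), 1, position)


def switching_field(design: GradientDesign, swap_times: Sequence[float],
                    first_direction: str = "down") -> ConcentrationField:
    """Spatially uniform field alternating between the two media at each swap.

    Each entry of ``swap_times`` triggers one smooth transition of timescale
    ``design.tau``; transitions alternate direction starting with
    ``first_direction``.
    """
    swaps = sorted(swap_times)
    start_high = first_direction == "down"

    def _eval(g, t):
        t = np.asarray(t, dtype=float)
        c = np.full(t.shape if t.ndim else (), design.c_max if start_high
                    else design.c_min, dtype=float)
        level_high = start_high
        for ts in swaps:
            s = _ramp((t - ts) / design.tau)
            if level_high:
                c = c - design.delta_c * s
            else:
                c = c + design.delta_c * s
            level_high = not level_high
        return c if np.ndim(c) else float(c)

    return ConcentrationField(_eval, design.c_min, design.c_max, tuple(swaps), 1)


# ---------------------------------------------------------------------------
# Design report
# ---------------------------------------------------------------------------

def design_report(design: GradientDesign, scenario_kind: str,
                  reference: Optional[GradientDesign] = None) -> dict:
    """Desk arithmetic for one gradient scenario.

    For ``dual_flow`` the temporal stimulus is the one experienced by a cell
    moving at ``v_c`` through the static spatial gradient ``dcdx_ref``
    (dC/dt = V_C dC/dx).  For ``taylor_aris`` and ``switching`` the temporal
    stimulus is set by the transition, dC/dt = (C_MAX - C_MIN)/tau; the
    gradient length scale is L = U tau and the spatial gradient is
    dC/dx = (C_MAX - C_MIN)/L.  Fold ratios compare the scenario against the
    dual-flow reference (``dcdx_ref``, ``width_scale``) and, when given,
    against the temporal stimulus of a second design.
    """
    out: dict = {"scenario_kind": scenario_kind, "mean_c": design.mean_c}
    if scenario_kind == "dual_flow":
        if design.v_c is None or design.dcdx_ref is None:
            raise ValueError("dual_flow report requires v_c and dcdx_ref")
        out["dcdx"] = design.dcdx_ref
        out["dcdt"] = temporal_gradient_from_motion(design.v_c, design.dcdx_ref)
        out["length_scale"] = design.width_scale
    elif scenario_kind in ("taylor_aris", "switching", "alternating_gradient"):
        if design.tau is None or design.tau <= 0:
            raise ValueError(f"{scenario_kind} report requires tau > 0")
        out["dcdt"] = design.delta_c / design.tau
        L = design.length_scale
        if L is None and design.u is not None:
            L = design.u * design.tau
        if L is not None:
            if L <= 0:
                raise ValueError("length scale must be positive")
            out["length_scale"] = L
            out["dcdx"] = design.delta_c / L
            out["fold_length_vs_width_scale"] = L / design.width_scale
    else:
        raise ValueError(f"unknown scenario_kind {scenario_kind!r}")
    if design.dcdx_ref is not None and out.get("dcdx"):
        out["fold_dcdx_below_ref"] = design.dcdx_ref / out["dcdx"]
    if reference is not None:
        ref_kind = "dual_flow" if (reference.tau is None) else "taylor_aris"
        ref = design_report(reference, ref_kind)
        if ref["dcdt"] == 0:
            raise ValueError("reference design has zero temporal gradient")
        out["fold_dcdt_vs_reference"] = out["dcdt"] / ref["dcdt"]
        if ref.get("dcdx"):
            out["fold_dcdx_vs_reference"] = out["dcdx"] / ref["dcdx"]
    return out


def format_design_report(report: dict) -> str:
    """Render a design report as aligned key-value text."""
    lines = [f"{k:<28s} {v:.6g}" if isinstance(v, (int, float)) else
             f"{k:<28s} {v}" for k, v in report.items()]
    return "\n".join(lines)
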