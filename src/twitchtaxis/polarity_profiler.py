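"""Sub-cellular fluorescence polarity: profiles, pole metrics, classes.

The retraction-motor fusion protein accumulates at the cell poles.  For
each cell and fluorescence frame we sample a longitudinal max-intensity
profile (the maximum over 10 parallel lines spanning the cell width, so
off-centreline foci are captured), normalize the two pole maxima by the
mean intensity of the central quarter of the cell (I1, I2), and classify
the pattern:

* mid-cell exclusion first: when the central mean exceeds both raw pole
  maxima the cell is close to division and is excluded;
* both I above threshold I_MIN -> bipolar, exactly one -> unipolar at
  that pole, neither -> nonpolar;
* a bipolar call with pole ratio above ``ratio_max`` is re-assigned
  unipolar at the stronger pole.

Pole 1 is the body-axis endpoint at ``centroid + (length/2) * axis`` with
the axis angle in [0, pi); arclength 0 of a profile sits at pole 1.
Thresholds are chosen per dataset from the anti-modes of the pooled
pole-intensity and pole-ratio distributions (an automated stand-in for
choosing them by eye).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

NONPOLAR = "nonpolar"
UNIPOLAR_POLE1 = "unipolar_pole1"
UNIPOLAR_POLE2 = "unipolar_pole2"
BIPOLAR = "bipolar"
EXCLUDED_MIDCELL = "excluded_midcell"

POLARITY_CLASSES = (NONPOLAR, UNIPOLAR_POLE1, UNIPOLAR_POLE2, BIPOLAR)


@dataclass
class ThresholdConfig:
    """Profiling geometry and classification thresholds.

    ``i_min`` is the normalized pole-intensity threshold above which a pole
    counts as occupied; ``ratio_max`` is the pole-asymmetry ratio above
    which an apparently bipolar cell is re-assigned unipolar.  The profile
    is the max over ``n_lines`` parallel lines ``line_spacing`` µm apart
    (spanning ~0.9 µm, one cell width); each pole window covers
    ``pole_fraction`` of the cell length and the normalization region the
    central ``mid_fraction``.
    """

    i_min: float = 2.0
    ratio_max: float = 3.0
    n_lines: int = 10
    line_spacing: float = 0.09     # µm
    pole_fraction: float = 0.1
    mid_fraction: float = 0.25
    sample_interval: float = 0.1   # µm along the cell axis (1 px equivalent)
    midcell_margin: float = 0.1    # relative excess required for exclusion

    def __post_init__(self) -> None:
        if self.i_min <= 0:
            raise ValueError("i_min must be positive")
        if self.ratio_max <= 1:
            raise ValueError("ratio_max must exceed 1")
        if self.n_lines < 1 or self.line_spacing <= 0:
            raise ValueError("invalid line layout")
        if not (0 < self.pole_fraction < 0.5 and 0 < self.mid_fraction <= 1):
            raise ValueError("invalid window fractions")


def sample_longitudinal_profile(fluor_image: np.ndarray, pose,
                                cfg: ThresholdConfig,
                                pixel_size: float) -> np.ndarray:
    """Max-intensity profile along the cell, arclength 0 at pole 1.

    Lays ``cfg.n_lines`` parallel segments with the pose's orientation and
    length, offset perpendicular to the axis at ``cfg.line_spacing``;
    samples the image by bilinear interpolation at ``cfg.sample_interval``
    steps and takes the maximum across lines at each arclength.  Sample
    positions falling outside the image are ignored (with a warning); an
    arclength with no valid sample yields NaN.
    """
    x, y = float(pose["x_um"]), float(pose["y_um"])
    length = float(pose["length_um"])
    theta = float(pose["orientation_rad"])
    axis = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-np.sin(theta), np.cos(theta)])

    n_samples = max(5, int(round(length / cfg.sample_interval)) + 1)
    s = np.linspace(0.0, 1.0, n_samples)
    along = (0.5 - s) * length                       # pole 1 at s = 0
    offsets = (np.arange(cfg.n_lines) - 0.5 * (cfg.n_lines - 1)) \
        * cfg.line_spacing

    px = x + np.outer(offsets, perp[0]) + along[None, :] * axis[0]
    py = y + np.outer(offsets, perp[1]) + along[None, :] * axis[1]
    rows = py / pixel_size - 0.5
    cols = px / pixel_size - 0.5
    inside = ((rows >= 0) & (rows <= fluor_image.shape[0] - 1) &
              (cols >= 0) & (cols <= fluor_image.shape[1] - 1))
    if not inside.all():
        logger.warning("profile extends outside the image; %d of %d samples "
                       "ignored", int((~inside).sum()), inside.size)
    vals = map_coordinates(fluor_image.astype(float),
                           [rows.clip(0, fluor_image.shape[0] - 1),
                            cols.clip(0, fluor_image.shape[1] - 1)],
                           order=1, mode="nearest")
    vals = np.where(inside, vals, -np.inf)
    profile = vals.max(axis=0)
    return np.where(np.isfinite(profile), profile, np.nan)


def pole_metrics(profile: np.ndarray, cfg: ThresholdConfig) -> dict:
    """Raw pole maxima, central mean and normalized intensities I1, I2.

    Pole 1's window covers arclength [0, pole_fraction], pole 2's
    [1 - pole_fraction, 1]; the central window spans ``mid_fraction`` of
    the length around the midpoint.  Returns NaN metrics (``valid=False``)
    when the central mean is not positive.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < 5:
        raise ValueError("profile too short")
    s = np.linspace(0.0, 1.0, n)
    p1 = np.nanmax(profile[s <= cfg.pole_fraction])
    p2 = np.nanmax(profile[s >= 1.0 - cfg.pole_fraction])
    mid_mask = np.abs(s - 0.5) <= 0.5 * cfg.mid_fraction
    mid = float(np.nanmean(profile[mid_mask]))
    if not np.isfinite(mid) or mid <= 0:
        return {"pole1_max": p1, "pole2_max": p2, "mid_mean": mid,
                "I1": np.nan, "I2": np.nan, "valid": False}
    return {"pole1_max": float(p1), "pole2_max": float(p2), "mid_mean": mid,
            "I1": float(p1 / mid), "I2": float(p2 / mid), "valid": True}


def classify_polarity(metrics: dict, cfg: ThresholdConfig) -> str:
    """Apply the classification rules in fixed precedence order.

    1. mid-cell exclusion (raw central mean above both raw pole maxima);
    2. threshold rules on I1, I2 against ``i_min`` (strict inequality);
    3. bipolar -> unipolar re-assignment when the pole ratio exceeds
       ``ratio_max``.

    The exclusion requires the central mean to exceed both pole maxima by
    ``midcell_margin`` (relative): division-site accumulations are several
    times brighter than cytoplasm, whereas in a signal-free cell the pole
    maxima sit marginally below the central mean only because intensity
    rolls off at the rounded pole tips.
    """
    if not metrics.get("valid", True):
        raise ValueError("cannot classify an invalid metrics record")
    lift = 1.0 + cfg.midcell_margin
    if metrics["mid_mean"] > lift * metrics["pole1_max"] and \
            metrics["mid_mean"] > lift * metrics["pole2_max"]:
        return EXCLUDED_MIDCELL
    i1, i2 = metrics["I1"], metrics["I2"]
    above1, above2 = i1 > cfg.i_min, i2 > cfg.i_min
    if above1 and above2:
        hi, lo = max(i1, i2), min(i1, i2)
        if lo > 0 and hi / lo > cfg.ratio_max:
            return UNIPOLAR_POLE1 if i1 >= i2 else UNIPOLAR_POLE2
        return BIPOLAR
    if above1:
        return UNIPOLAR_POLE1
    if above2:
        return UNIPOLAR_POLE2
    return NONPOLAR


def profile_cells(fluor_image: np.ndarray, poses: pd.DataFrame,
                  cfg: ThresholdConfig, pixel_size: float,
                  fluor_frame: int = 0, t_min: float = 0.0) -> pd.DataFrame:
    """Profile every pose against one fluorescence image.

    Returns one record per cell with the raw pole maxima, central mean and
    normalized pole intensities; classification is applied separately
    (after threshold calibration) with :func:`classify_records`.
    """
    rows = []
    for _, pose in poses.iterrows():
        profile = sample_longitudinal_profile(fluor_image, pose, cfg,
                                              pixel_size)
        m = pole_metrics(profile, cfg)
        rows.append({"cell_id": pose["cell_id"], "fluor_frame": fluor_frame,
                     "t_min": t_min, **m})
    return pd.DataFrame(rows)


def classify_records(records: pd.DataFrame,
                     cfg: ThresholdConfig) -> pd.DataFrame:
    """Attach ``polarity_class`` to a metrics table (invalid rows are
    labelled excluded with reason)."""
    out = records.copy()
    classes = []
    for _, r in out.iterrows():
        if not r.get("valid", True):
            classes.append("excluded_invalid")
        else:
            classes.append(classify_polarity(r, cfg))
    out["polarity_class"] = classes
    return out


def _antimode(values: np.ndarray) -> float | None:
    """Anti-mode of a 1-D sample: the density minimum between the two
    dominant modes of a log-scale KDE; None when unimodal."""
    v = np.log(values[values > 0])
    if v.size < 50 or np.ptp(v) < 1e-6:
        return None
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), 512)
    dens = kde(grid)
    # zero-pad so modes sitting on the domain boundary are found too
    padded = np.concatenate([[0.0], dens, [0.0]])
    peaks, props = find_peaks(padded, prominence=0.05 * dens.max())
    peaks = peaks - 1
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = np.clip(sorted(top2), 0, len(grid) - 1)
    valley = grid[lo + int(np.argmin(dens[lo:hi + 1]))]
    return float(np.exp(valley))


def calibrate_thresholds(records: pd.DataFrame,
                         default: ThresholdConfig | None = None) -> tuple:
    """Suggest (i_min, ratio_max) from a population of pole intensities.

    ``i_min`` is placed at the anti-mode of the pooled I1/I2 distribution
    (separating unoccupied from occupied poles); ``ratio_max`` at the
    anti-mode of the per-cell max/min pole ratio (separating symmetric
    from strongly one-sided localization).  Falls back to the defaults
    with a warning when a distribution is unimodal.  Returns
    ``(cfg, diagnostics)`` where diagnostics carries the pooled samples
    and histograms for operator review.
    """
    default = default or ThresholdConfig()
    valid = records[records.get("valid", True) == True]  # noqa: E712
    if len(valid) < 100:
        raise ValueError("need at least 100 valid records to calibrate")
    pooled = np.concatenate([valid.I1.to_numpy(), valid.I2.to_numpy()])
    ratios = np.maximum(valid.I1, valid.I2) / \
        np.maximum(np.minimum(valid.I1, valid.I2), 1e-9)
    i_min = _antimode(pooled)
    ratio_max = _antimode(ratios.to_numpy())
    warnings = []
    if i_min is None:
        warnings.append("pole-intensity distribution unimodal; default i_min")
        logger.warning(warnings[-1])
        i_min = default.i_min
    if ratio_max is None or ratio_max <= 1.0:
        warnings.append("pole-ratio distribution unimodal; default ratio_max")
        logger.warning(warnings[-1])
        ratio_max = default.ratio_max
    cfg = ThresholdConfig(
        i_min=float(i_min), ratio_max=float(ratio_max),
        n_lines=default.n_lines, line_spacing=default.line_spacing,
        pole_fraction=default.pole_fraction, mid_fraction=default.mid_fraction,
        sample_interval=default.sample_interval)
    diagnostics = {
        "pooled_intensities": pooled,
        "pole_ratios": np.asarray(ratios),
        "intensity_histogram": np.histogram(np.log(pooled[pooled > 0]), 64),
        "ratio_histogram": np.histogram(np.log(ratios[ratios > 0]), 64),
        "warnings": warnings,
    }
    return cfg, diagnostics
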