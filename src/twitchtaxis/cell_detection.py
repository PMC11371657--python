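"""Cell segmentation, pose estimation, frame linking and object filters.

A deliberately simple detector adequate for synthetic frames (it stands
in for heavyweight trackers used on real data): global threshold,
connected components, per-component pose from the pixel-coordinate
covariance.  Lengths are tip-to-tip extents along the principal axis;
widths the extent across it.  Linking is greedy nearest-neighbour with
zero gap tolerance.  Filters drop detritus without appreciable
fluorescence and cells with aspect ratio below 1.4 (cells not attached by
both poles).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger(__name__)

POSE_COLUMNS = ["cell_id", "frame", "t_min", "x_um", "y_um", "length_um",
                "width_um", "orientation_rad", "aspect_ratio", "mean_fluor"]


def _pose_from_coords(coords: np.ndarray, pixel_size: float) -> dict:
    """Pose from the pixel coordinates of one connected component.

    Orientation is the principal eigenvector of the coordinate covariance,
    reported as an axial angle from +x in [0, pi); length and width are
    the extents of the component along/across that axis plus one pixel
    (the footprint of a pixel itself).
    """
    s = pixel_size
    xs = (coords[:, 1] + 0.5) * s
    ys = (coords[:, 0] + 0.5) * s
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    theta = np.arctan2(major[1], major[0]) % np.pi
    axis = np.array([np.cos(theta), np.sin(theta)])
    proj = dx * axis[0] + dy * axis[1]
    perp = -dx * axis[1] + dy * axis[0]
    length = float(proj.max() - proj.min()) + s
    width = float(perp.max() - perp.min()) + s
    length, width = max(length, width), min(length, width)
    return {"x_um": cx, "y_um": cy, "length_um": length, "width_um": width,
            "orientation_rad": theta, "aspect_ratio": length / max(width, s)}


def segment_frame(image: np.ndarray, intensity_threshold: Optional[float]
                  = None, pixel_size: float = 0.1, frame: int = 0,
                  t_min: float = 0.0, min_area_um2: float = 0.5) -> list:
    """Detect cells in one frame; returns a list of pose dicts.

    Threshold (Otsu when not given) -> connected components -> pose from
    second moments.  Components smaller than ``min_area_um2`` are dropped
    as noise.  A blank (constant) image yields an empty list.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segment_frame expects a 2-D image")
    if image.size == 0 or image.max() == image.min():
        return []
    thr = intensity_threshold if intensity_threshold is not None \
        else threshold_otsu(image)
    mask = image > thr
    if not mask.any():
        return []
    lab = label(mask)
    min_px = max(1, int(min_area_um2 / pixel_size ** 2))
    poses = []
    for region in regionprops(lab):
        if region.area < min_px:
            continue
        pose = _pose_from_coords(region.coords, pixel_size)
        pose.update({"frame": frame, "t_min": t_min, "mean_fluor": np.nan})
        poses.append(pose)
    return poses


def segment_stack(stack: np.ndarray, pixel_size: float, dt: float,
                  intensity_threshold: Optional[float] = None) -> list:
    """Segment every frame of a stack; returns a list of per-frame pose
    lists (the input to :func:`link_tracks`)."""
    return [segment_frame(stack[f], intensity_threshold, pixel_size,
                          frame=f, t_min=f * dt)
            for f in range(stack.shape[0])]


def capsule_mask(pose, shape: tuple, pixel_size: float) -> np.ndarray:
    """Boolean spherocylinder footprint of a pose on an image grid."""
    s = pixel_size
    x, y = pose["x_um"], pose["y_um"]
    length, width = pose["length_um"], pose["width_um"]
    theta = pose["orientation_rad"]
    half_seg = max(0.0, 0.5 * (length - width))
    axis = np.array([np.cos(theta), np.sin(theta)])
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    px = (cols + 0.5) * s - x
    py = (rows + 0.5) * s - y
    proj = np.clip(px * axis[0] + py * axis[1], -half_seg, half_seg)
    return (px - proj * axis[0]) ** 2 + (py - proj * axis[1]) ** 2 \
        <= (0.5 * width) ** 2


def measure_mean_fluor(pose, fluor_image: np.ndarray,
                       pixel_size: float) -> float:
    """Mean fluorescence under the cell footprint."""
    s = pixel_size
    reach = 0.5 * pose["length_um"] + s
    r0 = max(0, int((pose["y_um"] - reach) / s))
    r1 = min(fluor_image.shape[0], int((pose["y_um"] + reach) / s) + 2)
    c0 = max(0, int((pose["x_um"] - reach) / s))
    c1 = min(fluor_image.shape[1], int((pose["x_um"] + reach) / s) + 2)
    sub = fluor_image[r0:r1, c0:c1]
    local = dict(pose)
    local["x_um"] = pose["x_um"] - c0 * s
    local["y_um"] = pose["y_um"] - r0 * s
    mask = capsule_mask(local, sub.shape, s)
    if not mask.any():
        return float("nan")
    return float(sub[mask].mean())


def link_tracks(frames_poses: Sequence[Sequence[dict]],
                max_step: float = 2.0) -> pd.DataFrame:
    """Greedy nearest-neighbour linking with zero gap tolerance.

    Distances above ``max_step`` (µm per frame) are not linked; the
    detection then starts a new track and the unmatched track terminates.
    Returns a single pose table with assigned ``cell_id``.
    """
    next_id = 0
    active: dict[int, dict] = {}
    rows: list[dict] = []
    for poses in frames_poses:
        poses = list(poses)
        assigned: dict[int, int] = {}
        if active and poses:
            prev_ids = list(active)
            prev_xy = np.array([[active[i]["x_um"], active[i]["y_um"]]
                                for i in prev_ids])
            cur_xy = np.array([[p["x_um"], p["y_um"]] for p in poses])
            tree = cKDTree(prev_xy)
            dists, idx = tree.query(cur_xy)
            order = np.argsort(dists)
            used = set()
            for k in order:
                if dists[k] > max_step:
                    continue
                tid = prev_ids[idx[k]]
                if tid in used:
                    # fall back: next-closest unused previous track
                    cand = tree.query(cur_xy[k], k=min(len(prev_ids), 4))
                    found = False
                    for d2, j2 in zip(np.atleast_1d(cand[0]),
                                      np.atleast_1d(cand[1])):
                        t2 = prev_ids[j2]
                        if t2 not in used and d2 <= max_step:
                            tid, found = t2, True
                            break
                    if not found:
                        continue
                assigned[k] = tid
                used.add(tid)
        new_active = {}
        for k, pose in enumerate(poses):
            tid = assigned.get(k)
            if tid is None:
                tid = next_id
                next_id += 1
            row = dict(pose)
            row["cell_id"] = tid
            rows.append(row)
            new_active[tid] = pose
        active = new_active
    if not rows:
        return pd.DataFrame(columns=POSE_COLUMNS)
    df = pd.DataFrame(rows)
    return df[[c for c in POSE_COLUMNS if c in df.columns] +
              [c for c in df.columns if c not in POSE_COLUMNS]]


def suggest_fluor_threshold(fluor_image: np.ndarray,
                            factor: float = 3.0) -> float:
    """Default 'appreciable fluorescence' cut: ``factor`` times the image
    background median."""
    return factor * float(np.median(fluor_image))


def filter_cells(poses: pd.DataFrame, min_mean_fluor: float,
                 min_aspect_ratio: float = 1.4) -> tuple:
    """Split poses into kept and rejected (with reasons).

    Keeps rows with ``mean_fluor >= min_mean_fluor`` and ``aspect_ratio >=
    min_aspect_ratio`` (boundary inclusive).  Rejection reasons are
    ``no_fluor`` and ``aspect_ratio``; a row failing both reports
    ``no_fluor``.  Idempotent and order-independent.
    """
    if poses.empty:
        return poses.copy(), poses.assign(reject_reason=pd.Series(dtype=str))
    fluor_ok = poses.mean_fluor >= min_mean_fluor
    aspect_ok = poses.aspect_ratio >= min_aspect_ratio
    kept = poses[fluor_ok & aspect_ok].copy()
    rejected = poses[~(fluor_ok & aspect_ok)].copy()
    rejected["reject_reason"] = np.where(~fluor_ok[rejected.index],
                                         "no_fluor", "aspect_ratio")
    if len(rejected):
        logger.info("filter_cells: rejected %d of %d poses", len(rejected),
                    len(poses))
    return kept, rejected
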