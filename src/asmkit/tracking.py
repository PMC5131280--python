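"""Bead localization and trajectory linking.

Functionalized microbeads bound to the cytoskeleton appear as bright,
roughly Gaussian spots on a dark background.  Positions are recovered with
an intensity-weighted center-of-mass estimator after median-background
subtraction, and linked frame-to-frame by greedy nearest-neighbour
assignment (beads are anchored, so motion between consecutive frames is
small compared with bead spacing).

Coordinate convention: 0-based pixel indices, positions reported at pixel
centers, x rightward (columns), y downward (rows).  Conversion to nm uses
the camera pixel size supplied by the caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["SpotDetection", "Trajectory", "locate_beads", "link_trajectories",
           "subtract_global_drift"]


@dataclass
class SpotDetection:
    """A single localized spot in one frame."""

    frame: int
    x_px: float
    y_px: float
    total_intensity: float
    roi: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max), inclusive
    x_nm: float | None = None
    y_nm: float | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.roi
        if not (c0 - 0.5 <= self.x_px <= c1 + 0.5 and r0 - 0.5 <= self.y_px <= r1 + 0.5):
            raise ValueError("spot position lies outside its ROI")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")


@dataclass
class Trajectory:
    """Uniformly sampled 2-D positions of one bead, in nm."""

    bead_id: int
    times: np.ndarray  # s
    x: np.ndarray      # nm
    y: np.ndarray      # nm
    frame_rate: float  # Hz

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) < 2:
            raise ValueError("trajectory must contain at least 2 samples")
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform at 1/frame_rate")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def locate_beads(
    frame: np.ndarray,
    threshold_quantile: float = 0.995,
    min_separation: float = 5.0,
    pixel_size_nm: float | None = None,
    roi_pad: int | None = None,
    frame_index: int = 0,
) -> list[SpotDetection]:
    """Localize bright spots in a single grayscale frame.

    The image median is subtracted (beads are sparse, so the median is a
    robust background estimate), negative values are clipped at zero, and
    connected regions above the ``threshold_quantile`` of the subtracted
    image become candidate spots.  Each spot's position is the
    intensity-weighted mean over its ROI — the above-threshold bounding box
    expanded by ``roi_pad`` pixels so the dim Gaussian skirt contributes to
    the weighted mean (truncating at the threshold contour would bias
    sub-pixel positions toward the ROI center).

    Candidate pairs closer than ``min_separation`` pixels are both rejected:
    their weighted means would contaminate each other.

    An empty or all-background frame yields an empty list.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must lie in (0, 1)")
    if img.size == 0:
        return []

    background = np.median(img)
    sub = np.clip(img - background, 0.0, None)
    thr = np.quantile(sub, threshold_quantile)
    mask = sub > thr
    if not mask.any():
        return []

    labels, n_spots = ndimage.label(mask)
    slices = ndimage.find_objects(labels)

    sat_level = None
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        sat_level = np.iinfo(np.asarray(frame).dtype).max

    detections: list[SpotDetection] = []
    for sl in slices:
        rows, cols = sl
        half = max(rows.stop - rows.start, cols.stop - cols.start)
        pad = roi_pad if roi_pad is not None else max(3, 2 * half)
        r0 = max(rows.start - pad, 0)
        r1 = min(rows.stop + pad, img.shape[0]) - 1
        c0 = max(cols.start - pad, 0)
        c1 = min(cols.stop + pad, img.shape[1]) - 1
        roi = sub[r0:r1 + 1, c0:c1 + 1]
        total = roi.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        y = float((roi * rr).sum() / total)
        x = float((roi * cc).sum() / total)
        saturated = bool(sat_level is not None and np.any(img[rows, cols] >= sat_level))
        det = SpotDetection(frame=frame_index, x_px=x, y_px=y,
                            total_intensity=float(total),
                            roi=(r0, r1, c0, c1), saturated=saturated)
        if pixel_size_nm is not None:
            det.x_nm = x * pixel_size_nm
            det.y_nm = y * pixel_size_nm
        detections.append(det)

    # reject mutually close spots whose ROIs would overlap
    keep = [True] * len(detections)
    for i in range(len(detections)):
        for j in range(i + 1, len(detections)):
            d = math.hypot(detections[i].x_px - detections[j].x_px,
                           detections[i].y_px - detections[j].y_px)
            if d < min_separation:
                keep[i] = keep[j] = False
                logger.warning("rejecting spot pair %d/%d at distance %.2f px "
                               "(< min_separation %.2f)", i, j, d, min_separation)
    return [d for d, k in zip(detections, keep) if k]


def link_trajectories(
    detections_per_frame: list[list[SpotDetection]],
    max_step_nm: float,
    pixel_size_nm: float,
    frame_rate: float,
    min_length: int = 2,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories by greedy nearest neighbour.

    Each active track claims its nearest detection in the next frame; a
    track whose nearest candidate is farther than ``max_step_nm`` ends.
    Ties (two candidates exactly equidistant) are broken toward the lower
    detection index and logged.  Unclaimed detections seed new tracks.
    Tracks shorter than ``min_length`` frames are dropped.
    """
    if len(detections_per_frame) < 2:
        raise ValueError("need detections for at least 2 consecutive frames")
    max_step_px = max_step_nm / pixel_size_nm

    # each track: list of (frame_index, x_px, y_px)
    finished: list[list[tuple[int, float, float]]] = []
    active: list[list[tuple[int, float, float]]] = [
        [(0, d.x_px, d.y_px)] for d in detections_per_frame[0]
    ]

    for f in range(1, len(detections_per_frame)):
        dets = detections_per_frame[f]
        claimed = [False] * len(dets)
        still_active = []
        for track in active:
            _, px, py = track[-1]
            best_j, best_d = -1, np.inf
            for j, d in enumerate(dets):
                if claimed[j]:
                    continue
                dist = math.hypot(d.x_px - px, d.y_px - py)
                if dist < best_d - 1e-12:
                    best_j, best_d = j, dist
                elif abs(dist - best_d) <= 1e-12 and best_j >= 0:
                    logger.info("ambiguous assignment at frame %d: detections %d and %d "
                                "equidistant; keeping lower index %d", f, best_j, j, best_j)
            if best_j >= 0 and best_d <= max_step_px:
                claimed[best_j] = True
                track.append((f, dets[best_j].x_px, dets[best_j].y_px))
                still_active.append(track)
            else:
                finished.append(track)
        for j, d in enumerate(dets):
            if not claimed[j]:
                still_active.append([(f, d.x_px, d.y_px)])
        active = still_active
    finished.extend(active)

    out: list[Trajectory] = []
    for bead_id, track in enumerate(t for t in finished if len(t) >= max(min_length, 2)):
        frames = np.array([p[0] for p in track], dtype=float)
        out.append(Trajectory(
            bead_id=bead_id,
            times=frames / frame_rate,
            x=np.array([p[1] for p in track]) * pixel_size_nm,
            y=np.array([p[2] for p in track]) * pixel_size_nm,
            frame_rate=frame_rate,
        ))
    return out


def subtract_global_drift(trajectories: list[Trajectory]) -> list[Trajectory]:
    """Remove the frame-wise ensemble-mean displacement from every trajectory.

    Off by default in the pipeline: the acquisition protocol this package
    models reports no drift correction.  Requires all trajectories to span
    the same frames.
    """
    if not trajectories:
        return []
    n = len(trajectories[0])
    if any(len(t) != n for t in trajectories):
        raise ValueError("global drift subtraction requires equal-length trajectories")
    mx = np.mean([t.x for t in trajectories], axis=0)
    my = np.mean([t.y for t in trajectories], axis=0)
    mx = mx - mx[0]
    my = my - my[0]
    return [
        Trajectory(t.bead_id, t.times, t.x - mx, t.y - my, t.frame_rate)
        for t in trajectories
    ]
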