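"""AR overlay projection, sphere detection, circle matching and TRE.

The target registration error (TRE) used here is the 2D distance in the
endoscopic image between a real structure and its CBCT overlay,
re-expressed in object-plane millimetres through the known sphere
diameter:

    TRE[mm] = TRE[px] · Ø_sphere[mm] / Ø_sphere[px].

This is *not* the 3D point-registration TRE of the fiducial-registration
literature; it measures what the surgeon sees — how far the overlay sits
from the real structure on screen.  The pixel diameter in the
denominator is taken from the *real* (detected) sphere, which anchors
the millimetre scale to the physical object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from . import config
from .camera import CameraIntrinsics, project, projected_sphere_radius_px
from .geometry import RigidTransform, camera_from_patient
from .simulator import AccuracyRun
from .tracking import estimate_patient_pose


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class OverlayCircle:
    """A circle in the image: a detected real sphere or a projected overlay."""

    center: tuple[float, float]
    radius_px: float
    source: str                 # "real" | "overlay"
    sphere_id: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.center)) or not np.isfinite(self.radius_px):
            raise EvaluationError("circle parameters must be finite")
        if self.radius_px <= 0:
            raise EvaluationError("circle radius must be positive")


def overlay_structures(
    structures: dict[str, tuple[np.ndarray, float]],
    tpo: RigidTransform,
    tmo: RigidTransform,
    tcm: RigidTransform,
    K: CameraIntrinsics,
    radius_mode: str = "tangent",
) -> tuple[list[OverlayCircle], int]:
    """Project CBCT-frame spheres into the endoscopic view.

    ``structures`` maps sphere id → (centre in the CBCT frame, radius in
    mm).  Centres are carried through the fusion chain (the inverse of
    TCP = TPO⁻¹·TMO·TCM) and projected; spheres behind the camera are
    dropped and counted.
    """
    cam_from_pat = camera_from_patient(tpo, tmo, tcm)
    circles: list[OverlayCircle] = []
    dropped = 0
    for sid in sorted(structures):
        center, r_mm = structures[sid]
        cam = cam_from_pat.apply(np.asarray(center, float))
        if cam[2] <= r_mm:
            dropped += 1
            continue
        uv = project(K, cam)
        r_px = projected_sphere_radius_px(K, float(cam[2]), r_mm, radius_mode)
        circles.append(
            OverlayCircle((float(uv[0]), float(uv[1])), float(r_px), "overlay", sid)
        )
    return circles, dropped


def _fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit; returns (cx, cy, r)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones(len(x))])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    return float(cx), float(cy), float(np.sqrt(max(c + cx * cx + cy * cy, 0.0)))


def detect_spheres(
    image: np.ndarray,
    threshold: float = 0.5,
    min_area_px: float = 5.0,
    min_circularity: float = 0.6,
) -> list[OverlayCircle]:
    """Segment bright circular blobs and measure sub-pixel centres/radii.

    Pipeline: background-normalized intensity threshold → connected
    components → size/circularity filter → centre from the intensity
    centroid (sub-pixel-exact for anti-aliased discs) → radius from a
    least-squares circle fit to the sub-pixel 0.5-level contour.
    Non-circular or border-clipped blobs are returned flagged
    ``ambiguous`` rather than silently dropped.
    """
    img = np.asarray(image, dtype=float)
    bg = float(np.median(img))
    fg = float(img.max())
    if fg - bg < 1e-6:
        return []
    norm = np.clip((img - bg) / (fg - bg), 0.0, 1.0)
    mask = norm > threshold
    labels = measure.label(mask)
    out: list[OverlayCircle] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        ambiguous = False
        perim = max(region.perimeter, 1e-9)
        circularity = 4.0 * np.pi * region.area / (perim * perim)
        if circularity < min_circularity:
            ambiguous = True
        y0, x0, y1, x1 = region.bbox
        if x0 == 0 or y0 == 0 or y1 == img.shape[0] or x1 == img.shape[1]:
            ambiguous = True
        # sub-pixel centre: intensity centroid over a padded patch
        py0, px0 = max(y0 - 2, 0), max(x0 - 2, 0)
        py1, px1 = min(y1 + 2, img.shape[0]), min(x1 + 2, img.shape[1])
        patch = norm[py0:py1, px0:px1]
        w = patch.sum()
        yy, xx = np.mgrid[py0:py1, px0:px1]
        cu = float((patch * xx).sum() / w)
        cv = float((patch * yy).sum() / w)
        contours = measure.find_contours(patch, threshold)
        if not contours:
            continue
        contour = max(contours, key=len)  # (row, col)
        fx, fy, r = _fit_circle(np.column_stack([contour[:, 1] + px0, contour[:, 0] + py0]))
        if r <= 0:
            continue
        out.append(OverlayCircle((cu, cv), r, "real", ambiguous=ambiguous))
    out.sort(key=lambda c: (c.center[1], c.center[0]))
    return out


@dataclass
class MatchResult:
    pairs: list[tuple[OverlayCircle, OverlayCircle]]   # (real, overlay)
    unmatched_real: list[OverlayCircle]
    unmatched_overlay: list[OverlayCircle]


def match_circles(
    real: list[OverlayCircle],
    overlay: list[OverlayCircle],
    max_distance_px: float = config.MATCH_MAX_DISTANCE_PX,
) -> MatchResult:
    """Mutual-nearest-neighbour pairing with a maximum-distance gate."""
    if not real or not overlay:
        return MatchResult([], list(real), list(overlay))
    rc = np.array([c.center for c in real])
    oc = np.array([c.center for c in overlay])
    d = np.linalg.norm(rc[:, None, :] - oc[None, :, :], axis=2)
    nn_r = d.argmin(axis=1)
    nn_o = d.argmin(axis=0)
    pairs, used_r, used_o = [], set(), set()
    for i, j in enumerate(nn_r):
        if nn_o[j] == i and d[i, j] <= max_distance_px:
            pairs.append((real[i], overlay[j]))
            used_r.add(i)
            used_o.add(int(j))
    return MatchResult(
        pairs,
        [c for i, c in enumerate(real) if i not in used_r],
        [c for j, c in enumerate(overlay) if j not in used_o],
    )


def compute_tre(
    real: OverlayCircle,
    overlay: OverlayCircle,
    sphere_diameter_mm: float = config.SPHERE_DIAMETER_MM,
) -> float:
    """TRE in mm: pixel centre distance scaled by Ø_mm / Ø_px (real sphere)."""
    diameter_px = 2.0 * real.radius_px
    if diameter_px <= 0:
        raise EvaluationError("non-positive detected sphere diameter")
    err_px = float(np.hypot(real.center[0] - overlay.center[0], real.center[1] - overlay.center[1]))
    return err_px * sphere_diameter_mm / diameter_px


TRE_COLUMNS = [
    "sphere_id",
    "distance_mm",
    "position_index",
    "u_real",
    "v_real",
    "u_ovl",
    "v_ovl",
    "diameter_px",
    "tre_mm",
]


def evaluate_run(
    run: AccuracyRun,
    real_source: str = "truth",
    overlay_intrinsics: CameraIntrinsics | None = None,
    sphere_diameter_mm: float = config.SPHERE_DIAMETER_MM,
    max_match_distance_px: float = config.MATCH_MAX_DISTANCE_PX,
) -> pd.DataFrame:
    """Turn a protocol run into per-sphere, per-position TRE records.

    For each frame the patient pose is re-estimated from the tracked
    side markers through the VRG, the CBCT spheres are overlaid via the
    fusion chain and paired with the real circles — either the
    simulator's rendered ground truth (``real_source="truth"``) or
    blob detections from the rendered image (``"detect"``).
    ``overlay_intrinsics`` lets the overlay path run with a deliberately
    different camera model (e.g. to study uncorrected distortion).
    """
    if real_source not in ("truth", "detect"):
        raise ValueError("real_source must be 'truth' or 'detect'")
    K_overlay = overlay_intrinsics or run.intrinsics
    rows = []
    for frame in run.frames:
        pose = estimate_patient_pose(run.vrg, frame.observations)
        if pose.tracking_lost:
            continue
        circles_ovl, _ = overlay_structures(
            run.structures, pose.tpo, run.tmo, run.tcm, K_overlay, run.radius_mode
        )
        if real_source == "truth":
            real = [
                OverlayCircle(t.center_px, t.radius_px, "real", t.sphere_id)
                for t in frame.truth
            ]
        else:
            if frame.image is None:
                raise EvaluationError("real_source='detect' needs rendered images")
            real = [c for c in detect_spheres(frame.image) if not c.ambiguous]
        matched = match_circles(real, circles_ovl, max_match_distance_px)
        for rc, oc in matched.pairs:
            rows.append(
                {
                    "sphere_id": oc.sphere_id,
                    "distance_mm": frame.distance_mm,
                    "position_index": frame.position_index,
                    "u_real": rc.center[0],
                    "v_real": rc.center[1],
                    "u_ovl": oc.center[0],
                    "v_ovl": oc.center[1],
                    "diameter_px": 2.0 * rc.radius_px,
                    "tre_mm": compute_tre(rc, oc, sphere_diameter_mm),
                }
            )
    return pd.DataFrame(rows, columns=TRE_COLUMNS)
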