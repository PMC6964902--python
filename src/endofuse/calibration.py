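"""Planar (Zhang-style) intrinsic calibration of the endoscope camera.

Given several views of a planar target with known board coordinates, the
pipeline is the classical one: a normalized-DLT homography per view,
closed-form intrinsics from the homography constraints on the image of
the absolute conic, extrinsics per view, then a joint nonlinear
refinement of intrinsics, distortion and all view poses minimizing the
total squared reprojection error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import config
from .camera import CameraIntrinsics, project
from .geometry import RigidTransform, orthonormalize


class CalibrationError(ValueError):
    """Raised for insufficient or degenerate calibration input."""


@dataclass(frozen=True)
class PlanarView:
    """Index-matched correspondences between a planar target and an image.

    ``object_points`` are (N,2) board coordinates in mm on the target's
    z=0 plane; ``image_points`` are (N,2) pixels.
    """

    object_points: np.ndarray
    image_points: np.ndarray
    view_id: str = ""

    def __post_init__(self) -> None:
        obj = np.asarray(self.object_points, dtype=float)
        if obj.ndim == 2 and obj.shape[1] == 3:
            if np.abs(obj[:, 2]).max() > 1e-12:
                raise CalibrationError("planar target points must lie on z=0")
            obj = obj[:, :2]
        img = np.asarray(self.image_points, dtype=float)
        if obj.shape[0] != img.shape[0]:
            raise CalibrationError("object/image point counts differ")
        if obj.shape[0] < 4:
            raise CalibrationError("a planar view needs at least 4 points")
        centered = obj - obj.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < config.COLLINEARITY_SV_RATIO * max(s[0], 1.0):
            raise CalibrationError("planar view points are collinear")
        object.__setattr__(self, "object_points", obj)
        object.__setattr__(self, "image_points", img)


@dataclass
class CalibrationResult:
    """Output of :func:`calibrate_intrinsics`."""

    intrinsics: CameraIntrinsics
    extrinsics: list[RigidTransform]       # camera←view_i poses of the board
    rms_px: float
    per_view_rms_px: np.ndarray
    initial_rms_px: float                  # RMS of the closed-form initialization
    n_residual_evals: int = 0

    def summary(self) -> str:
        K = self.intrinsics
        lines = [
            "Planar intrinsic calibration",
            f"  views                : {len(self.extrinsics)}",
            f"  fx, fy (px)          : {K.fx:.4f}, {K.fy:.4f}",
            f"  cx, cy (px)          : {K.cx:.4f}, {K.cy:.4f}",
            f"  skew (px)            : {K.skew:.6f}",
            f"  k1, k2, k3           : {K.dist[0]:+.6f}, {K.dist[1]:+.6f}, {K.dist[4]:+.6f}",
            f"  p1, p2               : {K.dist[2]:+.6f}, {K.dist[3]:+.6f}",
            f"  RMS reprojection (px): {self.rms_px:.3e} (init {self.initial_rms_px:.3e})",
        ]
        return "\n".join(lines)


def homography_dlt(object_xy: np.ndarray, image_uv: np.ndarray) -> np.ndarray:
    """Plane-to-image homography by the normalized DLT, H[2,2] = 1."""

    def normalizer(pts: np.ndarray) -> np.ndarray:
        c = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
        T = np.array([[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1.0]])
        return T

    To, Ti = normalizer(object_xy), normalizer(image_uv)
    n = len(object_xy)
    oh = np.column_stack([object_xy, np.ones(n)]) @ To.T
    ih = np.column_stack([image_uv, np.ones(n)]) @ Ti.T
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = oh
    A[0::2, 6:9] = -ih[:, [0]] * oh
    A[1::2, 3:6] = oh
    A[1::2, 6:9] = -ih[:, [1]] * oh
    _, _, Vt = np.linalg.svd(A)
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Ti) @ H @ To
    return H / H[2, 2]


def _vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    h_i, h_j = H[:, i], H[:, j]
    return np.array(
        [
            h_i[0] * h_j[0],
            h_i[0] * h_j[1] + h_i[1] * h_j[0],
            h_i[1] * h_j[1],
            h_i[2] * h_j[0] + h_i[0] * h_j[2],
            h_i[2] * h_j[1] + h_i[1] * h_j[2],
            h_i[2] * h_j[2],
        ]
    )


def _intrinsics_from_homographies(
    Hs: list[np.ndarray], width: int, height: int, estimate_skew: bool
) -> CameraIntrinsics:
    V = []
    for H in Hs:
        V.append(_vij(H, 0, 1))
        V.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    V = np.asarray(V)
    s = np.linalg.svd(V, compute_uv=False)
    if s[-2] < config.CALIB_DEGENERACY_RATIO * s[0]:
        raise CalibrationError(
            "degenerate view set: homography constraints are rank-deficient "
            "(views are near fronto-parallel or otherwise uninformative)"
        )
    _, _, Vt = np.linalg.svd(V)
    B11, B12, B22, B13, B23, B33 = Vt[-1]
    den = B11 * B22 - B12 * B12
    cy = (B12 * B13 - B11 * B23) / den
    lam = B33 - (B13 * B13 + cy * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 <= 0 or lam * B11 / den <= 0:
        raise CalibrationError("closed-form intrinsics are not positive definite")
    fx = float(np.sqrt(lam / B11))
    fy = float(np.sqrt(lam * B11 / den))
    skew = float(-B12 * fx * fx * fy / lam) if estimate_skew else 0.0
    cx = float(skew * cy / fy - B13 * fx * fx / lam)
    return CameraIntrinsics(
        fx=fx, fy=fy, cx=cx, cy=float(cy), width=width, height=height, skew=skew
    )


def _extrinsics_from_homography(K: np.ndarray, H: np.ndarray, view_id: str) -> RigidTransform:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = (Kinv @ H[:, i] for i in range(3))
    lam = 1.0 / np.linalg.norm(h1)
    r1, r2 = lam * h1, lam * h2
    r3 = np.cross(r1, r2)
    R = orthonormalize(np.column_stack([r1, r2, r3]))
    t = lam * h3
    if t[2] < 0:  # board must be in front of the camera
        R = orthonormalize(np.column_stack([-r1, -r2, r3]))
        t = -t
    return RigidTransform(R, t, source=view_id or "board", target="camera")


def calibrate_intrinsics(
    views: list[PlanarView],
    width: int,
    height: int,
    *,
    estimate_k3: bool = False,
    estimate_skew: bool = False,
    refine: bool = True,
) -> CalibrationResult:
    """Zhang planar calibration: closed-form init + joint LM refinement.

    Requires at least three views with distinct orientations; an
    all-fronto-parallel set leaves the intrinsic constraints
    rank-deficient and raises ``CalibrationError``.
    """
    if len(views) < config.MIN_CALIBRATION_VIEWS:
        raise CalibrationError(
            f"need >= {config.MIN_CALIBRATION_VIEWS} views, got {len(views)}"
        )
    Hs = [homography_dlt(v.object_points, v.image_points) for v in views]
    K0 = _intrinsics_from_homographies(Hs, width, height, estimate_skew)
    poses0 = [
        _extrinsics_from_homography(K0.matrix, H, v.view_id or f"view{i}")
        for i, (H, v) in enumerate(zip(Hs, views))
    ]

    obj3d = [np.column_stack([v.object_points, np.zeros(len(v.object_points))]) for v in views]
    img = np.concatenate([v.image_points for v in views])
    n_pts = np.array([len(v.object_points) for v in views])
    n_total = int(n_pts.sum())
    obj_all = np.concatenate(obj3d)
    view_idx = np.repeat(np.arange(len(views)), n_pts)

    def reproject_all(K: CameraIntrinsics, poses: list[RigidTransform]) -> np.ndarray:
        return np.concatenate(
            [project(K, pose.apply(o)) for o, pose in zip(obj3d, poses)]
        )

    def rms_of(K: CameraIntrinsics, poses: list[RigidTransform]) -> float:
        # RMS per pixel coordinate (matches the noise sigma per axis)
        d = reproject_all(K, poses) - img
        return float(np.sqrt(np.mean(d * d)))

    initial_rms = rms_of(K0, poses0)
    if not refine:
        per_view = _per_view_rms(K0, poses0, obj3d, views)
        return CalibrationResult(K0, poses0, initial_rms, per_view, initial_rms)

    # parameter vector: [fx, fy, cx, cy, (skew), k1, k2, p1, p2, (k3)] + 6 per view
    n_intr = 8 + int(estimate_skew) + int(estimate_k3)

    def pack() -> np.ndarray:
        p = [K0.fx, K0.fy, K0.cx, K0.cy]
        if estimate_skew:
            p.append(K0.skew)
        p += [0.0, 0.0, 0.0, 0.0]
        if estimate_k3:
            p.append(0.0)
        for pose in poses0:
            p.extend(Rotation.from_matrix(pose.rotation).as_rotvec())
            p.extend(pose.translation)
        return np.array(p)

    def split(p: np.ndarray):
        i = 4
        skew = p[i] if estimate_skew else 0.0
        i += int(estimate_skew)
        k1, k2, p1, p2 = p[i : i + 4]
        i += 4
        k3 = p[i] if estimate_k3 else 0.0
        i += int(estimate_k3)
        pose_params = p[i:].reshape(len(views), 6)
        return p[0], p[1], p[2], p[3], skew, (k1, k2, p1, p2, k3), pose_params

    def unpack(p: np.ndarray) -> tuple[CameraIntrinsics, list[RigidTransform]]:
        fx, fy, cx, cy, skew, dist, pose_params = split(p)
        K = CameraIntrinsics(
            fx=fx, fy=fy, cx=cx, cy=cy, width=width, height=height,
            skew=skew, dist=np.array(dist),
        )
        poses = [
            RigidTransform(
                Rotation.from_rotvec(pp[:3]).as_matrix(), pp[3:],
                source=poses0[j].source, target="camera",
            )
            for j, pp in enumerate(pose_params)
        ]
        return K, poses

    evals = [0]

    def residuals(p: np.ndarray) -> np.ndarray:
        # hot path: raw-array reprojection, no domain-object validation
        evals[0] += 1
        fx, fy, cx, cy, skew, (k1, k2, p1, p2, k3), pose_params = split(p)
        Rs = Rotation.from_rotvec(pose_params[:, :3]).as_matrix()
        cam = (
            np.einsum("nij,nj->ni", Rs[view_idx], obj_all)
            + pose_params[view_idx, 3:]
        )
        z = cam[:, 2]
        bad = z <= 1e-9
        z = np.where(bad, 1.0, z)
        x, y = cam[:, 0] / z, cam[:, 1] / z
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        uv = np.column_stack([fx * xd + skew * yd + cx, fy * yd + cy])
        res = uv - img
        res[bad] = 1e6
        return res.ravel()

    sol = least_squares(
        residuals,
        pack(),
        method="lm",
        ftol=config.REFINE_FTOL,
        xtol=1e-15,
        gtol=1e-15,
        max_nfev=config.REFINE_MAX_ITER * (n_intr + 6 * len(views)),
    )
    K, poses = unpack(sol.x)
    final_rms = rms_of(K, poses)
    if final_rms > initial_rms:  # refinement must not make things worse
        K, poses, final_rms = K0, poses0, initial_rms
    per_view = _per_view_rms(K, poses, obj3d, views)
    return CalibrationResult(K, poses, final_rms, per_view, initial_rms, evals[0])


def _per_view_rms(
    K: CameraIntrinsics,
    poses: list[RigidTransform],
    obj3d: list[np.ndarray],
    views: list[PlanarView],
) -> np.ndarray:
    out = []
    for o, pose, v in zip(obj3d, poses, views):
        d = project(K, pose.apply(o)) - v.image_points
        out.append(np.sqrt(np.mean(d * d)))
    return np.asarray(out)
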