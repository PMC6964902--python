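"""Camera pose (TCO) estimation from 2D–3D marker correspondences.

The minimal solver is a Grunert-style P3P: the law-of-cosines system in
the three view-ray depths is reduced to a quartic in one depth ratio via
the resultant of two quadratics; each real root yields a candidate pose
by a three-point rigid fit.  With the 25-marker calibration plate there
are always surplus points, so candidates are disambiguated by the
reprojection error of the remaining markers and the winner is polished
by Levenberg–Marquardt over all correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import config
from .camera import CameraIntrinsics, bearing_vectors, project
from .geometry import GeometryError, Point3, RigidTransform, matrix_to_quat
from .tracking import kabsch


class DegeneracyError(ValueError):
    """Raised when the correspondence geometry is degenerate."""


class PoseEstimationError(RuntimeError):
    """Raised when no acceptable pose can be found."""


@dataclass(frozen=True)
class Correspondence2D3D:
    """A tracked 3D marker (world/OTS frame, mm) and its pixel detection."""

    marker_id: str
    world_point: Point3
    image_point: tuple[float, float]

    def __post_init__(self) -> None:
        uv = np.asarray(self.image_point, dtype=float)
        if not np.all(np.isfinite(uv)):
            raise GeometryError("image point must be finite")
        object.__setattr__(self, "image_point", (float(uv[0]), float(uv[1])))


@dataclass
class PoseResult:
    pose: RigidTransform          # O←C camera pose
    rms_px: float
    inlier_ids: list[str]
    n_candidates: int


def _triangle_area(pts: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])))


def _resultant_quartic(cos_a, cos_b, cos_g, a2, b2, c2) -> np.ndarray:
    """Coefficients (ascending) of the quartic in v = s3/s1.

    Eliminates u = s2/s1 between the two law-of-cosines quadratics
    p(u) = u² − 2cosγ·u + (1 − (c²/b²)(1 + v² − 2v·cosβ))
    q(u) = u² − 2v·cosα·u + (v² − (a²/b²)(1 + v² − 2v·cosβ))
    via Res = α²·a0 − αβ·a1 + β² with α = q1−p1, β = q0−p0.
    """
    rb = 1.0 / b2
    # polynomials in v, ascending coefficients
    w = np.array([1.0, -2.0 * cos_b, 1.0])          # 1 + v² − 2v cosβ
    p0 = np.array([1.0, 0.0, 0.0]) - c2 * rb * w     # a0(v)
    p1c = -2.0 * cos_g                               # a1 (constant)
    q0 = np.array([0.0, 0.0, 1.0]) - a2 * rb * w     # b0(v)
    alpha = np.array([2.0 * cos_g, -2.0 * cos_a])    # q1 − p1 = −2v cosα + 2cosγ
    beta = q0 - p0
    res = P.polysub(
        P.polyadd(P.polymul(P.polymul(alpha, alpha), p0), P.polymul(beta, beta)),
        P.polymul(alpha, beta) * p1c,
    )
    out = np.zeros(5)
    out[: len(res)] = res
    return out


def p3p_solve(
    correspondences: list[Correspondence2D3D], K: CameraIntrinsics
) -> list[RigidTransform]:
    """All physically valid P3P poses for exactly three correspondences.

    Returns up to four O←C candidates, sorted by the lexicographic order
    of their rotation quaternions (scalar part >= 0) for determinism.
    Noiselessly, each candidate reprojects the defining triple exactly.
    """
    if len(correspondences) != 3:
        raise ValueError("p3p_solve takes exactly 3 correspondences")
    world = np.array([c.world_point.to_array() for c in correspondences])
    frame = correspondences[0].world_point.frame
    pix = np.array([c.image_point for c in correspondences])

    side = max(np.linalg.norm(world - world.mean(axis=0), axis=1).max(), 1e-9)
    if _triangle_area(world) < config.P3P_COLLINEARITY_TOL * side * side:
        raise DegeneracyError("the three world points are (near-)collinear")

    f = bearing_vectors(K, pix)  # unit rays, camera frame
    cos_a = float(f[1] @ f[2])   # opposite side a = |P2P3|
    cos_b = float(f[0] @ f[2])
    cos_g = float(f[0] @ f[1])
    a2 = float(np.sum((world[1] - world[2]) ** 2))
    b2 = float(np.sum((world[0] - world[2]) ** 2))
    c2 = float(np.sum((world[0] - world[1]) ** 2))

    coeffs = _resultant_quartic(cos_a, cos_b, cos_g, a2, b2, c2)
    scale = np.abs(coeffs).max()
    if scale == 0:
        return []
    coeffs = coeffs / scale
    roots = np.polynomial.polynomial.polyroots(coeffs)
    scale2 = max(a2, b2, c2)

    def polish(u: float, v: float) -> tuple[float, float] | None:
        """Newton on the 2x2 system in the depth ratios.

        g1 = (1+u²−2u·cosγ)·b² − w(v)·c²,  g2 = (u²+v²−2uv·cosα)·b² − w(v)·a²
        with w(v) = 1+v²−2v·cosβ.  Clustered quartic roots are only
        sqrt/cbrt(eps)-accurate; this restores full precision.
        """
        for _ in range(50):
            w = 1.0 + v * v - 2.0 * v * cos_b
            g1 = (1.0 + u * u - 2.0 * u * cos_g) * b2 - w * c2
            g2 = (u * u + v * v - 2.0 * u * v * cos_a) * b2 - w * a2
            if abs(g1) < 1e-12 * scale2 and abs(g2) < 1e-12 * scale2:
                return u, v
            j11 = (2.0 * u - 2.0 * cos_g) * b2
            j12 = -(2.0 * v - 2.0 * cos_b) * c2
            j21 = (2.0 * u - 2.0 * v * cos_a) * b2
            j22 = (2.0 * v - 2.0 * u * cos_a) * b2 - (2.0 * v - 2.0 * cos_b) * a2
            det = j11 * j22 - j12 * j21
            if abs(det) < 1e-300:
                return None
            du = (g1 * j22 - g2 * j12) / det
            dv = (j11 * g2 - j21 * g1) / det
            u, v = u - du, v - dv
        return None

    candidates_uv: list[tuple[float, float]] = []
    for r in roots:
        if abs(r.imag) > 1e-4 * max(1.0, abs(r.real)):
            continue
        v = float(r.real)
        if v <= 0:
            continue
        denom = 1.0 + v * v - 2.0 * v * cos_b
        if denom <= 0:
            continue
        s1sq = b2 / denom
        # u from the linear combination eliminating u²; near a multiple
        # root (alpha ≈ 0) both quadratic branches are seeded instead
        alpha = 2.0 * cos_g - 2.0 * v * cos_a
        beta = (v * v - a2 / b2 * denom) - (1.0 - c2 / b2 * denom)
        if abs(alpha) > 1e-6:
            seeds = [-beta / alpha]
        else:
            disc = cos_g * cos_g - (1.0 - c2 / s1sq)
            if disc < 0:
                continue
            seeds = [cos_g + np.sqrt(disc), cos_g - np.sqrt(disc)]
        for u0 in seeds:
            sol = polish(float(u0), v)
            if sol is None:
                continue
            u, v_ = sol
            if u <= 0 or v_ <= 0:
                continue
            if not any(
                abs(u - pu) < 1e-7 and abs(v_ - pv) < 1e-7 for pu, pv in candidates_uv
            ):
                candidates_uv.append((u, v_))

    poses: list[RigidTransform] = []
    seen: list[np.ndarray] = []
    for u, v in candidates_uv:
        denom = 1.0 + v * v - 2.0 * v * cos_b
        if denom <= 0:
            continue
        s1 = float(np.sqrt(b2 / denom))
        depths = s1 * np.array([1.0, u, v])
        cam_pts = f * depths[:, None]
        try:
            R, t, _ = kabsch(world, cam_pts)  # camera←world
        except DegeneracyError:
            continue
        pose = RigidTransform(R, t, source=frame, target="camera").invert()  # O←C
        q = matrix_to_quat(pose.rotation)
        if any(np.allclose(q, qs, atol=1e-8) for qs in seen):
            continue
        seen.append(q)
        poses.append(pose)

    order = np.lexsort(np.array([matrix_to_quat(p.rotation) for p in poses]).T[::-1]) if poses else []
    return [poses[i] for i in order]


def _reprojection_rms(
    pose: RigidTransform, world: np.ndarray, pix: np.ndarray, K: CameraIntrinsics
) -> float:
    cam = pose.invert().apply(world)
    if np.any(cam[:, 2] <= 0):
        return np.inf
    d = project(K, cam) - pix
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _refine_pose(
    pose: RigidTransform, world: np.ndarray, pix: np.ndarray, K: CameraIntrinsics, frame: str
) -> RigidTransform:
    inv = pose.invert()  # camera←world

    def unpack(p: np.ndarray) -> RigidTransform:
        return RigidTransform(
            Rotation.from_rotvec(p[:3]).as_matrix(), p[3:], source=frame, target="camera"
        )

    def residuals(p: np.ndarray) -> np.ndarray:
        cw = unpack(p)
        cam = cw.apply(world)
        if np.any(cam[:, 2] <= 1e-9):
            return np.full(2 * len(world), 1e6)
        return (project(K, cam) - pix).ravel()

    x0 = np.concatenate([Rotation.from_matrix(inv.rotation).as_rotvec(), inv.translation])
    sol = least_squares(
        residuals, x0, method="lm", ftol=config.REFINE_FTOL, xtol=1e-15, gtol=1e-15,
        max_nfev=2000,
    )
    return unpack(sol.x).invert()


def _select_triple(world: np.ndarray, ids: list[str]) -> tuple[int, int, int]:
    """Maximal-area triangle; ties broken by sorted marker id order."""
    n = len(world)
    idx_order = sorted(range(n), key=lambda i: ids[i])
    best, best_area = None, -1.0
    for tri in combinations(idx_order, 3):
        area = _triangle_area(world[list(tri)])
        if area > best_area + 1e-12:
            best, best_area = tri, area
    return best  # type: ignore[return-value]


def estimate_camera_pose(
    correspondences: list[Correspondence2D3D],
    K: CameraIntrinsics,
    *,
    ransac: bool = False,
    ransac_threshold_px: float = 2.0,
    ransac_iterations: int = 200,
    max_rms_px: float = np.inf,
    seed: int = 0,
) -> PoseResult:
    """Estimate TCO from >= 4 correspondences.

    P3P on the maximal-area triple, disambiguation by the reprojection
    of the remaining points, LM refinement over all (inlier)
    correspondences.  RANSAC is off by default: the calibration plate is
    a controlled setting without gross outliers.
    """
    if len(correspondences) < 4:
        raise DegeneracyError("pose estimation needs at least 4 correspondences")
    cs = sorted(correspondences, key=lambda c: c.marker_id)
    ids = [c.marker_id for c in cs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker_id in correspondence set")
    world = np.array([c.world_point.to_array() for c in cs])
    pix = np.array([c.image_point for c in cs])
    frame = cs[0].world_point.frame

    inlier_mask = np.ones(len(cs), dtype=bool)
    if ransac:
        rng = np.random.default_rng(seed)
        best_inliers = None
        for _ in range(ransac_iterations):
            tri = rng.choice(len(cs), size=3, replace=False)
            if _triangle_area(world[tri]) < 1e-9:
                continue
            try:
                cands = p3p_solve([cs[i] for i in tri], K)
            except DegeneracyError:
                continue
            for cand in cands:
                cam = cand.invert().apply(world)
                ok = cam[:, 2] > 0
                err = np.full(len(cs), np.inf)
                if ok.any():
                    d = project(K, np.clip(cam, [-1e9, -1e9, 1e-6], None)) - pix
                    err[ok] = np.linalg.norm(d[ok], axis=1)
                inl = err < ransac_threshold_px
                if best_inliers is None or inl.sum() > best_inliers.sum():
                    best_inliers = inl
        if best_inliers is None or best_inliers.sum() < 4:
            raise PoseEstimationError("RANSAC found no consensus set")
        inlier_mask = best_inliers

    w_in, p_in = world[inlier_mask], pix[inlier_mask]
    ids_in = [i for i, m in zip(ids, inlier_mask) if m]
    tri = _select_triple(w_in, ids_in)
    triple = [
        Correspondence2D3D(ids_in[i], Point3.from_array(w_in[i], frame), tuple(p_in[i]))
        for i in tri
    ]
    candidates = p3p_solve(triple, K)
    if not candidates:
        raise PoseEstimationError("P3P produced no real pose candidate")
    rest = np.setdiff1d(np.arange(len(w_in)), np.array(tri))
    scores = [
        _reprojection_rms(c, w_in[rest] if len(rest) else w_in, p_in[rest] if len(rest) else p_in, K)
        for c in candidates
    ]
    best = candidates[int(np.argmin(scores))]
    if not np.isfinite(min(scores)):
        raise PoseEstimationError("all P3P candidates place points behind the camera")
    pose = _refine_pose(best, w_in, p_in, K, frame)
    rms = _reprojection_rms(pose, w_in, p_in, K)
    if rms > max_rms_px:
        raise PoseEstimationError(f"refined pose RMS {rms:.2f} px exceeds limit {max_rms_px}")
    return PoseResult(pose=pose, rms_px=rms, inlier_ids=ids_in, n_candidates=len(candidates))
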