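"""Distorted pinhole model of the endoscope camera.

The model is the standard Zhang-era one: perspective division to the
normalized image plane, a radial (k1, k2, k3) + tangential (p1, p2)
distortion polynomial, then the affine intrinsic map

    u = fx·x' + skew·y' + cx,   v = fy·y' + cy.

A 35 mm-coupler endoscope is dominated by low-order radial terms, so k3
defaults to zero and is only estimated on request during calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .geometry import GeometryError, Point3


class BehindCameraError(ValueError):
    """A point with z <= 0 cannot be projected."""


class ConvergenceError(RuntimeError):
    """Iterative undistortion failed to converge."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with lens distortion.

    ``dist`` holds (k1, k2, p1, p2, k3) — radial k's, tangential p's —
    dimensionless coefficients acting on normalized image coordinates.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    skew: float = 0.0
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise GeometryError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise GeometryError("principal point must lie inside the image")
        d = np.asarray(self.dist, dtype=float).reshape(5).copy()
        d.flags.writeable = False
        object.__setattr__(self, "dist", d)

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, self.skew, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def image_size(self) -> tuple[int, int]:
        return (self.width, self.height)

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics of the same lens on a sensor rescaled by ``factor``.

        Distortion coefficients act on normalized coordinates and are
        unchanged; all pixel quantities scale.
        """
        return CameraIntrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=self.cx * factor,
            cy=self.cy * factor,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
            skew=self.skew * factor,
            dist=self.dist,
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "skew": self.skew,
            "dist": [float(x) for x in self.dist],
            "width": self.width,
            "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
            skew=float(d.get("skew", 0.0)),
            dist=np.asarray(d.get("dist", np.zeros(5)), dtype=float),
        )


def default_endoscope(scale: float = 1.0) -> CameraIntrinsics:
    """The simulated endoscope: 2590x1942 sensor, wide-angle lens defaults."""
    k = CameraIntrinsics(
        fx=config.DEFAULT_FX,
        fy=config.DEFAULT_FY,
        cx=config.SENSOR_WIDTH / 2.0,
        cy=config.SENSOR_HEIGHT / 2.0,
        width=config.SENSOR_WIDTH,
        height=config.SENSOR_HEIGHT,
        dist=np.array([config.DEFAULT_K1, config.DEFAULT_K2, 0.0, 0.0, 0.0]),
    )
    return k.scaled(scale) if scale != 1.0 else k


def distort_normalized(dist: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Apply the distortion polynomial to normalized coordinates (N,2)."""
    k1, k2, p1, p2, k3 = np.asarray(dist, dtype=float).reshape(5)
    xy = np.asarray(xy, dtype=float)
    single = xy.ndim == 1
    xy = np.atleast_2d(xy)
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    out = np.column_stack([xd, yd])
    return out[0] if single else out


def project(K: CameraIntrinsics, points_cam: "np.ndarray | Point3") -> np.ndarray:
    """Project camera-frame points (mm) to pixel coordinates.

    Accepts a single ``Point3`` (frame must be ``camera``), a 3-vector or
    an (N,3) array; returns (2,) or (N,2) pixels.  Points with z <= 0
    are rejected.
    """
    if isinstance(points_cam, Point3):
        if points_cam.frame != "camera":
            raise GeometryError(f"expected a camera-frame point, got '{points_cam.frame}'")
        points_cam = points_cam.to_array()
    p = np.asarray(points_cam, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(p[:, 2] <= 0):
        raise BehindCameraError("point(s) at z <= 0 cannot be projected")
    xy = p[:, :2] / p[:, 2:3]
    xyd = distort_normalized(K.dist, xy)
    u = K.fx * xyd[:, 0] + K.skew * xyd[:, 1] + K.cx
    v = K.fy * xyd[:, 1] + K.cy
    out = np.column_stack([u, v])
    return out[0] if single else out


def undistort(
    K: CameraIntrinsics,
    pixels: np.ndarray,
    tol: float = config.UNDISTORT_TOL,
    max_iter: int = config.UNDISTORT_MAX_ITER,
) -> np.ndarray:
    """Invert the distortion: pixels → undistorted normalized coordinates.

    Fixed-point iteration x ← (xd − tangential(x)) / radial(x), which
    converges for the distortion magnitudes of real endoscope optics;
    non-convergence raises ``ConvergenceError``.
    """
    k1, k2, p1, p2, k3 = K.dist
    px = np.asarray(pixels, dtype=float)
    single = px.ndim == 1
    px = np.atleast_2d(px)
    yd = (px[:, 1] - K.cy) / K.fy
    xd = (px[:, 0] - K.cx - K.skew * yd) / K.fx
    x, y = xd.copy(), yd.copy()
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        x_new = (xd - dx) / radial
        y_new = (yd - dy) / radial
        step = max(np.abs(x_new - x).max(), np.abs(y_new - y).max())
        x, y = x_new, y_new
        if step < tol:
            break
    else:
        raise ConvergenceError(f"undistortion did not converge within {max_iter} iterations")
    out = np.column_stack([x, y])
    return out[0] if single else out


def bearing_vectors(K: CameraIntrinsics, pixels: np.ndarray) -> np.ndarray:
    """Unit view rays in the camera frame for the given pixels (N,3)."""
    xy = np.atleast_2d(undistort(K, pixels))
    f = np.column_stack([xy, np.ones(len(xy))])
    return f / np.linalg.norm(f, axis=1, keepdims=True)


def projected_sphere_radius_px(
    K: CameraIntrinsics, z_mm: float, radius_mm: float, mode: str = "tangent"
) -> float:
    """Apparent pixel radius of a sphere of ``radius_mm`` at depth ``z_mm``.

    ``tangent`` uses the small-sphere approximation f·r/z; ``exact`` uses
    the tangent-cone half-angle, f·r/sqrt(z²−r²), which matters only when
    the sphere subtends a large angle.
    """
    f = 0.5 * (K.fx + K.fy)
    if z_mm <= radius_mm:
        raise BehindCameraError("sphere centre too close to the camera")
    if mode == "exact":
        return f * radius_mm / float(np.sqrt(z_mm * z_mm - radius_mm * radius_mm))
    return f * radius_mm / z_mm
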