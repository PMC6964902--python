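"""Rigid-transform algebra over named coordinate frames.

Every transform is an element of SE(3) labelled ``target ← source``: a
transform with ``source="camera"``, ``target="ots"`` maps camera-frame
coordinates into the optical-tracking (world) frame.  Composition chains
the labels and refuses mismatches, which catches plumbing errors in the
fusion chain at the point where they are introduced rather than three
matrix products later.

The navigation chain uses four frames:

* ``ots``     — the optical tracking system / world frame (O),
* ``marker``  — the endoscope-mounted marker disc (M),
* ``camera``  — the endoscope camera (C),
* ``cbct``    — the patient / CBCT frame (P).

The image-fusion identities are ``TCO = TMO ∘ TCM`` and
``TCP = TPO⁻¹ ∘ (TMO ∘ TCM)``, with TXO denoting the pose of frame X in
the world, i.e. the O←X transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from . import config


class FrameError(ValueError):
    """Raised when transform frame labels do not chain."""


class GeometryError(ValueError):
    """Raised for numerically invalid geometric input."""


def _check_rotation(R: np.ndarray, tol: float = config.ORTHONORMALITY_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise GeometryError(f"rotation must be 3x3, got {R.shape}")
    err = np.abs(R @ R.T - np.eye(3)).max()
    det = np.linalg.det(R)
    if err > tol or abs(det - 1.0) > tol:
        raise GeometryError(
            f"matrix is not a proper rotation (orthonormality error {err:.2e}, det {det:.12f})"
        )
    return R


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD (nearest in Frobenius norm)."""
    U, _, Vt = np.linalg.svd(np.asarray(R, dtype=float))
    D = np.diag([1.0, 1.0, np.linalg.det(U @ Vt)])
    return U @ D @ Vt


@dataclass(frozen=True)
class Point3:
    """A 3D point (mm) tagged with the frame its coordinates live in."""

    x: float
    y: float
    z: float
    frame: str = "ots"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise GeometryError("point coordinates must be finite")

    @classmethod
    def from_array(cls, a: np.ndarray, frame: str = "ots") -> "Point3":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class RigidTransform:
    """An SE(3) element mapping ``source``-frame coordinates into ``target``.

    ``rotation`` is a proper orthonormal 3x3 matrix, ``translation`` a
    3-vector in millimetres.  Validation happens at construction; the
    arrays are copied and made read-only.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source: str = "source"
    target: str = "target"

    def __post_init__(self) -> None:
        R = _check_rotation(self.rotation).copy()
        t = np.asarray(self.translation, dtype=float).reshape(3).copy()
        if not np.all(np.isfinite(t)):
            raise GeometryError("translation must be finite")
        R.flags.writeable = False
        t.flags.writeable = False
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # --- constructors -----------------------------------------------------
    @classmethod
    def identity(cls, frame: str = "ots", source: str | None = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source=source or frame, target=frame)

    @classmethod
    def from_matrix(cls, M: np.ndarray, source: str, target: str) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise GeometryError("homogeneous matrix must be 4x4")
        return cls(M[:3, :3], M[:3, 3], source=source, target=target)

    @classmethod
    def from_rotvec(
        cls, rotvec: np.ndarray, translation: np.ndarray, source: str, target: str
    ) -> "RigidTransform":
        return cls(
            Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
            translation,
            source=source,
            target=target,
        )

    # --- algebra ----------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first).

        Frames must chain: ``(A←B) ∘ (B←C) = A←C``.
        """
        if self.source != other.target:
            raise FrameError(
                f"cannot compose {self.target}←{self.source} with "
                f"{other.target}←{other.source}: '{self.source}' != '{other.target}'"
            )
        R = self.rotation @ other.rotation
        if np.abs(R @ R.T - np.eye(3)).max() > config.COMPOSE_DRIFT_TOL:
            R = orthonormalize(R)
        t = self.rotation @ other.translation + self.translation
        return RigidTransform(R, t, source=other.source, target=self.target)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, source=self.target, target=self.source)

    def apply(self, p: "Point3 | np.ndarray") -> "Point3 | np.ndarray":
        """Map a point (or an (N,3) array) from the source into the target frame.

        ``Point3`` inputs are frame-checked; bare arrays are trusted.
        """
        if isinstance(p, Point3):
            if p.frame != self.source:
                raise FrameError(
                    f"point is in frame '{p.frame}', transform expects '{self.source}'"
                )
            return Point3.from_array(self.rotation @ p.to_array() + self.translation, self.target)
        a = np.asarray(p, dtype=float)
        return a @ self.rotation.T + self.translation

    def relabel(self, source: str | None = None, target: str | None = None) -> "RigidTransform":
        return RigidTransform(
            self.rotation,
            self.translation,
            source=source if source is not None else self.source,
            target=target if target is not None else self.target,
        )

    # --- metrics ----------------------------------------------------------
    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Geodesic angle (rad) between the two rotations."""
        return rotation_angle(self.rotation.T @ other.rotation)

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))

    def is_close(self, other: "RigidTransform", rot_tol: float = 1e-9, trans_tol: float = 1e-9) -> bool:
        return (
            self.rotation_angle_to(other) <= rot_tol
            and self.translation_distance_to(other) <= trans_tol
        )


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle (rad) of a rotation matrix, robust near 0 and π."""
    return float(np.linalg.norm(Rotation.from_matrix(orthonormalize(R)).as_rotvec()))


# --- the fusion equations --------------------------------------------------

def camera_pose_from_marker(tmo: RigidTransform, tcm: RigidTransform) -> RigidTransform:
    """Camera pose in the world: ``TCO = TMO ∘ TCM``.

    TMO is the tracked endoscope-marker pose (O←M) and TCM the fixed
    hand-eye transform (M←C); the product is the O←C camera pose.
    """
    return tmo @ tcm


def patient_to_camera(
    tpo: RigidTransform, tmo: RigidTransform, tcm: RigidTransform
) -> RigidTransform:
    """The fusion transform ``TCP = TPO⁻¹ ∘ (TMO ∘ TCM)``.

    This is the camera pose expressed in the patient/CBCT frame (P←C).
    To map a CBCT-frame point into camera coordinates for projection,
    apply its inverse — see :func:`camera_from_patient`.
    """
    return tpo.invert() @ (tmo @ tcm)


def camera_from_patient(
    tpo: RigidTransform, tmo: RigidTransform, tcm: RigidTransform
) -> RigidTransform:
    """The C←P transform that carries CBCT points into the camera frame."""
    return patient_to_camera(tpo, tmo, tcm).invert()


# --- rotation representation conversions -----------------------------------

def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) with scalar part >= 0."""
    _check_rotation(R)
    q = Rotation.from_matrix(R).as_quat()  # (x, y, z, w)
    q = np.array([q[3], q[0], q[1], q[2]])
    if q[0] < 0 or (q[0] == 0 and (q[np.nonzero(q)[0][0]] if q.any() else 1) < 0):
        q = -q
    return q


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if n == 0:
        raise GeometryError("zero quaternion")
    q = q / n
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def matrix_to_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """(unit axis, angle in [0, π]); axis is (0,0,1) by convention at angle 0."""
    _check_rotation(R)
    rv = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-300:
        return np.array([0.0, 0.0, 1.0]), 0.0
    return rv / angle, angle


def axis_angle_to_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n == 0:
        raise GeometryError("zero rotation axis")
    return Rotation.from_rotvec(axis / n * angle).as_matrix()


# --- frame graph ------------------------------------------------------------

@dataclass
class FrameGraph:
    """A set of rigid transforms organised as an undirected graph of frames.

    Querying a (target, source) pair composes transforms along the
    shortest registered path, inverting edges as needed.  Redundant
    edges make loops whose consistency can be audited.
    """

    _edges: dict[tuple[str, str], RigidTransform] = field(default_factory=dict)

    def add(self, t: RigidTransform) -> None:
        self._edges[(t.target, t.source)] = t

    def frames(self) -> set[str]:
        out: set[str] = set()
        for tgt, src in self._edges:
            out.update((tgt, src))
        return out

    def _neighbors(self, frame: str) -> Iterable[tuple[str, RigidTransform]]:
        for (tgt, src), t in self._edges.items():
            if src == frame:
                yield tgt, t
            if tgt == frame:
                yield src, t.invert()

    def get(self, target: str, source: str) -> RigidTransform:
        if target == source:
            return RigidTransform.identity(target)
        # BFS with deterministic neighbor order
        prev: dict[str, tuple[str, RigidTransform]] = {}
        queue = [source]
        seen = {source}
        while queue:
            cur = queue.pop(0)
            for nxt, t in sorted(self._neighbors(cur), key=lambda it: it[0]):
                if nxt in seen:
                    continue
                seen.add(nxt)
                prev[nxt] = (cur, t)
                if nxt == target:
                    queue = []
                    break
                queue.append(nxt)
        if target not in prev:
            raise FrameError(f"no path from '{source}' to '{target}' in frame graph")
        chain: list[RigidTransform] = []
        node = target
        while node != source:
            node, t = prev[node]
            chain.append(t)
        out = RigidTransform.identity(source)
        for t in reversed(chain):
            out = t @ out
        return out.relabel(source=source, target=target)

    def cycle_consistency(self, target: str, source: str) -> tuple[float, float]:
        """Compare a direct edge against the best indirect path.

        Returns (rotation angle rad, translation mm) between the direct
        edge and the composition found when that edge is removed.
        Raises ``FrameError`` if there is no redundant path.
        """
        key = (target, source)
        if key not in self._edges:
            raise FrameError(f"no direct edge {target}←{source}")
        direct = self._edges[key]
        rest = FrameGraph({k: v for k, v in self._edges.items() if k != key})
        indirect = rest.get(target, source)
        return direct.rotation_angle_to(indirect), direct.translation_distance_to(indirect)
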