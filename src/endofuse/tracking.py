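"""Marker tracking, rigid point-set registration and motion compensation.

The optical tracking system reports 3D marker positions in its own
(world) frame.  At CBCT-acquisition time the patient-surface markers are
frozen into a virtual reference grid (VRG) tied to the CBCT frame; every
later frame is registered against that reference to recover the current
patient pose TPO, so the CBCT overlay follows patient motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import config
from .geometry import GeometryError, Point3, RigidTransform


class DegeneracyError(ValueError):
    """Point configuration too degenerate for a unique rigid fit."""


@dataclass(frozen=True)
class MarkerObservation:
    """One tracked optical marker in the OTS frame at one time step."""

    marker_id: str
    position: Point3
    visible: bool = True

    def __post_init__(self) -> None:
        if self.visible and not np.all(np.isfinite(self.position.to_array())):
            raise GeometryError("visible markers must have finite positions")


def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit dst ≈ R·src + t via cross-covariance SVD.

    Includes the determinant (reflection) guard, which matters for the
    near-planar marker sets of surgical phantoms.  Returns (R, t, FRE)
    with FRE the RMS residual in mm.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must be matching (N,3) arrays")
    if len(src) < 3:
        raise DegeneracyError("rigid registration needs at least 3 points")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < config.COLLINEARITY_SV_RATIO * max(sv[0], 1.0):
        raise DegeneracyError("source points are (near-)collinear")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    resid = dst - (src @ R.T + t)
    fre = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    return R, t, fre


def register_point_sets(
    src: "Mapping[str, np.ndarray] | np.ndarray",
    dst: "Mapping[str, np.ndarray] | np.ndarray",
    *,
    source_frame: str = "source",
    target_frame: str = "target",
) -> tuple[RigidTransform, float]:
    """Closed-form rigid registration of corresponding point sets.

    Mappings are matched by id (sorted order, intersection of keys);
    bare arrays are matched row-by-row.  Returns the target←source
    transform and the fiducial registration error (RMS, mm).
    """
    if isinstance(src, Mapping) or isinstance(dst, Mapping):
        if not (isinstance(src, Mapping) and isinstance(dst, Mapping)):
            raise ValueError("either both or neither point set may be a mapping")
        common = sorted(set(src) & set(dst))
        if len(common) < 3:
            raise DegeneracyError(f"only {len(common)} common marker ids (need >= 3)")
        s = np.array([np.asarray(src[k], float).reshape(3) for k in common])
        d = np.array([np.asarray(dst[k], float).reshape(3) for k in common])
    else:
        s, d = np.asarray(src, float), np.asarray(dst, float)
    R, t, fre = kabsch(s, d)
    return RigidTransform(R, t, source=source_frame, target=target_frame), fre


@dataclass
class VirtualReferenceGrid:
    """Patient-surface marker configuration frozen at CBCT time.

    ``reference_positions`` are OTS-frame marker positions at
    acquisition; ``cbct_from_ots`` maps that snapshot of the OTS frame
    into the CBCT frame (identity when the CBCT frame is *defined* as
    the OTS frame at acquisition, as with a rigidly integrated C-arm).
    """

    reference_positions: dict[str, np.ndarray]
    cbct_from_ots: RigidTransform
    registration_fre_mm: float = 0.0

    def __post_init__(self) -> None:
        if len(self.reference_positions) < config.MIN_TRACKING_MARKERS:
            raise DegeneracyError("a VRG needs at least 3 reference markers")
        pts = np.array(list(self.reference_positions.values()))
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < config.COLLINEARITY_SV_RATIO * max(sv[0], 1.0):
            raise DegeneracyError("VRG reference markers are collinear")


@dataclass
class PatientPoseResult:
    """Output of :func:`estimate_patient_pose`; check ``tracking_lost`` first."""

    tpo: RigidTransform | None      # O←P (cbct) pose, None when tracking is lost
    fre_mm: float
    n_markers: int
    tracking_lost: bool = False


def _visible_positions(observations: Sequence[MarkerObservation]) -> dict[str, np.ndarray]:
    return {o.marker_id: o.position.to_array() for o in observations if o.visible}


def build_vrg(
    observations: Sequence[MarkerObservation],
    hybrid_cbct_positions: Mapping[str, np.ndarray] | None = None,
) -> VirtualReferenceGrid:
    """Freeze the current marker observations into a VRG.

    With hybrid (optical + radiopaque) marker positions known in the
    CBCT frame, the OTS→CBCT transform is estimated by rigid
    registration; without them the CBCT frame is defined to coincide
    with the OTS frame at acquisition time.
    """
    ref = _visible_positions(observations)
    if len(ref) < config.MIN_TRACKING_MARKERS:
        raise DegeneracyError(f"need >= 3 visible markers to build a VRG, got {len(ref)}")
    if hybrid_cbct_positions is not None:
        t, fre = register_point_sets(
            ref, hybrid_cbct_positions, source_frame="ots", target_frame="cbct"
        )
        return VirtualReferenceGrid(ref, t, fre)
    return VirtualReferenceGrid(ref, RigidTransform.identity("cbct", source="ots"))


def estimate_patient_pose(
    vrg: VirtualReferenceGrid, observations: Sequence[MarkerObservation]
) -> PatientPoseResult:
    """Current patient pose TPO (O←P) from the markers shared with the VRG.

    The reference-to-current registration gives the motion of the
    patient in the OTS frame since acquisition; composing with the
    OTS→CBCT mapping yields TPO.  Fewer than 3 shared visible markers is
    a tracking-loss *state*, reported rather than raised, since marker
    occlusion is a normal transient during surgery.
    """
    current = _visible_positions(observations)
    shared = sorted(set(current) & set(vrg.reference_positions))
    if len(shared) < config.MIN_TRACKING_MARKERS:
        return PatientPoseResult(None, np.inf, len(shared), tracking_lost=True)
    motion, fre = register_point_sets(
        {k: vrg.reference_positions[k] for k in shared},
        {k: current[k] for k in shared},
        source_frame="ots@cbct",
        target_frame="ots",
    )
    # motion maps acquisition-time OTS coords to current ones; chaining
    # through cbct_from_ots⁻¹ (acquisition-OTS ← CBCT) makes it the O←P pose.
    ots_acq_from_cbct = vrg.cbct_from_ots.invert().relabel(target="ots@cbct")
    tpo = motion @ ots_acq_from_cbct
    return PatientPoseResult(tpo, fre, len(shared))
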