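"""Hand-eye calibration: the fixed marker→camera transform TCM.

The OTS tracks the endoscope-mounted marker (TMO, O←M) while the
calibration plate gives an independent camera pose (TCO, O←C) per view.
Because both poses live in the *same* world frame, each view yields an
exact per-sample estimate X_i = TMO_i⁻¹ ∘ TCO_i of TCM, and averaging
those ("direct" path) is the natural least-squares estimator.  The
classical AX = XB formulation over relative motions is provided as an
independent cross-check; it requires at least two relative motions with
non-parallel rotation axes, a condition that fails on the protocol
where the endoscope is held fixed and only the plate moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    RigidTransform,
    matrix_to_axis_angle,
    matrix_to_quat,
    quat_to_matrix,
    rotation_angle,
)
from .tracking import DegeneracyError, kabsch


@dataclass(frozen=True)
class HandEyeSample:
    """Simultaneous marker pose (from the OTS) and camera pose (from P3P)."""

    tmo: RigidTransform   # O←M
    tco: RigidTransform   # O←C


@dataclass
class HandEyeResult:
    tcm: RigidTransform   # M←C
    rotation_residuals_rad: np.ndarray
    translation_residuals_mm: np.ndarray
    method: str

    @property
    def rms_rotation_rad(self) -> float:
        return float(np.sqrt(np.mean(self.rotation_residuals_rad**2)))

    @property
    def rms_translation_mm(self) -> float:
        return float(np.sqrt(np.mean(self.translation_residuals_mm**2)))


def average_rotations(Rs: list[np.ndarray]) -> np.ndarray:
    """Chordal-mean rotation via the quaternion outer-product eigen-method.

    Quaternion signs are aligned to the first sample, which resolves the
    double cover before accumulation.
    """
    qs = np.array([matrix_to_quat(R) for R in Rs])
    qs[np.einsum("ij,j->i", qs, qs[0]) < 0] *= -1
    M = qs.T @ qs
    w, V = np.linalg.eigh(M)
    return quat_to_matrix(V[:, -1])


def _per_sample_estimates(samples: list[HandEyeSample]) -> list[RigidTransform]:
    return [s.tmo.invert() @ s.tco for s in samples]


def _residuals(
    samples: list[HandEyeSample], tcm: RigidTransform
) -> tuple[np.ndarray, np.ndarray]:
    rot, tr = [], []
    for s in samples:
        predicted = s.tmo @ tcm  # reconstructed TCO
        rot.append(predicted.rotation_angle_to(s.tco))
        tr.append(predicted.translation_distance_to(s.tco))
    return np.asarray(rot), np.asarray(tr)


def _solve_direct(samples: list[HandEyeSample]) -> RigidTransform:
    xs = _per_sample_estimates(samples)
    R = average_rotations([x.rotation for x in xs])
    t = np.mean([x.translation for x in xs], axis=0)
    return RigidTransform(R, t, source="camera", target="marker")


def _relative_motions(
    samples: list[HandEyeSample],
) -> tuple[list[RigidTransform], list[RigidTransform]]:
    A, B = [], []
    n = len(samples)
    for i in range(n - 1):
        for j in range(i + 1, min(i + 4, n)):  # consecutive-ish pairs keep O(n)
            A.append(samples[i].tmo.invert() @ samples[j].tmo)
            B.append(samples[i].tco.invert() @ samples[j].tco)
    return A, B


def _solve_axxb(samples: list[HandEyeSample]) -> RigidTransform:
    A, B = _relative_motions(samples)
    axes_a, axes_b, weights = [], [], []
    for a, b in zip(A, B):
        ax_a, ang_a = matrix_to_axis_angle(a.rotation)
        ax_b, ang_b = matrix_to_axis_angle(b.rotation)
        if min(ang_a, ang_b) < 1e-8:
            continue
        w = 0.5 * (ang_a + ang_b)
        axes_a.append(ax_a * w)
        axes_b.append(ax_b * w)
        weights.append(w)
    if len(axes_a) < 2:
        raise DegeneracyError(
            "AX=XB requires at least two relative motions with non-zero rotation"
        )
    axes_a, axes_b = np.asarray(axes_a), np.asarray(axes_b)
    sv = np.linalg.svd(axes_b, compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise DegeneracyError(
            "AX=XB is degenerate: all relative rotation axes are (near-)parallel"
        )
    # rotation: RX aligning the B-axes onto the A-axes (Kabsch without translation)
    H = axes_b.T @ axes_a
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    RX = Vt.T @ D @ U.T
    # translation: (RA − I)·tX = RX·tB − tA, stacked linear least squares
    M = np.concatenate([a.rotation - np.eye(3) for a in A])
    rhs = np.concatenate([RX @ b.translation - a.translation for a, b in zip(A, B)])
    tX, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return RigidTransform(RX, tX, source="camera", target="marker")


def solve_hand_eye(
    samples: list[HandEyeSample],
    method: str = "direct",
    on_degenerate: str = "fallback",
) -> HandEyeResult:
    """Estimate TCM (M←C) from paired marker/camera poses.

    ``method`` selects the solver path: ``"direct"`` (per-sample
    estimates, quaternion rotation averaging, mean translation) or
    ``"axxb"`` (relative motions; rotation from axis correspondences,
    translation by linear least squares).  When the AX=XB geometry is
    degenerate — all relative rotation axes parallel, e.g. a fixed
    endoscope — ``on_degenerate="fallback"`` reverts to the direct path
    with a warning, while ``"raise"`` propagates the degeneracy error.
    """
    if len(samples) < 1 or (method == "axxb" and len(samples) < 2):
        raise ValueError("not enough hand-eye samples")
    if method not in ("direct", "axxb"):
        raise ValueError(f"unknown hand-eye method '{method}'")
    used = method
    if method == "axxb":
        try:
            tcm = _solve_axxb(samples)
        except DegeneracyError as exc:
            if on_degenerate != "fallback":
                raise
            warnings.warn(f"AX=XB degenerate ({exc}); falling back to direct averaging")
            tcm = _solve_direct(samples)
            used = "direct (axxb fallback)"
    else:
        tcm = _solve_direct(samples)
    rot_res, tr_res = _residuals(samples, tcm)
    return HandEyeResult(tcm, rot_res, tr_res, used)
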