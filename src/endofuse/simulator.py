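"""Virtual rig: synthetic phantoms, tracking data and endoscope images.

Everything the physical system measures is generated here so the whole
pipeline is testable without hardware: the sphere-grid accuracy phantom
(13 steel spheres of 2 mm diameter in the central 20x20 mm of a
60x60 mm plate, 11 optical side markers), the 25-marker calibration
plate, a checkerboard, the endoscope-marker disc, a distorted-pinhole
endoscope (2590x1942 px sensor) and the optical tracker, abstracted as
a 3D marker sensor with configurable isotropic Gaussian noise.

All randomness flows from a single seeded generator per entry point;
noise is always drawn and then scaled by sigma, so sigma = 0 is the
continuous limit of the noisy model rather than a separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .camera import (
    CameraIntrinsics,
    default_endoscope,
    project,
    projected_sphere_radius_px,
    undistort,
)
from .geometry import RigidTransform, axis_angle_to_matrix
from .handeye import HandEyeSample
from .pose import Correspondence2D3D, estimate_camera_pose
from .tracking import MarkerObservation, VirtualReferenceGrid, build_vrg, register_point_sets
from .geometry import Point3

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# Fixed rig geometry: the camera pose in the OTS frame and the hand-eye
# transform of the endoscope-marker disc.  Arbitrary but non-trivial, so
# every frame of the fusion chain is exercised.
DEFAULT_TCO = RigidTransform(
    axis_angle_to_matrix(np.array([0.3, -0.5, 0.8]), 0.45),
    np.array([120.0, -80.0, 300.0]),
    source="camera",
    target="ots",
)
DEFAULT_TCM = RigidTransform(
    axis_angle_to_matrix(np.array([1.0, 0.4, -0.3]), 1.9),
    np.array([18.0, -25.0, 62.0]),
    source="camera",
    target="marker",
)

# Endoscope-marker disc: optical markers on a 5 cm disc, in its own frame.
EM_MARKERS = {
    "em0": np.array([0.0, 0.0, 0.0]),
    "em1": np.array([22.0, 0.0, 0.0]),
    "em2": np.array([-11.0, 19.0, 0.0]),
    "em3": np.array([-11.0, -19.0, 0.0]),
    "em4": np.array([0.0, 10.0, 4.0]),
}


@dataclass(frozen=True)
class GridPhantom:
    """The sphere-grid accuracy phantom."""

    sphere_ids: tuple[str, ...]
    sphere_centers: np.ndarray        # (13,3) plate frame, mm, z=0
    sphere_diameters_mm: np.ndarray   # (13,)
    marker_ids: tuple[str, ...]
    marker_positions: np.ndarray      # (11,3) plate border, mm
    plate_size_mm: float = 60.0
    roi_size_mm: float = 20.0

    @property
    def markers(self) -> dict[str, np.ndarray]:
        return dict(zip(self.marker_ids, self.marker_positions))

    @property
    def spheres(self) -> dict[str, np.ndarray]:
        return dict(zip(self.sphere_ids, self.sphere_centers))


def make_grid_phantom(
    seed: int = 0,
    n_spheres: int = 13,
    n_markers: int = 11,
    min_spacing_mm: float = 3.0,
    diameter_mm: float = 2.0,
    diameter_tolerance_mm: float = 0.0,
) -> GridPhantom:
    """Deterministic jittered-lattice layout of the accuracy grid.

    Sphere centres sit on a 4x4 lattice (5 mm pitch) inside the central
    20x20 mm ROI, jittered by up to ±1 mm per axis — which guarantees
    the 3 mm minimum spacing by construction — with 16 − n sites
    removed at random.  The published grid's exact layout is not public;
    this is a stand-in with the stated constraints.  The 5 µm machining
    tolerance can be emulated via ``diameter_tolerance_mm`` (uniform ±).
    """
    rng = np.random.default_rng(seed)
    pitch = 5.0
    grid = np.array([(x, y) for y in (-7.5, -2.5, 2.5, 7.5) for x in (-7.5, -2.5, 2.5, 7.5)])
    if n_spheres > len(grid):
        raise ValueError("at most 16 spheres fit the lattice")
    jitter_amp = (pitch - min_spacing_mm) / 2.0
    jitter = rng.uniform(-jitter_amp, jitter_amp, size=grid.shape)
    keep = np.sort(rng.choice(len(grid), size=n_spheres, replace=False))
    centers2d = grid[keep] + jitter[keep]
    centers = np.column_stack([centers2d, np.zeros(n_spheres)])
    diam_noise = rng.uniform(-1.0, 1.0, size=n_spheres)
    diameters = diameter_mm + diameter_tolerance_mm * diam_noise

    # side markers: equally spaced along the plate border (inset 3 mm)
    half = 27.0
    per = 8.0 * half
    s = np.linspace(0.0, per, n_markers, endpoint=False)
    pts = []
    for si in s:
        k, r = divmod(si, 2.0 * half)
        if k == 0:
            pts.append((-half + r, -half))
        elif k == 1:
            pts.append((half, -half + r))
        elif k == 2:
            pts.append((half - r, half))
        else:
            pts.append((-half, half - r))
    markers = np.column_stack([np.array(pts), np.zeros(n_markers)])
    return GridPhantom(
        sphere_ids=tuple(f"s{i:02d}" for i in range(n_spheres)),
        sphere_centers=centers,
        sphere_diameters_mm=diameters,
        marker_ids=tuple(f"g{i:02d}" for i in range(n_markers)),
        marker_positions=markers,
    )


def make_calibration_plate(n_side: int = 5, spacing_mm: float = 8.0) -> dict[str, np.ndarray]:
    """The 25-marker planar calibration plate (z = 0 in its own frame)."""
    half = (n_side - 1) / 2.0
    out = {}
    for i in range(n_side):
        for j in range(n_side):
            out[f"cp{i * n_side + j:02d}"] = np.array(
                [(j - half) * spacing_mm, (i - half) * spacing_mm, 0.0]
            )
    return out


def make_checkerboard(rows: int = 7, cols: int = 9, square_mm: float = 5.0) -> np.ndarray:
    """Inner-corner grid of a checkerboard, (rows*cols, 3), z = 0, centred."""
    ys, xs = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack(
        [
            (xs.ravel() - (cols - 1) / 2.0) * square_mm,
            (ys.ravel() - (rows - 1) / 2.0) * square_mm,
            np.zeros(rows * cols),
        ]
    )
    return pts


@dataclass
class SceneState:
    """One configuration of the rig: all poses, intrinsics and noise levels."""

    camera_pose: RigidTransform                     # O←C
    em_pose: RigidTransform                         # O←M
    phantom_pose: RigidTransform                    # O←P
    intrinsics: CameraIntrinsics
    sigma_marker_mm: float = 0.0
    sigma_pixel: float = 0.0
    seed: int = 0


def observe_markers(
    pose: RigidTransform,
    markers: dict[str, np.ndarray],
    sigma_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    occluded: frozenset[str] | set[str] = frozenset(),
) -> list[MarkerObservation]:
    """Tracker output for an object's markers: pose-mapped + Gaussian noise.

    Noise is always drawn when an ``rng`` is supplied (then scaled by
    sigma), keeping outputs continuous in sigma at fixed seed.
    """
    ids = sorted(markers)
    local = np.array([markers[i] for i in ids])
    world = pose.apply(local)
    if rng is not None:
        world = world + sigma_mm * rng.standard_normal(world.shape)
    elif sigma_mm > 0:
        raise ValueError("sigma_mm > 0 requires an rng")
    return [
        MarkerObservation(i, Point3.from_array(w, pose.target), visible=i not in occluded)
        for i, w in zip(ids, world)
    ]


# ---------------------------------------------------------------------------
# image rendering


def render_circles(
    width: int,
    height: int,
    centers_px: np.ndarray,
    radii_px: np.ndarray,
    background: float = 0.10,
    foreground: float = 0.92,
    sigma_pixel: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Anti-aliased filled circles on a uniform background, float in [0,1].

    Per-pixel coverage is the clipped signed distance to the circle
    edge, a sub-pixel-accurate model for circles more than a pixel
    across.  Pixel noise (same 0–1 scale) is added after compositing.
    """
    img = np.full((height, width), background, dtype=float)
    centers_px = np.atleast_2d(np.asarray(centers_px, dtype=float))
    radii_px = np.atleast_1d(np.asarray(radii_px, dtype=float))
    for (u, v), r in zip(centers_px, radii_px):
        if r <= 0:
            continue
        x0 = max(int(np.floor(u - r - 2)), 0)
        x1 = min(int(np.ceil(u + r + 2)) + 1, width)
        y0 = max(int(np.floor(v - r - 2)), 0)
        y1 = min(int(np.ceil(v + r + 2)) + 1, height)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((xx - u) ** 2 + (yy - v) ** 2)
        cov = np.clip(r - d + 0.5, 0.0, 1.0)
        patch = img[y0:y1, x0:x1]
        np.maximum(patch, background + (foreground - background) * cov, out=patch)
    if rng is not None:
        img = img + sigma_pixel * rng.standard_normal(img.shape)
    elif sigma_pixel > 0:
        raise ValueError("sigma_pixel > 0 requires an rng")
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class TruthCircle:
    """Ground-truth projected sphere: centre/radius in pixels, depth in mm."""

    sphere_id: str
    center_px: tuple[float, float]
    radius_px: float
    z_mm: float


def sphere_ground_truth(
    K: CameraIntrinsics,
    phantom: GridPhantom,
    camera_from_phantom: RigidTransform,
    radius_mode: str = "tangent",
) -> list[TruthCircle]:
    """Projected circles of the phantom spheres visible to the camera.

    Spheres behind the camera are dropped; a circle is reported when its
    centre projects inside the image bounds.
    """
    cam = camera_from_phantom.apply(phantom.sphere_centers)
    out = []
    for sid, c, diam in zip(phantom.sphere_ids, cam, phantom.sphere_diameters_mm):
        r_mm = diam / 2.0
        if c[2] <= r_mm:
            continue
        uv = project(K, c)
        if not (0 <= uv[0] < K.width and 0 <= uv[1] < K.height):
            continue
        r_px = projected_sphere_radius_px(K, float(c[2]), r_mm, radius_mode)
        out.append(TruthCircle(sid, (float(uv[0]), float(uv[1])), float(r_px), float(c[2])))
    return out


def render_endoscope_image(
    scene: SceneState,
    phantom: GridPhantom,
    radius_mode: str = "tangent",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[TruthCircle]]:
    """Render the phantom through the endoscope; return image + ground truth."""
    cam_from_ph = scene.camera_pose.invert() @ scene.phantom_pose
    truth = sphere_ground_truth(scene.intrinsics, phantom, cam_from_ph, radius_mode)
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    img = render_circles(
        scene.intrinsics.width,
        scene.intrinsics.height,
        np.array([t.center_px for t in truth]).reshape(-1, 2),
        np.array([t.radius_px for t in truth]),
        sigma_pixel=scene.sigma_pixel,
        rng=rng,
    )
    return img, truth


# ---------------------------------------------------------------------------
# calibration-data generators


def simulate_checkerboard_views(
    K: CameraIntrinsics,
    n_views: int = 15,
    rows: int = 7,
    cols: int = 9,
    square_mm: float = 5.0,
    sigma_pixel: float = 0.0,
    seed: int = 0,
    distance_mm: tuple[float, float] = (60.0, 120.0),
    max_tilt_deg: float = 35.0,
):
    """Checkerboard poses at multiple perspectives + exact/noisy corners.

    Returns (views, poses) where each view holds board coordinates and
    pixel corners (noise scaled by ``sigma_pixel``), and each pose is
    the camera←board transform used to generate it.
    """
    from .calibration import PlanarView  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    board = make_checkerboard(rows, cols, square_mm)
    views, poses = [], []
    attempts = 0
    while len(views) < n_views and attempts < 50 * n_views:
        attempts += 1
        tilt = np.deg2rad(rng.uniform(8.0, max_tilt_deg))
        azim = rng.uniform(0.0, 2.0 * np.pi)
        roll = rng.uniform(0.0, 2.0 * np.pi)
        axis = np.array([np.cos(azim), np.sin(azim), 0.0])
        R = axis_angle_to_matrix(np.array([0, 0, 1.0]), roll) @ axis_angle_to_matrix(axis, tilt)
        z = rng.uniform(*distance_mm)
        margin = 0.75
        off = rng.uniform(-margin, margin, size=2) * np.array(
            [K.width, K.height]
        ) / (2.0 * np.array([K.fx, K.fy])) * z * 0.4
        pose = RigidTransform(R, np.array([off[0], off[1], z]), source="board", target="camera")
        cam = pose.apply(board)
        if np.any(cam[:, 2] <= 1.0):
            continue
        px = project(K, cam)
        if px[:, 0].min() < 2 or px[:, 1].min() < 2:
            continue
        if px[:, 0].max() > K.width - 3 or px[:, 1].max() > K.height - 3:
            continue
        noise = rng.standard_normal(px.shape)
        views.append(
            PlanarView(board[:, :2], px + sigma_pixel * noise, view_id=f"view{len(views)}")
        )
        poses.append(pose)
    if len(views) < n_views:
        raise RuntimeError("could not place the requested number of checkerboard views")
    return views, poses


def _random_pose_viewing_origin(
    rng: np.random.Generator, distance_mm: tuple[float, float] = (80.0, 150.0),
    cone_deg: float = 35.0,
) -> RigidTransform:
    """Camera←plate pose with the camera looking roughly at the plate centre."""
    tilt = np.deg2rad(rng.uniform(5.0, cone_deg))
    azim = rng.uniform(0, 2 * np.pi)
    roll = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(azim), np.sin(azim), 0.0])
    R = axis_angle_to_matrix(np.array([0, 0, 1.0]), roll) @ axis_angle_to_matrix(axis, tilt)
    z = rng.uniform(*distance_mm)
    off = rng.uniform(-8.0, 8.0, size=2)
    return RigidTransform(R, np.array([off[0], off[1], z]), source="plate", target="camera")


@dataclass
class HandEyeDataset:
    samples: list[HandEyeSample]
    true_tcm: RigidTransform
    true_tcos: list[RigidTransform]
    pose_rms_px: np.ndarray


def simulate_hand_eye_dataset(
    n_views: int = 20,
    mode: str = "moving_endoscope",
    K: CameraIntrinsics | None = None,
    tcm: RigidTransform = DEFAULT_TCM,
    sigma_marker_mm: float = 0.0,
    sigma_pixel: float = 0.0,
    seed: int = 0,
) -> HandEyeDataset:
    """Full-pipeline hand-eye data: OTS marker tracking + P3P camera poses.

    Per view the 25-marker plate is observed by the tracker (3D, with
    marker noise) and photographed by the endoscope (2D, with pixel
    noise); TCO comes from :func:`estimate_camera_pose` and TMO from
    registering the endoscope-marker disc's observed points, exactly as
    the physical workflow does.

    ``mode="fixed_endoscope"`` reproduces the protocol where the scope
    sits in a surgical arm and only the plate moves (constant TMO — the
    AX=XB path is then degenerate); ``"moving_endoscope"`` varies the
    scope pose so both solver paths are well conditioned.
    """
    if mode not in ("moving_endoscope", "fixed_endoscope"):
        raise ValueError(f"unknown hand-eye mode '{mode}'")
    K = K or default_endoscope(0.25)
    rng = np.random.default_rng(seed)
    plate = make_calibration_plate()
    fixed_tco = DEFAULT_TCO

    samples, tcos, rms = [], [], []
    attempts = 0
    while len(samples) < n_views and attempts < 50 * n_views:
        attempts += 1
        cam_from_plate = _random_pose_viewing_origin(rng)
        if mode == "moving_endoscope":
            # plate fixed at the world origin, endoscope moves around it
            plate_world = RigidTransform.identity("ots", source="plate")
            tco_true = (plate_world @ cam_from_plate.invert()).relabel(
                source="camera", target="ots"
            )
        else:
            # endoscope fixed in a surgical arm, plate moved by hand
            tco_true = fixed_tco
            plate_world = tco_true @ cam_from_plate
        cam_pts = cam_from_plate.apply(np.array([plate[k] for k in sorted(plate)]))
        if np.any(cam_pts[:, 2] <= 1.0):
            continue
        px = project(K, cam_pts)
        if (px.min(axis=0) < 2).any() or px[:, 0].max() > K.width - 3 or px[:, 1].max() > K.height - 3:
            continue
        px = px + sigma_pixel * rng.standard_normal(px.shape)
        ots_obs = observe_markers(plate_world, plate, sigma_marker_mm, rng)
        world_by_id = {o.marker_id: o.position for o in ots_obs}
        corrs = [
            Correspondence2D3D(mid, world_by_id[mid], tuple(uv))
            for mid, uv in zip(sorted(plate), px)
        ]
        pose_res = estimate_camera_pose(corrs, K)
        tmo_true = tco_true @ tcm.invert()
        em_obs = observe_markers(tmo_true, EM_MARKERS, sigma_marker_mm, rng)
        tmo_est, _ = register_point_sets(
            EM_MARKERS,
            {o.marker_id: o.position.to_array() for o in em_obs},
            source_frame="marker",
            target_frame="ots",
        )
        samples.append(HandEyeSample(tmo=tmo_est, tco=pose_res.pose))
        tcos.append(tco_true)
        rms.append(pose_res.rms_px)
    if len(samples) < n_views:
        raise RuntimeError("could not generate the requested number of hand-eye views")
    return HandEyeDataset(samples, tcm, tcos, np.asarray(rms))


# ---------------------------------------------------------------------------
# the accuracy protocol


@dataclass
class ProtocolFrame:
    distance_mm: float
    position_index: int
    phantom_pose: RigidTransform              # true O←plate pose
    observations: list[MarkerObservation]     # noisy side-marker tracking
    truth: list[TruthCircle]
    image: np.ndarray | None = None


@dataclass
class AccuracyRun:
    """Everything produced by one pass of the sphere-grid protocol."""

    intrinsics: CameraIntrinsics
    tco: RigidTransform
    tmo: RigidTransform
    tcm: RigidTransform
    phantom: GridPhantom
    vrg: VirtualReferenceGrid
    structures: dict[str, tuple[np.ndarray, float]]   # id → (centre cbct, radius mm)
    frames: list[ProtocolFrame]
    radius_mode: str
    sigma_marker_mm: float
    sigma_pixel: float
    seed: int

    @property
    def distances(self) -> list[float]:
        return sorted({f.distance_mm for f in self.frames})


def fov_positions(
    n: int, radius_px: float, center: tuple[float, float], phase: float = 0.0
) -> np.ndarray:
    """n target pixels covering a disc: sunflower (Fibonacci) layout."""
    i = np.arange(n)
    r = radius_px * np.sqrt((i + 0.5) / n)
    th = i * GOLDEN_ANGLE + phase
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def run_accuracy_protocol(
    distances: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    positions_per_distance: int = 100,
    *,
    intrinsics: CameraIntrinsics | None = None,
    image_scale: float = 0.25,
    sigma_marker_mm: float = 0.0,
    sigma_pixel: float = 0.0,
    seed: int = 0,
    render: bool = True,
    radius_mode: str = "tangent",
    in_plane_rotation_deg: float = 25.0,
    fov_fraction: float = 0.9,
    phantom: GridPhantom | None = None,
) -> AccuracyRun:
    """The sphere-grid accuracy protocol on the virtual rig.

    The endoscope is fixed; at each working distance the grid, kept
    perpendicular to the line of sight, is translated in its plane (plus
    an optional in-plane rotation) through ``positions_per_distance``
    poses whose projections cover the endoscopic field of view.  A CBCT
    acquisition at a reference pose freezes the VRG and defines the
    sphere structures in the CBCT frame; each protocol frame then emits
    noisy side-marker tracking data, the projected ground-truth circles
    and (optionally) a rendered endoscope image.
    """
    K = intrinsics or default_endoscope(image_scale)
    rng = np.random.default_rng(seed)
    phantom = phantom or make_grid_phantom(seed)
    tco, tcm = DEFAULT_TCO, DEFAULT_TCM
    tmo = tco @ tcm.invert()

    # CBCT acquisition: grid centred on the optical axis at 20 mm
    ref_cam_from_plate = RigidTransform(
        np.eye(3), np.array([0.0, 0.0, 20.0]), source="plate", target="camera"
    )
    tpo_ref = tco @ ref_cam_from_plate
    obs_ref = observe_markers(tpo_ref, phantom.markers, sigma_marker_mm, rng)
    vrg = build_vrg(obs_ref)
    # CBCT frame == OTS frame at acquisition: structures are the world
    # coordinates of the sphere centres at that instant.
    centers_cbct = tpo_ref.apply(phantom.sphere_centers)
    structures = {
        sid: (centers_cbct[i], float(phantom.sphere_diameters_mm[i] / 2.0))
        for i, sid in enumerate(phantom.sphere_ids)
    }

    cam_radius = fov_fraction * min(K.cx, K.cy)
    frames: list[ProtocolFrame] = []
    for d in distances:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        targets = fov_positions(positions_per_distance, cam_radius, (K.cx, K.cy), phase)
        angles = np.deg2rad(in_plane_rotation_deg) * rng.uniform(
            -1.0, 1.0, size=positions_per_distance
        )
        norm_xy = undistort(K, targets)
        for idx in range(positions_per_distance):
            offset = norm_xy[idx] * d
            cam_from_plate = RigidTransform(
                axis_angle_to_matrix(np.array([0.0, 0.0, 1.0]), float(angles[idx])),
                np.array([offset[0], offset[1], d]),
                source="plate",
                target="camera",
            )
            tpo = tco @ cam_from_plate
            obs = observe_markers(tpo, phantom.markers, sigma_marker_mm, rng)
            truth = sphere_ground_truth(K, phantom, cam_from_plate, radius_mode)
            img = None
            if render:
                img = render_circles(
                    K.width,
                    K.height,
                    np.array([t.center_px for t in truth]).reshape(-1, 2),
                    np.array([t.radius_px for t in truth]),
                    sigma_pixel=sigma_pixel,
                    rng=rng,
                )
            frames.append(ProtocolFrame(float(d), idx, tpo, obs, truth, img))
    return AccuracyRun(
        intrinsics=K,
        tco=tco,
        tmo=tmo,
        tcm=tcm,
        phantom=phantom,
        vrg=vrg,
        structures=structures,
        frames=frames,
        radius_mode=radius_mode,
        sigma_marker_mm=sigma_marker_mm,
        sigma_pixel=sigma_pixel,
        seed=seed,
    )
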