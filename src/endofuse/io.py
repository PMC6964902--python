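"""Plain-text interchange formats for every pipeline boundary.

Transforms and intrinsics travel as JSON, point correspondences and
marker streams as CSV, segmented CBCT structures as a JSON list of
{type, center/centerline, radius_mm} objects.  All readers validate
what the corresponding domain type requires (orthonormality, column
presence, frame labels).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import PlanarView
from .camera import CameraIntrinsics
from .geometry import Point3, RigidTransform
from .handeye import HandEyeSample
from .pose import Correspondence2D3D
from .tracking import MarkerObservation

# --- rigid transforms -------------------------------------------------------


def transform_to_dict(t: RigidTransform) -> dict:
    return {
        "source": t.source,
        "target": t.target,
        "rotation": [float(x) for x in t.rotation.ravel()],
        "translation_mm": [float(x) for x in t.translation],
    }


def transform_from_dict(d: dict) -> RigidTransform:
    return RigidTransform(
        np.asarray(d["rotation"], dtype=float).reshape(3, 3),
        np.asarray(d["translation_mm"], dtype=float),
        source=d["source"],
        target=d["target"],
    )


def save_transform(t: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(t), indent=2))


def load_transform(path: str | Path) -> RigidTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))


# --- intrinsics --------------------------------------------------------------


def save_intrinsics(K: CameraIntrinsics, path: str | Path) -> None:
    d = K.to_dict()
    d["dist"] = [d["dist"][0], d["dist"][1], d["dist"][2], d["dist"][3], d["dist"][4]]
    Path(path).write_text(json.dumps(d, indent=2))


def load_intrinsics(path: str | Path) -> CameraIntrinsics:
    return CameraIntrinsics.from_dict(json.loads(Path(path).read_text()))


# --- planar calibration views ------------------------------------------------

PLANAR_COLUMNS = ["view_id", "point_id", "X_mm", "Y_mm", "u_px", "v_px"]


def save_planar_views(views: Sequence[PlanarView], path: str | Path) -> None:
    rows = []
    for v in views:
        for pid, (obj, img) in enumerate(zip(v.object_points, v.image_points)):
            rows.append(
                {
                    "view_id": v.view_id,
                    "point_id": pid,
                    "X_mm": obj[0],
                    "Y_mm": obj[1],
                    "u_px": img[0],
                    "v_px": img[1],
                }
            )
    pd.DataFrame(rows, columns=PLANAR_COLUMNS).to_csv(path, index=False)


def load_planar_views(path: str | Path) -> list[PlanarView]:
    df = pd.read_csv(path)
    missing = set(PLANAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"planar-view CSV missing columns: {sorted(missing)}")
    views = []
    for vid, sub in df.groupby("view_id", sort=True):
        sub = sub.sort_values("point_id")
        views.append(
            PlanarView(
                sub[["X_mm", "Y_mm"]].to_numpy(float),
                sub[["u_px", "v_px"]].to_numpy(float),
                view_id=str(vid),
            )
        )
    return views


# --- 2D-3D correspondences ---------------------------------------------------

CORR_COLUMNS = ["marker_id", "X_mm", "Y_mm", "Z_mm", "u_px", "v_px"]


def save_correspondences(cs: Sequence[Correspondence2D3D], path: str | Path) -> None:
    rows = [
        {
            "marker_id": c.marker_id,
            "X_mm": c.world_point.x,
            "Y_mm": c.world_point.y,
            "Z_mm": c.world_point.z,
            "u_px": c.image_point[0],
            "v_px": c.image_point[1],
        }
        for c in cs
    ]
    pd.DataFrame(rows, columns=CORR_COLUMNS).to_csv(path, index=False)


def load_correspondences(path: str | Path, frame: str = "ots") -> list[Correspondence2D3D]:
    df = pd.read_csv(path)
    missing = set(CORR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"correspondence CSV missing columns: {sorted(missing)}")
    return [
        Correspondence2D3D(
            str(r.marker_id),
            Point3(float(r.X_mm), float(r.Y_mm), float(r.Z_mm), frame),
            (float(r.u_px), float(r.v_px)),
        )
        for r in df.itertuples()
    ]


# --- hand-eye samples --------------------------------------------------------


def save_hand_eye_samples(samples: Sequence[HandEyeSample], path: str | Path) -> None:
    data = [
        {"TMO": transform_to_dict(s.tmo), "TCO": transform_to_dict(s.tco)} for s in samples
    ]
    Path(path).write_text(json.dumps(data, indent=2))


def load_hand_eye_samples(path: str | Path) -> list[HandEyeSample]:
    data = json.loads(Path(path).read_text())
    return [
        HandEyeSample(transform_from_dict(d["TMO"]), transform_from_dict(d["TCO"]))
        for d in data
    ]


# --- marker streams ----------------------------------------------------------

MARKER_COLUMNS = ["t", "marker_id", "X_mm", "Y_mm", "Z_mm", "visible"]


def save_marker_stream(
    stream: dict[float, Sequence[MarkerObservation]], path: str | Path
) -> None:
    rows = []
    for t, obs in sorted(stream.items()):
        for o in obs:
            rows.append(
                {
                    "t": t,
                    "marker_id": o.marker_id,
                    "X_mm": o.position.x,
                    "Y_mm": o.position.y,
                    "Z_mm": o.position.z,
                    "visible": int(o.visible),
                }
            )
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, index=False)


def load_marker_stream(path: str | Path) -> dict[float, list[MarkerObservation]]:
    df = pd.read_csv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker-stream CSV missing columns: {sorted(missing)}")
    out: dict[float, list[MarkerObservation]] = {}
    for r in df.itertuples():
        out.setdefault(float(r.t), []).append(
            MarkerObservation(
                str(r.marker_id),
                Point3(float(r.X_mm), float(r.Y_mm), float(r.Z_mm), "ots"),
                visible=bool(r.visible),
            )
        )
    return out


# --- segmented CBCT structures ----------------------------------------------


def save_structures(structures: dict[str, tuple[np.ndarray, float]], path: str | Path) -> None:
    data = [
        {
            "id": sid,
            "type": "sphere",
            "center_mm": [float(x) for x in center],
            "radius_mm": float(radius),
        }
        for sid, (center, radius) in sorted(structures.items())
    ]
    Path(path).write_text(json.dumps(data, indent=2))


def load_structures(path: str | Path) -> dict[str, tuple[np.ndarray, float]]:
    data = json.loads(Path(path).read_text())
    out = {}
    for item in data:
        if item.get("type", "sphere") != "sphere":
            continue  # tube centerlines are accepted in the file but not overlaid here
        out[str(item["id"])] = (
            np.asarray(item["center_mm"], dtype=float),
            float(item["radius_mm"]),
        )
    return out


# --- TRE records -------------------------------------------------------------


def save_tre_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def load_tre_records(path: str | Path) -> pd.DataFrame:
    from .overlay import TRE_COLUMNS

    df = pd.read_csv(path)
    missing = set(TRE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TRE record CSV missing columns: {sorted(missing)}")
    return df
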