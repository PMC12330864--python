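"""Pose-track normalization and kinematics for open-field recordings.

Tracks come from a markerless pose estimator (DeepLabCut CSV layout) as
per-frame image coordinates of an 8-point skeleton. Because the camera can
shift between sessions, coordinates are first re-expressed in an arena
frame using the four manually identified open-field corners: translate the
bottom-left corner to the origin, rotate so the bottom wall lies on the
x-axis, and scale each axis by the corresponding wall length so every wall
spans [0, 1].

From the normalized track we derive:

* barycenter — mean of the neck and body-midpoint markers;
* speed — per-frame Euclidean displacement of the barycenter;
* head movement — per-frame change of the egocentric head-point vector
  (nose, both ears) after centering on the barycenter and rotating by
  ``exp(i*(pi/2 - phi))``, where ``phi`` is the barycenter-to-neck angle.
  The rotation removes the animal's heading, so rigid translation and
  rotation of the whole body produce zero head movement;
* memory index — normalized novel-vs-familiar exploration-time contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InvalidArgument

BODY_PARTS = (
    "nose",
    "ear_left",
    "ear_right",
    "neck",
    "body_mid",
    "tail_base",
    "tail_mid",
    "tail_end",
)
HEAD_PARTS = ("nose", "ear_left", "ear_right")

#: Corner order convention: bottom-left, bottom-right, top-right, top-left.
UNIT_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates plus arena corners.

    ``points`` maps each body-part name to an (n_frames, 2) array of x, y
    coordinates (pixels before normalization, arena units after).
    ``corners`` holds the 4 arena corners in the same frame, ordered
    bottom-left, bottom-right, top-right, top-left.
    """

    points: dict[str, np.ndarray]
    corners: np.ndarray
    fps: float
    likelihoods: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidArgument("fps must be positive")
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise InvalidArgument("corners must be a 4x2 array")
        lengths = {k: np.asarray(v).shape[0] for k, v in self.points.items()}
        if len(set(lengths.values())) > 1:
            raise InvalidArgument(f"body parts have unequal frame counts: {lengths}")

    @property
    def frame_count(self) -> int:
        return next(iter(self.points.values())).shape[0]

    def require_parts(self, parts) -> None:
        missing = [p for p in parts if p not in self.points]
        if missing:
            raise InvalidArgument(f"missing body parts: {missing}")


@dataclass
class KinematicSeries:
    """Per-frame scalar kinematic series (speed or head movement)."""

    values: np.ndarray
    kind: str
    fps: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def per_second(self) -> np.ndarray:
        """Convert arena-units/frame to arena-units/second."""
        return self.values * self.fps


# ---------------------------------------------------------------------------
# Arena normalization
# ---------------------------------------------------------------------------

def normalize_arena(track: PoseTrack) -> PoseTrack:
    """Re-express a track in arena coordinates with walls spanning [0, 1].

    The transform is: translate the bottom-left corner to the origin,
    rotate by minus the bottom-wall angle so the bottom wall lies on the
    x-axis and the left wall on the y-axis, then divide x by the bottom
    wall length and y by the left wall length (non-square arenas are
    handled by this per-axis scaling).
    """
    c = track.corners
    bottom = c[1] - c[0]
    left = c[3] - c[0]
    cross = bottom[0] * left[1] - bottom[1] * left[0]
    if abs(cross) < 1e-12 * max(np.linalg.norm(bottom), 1.0) ** 2:
        raise InvalidArgument("degenerate arena corners (collinear)")
    angle = np.arctan2(bottom[1], bottom[0])
    rot = np.array(
        [[np.cos(-angle), -np.sin(-angle)], [np.sin(-angle), np.cos(-angle)]]
    )

    def transform(xy: np.ndarray) -> np.ndarray:
        shifted = xy - c[0]
        rotated = shifted @ rot.T
        rotated_left = rot @ left
        scale = np.array([np.linalg.norm(bottom), rotated_left[1]])
        return rotated / scale

    points = {k: transform(np.asarray(v, dtype=float)) for k, v in track.points.items()}
    corners = transform(c)
    meta = dict(track.meta)
    meta["arena_normalized"] = True
    return PoseTrack(
        points=points,
        corners=corners,
        fps=track.fps,
        likelihoods=track.likelihoods,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def barycenter(track: PoseTrack) -> np.ndarray:
    """Per-frame barycenter: mean of the neck and body-midpoint markers."""
    track.require_parts(("neck", "body_mid"))
    return (track.points["neck"] + track.points["body_mid"]) / 2.0


def compute_speed(track: PoseTrack) -> KinematicSeries:
    """Instantaneous barycenter speed between consecutive frames."""
    if track.frame_count < 2:
        raise InvalidArgument("need at least 2 frames for speed")
    bc = barycenter(track)
    disp = np.diff(bc, axis=0)
    speed = np.hypot(disp[:, 0], disp[:, 1])
    return KinematicSeries(values=speed, kind="speed", fps=track.fps)


def egocentric_coords(track: PoseTrack, parts=BODY_PARTS) -> dict[str, np.ndarray]:
    """Barycenter-centered, heading-corrected coordinates per body part.

    Each point is centered on the barycenter and rotated by
    ``exp(i*(pi/2 - phi))`` with ``phi`` the barycenter-to-neck angle, so
    the neck always points along +y and the animal's orientation in the
    arena is removed.
    """
    track.require_parts(("neck", "body_mid"))
    bc = barycenter(track)
    neck = track.points["neck"] - bc
    phi = np.arctan2(neck[:, 1], neck[:, 0])
    rotor = np.exp(1j * (np.pi / 2 - phi))
    out = {}
    for part in parts:
        if part not in track.points:
            continue
        centered = track.points[part] - bc
        z = (centered[:, 0] + 1j * centered[:, 1]) * rotor
        out[part] = np.column_stack([z.real, z.imag])
    return out


def compute_head_movement(track: PoseTrack) -> KinematicSeries:
    """Frame-to-frame norm of the egocentric head-point 6-vector.

    The head vector stacks the egocentric x, y coordinates of the nose and
    both ears; its change between consecutive frames measures head motion
    independent of locomotion and body rotation.
    """
    if track.frame_count < 2:
        raise InvalidArgument("need at least 2 frames for head movement")
    track.require_parts(HEAD_PARTS)
    ego = egocentric_coords(track, parts=HEAD_PARTS)
    head = np.hstack([ego[p] for p in HEAD_PARTS])  # (n, 6)
    diffs = np.diff(head, axis=0)
    return KinematicSeries(
        values=np.linalg.norm(diffs, axis=1), kind="head_movement", fps=track.fps
    )


def memory_index(t_new: float, t_familiar: float) -> float:
    """Normalized exploration-time contrast in [-1, 1]; 0 is chance level.

    ``(t_new - t_familiar) / (t_new + t_familiar)`` for the novel and
    familiar objects of a recognition task. Returns NaN when neither
    object was explored.
    """
    if t_new < 0 or t_familiar < 0:
        raise InvalidArgument("exploration times must be non-negative")
    total = t_new + t_familiar
    if total == 0:
        import warnings

        warnings.warn("no exploration at all; memory index undefined")
        return float("nan")
    return (t_new - t_familiar) / total


# ---------------------------------------------------------------------------
# DeepLabCut CSV I/O
# ---------------------------------------------------------------------------

def write_dlc_csv(track: PoseTrack, path: str | Path, scorer: str = "synthetic") -> None:
    """Write a track in the DeepLabCut 3-row-header CSV layout."""
    import json

    parts = [p for p in BODY_PARTS if p in track.points]
    columns = pd.MultiIndex.from_tuples(
        [(scorer, p, coord) for p in parts for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    n = track.frame_count
    data = np.empty((n, len(columns)))
    for i, p in enumerate(parts):
        data[:, 3 * i] = track.points[p][:, 0]
        data[:, 3 * i + 1] = track.points[p][:, 1]
        lk = track.likelihoods.get(p) if track.likelihoods else None
        data[:, 3 * i + 2] = lk if lk is not None else 1.0
    pd.DataFrame(data, columns=columns).to_csv(path, index_label="frame")
    sidecar = {"corners": track.corners.tolist(), "fps": track.fps}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_dlc_csv(
    path: str | Path,
    corners: np.ndarray | None = None,
    fps: float | None = None,
) -> PoseTrack:
    """Read a DeepLabCut-layout CSV; corners/fps from the JSON sidecar if present."""
    import json

    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if corners is None:
            corners = np.asarray(sidecar["corners"])
        if fps is None:
            fps = float(sidecar["fps"])
    if corners is None or fps is None:
        raise InvalidArgument("corners and fps required (sidecar missing)")
    points: dict[str, np.ndarray] = {}
    likelihoods: dict[str, np.ndarray] = {}
    scorer = df.columns[0][0]
    parts = list(dict.fromkeys(c[1] for c in df.columns))
    for p in parts:
        points[p] = np.column_stack(
            [df[(scorer, p, "x")].to_numpy(), df[(scorer, p, "y")].to_numpy()]
        )
        if (scorer, p, "likelihood") in df.columns:
            likelihoods[p] = df[(scorer, p, "likelihood")].to_numpy()
    return PoseTrack(
        points=points,
        corners=np.asarray(corners, dtype=float),
        fps=float(fps),
        likelihoods=likelihoods or None,
        meta={"source": str(path)},
    )
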