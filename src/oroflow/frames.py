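"""Rigid-body poses and the cranium-bound anatomical coordinate system (ACS).

The ACS is attached to the neurocranium with its origin near the esophagus
entrance (midsagittal, caudal tip of the chewing pad, approximating the
static pharyngeal-jaw position): x points anteriorly along the
pharyngeal-process plate, y dorsally in the midsagittal plane, z to the
animal's right (x cross y).  Expressing tracer and locator trajectories in
this frame removes whole-body swimming motion, so intraoral flow velocities
are relative to the esophagus entrance.

Per-frame neurocranium poses are least-squares rigid fits (Kabsch) of the
implanted bone markers to their bone-model (CT) coordinates; frames with
fewer than three visible markers are marked pose-missing rather than
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectories import TrajectorySet

__all__ = [
    "RigidPose",
    "AnatomicalLandmarks",
    "FrameSeries",
    "DegenerateFrameError",
    "fit_rigid_pose",
    "fit_pose_series",
    "build_acs",
    "to_anatomical",
    "to_world",
]


class DegenerateFrameError(ValueError):
    """Raised when a rigid fit is under-determined (too few / collinear points)."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message if frame is None else f"frame {frame}: {message}")
        self.frame = frame


@dataclass
class RigidPose:
    """A proper rigid transform ``p_world = rotation @ p_local + translation``."""

    rotation: np.ndarray  # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,) mm
    rmsd: float = 0.0  # mm
    frame: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1), not a reflection")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Map local coordinates to world coordinates."""
        return np.asarray(p) @ self.rotation.T + self.translation

    def invert(self, p: np.ndarray) -> np.ndarray:
        """Map world coordinates to local coordinates."""
        return (np.asarray(p) - self.translation) @ self.rotation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidPose(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
            frame=self.frame,
        )


#: Per-frame pose series; ``None`` marks a pose-missing frame.
FrameSeries = list


@dataclass
class AnatomicalLandmarks:
    """Bone-model-space landmarks that define the ACS.

    origin
        Caudal tip of the chewing pad on the midsagittal plane (the
        esophagus-entrance surrogate).
    x_axis_pair
        Two points on a line parallel to the pharyngeal-process plate;
        ``x_axis_pair[1] - x_axis_pair[0]`` points anteriorly.
    y_hint
        A point dorsal of ``origin`` in the midsagittal plane; its direction
        from the origin, orthogonalised against x, gives the dorsal y axis.
    """

    origin: np.ndarray
    x_axis_pair: tuple[np.ndarray, np.ndarray]
    y_hint: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x_axis_pair = (
            np.asarray(self.x_axis_pair[0], dtype=float),
            np.asarray(self.x_axis_pair[1], dtype=float),
        )
        self.y_hint = np.asarray(self.y_hint, dtype=float)
        x = self.x_axis_pair[1] - self.x_axis_pair[0]
        if np.linalg.norm(x) < 1e-12:
            raise ValueError("x_axis_pair points must be distinct")
        y = self.y_hint - self.origin
        if np.linalg.norm(np.cross(x, y)) < 1e-12 * np.linalg.norm(x) * max(np.linalg.norm(y), 1e-30):
            raise ValueError("y_hint must not be collinear with the x axis")

    def axes(self) -> np.ndarray:
        """Orthonormal right-handed axes as columns [x y z] in bone-model space."""
        x = self.x_axis_pair[1] - self.x_axis_pair[0]
        x = x / np.linalg.norm(x)
        y = self.y_hint - self.origin
        y = y - (y @ x) * x
        ny = np.linalg.norm(y)
        if ny < 1e-12:
            raise ValueError("degenerate landmarks: y_hint collinear with x axis")
        y = y / ny
        z = np.cross(x, y)
        return np.column_stack([x, y, z])


def fit_rigid_pose(
    reference_points: np.ndarray,
    observed_points: np.ndarray,
    frame: int = 0,
) -> RigidPose:
    """Least-squares rigid fit (Kabsch) mapping reference to observed points.

    Rows with a missing (NaN) observation on either side are excluded; at
    least three non-collinear correspondences must remain.  Reflections are
    rejected by construction (the SVD determinant correction).
    """
    ref = np.asarray(reference_points, dtype=float)
    obs = np.asarray(observed_points, dtype=float)
    if ref.shape != obs.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference and observed points must both be (n, 3)")
    ok = ~(np.isnan(ref).any(axis=1) | np.isnan(obs).any(axis=1))
    ref, obs = ref[ok], obs[ok]
    if ref.shape[0] < 3:
        raise DegenerateFrameError(
            f"only {ref.shape[0]} usable correspondences (need >= 3)", frame
        )
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    # collinear configurations leave rotation about the line unconstrained
    s = np.linalg.svd(ref_c, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise DegenerateFrameError("collinear marker configuration", frame)
    H = ref_c.T @ obs_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = obs.mean(axis=0) - R @ ref.mean(axis=0)
    resid = obs - (ref @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidPose(rotation=R, translation=t, rmsd=rmsd, frame=frame)


def fit_pose_series(
    ts: TrajectorySet,
    marker_names: list[str],
    reference_coords: dict[str, np.ndarray],
) -> FrameSeries:
    """Fit one rigid pose per frame from the named bone markers.

    Frames where fewer than three markers are visible yield ``None``
    (pose-missing) instead of an extrapolated pose.
    """
    ref = np.array([reference_coords[m] for m in marker_names], dtype=float)
    poses: FrameSeries = []
    for i in range(ts.n_frames):
        obs = np.array([ts.points[m][i] for m in marker_names])
        try:
            poses.append(fit_rigid_pose(ref, obs, frame=int(ts.frame_index[i])))
        except DegenerateFrameError:
            poses.append(None)
    return poses


def build_acs(neuro_poses: FrameSeries, landmarks: AnatomicalLandmarks) -> FrameSeries:
    """Compose neurocranium poses with the fixed landmark-defined ACS offset.

    Returns, per frame, the pose of the ACS in world coordinates (or ``None``
    where the neurocranium pose is missing).  Because the offset is constant
    in bone-model space, the ACS is rigidly cranium-fixed.
    """
    axes = landmarks.axes()
    offset = RigidPose(rotation=axes, translation=landmarks.origin)
    return [None if p is None else p.compose(offset) for p in neuro_poses]


def _transform_set(ts: TrajectorySet, acs: FrameSeries, inverse: bool) -> TrajectorySet:
    if len(acs) != ts.n_frames:
        raise ValueError(
            f"frame mismatch: {len(acs)} poses for {ts.n_frames} frames"
        )
    out = ts.copy()
    for name, arr in out.points.items():
        for i, pose in enumerate(acs):
            if pose is None:
                arr[i] = np.nan
            elif not np.isnan(arr[i]).any():
                arr[i] = pose.apply(arr[i]) if inverse else pose.invert(arr[i])
    return out


def to_anatomical(ts: TrajectorySet, acs: FrameSeries) -> TrajectorySet:
    """Re-express a world-frame TrajectorySet in the per-frame ACS."""
    if ts.coordinate_frame != "world":
        raise ValueError("to_anatomical expects a world-frame TrajectorySet")
    out = _transform_set(ts, acs, inverse=False)
    out.coordinate_frame = "anatomical"
    return out


def to_world(ts: TrajectorySet, acs: FrameSeries) -> TrajectorySet:
    """Inverse of :func:`to_anatomical`."""
    if ts.coordinate_frame != "anatomical":
        raise ValueError("to_world expects an anatomical-frame TrajectorySet")
    out = _transform_set(ts, acs, inverse=True)
    out.coordinate_frame = "world"
    return out
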