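"""Key-pose object motion: linear position, SLERP orientation interpolation.

A motion plan lists key poses at normalized key timestamps in [0, 1] together
with a process duration.  Intermediate poses are sampled at evenly spaced
normalized timestamps (endpoints included); within a key-pose segment the
translation interpolates linearly and the rotation follows the shorter
great-circle arc (quaternion SLERP, via :mod:`scipy.spatial.transform`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import ValidationError
from .geometry import Pose


@dataclass(frozen=True)
class KeyPose:
    t_norm: float
    pose: Pose

    def __post_init__(self):
        if not 0.0 <= self.t_norm <= 1.0:
            raise ValidationError(f"key timestamp {self.t_norm} outside [0, 1]")


@dataclass
class MotionPlan:
    """Ordered key poses (t_norm strictly increasing, 0 first, 1 last)."""

    key_poses: List[KeyPose]
    duration: float          # s
    n_steps: int = 2

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError("motion duration must be > 0")
        if self.n_steps < 2:
            raise ValidationError("a motion plan needs at least 2 steps")
        t = np.array([k.t_norm for k in self.key_poses])
        if len(t) < 1:
            raise ValidationError("a motion plan needs at least one key pose")
        if len(t) == 1:
            if t[0] != 0.0:
                raise ValidationError("a single key pose must sit at t_norm = 0")
        else:
            if t[0] != 0.0 or t[-1] != 1.0 or np.any(np.diff(t) <= 0):
                raise ValidationError(
                    "key timestamps must be strictly increasing from 0 to 1")
        self._t = t
        self._slerp = None
        if len(t) > 1:
            rots = Rotation.from_matrix(
                np.stack([k.pose.rotation for k in self.key_poses]))
            self._slerp = Slerp(t, rots)
        self._translations = np.stack([k.pose.translation for k in self.key_poses])

    @classmethod
    def static(cls, pose: Pose, duration: float, n_steps: int = 2) -> "MotionPlan":
        """A plan that holds one pose for the whole process."""
        return cls([KeyPose(0.0, pose), KeyPose(1.0, pose)], duration, n_steps)


def sample_timestamps(n_steps: int) -> np.ndarray:
    """``n_steps`` evenly spaced normalized timestamps including 0 and 1."""
    if n_steps < 2:
        raise ValidationError("need at least 2 timestamps (start and end)")
    return np.linspace(0.0, 1.0, n_steps)


def interpolate_pose(plan: MotionPlan, t_norm: float) -> Pose:
    """Pose at normalized time ``t_norm``: linear position, SLERP orientation.

    At a key timestamp the key pose is returned exactly.
    """
    if not 0.0 <= t_norm <= 1.0:
        raise ValidationError(f"t_norm {t_norm} outside [0, 1]")
    t = plan._t
    exact = np.flatnonzero(t == t_norm)
    if exact.size:
        return plan.key_poses[int(exact[0])].pose
    i = int(np.searchsorted(t, t_norm)) - 1
    frac = (t_norm - t[i]) / (t[i + 1] - t[i])
    translation = (1.0 - frac) * plan._translations[i] + frac * plan._translations[i + 1]
    rotation = plan._slerp([t_norm]).as_matrix()[0]
    # re-orthonormalize against accumulated round-off
    u, _, vt = np.linalg.svd(rotation)
    rotation = u @ vt
    return Pose.from_rotation_translation(rotation, translation)


def sample_poses(plan: MotionPlan) -> List[Pose]:
    """Interpolated poses at the plan's evenly spaced timestamps."""
    return [interpolate_pose(plan, float(t)) for t in sample_timestamps(plan.n_steps)]
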