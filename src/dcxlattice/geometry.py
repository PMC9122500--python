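"""Rigid transforms and small geometric utilities.

All coordinates are in angstroms throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))

    @property
    def is_proper(self) -> bool:
        R = self.rotation
        return bool(
            np.allclose(R @ R.T, np.eye(3), atol=1e-8) and np.linalg.det(R) > 0
        )

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform()
        for _ in range(n):
            out = self.compose(out)
        return out

    @staticmethod
    def translation_only(t) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, float))


def fit_rigid_transform(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping point set src onto dst (Kabsch)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - cd, src - cs)
    R = rot.as_matrix()
    return RigidTransform(R, cd - R @ cs)


def random_rotation_small(max_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix with axis uniform on the sphere and angle uniform in [0, max_angle].

    Composed via unit quaternions, so the parameterization is regular at angle 0.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    q = np.concatenate([np.sin(angle / 2.0) * axis, [np.cos(angle / 2.0)]])
    return Rotation.from_quat(q).as_matrix()


def random_rotation_uniform(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (for pose randomization)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()
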