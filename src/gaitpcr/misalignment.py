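"""Frontal-plane misalignment of a virtual IMU on the pelvis.

A wearable sensor strapped to the lower back rarely sits perfectly
aligned with the pelvis anatomical frame; rotation in the frontal plane
(about the anterior-posterior y-axis) is the common attachment error.
This module expresses mid-ASIS accelerations in the frame of a virtual
IMU rotated by a configurable frontal-plane angle.  At 0 degrees the IMU
frame coincides with the pelvis frame.

Because the rotation axis is y, the anterior-posterior acceleration
component is exactly invariant under every misalignment angle, and the
per-sample acceleration norm is preserved; both properties are exercised
by the test suite.

Sign convention: positive angles tip the IMU's superior axis toward the
subject's right.  Estimation errors are symmetric in the sign of the
angle, so this choice does not affect conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MisalignmentCondition",
    "NAMED_CONDITIONS",
    "DEFAULT_GRID_DEG",
    "default_conditions",
    "conditions_from_grid",
    "frontal_rotation",
    "virtual_imu_accel",
    "misalign_pelvis_accel",
]

#: canonical condition labels and their frontal-plane angles (degrees)
NAMED_CONDITIONS = {
    "M20": -20.0,
    "M10": -10.0,
    "ZERO": 0.0,
    "P10": 10.0,
    "P20": 20.0,
}

DEFAULT_GRID_DEG = (-20.0, -10.0, 0.0, 10.0, 20.0)


@dataclass(frozen=True)
class MisalignmentCondition:
    label: str
    theta_deg: float

    def __post_init__(self) -> None:
        if self.label in NAMED_CONDITIONS and not np.isclose(
            self.theta_deg, NAMED_CONDITIONS[self.label]
        ):
            raise ValueError(
                f"label {self.label} requires theta = "
                f"{NAMED_CONDITIONS[self.label]} deg, got {self.theta_deg}"
            )

    @classmethod
    def from_label(cls, label: str) -> "MisalignmentCondition":
        if label not in NAMED_CONDITIONS:
            raise KeyError(f"unknown condition label {label!r}")
        return cls(label, NAMED_CONDITIONS[label])

    @classmethod
    def from_angle(cls, theta_deg: float) -> "MisalignmentCondition":
        for label, theta in NAMED_CONDITIONS.items():
            if np.isclose(theta_deg, theta):
                return cls(label, theta)
        sign = "P" if theta_deg >= 0 else "M"
        return cls(f"{sign}{abs(theta_deg):g}", float(theta_deg))


def default_conditions() -> list[MisalignmentCondition]:
    return [MisalignmentCondition(lbl, th) for lbl, th in NAMED_CONDITIONS.items()]


def conditions_from_grid(grid_deg) -> list[MisalignmentCondition]:
    conds = [MisalignmentCondition.from_angle(th) for th in grid_deg]
    if not any(c.theta_deg == 0.0 for c in conds):
        raise ValueError("condition grid must contain 0 degrees (ZERO)")
    return conds


def frontal_rotation(theta_deg: float) -> np.ndarray:
    """Rotation by ``theta_deg`` about the anterior-posterior (y) axis.

    R(0) is the identity and R(-theta) = R(theta)^T.
    """
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


#: standard gravity, m/s^2
GRAVITY = 9.81


def virtual_imu_accel(
    accel_global: np.ndarray,
    pelvis_R: np.ndarray,
    theta_deg: float,
    add_gravity: bool = False,
) -> np.ndarray:
    """Transform global-frame accelerations into the virtual-IMU frame.

    a_imu(t) = R(theta)^T . pelvis_R(t)^T . a_global(t); at theta = 0 this
    is the pelvis-frame acceleration.

    Marker-derived accelerations contain no gravitational component; a
    physical accelerometer additionally senses the reaction to gravity.
    ``add_gravity`` injects (0, 0, +g) in the global frame before the
    transformation for such realism studies (off by default: the
    estimation analysis is defined on gravity-free accelerations).

    Parameters
    ----------
    accel_global : (n, 3) global-frame accelerations
    pelvis_R : (n, 3, 3) pelvis-to-global rotation series
    theta_deg : frontal-plane misalignment angle
    add_gravity : include the gravitational reaction along global +z
    """
    accel_global = np.asarray(accel_global, dtype=float)
    if add_gravity:
        accel_global = accel_global + np.array([0.0, 0.0, GRAVITY])
    pelvis_R = np.asarray(pelvis_R, dtype=float)
    if accel_global.shape[0] != pelvis_R.shape[0]:
        raise ValueError(
            f"length mismatch: {accel_global.shape[0]} acceleration samples "
            f"vs {pelvis_R.shape[0]} rotations"
        )
    a_pelvis = np.einsum("nij,nj->ni", pelvis_R.transpose(0, 2, 1), accel_global)
    return a_pelvis @ frontal_rotation(theta_deg)


def misalign_pelvis_accel(accel_pelvis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Re-express pelvis-frame accelerations in a misaligned IMU frame.

    ``accel_pelvis`` is (3, n) with axis rows x/y/z (the cohort waveform
    convention); returns the same shape.
    """
    accel_pelvis = np.asarray(accel_pelvis, dtype=float)
    if accel_pelvis.shape[0] != 3:
        raise ValueError("accel_pelvis must be (3, n)")
    return frontal_rotation(theta_deg).T @ accel_pelvis
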