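"""Raw trial preprocessing: filtering, gait events, virtual-IMU kinematics.

Turns marker trajectories and ground-reaction forces into the quantities
the estimator consumes: zero-lag low-pass filtered signals, heel-contact
events from the vertical GRF, the acceleration of the virtual mid-ASIS
point by central differences, the pelvis anatomical frame, Cardan angles,
and 101-point time-normalized gait-cycle waveforms.

Conventions: right-handed axes with x toward the subject's right
(medio-lateral), y anterior, z superior.  Rotation matrices map
pelvis-frame vectors to the global frame (axes as columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .layout import N_POINTS

__all__ = [
    "GaitTrial",
    "GaitCycle",
    "butterworth_zero_lag",
    "detect_heel_contacts",
    "masis_acceleration",
    "pelvis_rotation",
    "pelvis_rotation_series",
    "cardan_xyz",
    "cardan_to_matrix",
    "time_normalize",
    "process_trial",
    "trial_to_csv",
    "trial_from_csv",
]

REQUIRED_PELVIS_MARKERS = ("LASIS", "RASIS", "LPSIS", "RPSIS")


@dataclass
class GaitTrial:
    """One walking trial: marker trajectories plus ground reaction forces."""

    markers: dict[str, np.ndarray]  # name -> (n, 3) meters, global frame
    marker_rate: float = 200.0
    grf: np.ndarray | None = None   # (m, 3) newtons; column 2 is vertical
    grf_rate: float = 1000.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        lengths = {v.shape[0] for v in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker sequences have unequal lengths: {lengths}")
        for name, v in self.markers.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValueError(f"marker {name} must be (n, 3)")
        if self.marker_rate <= 0 or self.grf_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.grf is not None:
            self.grf = np.asarray(self.grf, dtype=float)

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def vertical_grf(self) -> np.ndarray:
        if self.grf is None:
            raise ValueError("trial has no GRF data")
        return self.grf[:, 2]


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle: ipsilateral heel contact to the next, in seconds."""

    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")


def butterworth_zero_lag(
    series: np.ndarray, fs: float, fc: float, order: int = 4
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter (forward-backward application).

    ``order`` is the order of the underlying one-pass filter; the
    forward-backward pass doubles the effective magnitude order and cancels
    the phase.  No cutoff-frequency correction is applied.  Works on 1-D
    series or (n, d) arrays (filtered along axis 0).
    """
    series = np.asarray(series, dtype=float)
    if fc <= 0:
        raise ValueError("cutoff frequency must be positive")
    if fc >= fs / 2.0:
        raise ValueError(f"cutoff {fc} Hz must be below Nyquist ({fs / 2.0} Hz)")
    if series.shape[0] <= 3 * (order + 1):
        raise ValueError("series too short for zero-lag filtering")
    b, a = butter(order, fc / (fs / 2.0), btype="low")
    return filtfilt(b, a, series, axis=0)


def detect_heel_contacts(
    vertical_grf: np.ndarray,
    fs: float,
    threshold: float = 20.0,
    refractory: float = 0.05,
    refine_series: np.ndarray | None = None,
) -> np.ndarray:
    """Heel-contact times from the (filtered) vertical GRF, in seconds.

    An event is an upward crossing of ``threshold`` preceded by at least
    ``refractory`` seconds below it, which suppresses re-triggering on
    force oscillations around the threshold.  Crossing times are refined
    by linear interpolation between the bracketing samples.

    A zero-lag low-pass filter smears the sharp loading onset backward in
    time, so thresholding the filtered force alone biases events early.
    Pass the raw force as ``refine_series`` to re-locate each event at the
    nearest raw upward crossing within one refractory window, recovering
    millisecond-level timing while keeping the filtered signal's
    robustness to baseline noise.
    """
    f = np.asarray(vertical_grf, dtype=float)
    below = f < threshold
    n_ref = max(1, int(round(refractory * fs)))
    raw = None if refine_series is None else np.asarray(refine_series, float)

    def crossing_time(series: np.ndarray, i: int) -> float:
        lo, hi = series[i - 1], series[i]
        frac = 0.0 if hi == lo else (threshold - lo) / (hi - lo)
        return (i - 1 + frac) / fs

    events = []
    for i in range(1, len(f)):
        if below[i - 1] and not below[i]:
            lo = max(0, i - n_ref)
            if not np.all(below[lo:i]):
                continue
            if raw is None:
                events.append(crossing_time(f, i))
                continue
            j0 = max(1, i - n_ref)
            j1 = min(len(raw) - 1, i + n_ref)
            refined = None
            for j in range(j0, j1 + 1):
                if raw[j - 1] < threshold <= raw[j]:
                    refined = crossing_time(raw, j)
                    break
            events.append(refined if refined is not None else crossing_time(f, i))
    return np.asarray(events)


def masis_acceleration(
    lasis: np.ndarray, rasis: np.ndarray, dt: float
) -> np.ndarray:
    """Global-frame acceleration of the virtual mid-ASIS point.

    Central second difference a[t] = (p[t+1] - 2 p[t] + p[t-1]) / dt^2,
    exact for quadratic trajectories; endpoint values are replicated from
    the nearest interior sample so the output keeps the input length.
    """
    lasis = np.asarray(lasis, dtype=float)
    rasis = np.asarray(rasis, dtype=float)
    if lasis.shape != rasis.shape:
        raise ValueError("LASIS and RASIS sequences must have equal shapes")
    if lasis.shape[0] < 3:
        raise ValueError("need at least 3 samples for central differences")
    p = 0.5 * (lasis + rasis)
    a = np.empty_like(p)
    a[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / dt**2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def pelvis_rotation(
    lasis: np.ndarray, rasis: np.ndarray, lpsis: np.ndarray, rpsis: np.ndarray
) -> np.ndarray:
    """Pelvis anatomical frame from the four iliac-spine landmarks.

    x = unit(RASIS - LASIS); z = unit(x cross anterior) with the provisional
    anterior direction from mid-PSIS to mid-ASIS; y = z cross x.  The
    returned 3x3 matrix has the axes as columns (pelvis -> global).
    """
    R = pelvis_rotation_series(
        np.asarray(lasis, float)[None],
        np.asarray(rasis, float)[None],
        np.asarray(lpsis, float)[None],
        np.asarray(rpsis, float)[None],
    )
    return R[0]


def pelvis_rotation_series(
    lasis: np.ndarray, rasis: np.ndarray, lpsis: np.ndarray, rpsis: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`pelvis_rotation` over (n, 3) landmark sequences."""
    lasis, rasis, lpsis, rpsis = (
        np.asarray(m, dtype=float) for m in (lasis, rasis, lpsis, rpsis)
    )
    x = rasis - lasis
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(xn < 1e-12):
        raise ValueError("coincident ASIS landmarks")
    x = x / xn
    anterior = 0.5 * (lasis + rasis) - 0.5 * (lpsis + rpsis)
    an = np.linalg.norm(anterior, axis=1, keepdims=True)
    if np.any(an < 1e-12):
        raise ValueError("coincident ASIS/PSIS midpoints")
    anterior = anterior / an
    z = np.cross(x, anterior)
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(zn < 1e-9):
        raise ValueError("degenerate pelvis geometry: landmarks collinear")
    z = z / zn
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


def cardan_xyz(R: np.ndarray) -> tuple[float, float, float]:
    """Cardan angles (degrees) for the x-y-z sequence: R = Rx Ry Rz.

    The middle angle is confined to [-90, 90] degrees.  Raises near gimbal
    lock (|cos theta_y| < 1e-8) where the x and z rotations degenerate.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be 3x3")
    if abs(np.linalg.det(R) - 1.0) > 1e-6 or np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6:
        raise ValueError("R is not a proper rotation matrix")
    sy = np.clip(R[0, 2], -1.0, 1.0)
    cy = np.hypot(R[0, 0], R[0, 1])
    if cy < 1e-8:
        raise ValueError(
            "gimbal lock: theta_y is within ~1e-8 of +/-90 degrees; "
            "x and z rotations are indistinguishable"
        )
    theta_y = np.arctan2(sy, cy)
    theta_x = np.arctan2(-R[1, 2], R[2, 2])
    theta_z = np.arctan2(-R[0, 1], R[0, 0])
    return tuple(np.degrees((theta_x, theta_y, theta_z)))


def cardan_to_matrix(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Compose R = Rx(theta_x) Ry(theta_y) Rz(theta_z), angles in degrees."""
    a, b, c = np.radians([theta_x, theta_y, theta_z])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array(
        [
            [cb * cc, -cb * sc, sb],
            [ca * sc + sa * sb * cc, ca * cc - sa * sb * sc, -sa * cb],
            [sa * sc - ca * sb * cc, sa * cc + ca * sb * sc, ca * cb],
        ]
    )


def time_normalize(
    series: np.ndarray, cycle: GaitCycle, fs: float
) -> np.ndarray:
    """Resample one gait cycle onto 101 equally spaced instants (0-100 %).

    Linear interpolation; works on 1-D series or (n, d) arrays sampled at
    ``fs`` starting at time zero.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    t_end = (n - 1) / fs
    if cycle.start_time < 0 or cycle.end_time > t_end + 1e-12:
        raise ValueError(
            f"cycle [{cycle.start_time}, {cycle.end_time}] s outside the "
            f"recorded span [0, {t_end}] s"
        )
    t = np.arange(n) / fs
    ti = np.linspace(cycle.start_time, cycle.end_time, N_POINTS)
    if series.ndim == 1:
        return np.interp(ti, t, series)
    return np.column_stack([np.interp(ti, t, series[:, j]) for j in range(series.shape[1])])


def process_trial(
    trial: GaitTrial,
    marker_cutoff: float = 10.0,
    grf_cutoff: float = 6.0,
    filter_order: int = 4,
    contact_threshold: float = 20.0,
):
    """Markers + GRF -> pelvis-frame mid-ASIS acceleration waveform.

    Filters marker trajectories (10 Hz) and the vertical GRF (6 Hz) with
    zero-lag Butterworth filters, detects heel contacts, takes the first
    complete gait cycle, computes the mid-ASIS acceleration by central
    differences, expresses it in the per-frame pelvis frame, and
    time-normalizes to 101 points.

    Returns ``(accel_101x3_pelvis_frame, rotation_series, cycle, events)``.
    """
    for name in REQUIRED_PELVIS_MARKERS:
        if name not in trial.markers:
            raise ValueError(f"trial is missing required marker {name}")
    filt = {
        name: butterworth_zero_lag(trial.markers[name], trial.marker_rate,
                                   marker_cutoff, filter_order)
        for name in REQUIRED_PELVIS_MARKERS
    }
    vgrf = butterworth_zero_lag(trial.vertical_grf, trial.grf_rate, grf_cutoff,
                                filter_order)
    events = detect_heel_contacts(vgrf, trial.grf_rate, contact_threshold,
                                  refine_series=trial.vertical_grf)
    if len(events) < 2:
        raise ValueError("fewer than two heel contacts detected")
    cycle = GaitCycle(float(events[0]), float(events[1]))

    dt = 1.0 / trial.marker_rate
    accel_global = masis_acceleration(filt["LASIS"], filt["RASIS"], dt)
    R = pelvis_rotation_series(filt["LASIS"], filt["RASIS"],
                               filt["LPSIS"], filt["RPSIS"])
    accel_pelvis = np.einsum("nij,nj->ni", R.transpose(0, 2, 1), accel_global)
    waveform = time_normalize(accel_pelvis, cycle, trial.marker_rate)
    return waveform, R, cycle, events


# ---------------------------------------------------------------------------
# CSV dialect: trajectories `time,<MARKER>_X,...`; GRF `time,Fx,Fy,Fz`
# ---------------------------------------------------------------------------

def trial_to_csv(trial: GaitTrial, traj_path, grf_path=None) -> None:
    t = np.arange(trial.n_frames) / trial.marker_rate
    cols = {"time": t}
    for name, xyz in trial.markers.items():
        for j, ax in enumerate("XYZ"):
            cols[f"{name}_{ax}"] = xyz[:, j]
    pd.DataFrame(cols).to_csv(traj_path, index=False)
    if grf_path is not None and trial.grf is not None:
        tg = np.arange(trial.grf.shape[0]) / trial.grf_rate
        pd.DataFrame(
            {"time": tg, "Fx": trial.grf[:, 0], "Fy": trial.grf[:, 1],
             "Fz": trial.grf[:, 2]}
        ).to_csv(grf_path, index=False)


def trial_from_csv(traj_path, grf_path=None, metadata: dict | None = None) -> GaitTrial:
    df = pd.read_csv(traj_path)
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("trajectory file must contain at least two samples")
    marker_rate = 1.0 / float(np.mean(np.diff(t)))
    names = sorted({c[:-2] for c in df.columns if c.endswith(("_X", "_Y", "_Z"))})
    markers = {
        name: np.column_stack([df[f"{name}_{ax}"].to_numpy(float) for ax in "XYZ"])
        for name in names
    }
    grf = None
    grf_rate = 1000.0
    if grf_path is not None:
        gf = pd.read_csv(grf_path)
        tg = gf["time"].to_numpy(float)
        grf_rate = 1.0 / float(np.mean(np.diff(tg)))
        grf = gf[["Fx", "Fy", "Fz"]].to_numpy(float)
    return GaitTrial(markers=markers, marker_rate=marker_rate, grf=grf,
                     grf_rate=grf_rate, metadata=metadata or {})
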