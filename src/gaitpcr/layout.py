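"""Fixed variable and matrix-column layout shared by every stage.

All waveforms live on a 101-point grid covering one gait cycle (0-100 %
of the cycle, endpoints included).  Accelerations are expressed in the
pelvis (or virtual-IMU) frame with axes

    x : medio-lateral (positive toward the subject's right)
    y : anterior-posterior (positive anterior)
    z : superior-inferior (positive superior)

Output variables are 12 segment/joint angles (pelvis, hip, knee, ankle;
sagittal, frontal, horizontal plane; degrees) followed by 9 joint moments
(hip, knee, ankle; same planes; N.m/kg).  The stacked cohort matrices use
one row per subject:

    X : n x 303  = 3 acceleration axes x 101 points (x block, y block, z block)
    Y : n x 2121 = 12 angle waveforms then 9 moment waveforms, 101 points each
"""

from __future__ import annotations

N_POINTS = 101

ACCEL_AXES = ("x", "y", "z")

PLANES = ("sagittal", "frontal", "horizontal")

ANGLE_SEGMENTS = ("pelvis", "hip", "knee", "ankle")
MOMENT_JOINTS = ("hip", "knee", "ankle")

ANGLE_VARIABLES = tuple(
    f"{seg}_{plane}_angle" for seg in ANGLE_SEGMENTS for plane in PLANES
)
MOMENT_VARIABLES = tuple(
    f"{joint}_{plane}_moment" for joint in MOMENT_JOINTS for plane in PLANES
)
OUTPUT_VARIABLES = ANGLE_VARIABLES + MOMENT_VARIABLES

N_ANGLE_VARIABLES = len(ANGLE_VARIABLES)      # 12
N_MOMENT_VARIABLES = len(MOMENT_VARIABLES)    # 9
N_OUTPUT_VARIABLES = len(OUTPUT_VARIABLES)    # 21

N_INPUT_COLUMNS = len(ACCEL_AXES) * N_POINTS              # 303
N_ANGLE_COLUMNS = N_ANGLE_VARIABLES * N_POINTS            # 1212
N_MOMENT_COLUMNS = N_MOMENT_VARIABLES * N_POINTS          # 909
N_OUTPUT_COLUMNS = N_OUTPUT_VARIABLES * N_POINTS          # 2121


def variable_slice(variable: str) -> slice:
    """Column slice of ``variable`` inside a stacked output row."""
    idx = OUTPUT_VARIABLES.index(variable)
    return slice(idx * N_POINTS, (idx + 1) * N_POINTS)


def axis_slice(axis: str) -> slice:
    """Column slice of acceleration ``axis`` inside a stacked input row."""
    idx = ACCEL_AXES.index(axis)
    return slice(idx * N_POINTS, (idx + 1) * N_POINTS)
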