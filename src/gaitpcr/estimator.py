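"""PCA-score regression linking pelvic accelerations to gait waveforms.

The estimation model compresses the cohort's stacked acceleration matrix
(n x 303) and joint angle/moment matrix (n x 2121) with principal
component analysis, retaining the smallest number of components whose
cumulative contribution rate (CCR, the cumulative fraction of variance
explained) reaches a threshold (default 90 %).  Each retained output
score is then regressed on all retained input scores by ordinary least
squares.  Prediction for a new subject is project -> regress ->
reconstruct:

    s_in  = L_in (x - mu_in)
    s_out = B s_in + b0
    y_hat = mu_out + L_out^T s_out

Leave-one-out cross-validation refits the whole chain without the held-out
subject; misalignment of the virtual IMU enters only at prediction time,
as a frontal-plane rotation of the held-out subject's accelerations
(models are calibrated on well-aligned data).

PCA is performed on centered, unscaled columns (the waveform-PCA
convention: columns within each block share units); a unit-variance
option is exposed for sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import layout
from .misalignment import MisalignmentCondition, default_conditions, misalign_pelvis_accel
from .synthetic import SubjectWaveforms

__all__ = [
    "CohortMatrices",
    "PCAModel",
    "RegressionSet",
    "EstimationModel",
    "LOOCVResult",
    "assemble_matrices",
    "fit_pca",
    "pca_project",
    "pca_reconstruct",
    "fit_score_regressions",
    "fit_estimation_model",
    "predict_waveforms",
    "run_loocv",
    "save_model",
    "load_model",
]


@dataclass
class CohortMatrices:
    """Stacked per-subject waveform rows.

    ``X`` columns: x-axis points 0-100, then y, then z (303 total).
    ``Y`` columns: 12 angle waveforms then 9 moment waveforms, 101 points
    each (2121 total), in :data:`gaitpcr.layout.OUTPUT_VARIABLES` order.
    """

    X: np.ndarray
    Y: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[1] != layout.N_INPUT_COLUMNS:
            raise ValueError(f"X must have {layout.N_INPUT_COLUMNS} columns")
        if self.Y.shape[1] != layout.N_OUTPUT_COLUMNS:
            raise ValueError(f"Y must have {layout.N_OUTPUT_COLUMNS} columns")
        if self.X.shape[0] != self.Y.shape[0] or self.X.shape[0] != len(self.subject_ids):
            raise ValueError("row counts of X, Y and subject_ids must agree")


def assemble_matrices(cohort: list[SubjectWaveforms]) -> CohortMatrices:
    """Stack subject waveforms into the input and output cohort matrices."""
    X_rows, Y_rows, ids = [], [], []
    for subj in cohort:
        if subj.accel_pelvis_frame.shape != (3, layout.N_POINTS):
            raise ValueError(f"subject {subj.subject_id}: malformed accelerations")
        if subj.outputs.shape != (layout.N_OUTPUT_VARIABLES, layout.N_POINTS):
            raise ValueError(f"subject {subj.subject_id}: malformed outputs")
        if not np.all(np.isfinite(subj.accel_pelvis_frame)) or not np.all(
            np.isfinite(subj.outputs)
        ):
            raise ValueError(f"subject {subj.subject_id}: non-finite waveform values")
        X_rows.append(subj.accel_pelvis_frame.reshape(-1))
        Y_rows.append(subj.outputs.reshape(-1))
        ids.append(subj.subject_id)
    return CohortMatrices(np.vstack(X_rows), np.vstack(Y_rows), ids)


@dataclass
class PCAModel:
    """Principal components of one cohort matrix.

    ``loadings`` rows are the orthonormal component directions (the
    loading matrix); scores are computed as loadings @ (row - means).
    """

    column_means: np.ndarray        # (p,)
    loadings: np.ndarray            # (m, p), orthonormal rows
    explained_variances: np.ndarray  # (m,), descending
    total_variance: float
    ccr_threshold: float
    column_scales: np.ndarray | None = None  # set when standardize=True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def ccr(self) -> float:
        """Cumulative contribution rate attained by the retained components."""
        return float(self.explained_variances.sum() / self.total_variance)


def fit_pca(
    M: np.ndarray,
    ccr_threshold: float = 0.90,
    n_components: int | None = None,
    standardize: bool = False,
) -> PCAModel:
    """Fit PCA on centered (optionally standardized) columns of ``M``.

    The component count is the smallest m whose CCR reaches
    ``ccr_threshold``, capped at rows - 1 and at the matrix rank; pass
    ``n_components`` to freeze the count instead.  Component signs are
    fixed so each loading row's largest-magnitude entry is positive,
    making runs reproducible across platforms.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("M must be 2-D with at least two rows")
    if not 0.0 < ccr_threshold <= 1.0:
        raise ValueError("ccr_threshold must lie in (0, 1]")
    n = M.shape[0]
    means = M.mean(axis=0)
    C = M - means
    scales = None
    if standardize:
        scales = C.std(axis=0, ddof=1)
        scales[scales < 1e-12] = 1.0
        C = C / scales

    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = float(eigvals.sum())
    if total <= 1e-15:
        raise ValueError("matrix has zero total variance (all rows identical)")

    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components is None:
        ccr = np.cumsum(eigvals) / total
        m = int(np.searchsorted(ccr, ccr_threshold - 1e-12) + 1)
        m = min(m, n - 1, rank)
    else:
        if n_components < 1:
            raise ValueError("n_components must be positive")
        m = min(int(n_components), n - 1, rank)

    loadings = Vt[:m].copy()
    # deterministic sign: largest-magnitude entry of each component positive
    for i in range(m):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    return PCAModel(
        column_means=means,
        loadings=loadings,
        explained_variances=eigvals[:m],
        total_variance=total,
        ccr_threshold=ccr_threshold,
        column_scales=scales,
    )


def pca_project(model: PCAModel, row: np.ndarray) -> np.ndarray:
    """Scores of one row (or an (n, p) stack of rows)."""
    row = np.asarray(row, dtype=float)
    if row.shape[-1] != model.column_means.shape[0]:
        raise ValueError(
            f"row length {row.shape[-1]} != {model.column_means.shape[0]}"
        )
    C = row - model.column_means
    if model.column_scales is not None:
        C = C / model.column_scales
    return C @ model.loadings.T


def pca_reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Row reconstruction from scores (inverse of the projection on the span)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[-1] != model.n_components:
        raise ValueError(
            f"scores length {scores.shape[-1]} != {model.n_components}"
        )
    C = scores @ model.loadings
    if model.column_scales is not None:
        C = C * model.column_scales
    return model.column_means + C


@dataclass
class RegressionSet:
    """One OLS regression per output score on all input scores."""

    intercepts: np.ndarray    # (m_out,)
    coefficients: np.ndarray  # (m_out, m_in)

    def predict(self, scores_in: np.ndarray) -> np.ndarray:
        return self.intercepts + np.asarray(scores_in, float) @ self.coefficients.T


def fit_score_regressions(S_in: np.ndarray, S_out: np.ndarray) -> RegressionSet:
    """Ordinary least squares of every output score on all input scores."""
    S_in = np.asarray(S_in, dtype=float)
    S_out = np.asarray(S_out, dtype=float)
    n, m_in = S_in.shape
    if S_out.shape[0] != n:
        raise ValueError("S_in and S_out must have equal row counts")
    if n <= m_in + 1:
        raise ValueError(
            f"underdetermined regression: n = {n} <= m_in + 1 = {m_in + 1}"
        )
    A = np.column_stack([np.ones(n), S_in])
    beta, *_ = np.linalg.lstsq(A, S_out, rcond=None)
    return RegressionSet(intercepts=beta[0].copy(), coefficients=beta[1:].T.copy())


@dataclass
class EstimationModel:
    input_pca: PCAModel
    output_pca: PCAModel
    regressions: RegressionSet
    training_subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.regressions.coefficients.shape != (
            self.output_pca.n_components,
            self.input_pca.n_components,
        ):
            raise ValueError("regression dimensions do not match the PCA models")


def fit_estimation_model(
    matrices: CohortMatrices,
    ccr_threshold: float = 0.90,
    n_components_in: int | None = None,
    n_components_out: int | None = None,
    standardize: bool = False,
) -> EstimationModel:
    """Fit the full PCA + score-regression chain on a training cohort."""
    input_pca = fit_pca(matrices.X, ccr_threshold, n_components_in, standardize)
    output_pca = fit_pca(matrices.Y, ccr_threshold, n_components_out, standardize)
    S_in = pca_project(input_pca, matrices.X)
    S_out = pca_project(output_pca, matrices.Y)
    regressions = fit_score_regressions(S_in, S_out)
    return EstimationModel(input_pca, output_pca, regressions,
                           list(matrices.subject_ids))


def predict_waveforms(model: EstimationModel, accel_row: np.ndarray) -> np.ndarray:
    """Predict a 2121-entry output row from a 303-entry acceleration row."""
    scores_in = pca_project(model.input_pca, accel_row)
    scores_out = model.regressions.predict(scores_in)
    return pca_reconstruct(model.output_pca, scores_out)


@dataclass
class LOOCVResult:
    """Held-out predictions for every subject under every condition."""

    subject_ids: list[str]
    conditions: list[MisalignmentCondition]
    #: predictions[label] is an (n_subjects, 2121) array of held-out rows
    predictions: dict[str, np.ndarray]
    actual: np.ndarray  # (n_subjects, 2121)
    #: per-fold diagnostics: retained component counts and attained CCRs
    fold_components_in: np.ndarray
    fold_components_out: np.ndarray
    fold_ccr_in: np.ndarray
    fold_ccr_out: np.ndarray

    @property
    def n_training_rows(self) -> int:
        return len(self.subject_ids) - 1


def run_loocv(
    cohort: list[SubjectWaveforms],
    conditions: list[MisalignmentCondition] | None = None,
    ccr_threshold: float = 0.90,
    component_mode: str = "per-fold",
    standardize: bool = False,
) -> LOOCVResult:
    """Leave-one-out cross-validation under a misalignment-condition grid.

    For each fold the chain is refit on the remaining subjects' aligned
    (pelvis-frame) accelerations and outputs; component counts are
    re-selected per fold by the CCR rule (``component_mode='per-fold'``)
    or frozen at the counts selected once on the full cohort
    (``component_mode='frozen'``).  The held-out subject's accelerations
    are rotated into each condition's virtual-IMU frame before prediction;
    its own data never enter the fit.
    """
    if conditions is None:
        conditions = default_conditions()
    if component_mode not in ("per-fold", "frozen"):
        raise ValueError("component_mode must be 'per-fold' or 'frozen'")
    n = len(cohort)
    matrices = assemble_matrices(cohort)

    frozen_in = frozen_out = None
    if component_mode == "frozen":
        frozen_in = fit_pca(matrices.X, ccr_threshold, standardize=standardize).n_components
        frozen_out = fit_pca(matrices.Y, ccr_threshold, standardize=standardize).n_components

    min_rows = 4
    if n < min_rows:
        raise ValueError(f"cohort of {n} subjects is too small for LOOCV")

    predictions = {
        c.label: np.empty((n, layout.N_OUTPUT_COLUMNS)) for c in conditions
    }
    comp_in = np.empty(n, dtype=int)
    comp_out = np.empty(n, dtype=int)
    ccr_in = np.empty(n)
    ccr_out = np.empty(n)

    for s in range(n):
        keep = np.arange(n) != s
        train = CohortMatrices(
            matrices.X[keep], matrices.Y[keep],
            [sid for i, sid in enumerate(matrices.subject_ids) if i != s],
        )
        model = fit_estimation_model(
            train, ccr_threshold,
            n_components_in=frozen_in, n_components_out=frozen_out,
            standardize=standardize,
        )
        comp_in[s] = model.input_pca.n_components
        comp_out[s] = model.output_pca.n_components
        ccr_in[s] = model.input_pca.ccr
        ccr_out[s] = model.output_pca.ccr
        accel = cohort[s].accel_pelvis_frame
        for cond in conditions:
            row = misalign_pelvis_accel(accel, cond.theta_deg).reshape(-1)
            predictions[cond.label][s] = predict_waveforms(model, row)

    return LOOCVResult(
        subject_ids=list(matrices.subject_ids),
        conditions=list(conditions),
        predictions=predictions,
        actual=matrices.Y,
        fold_components_in=comp_in,
        fold_components_out=comp_out,
        fold_ccr_in=ccr_in,
        fold_ccr_out=ccr_out,
    )


# ---------------------------------------------------------------------------
# on-disk model bundle: CSVs + JSON manifest
# ---------------------------------------------------------------------------

def _pca_to_dir(pca: PCAModel, d: Path, prefix: str) -> dict:
    pd.DataFrame(pca.column_means[None]).to_csv(d / f"{prefix}_means.csv",
                                                index=False, header=False)
    pd.DataFrame(pca.loadings).to_csv(d / f"{prefix}_loadings.csv",
                                      index=False, header=False)
    pd.DataFrame(pca.explained_variances[None]).to_csv(
        d / f"{prefix}_eigenvalues.csv", index=False, header=False
    )
    return {
        "n_components": pca.n_components,
        "total_variance": pca.total_variance,
        "ccr_threshold": pca.ccr_threshold,
        "ccr": pca.ccr,
        "standardized": pca.column_scales is not None,
    }


def _pca_from_dir(d: Path, prefix: str, meta: dict) -> PCAModel:
    means = pd.read_csv(d / f"{prefix}_means.csv", header=None).to_numpy(float)[0]
    loadings = pd.read_csv(d / f"{prefix}_loadings.csv", header=None).to_numpy(float)
    eig = pd.read_csv(d / f"{prefix}_eigenvalues.csv", header=None).to_numpy(float)[0]
    scales = None
    if meta.get("standardized"):
        scales = pd.read_csv(d / f"{prefix}_scales.csv", header=None).to_numpy(float)[0]
    return PCAModel(means, loadings, eig, meta["total_variance"],
                    meta["ccr_threshold"], scales)


def save_model(model: EstimationModel, directory) -> None:
    """Write an estimation model as a documented CSV + JSON bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "gaitpcr-estimation-model",
        "version": 1,
        "input_columns": layout.N_INPUT_COLUMNS,
        "output_columns": layout.N_OUTPUT_COLUMNS,
        "output_variables": list(layout.OUTPUT_VARIABLES),
        "accel_axes": list(layout.ACCEL_AXES),
        "n_points": layout.N_POINTS,
        "training_subject_ids": model.training_subject_ids,
        "input_pca": _pca_to_dir(model.input_pca, d, "input"),
        "output_pca": _pca_to_dir(model.output_pca, d, "output"),
    }
    if model.input_pca.column_scales is not None:
        pd.DataFrame(model.input_pca.column_scales[None]).to_csv(
            d / "input_scales.csv", index=False, header=False
        )
        pd.DataFrame(model.output_pca.column_scales[None]).to_csv(
            d / "output_scales.csv", index=False, header=False
        )
    pd.DataFrame(model.regressions.intercepts[None]).to_csv(
        d / "regression_intercepts.csv", index=False, header=False
    )
    pd.DataFrame(model.regressions.coefficients).to_csv(
        d / "regression_coefficients.csv", index=False, header=False
    )
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory) -> EstimationModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("format") != "gaitpcr-estimation-model":
        raise ValueError(f"{d} is not a gaitpcr model bundle")
    input_pca = _pca_from_dir(d, "input", manifest["input_pca"])
    output_pca = _pca_from_dir(d, "output", manifest["output_pca"])
    intercepts = pd.read_csv(d / "regression_intercepts.csv",
                             header=None).to_numpy(float)[0]
    coefficients = pd.read_csv(d / "regression_coefficients.csv",
                               header=None).to_numpy(float)
    return EstimationModel(
        input_pca, output_pca, RegressionSet(intercepts, coefficients),
        manifest.get("training_subject_ids", []),
    )
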