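"""Identification analysis: match predicted to observed activity patterns.

Given P predicted and P observed test-set activity patterns over the same
voxels, build the P-by-P matrix of Pearson correlations across voxels —
element (n, m) correlates the *predicted* pattern of image n with the
*observed* pattern of image m.  Image m is identified correctly when the
diagonal element (m, m) is the strict maximum of column m; accuracy is the
fraction of correctly identified images, with chance level 1/P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .encoding import ResponseMatrix
from .errors import AlignmentError, DataError, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class IdentificationResult:
    """Correlation matrix, per-image correctness and summary accuracy."""

    corr_matrix: np.ndarray
    correct_flags: np.ndarray
    n_correct: int
    accuracy: float
    roi_accuracies: Optional[dict[str, float]] = None
    n_degenerate: int = 0

    @property
    def n_images(self) -> int:
        return self.corr_matrix.shape[0]

    def accuracy_percent(self) -> str:
        """Accuracy formatted to one decimal percent (report style)."""
        return f"{100.0 * self.accuracy:.1f}%"


def _unit_rows(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Center each row and scale to unit norm; zero-variance rows become zero."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    degenerate = int(np.sum(norms[:, 0] == 0.0))
    safe = np.where(norms > 0, norms, 1.0)
    return centered / safe, degenerate


def correlation_matrix(predicted: ResponseMatrix, observed: ResponseMatrix) -> np.ndarray:
    """P x P Pearson correlations across voxels.

    Row n, column m holds corr(predicted pattern of image n, observed pattern
    of image m).  Zero-variance patterns correlate 0 with everything and emit
    a logged warning instead of an exception.
    """
    if list(predicted.voxel_ids) != list(observed.voxel_ids):
        raise AlignmentError("predicted and observed voxel ids differ")
    P = predicted.values.shape[0]
    if observed.values.shape[0] != P:
        raise ShapeError(
            f"predicted has {P} stimuli but observed has {observed.values.shape[0]}"
        )
    if P < 2:
        raise ShapeError("identification needs at least 2 test stimuli")
    if predicted.values.shape[1] < 2:
        raise ShapeError("identification needs at least 2 voxels")

    zp, deg_p = _unit_rows(predicted.values)
    zo, deg_o = _unit_rows(observed.values)
    if deg_p or deg_o:
        logger.warning(
            "degenerate zero-variance patterns: %d predicted, %d observed; "
            "their correlations are set to 0", deg_p, deg_o,
        )
    return np.clip(zp @ zo.T, -1.0, 1.0)


def identify(corr: np.ndarray) -> IdentificationResult:
    """Score a correlation matrix: column m is correct iff its diagonal entry
    is the strict maximum of the column (ties count as incorrect)."""
    corr = np.asarray(corr, dtype=np.float64)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ShapeError(f"correlation matrix must be square, got {corr.shape}")
    if not np.isfinite(corr).all():
        raise DataError("correlation matrix contains non-finite values")
    P = corr.shape[0]
    flags = np.zeros(P, dtype=bool)
    for m in range(P):
        col = corr[:, m]
        diag = col[m]
        rivals = np.delete(col, m)
        flags[m] = bool(diag > rivals.max())
    n_correct = int(flags.sum())
    return IdentificationResult(corr, flags, n_correct, n_correct / P)


def chance_accuracy_mc(
    n_images: int = 120,
    n_voxels: int = 500,
    n_replicates: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo identification accuracies under exchangeable random
    predictions: predicted and observed patterns are independent standard
    normal, so the expected accuracy is the chance level 1/n_images."""
    accs = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, 404, r])
        pred = ResponseMatrix(
            rng.standard_normal((n_images, n_voxels)),
            [f"v{k}" for k in range(n_voxels)],
            [f"s{k}" for k in range(n_images)],
        )
        obs = ResponseMatrix(
            rng.standard_normal((n_images, n_voxels)),
            list(pred.voxel_ids), list(pred.stimulus_ids),
        )
        accs[r] = identify(correlation_matrix(pred, obs)).accuracy
    return accs


def identify_by_roi(
    predicted: ResponseMatrix,
    observed: ResponseMatrix,
    roi_labels: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict[str, IdentificationResult]:
    """Run the identification analysis separately within each ROI.

    ``roi_labels`` maps ROI name to voxel-id list; when omitted, the observed
    matrix's own ``roi_labels`` are used.  Empty ROIs are skipped with a
    warning; single-voxel ROIs are degenerate (Pearson needs >= 2 voxels) and
    yield an all-zero correlation matrix with accuracy NaN ("undefined").
    """
    if roi_labels is None:
        roi_labels = observed.rois()
        if not roi_labels:
            raise DataError("no ROI labels available on the observed matrix")
    results: dict[str, IdentificationResult] = {}
    for roi, voxels in roi_labels.items():
        voxels = [v for v in voxels if v in set(predicted.voxel_ids)]
        if len(voxels) == 0:
            logger.warning("ROI %s has no voxels; skipped", roi)
            continue
        if len(voxels) == 1:
            logger.warning("ROI %s has a single voxel; identification undefined", roi)
            P = predicted.values.shape[0]
            results[roi] = IdentificationResult(
                np.zeros((P, P)), np.zeros(P, dtype=bool), 0, float("nan"), n_degenerate=P,
            )
            continue
        corr = correlation_matrix(predicted.restrict(voxels), observed.restrict(voxels))
        results[roi] = identify(corr)
    return results
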