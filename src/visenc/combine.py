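"""Fuse two sets of predicted activity patterns by (weighted) averaging.

The combined model of the analysis simply averages, voxel by voxel, the
patterns predicted by the stimulus encoding model and the region-to-region
model.  Raw averaging is the default for fidelity; an optional per-voxel
z-scoring switch puts the two inputs on a common scale first when their
prediction scales differ.
"""

from __future__ import annotations

import numpy as np

from .encoding import ResponseMatrix
from .errors import AlignmentError, ConfigurationError


def _zscore_per_voxel(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def combine_predictions(
    pred_a: ResponseMatrix,
    pred_b: ResponseMatrix,
    weight_a: float = 0.5,
    standardize: bool = False,
) -> ResponseMatrix:
    """Elementwise ``weight_a * A + (1 - weight_a) * B``.

    ``weight_a = 0.5`` (the default) is the plain average.  With
    ``standardize=True`` each input is z-scored per voxel before mixing.
    """
    if not (0.0 <= weight_a <= 1.0):
        raise ConfigurationError(f"weight_a must lie in [0, 1], got {weight_a}")
    if list(pred_a.stimulus_ids) != list(pred_b.stimulus_ids):
        raise AlignmentError("predictions have different stimulus ids")
    if list(pred_a.voxel_ids) != list(pred_b.voxel_ids):
        raise AlignmentError("predictions have different voxel ids")
    a, b = pred_a.values, pred_b.values
    if standardize:
        a, b = _zscore_per_voxel(a), _zscore_per_voxel(b)
    vals = weight_a * a + (1.0 - weight_a) * b
    labels = dict(pred_a.roi_labels) if pred_a.roi_labels else None
    return ResponseMatrix(vals, list(pred_a.voxel_ids), list(pred_a.stimulus_ids), labels)
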