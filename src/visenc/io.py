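"""File formats: HDF5 interchange, CSV/NPY fallbacks, ROI JSON, result JSON.

Canonical interchange is HDF5 for the large matrices (features, responses,
models) and JSON for metadata and identification results; CSV is kept for
human inspection.  All writers/readers round-trip values and identifiers
losslessly.  Voxel indices in ROI files are names (strings) matching the
voxel ids of the response matrices; plain integers are accepted and mapped
to positional voxel ids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .encoding import EncodingModel, ResponseMatrix, TrainConfig
from .errors import DataError, ShapeError
from .gabor import FeatureMatrix, PyramidConfig, WaveletSpec
from .identification import IdentificationResult

logger = logging.getLogger(__name__)

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(group: h5py.Group, name: str, values: Sequence[str]) -> None:
    group.create_dataset(name, data=np.array(list(values), dtype=object), dtype=_STR)


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    if name not in group:
        raise DataError(f"dataset {name!r} missing from {group.file.filename}")
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


# ---------------------------------------------------------------------------
# FeatureMatrix

def write_features(path, fm: FeatureMatrix, config: Optional[PyramidConfig] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fm.values)
        _write_strings(f, "stimulus_ids", fm.stimulus_ids)
        spec_rows = [
            (
                -1 if s.is_luminance else s.frequency,
                -1 if s.is_luminance else s.grid_row,
                -1 if s.is_luminance else s.grid_col,
                -1.0 if s.is_luminance else s.orientation,
                s.is_luminance,
            )
            for s in fm.channel_specs
        ]
        dt = np.dtype(
            [("frequency", "i4"), ("grid_row", "i4"), ("grid_col", "i4"),
             ("orientation", "f8"), ("is_luminance", "?")]
        )
        f.create_dataset("channel_specs", data=np.array(spec_rows, dtype=dt))
        if config is not None:
            f.attrs["config"] = json.dumps(asdict(config))


def read_features(path) -> tuple[FeatureMatrix, Optional[PyramidConfig]]:
    with h5py.File(path, "r") as f:
        if "values" not in f or "channel_specs" not in f:
            raise DataError(f"{path} is not a feature file (missing datasets)")
        values = f["values"][()]
        ids = _read_strings(f, "stimulus_ids")
        specs = []
        for row in f["channel_specs"][()]:
            if bool(row["is_luminance"]):
                specs.append(WaveletSpec(is_luminance=True))
            else:
                specs.append(
                    WaveletSpec(
                        frequency=int(row["frequency"]),
                        grid_row=int(row["grid_row"]),
                        grid_col=int(row["grid_col"]),
                        orientation=float(row["orientation"]),
                    )
                )
        config = None
        if "config" in f.attrs:
            d = json.loads(f.attrs["config"])
            d["frequencies"] = tuple(d["frequencies"])
            d["orientations"] = tuple(d["orientations"])
            config = PyramidConfig(**d)
    return FeatureMatrix(values, specs, ids), config


# ---------------------------------------------------------------------------
# ResponseMatrix

def write_responses(path, rm: ResponseMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rm.values)
        _write_strings(f, "voxel_ids", rm.voxel_ids)
        _write_strings(f, "stimulus_ids", rm.stimulus_ids)
        if rm.roi_labels is not None:
            f.attrs["roi_labels"] = json.dumps(rm.roi_labels)


def read_responses(path) -> ResponseMatrix:
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise DataError(f"{path} is not a response file (missing 'values')")
        values = f["values"][()]
        voxel_ids = _read_strings(f, "voxel_ids")
        stimulus_ids = _read_strings(f, "stimulus_ids")
        labels = json.loads(f.attrs["roi_labels"]) if "roi_labels" in f.attrs else None
    return ResponseMatrix(values, voxel_ids, stimulus_ids, labels)


def write_responses_csv(path, rm: ResponseMatrix) -> None:
    df = pd.DataFrame(rm.values, index=rm.stimulus_ids, columns=rm.voxel_ids)
    df.index.name = "stimulus_id"
    df.to_csv(path, float_format="%.17g")


def read_responses_csv(path) -> ResponseMatrix:
    df = pd.read_csv(path, index_col=0)
    return ResponseMatrix(df.to_numpy(dtype=np.float64), [str(c) for c in df.columns],
                          [str(i) for i in df.index])


# ---------------------------------------------------------------------------
# EncodingModel

def write_model(path, model: EncodingModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kernels", data=model.kernels)
        f.create_dataset("constants", data=model.constants)
        _write_strings(f, "channel_ids", model.channel_ids)
        _write_strings(f, "voxel_ids", model.voxel_ids)
        if model.channel_means is not None:
            f.create_dataset("channel_means", data=model.channel_means)
            f.create_dataset("channel_sds", data=model.channel_sds)
        f.attrs["train_config"] = json.dumps(asdict(model.train_config))
        f.attrs["diagnostics"] = json.dumps(model.diagnostics)


def read_model(path) -> EncodingModel:
    with h5py.File(path, "r") as f:
        if "kernels" not in f:
            raise DataError(f"{path} is not a model file (missing 'kernels')")
        kernels = f["kernels"][()]
        constants = f["constants"][()]
        channel_ids = _read_strings(f, "channel_ids")
        voxel_ids = _read_strings(f, "voxel_ids")
        means = f["channel_means"][()] if "channel_means" in f else None
        sds = f["channel_sds"][()] if "channel_sds" in f else None
        cfg = TrainConfig(**json.loads(f.attrs["train_config"]))
        diags = json.loads(f.attrs["diagnostics"]) if "diagnostics" in f.attrs else []
    return EncodingModel(kernels, constants, channel_ids, voxel_ids, means, sds, cfg, diags)


# ---------------------------------------------------------------------------
# Synthetic ground truth

def write_ground_truth(path, gt) -> None:
    with h5py.File(path, "w") as f:
        for name in ("true_kernels", "true_constants", "latent_train", "latent_test",
                     "latent_loadings", "signal_train", "signal_test"):
            f.create_dataset(name, data=getattr(gt, name))
        if gt.loc_mixing is not None:
            f.create_dataset("loc_mixing", data=gt.loc_mixing)
        f.attrs["roi_labels"] = json.dumps(gt.roi_labels)
        f.attrs["params"] = json.dumps(gt.params)
        f.attrs["seed"] = gt.seed


def read_ground_truth(path):
    from .simulate import SyntheticGroundTruth

    with h5py.File(path, "r") as f:
        kwargs = {
            name: f[name][()]
            for name in ("true_kernels", "true_constants", "latent_train", "latent_test",
                         "latent_loadings", "signal_train", "signal_test")
        }
        mixing = f["loc_mixing"][()] if "loc_mixing" in f else None
        return SyntheticGroundTruth(
            roi_labels=json.loads(f.attrs["roi_labels"]),
            params=json.loads(f.attrs["params"]),
            seed=int(f.attrs["seed"]),
            loc_mixing=mixing,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# ROI files and identification results

def write_rois(path, rois: dict[str, list]) -> None:
    Path(path).write_text(json.dumps(rois, indent=2, sort_keys=True))


def read_rois(path, voxel_ids: Optional[Sequence[str]] = None) -> dict[str, list[str]]:
    """Read {roi_name: [voxel ids]} JSON.  Integer entries are mapped to
    positional voxel ids when `voxel_ids` is given.  Overlapping ROIs are
    accepted; the overlap is logged."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise DataError(f"{path}: ROI file must be a JSON object")
    out: dict[str, list[str]] = {}
    for roi, members in raw.items():
        resolved = []
        for m in members:
            if isinstance(m, int):
                if voxel_ids is None:
                    raise DataError(f"{path}: integer voxel index {m} but no voxel ids to map onto")
                if not (0 <= m < len(voxel_ids)):
                    raise DataError(f"{path}: voxel index {m} out of range")
                resolved.append(voxel_ids[m])
            else:
                resolved.append(str(m))
        out[roi] = resolved
    seen: dict[str, str] = {}
    for roi, members in out.items():
        for m in members:
            if m in seen:
                logger.info("ROI overlap: voxel %s in both %s and %s", m, seen[m], roi)
            else:
                seen[m] = roi
    return out


def identification_to_dict(result: IdentificationResult) -> dict:
    d = {
        "n_images": int(result.n_images),
        "n_correct": int(result.n_correct),
        "accuracy": None if np.isnan(result.accuracy) else float(result.accuracy),
        "accuracy_percent": None if np.isnan(result.accuracy) else f"{100 * result.accuracy:.1f}%",
        "correct_flags": [bool(b) for b in result.correct_flags],
        "n_degenerate": int(result.n_degenerate),
    }
    if result.roi_accuracies is not None:
        d["roi_accuracies"] = {
            k: (None if v is None or np.isnan(v) else float(v))
            for k, v in result.roi_accuracies.items()
        }
    return d


def write_identification(path, result: IdentificationResult, matrix_path=None) -> None:
    Path(path).write_text(json.dumps(identification_to_dict(result), indent=2, sort_keys=True))
    if matrix_path is not None:
        np.savetxt(matrix_path, result.corr_matrix, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# Optional adapter: MATLAB-format response matrices
#
# The public dataset this analysis was designed around ships as MATLAB files
# with its own (1-based) voxel indexing.  This adapter is deliberately
# separate from the package's native formats: it converts one named
# stimuli-by-voxels array into a ResponseMatrix with 0-based positional voxel
# ids.  It needs scipy (v5 MAT files) or falls back to h5py (v7.3).

def read_mat_responses(path, variable: str, transpose: bool = False) -> ResponseMatrix:
    """Load a stimuli x voxels array named `variable` from a MATLAB file.

    ``transpose=True`` for files storing voxels x stimuli.  Voxel ids are
    positional (``v0000`` ...); any ROI files using the dataset's own 1-based
    indexing must be shifted by -1 before use with :func:`read_rois`.
    """
    try:
        from scipy.io import loadmat

        data = loadmat(path, variable_names=[variable])
        if variable not in data:
            raise DataError(f"{path}: no variable {variable!r}")
        values = np.asarray(data[variable], dtype=np.float64)
    except NotImplementedError:  # MATLAB v7.3 files are HDF5 underneath
        with h5py.File(path, "r") as f:
            if variable not in f:
                raise DataError(f"{path}: no variable {variable!r}")
            values = np.asarray(f[variable][()], dtype=np.float64).T
    if transpose:
        values = values.T
    n, v = values.shape
    return ResponseMatrix(
        values,
        [f"v{j:04d}" for j in range(v)],
        [f"s{i:05d}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# Images

def load_images(path, image_size: int) -> np.ndarray:
    """Load a stimulus stack from an NPY file or a directory of PNGs
    (lexicographic file order = stimulus order)."""
    from PIL import Image

    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir() if q.suffix.lower() == ".png")
        if not files:
            raise DataError(f"no PNG files found in {p}")
        stack = np.stack([np.asarray(Image.open(q).convert("L"), dtype=np.float64) for q in files])
    elif p.suffix == ".npy":
        stack = np.load(p)
    else:
        raise DataError(f"unsupported image input {p} (expected a directory of PNGs or an .npy stack)")
    if stack.ndim != 3 or stack.shape[1] != image_size or stack.shape[2] != image_size:
        raise ShapeError(f"expected (n, {image_size}, {image_size}) images, got {stack.shape}")
    return stack
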