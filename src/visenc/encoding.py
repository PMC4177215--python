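"""Per-voxel linear encoding models fit by early-stopped gradient descent.

Each voxel's response across stimuli is modelled as ``y = X h + c + noise``
with a design matrix ``X`` (stimuli x input channels), a per-voxel kernel
``h`` and an intercept ``c``.  The machinery is agnostic to what the input
channels are: Gabor features of the stimuli give the stimulus encoding model
(VBEM); another region's voxel activity patterns give the analogical
region-to-region model (AVBEM).  No code path distinguishes the two.

Estimation is deliberately NOT a closed-form least-squares solve.  For each
voxel a fixed fraction of the training rows is set aside as a *stopping set*;
full-batch gradient descent on the summed squared error starts from a zero
kernel and the snapshot with the lowest stopping-set error is kept, so the
coefficient magnitudes are shrunk before over-fitting sets in.  A bootstrap
loop resamples the remaining (estimation) rows and the final kernel and
intercept are the averages over bootstrap rounds.

All randomness (stopping-set draw, bootstrap resampling) is a deterministic
function of ``(config.seed, voxel_index, round_index)``; identical inputs and
seeds reproduce models bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError, DataError, ShapeError

logger = logging.getLogger(__name__)

# Above this channel count the Gram precomputation (q+1)^2 becomes more
# expensive than iterating with the raw design; switch to direct gradients.
_GRAM_MAX_Q = 3000


@dataclass
class DesignMatrix:
    """Stimuli-by-channels design (the model's input channels)."""

    values: np.ndarray
    channel_ids: list[str]
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("DesignMatrix values must be 2-D (stimuli x channels)")
        p, q = self.values.shape
        if p < 2:
            raise DataError(f"need at least 2 stimuli, got {p}")
        if q < 1:
            raise DataError("need at least 1 input channel")
        if len(self.channel_ids) != q or len(self.stimulus_ids) != p:
            raise ShapeError("channel/stimulus id counts do not match values shape")
        if not np.isfinite(self.values).all():
            raise DataError("DesignMatrix contains non-finite values")


@dataclass
class ResponseMatrix:
    """Stimuli-by-voxels response amplitudes, with optional ROI labels."""

    values: np.ndarray
    voxel_ids: list[str]
    stimulus_ids: list[str]
    roi_labels: Optional[dict[str, str]] = None  # voxel_id -> ROI name

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("ResponseMatrix values must be 2-D (stimuli x voxels)")
        n, v = self.values.shape
        if len(self.voxel_ids) != v or len(self.stimulus_ids) != n:
            raise ShapeError("voxel/stimulus id counts do not match values shape")
        if not np.isfinite(self.values).all():
            raise DataError("ResponseMatrix contains non-finite values")
        if self.roi_labels is not None:
            unknown = set(self.roi_labels) - set(self.voxel_ids)
            if unknown:
                raise AlignmentError(f"roi_labels reference unknown voxels: {sorted(unknown)[:5]}")

    def as_design(self) -> DesignMatrix:
        """Use these voxel patterns as input channels (the AVBEM design)."""
        return DesignMatrix(self.values, list(self.voxel_ids), list(self.stimulus_ids))

    def restrict(self, voxel_ids: Sequence[str]) -> "ResponseMatrix":
        """Column subset preserving order of `voxel_ids`."""
        index = {v: i for i, v in enumerate(self.voxel_ids)}
        missing = [v for v in voxel_ids if v not in index]
        if missing:
            raise AlignmentError(f"unknown voxel ids: {missing[:5]}")
        cols = [index[v] for v in voxel_ids]
        labels = None
        if self.roi_labels is not None:
            labels = {v: self.roi_labels[v] for v in voxel_ids if v in self.roi_labels}
        return ResponseMatrix(self.values[:, cols], list(voxel_ids), list(self.stimulus_ids), labels)

    def rois(self) -> dict[str, list[str]]:
        """Invert roi_labels into ROI -> ordered voxel-id lists."""
        out: dict[str, list[str]] = {}
        if self.roi_labels:
            for v in self.voxel_ids:
                roi = self.roi_labels.get(v)
                if roi is not None:
                    out.setdefault(roi, []).append(v)
        return out


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the gradient-descent / early-stopping estimator.

    ``learning_rate`` is the step applied to the summed-squared-error
    gradient on standardized channels; it is capped at 0.9 / lambda_max of
    the (augmented) Gram matrix of each bootstrap sample so descent stays
    stable on strongly correlated designs.  ``stopping_fraction`` of the
    training rows is held out once per voxel as the stopping set;
    performance on it is evaluated every ``eval_every`` iterations and
    descent halts after ``patience`` evaluations without a relative
    improvement of at least ``min_rel_improvement``.
    """

    learning_rate: float = 1e-4
    max_iters: int = 5000
    stopping_fraction: float = 0.20
    patience: int = 20
    eval_every: int = 10
    n_bootstrap: int = 10
    seed: int = 0
    standardize_channels: bool = True
    min_rel_improvement: float = 1e-4
    early_stopping: bool = True  # False: run to max_iters, keep the final iterate

    def __post_init__(self) -> None:
        if not (0.0 < self.stopping_fraction < 1.0):
            raise ConfigurationError("stopping_fraction must lie in (0, 1)")
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_iters < 1 or self.eval_every < 1 or self.patience < 1:
            raise ConfigurationError("max_iters, eval_every and patience must be >= 1")


@dataclass
class EncodingModel:
    """Fitted multi-voxel linear encoding model.

    ``kernels`` has one column per voxel (in the standardized-channel space
    when standardization was on); ``constants`` are the per-voxel
    intercepts.  ``channel_means``/``channel_sds`` hold the training-set
    standardization; both are None when standardization was off.
    """

    kernels: np.ndarray            # (q, V)
    constants: np.ndarray          # (V,)
    channel_ids: list[str]
    voxel_ids: list[str]
    channel_means: Optional[np.ndarray]
    channel_sds: Optional[np.ndarray]
    train_config: TrainConfig
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        self.constants = np.asarray(self.constants, dtype=np.float64)
        q, v = self.kernels.shape
        if len(self.channel_ids) != q or len(self.voxel_ids) != v or self.constants.shape != (v,):
            raise ShapeError("EncodingModel dimensions are inconsistent")
        if not (np.isfinite(self.kernels).all() and np.isfinite(self.constants).all()):
            raise DataError("EncodingModel contains non-finite parameters")

    def restrict(self, voxel_ids: Sequence[str]) -> "EncodingModel":
        index = {v: i for i, v in enumerate(self.voxel_ids)}
        missing = [v for v in voxel_ids if v not in index]
        if missing:
            raise AlignmentError(f"unknown voxel ids: {missing[:5]}")
        cols = [index[v] for v in voxel_ids]
        diags = [self.diagnostics[i] for i in cols] if self.diagnostics else []
        return EncodingModel(
            self.kernels[:, cols], self.constants[cols], list(self.channel_ids),
            list(voxel_ids), self.channel_means, self.channel_sds, self.train_config, diags,
        )


def _standardization(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant channels pass through centered
    return mu, sd


def _spectral_cap(matvec, dim: int, n_iter: int = 30) -> float:
    """Largest eigenvalue of a PSD operator by deterministic power iteration."""
    v = np.ones(dim) / np.sqrt(dim)
    lam = 0.0
    for _ in range(n_iter):
        w = matvec(v)
        lam = float(np.linalg.norm(w))
        if lam <= 0:
            return 0.0
        v = w / lam
    return lam


def _descend(
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_stop: np.ndarray,
    y_stop: np.ndarray,
    config: TrainConfig,
) -> tuple[np.ndarray, float, dict]:
    """Early-stopped full-batch gradient descent from a zero kernel.

    The intercept is treated the standard unpenalized way: design columns and
    responses are centered on the fit rows, descent runs on the kernel alone,
    and the intercept is recovered in closed form from the fit-row means.
    (Descending on an explicit all-ones channel instead injects a large
    transient into every correlated channel while the intercept converges,
    which visibly degrades the early-stopped path.)  Returns the kernel
    snapshot with minimal stopping-set summed squared error, its intercept,
    and diagnostics.
    """
    xbar = X_fit.mean(axis=0)
    ybar = float(y_fit.mean())
    A_fit = X_fit - xbar
    y_fit = y_fit - ybar
    A_stop = X_stop - xbar
    y_stop = y_stop - ybar
    n_fit, d = A_fit.shape
    use_gram = d <= _GRAM_MAX_Q
    if use_gram:
        G = A_fit.T @ A_fit
        b = A_fit.T @ y_fit
        lam_max = _spectral_cap(lambda v: G @ v, d)
        grad_fn = lambda theta: 2.0 * (G @ theta - b)
    else:
        b = A_fit.T @ y_fit
        lam_max = _spectral_cap(lambda v: A_fit.T @ (A_fit @ v), d)
        grad_fn = lambda theta: 2.0 * (A_fit.T @ (A_fit @ theta) - b)

    eta = config.learning_rate
    if lam_max > 0:
        eta = min(eta, 0.9 / lam_max)

    theta = np.zeros(d)
    best = theta.copy()
    best_err = float(np.sum(y_stop * y_stop))  # stopping error at the zero model
    bad_evals = 0
    it = 0
    while it < config.max_iters:
        theta -= eta * grad_fn(theta)
        it += 1
        if config.early_stopping and (it % config.eval_every == 0 or it == config.max_iters):
            resid = A_stop @ theta - y_stop
            err = float(resid @ resid)
            if not np.isfinite(err):
                theta = best.copy()
                break
            if err < best_err * (1.0 - config.min_rel_improvement):
                best_err = err
                best = theta.copy()
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= config.patience:
                    break
    if not config.early_stopping:
        best = theta
        resid = A_stop @ theta - y_stop
        best_err = float(resid @ resid)
    constant = ybar - float(xbar @ best)
    return best, constant, {"iterations": it, "stopping_sse": best_err, "step": eta}


def fit_voxel(
    X,
    y: np.ndarray,
    config: TrainConfig,
    voxel_index: int = 0,
    _standardized: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, float, dict]:
    """Fit one voxel's kernel and intercept.

    Returns ``(kernel, constant, diagnostics)``.  The kernel lives in the
    standardized channel space when ``config.standardize_channels`` is on.
    A constant response vector short-circuits to a zero kernel with the
    mean as intercept and a ``degenerate`` diagnostics flag.
    """
    values = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.shape[0] != values.shape[0]:
        raise ShapeError(f"response vector of length {y.shape} does not match {values.shape[0]} stimuli")
    if not np.isfinite(y).all():
        raise DataError("response vector contains non-finite values")
    p, q = values.shape

    if _standardized is not None:
        Z, mu, sd = _standardized
    elif config.standardize_channels:
        mu, sd = _standardization(values)
        Z = (values - mu) / sd
    else:
        Z, mu, sd = values, None, None

    if np.ptp(y) == 0.0:
        logger.warning("voxel %d has a constant response; returning the degenerate model", voxel_index)
        diag = {"degenerate": True, "rounds": []}
        return np.zeros(q), float(y.mean()), diag

    rng_stop = np.random.default_rng([config.seed, voxel_index, 0])
    n_stop = int(round(config.stopping_fraction * p))
    n_stop = min(max(n_stop, 1), p - 2)
    stop_idx = np.sort(rng_stop.choice(p, size=n_stop, replace=False))
    est_mask = np.ones(p, dtype=bool)
    est_mask[stop_idx] = False
    est_idx = np.flatnonzero(est_mask)

    X_est = Z[est_idx]
    y_est = y[est_idx]
    X_stop = Z[stop_idx]
    y_stop = y[stop_idx]

    kernels = []
    constants = []
    round_diags = []
    for r in range(config.n_bootstrap):
        if config.n_bootstrap == 1:
            X_fit, y_fit = X_est, y_est
        else:
            rng_r = np.random.default_rng([config.seed, voxel_index, 1 + r])
            take = rng_r.integers(0, est_idx.size, size=est_idx.size)
            X_fit, y_fit = X_est[take], y_est[take]
        kern, const, d = _descend(X_fit, y_fit, X_stop, y_stop, config)
        kernels.append(kern)
        constants.append(const)
        round_diags.append(d)
    diag = {"degenerate": False, "rounds": round_diags, "n_stopping": int(n_stop)}
    return np.mean(kernels, axis=0), float(np.mean(constants)), diag


def fit_region(X: DesignMatrix, Y: ResponseMatrix, config: TrainConfig) -> EncodingModel:
    """Fit every voxel of ``Y`` independently against the shared design ``X``.

    Per-voxel stopping sets and bootstrap draws are seeded from
    ``(config.seed, voxel_index)`` so the whole model is reproducible.
    """
    if list(X.stimulus_ids) != list(Y.stimulus_ids):
        raise AlignmentError("design and response matrices have different stimulus ids")
    p, q = X.values.shape
    n_vox = len(Y.voxel_ids)

    if config.standardize_channels:
        mu, sd = _standardization(X.values)
        Z = (X.values - mu) / sd
        std = (Z, mu, sd)
    else:
        mu = sd = None
        std = (X.values, None, None)

    kernels = np.empty((q, n_vox))
    constants = np.empty(n_vox)
    diags: list[dict] = []
    report_every = max(1, n_vox // 10)
    for v in range(n_vox):
        kernels[:, v], constants[v], d = fit_voxel(X, Y.values[:, v], config, voxel_index=v, _standardized=std)
        diags.append(d)
        if (v + 1) % report_every == 0 or v + 1 == n_vox:
            logger.info("fit_region: %d/%d voxels done", v + 1, n_vox)
    return EncodingModel(kernels, constants, list(X.channel_ids), list(Y.voxel_ids), mu, sd, config, diags)


def predict(model: EncodingModel, X_new: DesignMatrix) -> ResponseMatrix:
    """Predicted activity patterns for new stimuli."""
    if list(X_new.channel_ids) != list(model.channel_ids):
        raise AlignmentError("design channels do not match the model's training channels")
    Z = X_new.values
    if model.channel_means is not None:
        Z = (Z - model.channel_means) / model.channel_sds
    vals = Z @ model.kernels + model.constants
    return ResponseMatrix(vals, list(model.voxel_ids), list(X_new.stimulus_ids))
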