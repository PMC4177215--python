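"""Synthetic stimuli and coupled two-region voxel responses.

The generator emulates the statistical structure the encoding/identification
analysis assumes, at desk scale, so the whole pipeline is testable without
any data download:

* ``generate_images`` makes grayscale stimulus stacks — 1/f ("pink") noise
  with natural-image-like amplitude spectra, or composites of a few random
  Gabor wavelets.

* ``generate_erc`` builds an early-retinotopic-cortex-like target region:
  each voxel responds as a sparse, spatially localized linear function of
  the Gabor features (``y = X h + c + noise``), optionally mixed with a
  latent stimulus-driven component that is NOT a linear function of the
  features.  The latent share per voxel follows its ROI (V1 low, V3 high),
  emulating the idea that later areas carry more non-feature (top-down)
  signal.  ROI labels (V1/V2/V3) are assigned by the frequency band of each
  voxel's true kernel: high-frequency kernels -> V1, low -> V3.

* ``generate_loc`` builds a lateral-occipital-complex-like source region:
  each LOC voxel is a sparse random mixture of the *noise-free* ERC signal
  components plus independent noise, so a linear LOC -> ERC mapping exists
  but must be estimated through noise — exactly the premise of the
  region-to-region (AVBEM) model.  The mixture may be biased toward ERC
  voxels with low-frequency kernels (V3) to emulate an inverse sub-ROI
  gradient between the two models.

Per-voxel SNR is signal s.d. / noise s.d.; test responses average
``test_repeats`` independent noise draws, mirroring repeated presentation of
each test stimulus.  Every generator takes an explicit integer seed and is
bit-reproducible; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .encoding import ResponseMatrix
from .errors import ConfigurationError, ShapeError
from .gabor import FeatureMatrix, PyramidConfig, WaveletSpec, build_pyramid, render_wavelet

ROI_NAMES = ("V1", "V2", "V3")

# Latent (non-feature) signal share per ROI in the shared-signal study
# configuration: early areas are mostly feature-driven, later ones carry more
# shared top-down signal.
DEFAULT_LATENT_SHARES: dict[str, float] = {"V1": 0.2, "V2": 0.45, "V3": 0.7}


@dataclass(frozen=True)
class NoiseSpec:
    """Per-voxel noise level and test-set repeat averaging.

    ``snr`` is signal s.d. over noise s.d. (``math.inf`` means noiseless);
    test responses are means over ``test_repeats`` independent noise draws,
    so their effective noise s.d. is noise s.d. / sqrt(test_repeats).
    """

    snr: float = 2.0
    test_repeats: int = 13

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ConfigurationError(f"snr must be positive, got {self.snr}")
        if self.test_repeats < 1:
            raise ConfigurationError("test_repeats must be >= 1")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score parameter recovery on simulated data."""

    true_kernels: np.ndarray          # (q, V_erc), on the raw feature scale
    true_constants: np.ndarray        # (V_erc,)
    latent_train: np.ndarray          # (p, k)
    latent_test: np.ndarray           # (P, k)
    latent_loadings: np.ndarray       # (k, V_erc), scaled
    signal_train: np.ndarray          # (p, V_erc) noise-free
    signal_test: np.ndarray           # (P, V_erc) noise-free
    roi_labels: dict[str, str]        # voxel_id -> ROI
    params: dict
    seed: int
    loc_mixing: Optional[np.ndarray] = None  # (V_erc, V_loc), set by generate_loc


def _pink_noise(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.sqrt(fx * fx + fy * fy)
    amp = np.zeros_like(radius)
    amp[radius > 0] = 1.0 / radius[radius > 0]
    white = rng.standard_normal((n, size, size))
    spectra = np.fft.fft2(white) * amp
    imgs = np.real(np.fft.ifft2(spectra))
    lo = imgs.min(axis=(1, 2), keepdims=True)
    hi = imgs.max(axis=(1, 2), keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (imgs - lo) / span


def _gabor_composites(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    freqs = tuple(f for f in (1, 2, 4, 8) if f <= size / 2)
    cfg = PyramidConfig(image_size=size, frequencies=freqs)
    specs = [s for s in build_pyramid(cfg) if not s.is_luminance]
    base = 0.1 * (_pink_noise(rng, n, size) - 0.5)
    out = np.empty((n, size, size))
    for i in range(n):
        img = base[i].copy()
        for _ in range(int(rng.integers(3, 11))):
            spec = specs[int(rng.integers(len(specs)))]
            even, odd = render_wavelet(spec, cfg)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.5)
            img += amp * (np.cos(phase) * even + np.sin(phase) * odd)
        lo, hi = img.min(), img.max()
        out[i] = (img - lo) / (hi - lo if hi > lo else 1.0)
    return out


def generate_images(n: int, size: int = 128, kind: str = "pink_noise", seed: int = 0) -> np.ndarray:
    """Deterministic grayscale stimulus stack of shape (n, size, size) in [0, 1]."""
    if n < 1:
        raise ShapeError(f"need at least one image, got n={n}")
    rng = np.random.default_rng([seed, 101])
    if kind == "pink_noise":
        return _pink_noise(rng, n, size)
    if kind == "gabor_composite":
        return _gabor_composites(rng, n, size)
    raise ConfigurationError(f"unknown image kind {kind!r}")


def _frequency_pair_for_roi(frequencies: list[int], roi_index: int) -> list[int]:
    """Adjacent frequency pair for a voxel's ROI: V1 -> highest, V3 -> lowest."""
    freqs = sorted(frequencies)
    if len(freqs) == 1:
        return freqs
    n_pairs = len(freqs) - 1
    # roi_index 0 (V1) -> last pair, 2 (V3) -> first pair
    pair = round((2 - roi_index) / 2 * (n_pairs - 1))
    return freqs[pair : pair + 2]


def _localized_kernel(
    rng: np.random.Generator,
    specs: list[WaveletSpec],
    q: int,
    sparsity: float,
    roi_index: int,
    frequencies: list[int],
    orientations: list[float],
) -> np.ndarray:
    """Sparse kernel confined to one spatial neighborhood x 1-2 adjacent
    orientations x 2 adjacent frequencies (chosen by ROI band)."""
    pair = _frequency_pair_for_roi(frequencies, roi_index)
    oris = sorted(orientations)
    o_start = int(rng.integers(len(oris)))
    n_ori = int(rng.integers(1, 3))
    chosen_oris = {oris[(o_start + k) % len(oris)] for k in range(n_ori)}
    center = rng.uniform(0.2, 0.8, size=2)  # (y, x) in image-extent units

    k_target = max(1, round(sparsity * q))
    candidates = []
    for idx, s in enumerate(specs):
        if s.is_luminance or s.frequency not in pair or s.orientation not in chosen_oris:
            continue
        cy = (s.grid_row + 0.5) / s.frequency
        cx = (s.grid_col + 0.5) / s.frequency
        d2 = (cy - center[0]) ** 2 + (cx - center[1]) ** 2
        candidates.append((d2, idx))
    candidates.sort()
    support = [idx for _, idx in candidates[:k_target]]
    h = np.zeros(q)
    h[support] = rng.standard_normal(len(support))
    if not h.any():  # ensure at least one nonzero weight
        h[support[0] if support else 0] = 1.0
    return h


def _resolve_share(latent_share: Union[float, Mapping[str, float]], roi: str) -> float:
    if isinstance(latent_share, Mapping):
        share = float(latent_share.get(roi, 0.0))
    else:
        share = float(latent_share)
    if not (0.0 <= share <= 1.0):
        raise ConfigurationError(f"latent share must lie in [0, 1], got {share}")
    return share


def _noisy(
    rng: np.random.Generator, signal: np.ndarray, noise_sd: np.ndarray, repeats: int
) -> np.ndarray:
    draws = rng.standard_normal((repeats,) + signal.shape)
    return signal + noise_sd * draws.mean(axis=0)


def generate_erc(
    features: FeatureMatrix,
    n_train: int,
    n_voxels: int = 60,
    kernel_sparsity: float = 0.01,
    noise: NoiseSpec = NoiseSpec(),
    roi_scheme: str = "frequency_bands",
    latent_share: Union[float, Mapping[str, float]] = 0.0,
    n_latent: int = 3,
    seed: int = 0,
) -> tuple[ResponseMatrix, ResponseMatrix, SyntheticGroundTruth]:
    """Simulate a feature-driven target region from a featurized stimulus set.

    The first ``n_train`` rows of ``features`` are the training stimuli, the
    rest the test stimuli.  Per voxel v:

        y_v = X h_v + c_v + a_v . z + noise

    with a sparse localized kernel ``h_v``, latent per-stimulus components
    ``z`` (shared across voxels, independent of the features), and i.i.d.
    normal noise scaled so signal s.d. / noise s.d. equals ``noise.snr``.
    ``latent_share`` (scalar or per-ROI mapping) sets the fraction of signal
    variance carried by the latent components; 0 gives the pure linear
    feature model.  Test responses average ``noise.test_repeats`` draws.
    """
    if not (0.0 < kernel_sparsity <= 1.0):
        raise ConfigurationError(f"kernel_sparsity must lie in (0, 1], got {kernel_sparsity}")
    if roi_scheme != "frequency_bands":
        raise ConfigurationError(f"unknown roi_scheme {roi_scheme!r}")
    p_total, q = features.values.shape
    if not (1 <= n_train < p_total):
        raise ShapeError(f"n_train={n_train} incompatible with {p_total} featurized stimuli")
    n_test = p_total - n_train
    X_tr = features.values[:n_train]
    X_te = features.values[n_train:]
    freqs = sorted({s.frequency for s in features.channel_specs if not s.is_luminance})
    oris = sorted({s.orientation for s in features.channel_specs if not s.is_luminance})

    rng = np.random.default_rng([seed, 202])
    kernels = np.zeros((q, n_voxels))
    constants = rng.standard_normal(n_voxels)
    z_tr = rng.standard_normal((n_train, n_latent))
    z_te = rng.standard_normal((n_test, n_latent))
    loadings = np.zeros((n_latent, n_voxels))
    roi_of = {}
    voxel_ids = [f"erc_{v:04d}" for v in range(n_voxels)]

    sig_tr = np.empty((n_train, n_voxels))
    sig_te = np.empty((n_test, n_voxels))
    for v in range(n_voxels):
        roi_idx = v % len(ROI_NAMES)
        roi = ROI_NAMES[roi_idx]
        roi_of[voxel_ids[v]] = roi
        share = _resolve_share(latent_share, roi)

        h = _localized_kernel(rng, features.channel_specs, q, kernel_sparsity, roi_idx, freqs, oris)
        feat_tr = X_tr @ h
        sd_f = feat_tr.std()
        if sd_f > 0:
            h = h / sd_f
        lat = np.zeros(n_latent)
        lat[int(rng.integers(n_latent))] = rng.standard_normal() or 1.0
        lat_tr = z_tr @ lat
        sd_l = lat_tr.std()
        if sd_l > 0:
            lat = lat / sd_l

        h *= np.sqrt(1.0 - share)
        lat *= np.sqrt(share)
        kernels[:, v] = h
        loadings[:, v] = lat
        sig_tr[:, v] = X_tr @ h + z_tr @ lat
        sig_te[:, v] = X_te @ h + z_te @ lat

    sig_sd = sig_tr.std(axis=0)
    noise_sd = np.zeros(n_voxels) if np.isinf(noise.snr) else sig_sd / noise.snr

    rng_noise = np.random.default_rng([seed, 203])
    y_tr = _noisy(rng_noise, sig_tr + constants, noise_sd, 1)
    y_te = _noisy(rng_noise, sig_te + constants, noise_sd, noise.test_repeats)

    train_ids = list(features.stimulus_ids[:n_train])
    test_ids = list(features.stimulus_ids[n_train:])
    gt = SyntheticGroundTruth(
        true_kernels=kernels,
        true_constants=constants,
        latent_train=z_tr,
        latent_test=z_te,
        latent_loadings=loadings,
        signal_train=sig_tr,
        signal_test=sig_te,
        roi_labels=dict(roi_of),
        params={
            "n_voxels": n_voxels,
            "kernel_sparsity": kernel_sparsity,
            "snr": noise.snr,
            "test_repeats": noise.test_repeats,
            "latent_share": dict(latent_share) if isinstance(latent_share, Mapping) else latent_share,
            "n_latent": n_latent,
            "noise_sd": noise_sd.tolist(),
        },
        seed=seed,
    )
    train = ResponseMatrix(y_tr, voxel_ids, train_ids, dict(roi_of))
    test = ResponseMatrix(y_te, list(voxel_ids), test_ids, dict(roi_of))
    return train, test, gt


def generate_loc(
    erc_train: ResponseMatrix,
    erc_test: ResponseMatrix,
    ground_truth: SyntheticGroundTruth,
    n_voxels: int = 40,
    mixing_density: float = 0.2,
    noise: NoiseSpec = NoiseSpec(snr=0.5),
    low_freq_bias: float = 0.0,
    seed: int = 0,
) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Simulate a source region whose voxels mix the noise-free ERC signals.

    Each LOC voxel is a sparse random linear mixture (density
    ``mixing_density``) of the ERC *signal* components — never of the ERC
    measurement noise — plus independent noise at ``noise.snr``, so a linear
    LOC -> ERC mapping exists but is noisy.  ``low_freq_bias`` b rescales
    mixing weights by (1+b) for V3 (low-frequency-kernel) ERC voxels and
    1/(1+b) for V1 voxels, biasing the LOC toward low-frequency signals.
    The effective mixing matrix is stored on ``ground_truth.loc_mixing``.
    """
    if not (0.0 < mixing_density <= 1.0):
        raise ConfigurationError(f"mixing_density must lie in (0, 1], got {mixing_density}")
    if low_freq_bias < 0:
        raise ConfigurationError("low_freq_bias must be >= 0")
    S_tr = ground_truth.signal_train
    S_te = ground_truth.signal_test
    if S_tr.shape != erc_train.values.shape or S_te.shape != erc_test.values.shape:
        raise ShapeError("ERC matrices do not match the ground truth they came with")
    v_erc = S_tr.shape[1]
    erc_ids = sorted(ground_truth.roi_labels)  # erc_#### sorts by index
    rois = np.array([ground_truth.roi_labels[v] for v in erc_ids])

    rng = np.random.default_rng([seed, 301])
    mask = rng.random((v_erc, n_voxels)) < mixing_density
    for j in np.flatnonzero(~mask.any(axis=0)):
        mask[int(rng.integers(v_erc)), j] = True
    M = np.where(mask, rng.standard_normal((v_erc, n_voxels)), 0.0)
    if low_freq_bias > 0:
        scale = np.ones(v_erc)
        scale[rois == "V1"] = 1.0 / (1.0 + low_freq_bias)
        scale[rois == "V3"] = 1.0 + low_freq_bias
        M = M * scale[:, None]

    sig_tr = S_tr @ M
    sd = sig_tr.std(axis=0)
    M = M / np.where(sd > 0, sd, 1.0)
    sig_tr = S_tr @ M
    sig_te = S_te @ M
    ground_truth.loc_mixing = M

    noise_sd = np.zeros(n_voxels) if np.isinf(noise.snr) else sig_tr.std(axis=0) / noise.snr
    rng_noise = np.random.default_rng([seed, 302])
    y_tr = _noisy(rng_noise, sig_tr, noise_sd, 1)
    y_te = _noisy(rng_noise, sig_te, noise_sd, noise.test_repeats)

    voxel_ids = [f"loc_{v:04d}" for v in range(n_voxels)]
    # Stimulus ids follow the ERC matrices (the same stimuli drive both regions).
    return (
        ResponseMatrix(y_tr, voxel_ids, list(erc_train.stimulus_ids)),
        ResponseMatrix(y_te, list(voxel_ids), list(erc_test.stimulus_ids)),
    )
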