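"""Gabor wavelet pyramid featurization of grayscale images.

A pyramid is a fixed dictionary of quadrature-pair Gabor wavelets covering a
square field of view at several spatial frequencies.  At frequency ``n``
cycles/FOV the wavelets sit on an ``n``-by-``n`` grid tiling the image, each
grid cell carrying one wavelet per orientation; a single luminance-only
wavelet (a uniform filter over the whole image) is prepended.  With the
default six frequencies (1, 2, 4, 8, 16, 32 cycles/FOV) and eight
orientations the dictionary holds (1 + 4 + 16 + 64 + 256 + 1024) * 8 + 1 =
10,921 wavelets.

Featurization projects each (mean-subtracted) image onto the even- and
odd-phase components of every wavelet, takes the quadrature magnitude, and
applies a compressive ``log(offset + magnitude)`` nonlinearity.  The result
is one non-negative feature vector per image, used downstream as the input
channels of the stimulus encoding model.

Filters are rendered on the full image canvas.  Both quadrature phases are
DC-corrected (a multiple of the Gaussian envelope is subtracted so each
filter sums to zero) and the odd phase is orthogonalized against the even
phase, so the pair is an exact numerical quadrature basis even where the
envelope is truncated by the canvas edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DataError, ShapeError

DEFAULT_FREQUENCIES: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
DEFAULT_ORIENTATIONS: tuple[float, ...] = tuple(22.5 * k for k in range(8))

# Chunk size (wavelets per matmul block) when featurizing; bounds memory at
# roughly chunk * image_size**2 * 16 bytes for the rendered filter bank.
_FEATURIZE_CHUNK = 256


@dataclass(frozen=True)
class PyramidConfig:
    """Parameters of the Gabor wavelet dictionary.

    Parameters
    ----------
    image_size:
        Pixels per image side; filters are rendered on this canvas.
    field_of_view:
        Visual angle in degrees spanned by the image.  Metadata only — all
        geometry is expressed in cycles per FOV and pixels.
    frequencies:
        Carrier frequencies in integer cycles/FOV.  Frequency ``n`` places
        wavelets on an ``n``-by-``n`` grid.
    orientations:
        Carrier orientations in degrees, counterclockwise from horizontal,
        each in [0, 180).
    bandwidth_octaves:
        Half-amplitude spatial-frequency bandwidth of the Gaussian envelope,
        in octaves.  Sets the envelope s.d. proportional to the carrier
        wavelength.
    include_luminance:
        Whether to prepend the luminance-only wavelet.
    log_offset:
        Constant inside the compressive log: feature = log(offset + magnitude).
    """

    image_size: int = 128
    field_of_view: float = 20.0
    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    bandwidth_octaves: float = 1.0
    include_luminance: bool = True
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ConfigurationError(f"image_size must be positive, got {self.image_size}")
        if not self.frequencies:
            raise ConfigurationError("at least one frequency is required")
        nyquist = self.image_size / 2
        for f in self.frequencies:
            if f <= 0:
                raise ConfigurationError(f"frequency must be positive, got {f}")
            if f > nyquist:
                raise ConfigurationError(
                    f"frequency {f} cycles/FOV exceeds the Nyquist limit "
                    f"{nyquist:g} for image_size {self.image_size}"
                )
        for o in self.orientations:
            if not (0.0 <= o < 180.0):
                raise ConfigurationError(f"orientation must lie in [0, 180), got {o}")
        if self.log_offset <= 0:
            raise ConfigurationError(f"log_offset must be positive, got {self.log_offset}")
        if self.bandwidth_octaves <= 0:
            raise ConfigurationError("bandwidth_octaves must be positive")

    @property
    def n_wavelets(self) -> int:
        n = sum(f * f for f in self.frequencies) * len(self.orientations)
        return n + (1 if self.include_luminance else 0)

    def envelope_sigma(self, frequency: int) -> float:
        """Gaussian envelope s.d. in pixels for a carrier at `frequency`.

        Standard Gabor parameterization: for a half-amplitude frequency
        bandwidth of ``b`` octaves,
        sigma = (wavelength / pi) * sqrt(ln 2 / 2) * (2^b + 1) / (2^b - 1),
        so sigma scales with the carrier period.
        """
        wavelength = self.image_size / frequency
        b = self.bandwidth_octaves
        return wavelength / math.pi * math.sqrt(math.log(2) / 2) * (2**b + 1) / (2**b - 1)


@dataclass(frozen=True)
class WaveletSpec:
    """One wavelet of the pyramid.

    The luminance wavelet carries ``is_luminance=True`` and no frequency,
    grid position or orientation.
    """

    frequency: Optional[int] = None
    grid_row: Optional[int] = None
    grid_col: Optional[int] = None
    orientation: Optional[float] = None
    is_luminance: bool = False

    def __post_init__(self) -> None:
        if self.is_luminance:
            if any(v is not None for v in (self.frequency, self.grid_row, self.grid_col, self.orientation)):
                raise ConfigurationError("luminance wavelet carries no frequency/position/orientation")
        else:
            if self.frequency is None or self.grid_row is None or self.grid_col is None or self.orientation is None:
                raise ConfigurationError("non-luminance wavelet needs frequency, grid position and orientation")
            if not (0 <= self.grid_row < self.frequency and 0 <= self.grid_col < self.frequency):
                raise ConfigurationError(
                    f"grid position ({self.grid_row}, {self.grid_col}) outside the "
                    f"{self.frequency}x{self.frequency} grid"
                )

    @property
    def channel_id(self) -> str:
        if self.is_luminance:
            return "lum"
        return f"f{self.frequency:03d}_r{self.grid_row:03d}_c{self.grid_col:03d}_o{self.orientation:05.1f}"


@dataclass
class FeatureMatrix:
    """Stimuli-by-channels feature values with channel and stimulus metadata."""

    values: np.ndarray
    channel_specs: list[WaveletSpec]
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("FeatureMatrix values must be 2-D (stimuli x channels)")
        n, q = self.values.shape
        if q != len(self.channel_specs):
            raise ShapeError(f"{q} columns but {len(self.channel_specs)} channel specs")
        if n != len(self.stimulus_ids):
            raise ShapeError(f"{n} rows but {len(self.stimulus_ids)} stimulus ids")
        if not np.isfinite(self.values).all():
            raise DataError("FeatureMatrix contains non-finite values")

    @property
    def channel_ids(self) -> list[str]:
        return [s.channel_id for s in self.channel_specs]

    def as_design(self):
        """View the features as an encoding-model design matrix."""
        from .encoding import DesignMatrix

        return DesignMatrix(self.values, self.channel_ids, list(self.stimulus_ids))


def build_pyramid(config: PyramidConfig) -> list[WaveletSpec]:
    """Enumerate the wavelet dictionary in canonical order.

    Luminance first (if included), then frequencies ascending, grid positions
    row-major, orientations ascending within each grid cell.
    """
    specs: list[WaveletSpec] = []
    if config.include_luminance:
        specs.append(WaveletSpec(is_luminance=True))
    for f in sorted(config.frequencies):
        for row in range(f):
            for col in range(f):
                for o in sorted(config.orientations):
                    specs.append(WaveletSpec(frequency=f, grid_row=row, grid_col=col, orientation=o))
    return specs


def render_wavelet(spec: WaveletSpec, config: PyramidConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one wavelet as an (even-phase, odd-phase) quadrature pair.

    Both components are image_size x image_size float arrays on the full
    canvas.  The luminance wavelet is a uniform filter with unit sum and an
    all-zero odd component.
    """
    s = config.image_size
    if spec.is_luminance:
        even = np.full((s, s), 1.0 / (s * s))
        return even, np.zeros((s, s))

    f = int(spec.frequency)
    # Grid cell centers at ((i + 0.5)/n, (j + 0.5)/n) of the image extent.
    yc = (spec.grid_row + 0.5) / f * s
    xc = (spec.grid_col + 0.5) / f * s
    px = np.arange(s) + 0.5
    u = px[np.newaxis, :] - xc          # horizontal offset, pixels
    v = yc - px[:, np.newaxis]          # vertical offset, y axis pointing up

    theta = math.radians(spec.orientation)
    wavelength = s / f
    proj = u * math.cos(theta) + v * math.sin(theta)
    sigma = config.envelope_sigma(f)
    envelope = np.exp(-(u * u + v * v) / (2.0 * sigma * sigma))
    phase = 2.0 * math.pi * proj / wavelength
    even = envelope * np.cos(phase)
    odd = envelope * np.sin(phase)

    # Zero-DC correction: subtract a multiple of the envelope so each phase
    # sums to zero even where the canvas truncates the Gaussian.
    esum = envelope.sum()
    even -= (even.sum() / esum) * envelope
    odd -= (odd.sum() / esum) * envelope
    # One Gram-Schmidt step: make the quadrature pair exactly orthogonal.
    denom = float(np.vdot(even, even))
    if denom > 0:
        odd -= (float(np.vdot(odd, even)) / denom) * even
    return even, odd


def _as_image_stack(images, size: int) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3 or arr.shape[1] != size or arr.shape[2] != size:
        raise ShapeError(
            f"expected images of shape (n, {size}, {size}), got {arr.shape}"
        )
    if not np.isfinite(arr).all():
        raise DataError("image stack contains non-finite pixels")
    if arr.size and arr.max() > 1.5:
        # 8-bit style inputs; bring onto the canonical [0, 1] scale.
        arr = arr / 255.0
    return arr


def featurize(
    images,
    pyramid: Sequence[WaveletSpec],
    config: PyramidConfig,
    stimulus_ids: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Transform an image stack into log-magnitude Gabor features.

    For each wavelet ``w`` and image ``I`` the feature is
    ``log(log_offset + sqrt((I.even_w)^2 + (I.odd_w)^2))`` where the inner
    products are taken on the per-image mean-subtracted pixels.  The
    luminance channel sees the raw (non-mean-subtracted) image through the
    uniform unit-sum filter, with the same log transform.
    """
    arr = _as_image_stack(images, config.image_size)
    n = arr.shape[0]
    if stimulus_ids is None:
        stimulus_ids = [f"img_{i:05d}" for i in range(n)]
    elif len(stimulus_ids) != n:
        raise ShapeError(f"{len(stimulus_ids)} stimulus ids for {n} images")

    flat_raw = arr.reshape(n, -1)
    flat_centered = flat_raw - flat_raw.mean(axis=1, keepdims=True)

    pyramid = list(pyramid)
    q = len(pyramid)
    out = np.empty((n, q), dtype=np.float64)
    for start in range(0, q, _FEATURIZE_CHUNK):
        block = pyramid[start : start + _FEATURIZE_CHUNK]
        evens = np.empty((len(block), flat_raw.shape[1]))
        odds = np.empty_like(evens)
        lum_cols = []
        for k, spec in enumerate(block):
            e, o = render_wavelet(spec, config)
            evens[k] = e.ravel()
            odds[k] = o.ravel()
            if spec.is_luminance:
                lum_cols.append(k)
        re = flat_centered @ evens.T
        ro = flat_centered @ odds.T
        mag = np.hypot(re, ro)
        for k in lum_cols:
            mag[:, k] = np.abs(flat_raw @ evens[k])
        out[:, start : start + len(block)] = np.log(config.log_offset + mag)
    return FeatureMatrix(out, pyramid, list(stimulus_ids))
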