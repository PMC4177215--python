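"""Synthetic data generator: stimuli, coupled two-region responses."""

import numpy as np
import pytest

from visenc import (
    ConfigurationError,
    DesignMatrix,
    NoiseSpec,
    PyramidConfig,
    ShapeError,
    TrainConfig,
    build_pyramid,
    featurize,
    fit_region,
    generate_erc,
    generate_images,
    generate_loc,
)

SMALL_PYRAMID = PyramidConfig(image_size=64, frequencies=(1, 2, 4))


@pytest.fixture(scope="module")
def small_features():
    cfg = SMALL_PYRAMID
    imgs = generate_images(60, cfg.image_size, "pink_noise", seed=5)
    return featurize(imgs, build_pyramid(cfg), cfg)


def test_images_deterministic_per_seed():
    a = generate_images(4, 64, "pink_noise", seed=9)
    b = generate_images(4, 64, "pink_noise", seed=9)
    c = generate_images(4, 64, "pink_noise", seed=10)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
    g = generate_images(3, 64, "gabor_composite", seed=9)
    assert np.array_equal(g, generate_images(3, 64, "gabor_composite", seed=9))
    assert g.min() >= 0.0 and g.max() <= 1.0


def test_image_generation_validation():
    with pytest.raises(ShapeError):
        generate_images(0, 64)
    with pytest.raises(ConfigurationError):
        generate_images(2, 64, kind="photographs")


def test_pink_noise_spectral_slope():
    """Radially averaged log-amplitude spectra fall off roughly as 1/f."""
    imgs = generate_images(20, 128, "pink_noise", seed=1)
    size = 128
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.sqrt(fx**2 + fy**2).ravel()
    bins = np.geomspace(radius[radius > 0].min(), 0.5, 20)
    slopes = []
    for img in imgs:
        amp = np.abs(np.fft.fft2(img - img.mean())).ravel()
        mids, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (radius >= lo) & (radius < hi)
            if sel.sum() > 3:
                mids.append(np.sqrt(lo * hi))
                means.append(amp[sel].mean())
        slopes.append(np.polyfit(np.log(mids), np.log(means), 1)[0])
    assert -1.4 <= np.mean(slopes) <= -0.6


def test_erc_noiseless_limit_is_exact(small_features):
    train, test, gt = generate_erc(
        small_features, n_train=50, n_voxels=8, noise=NoiseSpec(snr=np.inf), seed=3
    )
    expected_train = small_features.values[:50] @ gt.true_kernels + gt.true_constants
    expected_test = small_features.values[50:] @ gt.true_kernels + gt.true_constants
    # matrix-product association differs from the per-voxel generator loop
    # only at machine precision; no noise term is present
    assert np.max(np.abs(train.values - expected_train)) < 1e-12
    assert np.max(np.abs(test.values - expected_test)) < 1e-12
    assert np.array_equal(train.values, gt.signal_train + gt.true_constants)


def test_erc_deterministic_and_labelled(small_features):
    a = generate_erc(small_features, n_train=50, n_voxels=9, seed=4)
    b = generate_erc(small_features, n_train=50, n_voxels=9, seed=4)
    assert np.array_equal(a[0].values, b[0].values)
    assert np.array_equal(a[2].true_kernels, b[2].true_kernels)
    assert set(a[0].roi_labels.values()) == {"V1", "V2", "V3"}


def test_erc_kernels_are_sparse_and_band_localized(small_features):
    _, _, gt = generate_erc(small_features, n_train=50, n_voxels=9, kernel_sparsity=0.02, seed=6)
    specs = small_features.channel_specs
    q = len(specs)
    top_freq = {"V1": [], "V2": [], "V3": []}
    for v, vid in enumerate(sorted(gt.roi_labels)):
        support = np.flatnonzero(gt.true_kernels[:, v])
        assert 1 <= support.size <= max(1, round(0.02 * q))
        freqs = sorted({specs[j].frequency for j in support})
        assert len(freqs) <= 2  # confined to two adjacent frequency bands
        if len(freqs) == 2:
            idx = sorted({s.frequency for s in specs if not s.is_luminance})
            assert idx.index(freqs[1]) - idx.index(freqs[0]) == 1
        top_freq[gt.roi_labels[vid]].append(max(freqs))
    # frequency-band ROI scheme: V1 highest band, V3 lowest
    assert min(top_freq["V1"]) >= max(top_freq["V3"])
    assert np.mean(top_freq["V1"]) >= np.mean(top_freq["V2"]) >= np.mean(top_freq["V3"])


def test_empirical_snr_matches_request():
    cfg = PyramidConfig(frequencies=(1, 2, 4))
    imgs = generate_images(510, 128, "pink_noise", seed=2)
    fm = featurize(imgs, build_pyramid(cfg), cfg)
    train, _, gt = generate_erc(fm, n_train=500, n_voxels=30, noise=NoiseSpec(snr=2.0), seed=2)
    residual = train.values - (gt.signal_train + gt.true_constants)
    empirical = gt.signal_train.std(axis=0) / residual.std(axis=0)
    assert np.all(np.abs(empirical - 2.0) / 2.0 < 0.15)


def test_generator_parameter_validation(small_features):
    with pytest.raises(ConfigurationError):
        generate_erc(small_features, n_train=50, kernel_sparsity=0.0)
    with pytest.raises(ConfigurationError):
        generate_erc(small_features, n_train=50, noise=NoiseSpec(snr=-1.0))
    train, test, gt = generate_erc(small_features, n_train=50, n_voxels=4, seed=1)
    with pytest.raises(ConfigurationError):
        generate_loc(train, test, gt, mixing_density=0.0)


def test_noise_free_loc_linearly_reconstructs_erc(small_features):
    """With invertible square mixing and no noise, least squares recovers the
    target-region signals from the source region exactly."""
    train, test, gt = generate_erc(
        small_features, n_train=50, n_voxels=12, noise=NoiseSpec(snr=np.inf), seed=3
    )
    loc_train, loc_test = generate_loc(
        train, test, gt, n_voxels=12, mixing_density=1.0, noise=NoiseSpec(snr=np.inf), seed=3
    )
    W = np.linalg.lstsq(loc_train.values, gt.signal_train, rcond=None)[0]
    assert np.max(np.abs(loc_test.values @ W - gt.signal_test)) < 1e-6
    assert gt.loc_mixing is not None


def test_loc_deterministic(small_features):
    train, test, gt = generate_erc(small_features, n_train=50, n_voxels=6, seed=8)
    a = generate_loc(train, test, gt, n_voxels=10, seed=8)
    b = generate_loc(train, test, gt, n_voxels=10, seed=8)
    assert np.array_equal(a[0].values, b[0].values)
    assert np.array_equal(a[1].values, b[1].values)
    assert a[0].stimulus_ids == train.stimulus_ids


def test_kernel_recovery_on_synthetic_region():
    """Parameter recovery: fitted kernels correlate with the generating
    kernels (mean over voxels > 0.6, seeds 0-4)."""
    cfg = PyramidConfig(frequencies=(1, 2, 4))
    pyramid = build_pyramid(cfg)
    means = []
    for seed in range(5):
        imgs = generate_images(640, 128, "pink_noise", seed=seed)
        ids = [f"s{i:05d}" for i in range(640)]
        fm = featurize(imgs, pyramid, cfg, stimulus_ids=ids)
        train, _, gt = generate_erc(fm, n_train=600, n_voxels=60, noise=NoiseSpec(snr=2.0), seed=seed)
        X = DesignMatrix(fm.values[:600], fm.channel_ids, ids[:600])
        model = fit_region(X, train, TrainConfig(seed=seed))
        raw_kernels = model.kernels / model.channel_sds[:, None]
        corr = [
            np.corrcoef(raw_kernels[:, v], gt.true_kernels[:, v])[0, 1]
            for v in range(60)
        ]
        means.append(np.mean(corr))
    assert np.mean(means) > 0.6
    assert min(means) > 0.5


def test_subroi_gradients_are_inverse(shared_study_results):
    """Feature-driven identification falls from V1 to V3 while source-region
    identification rises, when the source mixing favors low-frequency voxels."""
    vbem = {r: [] for r in ("V1", "V2", "V3")}
    avbem = {r: [] for r in ("V1", "V2", "V3")}
    for result in shared_study_results.values():
        for roi in vbem:
            vbem[roi].append(result["identification"]["vbem"]["roi_accuracies"][roi])
            avbem[roi].append(result["identification"]["avbem"]["roi_accuracies"][roi])
    v = {r: np.mean(a) for r, a in vbem.items()}
    a = {r: np.mean(x) for r, x in avbem.items()}
    print("stimulus-model ROI accuracies:", v)
    print("region-model ROI accuracies:", a)
    assert v["V1"] >= v["V2"] >= v["V3"]
    assert a["V1"] <= a["V2"] <= a["V3"]
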