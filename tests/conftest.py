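"""Shared fixtures: the two desk-scale simulation studies.

Both studies are expensive (a few hundred seconds total), so they are run
once per session and shared between the module-level property tests and the
acceptance tests.
"""

from __future__ import annotations

import pytest

from visenc import SHARED_SIGNAL_STUDY, VBEM_STUDY, PipelineConfig, run_pipeline

VBEM_STUDY_SEEDS = (0, 1, 2)
SHARED_STUDY_SEEDS = (0, 1, 2, 3, 4)


def run_study(spec, mode, seed, out_dir):
    return run_pipeline(
        PipelineConfig(mode=mode, seed=seed, out_dir=str(out_dir), simulation=spec)
    )


@pytest.fixture(scope="session")
def vbem_study_results(tmp_path_factory):
    """Stimulus-model study: feature-driven target region, SNR 2, seeds 0-2."""
    base = tmp_path_factory.mktemp("vbem_study")
    return {
        seed: run_study(VBEM_STUDY, "vbem", seed, base / f"seed{seed}")
        for seed in VBEM_STUDY_SEEDS
    }


@pytest.fixture(scope="session")
def shared_study_results(tmp_path_factory):
    """Shared-signal study: latent components rising V1->V3, noisy source
    region biased toward low-frequency voxels; all three models per seed."""
    base = tmp_path_factory.mktemp("shared_study")
    return {
        seed: run_study(SHARED_SIGNAL_STUDY, "combined", seed, base / f"seed{seed}")
        for seed in SHARED_STUDY_SEEDS
    }
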