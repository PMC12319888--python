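"""Shared fixtures: protocols, parameter draws, and the (expensive)
noise-propagation study reused by several tests."""

import numpy as np
import pytest

from gmexi.protocol import default_clinical_protocol
from gmexi.synthetic import recovery_study, sample_ground_truth

#: study conditions of the scaled noise-propagation experiment: 500 voxels
#: (scaled from 10,000), Rician σ = 0.02 (SNR 50 at b0), 20 directions,
#: flat ground-truth ranges, SMEX generation.  Fixed once.
STUDY_N = 500
STUDY_SIGMA = 0.02
STUDY_SEED = 7


@pytest.fixture(scope="session")
def clinical_protocol():
    return default_clinical_protocol()


@pytest.fixture(scope="session")
def flat_draws():
    """100 interior parameter draws from the flat gray-matter ranges."""
    return sample_ground_truth(100, seed=11).params


@pytest.fixture(scope="session")
def wide_pulse_study(clinical_protocol):
    """SMEX-generated noisy study at the acquisition pulse width δ = 16.5 ms,
    fit with both models."""
    gt = sample_ground_truth(STUDY_N, seed=STUDY_SEED)
    out = recovery_study(
        gt,
        clinical_protocol,
        fitted_models=("nexi", "smex"),
        sigma=STUDY_SIGMA,
        delta_scenarios=(16.5,),
        seed=STUDY_SEED,
    )
    return gt, out[16.5]


@pytest.fixture(scope="session")
def narrow_pulse_study(clinical_protocol):
    """Same ground truth and noise level with δ reduced to 4 ms (NEXI fits:
    the narrow-pulse approximation is the hypothesis under test)."""
    gt = sample_ground_truth(STUDY_N, seed=STUDY_SEED)
    out = recovery_study(
        gt,
        clinical_protocol,
        fitted_models=("nexi",),
        sigma=STUDY_SIGMA,
        delta_scenarios=(4.0,),
        seed=STUDY_SEED + 1,
    )
    return gt, out[4.0]
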