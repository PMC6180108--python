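import numpy as np
import pytest

from vigikit import (RegulationProfile, StageSignatureModel, classify_recording,
                     simulate_stage_sequence, synthesize_eeg)


@pytest.fixture(scope="session")
def clean_signature():
    """High-snr signature so stage signatures are unambiguous."""
    return StageSignatureModel(snr=10.0)


@pytest.fixture(scope="session")
def adaptive_pair(clean_signature):
    """(ground-truth timecourse, synthetic recording) for an adaptive profile."""
    tc = simulate_stage_sequence(RegulationProfile.adaptive(), 900, seed=11)
    rec = synthesize_eeg(tc, signature=clean_signature, seed=42)
    return tc, rec


@pytest.fixture(scope="session")
def adaptive_staged(adaptive_pair):
    tc, rec = adaptive_pair
    return tc, rec, classify_recording(rec)


def agreement(pred, truth) -> float:
    return float(np.mean([a is b for a, b in zip(pred.stages, truth.stages)]))
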