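import numpy as np
import pytest

from lespeech.synth import CohortSpec, VoiceSpec, gen_cohort, gen_voice


@pytest.fixture(scope="session")
def clean_voice():
    """Perturbation-free 150 Hz voice (no jitter, no shimmer, no noise)."""
    return gen_voice(
        VoiceSpec(f0_hz=150.0, jitter_pct=0.0, shimmer_pct=0.0, snr_db=None), seed=11
    )


@pytest.fixture(scope="session")
def typical_voice():
    """Mildly perturbed voice resembling healthy phonation."""
    return gen_voice(
        VoiceSpec(f0_hz=120.0, jitter_pct=0.5, shimmer_pct=2.0, snr_db=25.0), seed=12
    )


@pytest.fixture(scope="session")
def white_noise_waveform():
    from lespeech.acoustics import Waveform

    rng = np.random.default_rng(13)
    return Waveform(0.3 * rng.standard_normal(32000), 16000)


@pytest.fixture(scope="session")
def small_cohort():
    """20 PALS + 6 controls with QA contamination, fixed seed."""
    return gen_cohort(
        CohortSpec(
            n_pals=20,
            n_controls=6,
            note_contamination_frac=0.05,
            transcript_corruption_frac=0.03,
            seed=42,
        )
    )
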