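import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ctbskit import CohortConfig, generate_cohort, preprocess_trials

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_block(subject_id, amplitudes, block_kind="baseline", block_index=1,
               time_min=None, emg=None):
    """Single-block trial table from a list of amplitudes."""
    n = len(amplitudes)
    return pd.DataFrame({
        "subject_id": subject_id,
        "block_kind": block_kind,
        "baseline_block_index": block_index if block_kind == "baseline" else np.nan,
        "block_time_min": time_min if block_kind == "post" else np.nan,
        "trial_index": np.arange(1, n + 1),
        "amplitude_mv": np.asarray(amplitudes, dtype=float),
        **({"pre_stim_emg_uv": emg} if emg is not None else {}),
    })


def make_subject_trials(subject_id, baseline_mv, post_means, n_base_blocks=3,
                        n_base=30, n_post=30):
    """Noise-free multi-block layout: constant amplitude per block."""
    frames = [
        make_block(subject_id, [baseline_mv] * n_base, block_index=b)
        for b in range(1, n_base_blocks + 1)
    ]
    frames += [
        make_block(subject_id, [m] * n_post, block_kind="post", time_min=t)
        for t, m in post_means.items()
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort plus its preprocessed outputs."""
    subjects, trials, truth = generate_cohort(CohortConfig(), seed=20200313)
    flagged, blocks = preprocess_trials(trials)
    return {"subjects": subjects, "trials": trials, "truth": truth,
            "flagged": flagged, "blocks": blocks}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
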