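import numpy as np
import pandas as pd
import pytest

from itfuse import EffectSpec, ExperimentConfig


@pytest.fixture
def eeg_only_config():
    return ExperimentConfig.eeg_only(n_subjects=2, seed=11)


@pytest.fixture
def quiet_effects():
    """All noise sources off: injection recovery must be exact."""
    return EffectSpec(noise_sd_eeg=0.0, noise_sd_bold=0.0,
                      amplitude_jitter_sd=0.0, bold_jitter_sd=0.0)


def make_null_tables(rep: int, n_trials: int = 240, feature_ids=("E", "R")):
    """Feature/trial tables with responses independent of everything.

    Used for null-calibration checks: any information estimate on these
    tables should be centred at zero after bias correction.
    """
    rng = np.random.default_rng(1_000_003 + rep)
    trials = np.arange(n_trials)
    feats = pd.concat(
        [
            pd.DataFrame(
                {"trial": trials, "feature_id": fid, "value": rng.standard_normal(n_trials)}
            )
            for fid in feature_ids
        ],
        ignore_index=True,
    )
    schedule = pd.DataFrame(
        {
            "subject": 0,
            "trial": trials,
            "informativeness": np.tile(["high", "low"], n_trials // 2),
            "prioritization": np.tile(["yes", "yes", "no", "no"], n_trials // 4),
            "category": np.tile(["face", "face", "car", "car"], n_trials // 4),
            "hemifield": np.tile(["left", "right"], n_trials // 2),
            "rt": 150.0 + rng.gamma(4.0, 60.0, n_trials),
            "decision": np.where(rng.random(n_trials) < 0.5, "face", "car"),
        }
    )
    schedule["responded_within_1s"] = schedule["rt"] <= 1000.0
    return feats, schedule
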