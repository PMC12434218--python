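import numpy as np
import pytest

from nutriscore.scoring import (
    InterventionEpisode,
    PatientRecord,
    ScoreWindow,
    SupportLevel,
    WeightScheme,
)

LEVELS = [l for l in SupportLevel if l is not SupportLevel.NONE]


def make_record(episodes, patient_id="p1", followup=100, covariates=None):
    eps = [
        InterventionEpisode(patient_id=patient_id, level=lvl, start_day=s, end_day=e)
        for lvl, s, e in episodes
    ]
    return PatientRecord(
        patient_id=patient_id,
        episodes=eps,
        covariates=covariates,
        followup_days=followup,
    )


def random_record(rng, patient_id="p1", max_day=130, n_max=8):
    """Random episode set, possibly overlapping, for oracle comparisons."""
    n = int(rng.integers(0, n_max + 1))
    episodes = []
    for _ in range(n):
        start = int(rng.integers(0, max_day))
        end = start + int(rng.integers(0, 40))
        level = LEVELS[int(rng.integers(0, len(LEVELS)))]
        episodes.append((level, start, end))
    followup = max([e for _, _, e in episodes], default=0) + 1
    return make_record(episodes, patient_id=patient_id, followup=max(100, followup))


def brute_force_auc(record, weights, window, overlap_mode):
    """Day-by-day oracle: per-day per-level summation / per-day maximum."""
    total = 0.0
    for day in range(window.first_day, window.last_day + 1):
        active = {
            ep.level for ep in record.episodes if ep.start_day <= day <= ep.end_day
        }
        if overlap_mode == "additive":
            total += sum(weights[lvl] for lvl in active)
        else:
            total += weights[max(active)] if active else 0.0
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def weights():
    return WeightScheme()


@pytest.fixture
def window():
    return ScoreWindow(0, 99)
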