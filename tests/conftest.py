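import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tectalmsi.recordings import CellDataset, StimulusCondition, TrialRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_trial(cell_id, idx, cond, n_spikes, t0=10.0, gap=5.0):
    """A trial whose spike count is exactly n_spikes, spikes well inside
    the default counting window."""
    times = t0 + gap * np.arange(n_spikes) if n_spikes else np.empty(0)
    return TrialRecord(cell_id, idx, cond, spike_times_ms=times)


def make_cell(
    single_v_counts,
    single_hb_counts,
    paired_counts_by_isi,
    cell_id="c1",
    stage="st44_46",
    drug="none",
    pair=("V", "HB"),
):
    """Hand-built CellDataset with exact single and paired spike counts.

    paired_counts_by_isi: {isi_ms: [counts]}, crossmodal by default.
    """
    trials = []
    idx = 0
    for n in single_v_counts:
        trials.append(make_trial(cell_id, idx, StimulusCondition("single", "V"), n))
        idx += 1
    for n in single_hb_counts:
        trials.append(make_trial(cell_id, idx, StimulusCondition("single", "HB"), n))
        idx += 1
    for isi, counts in paired_counts_by_isi.items():
        cond = StimulusCondition("paired", pair[0], pair[1], float(isi))
        for n in counts:
            trials.append(make_trial(cell_id, idx, cond, n))
            idx += 1
    return CellDataset(cell_id, stage, drug, trials)


@pytest.fixture(scope="session")
def young_population():
    from tectalmsi.synthetic import generate_population, preset

    return generate_population(preset("st44_46", n_cells=12, seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
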