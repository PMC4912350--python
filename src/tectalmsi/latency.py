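"""First-spike onset statistics and paired-versus-single comparisons.

Paired crossmodal stimulation speeds up spiking onset relative to single
stimulation.  Per condition the module pools each trial's first
post-stimulus spike time, summarises the pooled times by Tukey
median-of-halves quartiles, and compares per-cell median onsets between
conditions with a paired (within-cell) or unpaired (between-group)
t-test.  Paired-trial onsets are referenced to the second stimulus by
default, so curves at different ISIs are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recordings import CellDataset, TrialRecord

__all__ = [
    "OnsetSummary",
    "first_spike_times",
    "onset_summary",
    "compare_onsets",
    "LatencyAnalysis",
    "LatencyResults",
]


@dataclass
class OnsetSummary:
    """Quartiles of pooled first-spike times for one condition."""

    condition: str
    q25: float
    q50: float
    q75: float
    n_trials_with_spikes: int


def first_spike_times(
    trials: list[TrialRecord], reference: str = "first_stimulus"
) -> np.ndarray:
    """Per trial, the earliest spike after the chosen reference stimulus
    (ms); spike-free trials are excluded.

    ``reference="second_stimulus"`` subtracts the ISI, so paired onsets are
    measured from the stimulus that completes the pair; for single trials
    the two references coincide.
    """
    if reference not in ("first_stimulus", "second_stimulus"):
        raise ValueError(f"unknown reference {reference!r}")
    out = []
    for t in trials:
        if t.spike_times_ms is None or t.spike_times_ms.size == 0:
            continue
        offset = 0.0
        if reference == "second_stimulus" and t.condition.kind == "paired":
            offset = t.condition.isi_ms
        after = t.spike_times_ms[t.spike_times_ms >= offset]
        if after.size:
            out.append(after[0] - offset)
    return np.asarray(out, dtype=float)


def _tukey_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median-of-halves quartiles, the median excluded from both halves
    when n is odd.  Conventions differ across software; this one is fixed
    and documented so summaries are comparable across runs."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("no spike times to summarise")
    if n == 1:
        return float(v[0]), float(v[0]), float(v[0])
    half = n // 2
    return float(np.median(v[:half])), float(np.median(v)), float(np.median(v[-half:]))


def onset_summary(times: np.ndarray, condition: str = "") -> OnsetSummary:
    """Quartile summary of pooled first-spike times."""
    q25, q50, q75 = _tukey_quartiles(np.asarray(times, dtype=float))
    return OnsetSummary(condition, q25, q50, q75, int(np.asarray(times).size))


def compare_onsets(
    onsets_a, onsets_b, design: str = "paired"
) -> tuple[float, float]:
    """t-test between two vectors of per-cell median onsets.

    ``design="paired"`` matches elements cell-by-cell (within-cell paired
    vs single comparison); ``"unpaired"`` compares independent groups.
    Identical paired vectors (zero variance of differences) return (0, 1)
    rather than an undefined statistic.  Fewer than 3 observations per arm
    is allowed but flagged by a warning in the calling analysis.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    if design == "paired":
        if a.size != b.size:
            raise ValueError("paired design requires equal-length vectors")
        if a.size < 2:
            raise ValueError("need >= 2 cells for a paired comparison")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            return (0.0, 1.0) if np.allclose(d, 0.0) else (np.inf * np.sign(d.mean()), 0.0)
        t, p = stats.ttest_rel(a, b)
    elif design == "unpaired":
        if a.size < 2 or b.size < 2:
            raise ValueError("need >= 2 observations per group")
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            same = np.allclose(a.mean(), b.mean())
            return (0.0, 1.0) if same else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
        t, p = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    return float(t), float(p)


class LatencyAnalysis:
    """Model object: onset statistics for a population of cells.

    Computes, per cell, the median single-trial onset (both modalities
    pooled) and the median paired-trial onset referenced to the second
    stimulus, plus pooled per-condition quartile summaries.
    """

    def __init__(self, datasets: list[CellDataset], paired_reference: str = "second_stimulus"):
        self.datasets = list(datasets)
        self.paired_reference = paired_reference

    def fit(self) -> "LatencyResults":
        rows = []
        pooled_single: list[float] = []
        pooled_paired_by_isi: dict[float, list[float]] = {}
        for cell in self.datasets:
            singles = [t for t in cell.trials if t.condition.kind == "single"]
            paired = cell.paired_trials(crossmodal=True)
            st_single = first_spike_times(singles, "first_stimulus")
            st_paired = first_spike_times(paired, self.paired_reference)
            if st_single.size == 0 or st_paired.size == 0:
                continue
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "stage_group": cell.stage_group,
                    "drug": cell.drug,
                    "median_single_ms": float(np.median(st_single)),
                    "median_paired_ms": float(np.median(st_paired)),
                    "n_single": int(st_single.size),
                    "n_paired": int(st_paired.size),
                }
            )
            pooled_single.extend(st_single)
            for t in paired:
                fs = first_spike_times([t], self.paired_reference)
                if fs.size:
                    pooled_paired_by_isi.setdefault(t.condition.isi_ms, []).append(fs[0])
        per_cell = pd.DataFrame(rows)
        summaries = []
        if pooled_single:
            summaries.append(onset_summary(np.asarray(pooled_single), "single"))
        for isi, vals in sorted(pooled_paired_by_isi.items()):
            summaries.append(onset_summary(np.asarray(vals), f"paired_isi{isi:g}"))
        return LatencyResults(self, per_cell, summaries)


class LatencyResults:
    """Fitted latency analysis: per-cell medians, pooled quartile
    summaries, and the paired-vs-single comparison."""

    def __init__(self, model, per_cell: pd.DataFrame, summaries: list[OnsetSummary]):
        self.model = model
        self.per_cell = per_cell
        self.summaries = summaries

    def paired_vs_single(self) -> tuple[float, float]:
        """Within-cell paired t-test of median paired vs single onsets;
        negative t means paired responses are faster."""
        return compare_onsets(
            self.per_cell["median_paired_ms"],
            self.per_cell["median_single_ms"],
            design="paired",
        )

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": s.condition,
                    "q25_ms": s.q25,
                    "q50_ms": s.q50,
                    "q75_ms": s.q75,
                    "n": s.n_trials_with_spikes,
                }
                for s in self.summaries
            ]
        )

    def summary(self) -> str:
        t, p = self.paired_vs_single()
        lines = ["First-spike latency analysis", "=" * 40]
        lines.append(f"{len(self.per_cell)} cells with spikes in both conditions")
        lines.append(
            f"paired vs single median onset: t = {t:.3f}, p = {p:.4g} "
            f"({'paired faster' if t < 0 else 'paired not faster'})"
        )
        return "\n".join(lines)
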