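"""Data model, file I/O, spike detection, and response-window counting.

The unit of analysis is a :class:`CellDataset`: every stimulus presentation
(trial) recorded from one tectal neuron under one drug condition.  A trial
carries either a list of spike times (loose cell-attached recording) or a
continuous voltage-clamp current trace (see :mod:`tectalmsi.conductance`),
or both.

Conventions
-----------
* Spike times are milliseconds relative to the FIRST stimulus of the trial,
  0-based, strictly increasing.
* Counting windows are half-open intervals ``[a, b)``.
* Interstimulus interval (ISI) is stored unsigned on the condition; the
  signed convention (positive = visual first, negative = hindbrain first)
  is derived where order matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusCondition",
    "TrialRecord",
    "CellDataset",
    "SpikeDetectionParams",
    "detect_spikes",
    "count_response_spikes",
    "load_dataset",
    "save_dataset",
    "validate_dataset",
]

MODALITIES = ("V", "HB")

#: Column order of the event-data CSV schema (one row per trial).
EVENT_COLUMNS = [
    "cell_id",
    "stage_group",
    "drug",
    "kind",
    "modality_first",
    "modality_second",
    "isi_ms",
    "trial_index",
    "spike_times_ms",
]


class DatasetFormatError(ValueError):
    """Raised when an event-data file violates the tabular schema."""


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus arrangement: a single pulse or a pair separated by an ISI.

    Parameters
    ----------
    kind : {"single", "paired"}
    modality_first : {"V", "HB"}
        Pathway stimulated first (optic chiasm = visual, hindbrain =
        mechanosensory).
    modality_second : {"V", "HB", "none"}
        Second pathway for paired trials; ``"none"`` for singles.
    isi_ms : float
        Interstimulus interval in ms; 0 for single trials.
    """

    kind: str
    modality_first: str
    modality_second: str = "none"
    isi_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("single", "paired"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.modality_first not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality_first!r}")
        if self.kind == "single":
            if self.modality_second != "none" or self.isi_ms != 0:
                raise ValueError(
                    "single trials require modality_second='none' and isi_ms=0"
                )
        else:
            if self.modality_second not in MODALITIES:
                raise ValueError("paired trials require a second modality")
            if self.isi_ms < 0:
                raise ValueError("isi_ms must be non-negative")

    @property
    def crossmodal(self) -> bool:
        return self.kind == "paired" and self.modality_first != self.modality_second

    @property
    def order_label(self) -> str:
        """Compact condition label: "V", "HB", "VH", "HV", "VV" or "HH"."""
        if self.kind == "single":
            return self.modality_first
        short = {"V": "V", "HB": "H"}
        return short[self.modality_first] + short[self.modality_second]

    @property
    def signed_isi_ms(self) -> float:
        """Signed ISI: positive when V leads, negative when HB leads.

        Same-modality pairs are reported positive (order carries no
        information there).
        """
        if self.kind == "single":
            return 0.0
        if self.modality_first == "HB" and self.modality_second == "V":
            return -self.isi_ms
        return self.isi_ms


@dataclass
class TrialRecord:
    """One stimulus presentation for one cell.

    Exactly one of ``spike_times_ms`` / ``trace`` is needed for a given
    analysis path; both may be present.
    """

    cell_id: str
    trial_index: int
    condition: StimulusCondition
    spike_times_ms: np.ndarray | None = None
    trace: object | None = None  # CurrentTrace or (CurrentTrace, CurrentTrace)

    def __post_init__(self) -> None:
        if self.spike_times_ms is not None:
            st = np.asarray(self.spike_times_ms, dtype=float)
            if st.ndim != 1:
                raise ValueError("spike_times_ms must be one-dimensional")
            if st.size and (np.any(st < 0) or np.any(np.diff(st) <= 0)):
                raise ValueError("spike times must be >= 0 and strictly increasing")
            self.spike_times_ms = st


@dataclass
class CellDataset:
    """All trials for one cell under one drug condition."""

    cell_id: str
    stage_group: str  # "st44_46" | "st48_49"
    drug: str = "none"  # "none" | "picrotoxin"
    trials: list[TrialRecord] = field(default_factory=list)

    def single_trials(self, modality: str) -> list[TrialRecord]:
        return [
            t
            for t in self.trials
            if t.condition.kind == "single" and t.condition.modality_first == modality
        ]

    def paired_trials(
        self, crossmodal: bool | None = None, modality: str | None = None
    ) -> list[TrialRecord]:
        """Paired trials, optionally filtered to crossmodal or to a unimodal
        pair of the given modality."""
        out = [t for t in self.trials if t.condition.kind == "paired"]
        if crossmodal is not None:
            out = [t for t in out if t.condition.crossmodal == crossmodal]
        if modality is not None:
            out = [
                t
                for t in out
                if t.condition.modality_first == modality
                and t.condition.modality_second == modality
            ]
        return out

    @property
    def n_single_trials_per_modality(self) -> dict[str, int]:
        return {m: len(self.single_trials(m)) for m in MODALITIES}


@dataclass(frozen=True)
class SpikeDetectionParams:
    """Amplitude-threshold event detection and response-window parameters.

    ``window_ms`` is the post-stimulus spike-counting window; for paired
    trials counting spans ``[0, isi + window_ms)`` so the combined response
    covers the whole pair.  ``polarity="absolute"`` detects crossings of
    ``|x| >= threshold`` (cell-attached spikes can be biphasic).
    """

    threshold: float = 5.0
    polarity: str = "absolute"  # "positive" | "negative" | "absolute"
    refractory_ms: float = 2.0
    window_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative", "absolute"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.refractory_ms <= 0 or self.window_ms <= 0:
            raise ValueError("refractory_ms and window_ms must be positive")
        if self.polarity != "absolute" and self.threshold == 0:
            raise ValueError("threshold must be non-zero for signed polarity")


def detect_spikes(
    samples: Sequence[float],
    params: SpikeDetectionParams,
    sampling_rate_hz: float,
) -> np.ndarray:
    """Detect threshold-crossing onsets in a uniformly sampled trace.

    Returns onset times in ms (strictly increasing).  Crossings closer than
    ``params.refractory_ms`` to the previous accepted onset are collapsed
    into that earlier event.
    """
    if sampling_rate_hz <= 0:
        raise DatasetFormatError("sampling_rate_hz must be positive")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        return np.empty(0)
    if params.polarity == "positive":
        above = x >= params.threshold
    elif params.polarity == "negative":
        above = x <= params.threshold
    else:
        above = np.abs(x) >= abs(params.threshold)
    # onset = first suprathreshold sample of each excursion
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if onsets.size == 0:
        return np.empty(0)
    dt_ms = 1000.0 / sampling_rate_hz
    times = onsets * dt_ms
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= params.refractory_ms:
            kept.append(t)
    return np.asarray(kept)


def count_response_spikes(trial: TrialRecord, params: SpikeDetectionParams) -> int:
    """Spikes in the response window: ``[0, window)`` for single trials,
    ``[0, isi + window)`` for paired trials."""
    if trial.spike_times_ms is None:
        raise ValueError(f"trial {trial.cell_id}/{trial.trial_index} has no spikes")
    end = params.window_ms
    if trial.condition.kind == "paired":
        end += trial.condition.isi_ms
    st = trial.spike_times_ms
    return int(np.count_nonzero((st >= 0) & (st < end)))


# ---------------------------------------------------------------------------
# Event-data CSV I/O


def _format_spikes(st: np.ndarray | None) -> str:
    if st is None or len(st) == 0:
        return ""
    return ";".join(repr(float(v)) for v in st)


def _parse_spikes(s: str) -> np.ndarray:
    if s is None or s == "" or (isinstance(s, float) and np.isnan(s)):
        return np.empty(0)
    return np.asarray([float(v) for v in str(s).split(";")], dtype=float)


def save_dataset(
    datasets: Iterable[CellDataset], path, metadata: dict | None = None
) -> None:
    """Write event data to CSV (one row per trial, deterministic column
    order) with an optional JSON metadata sidecar at ``<path>.meta.json``."""
    rows = []
    for ds in datasets:
        for t in ds.trials:
            c = t.condition
            rows.append(
                {
                    "cell_id": ds.cell_id,
                    "stage_group": ds.stage_group,
                    "drug": ds.drug,
                    "kind": c.kind,
                    "modality_first": c.modality_first,
                    "modality_second": c.modality_second,
                    "isi_ms": repr(float(c.isi_ms)),
                    "trial_index": t.trial_index,
                    "spike_times_ms": _format_spikes(t.spike_times_ms),
                }
            )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)
    if metadata is not None:
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)


def load_dataset(path) -> list[CellDataset]:
    """Read event data written by :func:`save_dataset`.

    Round-trips bit-exactly: spike times are serialised with ``repr`` and
    parsed back with ``float``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing column(s): {', '.join(missing)}")
    datasets: dict[tuple, CellDataset] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based, after header
        try:
            cond = StimulusCondition(
                kind=row.kind,
                modality_first=row.modality_first,
                modality_second=row.modality_second,
                isi_ms=float(row.isi_ms),
            )
            trial = TrialRecord(
                cell_id=row.cell_id,
                trial_index=int(row.trial_index),
                condition=cond,
                spike_times_ms=_parse_spikes(row.spike_times_ms),
            )
        except (ValueError, TypeError) as exc:
            raise DatasetFormatError(f"row {rownum}: {exc}") from exc
        key = (row.cell_id, row.drug)
        if key not in datasets:
            datasets[key] = CellDataset(
                cell_id=row.cell_id, stage_group=row.stage_group, drug=row.drug
            )
        datasets[key].trials.append(trial)
    return list(datasets.values())


def validate_dataset(dataset: CellDataset, require_spiking: bool = True) -> list[str]:
    """Check the per-cell invariants; returns a (possibly empty) list of
    human-readable violations.

    A cell enters the crossmodal analysis only if it responds to both optic
    chiasm and hindbrain stimulation: at least one single trial per modality
    and, when ``require_spiking``, a non-zero mean single-trial spike count
    for each.
    """
    out: list[str] = []
    if dataset.stage_group not in ("st44_46", "st48_49"):
        out.append(f"unknown stage_group {dataset.stage_group!r}")
    if dataset.drug not in ("none", "picrotoxin"):
        out.append(f"unknown drug {dataset.drug!r}")
    for m in MODALITIES:
        singles = dataset.single_trials(m)
        if not singles:
            out.append(f"no single-modality trials for {m}")
            continue
        if require_spiking:
            counted = [t for t in singles if t.spike_times_ms is not None]
            if counted and all(len(t.spike_times_ms) == 0 for t in counted):
                out.append(f"no spikes in any single {m} trial")
    for t in dataset.trials:
        st = t.spike_times_ms
        if st is None and t.trace is None:
            out.append(f"trial {t.trial_index}: neither spikes nor trace")
        if st is not None and st.size > 1 and np.any(np.diff(st) <= 0):
            out.append(f"trial {t.trial_index}: spike times not strictly increasing")
    return out


def with_detected_spikes(
    dataset: CellDataset, params: SpikeDetectionParams
) -> CellDataset:
    """Return a copy of the dataset in which every trial that carries a trace
    but no spike times gets spike times from :func:`detect_spikes`."""
    new_trials = []
    for t in dataset.trials:
        if t.spike_times_ms is None and t.trace is not None:
            tr = t.trace[0] if isinstance(t.trace, tuple) else t.trace
            st = detect_spikes(tr.samples, params, tr.sampling_rate_hz)
            t = replace(t, spike_times_ms=st)
        new_trials.append(t)
    return replace(dataset, trials=new_trials)
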