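"""HDF5 container for continuous voltage-clamp traces.

Layout: one group per cell, one group per trial under it, and one dataset
per holding-potential sweep:

    /<cell_id>/trial<idx>/hold<n>   (float64 samples, pA)

with attributes ``sampling_rate_hz``, ``holding_potential_mv``, ``units``
and ``stimulus_times_ms`` on each sweep, and the trial's stimulus
condition on the trial group.  Event-level (spike time) data live in the
CSV schema of :mod:`tectalmsi.recordings`; this container only carries
what cannot reasonably go in a text table.
"""

from __future__ import annotations

import h5py
import numpy as np

from .conductance import CurrentTrace
from .recordings import CellDataset, StimulusCondition, TrialRecord

__all__ = ["save_traces", "load_traces"]


def save_traces(datasets: list[CellDataset], path) -> None:
    """Write every trace-bearing trial of the datasets to an HDF5 file."""
    with h5py.File(path, "w") as f:
        for ds in datasets:
            gcell = f.require_group(ds.cell_id)
            gcell.attrs["stage_group"] = ds.stage_group
            gcell.attrs["drug"] = ds.drug
            for t in ds.trials:
                if t.trace is None:
                    continue
                gtrial = gcell.create_group(f"trial{t.trial_index}")
                c = t.condition
                gtrial.attrs.update(
                    {
                        "kind": c.kind,
                        "modality_first": c.modality_first,
                        "modality_second": c.modality_second,
                        "isi_ms": float(c.isi_ms),
                    }
                )
                sweeps = t.trace if isinstance(t.trace, tuple) else (t.trace,)
                for sweep in sweeps:
                    d = gtrial.create_dataset(
                        f"hold{sweep.holding_potential_mv:g}", data=sweep.samples
                    )
                    d.attrs["sampling_rate_hz"] = sweep.sampling_rate_hz
                    d.attrs["holding_potential_mv"] = sweep.holding_potential_mv
                    d.attrs["units"] = "pA"
                    d.attrs["stimulus_times_ms"] = np.asarray(
                        sweep.stimulus_times_ms, dtype=float
                    )


def load_traces(path) -> list[CellDataset]:
    """Read an HDF5 trace container written by :func:`save_traces`.

    Trials with two sweeps get ``trace = (sweep, sweep)`` ordered by
    holding potential ascending — i.e. (−45 mV, +5 mV), the order the
    conductance analysis expects."""
    out = []
    with h5py.File(path, "r") as f:
        for cell_id in sorted(f):
            gcell = f[cell_id]
            ds = CellDataset(
                cell_id=cell_id,
                stage_group=gcell.attrs["stage_group"],
                drug=gcell.attrs["drug"],
            )
            trial_names = sorted(gcell, key=lambda s: int(s.removeprefix("trial")))
            for name in trial_names:
                gtrial = gcell[name]
                cond = StimulusCondition(
                    kind=gtrial.attrs["kind"],
                    modality_first=gtrial.attrs["modality_first"],
                    modality_second=gtrial.attrs["modality_second"],
                    isi_ms=float(gtrial.attrs["isi_ms"]),
                )
                sweeps = []
                for dname in sorted(
                    gtrial, key=lambda s: float(s.removeprefix("hold"))
                ):
                    d = gtrial[dname]
                    sweeps.append(
                        CurrentTrace(
                            samples=d[()],
                            sampling_rate_hz=float(d.attrs["sampling_rate_hz"]),
                            holding_potential_mv=float(
                                d.attrs["holding_potential_mv"]
                            ),
                            stimulus_times_ms=list(d.attrs["stimulus_times_ms"]),
                        )
                    )
                trace = tuple(sweeps) if len(sweeps) > 1 else sweeps[0]
                ds.trials.append(
                    TrialRecord(
                        cell_id=cell_id,
                        trial_index=int(name.removeprefix("trial")),
                        condition=cond,
                        trace=trace,
                    )
                )
            out.append(ds)
    return out
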