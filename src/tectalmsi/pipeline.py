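"""End-to-end orchestration: simulate or load → count → tuning →
linearity → latency → (optionally) conductance → report.

:func:`run` executes every stage on a population described by a
:class:`PipelineConfig`, writes each stage's table as CSV into the output
directory, and distils the group-level statistics into one
machine-readable ``summary.json``.  Every stochastic stage receives a
substream derived from the master seed, so a fixed config yields
byte-identical outputs across runs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

from .latency import LatencyAnalysis
from .linearity import LinearityAnalysis
from .recordings import SpikeDetectionParams, load_dataset
from .synthetic import generate_population, preset
from .tuning import MSITuning

__all__ = ["PipelineConfig", "CohortSpec", "run"]

log = logging.getLogger("tectalmsi")


@dataclass(frozen=True)
class CohortSpec:
    """One simulated study condition: a generator preset plus overrides."""

    preset: str  # "st44_46" | "st48_49" | "picrotoxin"
    n_cells: int = 30
    overrides: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Everything :func:`run` needs.

    Exactly one input source: ``events_csv`` (a recordings CSV) or
    ``cohorts`` (conditions to simulate).  ``seed`` is the master seed;
    generator cohorts get ``seed + cohort index``, the linearity resampler
    gets ``seed`` directly.
    """

    events_csv: str | None = None
    cohorts: list[CohortSpec] = field(default_factory=list)
    traces_h5: str | None = None
    simulate_conductance: bool = False
    conductance_n_cells: int = 12
    detection: SpikeDetectionParams = field(default_factory=SpikeDetectionParams)
    pool_order: bool = True
    reps: int = 10_000
    k: int = 4
    z_crit: float = 1.97
    out_dir: str = "tectalmsi_out"
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if (self.events_csv is None) == (not self.cohorts):
            raise ValueError("provide exactly one of events_csv or cohorts")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written
    to ``<out_dir>/summary.json``)."""
    t_start = time.perf_counter()
    if config.verbose:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input ------------------------------------------------------------
    if config.events_csv is not None:
        datasets = load_dataset(config.events_csv)
        log.info("loaded %d cells from %s", len(datasets), config.events_csv)
    else:
        datasets = []
        for i, spec in enumerate(config.cohorts):
            cfg = preset(spec.preset, n_cells=spec.n_cells, seed=config.seed + i)
            if spec.overrides:
                cfg = replace(cfg, **spec.overrides)
            cells = generate_population(cfg)
            # cohort index disambiguates cell ids across cohorts
            for c in cells:
                c.cell_id = f"{spec.preset}_{c.cell_id}"
                for t in c.trials:
                    t.cell_id = c.cell_id
            datasets.extend(cells)
            log.info("simulated cohort %s: %d cells", spec.preset, len(cells))
    if not datasets:
        summary = {"n_cells": 0, "stages": {}}
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
        return summary

    summary: dict = {"n_cells": len(datasets), "stages": {}}

    # --- MSI tuning -------------------------------------------------------
    t0 = time.perf_counter()
    tuning_res = MSITuning(
        datasets, "MSIn", pool_order=config.pool_order, params=config.detection
    ).fit()
    tuning_res.curve_table().to_csv(out / "tuning_curves.csv", index=False)
    tuning_res.peak_table().to_csv(out / "tuning_peaks.csv", index=False)
    for g, al in tuning_res.aligned.items():
        al.as_frame().to_csv(out / f"aligned_{g}.csv", index=False)
    if tuning_res.excluded:
        log.warning("%d cells excluded (zero single response)", len(tuning_res.excluded))
    tuning_summary = {
        "groups": tuning_res.group_stats["groups"],
        "comparisons": tuning_res.group_stats["comparisons"],
        "n_excluded": len(tuning_res.excluded),
        "curve_f_tests": {},
    }
    names = sorted({g for g in tuning_res.aligned})
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            F, df1, df2, p = tuning_res.compare_groups(a, b)
            tuning_summary["curve_f_tests"][f"{a}|{b}"] = {
                "F": F, "df1": df1, "df2": df2, "p": p
            }
    summary["stages"]["msi_tuning"] = _jsonable(tuning_summary)
    log.info("msi stage: %.2f s", time.perf_counter() - t0)

    # --- linearity --------------------------------------------------------
    t0 = time.perf_counter()
    lin_res = LinearityAnalysis(
        datasets,
        "crossmodal",
        params=config.detection,
        k=config.k,
        reps=config.reps,
        z_crit=config.z_crit,
        seed=config.seed,
    ).fit()
    lin_res.result_table().to_csv(out / "linearity.csv", index=False)
    lin_res.classification_proportions().to_csv(
        out / "linearity_proportions.csv", index=False
    )
    lin_res.z_ecdf_table().to_csv(out / "z_ecdf.csv", index=False)
    lin_summary = {
        "proportions": lin_res.classification_proportions().to_dict("records"),
        "ks_tests": {},
    }
    lnames = sorted(lin_res.groups)
    for i, a in enumerate(lnames):
        for b in lnames[i + 1 :]:
            D, p = lin_res.compare_groups(a, b)
            lin_summary["ks_tests"][f"{a}|{b}"] = {"D": D, "p": p}
    summary["stages"]["linearity"] = _jsonable(lin_summary)
    log.info("linearity stage: %.2f s", time.perf_counter() - t0)

    # --- latency ----------------------------------------------------------
    t0 = time.perf_counter()
    lat_res = LatencyAnalysis(datasets).fit()
    lat_res.per_cell.to_csv(out / "latency_per_cell.csv", index=False)
    lat_res.summary_table().to_csv(out / "latency_quartiles.csv", index=False)
    t_stat, p = lat_res.paired_vs_single()
    summary["stages"]["latency"] = {
        "paired_vs_single_t": float(t_stat),
        "paired_vs_single_p": float(p),
        "n_cells": int(len(lat_res.per_cell)),
    }
    log.info("latency stage: %.2f s", time.perf_counter() - t0)

    # --- conductance (whole-cell traces: loaded or simulated) -------------
    trace_cells = None
    if config.traces_h5 is not None:
        from .traceio import load_traces

        trace_cells = load_traces(config.traces_h5)
    elif config.simulate_conductance:
        trace_cells = _simulate_conductance_cohorts(config)
    if trace_cells is not None:
        t0 = time.perf_counter()
        from .conductance import ConductanceAnalysis

        cres = ConductanceAnalysis(trace_cells).fit()
        cres.tuning_table().to_csv(out / "conductance_msin.csv", index=False)
        cres.per_cell.to_csv(out / "conductance_scatter.csv", index=False)
        for comp, table in cres.anova_tables.items():
            table.to_csv(out / f"conductance_anova_{comp}.csv")
        summary["stages"]["conductance"] = _jsonable(
            {
                "stage_anova_p": {
                    c: cres.stage_effect_p(c) for c in ("excitatory", "inhibitory")
                },
                "per_stage_correlation": cres.scatter_stats["per_stage"],
                "slope_test": cres.scatter_stats["slope_test"],
            }
        )
        log.info("conductance stage: %.2f s", time.perf_counter() - t0)

    summary["elapsed_s"] = round(time.perf_counter() - t_start, 3)
    text = json.dumps(_strip_volatile(summary), sort_keys=True, indent=2)
    (out / "summary.json").write_text(text)
    return summary


def _simulate_conductance_cohorts(config: PipelineConfig):
    """One voltage-clamp cohort per stage: a shared tuning-shape law, the
    developmental contrast carried by the excitatory gain mean."""
    from .synthetic import (
        ConductanceParams,
        ProfileDistribution,
        generate_conductance_population,
    )

    exc_gain = {"st44_46": 1.6, "st48_49": 0.5}
    shared = ProfileDistribution(
        width_mean_ms=80.0, width_sd_ms=15.0,
        preferred_isi_choices=(50.0, 100.0, 200.0),
    )
    cells = []
    for j, stage in enumerate(("st44_46", "st48_49")):
        cfg = preset(
            stage if stage == "st44_46" else "st48_49",
            n_cells=config.conductance_n_cells,
            seed=config.seed + 100 + j,
            isi_grid_ms=(50.0, 100.0, 200.0, 500.0),
            n_paired_trials=2,
            profile_distribution=shared,
            conductance_params=ConductanceParams(sampling_rate_hz=2000.0),
        )
        cohort = generate_conductance_population(
            cfg, exc_gain_mean=exc_gain[stage], inh_gain_mean=1.0
        )
        for c in cohort:
            c.cell_id = f"{stage}_vc_{c.cell_id}"
        cells.extend(cohort)
    return cells


def _strip_volatile(summary: dict) -> dict:
    """Remove wall-clock fields so summary.json is identical across runs
    of the same config+seed."""
    out = dict(summary)
    out.pop("elapsed_s", None)
    return out
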