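"""Excitatory/inhibitory conductance decomposition and Fig-7-style statistics.

Voltage-clamp currents recorded at the reversal potential of one synaptic
component isolate the other: holding at the Cl− reversal (−45 mV) zeroes
GABA_A currents and leaves glutamatergic (excitatory) current; holding at
the glutamate reversal (+5 mV) leaves GABA_A (inhibitory) current.  The
isolated current converts to a conductance through

    g(t) = I(t) / (V_hold − E_rev)

with I in pA and potentials in mV, so g comes out in nS.  A pre-stimulus
baseline is subtracted from I before division, which makes the conversion
exactly linear in I.

The module then applies the spike-count MSI index to conductance response
magnitudes (peak by default, integral optionally) and runs the two group
comparisons: a two-way ANOVA (stage × ISI) per component, and the per-cell
excitatory-vs-inhibitory scatter statistics (Pearson r per stage and an
extra-sum-of-squares test for a difference in regression slopes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "E_REV_EXC_MV",
    "E_REV_INH_MV",
    "CurrentTrace",
    "ConductancePair",
    "ConductanceMSI",
    "current_to_conductance",
    "response_magnitude",
    "conductance_msin",
    "ei_stage_comparison",
    "ei_scatter_stats",
    "ConductanceAnalysis",
]

#: Reversal potential of AMPA/NMDA (excitatory) currents, mV.
E_REV_EXC_MV = 5.0
#: Reversal potential of GABA_A (inhibitory) currents, mV.
E_REV_INH_MV = -45.0


@dataclass
class CurrentTrace:
    """A uniformly sampled voltage-clamp current record.

    samples are pA; holding_potential is mV; stimulus_times_ms are relative
    to the start of the sweep.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    holding_potential_mv: float
    stimulus_times_ms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms


@dataclass
class ConductancePair:
    """Excitatory and inhibitory conductance series (nS) for one trial."""

    g_exc: np.ndarray
    g_inh: np.ndarray
    sampling_rate_hz: float
    stimulus_times_ms: list = field(default_factory=list)
    e_rev_exc_mv: float = E_REV_EXC_MV
    e_rev_inh_mv: float = E_REV_INH_MV
    # holding potential used to isolate each component equals the reversal
    # potential of the OTHER component
    hold_for_exc_mv: float = E_REV_INH_MV
    hold_for_inh_mv: float = E_REV_EXC_MV


@dataclass
class ConductanceMSI:
    """Per-cell conductance-level MSI tuning for one synaptic component."""

    cell_id: str
    component: str  # "excitatory" | "inhibitory"
    stage_group: str
    values: dict[float, float]  # isi_ms -> MSIn
    sm: float  # larger single-modality magnitude (denominator)

    @property
    def max_msin(self) -> float:
        return max(self.values.values())

    @property
    def preferred_isi_ms(self) -> float:
        best = self.max_msin
        return min(isi for isi, v in self.values.items() if v == best)


def current_to_conductance(
    trace: CurrentTrace, e_rev_mv: float, baseline_ms: float = 50.0
) -> np.ndarray:
    """Convert an isolated synaptic current into a conductance series (nS).

    The mean current over the ``baseline_ms`` immediately preceding the
    first stimulus (or the start of the sweep when no stimulus time is
    recorded) is subtracted before dividing by the driving force.
    """
    drive = trace.holding_potential_mv - e_rev_mv
    if abs(drive) <= 5.0:
        raise ValueError(
            f"degenerate driving force: V_hold={trace.holding_potential_mv} mV, "
            f"E_rev={e_rev_mv} mV"
        )
    i = trace.samples
    t0 = min(trace.stimulus_times_ms) if trace.stimulus_times_ms else 0.0
    lo = max(0, int(round((t0 - baseline_ms) / trace.dt_ms)))
    hi = int(round(t0 / trace.dt_ms))
    baseline = i[lo:hi].mean() if hi > lo else 0.0
    return (i - baseline) / drive


def decompose_trial(
    trace_at_einh: CurrentTrace,
    trace_at_eexc: CurrentTrace,
    baseline_ms: float = 50.0,
) -> ConductancePair:
    """Build the E/I conductance pair from the two holding-potential sweeps.

    ``trace_at_einh`` was recorded at the inhibitory reversal (isolates
    excitation); ``trace_at_eexc`` at the excitatory reversal (isolates
    inhibition).
    """
    g_exc = current_to_conductance(trace_at_einh, E_REV_EXC_MV, baseline_ms)
    g_inh = current_to_conductance(trace_at_eexc, E_REV_INH_MV, baseline_ms)
    return ConductancePair(
        g_exc=g_exc,
        g_inh=g_inh,
        sampling_rate_hz=trace_at_einh.sampling_rate_hz,
        stimulus_times_ms=list(trace_at_einh.stimulus_times_ms),
    )


def response_magnitude(
    g: np.ndarray,
    sampling_rate_hz: float,
    window_ms: tuple[float, float],
    mode: str = "peak",
) -> float:
    """Response size of a conductance transient within ``[start, stop)`` ms.

    ``mode="peak"`` returns the maximum (nS); ``mode="integral"`` the
    rectangle-rule integral (nS·ms).  Magnitudes are clamped at 0 — baseline
    noise can drive the windowed maximum slightly negative, which would
    break the MSI index's lower bound — with a warning.
    """
    dt_ms = 1000.0 / sampling_rate_hz
    lo = max(0, int(round(window_ms[0] / dt_ms)))
    hi = min(g.size, int(round(window_ms[1] / dt_ms)))
    seg = g[lo:hi]
    if seg.size == 0:
        return 0.0
    if mode == "peak":
        out = float(seg.max())
    elif mode == "integral":
        out = float(seg.sum() * dt_ms)
    else:
        raise ValueError(f"unknown magnitude mode {mode!r}")
    if out < 0:
        warnings.warn("negative response magnitude clamped to 0", stacklevel=2)
        out = 0.0
    return out


def conductance_msin(
    cell,
    component: str,
    window_ms: float = 500.0,
    mode: str = "peak",
    baseline_ms: float = 50.0,
) -> ConductanceMSI:
    """Conductance-level MSI tuning curve for one cell and one component.

    SM is the larger of the two single-modality magnitudes; CM the mean
    paired magnitude at each ISI, measured over ``[0, isi + window)`` from
    the first stimulus.  MSIn = (CM − SM)/SM, as for spike counts.
    """
    if component not in ("excitatory", "inhibitory"):
        raise ValueError(f"unknown component {component!r}")

    def magnitude(trial) -> float:
        tr_inh_hold, tr_exc_hold = trial.trace  # (at E_rev_inh, at E_rev_exc)
        pair = decompose_trial(tr_inh_hold, tr_exc_hold, baseline_ms)
        g = pair.g_exc if component == "excitatory" else pair.g_inh
        # window is relative to the first stimulus within the sweep
        t0 = min(pair.stimulus_times_ms) if pair.stimulus_times_ms else 0.0
        end = window_ms + (
            trial.condition.isi_ms if trial.condition.kind == "paired" else 0.0
        )
        return response_magnitude(g, pair.sampling_rate_hz, (t0, t0 + end), mode)

    singles = {
        m: [magnitude(t) for t in cell.single_trials(m) if t.trace is not None]
        for m in ("V", "HB")
    }
    means = {m: np.mean(v) for m, v in singles.items() if v}
    if not means:
        raise ValueError(f"cell {cell.cell_id}: no single-modality traces")
    sm = max(means.values())
    if sm <= 0:
        raise ValueError(f"cell {cell.cell_id}: zero single-modality magnitude")
    by_isi: dict[float, list[float]] = {}
    for t in cell.paired_trials(crossmodal=True):
        if t.trace is None:
            continue
        by_isi.setdefault(t.condition.isi_ms, []).append(magnitude(t))
    values = {isi: (np.mean(v) - sm) / sm for isi, v in sorted(by_isi.items())}
    return ConductanceMSI(
        cell_id=cell.cell_id,
        component=component,
        stage_group=cell.stage_group,
        values=values,
        sm=float(sm),
    )


def ei_stage_comparison(msis: list[ConductanceMSI]) -> pd.DataFrame:
    """Two-way ANOVA (stage × ISI, with interaction) on MSIn values for one
    component.  Returns the statsmodels ANOVA table (type-II sums of
    squares); rows: stage, ISI, interaction, residual.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = [
        {"stage": m.stage_group, "isi": isi, "msin": v}
        for m in msis
        for isi, v in m.values.items()
    ]
    df = pd.DataFrame(rows)
    if df["stage"].nunique() < 2 or df["isi"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >=2 levels of stage and ISI")
    model = ols("msin ~ C(stage) * C(isi)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def ei_scatter_stats(pairs: pd.DataFrame) -> dict:
    """Per-stage correlation and slope-difference test for the per-cell
    (max excitatory MSIn, max inhibitory MSIn) scatter.

    ``pairs`` needs columns ``stage``, ``max_exc_msin``, ``max_inh_msin``.
    Returns Pearson r (and p) per stage plus an extra-sum-of-squares F-test
    of a common slope against separate slopes, df (1, N − 4): the restricted
    model allows separate intercepts only.
    """
    stages = sorted(pairs["stage"].unique())
    if len(stages) != 2:
        raise ValueError("slope comparison requires exactly two stages")
    out: dict = {"per_stage": {}}
    for st in stages:
        sub = pairs[pairs["stage"] == st]
        if len(sub) < 3:
            raise ValueError(f"stage {st}: need >=3 cells for correlation")
        r, p = stats.pearsonr(sub["max_exc_msin"], sub["max_inh_msin"])
        out["per_stage"][st] = {"r": float(r), "p": float(p), "n": int(len(sub))}

    x = pairs["max_inh_msin"].to_numpy(float)
    y = pairs["max_exc_msin"].to_numpy(float)
    is_b = (pairs["stage"] == stages[1]).to_numpy()
    n = x.size
    # restricted: separate intercepts, common slope (3 params)
    X1 = np.column_stack([np.ones(n), is_b.astype(float), x])
    # full: separate intercepts and slopes (4 params)
    X2 = np.column_stack([X1, x * is_b])
    rss1 = _ols_rss(X1, y)
    rss2 = _ols_rss(X2, y)
    df2 = n - 4
    if df2 <= 0:
        raise ValueError("not enough cells for the slope-comparison F-test")
    F = max(rss1 - rss2, 0.0) / (rss2 / df2)
    out["slope_test"] = {
        "F": float(F),
        "df1": 1,
        "df2": int(df2),
        "p": float(stats.f.sf(F, 1, df2)),
    }
    return out


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


class ConductanceAnalysis:
    """Model object: conductance-level MSI and E/I statistics for a
    population of cells with voltage-clamp trace pairs.

    Parameters
    ----------
    datasets : list of CellDataset
        Trials must carry ``trace = (sweep at −45 mV, sweep at +5 mV)``.
    mode : {"peak", "integral"}
    window_ms, baseline_ms : float
    """

    def __init__(self, datasets, mode="peak", window_ms=500.0, baseline_ms=50.0):
        self.datasets = list(datasets)
        self.mode = mode
        self.window_ms = window_ms
        self.baseline_ms = baseline_ms

    def fit(self) -> "ConductanceResults":
        msis = {"excitatory": [], "inhibitory": []}
        rows = []
        for cell in self.datasets:
            rec = {"cell_id": cell.cell_id, "stage": cell.stage_group}
            for comp in ("excitatory", "inhibitory"):
                m = conductance_msin(
                    cell, comp, self.window_ms, self.mode, self.baseline_ms
                )
                msis[comp].append(m)
                key = "max_exc_msin" if comp == "excitatory" else "max_inh_msin"
                rec[key] = m.max_msin
            rows.append(rec)
        per_cell = pd.DataFrame(rows)
        anova = {c: ei_stage_comparison(v) for c, v in msis.items()}
        scatter = ei_scatter_stats(per_cell)
        return ConductanceResults(self, msis, per_cell, anova, scatter)


class ConductanceResults:
    """Fitted conductance analysis: per-cell tuning, ANOVA tables, scatter
    statistics."""

    def __init__(self, model, msis, per_cell, anova_tables, scatter_stats):
        self.model = model
        self.msis = msis
        self.per_cell = per_cell
        self.anova_tables = anova_tables
        self.scatter_stats = scatter_stats

    def stage_effect_p(self, component: str) -> float:
        return float(self.anova_tables[component].loc["C(stage)", "PR(>F)"])

    def tuning_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": m.cell_id,
                "component": m.component,
                "stage": m.stage_group,
                "isi_ms": isi,
                "msin": v,
            }
            for comp in self.msis.values()
            for m in comp
            for isi, v in m.values.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Conductance MSI analysis", "=" * 40]
        lines.append(f"mode: {self.model.mode}, window {self.model.window_ms} ms")
        for comp in ("excitatory", "inhibitory"):
            p = self.stage_effect_p(comp)
            lines.append(f"{comp}: stage main effect p = {p:.4f} (2-way ANOVA)")
        for st, d in self.scatter_stats["per_stage"].items():
            lines.append(
                f"E vs I max MSIn, {st}: r = {d['r']:.3f}, p = {d['p']:.2g} "
                f"(n={d['n']})"
            )
        sl = self.scatter_stats["slope_test"]
        lines.append(
            f"slope difference: F = {sl['F']:.3f} ({sl['df1']},{sl['df2']}), "
            f"p = {sl['p']:.4f}"
        )
        return "\n".join(lines)
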