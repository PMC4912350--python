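"""Spike-count MSI indices versus ISI, peak statistics, aligned population
tuning curves, and nested-curve comparison.

The multisensory index for a crossmodal pair is

    MSIn = (CM − SM) / SM

where CM is the mean spike count over the paired trials at one ISI and SM
is the cell's maximal mean single-stimulus count over the two modalities —
the index is the fractional gain relative to the best unimodal response,
so it is comparable across cells with different overall output.  The
paired-pulse ratio (PPR) for same-modality pairs is the same formula with
SM the mean single count of the repeated modality.  Both are bounded below
by −1 because counts are non-negative.

Population tuning shape is compared after aligning each cell's curve at
its preferred ISI (the interval of maximal index): curves are re-keyed by
ΔISI = isi − preferred_isi and averaged per offset.  Group tuning widths
are compared by fitting a Gaussian-on-floor to each group's aligned points
and testing one shared curve against two separate curves with an
extra-sum-of-squares F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .recordings import (
    CellDataset,
    SpikeDetectionParams,
    count_response_spikes,
    validate_dataset,
)

__all__ = [
    "MSITuningCurve",
    "AlignedCurveSet",
    "CurveFitResult",
    "UndefinedIndexError",
    "msin",
    "cell_tuning_curve",
    "preferred_isi",
    "align_curves",
    "fit_tuning_curve",
    "compare_curves_f_test",
    "group_summary",
    "MSITuning",
    "MSITuningResults",
]


class UndefinedIndexError(ValueError):
    """The index denominator (mean single-stimulus response) is zero."""


def msin(cm: float, sm: float) -> float:
    """(CM − SM)/SM; requires SM > 0.  Shared by MSIn and PPR, which differ
    only in which single-stimulus mean supplies SM."""
    if sm <= 0:
        raise UndefinedIndexError(f"single-response mean must be positive, got {sm}")
    return (cm - sm) / sm


@dataclass
class MSITuningCurve:
    """Per-ISI index values for one cell.

    Keys of ``values`` are signed ISIs (positive = V first, negative = HB
    first) unless orders were pooled, in which case they are |ISI|.
    """

    cell_id: str
    index_kind: str  # "MSIn" | "PPR"
    values: dict[float, float]
    sm: float
    stage_group: str = ""
    drug: str = "none"

    @property
    def max_index(self) -> float:
        return preferred_isi(self)[1]

    @property
    def preferred_isi_ms(self) -> float:
        return preferred_isi(self)[0]


def preferred_isi(curve: MSITuningCurve) -> tuple[float, float]:
    """Argmax of the tuning map; ties broken toward the smallest |ISI|
    (deterministic, and conservative toward short-interval tuning)."""
    if not curve.values:
        raise ValueError(f"cell {curve.cell_id}: empty tuning curve")
    best = max(curve.values.values())
    winners = [isi for isi, v in curve.values.items() if v == best]
    winners.sort(key=lambda i: (abs(i), i))
    return winners[0], best


def cell_tuning_curve(
    cell: CellDataset,
    index_kind: str = "MSIn",
    params: SpikeDetectionParams | None = None,
    pool_order: bool = True,
    ppr_modality: str = "V",
) -> MSITuningCurve:
    """Index-versus-ISI curve for one cell.

    For MSIn, SM is the larger of the two single-modality mean counts
    (the cell's maximal single-stimulus response) and CM the mean
    crossmodal paired count at each ISI.  For PPR, SM is the mean single
    count of ``ppr_modality`` and CM the mean same-modality paired count.
    With ``pool_order`` the two crossmodal presentation orders are pooled
    onto |ISI| before averaging; otherwise keys are signed ISIs.
    """
    params = params or SpikeDetectionParams()
    problems = validate_dataset(cell, require_spiking=False)
    if problems:
        raise ValueError(f"cell {cell.cell_id}: " + "; ".join(problems))

    def mean_count(trials) -> float:
        return float(np.mean([count_response_spikes(t, params) for t in trials]))

    if index_kind == "MSIn":
        singles = {m: cell.single_trials(m) for m in ("V", "HB")}
        if not all(singles.values()):
            raise ValueError(f"cell {cell.cell_id}: MSIn needs both modalities")
        sm = max(mean_count(v) for v in singles.values())
        paired = cell.paired_trials(crossmodal=True)
    elif index_kind == "PPR":
        singles_m = cell.single_trials(ppr_modality)
        if not singles_m:
            raise ValueError(
                f"cell {cell.cell_id}: PPR needs single {ppr_modality} trials"
            )
        sm = mean_count(singles_m)
        paired = cell.paired_trials(crossmodal=False, modality=ppr_modality)
    else:
        raise ValueError(f"unknown index_kind {index_kind!r}")
    if sm <= 0:
        raise UndefinedIndexError(
            f"cell {cell.cell_id}: zero single-stimulus response (excluded)"
        )
    by_isi: dict[float, list[int]] = {}
    for t in paired:
        key = abs(t.condition.signed_isi_ms) if pool_order else t.condition.signed_isi_ms
        by_isi.setdefault(key, []).append(count_response_spikes(t, params))
    values = {isi: msin(float(np.mean(c)), sm) for isi, c in sorted(by_isi.items())}
    return MSITuningCurve(
        cell_id=cell.cell_id,
        index_kind=index_kind,
        values=values,
        sm=sm,
        stage_group=cell.stage_group,
        drug=cell.drug,
    )


@dataclass
class AlignedCurveSet:
    """Peak-aligned population tuning curve: ΔISI → (mean, sem, n)."""

    group: str
    offsets: dict[float, tuple[float, float, int]]
    n_cells: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"delta_isi_ms": d, "mean": m, "sem": s, "n": n}
            for d, (m, s, n) in sorted(self.offsets.items())
        ]
        return pd.DataFrame(rows)


def align_curves(curves: list[MSITuningCurve], group: str = "") -> AlignedCurveSet:
    """Re-key every cell's curve by ΔISI = isi − preferred_isi and average
    per offset over the cells contributing that offset.  SEM is 0 by
    convention when a single cell contributes."""
    pooled: dict[float, list[float]] = {}
    for c in curves:
        pref, _ = preferred_isi(c)
        for isi, v in c.values.items():
            pooled.setdefault(isi - pref, []).append(v)
    offsets = {}
    for d, vals in pooled.items():
        arr = np.asarray(vals, float)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        offsets[d] = (float(arr.mean()), sem, int(arr.size))
    return AlignedCurveSet(group=group, offsets=offsets, n_cells=len(curves))


def aligned_points(curves: list[MSITuningCurve]) -> np.ndarray:
    """All (ΔISI, value) points from peak-aligned per-cell curves, one row
    per (cell, ISI) observation."""
    pts = []
    for c in curves:
        pref, _ = preferred_isi(c)
        pts.extend((isi - pref, v) for isi, v in c.values.items())
    return np.asarray(pts, float)


def mean_aligned_points(
    curves: list[MSITuningCurve], min_cells: int = 3
) -> np.ndarray:
    """(ΔISI, group-mean value) points from the peak-aligned population
    curve, keeping offsets with at least ``min_cells`` contributing cells.

    Averaging across cells before fitting removes the within-cell
    clustering of the raw pooled points, so curve-comparison F-tests on
    these points are much closer to nominal calibration.
    """
    al = align_curves(curves)
    return np.asarray(
        [[d, m] for d, (m, _s, n) in sorted(al.offsets.items()) if n >= min_cells],
        float,
    )


@dataclass
class CurveFitResult:
    """Least-squares Gaussian-on-floor fit to (ΔISI, value) points."""

    amplitude: float
    width_ms: float
    floor: float
    rss: float
    df: int
    converged: bool = True
    model: str = "gaussian_on_floor"

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.amplitude, self.width_ms, self.floor)


def _gaussian_on_floor(x, amplitude, width, floor):
    return floor + amplitude * np.exp(-0.5 * (x / width) ** 2)


def fit_tuning_curve(points: np.ndarray) -> CurveFitResult:
    """Fit ``value = floor + amplitude·exp(−ΔISI²/(2·width²))``.

    Initialisation is fixed and deterministic: amplitude = max − min,
    floor = min, width = half the ΔISI range (1 ms floor on the range for
    degenerate spans).  Non-convergence returns a flagged result with the
    RSS of the initial iterate.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (delta_isi, value) points")
    x, y = pts[:, 0], pts[:, 1]
    span = max(x.max() - x.min(), 1.0)
    p0 = (y.max() - y.min(), span / 2.0, y.min())
    df = x.size - 3
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gaussian_on_floor, x, y, p0=p0, maxfev=10_000
            )
        resid = y - _gaussian_on_floor(x, *popt)
        return CurveFitResult(
            amplitude=float(popt[0]),
            width_ms=float(abs(popt[1])),
            floor=float(popt[2]),
            rss=float(resid @ resid),
            df=df,
        )
    except RuntimeError:
        resid = y - _gaussian_on_floor(x, *p0)
        return CurveFitResult(
            amplitude=float(p0[0]),
            width_ms=float(p0[1]),
            floor=float(p0[2]),
            rss=float(resid @ resid),
            df=df,
            converged=False,
        )


def compare_curves_f_test(
    points_a: np.ndarray, points_b: np.ndarray
) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares test: is the pooled data best fit by one curve
    or by two separate curves?

    F = ((RSS₁ − RSS₂)/(df₁ − df₂)) / (RSS₂/df₂) with RSS₁ from a single
    pooled fit and RSS₂ = RSS_A + RSS_B from per-group fits.  Returns
    (F, df1 − df2, df2, p).
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    pooled = fit_tuning_curve(np.vstack([a, b]))
    fa = fit_tuning_curve(a)
    fb = fit_tuning_curve(b)
    rss1, df1 = pooled.rss, pooled.df
    rss2 = fa.rss + fb.rss
    df2 = fa.df + fb.df
    if df2 <= 0:
        raise ValueError("not enough points for separate-curve fits")
    num_df = df1 - df2
    F = max(rss1 - rss2, 0.0) / num_df / (rss2 / df2)
    p = float(stats.f.sf(F, num_df, df2))
    return float(F), int(num_df), int(df2), p


def _tukey_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median-of-halves quartiles (median excluded from halves for odd n)."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    if n == 0:
        raise ValueError("no values")
    if n == 1:
        return float(v[0]), float(v[0]), float(v[0])
    half = n // 2
    lower, upper = v[:half], v[-half:]
    return float(np.median(lower)), float(np.median(v)), float(np.median(upper))


def group_summary(
    curves: list[MSITuningCurve],
    grouping: dict[str, list[str]] | None = None,
    bonferroni: bool = True,
) -> dict:
    """Per-group peak statistics and between-group tests.

    Groups default to stage_group/drug labels.  Reports mean ± SEM of the
    per-cell maximal index (compared with an unpaired t-test) and median
    and IQR of the preferred |ISI| (compared with a Mann-Whitney U test);
    p-values are Bonferroni-adjusted across the pairwise comparisons when
    more than one is made.
    """
    if grouping is None:
        keys = sorted({(c.stage_group, c.drug) for c in curves})
        grouping = {
            (f"{st}" if dr == "none" else f"{st}+{dr}"): [
                c.cell_id for c in curves if (c.stage_group, c.drug) == (st, dr)
            ]
            for st, dr in keys
        }
    by_id = {c.cell_id: c for c in curves}
    out: dict = {"groups": {}, "comparisons": []}
    stats_by_group: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g, ids in grouping.items():
        gc = [by_id[i] for i in ids]
        if not gc:
            continue
        peaks = np.asarray([c.max_index for c in gc])
        prefs = np.asarray([abs(c.preferred_isi_ms) for c in gc])
        q25, q50, q75 = _tukey_quartiles(prefs)
        out["groups"][g] = {
            "n": int(peaks.size),
            "max_index_mean": float(peaks.mean()),
            "max_index_sem": float(peaks.std(ddof=1) / np.sqrt(peaks.size))
            if peaks.size > 1
            else 0.0,
            "preferred_isi_median": q50,
            "preferred_isi_iqr": q75 - q25,
        }
        stats_by_group[g] = (peaks, prefs)
    names = list(stats_by_group)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs) if bonferroni else 1
    for a, b in pairs:
        pa, ia = stats_by_group[a]
        pb, ib = stats_by_group[b]
        if pa.size < 2 or pb.size < 2:
            raise ValueError(
                f"groups {a!r} vs {b!r}: need >= 2 cells per group for tests"
            )
        t, p_t = stats.ttest_ind(pa, pb)
        u, p_u = stats.mannwhitneyu(ia, ib, alternative="two-sided")
        out["comparisons"].append(
            {
                "groups": (a, b),
                "max_index_t": float(t),
                "max_index_p": float(min(p_t * m, 1.0)),
                "preferred_isi_u": float(u),
                "preferred_isi_p": float(min(p_u * m, 1.0)),
                "bonferroni_m": m,
            }
        )
    return out


class MSITuning:
    """Model object: ISI tuning of a spike-count MSI index for a population.

    Parameters
    ----------
    datasets : list of CellDataset
    index_kind : {"MSIn", "PPR"}
    pool_order : bool
        Pool the two crossmodal presentation orders onto |ISI|.
    params : SpikeDetectionParams, optional
        Supplies the spike-counting window.
    """

    def __init__(
        self,
        datasets: list[CellDataset],
        index_kind: str = "MSIn",
        pool_order: bool = True,
        params: SpikeDetectionParams | None = None,
        ppr_modality: str = "V",
    ):
        self.datasets = list(datasets)
        self.index_kind = index_kind
        self.pool_order = pool_order
        self.params = params or SpikeDetectionParams()
        self.ppr_modality = ppr_modality

    def fit(self) -> "MSITuningResults":
        curves, excluded = [], []
        for cell in self.datasets:
            try:
                curves.append(
                    cell_tuning_curve(
                        cell,
                        self.index_kind,
                        self.params,
                        self.pool_order,
                        self.ppr_modality,
                    )
                )
            except UndefinedIndexError:
                excluded.append(cell.cell_id)
        groups: dict[str, list[MSITuningCurve]] = {}
        for c in curves:
            label = c.stage_group if c.drug == "none" else f"{c.stage_group}+{c.drug}"
            groups.setdefault(label, []).append(c)
        aligned = {g: align_curves(cs, group=g) for g, cs in groups.items()}
        summary = group_summary(curves) if curves else {"groups": {}, "comparisons": []}
        return MSITuningResults(self, curves, excluded, aligned, summary)


class MSITuningResults:
    """Fitted tuning analysis: per-cell curves, aligned population curves,
    group summaries, and curve-comparison tests."""

    def __init__(self, model, curves, excluded, aligned, group_stats):
        self.model = model
        self.curves = curves
        self.excluded = excluded
        self.aligned = aligned
        self.group_stats = group_stats

    def curve_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "index_kind": c.index_kind,
                "stage_group": c.stage_group,
                "drug": c.drug,
                "isi_ms": isi,
                "index": v,
                "sm": c.sm,
            }
            for c in self.curves
            for isi, v in sorted(c.values.items())
        ]
        return pd.DataFrame(rows)

    def peak_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "stage_group": c.stage_group,
                "drug": c.drug,
                "max_index": c.max_index,
                "preferred_isi_ms": c.preferred_isi_ms,
            }
            for c in self.curves
        ]
        return pd.DataFrame(rows)

    def compare_groups(self, group_a: str, group_b: str):
        """Nested-curve F-test between two groups' aligned tuning points."""
        by_group: dict[str, list[MSITuningCurve]] = {}
        for c in self.curves:
            label = c.stage_group if c.drug == "none" else f"{c.stage_group}+{c.drug}"
            by_group.setdefault(label, []).append(c)
        return compare_curves_f_test(
            aligned_points(by_group[group_a]), aligned_points(by_group[group_b])
        )

    def summary(self) -> str:
        lines = [f"{self.model.index_kind} tuning analysis", "=" * 40]
        lines.append(
            f"{len(self.curves)} cells analysed, {len(self.excluded)} excluded "
            "(zero single-stimulus response)"
        )
        for g, d in self.group_stats["groups"].items():
            lines.append(
                f"{g}: max {self.model.index_kind} = {d['max_index_mean']:.2f} "
                f"± {d['max_index_sem']:.2f} (n={d['n']}); preferred ISI median "
                f"{d['preferred_isi_median']:.0f} ms, IQR {d['preferred_isi_iqr']:.0f} ms"
            )
        for cmp_ in self.group_stats["comparisons"]:
            a, b = cmp_["groups"]
            lines.append(
                f"{a} vs {b}: max-index t-test p = {cmp_['max_index_p']:.4f}; "
                f"preferred-ISI Mann-Whitney p = {cmp_['preferred_isi_p']:.4f}"
                + (
                    f" (Bonferroni m={cmp_['bonferroni_m']})"
                    if cmp_["bonferroni_m"] > 1
                    else ""
                )
            )
        return "\n".join(lines)
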