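"""Additive-prediction resampling null, z-scores, and ternary linearity
classification.

Does a paired response exceed, match, or fall short of the sum of the two
single-modality responses?  The additive prediction is built from the
single trials themselves: every ordered pair of one trial from each
baseline condition yields one predicted sum (33 × 33 single trials give
1089 sums), and the experimental paired mean — an average over 4 paired
trials — is mirrored by repeatedly drawing 4 sums with replacement and
averaging, 10,000 times.  The actual paired mean is then expressed as a
z-score against the mean and standard deviation of that replicate
distribution; |z| beyond 1.97 (two standard deviations) classifies the
cell's interaction as supralinear (z > +1.97) or sublinear (z < −1.97),
otherwise linear.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .recordings import CellDataset, SpikeDetectionParams, count_response_spikes

__all__ = [
    "Z_CRIT",
    "LinearityResult",
    "enumerate_pair_sums",
    "bootstrap_null",
    "z_score",
    "classify",
    "compare_z_distributions",
    "exact_null_oracle",
    "cell_linearity",
    "LinearityAnalysis",
    "LinearityResults",
]

#: Classification threshold: two standard deviations from the predicted sum.
Z_CRIT = 1.97


@dataclass
class LinearityResult:
    """Per-cell resampling-null summary and classification for one pair type."""

    cell_id: str
    pair_type: str  # "crossmodal" | "unimodal_V" | "unimodal_HB"
    isi_ms: float  # ISI of the maximal paired response
    actual_mean: float
    null_mean: float
    null_sd: float
    z: float
    classification: str
    n_resamples: int
    n_possible_sums: int
    degenerate_null: bool = False
    per_isi_z: dict[float, float] | None = None


def enumerate_pair_sums(counts_a, counts_b) -> np.ndarray:
    """All |A|·|B| ordered-pair sums of single-trial spike counts."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both single-trial count lists must be non-empty")
    return np.add.outer(a, b).ravel()


def bootstrap_null(
    sums,
    k: int = 4,
    reps: int = 10_000,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Resampled distribution of the mean of ``k`` predicted sums.

    Each replicate draws ``k`` sums uniformly with replacement and records
    their mean; repeated ``reps`` times.  Returns (mean, sd, replicates);
    the sd is the population standard deviation of the replicate set — the
    replicates ARE the null distribution, not a sample from a larger one.
    """
    sums = np.asarray(sums, dtype=float)
    if sums.size == 0:
        raise ValueError("sums must be non-empty")
    if k < 1 or reps < 1:
        raise ValueError("k and reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.integers(0, sums.size, size=(reps, k))
    samples = sums[draws].mean(axis=1)
    return float(samples.mean()), float(samples.std(ddof=0)), samples


def exact_null_oracle(sums, k: int) -> tuple[float, float]:
    """Exact mean and sd of the mean of ``k`` with-replacement draws, by
    full enumeration of the |sums|^k equally likely outcomes.

    Validation oracle for :func:`bootstrap_null`; only feasible for small
    inputs.
    """
    sums = np.asarray(sums, dtype=float)
    if sums.size**k > 2_000_000:
        raise ValueError("enumeration too large; use smaller inputs")
    means = np.array([np.mean(combo) for combo in product(sums, repeat=k)])
    return float(means.mean()), float(means.std(ddof=0))


def z_score(actual_mean: float, null_mean: float, null_sd: float) -> float:
    """(actual − null mean)/null sd; requires a non-degenerate null."""
    if null_sd <= 0:
        raise ValueError("null_sd must be positive; degenerate null")
    return (actual_mean - null_mean) / null_sd


def classify(z: float, z_crit: float = Z_CRIT) -> str:
    """Ternary call with strict inequalities: |z| exactly at the threshold
    is still linear."""
    if z > z_crit:
        return "supralinear"
    if z < -z_crit:
        return "sublinear"
    return "linear"


def compare_z_distributions(group_a, group_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of z-score distributions."""
    res = stats.ks_2samp(np.asarray(group_a, float), np.asarray(group_b, float))
    return float(res.statistic), float(res.pvalue)


def _pair_counts(
    cell: CellDataset, pair_type: str, params: SpikeDetectionParams
) -> tuple[np.ndarray, np.ndarray, dict[float, list[int]]]:
    """Single-trial counts for the two baseline conditions of a pair type
    plus paired counts grouped by |ISI|."""
    if pair_type == "crossmodal":
        counts_a = [count_response_spikes(t, params) for t in cell.single_trials("V")]
        counts_b = [count_response_spikes(t, params) for t in cell.single_trials("HB")]
        paired = cell.paired_trials(crossmodal=True)
    elif pair_type in ("unimodal_V", "unimodal_HB"):
        m = "V" if pair_type == "unimodal_V" else "HB"
        counts_a = [count_response_spikes(t, params) for t in cell.single_trials(m)]
        counts_b = counts_a
        paired = cell.paired_trials(crossmodal=False, modality=m)
    else:
        raise ValueError(f"unknown pair_type {pair_type!r}")
    by_isi: dict[float, list[int]] = {}
    for t in paired:
        by_isi.setdefault(t.condition.isi_ms, []).append(
            count_response_spikes(t, params)
        )
    return np.asarray(counts_a), np.asarray(counts_b), by_isi


def cell_linearity(
    cell: CellDataset,
    pair_type: str = "crossmodal",
    params: SpikeDetectionParams | None = None,
    k: int = 4,
    reps: int = 10_000,
    z_crit: float = Z_CRIT,
    seed: int = 0,
    summary_isi: str = "max",
) -> LinearityResult:
    """Resampling-null linearity analysis for one cell and pair type.

    ``summary_isi="max"`` classifies the maximal mean paired response over
    ISIs (the scatter-plot convention); per-ISI z-scores are always
    computed and attached.  A degenerate null (all sums identical) falls
    back to exact comparison with a flag.
    """
    params = params or SpikeDetectionParams()
    counts_a, counts_b, by_isi = _pair_counts(cell, pair_type, params)
    if not by_isi:
        raise ValueError(f"cell {cell.cell_id}: no paired trials for {pair_type}")
    sums = enumerate_pair_sums(counts_a, counts_b)
    # substream: master seed + stable per-cell/pair identifiers (crc32 is
    # stable across processes, unlike the builtin str hash)
    ss = np.random.SeedSequence(
        (
            seed,
            zlib.crc32(cell.cell_id.encode()),
            {"crossmodal": 0, "unimodal_V": 1, "unimodal_HB": 2}[pair_type],
        )
    )
    null_mean, null_sd, _ = bootstrap_null(sums, k=k, reps=reps, rng=np.random.default_rng(ss))
    isi_means = {isi: float(np.mean(c)) for isi, c in by_isi.items()}
    degenerate = null_sd <= 0

    def z_of(actual: float) -> float:
        if degenerate:
            return 0.0 if actual == null_mean else np.inf * np.sign(actual - null_mean)
        return z_score(actual, null_mean, null_sd)

    per_isi_z = {isi: z_of(m) for isi, m in isi_means.items()}
    if summary_isi == "max":
        best_isi = max(isi_means, key=lambda i: (isi_means[i], -i))
    else:
        best_isi = float(summary_isi)
    actual = isi_means[best_isi]
    z = z_of(actual)
    return LinearityResult(
        cell_id=cell.cell_id,
        pair_type=pair_type,
        isi_ms=best_isi,
        actual_mean=actual,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        classification=classify(z, z_crit) if np.isfinite(z) else (
            "linear" if actual == null_mean else
            ("supralinear" if actual > null_mean else "sublinear")
        ),
        n_resamples=reps,
        n_possible_sums=int(counts_a.size * counts_b.size),
        degenerate_null=degenerate,
        per_isi_z=per_isi_z,
    )


class LinearityAnalysis:
    """Model object: resampling-null linearity for a population of cells.

    Parameters
    ----------
    datasets : list of CellDataset
    pair_type : {"crossmodal", "unimodal_V", "unimodal_HB"}
    k, reps : int
        Paired trials mirrored per replicate, and number of replicates.
    z_crit : float
    seed : int
        Master seed; per-cell substreams derive from it.
    """

    def __init__(
        self,
        datasets,
        pair_type: str = "crossmodal",
        params: SpikeDetectionParams | None = None,
        k: int = 4,
        reps: int = 10_000,
        z_crit: float = Z_CRIT,
        seed: int = 0,
    ):
        self.datasets = list(datasets)
        self.pair_type = pair_type
        self.params = params or SpikeDetectionParams()
        self.k = k
        self.reps = reps
        self.z_crit = z_crit
        self.seed = seed

    def fit(self) -> "LinearityResults":
        results = [
            cell_linearity(
                cell,
                self.pair_type,
                self.params,
                self.k,
                self.reps,
                self.z_crit,
                self.seed,
            )
            for cell in self.datasets
        ]
        groups: dict[str, list[LinearityResult]] = {}
        for cell, r in zip(self.datasets, results):
            label = (
                cell.stage_group if cell.drug == "none" else f"{cell.stage_group}+{cell.drug}"
            )
            groups.setdefault(label, []).append(r)
        return LinearityResults(self, results, groups)


class LinearityResults:
    """Fitted linearity analysis: per-cell results, per-group classification
    proportions, and between-group z-distribution comparisons."""

    def __init__(self, model, results, groups):
        self.model = model
        self.results = results
        self.groups = groups

    def result_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": r.cell_id,
                "pair_type": r.pair_type,
                "isi_ms": r.isi_ms,
                "actual_mean": r.actual_mean,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "classification": r.classification,
                "n_possible_sums": r.n_possible_sums,
                "degenerate_null": r.degenerate_null,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def classification_proportions(self) -> pd.DataFrame:
        rows = []
        for g, rs in self.groups.items():
            n = len(rs)
            counts = {c: sum(r.classification == c for r in rs) for c in
                      ("sublinear", "linear", "supralinear")}
            row = {"group": g, "n": n}
            row.update({f"n_{c}": v for c, v in counts.items()})
            row.update({f"frac_{c}": v / n for c, v in counts.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def compare_groups(self, group_a: str, group_b: str) -> tuple[float, float]:
        za = [r.z for r in self.groups[group_a] if np.isfinite(r.z)]
        zb = [r.z for r in self.groups[group_b] if np.isfinite(r.z)]
        return compare_z_distributions(za, zb)

    def z_ecdf_table(self) -> pd.DataFrame:
        rows = []
        for g, rs in self.groups.items():
            zs = np.sort([r.z for r in rs if np.isfinite(r.z)])
            for i, z in enumerate(zs):
                rows.append({"group": g, "z": float(z), "ecdf": (i + 1) / zs.size})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Linearity analysis ({self.model.pair_type})", "=" * 40]
        lines.append(
            f"k={self.model.k}, reps={self.model.reps}, "
            f"|z| threshold {self.model.z_crit}"
        )
        for _, row in self.classification_proportions().iterrows():
            lines.append(
                f"{row['group']}: n={row['n']}, sublinear {row['frac_sublinear']:.1%}, "
                f"linear {row['frac_linear']:.1%}, supralinear {row['frac_supralinear']:.1%}"
            )
        names = list(self.groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d, p = self.compare_groups(a, b)
                lines.append(f"{a} vs {b}: KS D = {d:.3f}, p = {p:.3f}")
        return "\n".join(lines)
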