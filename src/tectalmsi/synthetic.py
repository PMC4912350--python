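"""Synthetic populations of tectal-neuron recordings.

Every downstream stage of the pipeline is testable without real recordings
because this module generates :class:`~tectalmsi.recordings.CellDataset`
populations with the statistical structure the analyses are built to
detect:

* ISI-dependent enhancement/suppression of paired spike counts, through a
  per-cell *enhancement profile* — a Gaussian bump of gain on a suppression
  floor, ``G(isi)``;
* per-cell heterogeneity in preferred ISI, gain, and tuning width, drawn
  from a configurable :class:`ProfileDistribution`;
* stage- and drug-dependent presets (young tadpoles: high gain, short
  preferred ISIs, broad tuning; older tadpoles: lower gain, dispersed
  preferred ISIs, narrow tuning; picrotoxin: like young with very short
  preferred ISIs).  Preset parameter values are this package's own choices
  of realistic magnitudes, not fitted to any experimental dataset;
* a shifted-gamma first-spike latency law with an additive latency advance
  on paired trials;
* difference-of-exponentials excitatory and inhibitory conductance
  transients, synthesised into voltage-clamp currents at the two holding
  potentials.

Spike counts are Poisson.  Paired-trial counts follow one of two laws
(``paired_count_model``):

``"gain"``
    ``Poisson(base_rate · (1 + G(isi)))`` — the paired response is the
    single response scaled by the enhancement profile.  With ``G ≡ 0`` the
    paired response equals the single response and the MSI index is
    centred at 0.
``"additive"``
    ``Poisson((rate_V + rate_HB) · (1 + G(isi)))`` — with ``G ≡ 0`` the
    paired response is exactly the sum of the two single responses, the
    truth the linearity analysis's additive null hypothesises.  This is
    the calibration condition for the resampling z-score.

All randomness flows from ``numpy.random.SeedSequence(seed, cell_index)``,
so populations are bit-reproducible and individual cells independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .conductance import E_REV_EXC_MV, E_REV_INH_MV, CurrentTrace
from .recordings import CellDataset, StimulusCondition, TrialRecord

__all__ = [
    "DEFAULT_ISI_GRID_MS",
    "EnhancementProfile",
    "ProfileDistribution",
    "GeneratorConfig",
    "ConductanceParams",
    "enhancement_at",
    "generate_cell",
    "generate_population",
    "generate_conductance_trials",
    "generate_conductance_population",
    "preset",
    "PRESETS",
]

#: Default ISI grid (ms).  The experiments probed intervals up to 1000 ms;
#: the exact grid is configurable.
DEFAULT_ISI_GRID_MS = (50.0, 100.0, 150.0, 200.0, 250.0, 500.0, 750.0, 1000.0)


@dataclass(frozen=True)
class EnhancementProfile:
    """Gaussian-on-floor enhancement gain versus ISI.

    ``G(isi) = floor + (peak − floor)·exp(−(isi − preferred)² / (2·width²))``

    peak_gain is the expected MSI index at the preferred ISI;
    suppression_floor (in [−1, 0]) the asymptotic index at long ISI.
    """

    peak_gain: float
    preferred_isi_ms: float
    tuning_width_ms: float
    suppression_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.tuning_width_ms <= 0:
            raise ValueError("tuning_width_ms must be positive")
        if not -1.0 <= self.suppression_floor <= 0.0:
            raise ValueError("suppression_floor must lie in [-1, 0]")
        if self.peak_gain < self.suppression_floor:
            raise ValueError("peak_gain must not fall below suppression_floor")


def enhancement_at(profile: EnhancementProfile, isi_ms: float) -> float:
    """Evaluate the enhancement profile ``G`` at an ISI (ms)."""
    if np.any(np.asarray(isi_ms) <= 0):
        raise ValueError("isi_ms must be positive")
    span = profile.peak_gain - profile.suppression_floor
    z = (np.asarray(isi_ms, dtype=float) - profile.preferred_isi_ms) / (
        profile.tuning_width_ms
    )
    out = profile.suppression_floor + span * np.exp(-0.5 * z**2)
    return float(out) if np.isscalar(isi_ms) else out


@dataclass(frozen=True)
class ProfileDistribution:
    """Per-cell distribution over enhancement-profile parameters.

    Gains, widths and floors are normal (clipped to their valid ranges);
    the preferred ISI is categorical over ``preferred_isi_choices``.  A
    degenerate distribution (all sd 0, one choice) yields identical cells.
    """

    gain_mean: float = 1.0
    gain_sd: float = 0.3
    preferred_isi_choices: tuple[float, ...] = DEFAULT_ISI_GRID_MS
    preferred_isi_weights: tuple[float, ...] | None = None
    width_mean_ms: float = 200.0
    width_sd_ms: float = 40.0
    floor_mean: float = -0.3
    floor_sd: float = 0.1

    def sample(self, rng: np.random.Generator) -> EnhancementProfile:
        w = self.preferred_isi_weights
        p = None if w is None else np.asarray(w, float) / np.sum(w)
        preferred = float(rng.choice(self.preferred_isi_choices, p=p))
        floor = float(np.clip(rng.normal(self.floor_mean, self.floor_sd), -0.95, 0.0))
        gain = float(max(rng.normal(self.gain_mean, self.gain_sd), floor))
        width = float(max(rng.normal(self.width_mean_ms, self.width_sd_ms), 10.0))
        return EnhancementProfile(gain, preferred, width, floor)


@dataclass(frozen=True)
class ConductanceParams:
    """Kinetics and amplitudes of the synthetic E/I conductance transients.

    Rise/decay constants in ms, peak amplitudes in nS; inhibitory
    conductances are larger than excitatory ones, as recorded in tectal
    neurons.  ``noise_sd_pa`` is the Gaussian current noise per sample.
    """

    amp_exc_ns: float = 2.0
    amp_inh_ns: float = 6.0
    tau_rise_exc_ms: float = 2.0
    tau_decay_exc_ms: float = 30.0
    tau_rise_inh_ms: float = 5.0
    tau_decay_inh_ms: float = 80.0
    sampling_rate_hz: float = 10_000.0
    noise_sd_pa: float = 5.0
    pre_stimulus_ms: float = 100.0
    post_window_ms: float = 500.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one synthetic population.

    Defaults mirror the experimental design: 33 single-stimulus trials per
    modality and 4 paired trials per ISI, intervals up to 1000 ms.
    ``base_rate_spikes_per_trial`` is the Poisson mean single-trial spike
    count (both modalities; stimulus strengths were matched).  The latency
    law places a trial's first spike at ``offset + Gamma(shape, scale)`` ms
    after the driving stimulus; paired-trial first spikes are advanced by
    ``paired_latency_advance_ms`` (additive, ISI-independent).
    """

    n_cells: int = 30
    stage_group: str = "st48_49"
    drug: str = "none"
    isi_grid_ms: tuple[float, ...] = DEFAULT_ISI_GRID_MS
    n_single_trials: int = 33
    n_paired_trials: int = 4
    base_rate_spikes_per_trial: float = 4.0
    latency_shape: float = 2.0
    latency_scale_ms: float = 15.0
    latency_offset_ms: float = 20.0
    paired_latency_advance_ms: float = 15.0
    intra_burst_interval_ms: float = 15.0
    paired_count_model: str = "gain"  # "gain" | "additive"
    pair_orders: tuple[tuple[str, str], ...] = (("V", "HB"),)
    profile_distribution: ProfileDistribution = field(default_factory=ProfileDistribution)
    conductance_params: ConductanceParams = field(default_factory=ConductanceParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_single_trials < 1 or self.n_paired_trials < 1:
            raise ValueError("trial counts must be >= 1")
        if any(i <= 0 for i in self.isi_grid_ms):
            raise ValueError("all ISIs must be positive")
        if self.paired_count_model not in ("gain", "additive"):
            raise ValueError(f"unknown paired_count_model {self.paired_count_model!r}")
        if self.paired_latency_advance_ms < 0:
            raise ValueError("paired_latency_advance_ms must be >= 0")


def _cell_rng(config: GeneratorConfig, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, cell_index)))


def _draw_spike_train(
    rng: np.random.Generator,
    n_spikes: int,
    t_stimulus_ms: float,
    config: GeneratorConfig,
    advance_ms: float = 0.0,
) -> np.ndarray:
    """Spike times for one response burst, relative to the first stimulus.

    First spike at ``t_stimulus + max(offset − advance, 1) + Gamma``;
    later spikes follow at exponential intervals.
    """
    if n_spikes == 0:
        return np.empty(0)
    onset = max(config.latency_offset_ms - advance_ms, 1.0)
    first = t_stimulus_ms + onset + rng.gamma(config.latency_shape, config.latency_scale_ms)
    gaps = rng.exponential(config.intra_burst_interval_ms, size=n_spikes - 1) + 0.1
    return first + np.concatenate(([0.0], np.cumsum(gaps)))


def generate_cell(config: GeneratorConfig, cell_index: int) -> CellDataset:
    """One cell: single trials for both modalities plus paired trials at
    every ISI of the grid, all spike-count and latency structure drawn from
    the cell's own enhancement profile."""
    rng = _cell_rng(config, cell_index)
    profile = config.profile_distribution.sample(rng)
    cell_id = f"cell{cell_index:04d}"
    base = config.base_rate_spikes_per_trial
    trials: list[TrialRecord] = []
    idx = 0
    for modality in ("V", "HB"):
        cond = StimulusCondition("single", modality)
        for _ in range(config.n_single_trials):
            n = rng.poisson(base)
            trials.append(
                TrialRecord(cell_id, idx, cond, _draw_spike_train(rng, n, 0.0, config))
            )
            idx += 1
    for first, second in config.pair_orders:
        for isi in config.isi_grid_ms:
            cond = StimulusCondition("paired", first, second, float(isi))
            g = enhancement_at(profile, isi)
            if config.paired_count_model == "additive":
                rate = (base + base) * (1.0 + g)
            else:
                rate = base * (1.0 + g)
            rate = max(rate, 0.0)
            for _ in range(config.n_paired_trials):
                n = rng.poisson(rate)
                st = _draw_spike_train(
                    rng, n, isi, config, advance_ms=config.paired_latency_advance_ms
                )
                trials.append(TrialRecord(cell_id, idx, cond, st))
                idx += 1
    ds = CellDataset(cell_id, config.stage_group, config.drug, trials)
    ds.profile = profile  # generative truth, kept for parameter-recovery tests
    return ds


def generate_population(config: GeneratorConfig) -> list[CellDataset]:
    """Independent cells with per-cell profiles from the configured
    distribution; deterministic under a fixed seed."""
    return [generate_cell(config, i) for i in range(config.n_cells)]


# ---------------------------------------------------------------------------
# Presets

#: Stage/drug presets.  Magnitudes are chosen as realistic for tectal
#: neurons at these stages (young: roughly twice the older group's peak
#: gain, preferred ISIs concentrated at short intervals, broad tuning;
#: older: dispersed preferred ISIs, narrow tuning; picrotoxin: strong gain
#: at very short preferred ISIs, broad tuning); they are generator
#: conventions, not fits to any recorded dataset.
PRESETS: dict[str, ProfileDistribution] = {
    "st44_46": ProfileDistribution(
        gain_mean=1.2,
        gain_sd=0.4,
        preferred_isi_weights=(0.06, 0.10, 0.14, 0.45, 0.10, 0.08, 0.04, 0.03),
        width_mean_ms=100.0,
        width_sd_ms=20.0,
        floor_mean=-0.3,
        floor_sd=0.1,
    ),
    "st48_49": ProfileDistribution(
        gain_mean=0.55,
        gain_sd=0.2,
        preferred_isi_weights=(0.02, 0.04, 0.06, 0.08, 0.05, 0.40, 0.20, 0.15),
        width_mean_ms=60.0,
        width_sd_ms=15.0,
        floor_mean=-0.3,
        floor_sd=0.1,
    ),
    "picrotoxin": ProfileDistribution(
        gain_mean=2.0,
        gain_sd=0.5,
        preferred_isi_weights=(0.35, 0.30, 0.12, 0.08, 0.05, 0.05, 0.03, 0.02),
        width_mean_ms=300.0,
        width_sd_ms=60.0,
        floor_mean=-0.1,
        floor_sd=0.05,
    ),
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """A ready GeneratorConfig for one study condition.

    ``name`` is one of ``st44_46``, ``st48_49``, ``picrotoxin``; keyword
    overrides patch any GeneratorConfig field.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    stage = "st44_46" if name == "st44_46" else "st48_49"
    drug = "picrotoxin" if name == "picrotoxin" else "none"
    cfg = GeneratorConfig(
        stage_group=stage, drug=drug, profile_distribution=PRESETS[name]
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Conductance traces


def _transient(
    t_ms: np.ndarray, t0_ms: float, amp: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Difference-of-exponentials conductance transient, peak-normalised to
    ``amp`` (nS); zero before ``t0``."""
    s = np.clip(t_ms - t0_ms, 0.0, None)
    raw = np.exp(-s / tau_decay) - np.exp(-s / tau_rise)
    raw[t_ms < t0_ms] = 0.0
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    norm = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return amp * raw / norm


def _trace_pair(
    g_exc: np.ndarray,
    g_inh: np.ndarray,
    params: ConductanceParams,
    stim_times: list[float],
    rng: np.random.Generator,
) -> tuple[CurrentTrace, CurrentTrace]:
    """Currents at the two holding potentials for given E/I conductances.

    I(t) = g(t)·(V_hold − E_rev) in pA; at each holding potential only the
    non-zeroed component contributes.
    """

    def make(hold_mv: float, g: np.ndarray, e_rev: float) -> CurrentTrace:
        i = g * (hold_mv - e_rev)
        if params.noise_sd_pa > 0:
            i = i + rng.normal(0.0, params.noise_sd_pa, size=g.size)
        return CurrentTrace(i, params.sampling_rate_hz, hold_mv, list(stim_times))

    return (
        make(E_REV_INH_MV, g_exc, E_REV_EXC_MV),  # isolates excitation
        make(E_REV_EXC_MV, g_inh, E_REV_INH_MV),  # isolates inhibition
    )


def generate_conductance_trials(
    config: GeneratorConfig,
    profile_exc: EnhancementProfile,
    profile_inh: EnhancementProfile,
    cell_id: str = "cell0000",
    rng: np.random.Generator | None = None,
    amp_scale_exc: float = 1.0,
    amp_scale_inh: float = 1.0,
) -> CellDataset:
    """Voltage-clamp trials for one cell: per stimulus a single E and I
    transient; paired trials are the sum of the two time-shifted single
    transients scaled by ``1 + G_component(isi)``.

    Each trial's ``trace`` is the tuple (sweep at −45 mV, sweep at +5 mV).
    """
    p = config.conductance_params
    rng = rng if rng is not None else _cell_rng(config, 0)
    dt_ms = 1000.0 / p.sampling_rate_hz
    amp_e = p.amp_exc_ns * amp_scale_exc
    amp_i = p.amp_inh_ns * amp_scale_inh

    def single_g(t, t0, comp):
        if comp == "exc":
            return _transient(t, t0, amp_e, p.tau_rise_exc_ms, p.tau_decay_exc_ms)
        return _transient(t, t0, amp_i, p.tau_rise_inh_ms, p.tau_decay_inh_ms)

    trials: list[TrialRecord] = []
    idx = 0
    for modality in ("V", "HB"):
        dur = p.pre_stimulus_ms + p.post_window_ms
        t = np.arange(int(round(dur / dt_ms))) * dt_ms
        g_e = single_g(t, p.pre_stimulus_ms, "exc")
        g_i = single_g(t, p.pre_stimulus_ms, "inh")
        cond = StimulusCondition("single", modality)
        for _ in range(config.n_paired_trials):
            tr = _trace_pair(g_e, g_i, p, [p.pre_stimulus_ms], rng)
            trials.append(TrialRecord(cell_id, idx, cond, trace=tr))
            idx += 1
    for isi in config.isi_grid_ms:
        dur = p.pre_stimulus_ms + isi + p.post_window_ms
        t = np.arange(int(round(dur / dt_ms))) * dt_ms
        stims = [p.pre_stimulus_ms, p.pre_stimulus_ms + isi]
        ge = (single_g(t, stims[0], "exc") + single_g(t, stims[1], "exc")) * (
            1.0 + enhancement_at(profile_exc, isi)
        )
        gi = (single_g(t, stims[0], "inh") + single_g(t, stims[1], "inh")) * (
            1.0 + enhancement_at(profile_inh, isi)
        )
        cond = StimulusCondition("paired", "V", "HB", float(isi))
        for _ in range(config.n_paired_trials):
            tr = _trace_pair(ge, gi, p, stims, rng)
            trials.append(TrialRecord(cell_id, idx, cond, trace=tr))
            idx += 1
    ds = CellDataset(cell_id, config.stage_group, config.drug, trials)
    ds.profile_exc = profile_exc
    ds.profile_inh = profile_inh
    return ds


def generate_conductance_population(
    config: GeneratorConfig,
    exc_gain_mean: float = 1.0,
    inh_gain_mean: float = 1.0,
    gain_sd: float = 0.15,
    shared_factor_sd: float = 0.5,
) -> list[CellDataset]:
    """Population of conductance-trial cells with correlated per-cell E and
    I enhancement gains.

    A shared per-cell factor multiplies both component gains, producing the
    positive E-vs-I correlation seen across cells; the component means set
    the E:I enhancement ratio (stage-dependent in the presets of the
    experiments this emulates).
    """
    cells = []
    for i in range(config.n_cells):
        rng = _cell_rng(config, i)
        shared = max(rng.normal(1.0, shared_factor_sd), 0.2)
        pd_ = config.profile_distribution
        preferred = float(rng.choice(pd_.preferred_isi_choices))
        width = float(max(rng.normal(pd_.width_mean_ms, pd_.width_sd_ms), 10.0))
        g_e = max(shared * exc_gain_mean + rng.normal(0, gain_sd), 0.05)
        g_i = max(shared * inh_gain_mean + rng.normal(0, gain_sd), 0.05)
        prof_e = EnhancementProfile(g_e, preferred, width, 0.0)
        prof_i = EnhancementProfile(g_i, preferred, width, 0.0)
        cells.append(
            generate_conductance_trials(
                config, prof_e, prof_i, cell_id=f"cell{i:04d}", rng=rng
            )
        )
    return cells
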