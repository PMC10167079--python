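"""Parametric simulation of multi-participant, multi-group epoched ERP data.

The generative model is the standard additive evoked-response form: every
trial is a fixed participant-level ERP template (a sum of Gaussian-envelope
components, each with a fixed spatial topography) plus 1/f background noise.
This is exactly the signal model assumed by xDAWN-style spatial filtering,
which makes the simulator a ground-truth test bed for the decoding pipeline:
component amplitudes, latencies, their age-group modulation and their
congruent/incongruent modulation are all known by construction.

Defaults emulate a six-age-group flanker study: group sizes and per-condition
trial-count distributions follow the study's sample table, epochs span
-100..800 ms at 256 Hz over 32 channels (10-20 names), and the classic
visual ERP sequence P1/N1 (occipital), N2 (fronto-central) and P3 (parietal)
carries the structure. Children and the two oldest groups receive delayed,
larger early components (the u-shaped lifespan pattern), and the
condition-discriminative effect (larger incongruent N2, delayed P3) is
shifted 150 ms later in those groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ComponentSpec",
    "TrialCountSpec",
    "GroupSpec",
    "BehavioralSpec",
    "SimConfig",
    "EpochSet",
    "BIOSEMI32_CHANNELS",
    "gaussian_topography",
    "make_noise",
    "make_default_config",
    "make_scaled_config",
    "make_null_config",
    "simulate_participant",
    "simulate_dataset",
]

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CONDITIONS = (CONGRUENT, INCONGRUENT)

# Approximate 2D head positions (x: left->right, y: posterior->anterior) for
# the 32-channel BioSemi 10-20 layout; used only to build smooth topographies.
BIOSEMI32_CHANNELS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "AF3": (-0.35, 0.78), "AF4": (0.35, 0.78),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.58),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.30), "FC1": (-0.25, 0.28), "FC2": (0.25, 0.28),
    "FC6": (0.69, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.69, -0.30), "CP1": (-0.25, -0.28), "CP2": (0.25, -0.28),
    "CP6": (0.69, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.58),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.78), "PO4": (0.35, -0.78),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.97), "O2": (0.31, -0.95),
}


def gaussian_topography(center: str, ch_names: list[str],
                        sigma: float = 0.55) -> np.ndarray:
    """Unit-norm spatial weight vector: Gaussian falloff around an electrode.

    ``center`` must be a 10-20 name present in :data:`BIOSEMI32_CHANNELS`;
    ``ch_names`` selects (a subset of) that layout.
    """
    cx, cy = BIOSEMI32_CHANNELS[center]
    w = np.empty(len(ch_names))
    for i, name in enumerate(ch_names):
        x, y = BIOSEMI32_CHANNELS[name]
        w[i] = math.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
    return w / np.linalg.norm(w)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: a Gaussian temporal envelope with fixed topography.

    Amplitudes are in microvolts (signed: N-components negative), latencies
    and widths in milliseconds. ``latency_sd``/``amplitude_sd`` are
    between-participant jitters; ``condition_delta_*`` describe how the
    component changes on incongruent trials (e.g. a larger N2, a delayed P3).
    """

    name: str
    peak_latency: float
    amplitude: float
    width: float
    topography: np.ndarray
    latency_sd: float = 0.0
    amplitude_sd: float = 0.0
    condition_delta_amplitude: float = 0.0
    condition_delta_latency: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("component width must be > 0")
        topo = np.asarray(self.topography, dtype=float)
        nrm = np.linalg.norm(topo)
        if nrm == 0:
            raise ValueError("topography must be nonzero")
        if abs(nrm - 1.0) > 1e-8:
            topo = topo / nrm
        object.__setattr__(self, "topography", topo)


@dataclass(frozen=True)
class TrialCountSpec:
    """Truncated-normal distribution of per-condition trial counts."""

    mean: float
    sd: float
    min: int
    max: int

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError("trial counts require min <= mean <= max")


@dataclass(frozen=True)
class GroupSpec:
    """An age group: size, trial-count distributions, ERP modulation.

    ``component_overrides`` maps a component name to
    ``(latency offset in ms, amplitude scale)``; ``condition_shift_ms``
    translates the condition-discriminative (incongruent-minus-congruent)
    signature of every component in time, modelling groups whose conflict
    effect arrives later.
    """

    name: str
    n_participants: int
    trial_counts: dict[str, TrialCountSpec]
    component_overrides: dict[str, tuple[float, float]] = field(
        default_factory=dict)
    condition_shift_ms: float = 0.0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be > 0")
        missing = [c for c in CONDITIONS if c not in self.trial_counts]
        if missing:
            raise ValueError(f"trial_counts missing conditions {missing}")


@dataclass(frozen=True)
class BehavioralSpec:
    """Log-normal reaction times and per-condition error rates.

    ``rt_median_ms`` maps group name to the congruent-trial median RT;
    incongruent medians are multiplied by ``incongruent_rt_factor``
    (the flanker interference effect). The log-normal shape parameter is
    derived from the coefficient of variation ``rt_sd_ms / median``.
    """

    rt_median_ms: dict[str, float]
    rt_sd_ms: float = 120.0
    error_rate: dict[str, float] = field(
        default_factory=lambda: {CONGRUENT: 0.04, INCONGRUENT: 0.08})
    incongruent_rt_factor: float = 1.08

    def __post_init__(self):
        for cond, e in self.error_rate.items():
            if not 0 <= e < 1:
                raise ValueError(f"error_rate[{cond}] must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Complete description of a simulated dataset."""

    sfreq: float
    ch_names: list[str]
    epoch_window: tuple[float, float]       # (start ms, end ms)
    noise_sd: float
    noise_exponent: float
    snr_scale: float
    seed: int
    groups: list[GroupSpec]
    components: list[ComponentSpec]
    behavioral: BehavioralSpec

    def __post_init__(self):
        if self.sfreq <= 0:
            raise ValueError("sfreq must be > 0")
        start, end = self.epoch_window
        if not (start < 0 < end):
            raise ValueError("epoch_window must straddle stimulus onset")
        for c in self.components:
            if not (start <= c.peak_latency <= end):
                raise ValueError(
                    f"component {c.name} latency outside the epoch window")
            if len(c.topography) != self.n_channels:
                raise ValueError(
                    f"component {c.name} topography length != n_channels")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)


# ---------------------------------------------------------------------------
# the epoch container: the pipeline's universal currency
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched trials of one participant: trials x channels x samples (µV).

    ``times`` are seconds relative to stimulus onset, strictly increasing and
    uniformly spaced at 1/sfreq. Per-trial metadata: condition label,
    response correctness and reaction time (ms).
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    trial_labels: np.ndarray
    correctness: np.ndarray
    rt: np.ndarray
    participant_id: str
    group_label: str
    ch_names: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.trial_labels = np.asarray(self.trial_labels)
        self.correctness = np.asarray(self.correctness, dtype=bool)
        self.rt = np.asarray(self.rt, dtype=np.float64)
        n_trials, n_ch, n_samp = self.data.shape
        if len(self.times) != n_samp:
            raise ValueError("times length does not match data samples")
        for name, vec in (("trial_labels", self.trial_labels),
                          ("correctness", self.correctness),
                          ("rt", self.rt)):
            if len(vec) != n_trials:
                raise ValueError(f"{name} length does not match trial count")
        if len(self.ch_names) != n_ch:
            raise ValueError("ch_names length does not match channel count")
        if n_samp > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sfreq,
                                                  rtol=1e-6, atol=1e-9):
                raise ValueError("times must increase uniformly at 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        """Return a copy restricted to the given trial indices/boolean mask."""
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index].copy(),
            sfreq=self.sfreq,
            times=self.times.copy(),
            trial_labels=self.trial_labels[index].copy(),
            correctness=self.correctness[index].copy(),
            rt=self.rt[index].copy(),
            participant_id=self.participant_id,
            group_label=self.group_label,
            ch_names=list(self.ch_names),
        )

    def copy(self) -> "EpochSet":
        return self.select_trials(np.arange(self.n_trials))


def epoch_times(epoch_window: tuple[float, float], sfreq: float) -> np.ndarray:
    """Sample grid covering the window: k = floor(start*f)..floor(end*f).

    Both edges are floored onto the integer sample grid (k/sfreq seconds),
    so -100..800 ms at 256 Hz yields samples -26..204 — 231 samples.
    """
    start_s, end_s = epoch_window[0] / 1000.0, epoch_window[1] / 1000.0
    k0 = math.floor(start_s * sfreq + 1e-9)
    k1 = math.floor(end_s * sfreq + 1e-9)
    return np.arange(k0, k1 + 1) / sfreq


# ---------------------------------------------------------------------------
# noise and signal construction
# ---------------------------------------------------------------------------

def make_noise(n_channels: int, n_samples: int, sfreq: float,
               exponent: float, sd: float,
               rng: int | np.random.Generator) -> np.ndarray:
    """Channels x samples noise with a 1/f**exponent power spectrum.

    Generated by shaping white Gaussian noise in the frequency domain and
    rescaling each channel to zero mean and standard deviation ``sd``.
    ``exponent`` = 0 gives white noise; 1 gives pink (EEG-like) noise.
    """
    if n_samples <= 1:
        raise ValueError("n_samples must be > 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(rng)
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    s = x.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return x * (sd / s)


def _gauss(times_ms: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - latency) / width) ** 2)


def _condition_templates(config: SimConfig, group: GroupSpec,
                         rng: np.random.Generator
                         ) -> dict[str, np.ndarray]:
    """Participant-level noise-free templates for both conditions.

    The congruent template is the sum of components at this participant's
    drawn latencies/amplitudes. The incongruent template adds, per component,
    the analytic difference produced by the condition deltas, translated in
    time by the group's ``condition_shift_ms``.
    """
    times_ms = epoch_times(config.epoch_window, config.sfreq) * 1000.0
    n_samp = len(times_ms)
    cong = np.zeros((config.n_channels, n_samp))
    incong = np.zeros_like(cong)
    for comp in config.components:
        lat_off, amp_scale = group.component_overrides.get(comp.name,
                                                           (0.0, 1.0))
        lat = (comp.peak_latency + lat_off
               + rng.normal(0.0, comp.latency_sd))
        amp = ((comp.amplitude + rng.normal(0.0, comp.amplitude_sd))
               * amp_scale * config.snr_scale)
        base = amp * np.outer(comp.topography, _gauss(times_ms, lat,
                                                      comp.width))
        cong += base
        incong += base
        d_amp = comp.condition_delta_amplitude * config.snr_scale
        d_lat = comp.condition_delta_latency
        if d_amp != 0.0 or d_lat != 0.0:
            # incongruent-minus-congruent signature, shifted in time for
            # groups whose conflict effect arrives later
            t_shift = times_ms - group.condition_shift_ms
            diff = ((amp + d_amp) * _gauss(t_shift, lat + d_lat, comp.width)
                    - amp * _gauss(t_shift, lat, comp.width))
            incong += np.outer(comp.topography, diff)
    return {CONGRUENT: cong, INCONGRUENT: incong}


def _draw_trial_count(spec: TrialCountSpec, rng: np.random.Generator) -> int:
    """Rounded truncated-normal draw (redraw, then clip as a last resort)."""
    for _ in range(1000):
        n = int(round(rng.normal(spec.mean, spec.sd)))
        if spec.min <= n <= spec.max:
            return n
    return int(np.clip(round(spec.mean), spec.min, spec.max))


def simulate_participant(config: SimConfig, group: GroupSpec,
                         seed: int, participant_id: str = "p0") -> EpochSet:
    """Simulate one participant's epochs, behavior included.

    Trials are the participant's condition template plus fresh 1/f noise;
    reaction times are log-normal (group median, flanker interference factor
    on incongruent trials) and correctness is Bernoulli per condition.
    """
    if group.name not in {g.name for g in config.groups}:
        raise ValueError(f"group {group.name!r} not in config")
    rng = np.random.default_rng(seed)
    templates = _condition_templates(config, group, rng)
    times = epoch_times(config.epoch_window, config.sfreq)
    n_samp = len(times)

    labels: list[str] = []
    for cond in CONDITIONS:
        n = _draw_trial_count(group.trial_counts[cond], rng)
        if n <= 0:
            raise ValueError(f"non-positive trial count for {cond}")
        labels.extend([cond] * n)
    labels_arr = np.array(labels)
    rng.shuffle(labels_arr)
    n_trials = len(labels_arr)

    data = np.empty((n_trials, config.n_channels, n_samp))
    for i, cond in enumerate(labels_arr):
        data[i] = templates[cond] + make_noise(
            config.n_channels, n_samp, config.sfreq,
            config.noise_exponent, config.noise_sd, rng)

    beh = config.behavioral
    median = beh.rt_median_ms.get(group.name,
                                  float(np.mean(list(beh.rt_median_ms.values()))))
    cv = beh.rt_sd_ms / median
    sigma_log = math.sqrt(math.log(1.0 + cv**2))
    rts = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    for i, cond in enumerate(labels_arr):
        med = median * (beh.incongruent_rt_factor
                        if cond == INCONGRUENT else 1.0)
        rts[i] = med * math.exp(rng.normal(0.0, sigma_log))
        correct[i] = rng.random() >= beh.error_rate.get(cond, 0.0)

    return EpochSet(data=data, sfreq=config.sfreq, times=times,
                    trial_labels=labels_arr, correctness=correct, rt=rts,
                    participant_id=participant_id, group_label=group.name,
                    ch_names=list(config.ch_names))


def participant_seed(master_seed: int, group_index: int,
                     participant_index: int) -> int:
    """Deterministic per-participant seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, group_index, participant_index])
    return int(ss.generate_state(1)[0])


def simulate_dataset(config: SimConfig) -> list[EpochSet]:
    """One EpochSet per participant per group, deterministically seeded."""
    dataset: list[EpochSet] = []
    for gi, group in enumerate(config.groups):
        for pi in range(group.n_participants):
            pid = f"{group.name}-{pi:03d}"
            dataset.append(simulate_participant(
                config, group, participant_seed(config.seed, gi, pi), pid))
    return dataset


# ---------------------------------------------------------------------------
# default configurations (the study conditions)
# ---------------------------------------------------------------------------

# Group sample sizes and per-condition trial-count distributions
# (mean, sd, min, max), incongruent then congruent.
_GROUP_TABLE: list[tuple[str, int, tuple, tuple]] = [
    ("children", 46, (70.91, 15.30, 36, 98), (65.78, 13.27, 38, 94)),
    ("young", 39, (65.49, 24.31, 40, 109), (63.49, 22.59, 36, 109)),
    ("early-ma", 21, (97.05, 10.33, 79, 125), (92.90, 8.39, 75, 106)),
    ("late-ma", 25, (95.12, 10.65, 71, 109), (94.88, 9.01, 80, 113)),
    ("old<75", 40, (58.88, 19.73, 40, 111), (56.58, 14.42, 41, 92)),
    ("veryold>75", 38, (69.26, 21.07, 39, 105), (65.95, 21.60, 36, 101)),
]

# groups with delayed/enlarged early components and a late conflict effect
U_SHAPE_GROUPS = ("children", "old<75", "veryold>75")

_RT_MEDIANS = {"children": 650.0, "young": 450.0, "early-ma": 480.0,
               "late-ma": 520.0, "old<75": 580.0, "veryold>75": 620.0}


def _default_components(ch_names: list[str],
                        n2_latency: float = 250.0,
                        n2_delta: float = -3.0,
                        p3_delta_latency: float = 30.0) -> list[ComponentSpec]:
    return [
        ComponentSpec("P1", peak_latency=100.0, amplitude=5.0, width=25.0,
                      latency_sd=8.0, amplitude_sd=1.0,
                      topography=gaussian_topography("Oz", ch_names)),
        ComponentSpec("N1", peak_latency=160.0, amplitude=-6.0, width=30.0,
                      latency_sd=10.0, amplitude_sd=1.2,
                      topography=gaussian_topography("O2", ch_names)),
        ComponentSpec("N2", peak_latency=n2_latency, amplitude=-4.0,
                      width=40.0, latency_sd=12.0, amplitude_sd=1.0,
                      condition_delta_amplitude=n2_delta,
                      topography=gaussian_topography("Fz", ch_names)),
        ComponentSpec("P3", peak_latency=400.0, amplitude=8.0, width=80.0,
                      latency_sd=20.0, amplitude_sd=1.5,
                      condition_delta_latency=p3_delta_latency,
                      topography=gaussian_topography("Pz", ch_names)),
    ]


def _groups_from_table(table, overrides, shift_groups, shift_ms):
    groups = []
    for name, n, inc, cong in table:
        groups.append(GroupSpec(
            name=name, n_participants=n,
            trial_counts={INCONGRUENT: TrialCountSpec(*inc),
                          CONGRUENT: TrialCountSpec(*cong)},
            component_overrides=dict(overrides) if name in shift_groups else {},
            condition_shift_ms=shift_ms if name in shift_groups else 0.0,
        ))
    return groups


def make_default_config(seed: int = 0) -> SimConfig:
    """The full-scale study conditions: 209 participants, 6 groups, 256 Hz.

    Children and the two oldest groups get +80 ms latency and x1.4 amplitude
    on P1/N1 (the u-shaped lifespan pattern) and a +150 ms shift of the
    condition-discriminative N2/P3 signature.
    """
    ch_names = list(BIOSEMI32_CHANNELS)
    return SimConfig(
        sfreq=256.0,
        ch_names=ch_names,
        epoch_window=(-100.0, 800.0),
        noise_sd=3.0,
        noise_exponent=1.0,
        snr_scale=1.0,
        seed=seed,
        groups=_groups_from_table(
            _GROUP_TABLE,
            overrides={"P1": (80.0, 1.4), "N1": (80.0, 1.4)},
            shift_groups=U_SHAPE_GROUPS, shift_ms=150.0),
        components=_default_components(ch_names),
        behavioral=BehavioralSpec(rt_median_ms=dict(_RT_MEDIANS)),
    )


def make_scaled_config(seed: int = 0, n_per_group: int = 12,
                       trials_per_condition: int = 50,
                       sfreq: float = 64.0,
                       effect_latency: float = 200.0,
                       effect_shift: float = 200.0,
                       n_groups: int = 6) -> SimConfig:
    """Desk-scale study conditions for calibration and recovery runs.

    Same six groups at 12 participants each, 100 trials per participant,
    64 Hz; the condition-discriminative N2 effect sits at 200 ms for the
    adult groups and is shifted to 400 ms for children and the old groups.
    """
    ch_names = list(BIOSEMI32_CHANNELS)
    counts = TrialCountSpec(float(trials_per_condition), 0.0,
                            trials_per_condition, trials_per_condition)
    table = [(name, n_per_group, (counts.mean, 0.0, counts.min, counts.max),
              (counts.mean, 0.0, counts.min, counts.max))
             for name, _, _, _ in _GROUP_TABLE[:n_groups]]
    return SimConfig(
        sfreq=sfreq,
        ch_names=ch_names,
        epoch_window=(-100.0, 800.0),
        noise_sd=3.0,
        noise_exponent=1.0,
        snr_scale=1.0,
        seed=seed,
        groups=_groups_from_table(
            table,
            overrides={"P1": (80.0, 1.4), "N1": (80.0, 1.4)},
            shift_groups=U_SHAPE_GROUPS, shift_ms=effect_shift),
        components=_default_components(ch_names, n2_latency=effect_latency,
                                       p3_delta_latency=0.0),
        behavioral=BehavioralSpec(rt_median_ms=dict(_RT_MEDIANS),
                                  error_rate={CONGRUENT: 0.0,
                                              INCONGRUENT: 0.0}),
    )


def make_null_config(seed: int = 0, n_participants: int = 40,
                     trials_per_condition: int = 50,
                     sfreq: float = 32.0,
                     ch_names: list[str] | None = None) -> SimConfig:
    """No condition effect anywhere: the type-I-error study conditions."""
    if ch_names is None:
        ch_names = ["Fz", "Cz", "Pz", "Oz", "C3", "C4", "P3", "P4"]
    counts = TrialCountSpec(float(trials_per_condition), 0.0,
                            trials_per_condition, trials_per_condition)
    components = [replace(c, condition_delta_amplitude=0.0,
                          condition_delta_latency=0.0)
                  for c in _default_components(ch_names)]
    group = GroupSpec(name="null", n_participants=n_participants,
                      trial_counts={INCONGRUENT: counts, CONGRUENT: counts})
    return SimConfig(
        sfreq=sfreq, ch_names=ch_names, epoch_window=(-100.0, 800.0),
        noise_sd=3.0, noise_exponent=1.0, snr_scale=1.0, seed=seed,
        groups=[group], components=components,
        behavioral=BehavioralSpec(rt_median_ms={"null": 500.0},
                                  error_rate={CONGRUENT: 0.0,
                                              INCONGRUENT: 0.0}),
    )
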