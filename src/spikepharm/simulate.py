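"""Synthetic spike trains, voltage traces and cohorts with retained ground truth.

The generator emulates a 120-minute acute-pharmacology session from anaesthetised
rodent extracellular recording: 15 minutes of baseline activity, an intraperitoneal
injection at t = 900 s, then 105 minutes of continued recording (7200 s total).
Each unit is an inhomogeneous Poisson process with an absolute refractory period.
A drug response is a multiplicative step (optionally a linear ramp) in the firing
rate at a configurable onset time after the injection: ``effect_multiplier`` 2.8
means a +180 % rate increase, 0.2 means an 80 % reduction, 1.0 is a null unit.

Spike times are drawn by thinning a dominating homogeneous Poisson process at the
maximum of the rate function, which is exact for the piecewise-linear rate profiles
used here; the refractory period is then enforced by greedy deletion.  A single
cohort seed fans out to per-unit substreams keyed by unit index, so any one unit
can be regenerated bit-for-bit from its own ground-truth config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Session layout: 15 min baseline, injection, 105 min post-injection follow-up.
DEFAULT_INJECTION_TIME = 900.0
DEFAULT_SESSION_DURATION = 7200.0
# Absolute refractory period (s); physiological floor that keeps ISI statistics sane.
DEFAULT_REFRACTORY = 0.002
# Spontaneous-rate cap (spikes/s) accepting a unit as putative pyramidal.
PYRAMIDAL_RATE_CAP = 8.0

__all__ = [
    "DEFAULT_INJECTION_TIME",
    "DEFAULT_SESSION_DURATION",
    "DEFAULT_REFRACTORY",
    "PYRAMIDAL_RATE_CAP",
    "SimulationConfig",
    "SpikeTrain",
    "VoltageTrace",
    "EffectStratum",
    "GroupSpec",
    "PRESETS",
    "enforce_refractory",
    "simulate_homogeneous_train",
    "simulate_drug_response_train",
    "synthesize_voltage",
    "generate_cohort",
    "ground_truth_label",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated unit.

    Parameters
    ----------
    baseline_rate : float
        Pre-onset firing rate in spikes/s.  Pyramidal presets stay at or below
        8 spikes/s, the spontaneous-rate inclusion cap.
    effect_multiplier : float
        Post-onset rate factor relative to baseline.  1.0 is a null unit,
        2.8 encodes a +180 % excitatory response, 0.2 an 80 % reduction.
    onset_time : float
        Response onset in seconds *after* the injection.
    ramp_duration : float
        Seconds over which the rate ramps linearly from baseline to the
        post-onset level; 0 gives an instantaneous step.
    refractory : float
        Absolute refractory period in seconds.
    injection_time, session_duration : float
        Session layout in seconds.
    seed : int
        Seed for the unit's private random stream.
    """

    baseline_rate: float
    effect_multiplier: float = 1.0
    onset_time: float = 3000.0
    ramp_duration: float = 0.0
    refractory: float = DEFAULT_REFRACTORY
    injection_time: float = DEFAULT_INJECTION_TIME
    session_duration: float = DEFAULT_SESSION_DURATION
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_rate >= 0:
            raise ValueError(f"baseline_rate must be >= 0, got {self.baseline_rate}")
        if not self.effect_multiplier >= 0:
            raise ValueError(
                f"effect_multiplier must be >= 0, got {self.effect_multiplier}"
            )
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if not 0 <= self.injection_time <= self.session_duration:
            raise ValueError("injection_time must lie within the session")
        if not 0 <= self.onset_time <= self.session_duration - self.injection_time:
            raise ValueError(
                "onset_time must lie within the post-injection window "
                f"[0, {self.session_duration - self.injection_time}], got {self.onset_time}"
            )
        if self.ramp_duration < 0:
            raise ValueError("ramp_duration must be >= 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    @property
    def onset_abs(self) -> float:
        """Onset time on the session clock (seconds from recording start)."""
        return self.injection_time + self.onset_time

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous firing rate (spikes/s) at session times ``t``."""
        t = np.asarray(t, dtype=float)
        if self.ramp_duration > 0:
            frac = np.clip((t - self.onset_abs) / self.ramp_duration, 0.0, 1.0)
        else:
            frac = (t >= self.onset_abs).astype(float)
        return self.baseline_rate * (1.0 + frac * (self.effect_multiplier - 1.0))

    @property
    def max_rate(self) -> float:
        return self.baseline_rate * max(1.0, self.effect_multiplier)


@dataclass
class SpikeTrain:
    """Ordered spike times (s) for one unit over one session."""

    times: np.ndarray
    duration: float
    injection_time: float = DEFAULT_INJECTION_TIME
    unit_id: str = "unit"
    group: str | None = None
    ground_truth: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def count(self, t_start: float, t_end: float) -> int:
        """Number of spikes in the half-open window [t_start, t_end)."""
        i0, i1 = np.searchsorted(self.times, [t_start, t_end])
        return int(i1 - i0)

    def mean_rate(self, t_start: float = 0.0, t_end: float | None = None) -> float:
        """Mean firing rate (spikes/s) over [t_start, t_end)."""
        if t_end is None:
            t_end = self.duration
        if t_end <= t_start:
            raise ValueError("t_end must exceed t_start")
        return self.count(t_start, t_end) / (t_end - t_start)


@dataclass
class VoltageTrace:
    """Uniformly sampled extracellular signal, optionally with ground truth."""

    samples: np.ndarray
    sampling_rate: float
    noise_sd: float | None = None
    true_spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


def enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedily delete spikes closer than ``refractory`` to the last kept spike.

    Only runs of consecutive sub-refractory intervals need the sequential pass:
    once a gap >= refractory is met the greedy scan re-synchronises, so the
    common case (sparse violations) stays vectorised.
    """
    times = np.asarray(times, dtype=float)
    if refractory <= 0 or times.size < 2:
        return times
    diffs = np.diff(times)
    viol = np.flatnonzero(diffs < refractory)
    if viol.size == 0:
        return times
    keep = np.ones(times.size, dtype=bool)
    runs = np.split(viol, np.flatnonzero(np.diff(viol) > 1) + 1)
    for run in runs:
        last = times[run[0]]  # first spike of the run is always kept
        for j in range(run[0] + 1, run[-1] + 2):
            if times[j] - last < refractory:
                keep[j] = False
            else:
                last = times[j]
    return times[keep]


def _thin_poisson(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample the inhomogeneous process by thinning a dominating homogeneous one."""
    lam = config.max_rate
    duration = config.session_duration
    n_cand = rng.poisson(lam * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    u = rng.uniform(size=n_cand)
    times = cand[u * lam < config.rate_at(cand)]
    return enforce_refractory(times, config.refractory)


def simulate_homogeneous_train(
    rate: float,
    duration: float,
    refractory: float = DEFAULT_REFRACTORY,
    seed: int = 0,
    *,
    injection_time: float = DEFAULT_INJECTION_TIME,
    unit_id: str = "unit",
) -> SpikeTrain:
    """Stationary Poisson spike train with dead time (the null model).

    Equivalent to :func:`simulate_drug_response_train` with ``effect_multiplier``
    1.0 and the same seed — both consume the identical thinning stream.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    config = SimulationConfig(
        baseline_rate=rate,
        effect_multiplier=1.0,
        onset_time=0.0,
        refractory=refractory,
        injection_time=min(injection_time, duration),
        session_duration=duration,
        seed=seed,
    )
    return simulate_drug_response_train(config, unit_id=unit_id)


def simulate_drug_response_train(
    config: SimulationConfig,
    *,
    unit_id: str = "unit",
    group: str | None = None,
) -> SpikeTrain:
    """Simulate one session: baseline rate, then a step/ramp response at onset."""
    rng = np.random.default_rng(config.seed)
    times = _thin_poisson(config, rng)
    return SpikeTrain(
        times=times,
        duration=config.session_duration,
        injection_time=config.injection_time,
        unit_id=unit_id,
        group=group,
        ground_truth=config,
    )


def synthesize_voltage(
    train: SpikeTrain,
    peak_amplitude: float = 6.0,
    waveform_width: float = 0.001,
    noise_sd: float = 1.0,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
) -> VoltageTrace:
    """Render a spike train as a noisy extracellular voltage trace.

    A biphasic (one-cycle sine) template of total width ``waveform_width`` and
    peak |amplitude| ``peak_amplitude`` is added at each spike time on white
    Gaussian noise of SD ``noise_sd``; the positive peak is aligned to the spike
    time.  The constructed signal-to-noise ratio is peak_amplitude / noise_sd.
    """
    if waveform_width <= 0:
        raise ValueError("waveform_width must be positive")
    if sampling_rate < 10.0 / waveform_width:
        raise ValueError(
            "waveform under-sampled: need sampling_rate >= 10/waveform_width "
            f"= {10.0 / waveform_width:.1f} Hz, got {sampling_rate}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(train.duration * sampling_rate))
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    n_w = int(round(waveform_width * sampling_rate))
    tt = np.arange(n_w) / sampling_rate
    template = np.sin(2.0 * np.pi * tt / waveform_width)
    template = peak_amplitude * template / np.max(np.abs(template))
    peak_offset = int(np.argmax(np.abs(template)))

    for t in train.times:
        i0 = int(round(t * sampling_rate)) - peak_offset
        lo, hi = max(i0, 0), min(i0 + n_w, n)
        if hi > lo:
            samples[lo:hi] += template[lo - i0 : hi - i0]
    return VoltageTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        noise_sd=noise_sd,
        true_spike_times=train.times.copy(),
    )


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectStratum:
    """``n`` units whose effect multiplier is drawn uniform on [lo, hi]."""

    n: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.n < 0 or self.lo < 0 or self.hi < self.lo:
            raise ValueError(f"invalid effect stratum {self}")


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: effect strata plus onset and baseline ranges.

    ``onset_min`` is the (lo, hi) response-onset window in minutes after the
    injection; onsets are drawn uniformly on it.  Baseline rates are drawn
    uniform on ``baseline_hz``, kept comfortably under the 8 spikes/s pyramidal
    cap so that sampling noise in a 15-minute baseline cannot push a simulated
    pyramidal unit over the inclusion boundary.
    """

    label: str
    strata: tuple[EffectStratum, ...]
    onset_min: tuple[float, float] = (42.0, 64.0)
    baseline_hz: tuple[float, float] = (2.0, 7.5)

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("group needs at least one effect stratum")
        if self.n_neurons < 1:
            raise ValueError("group needs at least one neuron")
        if not 0 <= self.onset_min[0] <= self.onset_min[1]:
            raise ValueError(f"invalid onset window {self.onset_min}")

    @property
    def n_neurons(self) -> int:
        return sum(s.n for s in self.strata)


def _pct(lo: float, hi: float, n: int) -> EffectStratum:
    """Stratum from a percent-change range (+180 -> multiplier 2.8)."""
    return EffectStratum(n, 1.0 + lo / 100.0, 1.0 + hi / 100.0)


#: Group presets reproducing the reported per-group response structure:
#: counts of excited/inhibited/unaffected units, percent-change strata and
#: onset windows for the saline control and the 5/10/15 mg/kg dose groups.
PRESETS: dict[str, GroupSpec] = {
    "saline": GroupSpec(
        "saline",
        strata=(
            _pct(25, 70, 3),     # 3 excited, +25..70 %
            _pct(-70, -60, 2),   # 2 inhibited, 60..70 % reduction
            _pct(0, 0, 10),      # 10 unaffected
        ),
        onset_min=(47.0, 56.0),
    ),
    "don5": GroupSpec(
        "don5",
        strata=(
            _pct(25, 70, 3),     # magnitudes not reported for this dose;
            _pct(-70, -60, 3),   # saline-like modest effects assumed
            _pct(0, 0, 10),
        ),
        onset_min=(47.0, 64.0),
    ),
    "don10": GroupSpec(
        "don10",
        strata=(
            _pct(100, 115, 3),
            _pct(160, 180, 4),
            _pct(346, 346, 1),
            _pct(-80, -80, 1),
            _pct(0, 0, 5),
        ),
        onset_min=(47.0, 56.0),
    ),
    "don15": GroupSpec(
        "don15",
        strata=(
            _pct(120, 190, 4),
            _pct(240, 270, 3),
            _pct(310, 420, 3),
            _pct(-65, -55, 2),
            _pct(0, 0, 4),
        ),
        onset_min=(42.0, 61.0),
    ),
}


def ground_truth_label(config: SimulationConfig) -> str:
    """True response class implied by a simulation config."""
    if config.effect_multiplier > 1.0:
        return "excitatory"
    if config.effect_multiplier < 1.0:
        return "inhibitory"
    return "unaffected"


def generate_cohort(
    group_specs: Sequence[GroupSpec | str],
    seed: int = 0,
    *,
    injection_time: float = DEFAULT_INJECTION_TIME,
    session_duration: float = DEFAULT_SESSION_DURATION,
) -> list[SpikeTrain]:
    """Simulate every unit of one or more groups, ground truth attached.

    The global ``seed`` fans out to per-unit substreams via
    ``SeedSequence(seed, spawn_key=(unit_index,))``, so each unit is
    reproducible from the cohort seed and its index alone, and also from the
    ``seed`` stored in its own ground-truth config.
    """
    if not group_specs:
        raise ValueError("group_specs must be nonempty")
    specs = [PRESETS[g] if isinstance(g, str) else g for g in group_specs]
    trains: list[SpikeTrain] = []
    unit_index = 0
    for spec in specs:
        for stratum in spec.strata:
            for _ in range(stratum.n):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(unit_index,))
                rng = np.random.default_rng(ss)
                baseline = rng.uniform(*spec.baseline_hz)
                multiplier = rng.uniform(stratum.lo, stratum.hi)
                onset_s = rng.uniform(*spec.onset_min) * 60.0
                spike_seed = int(rng.integers(2**31))
                config = SimulationConfig(
                    baseline_rate=baseline,
                    effect_multiplier=multiplier,
                    onset_time=onset_s,
                    injection_time=injection_time,
                    session_duration=session_duration,
                    seed=spike_seed,
                )
                trains.append(
                    simulate_drug_response_train(
                        config,
                        unit_id=f"{spec.label}-{unit_index:03d}",
                        group=spec.label,
                    )
                )
                unit_index += 1
    return trains
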