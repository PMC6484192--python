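"""Spike detection from voltage traces: thresholding, height windows, SNR.

The detector mirrors a classic hardware chain: an amplitude threshold (in
multiples of the noise SD, on the absolute signal so negative-going
extracellular spikes need no second code path) finds excursions, each excursion
yields one event at its peak sample, events closer than a dead time are merged
keeping the larger peak, and a window discriminator then assigns events to a
single unit by peak height.  Units whose mean peak height is not more than
``min_snr`` times the background noise SD are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import DEFAULT_INJECTION_TIME, SpikeTrain, VoltageTrace

__all__ = [
    "SpikeEvent",
    "DetectionConfig",
    "estimate_noise_sd",
    "detect_spikes",
    "discriminate_unit",
    "unit_snr",
    "detect_unit",
]


@dataclass(frozen=True)
class SpikeEvent:
    """One threshold excursion: peak sample time (s) and |peak| height."""

    time: float
    peak_height: float


@dataclass(frozen=True)
class DetectionConfig:
    """Detector settings.

    threshold_k
        Detection threshold in multiples of the estimated noise SD.
    threshold_abs
        Absolute threshold in signal units; overrides ``threshold_k`` when set
        (needed e.g. for noiseless traces where the noise SD estimate is 0).
    height_window
        (low, high) peak-height window of the unit discriminator, in signal
        units; ``None`` keeps every event.
    min_snr
        Unit-inclusion criterion: mean peak height must exceed ``min_snr``
        times the noise SD (the ">2 separation from background" rule).
    dead_time
        Minimum event separation in seconds; closer events merge, keeping the
        larger peak (this also fuses the two lobes of a biphasic waveform).
    """

    threshold_k: float = 4.0
    threshold_abs: float | None = None
    height_window: tuple[float, float] | None = None
    min_snr: float = 2.0
    dead_time: float = 0.001

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if self.min_snr <= 0:
            raise ValueError("min_snr must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.height_window is not None:
            low, high = self.height_window
            if not (high > low > 0):
                raise ValueError(
                    f"height_window must satisfy high > low > 0, got {self.height_window}"
                )


def estimate_noise_sd(trace: VoltageTrace) -> float:
    """Robust background-noise SD: scaled median absolute deviation.

    The MAD (scaled to the Gaussian SD) is nearly blind to the sparse,
    large-amplitude spike samples riding on the noise floor.
    """
    if trace.samples.size == 0:
        raise ValueError("cannot estimate noise on an empty trace")
    return float(stats.median_abs_deviation(trace.samples, scale="normal"))


def detect_spikes(
    trace: VoltageTrace, config: DetectionConfig = DetectionConfig()
) -> list[SpikeEvent]:
    """Find threshold excursions of |signal| and return one event per peak.

    Events are ordered by time and at least ``config.dead_time`` apart; when
    two excursions fall within the dead time the larger peak survives.
    """
    x = np.abs(trace.samples)
    if config.threshold_abs is not None:
        threshold = float(config.threshold_abs)
    else:
        threshold = config.threshold_k * estimate_noise_sd(trace)
    above = x > threshold
    if not above.any():
        return []
    # Excursion boundaries: starts where `above` switches on, ends where off.
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]

    events: list[SpikeEvent] = []
    for s, e in zip(starts, stops):
        peak = s + int(np.argmax(x[s:e]))
        cand = SpikeEvent(time=peak / trace.sampling_rate, peak_height=float(x[peak]))
        if events and cand.time - events[-1].time < config.dead_time:
            if cand.peak_height > events[-1].peak_height:
                events[-1] = cand
        else:
            events.append(cand)
    return events


def discriminate_unit(
    events: list[SpikeEvent],
    height_window: tuple[float, float],
    *,
    duration: float,
    injection_time: float = DEFAULT_INJECTION_TIME,
    unit_id: str = "unit",
) -> SpikeTrain:
    """Window discrimination: keep events whose peak height falls in [low, high].

    A pure filter — output spike times are always a subset of the input event
    times, in the same order.
    """
    low, high = height_window
    if not low < high:
        raise ValueError(f"height_window must satisfy low < high, got {height_window}")
    kept = [ev.time for ev in events if low <= ev.peak_height <= high]
    return SpikeTrain(
        times=np.asarray(kept, dtype=float),
        duration=duration,
        injection_time=injection_time,
        unit_id=unit_id,
    )


def unit_snr(events: list[SpikeEvent], noise_sd: float) -> float:
    """Mean spike peak height over the noise SD; NaN when there are no events.

    The pipeline excludes units with SNR <= min_snr (default 2) or with an
    undefined (NaN) SNR.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not events:
        return float("nan")
    return float(np.mean([ev.peak_height for ev in events]) / noise_sd)


def detect_unit(
    trace: VoltageTrace,
    config: DetectionConfig = DetectionConfig(),
    *,
    injection_time: float = DEFAULT_INJECTION_TIME,
    unit_id: str = "unit",
) -> tuple[SpikeTrain, float]:
    """Full detection stage: threshold, discriminate, score SNR.

    Returns the unit's spike train and its SNR (mean retained peak height /
    noise SD, NaN when no event survives).
    """
    noise_sd = estimate_noise_sd(trace)
    events = detect_spikes(trace, config)
    if config.height_window is not None:
        kept = [
            ev
            for ev in events
            if config.height_window[0] <= ev.peak_height <= config.height_window[1]
        ]
    else:
        kept = events
    train = SpikeTrain(
        times=np.asarray([ev.time for ev in kept], dtype=float),
        duration=trace.duration,
        injection_time=injection_time,
        unit_id=unit_id,
    )
    snr = unit_snr(kept, noise_sd) if noise_sd > 0 else float("nan")
    return train, snr
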