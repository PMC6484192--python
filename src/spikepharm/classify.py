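"""Per-neuron response classification against the baseline ±2 SD band.

A unit responds when at least ``run_length`` (default 3) consecutive
post-injection PSTH bins leave the band baseline_mean ± k_sd × baseline_SD
(default k_sd = 2): above the band is excitatory, below is inhibitory.  The
comparison is strict, both directions use the same rule, and when runs of both
signs occur the earlier run decides the label (both are recorded).  Onset
latency is the start of the first qualifying run, in minutes after injection;
percent change is the mean rate over the qualifying bins relative to the
baseline mean.

Inclusion filters applied by the pipeline wrapper: spontaneous baseline rate
<= 8 spikes/s (putative pyramidal), detection SNR > 2 when a voltage stage was
run, and a non-degenerate baseline (zero baseline SD is classified with an SD
floor of one spike per bin but flagged and excluded from group tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BaselineStats, BinnedRate, baseline_statistics, make_psth
from .simulate import PYRAMIDAL_RATE_CAP, SpikeTrain

__all__ = [
    "ClassifierConfig",
    "ResponseClassification",
    "is_pyramidal",
    "classify_response",
    "onset_latency",
    "percent_change",
    "classify_train",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Response-rule settings: band width ``k_sd`` (in baseline SDs), required
    run length in bins, and the SD floor used for zero-variance baselines
    (rate equivalent of one spike per 60-s bin)."""

    k_sd: float = 2.0
    run_length: int = 3
    sd_floor: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")


@dataclass
class ResponseClassification:
    """Outcome of the band rule for one unit.

    ``excitatory_runs`` / ``inhibitory_runs`` hold (start, stop) absolute PSTH
    bin-index ranges (Python half-open) of every qualifying run;
    ``qualifying_bins`` are the bin indices of the winning direction's runs.
    """

    label: str  # "excitatory" | "inhibitory" | "unaffected"
    onset_latency_min: float | None
    percent_change: float | None
    qualifying_bins: list[int]
    excitatory_runs: list[tuple[int, int]]
    inhibitory_runs: list[tuple[int, int]]
    baseline: BaselineStats
    bin_width: float
    t_start: float
    degenerate_baseline: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None
    unit_id: str = "unit"
    group: str | None = None


def is_pyramidal(baseline_mean_rate: float, cap: float = PYRAMIDAL_RATE_CAP) -> bool:
    """Putative-pyramidal inclusion: spontaneous rate of ``cap`` spikes/s or
    less (inclusive boundary)."""
    if baseline_mean_rate < 0:
        raise ValueError(f"rate must be >= 0, got {baseline_mean_rate}")
    return baseline_mean_rate <= cap


def _qualifying_runs(mask: np.ndarray, run_length: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= run_length, as (start, stop) pairs."""
    runs: list[tuple[int, int]] = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= run_length:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def classify_response(
    psth: BinnedRate,
    baseline: BaselineStats,
    injection_time: float,
    config: ClassifierConfig = ClassifierConfig(),
) -> ResponseClassification:
    """Apply the ±k_sd·SD / run_length-consecutive-bins rule to one PSTH."""
    sd = baseline.sd_rate
    degenerate = sd == 0.0
    if degenerate:
        sd = config.sd_floor
    upper = baseline.mean_rate + config.k_sd * sd
    lower = baseline.mean_rate - config.k_sd * sd

    post = np.flatnonzero(psth.bin_starts >= injection_time - 1e-9)
    rates = psth.rates
    offset = int(post[0]) if post.size else psth.n_bins
    exc_runs = [
        (s + offset, e + offset)
        for s, e in _qualifying_runs(rates[post] > upper, config.run_length)
    ]
    inh_runs = [
        (s + offset, e + offset)
        for s, e in _qualifying_runs(rates[post] < lower, config.run_length)
    ]

    if not exc_runs and not inh_runs:
        label, runs = "unaffected", []
    elif not inh_runs or (exc_runs and exc_runs[0][0] < inh_runs[0][0]):
        label, runs = "excitatory", exc_runs
    else:
        label, runs = "inhibitory", inh_runs

    cls = ResponseClassification(
        label=label,
        onset_latency_min=None,
        percent_change=None,
        qualifying_bins=[i for s, e in runs for i in range(s, e)],
        excitatory_runs=exc_runs,
        inhibitory_runs=inh_runs,
        baseline=baseline,
        bin_width=psth.bin_width,
        t_start=psth.t_start,
        degenerate_baseline=degenerate,
    )
    if label != "unaffected":
        cls.onset_latency_min = onset_latency(cls, injection_time)
        if baseline.mean_rate > 0:
            cls.percent_change = percent_change(psth, baseline, cls)
    return cls


def onset_latency(
    classification: ResponseClassification, injection_time: float
) -> float:
    """Minutes from injection to the start of the first qualifying run."""
    if classification.label == "unaffected" or not classification.qualifying_bins:
        raise ValueError("onset latency undefined for an unaffected unit")
    first_bin = classification.qualifying_bins[0]
    run_start_s = classification.t_start + first_bin * classification.bin_width
    return (run_start_s - injection_time) / 60.0


def percent_change(
    psth: BinnedRate,
    baseline: BaselineStats,
    classification: ResponseClassification,
) -> float:
    """Percent rate change over the qualifying-run bins, relative to baseline.

    Positive for excitation; an 80 % reduction comes back as −80.0.
    """
    if classification.label == "unaffected" or not classification.qualifying_bins:
        raise ValueError("percent change undefined for an unaffected unit")
    if baseline.mean_rate <= 0:
        raise ValueError("percent change undefined for a zero baseline mean")
    response_rate = float(np.mean(psth.rates[classification.qualifying_bins]))
    return 100.0 * (response_rate - baseline.mean_rate) / baseline.mean_rate


def classify_train(
    train: SpikeTrain,
    config: ClassifierConfig = ClassifierConfig(),
    *,
    snr: float | None = None,
    min_snr: float = 2.0,
    pyramidal_cap: float = PYRAMIDAL_RATE_CAP,
) -> ResponseClassification:
    """Classify one session end to end and apply the inclusion filters.

    ``snr`` (from the detection stage, when one ran) triggers the low-SNR
    exclusion at ``min_snr``; trains read directly from timestamp files skip
    that filter.  Excluded units keep their classification but are flagged so
    group summaries can omit them.
    """
    psth = make_psth(train)
    baseline = baseline_statistics(psth, train.injection_time)
    cls = classify_response(psth, baseline, train.injection_time, config)
    cls.unit_id = train.unit_id
    cls.group = train.group
    if not is_pyramidal(baseline.mean_rate, cap=pyramidal_cap):
        cls.excluded = True
        cls.exclusion_reason = "non-pyramidal"
    elif snr is not None and not (snr > min_snr):
        cls.excluded = True
        cls.exclusion_reason = "low-snr"
    elif cls.degenerate_baseline:
        cls.excluded = True
        cls.exclusion_reason = "degenerate-baseline"
    return cls
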