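"""Binned firing-rate series: 1000-ms acquisition bins and 60-s PSTH bins.

Two representations of the same session are used downstream: a fine 1-s
acquisition series (the stored raw record) and a 60-s peri-stimulus time
histogram (PSTH) on which response classification operates.  Bins are
half-open [t, t + width) on a 0-based session clock; a trailing partial bin is
dropped and the spikes falling in it are reported, never silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import SpikeTrain

PSTH_BIN_WIDTH = 60.0
ACQUISITION_BIN_WIDTH = 1.0

__all__ = [
    "PSTH_BIN_WIDTH",
    "ACQUISITION_BIN_WIDTH",
    "BinnedRate",
    "BaselineStats",
    "bin_counts",
    "make_psth",
    "make_acquisition_series",
    "baseline_statistics",
]


@dataclass
class BinnedRate:
    """Spike counts over uniform half-open bins, with rates in spikes/s."""

    bin_width: float
    t_start: float
    counts: np.ndarray
    n_dropped_spikes: int = 0  # spikes in a trailing partial bin, if any

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def rates(self) -> np.ndarray:
        """Per-bin firing rate in spikes/s."""
        return self.counts / self.bin_width

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_bins) * self.bin_width

    @property
    def t_end(self) -> float:
        """End of the last complete bin."""
        return self.t_start + self.n_bins * self.bin_width


@dataclass(frozen=True)
class BaselineStats:
    """Mean and sample SD of the pre-injection PSTH bin rates (spikes/s)."""

    mean_rate: float
    sd_rate: float
    n_bins: int

    @property
    def degenerate(self) -> bool:
        """True when the baseline has zero variance (SD floor applies)."""
        return self.sd_rate == 0.0


def bin_counts(
    train: SpikeTrain, bin_width: float, t_start: float, t_end: float
) -> BinnedRate:
    """Count spikes in half-open bins [t, t + bin_width) covering [t_start, t_end).

    Only complete bins are kept; spikes falling in a trailing partial bin are
    counted in ``n_dropped_spikes``.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n_bins = int(np.floor((t_end - t_start) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("range shorter than one bin")
    complete_end = t_start + n_bins * bin_width
    times = train.times
    in_bins = times[(times >= t_start) & (times < complete_end)]
    idx = ((in_bins - t_start) // bin_width).astype(int)
    # A float-rounding artefact could map a time at the very edge to n_bins.
    idx = np.minimum(idx, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    dropped = int(np.sum((times >= complete_end) & (times < t_end)))
    return BinnedRate(
        bin_width=bin_width, t_start=t_start, counts=counts, n_dropped_spikes=dropped
    )


def make_psth(train: SpikeTrain, bin_width: float = PSTH_BIN_WIDTH) -> BinnedRate:
    """Session PSTH at 60-s bins: a 7200-s session gives 120 bins, 15 of them
    before a 900-s injection."""
    if train.duration < bin_width:
        raise ValueError(
            f"session ({train.duration} s) shorter than one PSTH bin ({bin_width} s)"
        )
    return bin_counts(train, bin_width, 0.0, train.duration)


def make_acquisition_series(
    train: SpikeTrain, bin_width: float = ACQUISITION_BIN_WIDTH
) -> BinnedRate:
    """The fine (default 1000-ms) acquisition-rate series for the session."""
    return bin_counts(train, bin_width, 0.0, train.duration)


def baseline_statistics(psth: BinnedRate, injection_time: float) -> BaselineStats:
    """Mean and sample SD (n−1 denominator) of the pre-injection bin rates.

    Uses only bins that end at or before the injection.  These are the
    reference quantities for the ±2 SD response band; a zero SD is flagged via
    :attr:`BaselineStats.degenerate` so the classifier can apply its SD floor.
    """
    ends = psth.bin_starts + psth.bin_width
    mask = ends <= injection_time + 1e-9
    rates = psth.rates[mask]
    if rates.size < 2:
        raise ValueError(
            f"need >= 2 complete baseline bins before t={injection_time}, "
            f"got {rates.size}"
        )
    return BaselineStats(
        mean_rate=float(np.mean(rates)),
        sd_rate=float(np.std(rates, ddof=1)),
        n_bins=int(rates.size),
    )
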