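"""Group-level inference: paired pre/post t test, class counts, time courses.

Per group, each included unit contributes one (baseline mean rate, post mean
rate) pair; the paired Student t test with df = n − 1 evaluates the drug
effect, two-tailed at alpha = 0.05, with no correction across groups.  The
"post" mean covers the full 105-minute post-injection window.  Time courses
are per-bin mean ± SEM (SD/sqrt(n), n − 1 denominator) across included units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import make_psth
from .classify import ResponseClassification
from .simulate import SpikeTrain

__all__ = ["TTestResult", "GroupResult", "paired_t", "summarize_group", "response_scatter"]

LABELS = ("excitatory", "inhibitory", "unaffected")


@dataclass(frozen=True)
class TTestResult:
    """Paired t test outcome: t = mean(d) / (sd(d)/sqrt(n)), d = post − baseline."""

    t: float
    df: int
    p: float
    n: int
    mean_diff: float
    sem_diff: float
    degenerate: bool = False  # zero-variance differences: flagged, no t reported


@dataclass
class GroupResult:
    """Summary of one experimental group."""

    label: str
    n_neurons: int
    n_excluded: int
    counts: dict[str, int]
    ttest: TTestResult
    timecourse: pd.DataFrame  # columns: bin_start_s, mean_hz, sem_hz


def paired_t(
    baseline_means: Sequence[float], post_means: Sequence[float]
) -> TTestResult:
    """Paired-sample Student t test on per-neuron firing rates.

    Differences are post − baseline, so excitation gives a positive t.  The
    two-tailed p comes from Student's t with n − 1 degrees of freedom.
    Zero-variance differences yield a flagged degenerate result (t, p = NaN).
    """
    b = np.asarray(baseline_means, dtype=float)
    a = np.asarray(post_means, dtype=float)
    if b.ndim != 1 or b.shape != a.shape:
        raise ValueError("baseline and post vectors must be 1-D and equal length")
    n = b.size
    if n < 2:
        raise ValueError(f"paired test needs n >= 2 pairs, got {n}")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return TTestResult(
            t=math.nan, df=n - 1, p=math.nan, n=n,
            mean_diff=float(np.mean(d)), sem_diff=0.0, degenerate=True,
        )
    res = stats.ttest_rel(a, b)
    return TTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        n=n,
        mean_diff=float(np.mean(d)),
        sem_diff=sd / math.sqrt(n),
    )


def _post_mean_rate(train: SpikeTrain) -> float:
    return train.mean_rate(train.injection_time, train.duration)


def summarize_group(
    classifications: Sequence[ResponseClassification],
    sessions: Sequence[SpikeTrain],
    *,
    label: str | None = None,
) -> GroupResult:
    """Class counts, paired pre/post test and mean ± SEM time course.

    Units flagged ``excluded`` are omitted from the counts, the test and the
    time course but stay in ``n_excluded``, so counts + exclusions always add
    up to the cohort size.
    """
    if len(classifications) != len(sessions):
        raise ValueError("classifications and sessions must align")
    if not sessions:
        raise ValueError("empty group")
    included = [i for i, c in enumerate(classifications) if not c.excluded]
    if not included:
        raise ValueError("all units excluded; nothing to summarise")
    if label is None:
        label = sessions[0].group or "group"

    counts = {lab: 0 for lab in LABELS}
    for i in included:
        counts[classifications[i].label] += 1

    baseline_means = [classifications[i].baseline.mean_rate for i in included]
    post_means = [_post_mean_rate(sessions[i]) for i in included]
    ttest = paired_t(baseline_means, post_means)

    rate_matrix = np.vstack([make_psth(sessions[i]).rates for i in included])
    mean_hz = rate_matrix.mean(axis=0)
    if rate_matrix.shape[0] > 1:
        sem_hz = rate_matrix.std(axis=0, ddof=1) / math.sqrt(rate_matrix.shape[0])
    else:
        sem_hz = np.full(rate_matrix.shape[1], np.nan)
    psth0 = make_psth(sessions[included[0]])
    timecourse = pd.DataFrame(
        {"bin_start_s": psth0.bin_starts, "mean_hz": mean_hz, "sem_hz": sem_hz}
    )
    return GroupResult(
        label=label,
        n_neurons=len(sessions),
        n_excluded=len(sessions) - len(included),
        counts=counts,
        ttest=ttest,
        timecourse=timecourse,
    )


def response_scatter(
    sessions: Sequence[SpikeTrain],
    classifications: Sequence[ResponseClassification],
) -> pd.DataFrame:
    """Per-unit (baseline mean, post mean, label) table for scatter plots.

    One row per included unit; round-trips losslessly through the TSV writer.
    """
    if len(classifications) != len(sessions):
        raise ValueError("classifications and sessions must align")
    rows = [
        {
            "unit_id": s.unit_id,
            "baseline_hz": c.baseline.mean_rate,
            "post_hz": _post_mean_rate(s),
            "label": c.label,
        }
        for s, c in zip(sessions, classifications)
        if not c.excluded
    ]
    return pd.DataFrame(rows, columns=["unit_id", "baseline_hz", "post_hz", "label"])
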