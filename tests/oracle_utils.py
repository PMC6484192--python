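"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately re-derive results by the dumbest correct route (per-spike
loops, exhaustive window enumeration, hand formulas) and share no code with
the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_bin_counts(times, bin_width, t_start, n_bins):
    """Assign every spike to its bin by an explicit per-spike loop."""
    counts = [0] * n_bins
    for t in times:
        if t < t_start:
            continue
        k = int((t - t_start) // bin_width)
        if k < n_bins:
            counts[k] += 1
    return counts


def brute_force_classify(
    rates,
    bin_starts,
    bin_width,
    baseline_mean,
    baseline_sd,
    injection_time,
    k_sd=2.0,
    run_length=3,
    sd_floor=1.0 / 60.0,
):
    """Exhaustive window scan of the ±k·SD consecutive-bin rule.

    Enumerates every window of ``run_length`` consecutive post-injection bins,
    tests it wholly above / wholly below the band, and labels by the earlier
    qualifying window.  Returns (label, first_qualifying_bin or None).
    """
    sd = baseline_sd if baseline_sd > 0 else sd_floor
    upper = baseline_mean + k_sd * sd
    lower = baseline_mean - k_sd * sd
    post = [i for i, s in enumerate(bin_starts) if s >= injection_time - 1e-9]
    first_exc = None
    first_inh = None
    for w in range(len(post) - run_length + 1):
        window = post[w : w + run_length]
        if all(window[j + 1] == window[j] + 1 for j in range(run_length - 1)):
            if first_exc is None and all(rates[i] > upper for i in window):
                first_exc = window[0]
            if first_inh is None and all(rates[i] < lower for i in window):
                first_inh = window[0]
    if first_exc is None and first_inh is None:
        return "unaffected", None
    if first_inh is None or (first_exc is not None and first_exc < first_inh):
        return "excitatory", first_exc
    return "inhibitory", first_inh


def hand_paired_t(baseline, post):
    """Closed-form paired t: t = mean(d) / (sd(d)/sqrt(n)), d = post − baseline."""
    d = [p - b for b, p in zip(baseline, post)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n), n - 1


def random_psth_batch(rng, n, n_bins=120, bin_width=60.0):
    """Random Poisson PSTH count matrices with occasional planted excursions.

    Mixes pure-null series with series containing planted high/low segments of
    random length (1–6 bins, so some straddle the 3-bin criterion) and random
    placement, including both-direction cases.
    """
    out = []
    for _ in range(n):
        rate = rng.uniform(0.5, 8.0)
        lam = rate * bin_width
        counts = rng.poisson(lam, n_bins)
        for _ in range(rng.integers(0, 3)):
            ln = int(rng.integers(1, 7))
            start = int(rng.integers(15, n_bins - ln))
            if rng.random() < 0.5:
                counts[start : start + ln] = rng.poisson(lam * rng.uniform(2, 4), ln)
            else:
                counts[start : start + ln] = rng.poisson(lam * rng.uniform(0, 0.3), ln)
        out.append(counts)
    return out
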