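"""Least-biased duration statistics when the final period is truncated.

The terminal mark artificially cuts the last waveform period of a recording,
so its true duration is unknown — only a lower bound is observed.  For the
median this is often harmless: the median depends on ranks, not magnitudes,
so if the truncated period already ranks at or above the maximum of the
untruncated periods (and at least two untruncated periods exist), the median
computed with the truncated value included *is* the true median, whatever
the unknown true duration.  Otherwise the true median lies in a computable
range: from the median with the truncated value included at its observed
duration (the unknown true value at its smallest possible rank) up to the
median with the truncated value ranked above all others (true value
arbitrarily large).  The estimator reports the midpoint of that range as the
least-biased estimate.

Means have no such rank argument: including the truncated observation always
underestimates the true mean.  Three policies are provided; the default
includes the truncated value only when it is already the longest observation,
where excluding it would typically bias the mean down even further.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import waveforms as wf
from .model import Recording


def _median(values: list[float]) -> float:
    """Median with the even-count convention (mean of the two middle values)."""
    s = sorted(values)
    n = len(s)
    if n == 0:
        raise ValueError("median of empty list")
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return 0.5 * (s[mid - 1] + s[mid])


@dataclass(frozen=True)
class TruncationEstimate:
    """Range and point estimate of the true median period duration.

    ``median_low`` includes the truncated period at its observed duration;
    ``median_high`` is the limit as the unknown true duration tends to
    infinity (``inf`` when fewer than two untruncated periods exist).
    """

    median_low: float
    median_high: float
    estimate: float
    exact: bool
    method: str  # include-exact | midpoint | exclude | lower-bound | fallback


def true_median_estimate(untruncated: list[float], truncated_obs: float) -> TruncationEstimate:
    """Estimate the true median duration of a waveform whose final period is
    truncated.

    Parameters
    ----------
    untruncated
        Observed durations of the complete (untruncated) periods; may be empty.
    truncated_obs
        Observed (lower-bound) duration of the truncated final period.
    """
    if truncated_obs <= 0:
        raise ValueError(f"truncated duration must be positive, got {truncated_obs}")
    if any(d <= 0 for d in untruncated):
        raise ValueError("untruncated durations must be positive")
    k = len(untruncated)

    median_low = _median(list(untruncated) + [truncated_obs])

    # median_high: the truncated value ranked above every untruncated value.
    # With n = k + 1 values the top rank only reaches the median when k <= 1.
    if k >= 2:
        s = sorted(untruncated)
        n = k + 1
        mid = n // 2
        if n % 2 == 1:
            median_high = s[mid]  # top slot (index k) never selected since mid <= k - 1
        else:
            # indices mid-1 and mid of [s..., inf); mid == k only when n == 2
            median_high = 0.5 * (s[mid - 1] + s[mid])
    else:
        median_high = math.inf

    if math.isfinite(median_high) and median_low == median_high:
        return TruncationEstimate(median_low, median_high, median_low, True, "include-exact")
    if math.isfinite(median_high):
        est = 0.5 * (median_low + median_high)
        return TruncationEstimate(median_low, median_high, est, False, "midpoint")
    if k == 1:
        return TruncationEstimate(median_low, median_high, untruncated[0], False, "fallback")
    return TruncationEstimate(median_low, median_high, truncated_obs, False, "lower-bound")


MEAN_POLICIES = ("include", "exclude", "longest-include")


def mean_with_truncation(
    untruncated: list[float],
    truncated_obs: float,
    policy: str = "longest-include",
) -> tuple[float | None, str]:
    """Mean duration under a stated policy for the truncated final period.

    ``include`` averages all observations (always an underestimate of the
    true mean); ``exclude`` drops the truncated one (missing when nothing
    else exists); ``longest-include`` (default) includes it only when it is
    the longest observation.  Returns ``(value, flag)``; the flag records the
    branch taken.
    """
    if truncated_obs <= 0:
        raise ValueError(f"truncated duration must be positive, got {truncated_obs}")
    if any(d <= 0 for d in untruncated):
        raise ValueError("untruncated durations must be positive")
    if policy not in MEAN_POLICIES:
        raise ValueError(f"unknown mean policy {policy!r}")
    k = len(untruncated)
    if policy == "include":
        vals = list(untruncated) + [truncated_obs]
        return sum(vals) / len(vals), "underestimate"
    if policy == "exclude":
        if k == 0:
            return None, "missing:no-untruncated-periods"
        return sum(untruncated) / k, "excluded-truncated"
    # longest-include
    if k == 0 or truncated_obs > max(untruncated):
        vals = list(untruncated) + [truncated_obs]
        return sum(vals) / len(vals), "included:truncated-is-longest"
    return sum(untruncated) / k, "excluded:truncated-not-longest"


@dataclass(frozen=True)
class WaveformAdjustment:
    """Truncation-adjusted mean/median for the one waveform whose final
    period abuts the terminal mark."""

    label: str
    mean: float | None
    mean_flag: str
    median: float | None
    median_method: str
    median_exact: bool


def apply_truncation_criterion(
    recording: Recording,
    enabled: bool = True,
    mean_policy: str = "longest-include",
) -> WaveformAdjustment | None:
    """Compute adjusted mean/median for the truncated waveform of a recording.

    Only the waveform whose last period is closed by the terminal mark is
    affected; every other waveform's statistics are plain.  Returns None when
    the criterion is disabled or the recording is empty.
    """
    if not enabled or not recording.periods:
        return None
    last = recording.periods[-1]
    label = last.label
    durations = recording.durations(label)
    # the truncated observation is the final period; all earlier same-label
    # periods are complete
    untruncated = durations[:-1]
    est = true_median_estimate(untruncated, last.duration)
    mean, flag = mean_with_truncation(untruncated, last.duration, mean_policy)
    return WaveformAdjustment(
        label=label,
        mean=mean,
        mean_flag=flag,
        median=est.estimate,
        median_method=est.method,
        median_exact=est.exact,
    )
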