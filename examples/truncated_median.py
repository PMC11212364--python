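"""The truncated-wave criterion on the final, artificially cut period.

The last period of every recording is terminated by the end-of-recording
mark, so its true duration is unknown.  The estimator brackets the true
median and reports the least-biased point estimate.
"""

from epgkit import mean_with_truncation, true_median_estimate

# three prior complete ingestion periods, truncated one is the longest:
est = true_median_estimate([2.0, 4.0, 6.0], truncated_obs=9.0)
print(f"prior [2,4,6], truncated 9  -> median {est.estimate} ({est.method}, exact={est.exact})")

# the truncated period ranks in the middle: only a range is knowable
est = true_median_estimate([2.0, 10.0], truncated_obs=5.0)
print(f"prior [2,10], truncated 5   -> range [{est.median_low}, {est.median_high}], "
      f"estimate {est.estimate} ({est.method})")

# means have no rank argument; the default policy includes the truncated
# observation only when it is already the longest
for policy in ("include", "exclude", "longest-include"):
    value, flag = mean_with_truncation([2.0, 10.0], 5.0, policy)
    print(f"mean policy {policy:16s} -> {value} ({flag})")

# When the truncated period outranks every complete one, the median is exact
# whatever its true duration; otherwise the midpoint of the knowable range
# is the least-biased estimate, and means are always flagged.
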