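"""Fixed-effects meta-analysis of a discovery and a replication cohort.

Publications print odds ratios with CIs and P values rather than
standard errors; the helpers recover the log-scale SE from either and
the pooled estimate follows from inverse-variance weighting. The inputs
here are the published discovery (OR 1.02, 95% CI 1.01-1.04, P=2e-4)
and replication (OR 1.01, 95% CI 1.00-1.02, P=0.17) associations of a
CCB genetic risk score with diverticulosis.
"""

import dtmr

discovery = dtmr.study_from_summary("discovery", 1.02, 1.01, 1.04, pvalue=2e-4)
replication = dtmr.study_from_summary("replication", 1.01, 1.00, 1.02, pvalue=0.17)

for s in (discovery, replication):
    print(f"{s.label:12s} log-OR {s.log_effect:.5f}, se {s.se:.5f} (derived {s.source})")

pooled = dtmr.fixed_effects_meta([discovery, replication])
lo, hi = pooled.ratio_ci
print(f"\npooled OR {pooled.effect_ratio:.4f} (95% CI {lo:.4f}-{hi:.4f}), "
      f"P = {pooled.pvalue:.2g}")
print(f"study weights: {pooled.weights.round(3)}; "
      f"Q = {pooled.q:.2f} (P = {pooled.q_pvalue:.2f}), I^2 = {pooled.i2:.0%}")
print("rounded to two decimals the pooled estimate reads "
      f"{pooled.effect_ratio:.2f} ({lo:.2f}-{hi:.2f}).")
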