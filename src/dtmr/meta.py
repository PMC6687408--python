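"""Fixed-effects inverse-variance meta-analysis of cohort estimates.

Replication cohorts usually publish an odds ratio with a 95% CI and/or a
P value rather than a standard error, so helpers recover the SE of the
log effect from either. Pooling assumes a common true effect: weights
are proportional to 1/se^2, and between-study heterogeneity is
summarized by Cochran's Q and I^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

Z_95 = 1.959964


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort's estimate on the log scale."""

    label: str
    log_effect: float
    se: float
    source: str = "direct"  # direct | from_ci | from_p

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.label}: se must be positive")


@dataclass
class MetaResult:
    """Pooled fixed-effects estimate with heterogeneity summaries."""

    log_effect: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    weights: np.ndarray  # normalized, sum to 1
    q: float
    q_pvalue: float
    i2: float

    @property
    def effect_ratio(self) -> float:
        return math.exp(self.log_effect)

    @property
    def ratio_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def se_from_ci(effect_ratio: float, ci_low: float, ci_high: float) -> float:
    """SE of the log effect from a printed 95% CI on the ratio scale."""
    if not (0 < ci_low <= effect_ratio <= ci_high):
        raise ValueError(
            f"CI ordering violated: need 0 < {ci_low} <= {effect_ratio} <= {ci_high}"
        )
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)


def se_from_p(effect_ratio: float, pvalue: float) -> float:
    """SE of the log effect from a printed two-sided P value.

    se = |ln ratio| / z with z the standard-normal quantile of the
    two-sided P. Undefined at ratio 1 (no direction).
    """
    if effect_ratio <= 0 or effect_ratio == 1.0:
        raise ValueError("effect ratio must be positive and different from 1")
    if not (0 < pvalue < 1):
        raise ValueError("pvalue must lie in (0, 1)")
    z = stats.norm.isf(pvalue / 2.0)
    return abs(math.log(effect_ratio)) / z


def study_from_summary(
    label: str,
    effect_ratio: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    pvalue: float | None = None,
    prefer: str = "p",
) -> StudyEstimate:
    """Build a StudyEstimate from whatever a publication printed.

    When both a CI and a P value are available the P-derived SE is
    preferred by default: printed CIs are rounded more coarsely than
    printed P values and can disagree with the reported significance.
    """
    have_ci = ci_low is not None and ci_high is not None
    have_p = pvalue is not None
    if prefer == "p" and have_p:
        return StudyEstimate(label, math.log(effect_ratio), se_from_p(effect_ratio, pvalue), "from_p")
    if have_ci:
        return StudyEstimate(
            label, math.log(effect_ratio), se_from_ci(effect_ratio, ci_low, ci_high), "from_ci"
        )
    if have_p:
        return StudyEstimate(label, math.log(effect_ratio), se_from_p(effect_ratio, pvalue), "from_p")
    raise ValueError(f"study {label}: need a CI or a P value to derive the SE")


def fixed_effects_meta(estimates: list[StudyEstimate]) -> MetaResult:
    """Inverse-variance pooling under a common-effect model.

    pooled = sum(w*b)/sum(w) with w = 1/se^2; pooled se = 1/sqrt(sum w);
    Cochran's Q on len-1 degrees of freedom; I^2 = max(0, (Q-df)/Q).
    """
    if not estimates:
        raise ValueError("need at least one study estimate")
    b = np.array([e.log_effect for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    sw = w.sum()
    pooled = float((w * b).sum() / sw)
    se = math.sqrt(1.0 / sw)
    q = float((w * (b - pooled) ** 2).sum())
    df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else math.nan
    i2 = max(0.0, (q - df) / q) if q > 0 and df > 0 else 0.0
    z = abs(pooled) / se
    return MetaResult(
        log_effect=pooled,
        se=se,
        ci_low=pooled - Z_95 * se,
        ci_high=pooled + Z_95 * se,
        pvalue=float(2.0 * stats.norm.sf(z)),
        weights=w / sw,
        q=q,
        q_pvalue=q_p,
        i2=i2,
    )
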