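"""Mendelian-randomization estimators for drug-target proxies.

The exposure is genetically proxied SBP lowering through a drug-target
locus; outcomes are binary (betas are log odds ratios). Because
instruments are retained down to LD r^2 < 0.1, they are correlated and
the inverse-variance-weighted estimator is fit as generalized least
squares with covariance D r D (D = diag of outcome standard errors,
r = signed LD). Estimates are returned per 1 mmHg of genetically lower
SBP and can be rescaled to the average SBP reduction a drug class
achieves in randomized trials, so the result reads as the effect of a
trial-sized intervention. Odds ratios are converted to relative risks at
an assumed baseline incidence via the Zhang-Yu transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet
from .ld import LdMatrix

Z_95 = 1.959964


@dataclass(frozen=True)
class DrugClassDefinition:
    """A drug class and its trial-average SBP reduction used for rescaling."""

    drug_class: str
    rct_sbp_reduction_mmhg: float

    def __post_init__(self) -> None:
        if self.rct_sbp_reduction_mmhg <= 0:
            raise ValueError("RCT SBP reduction must be positive mmHg")


#: Trial-average SBP reductions (mmHg) by drug class.
RCT_REDUCTIONS = {
    "ACEI": DrugClassDefinition("ACEI", 21.14),
    "BB": DrugClassDefinition("BB", 9.51),
    "CCB": DrugClassDefinition("CCB", 8.90),
}


@dataclass
class MRResult:
    """One MR estimate: log effect per 1 mmHg genetically lower SBP
    (or per drug-class reduction after :func:`scale_to_rct`)."""

    method: str
    beta: float
    se: float
    n_snps: int
    ci_low: float = math.nan
    ci_high: float = math.nan
    pvalue: float = math.nan
    heterogeneity_q: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    intercept_pvalue: float | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z_95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z_95 * self.se
        if math.isnan(self.pvalue):
            self.pvalue = _wald_p(self.beta, self.se)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _wald_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(
    exposure_beta: float,
    exposure_se: float,
    outcome_beta: float,
    outcome_se: float,
) -> MRResult:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if exposure_beta == 0:
        raise ValueError("exposure beta is zero; Wald ratio undefined")
    beta = outcome_beta / exposure_beta
    se = abs(outcome_se / exposure_beta)
    return MRResult("wald", beta, se, n_snps=1)


def _extract_xy(
    instrument_set: InstrumentSet, outcome: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposure betas, outcome betas and outcome SEs in instrument order.

    ``outcome`` must already be harmonized to the exposure orientation."""
    out = outcome.set_index("SNP")
    missing = [v for v in instrument_set.variant_ids if v not in out.index]
    if missing:
        raise KeyError(f"instruments missing from outcome records: {missing}")
    out = out.loc[instrument_set.variant_ids]
    x = instrument_set.records["BETA"].to_numpy(dtype=float)
    y = out["BETA"].to_numpy(dtype=float)
    s = out["SE"].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("outcome SEs must be positive")
    return x, y, s


def _gls_sigma(ld: LdMatrix, outcome_se: np.ndarray) -> np.ndarray:
    r = ld.stabilized().r
    return r * np.outer(outcome_se, outcome_se)


def ivw_correlated(
    instrument_set: InstrumentSet,
    outcome: pd.DataFrame,
    ld: LdMatrix | None = None,
) -> MRResult:
    """Inverse-variance-weighted estimate allowing correlated instruments.

    Generalized weighted regression of outcome betas on exposure betas
    through the origin with Sigma = D r D: beta = (x'S^-1 x)^-1 x'S^-1 y,
    se = sqrt((x'S^-1 x)^-1). With identity LD this reduces exactly to
    the textbook fixed-effect IVW of per-variant Wald ratios. Cochran's Q
    is computed in the same metric with n_snps - 1 degrees of freedom.
    """
    if instrument_set.n_snps < 1:
        raise ValueError("ivw_correlated needs at least 1 instrument")
    ld = ld if ld is not None else instrument_set.ld
    x, y, s = _extract_xy(instrument_set, outcome)
    sigma = _gls_sigma(ld.submatrix(instrument_set.variant_ids), s)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "instrument covariance is singular even after PSD stabilization; "
            "clump at a stricter r2 threshold"
        ) from err
    xtsx = float(x @ sigma_inv @ x)
    beta = float(x @ sigma_inv @ y) / xtsx
    se = math.sqrt(1.0 / xtsx)
    resid = y - beta * x
    q = float(resid @ sigma_inv @ resid)
    df = instrument_set.n_snps - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else math.nan
    return MRResult(
        "ivw_correlated", beta, se, instrument_set.n_snps, heterogeneity_q=q, q_pvalue=q_p
    )


def egger_regression(
    instrument_set: InstrumentSet,
    outcome: pd.DataFrame,
    ld: LdMatrix | None = None,
) -> MRResult:
    """MR-Egger: the same generalized regression with a free intercept.

    The slope is the causal estimate; the intercept estimates directional
    pleiotropy (a nonzero value means the instruments affect the outcome
    other than through the proxied exposure).
    """
    if instrument_set.n_snps < 3:
        raise ValueError("egger_regression needs at least 3 instruments")
    ld = ld if ld is not None else instrument_set.ld
    x, y, s = _extract_xy(instrument_set, outcome)
    sigma = _gls_sigma(ld.submatrix(instrument_set.variant_ids), s)
    sigma_inv = np.linalg.inv(sigma)
    design = np.column_stack([np.ones_like(x), x])
    xtsx = design.T @ sigma_inv @ design
    cov = np.linalg.inv(xtsx)
    coef = cov @ design.T @ sigma_inv @ y
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    resid = y - design @ coef
    q = float(resid @ sigma_inv @ resid)
    df = instrument_set.n_snps - 2
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else math.nan
    return MRResult(
        "egger",
        slope,
        se_slope,
        instrument_set.n_snps,
        heterogeneity_q=q,
        q_pvalue=q_p,
        egger_intercept=intercept,
        intercept_pvalue=_wald_p(intercept, se_int),
    )


def _weighted_median_scan(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative normalized weight reaches 1/2."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5 - 1e-12))
    return float(v[min(idx, len(v) - 1)])


def weighted_median(
    instrument_set: InstrumentSet,
    outcome: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted median of per-variant Wald ratios (inverse-variance weights).

    Consistent when instruments carrying at least half the weight are
    valid. The SE comes from a seeded parametric bootstrap: betas are
    redrawn from their sampling distributions and the median recomputed.
    """
    if instrument_set.n_snps < 3:
        raise ValueError("weighted_median needs at least 3 instruments")
    x, y, s = _extract_xy(instrument_set, outcome)
    sx = instrument_set.records["SE"].to_numpy(dtype=float)
    ratios = y / x
    ratio_se = np.abs(s / x)
    weights = 1.0 / ratio_se**2
    beta = _weighted_median_scan(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(x, sx)
        yb = rng.normal(y, s)
        boot[b] = _weighted_median_scan(yb / xb, weights)
    se = float(boot.std(ddof=1))
    return MRResult("weighted_median", beta, se, instrument_set.n_snps)


def scale_to_rct(result: MRResult, drug: DrugClassDefinition) -> MRResult:
    """Rescale a per-mmHg estimate to the drug class's trial SBP reduction.

    Both beta and se are multiplied by the reduction, so the z statistic
    and P value are unchanged; the CI is recomputed on the scaled beta.
    """
    k = drug.rct_sbp_reduction_mmhg
    return replace(
        result,
        beta=result.beta * k,
        se=result.se * k,
        ci_low=math.nan,
        ci_high=math.nan,
        pvalue=result.pvalue,
    )


def or_to_rr(odds_ratio: float, baseline_incidence: float) -> float:
    """Zhang-Yu conversion of an odds ratio to a relative risk.

    RR = OR / (1 - p0 + p0 * OR) for baseline (unexposed) incidence p0.
    Monotone in OR and shrinking toward 1 as p0 grows.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not (0 < baseline_incidence < 1):
        raise ValueError("baseline incidence must lie in (0, 1)")
    p0 = baseline_incidence
    return odds_ratio / (1.0 - p0 + p0 * odds_ratio)


def result_to_rr(result: MRResult, baseline_incidence: float) -> tuple[float, float, float]:
    """Apply :func:`or_to_rr` to the point estimate and both CI bounds."""
    lo, hi = result.or_ci
    return (
        or_to_rr(result.odds_ratio, baseline_incidence),
        or_to_rr(lo, baseline_incidence),
        or_to_rr(hi, baseline_incidence),
    )


def orient_to_sbp_lowering(
    instruments: InstrumentSet, outcome: pd.DataFrame
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Re-sign effects so a positive exposure beta means SBP *lowering*.

    Exposure betas from an SBP GWAS are mmHg per effect allele; flipping
    the sign of both exposure and (harmonized) outcome betas for the
    raising alleles makes the MR slope read per 1 mmHg lower SBP, so a
    protective drug effect appears as RR < 1.
    """
    x = instruments.records["BETA"].to_numpy(dtype=float)
    # s = -1 where the recorded effect allele raises SBP: those alleles are
    # flipped to their SBP-lowering counterpart, which also flips the sign
    # of their outcome beta, EAF and LD correlations
    s = np.where(x > 0, -1.0, 1.0)
    exp = instruments.records.copy()
    exp["BETA"] = np.abs(x)  # mmHg lowered per (lowering) allele
    flipped = s < 0
    if "EA" in exp.columns and "OA" in exp.columns:
        ea, oa = exp["EA"].copy(), exp["OA"].copy()
        exp.loc[flipped, "EA"] = oa[flipped]
        exp.loc[flipped, "OA"] = ea[flipped]
    if "EAF" in exp.columns:
        exp.loc[flipped, "EAF"] = 1.0 - exp.loc[flipped, "EAF"]
    out = outcome.set_index("SNP").loc[instruments.variant_ids].reset_index()
    out["BETA"] = s * out["BETA"].to_numpy(dtype=float)
    r = instruments.ld.r * np.outer(s, s)
    oriented = InstrumentSet(
        instruments.drug_class,
        exp,
        LdMatrix(instruments.variant_ids, r),
        instruments.f_stat,
        instruments.r2,
    )
    return oriented, out
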