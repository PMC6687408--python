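"""Matched-SNP permutation null for GRS-phecode associations.

A PheWAS hit for a drug-target score could reflect blood pressure
generally rather than the drug target specifically. To test this, the
association is re-estimated many times with scores built from the same
*number* of variants sampled at random from genome-wide SBP-associated
SNPs (genome-wide significant, clumped to LD r^2 < 0.001 — stricter
than the within-locus clumping because the pool spans the genome). The
proportion of permutations with a consistent direction of effect and a
smaller P value than the observed association is the empirical adjusted
P value of the null hypothesis that any SBP-lowering score of that size
would show the association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import ld_clump
from .ld import LdMatrix
from .phewas import AssocResult, CaseControlSet, GenotypeMatrix

logger = logging.getLogger(__name__)

Z_95 = 1.959964


@dataclass
class PermutationConfig:
    """Controls for the matched-SNP permutation analysis."""

    n_permutations: int = 1000
    k: int = 24
    pool_p_threshold: float = 5e-8
    pool_r2_threshold: float = 0.001
    seed: int = 0
    exclude_failures_from_denominator: bool = True
    plus_one_correction: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class PermutationResult:
    """Observed association plus its permutation reference distribution."""

    observed: AssocResult
    estimates: pd.DataFrame  # columns: log_or, pvalue
    adjusted_p: float
    mean_or: float
    or_ci: tuple[float, float]  # empirical 2.5/97.5 percentiles
    or_ci_normal: tuple[float, float]  # normal-theory interval on mean log-OR
    n_failures: int = 0


def build_matched_pool(
    genomewide_sumstats: pd.DataFrame,
    ld: LdMatrix,
    config: PermutationConfig,
) -> pd.DataFrame:
    """Genome-wide significant SBP variants, clumped to the stricter r^2.

    The returned frame is the sampling pool; it must hold at least ``k``
    variants.
    """
    sig = genomewide_sumstats[genomewide_sumstats["P"] < config.pool_p_threshold]
    pool = ld_clump(sig, ld, config.pool_r2_threshold) if not sig.empty else sig
    if len(pool) < config.k:
        raise ValueError(
            f"matched pool holds {len(pool)} variants after filtering/clumping; "
            f"need at least k={config.k}"
        )
    return pool.reset_index(drop=True)


def exclude_correlated(
    sumstats: pd.DataFrame,
    ld: LdMatrix,
    target_ids,
    r2_max: float = 0.01,
) -> pd.DataFrame:
    """Drop variants in LD with the drug-target set from a pool input.

    In a genome-scale GWAS the drug-target locus is a vanishing fraction
    of the SBP-associated genome; in a compact synthetic genome it is
    not, so sampled scores would partially tag the target unless
    variants with r^2 > ``r2_max`` against any target variant are
    removed first.
    """
    targets = [t for t in target_ids if t in ld]
    keep = []
    for vid in sumstats["SNP"]:
        if vid in set(target_ids):
            keep.append(False)
        elif vid not in ld or not targets:
            keep.append(True)
        else:
            r2 = max(ld.r_between(vid, t) ** 2 for t in targets)
            keep.append(r2 <= r2_max)
    return sumstats.loc[np.asarray(keep, dtype=bool)]


def permutation_adjusted_p(
    observed: AssocResult,
    pool: pd.DataFrame,
    genotypes: GenotypeMatrix,
    case_control: CaseControlSet,
    covariates: pd.DataFrame,
    config: PermutationConfig,
    covariate_cols: tuple[str, ...] | None = None,
) -> PermutationResult:
    """Empirical adjusted P for one observed GRS-phecode association.

    Each permutation samples ``k`` distinct pool variants without
    replacement, builds a standardized GRS weighted by their SBP-lowering
    effects, and refits the same covariate-adjusted logistic model on the
    same case-control set. The adjusted P is the proportion of
    permutations whose effect has the observed sign and a smaller P.
    """
    if not observed.converged or math.isnan(observed.log_or):
        raise ValueError("observed association is not estimable")
    from .phewas import COVARIATE_PRESETS, _fit_logit

    covariate_cols = covariate_cols or COVARIATE_PRESETS["ukb"]
    rng = np.random.default_rng(config.seed)
    obs_sign = np.sign(observed.log_or)

    # Precompute what is identical across permutations: pool dosages
    # aligned to the SBP-lowering allele (mean-imputed), and the design
    # rows of the fixed case-control set. Per permutation only the score
    # column changes, so each iteration is one weighted sum plus one fit.
    row_of = {p: i for i, p in enumerate(genotypes.individual_ids)}
    col_of = {v: i for i, v in enumerate(genotypes.variant_ids)}
    missing = [v for v in pool["SNP"] if v not in col_of]
    if missing:
        raise KeyError(f"pool variants absent from genotypes: {missing}")
    pool_dosage = genotypes.dosages[:, [col_of[v] for v in pool["SNP"]]].copy()
    for j in range(pool_dosage.shape[1]):
        col = pool_dosage[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmean(col)
    lowering = pool["BETA"].to_numpy() <= 0  # EA lowers SBP where beta <= 0
    pool_dosage[:, ~lowering] = 2.0 - pool_dosage[:, ~lowering]
    pool_weight = np.abs(pool["BETA"].to_numpy())

    ids = sorted(case_control.case_ids) + sorted(case_control.control_ids)
    use_rows = np.array([row_of[i] for i in ids], dtype=int)
    y = np.zeros(len(ids))
    y[: case_control.n_case] = 1.0
    cov = covariates if "person_id" not in covariates.columns else covariates.set_index(
        "person_id"
    )
    cov = cov.loc[ids, list(covariate_cols)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(ids)), np.zeros(len(ids)), cov])

    rows = []
    n_failures = 0
    n_pool = len(pool)
    for _ in range(config.n_permutations):
        chosen = rng.choice(n_pool, size=config.k, replace=False)
        raw = pool_dosage[:, chosen] @ pool_weight[chosen]
        sd = raw.std(ddof=0)
        if sd == 0:
            n_failures += 1
            continue
        score = (raw - raw.mean()) / sd  # standardized over the full cohort
        design[:, 1] = score[use_rows]
        est = _fit_logit(y, design)
        if est is None:
            n_failures += 1
            continue
        log_or, _se, pvalue = est
        rows.append({"log_or": log_or, "pvalue": pvalue})

    estimates = pd.DataFrame(rows, columns=["log_or", "pvalue"])
    if n_failures:
        logger.warning("%d of %d permutation fits failed", n_failures, config.n_permutations)
    qualifying = int(
        ((np.sign(estimates["log_or"]) == obs_sign) & (estimates["pvalue"] < observed.pvalue)).sum()
    )
    denom = (
        len(estimates) if config.exclude_failures_from_denominator else config.n_permutations
    )
    if config.plus_one_correction:
        adjusted_p = (qualifying + 1) / (denom + 1)
    else:
        adjusted_p = qualifying / denom if denom else math.nan

    log_ors = estimates["log_or"].to_numpy()
    mean_log = float(log_ors.mean()) if len(log_ors) else math.nan
    if len(log_ors):
        lo, hi = np.percentile(log_ors, [2.5, 97.5])
        se = log_ors.std(ddof=1) / math.sqrt(len(log_ors)) if len(log_ors) > 1 else math.nan
        normal_ci = (math.exp(mean_log - Z_95 * se), math.exp(mean_log + Z_95 * se))
        empirical_ci = (math.exp(lo), math.exp(hi))
    else:
        normal_ci = empirical_ci = (math.nan, math.nan)

    return PermutationResult(
        observed=observed,
        estimates=estimates,
        adjusted_p=float(adjusted_p),
        mean_or=math.exp(mean_log) if not math.isnan(mean_log) else math.nan,
        or_ci=empirical_ci,
        or_ci_normal=normal_ci,
        n_failures=n_failures,
    )


def adjusted_p_from_counts(n_qualifying: int, n_permutations: int) -> float:
    """Adjusted P from raw counts (e.g. 10 of 1000 -> 0.01)."""
    if n_permutations < 1 or not (0 <= n_qualifying <= n_permutations):
        raise ValueError("counts must satisfy 0 <= qualifying <= permutations >= 1")
    return n_qualifying / n_permutations
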