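"""Synthetic cohorts with known ground truth for the whole pipeline.

Everything the analysis consumes can be generated here: LD-blocked
genotypes, an SBP-like quantitative trait with planted per-allele
effects in drug-target regions, GWAS summary statistics derived from
them (linear for SBP, logistic for binary outcomes), and an ICD-coded
phenome in which a chosen phecode depends on the drug-target genetic
risk score (or, alternatively, on genetically determined SBP itself).
The planted parameters are returned alongside the data so tests can
assert recovery.

Genotype model
--------------
Each LD block draws two haplotypes per individual from an exchangeable
latent Gaussian: latent = sqrt(rho)*shared + sqrt(1-rho)*noise,
thresholded at the allele-frequency quantile. Thresholding attenuates
correlation (tetrachoric vs Pearson), so the latent rho is calibrated by
bisection on the bivariate-normal orthant probability such that the
*dosage* correlation equals the requested ``within_block_r``. This is an
idealization of population LD: blocks are exactly exchangeable and
independent of each other, with no recombination gradient.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import io
from .instruments import GenomicRegion, regions_to_frame
from .ld import LdMatrix
from .phewas import GenotypeMatrix, PhecodeCatalog, build_grs


@dataclass(frozen=True)
class RegionSpec:
    """One planted drug-target region: variants and their SBP effect."""

    name: str
    drug_class: str
    variant_indices: tuple[int, ...]
    effect_mmhg: float  # per-allele effect on SBP; negative = lowering


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study scenario.

    Defaults describe the demo scenario: 20 000 individuals, 70 blocks
    of 5 variants at within-block dosage correlation 0.6, SBP noise SD
    19 mmHg (population-like SBP spread), planted per-allele effects of
    -2.5 mmHg (instrument F roughly 50-200, comparable to strong cis
    instruments), background SBP loci in the target-free blocks for the
    permutation pool, and a phenome of 40 phecodes in which the focal
    phecode (prevalence 0.10, a diverticulosis-like common outcome)
    carries a GRS effect of log(1.5) per SD.
    """

    n_individuals: int = 20_000
    n_blocks: int = 70
    block_size: int = 5
    within_block_r: float = 0.6
    maf_range: tuple[float, float] = (0.2, 0.5)
    target_region_spec: tuple[RegionSpec, ...] = ()
    grs_phecode_effect: float = math.log(1.5)
    n_phecodes: int = 40
    baseline_prevalences: float | tuple[float, ...] | None = None
    seed: int = 0

    # SBP model
    sbp_mean: float = 125.0
    noise_sd: float = 19.0
    n_background_loci: int = 40
    background_effect_mmhg: float = 2.5

    # binary outcomes for MR (per-mmHg-higher-SBP log odds ratios)
    outcome_effects: tuple[tuple[str, float, float], ...] = (
        ("CHD", 0.02, 0.05),
        ("stroke", 0.03, 0.05),
    )  # (name, log-OR per mmHg, prevalence)

    # phenome
    focal_phecode_index: int = 0
    focal_prevalence: float = 0.10
    phecode_effect_mode: str = "grs"  # "grs" | "sbp"
    grs_drug_class: str = "CCB"
    age_log_or: float = 0.02
    sex_log_or: float = 0.1

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be positive")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        planted = [i for r in self.target_region_spec for i in r.variant_indices]
        if len(planted) != len(set(planted)):
            raise ValueError("planted variant indices must be unique across regions")
        if self.phecode_effect_mode not in ("grs", "sbp"):
            raise ValueError("phecode_effect_mode must be 'grs' or 'sbp'")
        for p in np.atleast_1d(self.prevalence_vector()):
            if not (0 < p < 1):
                raise ValueError("prevalences must lie in (0, 1)")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    def prevalence_vector(self) -> np.ndarray:
        """Per-phecode baseline prevalences (focal phecode overridden)."""
        if self.baseline_prevalences is None:
            # log-uniform between 1% and 15%, deterministic in the seed
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
            prev = np.exp(rng.uniform(math.log(0.01), math.log(0.15), self.n_phecodes))
        elif np.isscalar(self.baseline_prevalences):
            prev = np.full(self.n_phecodes, float(self.baseline_prevalences))
        else:
            prev = np.asarray(self.baseline_prevalences, dtype=float)
            if len(prev) != self.n_phecodes:
                raise ValueError("baseline_prevalences length must equal n_phecodes")
            prev = prev.copy()
        prev[self.focal_phecode_index] = self.focal_prevalence
        return prev


def _sequential_regions(
    sizes: list[int], labels: list[str], drug_class: str, effect: float, first_block: int, block_size: int
) -> tuple[list[RegionSpec], int]:
    """Region specs placing one planted variant per LD block (variant 0 of
    each block), so clumping at any r^2 threshold retains all of them."""
    specs = []
    blk = first_block
    for size, label in zip(sizes, labels):
        idx = tuple((blk + j) * block_size for j in range(size))
        specs.append(RegionSpec(label, drug_class, idx, effect))
        blk += size
    return specs, blk


def ccb_like_config(**overrides) -> ScenarioConfig:
    """Scenario with a CCB-like target set: 24 variants across 10 regions.

    Mirrors the structure of a calcium-channel-blocker target set: ten
    gene regions contribute 1-4 genome-wide-significant variants each,
    every planted allele lowering SBP, no two planted variants in the
    same LD block (so all 24 survive clumping, as in the real set where
    retained pairs satisfy r^2 < 0.1).
    """
    block_size = overrides.get("block_size", 5)
    sizes = [4, 3, 3, 3, 2, 2, 2, 2, 2, 1]  # 24 variants over 10 regions
    labels = [f"CCB_gene{g + 1}" for g in range(len(sizes))]
    specs, _ = _sequential_regions(sizes, labels, "CCB", -2.5, 0, block_size)
    defaults = dict(target_region_spec=tuple(specs))
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def demo_config(**overrides) -> ScenarioConfig:
    """Three drug classes with the real study's instrument counts:
    1 variant for ACEI, 6 for BB (two genes), 24 for CCB (ten genes)."""
    block_size = overrides.get("block_size", 5)
    ccb, nxt = _sequential_regions(
        [4, 3, 3, 3, 2, 2, 2, 2, 2, 1],
        [f"CCB_gene{g + 1}" for g in range(10)],
        "CCB",
        -2.5,
        0,
        block_size,
    )
    acei, nxt = _sequential_regions([1], ["ACE"], "ACEI", -2.5, nxt, block_size)
    bb, nxt = _sequential_regions([3, 3], ["BB_gene1", "BB_gene2"], "BB", -2.5, nxt, block_size)
    defaults = dict(target_region_spec=tuple(ccb + acei + bb))
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


# ----------------------------------------------------------- genotypes


@lru_cache(maxsize=512)
def _latent_rho(maf: float, target_r: float) -> float:
    """Latent Gaussian correlation giving allele (hence dosage) correlation
    ``target_r`` at allele frequency ``maf``, by bisection on the
    bivariate-normal orthant probability."""
    if target_r == 0:
        return 0.0
    t = stats.norm.ppf(maf)

    def allele_r(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        p2 = stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True).cdf([t, t])
        return (p2 - maf**2) / (maf * (1 - maf))

    lo, hi = target_r, 1.0 - 1e-9  # thresholding attenuates: latent >= target
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if allele_r(mid) < target_r:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return (lo + hi) / 2.0


def simulate_genotypes(config: ScenarioConfig) -> tuple[GenotypeMatrix, LdMatrix]:
    """LD-blocked dosages plus the theoretical block LD matrix.

    Returns dosages in {0, 1, 2} and an LdMatrix with unit diagonal,
    ``within_block_r`` inside blocks and 0 across blocks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, b, m = config.n_individuals, config.n_blocks, config.block_size
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, b * m)

    dosages = np.empty((n, b * m))
    for blk in range(b):
        cols = slice(blk * m, (blk + 1) * m)
        block_maf = float(np.round(mafs[cols].mean(), 6))
        rho = _latent_rho(block_maf, config.within_block_r) if m > 1 else 0.0
        hap_sum = np.zeros((n, m))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, m))
            latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise
            thresholds = stats.norm.ppf(mafs[cols])
            hap_sum += (latent < thresholds).astype(float)
        dosages[:, cols] = hap_sum

    ids = [f"rs{i + 1}" for i in range(b * m)]
    chrom = [str(i // (10 * m) + 1) for i in range(b * m)]
    pos = [((i // m) % 10) * 1_000_000 + (i % m) * 1_000 + 1 for i in range(b * m)]
    variants = pd.DataFrame(
        {"SNP": ids, "CHR": chrom, "POS": pos, "EA": "A", "OA": "G", "MAF": mafs}
    )
    genotypes = GenotypeMatrix(
        dosages, [f"P{i + 1:06d}" for i in range(n)], variants
    )

    r = np.zeros((b * m, b * m))
    for blk in range(b):
        cols = slice(blk * m, (blk + 1) * m)
        r[cols, cols] = config.within_block_r
    np.fill_diagonal(r, 1.0)
    return genotypes, LdMatrix(ids, r)


# ----------------------------------------------------------- phenotypes


def simulate_quantitative_trait(
    genotypes: GenotypeMatrix,
    effects: dict[int, float] | np.ndarray,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
) -> np.ndarray:
    """trait = intercept + sum_j effect_j * dosage_j + N(0, noise_sd^2)."""
    n, m = genotypes.dosages.shape
    vec = np.zeros(m)
    if isinstance(effects, dict):
        for idx, eff in effects.items():
            if not (0 <= idx < m):
                raise IndexError(f"variant index {idx} outside [0, {m})")
            vec[idx] = eff
    else:
        effects = np.asarray(effects, dtype=float)
        if effects.shape != (m,):
            raise IndexError(f"effects length {effects.shape} != number of variants {m}")
        vec = effects
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    return intercept + genotypes.dosages @ vec + noise


def _solve_intercept(offset: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(sigmoid(c + offset)) = prevalence (Newton)."""
    c = math.log(prevalence / (1 - prevalence)) - float(offset.mean())
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(c + offset)))
        f = p.mean() - prevalence
        d = (p * (1 - p)).mean()
        if d <= 0:
            break
        step = f / d
        c -= step
        if abs(step) < 1e-12:
            break
    return c


def simulate_binary_outcome(
    liability: np.ndarray, prevalence: float, seed: int
) -> np.ndarray:
    """Bernoulli draw from logit(p) = c + liability, with c solved so the
    expected prevalence matches."""
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    c = _solve_intercept(liability, prevalence)
    p = 1.0 / (1.0 + np.exp(-(c + liability)))
    rng = np.random.default_rng(seed)
    return (rng.random(len(p)) < p).astype(float)


def derive_summary_stats(
    genotypes: GenotypeMatrix, phenotype: np.ndarray, trait_kind: str = "quantitative"
) -> pd.DataFrame:
    """Per-variant marginal GWAS on the given phenotype.

    Linear regression for a quantitative trait; logistic (beta = log OR)
    for a binary one. Monomorphic variants are emitted with P = 1, beta
    0, missing SE and a ``monomorphic`` flag rather than dropped.
    """
    y = np.asarray(phenotype, dtype=float)
    n, m = genotypes.dosages.shape
    if len(y) != n:
        raise ValueError("phenotype length must match number of individuals")
    if trait_kind not in ("quantitative", "binary"):
        raise ValueError("trait_kind must be 'quantitative' or 'binary'")

    g = genotypes.dosages
    eaf = g.mean(axis=0) / 2.0
    mono = g.std(axis=0) == 0

    betas = np.zeros(m)
    ses = np.full(m, np.nan)
    pvals = np.ones(m)
    if trait_kind == "quantitative":
        gc = g - g.mean(axis=0)
        yc = y - y.mean()
        sxx = (gc**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (gc * yc[:, None]).sum(axis=0) / sxx
        rss = ((yc[:, None] - gc * b) ** 2).sum(axis=0)
        dof = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / dof / sxx)
            tstat = b / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        ok = ~mono
        betas[ok], ses[ok], pvals[ok] = b[ok], se[ok], p[ok]
    else:
        for j in range(m):
            if mono[j]:
                continue
            design = np.column_stack([np.ones(n), g[:, j]])
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
                if fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse[1]):
                    betas[j] = fit.params[1]
                    ses[j] = fit.bse[1]
                    pvals[j] = fit.pvalues[1]
            except (np.linalg.LinAlgError, ValueError):
                pass

    out = genotypes.variants[["SNP", "CHR", "POS", "EA", "OA"]].copy()
    out["EAF"] = eaf
    out["BETA"] = betas
    out["SE"] = ses
    out["P"] = pvals
    out["N"] = n
    out["monomorphic"] = mono
    return out


# ------------------------------------------------------------ phenome


def synthetic_phecode_catalog(n_phecodes: int, sibling_every: int = 10) -> PhecodeCatalog:
    """A small phecode system with exclusion ranges.

    Phecode k sits at numeric value 100 + 2k with exclusion range
    (value - 1, value + 1); every ``sibling_every``-th phecode gets a
    *sibling* phecode at value + 1 inside the same range, so sibling
    cases are excluded from the primary phecode's controls (and vice
    versa). Each phecode maps from one ICD-10 and one ICD-9 code, plus
    an ICD-10 sub-code to exercise deduplication.
    """
    map_rows, def_rows = [], []
    for k in range(n_phecodes):
        value = 100 + 2 * k
        code = f"{value}"
        map_rows += [
            {"vocab": "ICD10", "code": f"Z{k:03d}", "phecode": code},
            {"vocab": "ICD10", "code": f"Z{k:03d}1", "phecode": code},
            {"vocab": "ICD9", "code": f"{1000 + k}", "phecode": code},
        ]
        def_rows.append(
            {
                "phecode": code,
                "label": f"synthetic condition {k}",
                "category": f"category {k % 8}",
                "exclude_range": f"{value - 1}-{value + 1}",
            }
        )
        if sibling_every and k % sibling_every == 0:
            sib = f"{value}.1"
            map_rows.append({"vocab": "ICD10", "code": f"Y{k:03d}", "phecode": sib})
            def_rows.append(
                {
                    "phecode": sib,
                    "label": f"synthetic condition {k} (related)",
                    "category": f"category {k % 8}",
                    "exclude_range": f"{value - 1}-{value + 1}",
                }
            )
    return PhecodeCatalog.from_frames(pd.DataFrame(map_rows), pd.DataFrame(def_rows))


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Age, sex (1 = female) and four genetic principal components."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    return pd.DataFrame(
        {
            "person_id": [f"P{i + 1:06d}" for i in range(n)],
            "age": rng.uniform(40, 70, n).round(1),
            "sex": (rng.random(n) < 0.54).astype(int),
            "PC1": rng.standard_normal(n),
            "PC2": rng.standard_normal(n),
            "PC3": rng.standard_normal(n),
            "PC4": rng.standard_normal(n),
        }
    )


def simulate_binary_phenome(
    covariates: pd.DataFrame,
    grs: np.ndarray | pd.Series,
    config: ScenarioConfig,
    catalog: PhecodeCatalog | None = None,
) -> pd.DataFrame:
    """ICD records for a phenome driven by the standardized score.

    Each primary phecode's case status follows logit(p) = c + beta*GRS +
    age/sex terms, with beta = ``grs_phecode_effect`` on the focal
    phecode and 0 elsewhere, and c solved so the expected prevalence is
    the configured baseline. Cases emit one (sometimes two) ICD codes
    that map back to the phecode; sibling phecodes are sparse background
    noise.
    """
    grs = np.asarray(grs, dtype=float)
    if abs(grs.mean()) > 1e-6 or abs(grs.std() - 1.0) > 1e-6:
        raise ValueError("grs must be standardized to mean 0, SD 1")
    catalog = catalog or synthetic_phecode_catalog(config.n_phecodes)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(covariates)
    prev = config.prevalence_vector()
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    base_offset = config.age_log_or * (age - age.mean()) + config.sex_log_or * (sex - sex.mean())

    # invert the catalog: phecode -> ICD-10 codes
    codes_of: dict[str, list[tuple[str, str]]] = {}
    for (vocab, code), phe in catalog.icd_map.items():
        codes_of.setdefault(phe, []).append((vocab, code))

    person_ids = covariates["person_id"].to_numpy()
    chunks: list[pd.DataFrame] = []

    def emit(case_idx: np.ndarray, vocabs_codes: list[tuple[str, str]]) -> None:
        if len(case_idx) == 0:
            return
        pick = rng.integers(len(vocabs_codes), size=len(case_idx))
        vocab = np.array([vc[0] for vc in vocabs_codes])[pick]
        code = np.array([vc[1] for vc in vocabs_codes])[pick]
        year = rng.integers(2000, 2017, size=len(case_idx))
        month = rng.integers(1, 13, size=len(case_idx))
        day = rng.integers(1, 29, size=len(case_idx))
        date = pd.Series(year).astype(str).str.cat(
            [pd.Series(month).astype(str).str.zfill(2), pd.Series(day).astype(str).str.zfill(2)],
            sep="-",
        )
        chunks.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[case_idx],
                    "vocab": vocab,
                    "code": code,
                    "date": date.to_numpy(),
                }
            )
        )

    for k in range(config.n_phecodes):
        phe = f"{100 + 2 * k}"
        beta = config.grs_phecode_effect if k == config.focal_phecode_index else 0.0
        offset = base_offset + beta * grs
        c = _solve_intercept(offset, prev[k])
        p = 1.0 / (1.0 + np.exp(-(c + offset)))
        cases = np.nonzero(rng.random(n) < p)[0]
        vocabs_codes = sorted(codes_of[phe])
        emit(cases, vocabs_codes)
        # occasional duplicate diagnosis for the same person
        emit(cases[rng.random(len(cases)) < 0.2], vocabs_codes)
    # sparse sibling diagnoses (excluded-range background, prevalence 1%)
    for phe in catalog.definitions.index:
        if "." not in phe:
            continue
        emit(np.nonzero(rng.random(n) < 0.01)[0], sorted(codes_of[phe]))

    out = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=["person_id", "vocab", "code", "date"]
    )
    return out


def simulate_phenome_pairs(
    covariates: pd.DataFrame,
    score: np.ndarray | pd.Series,
    config: ScenarioConfig,
    catalog: PhecodeCatalog | None = None,
) -> pd.DataFrame:
    """Person-phecode pairs drawn from the same phenome model as
    :func:`simulate_binary_phenome`, skipping ICD encoding.

    Equivalent in distribution to mapping the emitted ICD records back
    to phecodes (the realized draws differ); intended for calibration
    studies where the ICD round trip is not the point and the phenome
    must be regenerated many times.
    """
    score = np.asarray(score, dtype=float)
    catalog = catalog or synthetic_phecode_catalog(config.n_phecodes)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    n = len(covariates)
    prev = config.prevalence_vector()
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    base_offset = config.age_log_or * (age - age.mean()) + config.sex_log_or * (sex - sex.mean())
    person_ids = covariates["person_id"].to_numpy()

    ids_chunks, code_chunks = [], []
    for k in range(config.n_phecodes):
        beta = config.grs_phecode_effect if k == config.focal_phecode_index else 0.0
        offset = base_offset + beta * score
        c = _solve_intercept(offset, prev[k])
        p = 1.0 / (1.0 + np.exp(-(c + offset)))
        cases = np.nonzero(rng.random(n) < p)[0]
        ids_chunks.append(person_ids[cases])
        code_chunks.append(np.full(len(cases), f"{100 + 2 * k}", dtype=object))
    for phe in catalog.definitions.index:
        if "." not in phe:
            continue
        carriers = np.nonzero(rng.random(n) < 0.01)[0]
        ids_chunks.append(person_ids[carriers])
        code_chunks.append(np.full(len(carriers), phe, dtype=object))
    return pd.DataFrame(
        {"person_id": np.concatenate(ids_chunks), "phecode": np.concatenate(code_chunks)}
    )


# ------------------------------------------------------------ scenario


@dataclass
class ScenarioTruth:
    """The planted parameters of a scenario, for test assertions."""

    per_variant_sbp_effect: np.ndarray
    outcome_log_or_per_mmhg: dict[str, float]
    grs_phecode_effect: float
    focal_phecode: str
    focal_prevalence: float
    target_variants: dict[str, list[str]]  # drug class -> variant ids
    background_variants: list[str]
    phecode_effect_mode: str


@dataclass
class ScenarioBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: ScenarioConfig
    genotypes: GenotypeMatrix
    true_ld: LdMatrix
    sbp: np.ndarray
    sumstats_sbp: pd.DataFrame
    sumstats_outcomes: dict[str, pd.DataFrame]
    regions: list[GenomicRegion]
    grs_weights: pd.DataFrame
    grs: pd.Series
    icd_records: pd.DataFrame
    covariates: pd.DataFrame
    catalog: PhecodeCatalog
    truth: ScenarioTruth

    def write(self, out_dir) -> None:
        """Serialize all artifacts in the external interchange formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_sumstats(self.sumstats_sbp, out / "sumstats_sbp.tsv")
        for name, frame in self.sumstats_outcomes.items():
            io.write_sumstats(frame, out / f"sumstats_{name}.tsv")
        io.write_regions(regions_to_frame(self.regions), out / "regions.tsv")
        self.true_ld.write(out / "ld.tsv")
        io.write_genotypes(
            self.genotypes.dosages,
            self.genotypes.individual_ids,
            self.genotypes.variant_ids,
            out / "genotypes.tsv",
        )
        self.genotypes.variants.to_csv(out / "variants.csv", index=False)
        io.write_icd_records(self.icd_records, out / "icd.csv")
        io.write_covariates(self.covariates, out / "covariates.csv")
        io.write_grs_weights(self.grs_weights, out / "grs_weights.tsv")
        self.catalog.write(out / "phecode_map.csv", out / "phecode_defs.csv")
        truth = asdict(self.truth)
        truth["per_variant_sbp_effect"] = self.truth.per_variant_sbp_effect.tolist()
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def load_scenario(out_dir) -> dict:
    """Read the serialized artifacts of :meth:`ScenarioBundle.write`.

    Returns a dict with the same keys the writers used; the round trip
    is lossless up to text formatting of floats.
    """
    out = Path(out_dir)
    dosages = io.read_genotypes(out / "genotypes.tsv")
    variants = pd.read_csv(out / "variants.csv", dtype={"SNP": str, "CHR": str})
    genotypes = GenotypeMatrix(dosages.to_numpy(), list(dosages.index), variants)
    sumstats_outcomes = {
        p.stem.removeprefix("sumstats_"): io.read_sumstats(p)
        for p in sorted(out.glob("sumstats_*.tsv"))
        if p.stem != "sumstats_sbp"
    }
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    return {
        "genotypes": genotypes,
        "true_ld": LdMatrix.read(out / "ld.tsv"),
        "sumstats_sbp": io.read_sumstats(out / "sumstats_sbp.tsv"),
        "sumstats_outcomes": sumstats_outcomes,
        "regions": io.read_regions(out / "regions.tsv"),
        "grs_weights": io.read_grs_weights(out / "grs_weights.tsv"),
        "icd_records": io.read_icd_records(out / "icd.csv"),
        "covariates": io.read_covariates(out / "covariates.csv"),
        "catalog": PhecodeCatalog.read(out / "phecode_map.csv", out / "phecode_defs.csv"),
        "truth": truth,
    }


def build_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate a complete synthetic study from one config.

    Deterministic in ``config.seed``; every component stream draws from
    its own child seed, so scenarios differing only in seed share no
    randomness while identical configs are bit-identical.
    """
    genotypes, true_ld = simulate_genotypes(config)
    m = config.n_variants
    ids = genotypes.variant_ids

    effects = np.zeros(m)
    target_variants: dict[str, list[str]] = {}
    target_idx: set[int] = set()
    for spec in config.target_region_spec:
        for idx in spec.variant_indices:
            effects[idx] = spec.effect_mmhg
            target_idx.add(idx)
        target_variants.setdefault(spec.drug_class, []).extend(
            ids[i] for i in spec.variant_indices
        )

    # background SBP loci: first variant of blocks free of target variants
    target_blocks = {i // config.block_size for i in target_idx}
    free_blocks = [b for b in range(config.n_blocks) if b not in target_blocks]
    background: list[str] = []
    for j, blk in enumerate(free_blocks[: config.n_background_loci]):
        idx = blk * config.block_size
        sign = -1.0 if j % 2 == 0 else 1.0
        effects[idx] = sign * config.background_effect_mmhg
        background.append(ids[idx])

    # center the genetic contribution so the cohort mean sits at sbp_mean
    genetic_offset = float((genotypes.dosages @ effects).mean())
    sbp = simulate_quantitative_trait(
        genotypes,
        effects,
        config.noise_sd,
        seed=int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % 2**31),
        intercept=config.sbp_mean - genetic_offset,
    )
    sumstats_sbp = derive_summary_stats(genotypes, sbp, "quantitative")

    genetic_sbp = genotypes.dosages @ effects
    sumstats_outcomes: dict[str, pd.DataFrame] = {}
    outcome_truth: dict[str, float] = {}
    for j, (name, log_or_per_mmhg, prevalence) in enumerate(config.outcome_effects):
        liability = log_or_per_mmhg * (genetic_sbp - genetic_sbp.mean())
        seed_j = int(np.random.SeedSequence([config.seed, 4, j]).generate_state(1)[0] % 2**31)
        y = simulate_binary_outcome(liability, prevalence, seed_j)
        sumstats_outcomes[name] = derive_summary_stats(genotypes, y, "binary")
        outcome_truth[name] = log_or_per_mmhg

    # one short interval per planted variant (gene/promoter/enhancer
    # pieces of the target locus), covering only that variant
    regions: list[GenomicRegion] = []
    vmeta = genotypes.variants
    kinds = ["gene", "promoter", "enhancer"]
    for spec in config.target_region_spec:
        for j, idx in enumerate(spec.variant_indices):
            row = vmeta.iloc[idx]
            regions.append(
                GenomicRegion(
                    name=spec.name,
                    chrom=str(row["CHR"]),
                    start=int(row["POS"]),
                    end=int(row["POS"]) + 500,
                    kind=kinds[j % 3],
                    drug_class=spec.drug_class,
                )
            )

    # GRS weights for the scanned drug class, oriented to SBP lowering
    class_ids = target_variants.get(config.grs_drug_class, [])
    widx = [ids.index(v) for v in class_ids]
    grs_weights = pd.DataFrame(
        {
            "SNP": class_ids,
            "EA": ["A" if effects[i] <= 0 else "G" for i in widx],
            "WEIGHT": [abs(effects[i]) for i in widx],
        }
    )
    if not class_ids:
        raise ValueError(f"no target variants planted for drug class {config.grs_drug_class}")
    grs = build_grs(genotypes, grs_weights)

    covariates = simulate_covariates(config.n_individuals, config.seed)
    catalog = synthetic_phecode_catalog(config.n_phecodes)
    if config.phecode_effect_mode == "grs":
        predictor = grs.to_numpy()
    else:  # effect through SBP generally, not the drug target specifically
        predictor = (genetic_sbp - genetic_sbp.mean()) / genetic_sbp.std()
    icd_records = simulate_binary_phenome(covariates, predictor, config, catalog)

    truth = ScenarioTruth(
        per_variant_sbp_effect=effects,
        outcome_log_or_per_mmhg=outcome_truth,
        grs_phecode_effect=config.grs_phecode_effect,
        focal_phecode=f"{100 + 2 * config.focal_phecode_index}",
        focal_prevalence=config.focal_prevalence,
        target_variants=target_variants,
        background_variants=background,
        phecode_effect_mode=config.phecode_effect_mode,
    )
    return ScenarioBundle(
        config=config,
        genotypes=genotypes,
        true_ld=true_ld,
        sbp=sbp,
        sumstats_sbp=sumstats_sbp,
        sumstats_outcomes=sumstats_outcomes,
        regions=regions,
        grs_weights=grs_weights,
        grs=grs,
        icd_records=icd_records,
        covariates=covariates,
        catalog=catalog,
        truth=truth,
    )
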