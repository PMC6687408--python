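"""GRS construction and phenome-wide association scan over phecodes.

A genetic risk score (GRS) is built as the weighted sum of allele
dosages — weighted by each variant's SBP-lowering effect — and
standardized to mean 0, SD 1 across the analysis cohort. ICD-9/ICD-10
diagnosis records are grouped into phecodes; for each phecode, cases are
individuals carrying it, individuals carrying only a related phecode
(inside the phecode's exclusion ranges) are removed from the comparison,
and the remainder of the cohort serve as controls. Association is by
logistic regression of case status on the standardized GRS adjusted for
age, sex and genetic principal components, restricted to phecodes with
at least ``min_cases`` cases, with Benjamini-Hochberg control of the
false-discovery rate across the phenome.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

#: Covariate presets: discovery-biobank style (4 PCs) and replication style (3 PCs).
COVARIATE_PRESETS = {
    "ukb": ("age", "sex", "PC1", "PC2", "PC3", "PC4"),
    "biovu": ("age", "sex", "PC1", "PC2", "PC3"),
}


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    ``dosages`` is individuals x variants in [0, 2] (NaN = missing, mean
    imputed at scoring time); ``variants`` carries at least SNP, EA, OA.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.variants):
            raise ValueError("genotype matrix dimensions do not match id lists")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["SNP"])


def build_grs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> pd.Series:
    """Weighted, standardized genetic risk score per individual.

    ``weights`` columns: SNP, EA (effect allele), WEIGHT (mmHg SBP
    lowering per allele). Dosages counting the opposite allele are
    flipped (2 - d); missing dosages are mean-imputed per variant. The
    raw score sum(w_j * d_j) is standardized to mean 0, SD 1 over the
    cohort.
    """
    var = genotypes.variants.set_index("SNP")
    missing = [v for v in weights["SNP"] if v not in var.index]
    if missing:
        raise KeyError(f"weight variants absent from genotypes: {missing}")

    col = {v: i for i, v in enumerate(genotypes.variant_ids)}
    raw = np.zeros(len(genotypes.individual_ids))
    for row in weights.itertuples():
        d = genotypes.dosages[:, col[row.SNP]].copy()
        if np.isnan(d).any():
            d[np.isnan(d)] = np.nanmean(d)
        ea, oa = var.loc[row.SNP, "EA"], var.loc[row.SNP, "OA"]
        if row.EA == ea:
            pass
        elif row.EA == oa:
            d = 2.0 - d
        else:
            raise ValueError(
                f"weight allele {row.EA} for {row.SNP} matches neither dosage allele {ea}/{oa}"
            )
        raw += row.WEIGHT * d

    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("raw GRS has zero variance; cannot standardize")
    score = (raw - raw.mean()) / sd
    return pd.Series(score, index=pd.Index(genotypes.individual_ids, name="person_id"), name="grs")


# --------------------------------------------------------------- phecodes


def normalize_icd(code: str) -> str:
    """Case-fold and strip dots: real ICD files mix dialects."""
    return str(code).strip().upper().replace(".", "")


def normalize_phecode(code) -> str:
    """Canonical phecode string: trailing '.0' trimmed ('401.0' -> '401')."""
    s = str(code).strip()
    if s.endswith(".0"):
        s = s[:-2]
    return s


@dataclass
class PhecodeCatalog:
    """ICD-to-phecode map plus phecode definitions and exclusion ranges.

    ``icd_map``: (vocab, normalized ICD code) -> phecode.
    ``definitions``: indexed by phecode with label, category,
    exclude_ranges (list of (lo, hi) floats, inclusive) and sex
    ('F', 'M' or '' for both).
    """

    icd_map: dict[tuple[str, str], str]
    definitions: pd.DataFrame
    _prefix_lengths: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._prefix_lengths = sorted({len(k[1]) for k in self.icd_map}, reverse=True)

    def map_code(self, vocab: str, code: str) -> str | None:
        """Most-specific-prefix lookup of one ICD code."""
        norm = normalize_icd(code)
        for length in self._prefix_lengths:
            if length > len(norm):
                continue
            hit = self.icd_map.get((vocab, norm[:length]))
            if hit is not None:
                return hit
        return None

    def exclude_ranges(self, phecode: str) -> list[tuple[float, float]]:
        return self.definitions.loc[normalize_phecode(phecode), "exclude_ranges"]

    def sex_restriction(self, phecode: str) -> str:
        if "sex" not in self.definitions.columns:
            return ""
        val = self.definitions.loc[normalize_phecode(phecode), "sex"]
        return "" if pd.isna(val) else str(val)

    # ------------------------------------------------------------- I/O

    @staticmethod
    def _parse_ranges(spec) -> list[tuple[float, float]]:
        if spec is None or (isinstance(spec, float) and math.isnan(spec)) or str(spec).strip() == "":
            return []
        out = []
        for part in str(spec).split(";"):
            lo, hi = part.split("-")
            out.append((float(lo), float(hi)))
        return out

    @staticmethod
    def _format_ranges(ranges: list[tuple[float, float]]) -> str:
        return ";".join(f"{lo:g}-{hi:g}" for lo, hi in ranges)

    @classmethod
    def from_frames(cls, icd_map: pd.DataFrame, definitions: pd.DataFrame) -> "PhecodeCatalog":
        mapping = {
            (row.vocab, normalize_icd(row.code)): normalize_phecode(row.phecode)
            for row in icd_map.itertuples()
        }
        defs = definitions.copy()
        defs["phecode"] = defs["phecode"].map(normalize_phecode)
        defs["exclude_ranges"] = defs["exclude_range"].map(cls._parse_ranges)
        defs = defs.set_index("phecode")
        return cls(mapping, defs)

    @classmethod
    def read(cls, map_path, defs_path) -> "PhecodeCatalog":
        icd_map = pd.read_csv(map_path, dtype={"vocab": str, "code": str, "phecode": str})
        defs = pd.read_csv(defs_path, dtype={"phecode": str})
        return cls.from_frames(icd_map, defs)

    def write(self, map_path, defs_path) -> None:
        rows = [
            {"vocab": vocab, "code": code, "phecode": phecode}
            for (vocab, code), phecode in sorted(self.icd_map.items())
        ]
        pd.DataFrame(rows).to_csv(map_path, index=False)
        defs = self.definitions.reset_index()
        defs["exclude_range"] = defs["exclude_ranges"].map(self._format_ranges)
        cols = ["phecode", "label", "category", "exclude_range"]
        if "sex" in defs.columns:
            cols.append("sex")
        defs.to_csv(defs_path, index=False, columns=cols)


def map_icd_to_phecodes(icd_records: pd.DataFrame, catalog: PhecodeCatalog) -> pd.DataFrame:
    """Distinct (person_id, phecode) pairs from raw diagnosis records.

    Unmapped codes are counted and logged, never fatal.
    """
    if icd_records.empty:
        return pd.DataFrame(columns=["person_id", "phecode"])
    pairs = icd_records[["vocab", "code"]].drop_duplicates()
    pairs = pairs.assign(
        phecode=[catalog.map_code(v, c) for v, c in zip(pairs["vocab"], pairs["code"])]
    )
    n_unmapped = int(pairs["phecode"].isna().sum())
    if n_unmapped:
        logger.info("%d distinct ICD codes did not map to a phecode", n_unmapped)
    merged = icd_records.merge(pairs, on=["vocab", "code"], how="left")
    merged = merged.dropna(subset=["phecode"])
    out = merged[["person_id", "phecode"]].drop_duplicates().reset_index(drop=True)
    out["person_id"] = out["person_id"].astype(str)
    return out


@dataclass
class CaseControlSet:
    """Case/control/excluded partition of the cohort for one phecode."""

    phecode: str
    case_ids: set[str]
    control_ids: set[str]
    excluded_ids: set[str]

    def __post_init__(self) -> None:
        if self.case_ids & self.control_ids or self.case_ids & self.excluded_ids or (
            self.control_ids & self.excluded_ids
        ):
            raise ValueError("case/control/excluded sets must be disjoint")

    @property
    def n_case(self) -> int:
        return len(self.case_ids)

    @property
    def n_control(self) -> int:
        return len(self.control_ids)


def build_case_control(
    person_phecodes: pd.DataFrame,
    catalog: PhecodeCatalog,
    cohort_ids,
    phecode: str,
) -> CaseControlSet:
    """Partition the cohort into cases, controls and range-excluded persons.

    Cases carry the phecode; excluded persons lack it but carry some
    phecode inside its exclusion ranges (related conditions that would
    contaminate the control group); controls are everyone else.
    """
    phecode = normalize_phecode(phecode)
    if phecode not in catalog.definitions.index:
        raise KeyError(f"unknown phecode: {phecode}")
    cohort = {str(i) for i in cohort_ids}
    pp = person_phecodes[person_phecodes["person_id"].isin(cohort)]
    cases = set(pp.loc[pp["phecode"] == phecode, "person_id"])
    ranges = catalog.exclude_ranges(phecode)
    related: set[str] = set()
    if ranges:
        values = pp["phecode"].astype(float)
        mask = np.zeros(len(pp), dtype=bool)
        for lo, hi in ranges:
            mask |= (values >= lo) & (values <= hi)
        related = set(pp.loc[mask, "person_id"])
    excluded = related - cases
    controls = cohort - cases - excluded
    return CaseControlSet(phecode, cases, controls, excluded)


@dataclass
class AssocResult:
    """One phecode's association with the standardized GRS."""

    phecode: str
    log_or: float
    se: float
    pvalue: float
    n_case: int
    n_control: int
    converged: bool = True
    fdr_significant: bool = False

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)


def _fit_logit(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float] | None:
    """Fit a logistic model; return (beta, se, p) of column 1 or None."""
    # constant covariate columns (e.g. sex after a sex restriction) are dropped
    keep = np.concatenate([[True, True], design[:, 2:].std(axis=0) > 0])
    design = design[:, keep]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation/convergence become flags
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        ok = bool(fit.mle_retvals.get("converged", False)) and np.isfinite(fit.bse[1])
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        ok = False
    if not ok:
        return None
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def assoc_logistic(
    score: pd.Series,
    case_control: CaseControlSet,
    covariates: pd.DataFrame,
    covariate_cols: tuple[str, ...] = COVARIATE_PRESETS["ukb"],
) -> AssocResult:
    """Covariate-adjusted logistic regression of case status on the GRS.

    Non-convergence or perfect separation yields a flagged result with
    NaN estimates; such results are removed before FDR ranking.
    """
    ids = sorted(case_control.case_ids) + sorted(case_control.control_ids)
    y = np.zeros(len(ids))
    y[: case_control.n_case] = 1.0
    x = score.loc[ids].to_numpy(dtype=float)
    cov = covariates if "person_id" not in covariates.columns else covariates.set_index("person_id")
    cov = cov.loc[ids, list(covariate_cols)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(ids)), x, cov])
    est = _fit_logit(y, design)
    if est is None:
        return AssocResult(
            case_control.phecode,
            math.nan,
            math.nan,
            math.nan,
            case_control.n_case,
            case_control.n_control,
            converged=False,
        )
    beta, se, p = est
    return AssocResult(
        case_control.phecode,
        beta,
        se,
        p,
        case_control.n_case,
        case_control.n_control,
    )


def run_phewas(
    score: pd.Series,
    person_phecodes: pd.DataFrame,
    catalog: PhecodeCatalog,
    covariates: pd.DataFrame,
    covariate_cols: tuple[str, ...] = COVARIATE_PRESETS["ukb"],
    min_cases: int = 200,
    fdr: float = 0.05,
    sex_column: str = "sex",
    female_code: float = 1.0,
) -> pd.DataFrame:
    """Phenome-wide scan of the standardized GRS across all phecodes.

    Per phecode: case-control build (with related-phecode exclusions and
    any sex restriction the catalog declares) -> minimum-case floor ->
    adjusted logistic fit. Benjamini-Hochberg at ``fdr`` is applied
    across the phecodes that produced an estimate. Returns a DataFrame
    sorted by P with one row per emitted phecode; an empty frame is
    legal.
    """
    # one aligned numeric view of the cohort; phecode partitions are then
    # boolean masks over it, which keeps a 200+-phecode scan fast
    persons = list(score.index.astype(str))
    n = len(persons)
    row_of = {p: i for i, p in enumerate(persons)}
    cov_indexed = covariates if "person_id" not in covariates.columns else covariates.set_index(
        "person_id"
    )
    cov_arr = cov_indexed.loc[persons, list(covariate_cols)].to_numpy(dtype=float)
    base_design = np.column_stack([np.ones(n), score.to_numpy(dtype=float), cov_arr])
    sex_arr = (
        cov_indexed.loc[persons, sex_column].to_numpy(dtype=float)
        if sex_column in cov_indexed.columns
        else None
    )

    pp = person_phecodes[person_phecodes["person_id"].astype(str).isin(row_of)]
    pp_rows = pp["person_id"].astype(str).map(row_of).to_numpy(dtype=int)
    pp_values = pp["phecode"].astype(float).to_numpy()
    pp_codes = pp["phecode"].map(normalize_phecode).to_numpy()

    results: list[AssocResult] = []
    for phecode in catalog.definitions.index:
        in_cohort = np.ones(n, dtype=bool)
        restriction = catalog.sex_restriction(phecode)
        if restriction in ("F", "M") and sex_arr is not None:
            wanted = female_code if restriction == "F" else 1.0 - female_code
            in_cohort = sex_arr == wanted
        is_case = np.zeros(n, dtype=bool)
        is_case[pp_rows[pp_codes == phecode]] = True
        is_related = np.zeros(n, dtype=bool)
        for lo, hi in catalog.exclude_ranges(phecode):
            is_related[pp_rows[(pp_values >= lo) & (pp_values <= hi)]] = True
        use = in_cohort & (is_case | ~is_related)
        y = is_case[use].astype(float)
        n_case = int(y.sum())
        n_control = int(len(y) - n_case)
        if n_case < min_cases or n_control == 0:
            continue
        est = _fit_logit(y, base_design[use])
        if est is None:
            results.append(
                AssocResult(phecode, math.nan, math.nan, math.nan, n_case, n_control, converged=False)
            )
        else:
            beta, se, p = est
            results.append(AssocResult(phecode, beta, se, p, n_case, n_control))

    frame = pd.DataFrame(
        [
            {
                "phecode": r.phecode,
                "log_or": r.log_or,
                "odds_ratio": math.exp(r.log_or) if r.converged else math.nan,
                "se": r.se,
                "pvalue": r.pvalue,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "converged": r.converged,
            }
            for r in results
        ]
    )
    if frame.empty:
        frame["fdr_significant"] = pd.Series(dtype=bool)
        return frame
    frame["fdr_significant"] = False
    est = frame["converged"] & frame["pvalue"].notna()
    if est.any():
        flags, *_ = multipletests(frame.loc[est, "pvalue"], alpha=fdr, method="fdr_bh")
        frame.loc[est, "fdr_significant"] = flags
    frame = frame.merge(
        catalog.definitions.reset_index()[["phecode", "label", "category"]], on="phecode", how="left"
    )
    return frame.sort_values("pvalue", na_position="last").reset_index(drop=True)
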