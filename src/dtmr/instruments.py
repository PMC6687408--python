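"""Instrument selection for drug-target genetic proxies.

Variants that proxy pharmacological modulation of an antihypertensive
drug target are selected from systolic-blood-pressure (SBP) GWAS summary
statistics restricted to the target's gene/promoter/enhancer regions,
filtered at genome-wide significance (P < 5e-8 by default) and greedily
thinned ("clumped") so that no retained pair exceeds an LD r-squared
threshold (0.1 by default). Per-instrument strength is summarized by the
F statistic (beta/se)^2 and the variance explained
R^2 = 2*EAF*(1-EAF)*beta^2 / var(trait).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LdMatrix

logger = logging.getLogger(__name__)

DRUG_CLASSES = ("ACEI", "ARB", "BB", "CCB", "THIAZIDE")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GenomicRegion:
    """A drug-target interval (gene, promoter or enhancer), 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int
    kind: str = "gene"
    drug_class: str = "CCB"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    exclusion_list: tuple[str, ...] = ()
    trait_variance: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.trait_variance <= 0:
            raise ValueError("trait_variance must be positive")


@dataclass
class InstrumentSet:
    """Selected, strength-annotated instruments for one drug class.

    ``records`` holds the exposure summary statistics of the retained
    variants; ``ld`` the signed LD submatrix in the same order; ``f_stat``
    and ``r2`` the per-variant strength statistics.
    """

    drug_class: str
    records: pd.DataFrame
    ld: LdMatrix
    f_stat: np.ndarray = field(default_factory=lambda: np.array([]))
    r2: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records["SNP"])

    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def is_empty(self) -> bool:
        return self.n_snps == 0


def regions_to_frame(regions: list[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "CHR": [r.chrom for r in regions],
            "START": [r.start for r in regions],
            "END": [r.end for r in regions],
            "NAME": [r.name for r in regions],
            "KIND": [r.kind for r in regions],
            "DRUG_CLASS": [r.drug_class for r in regions],
        }
    )


def frame_to_regions(frame: pd.DataFrame) -> list[GenomicRegion]:
    return [
        GenomicRegion(
            name=row.NAME,
            chrom=str(row.CHR),
            start=int(row.START),
            end=int(row.END),
            kind=row.KIND,
            drug_class=row.DRUG_CLASS,
        )
        for row in frame.itertuples()
    ]


def filter_to_regions(
    sumstats: pd.DataFrame,
    regions: list[GenomicRegion] | pd.DataFrame,
    drug_class: str | None = None,
) -> pd.DataFrame:
    """Restrict summary statistics to variants inside target regions.

    Inclusion is 1-based and inclusive at both interval ends. Both files
    must use the same chromosome labelling; a complete mismatch (no label
    in common) is treated as an error rather than an empty result.
    """
    if isinstance(regions, pd.DataFrame):
        regions = frame_to_regions(regions)
    if drug_class is not None:
        regions = [r for r in regions if r.drug_class == drug_class]
    if not regions:
        return sumstats.iloc[0:0]

    ss_chroms = set(sumstats["CHR"].astype(str))
    region_chroms = {r.chrom for r in regions}
    if ss_chroms and region_chroms and not (ss_chroms & region_chroms):
        raise ValueError(
            "chromosome labels do not overlap between summary statistics "
            f"({sorted(ss_chroms)[:5]}...) and regions ({sorted(region_chroms)[:5]}...)"
        )

    chrom = sumstats["CHR"].astype(str).to_numpy()
    pos = sumstats["POS"].to_numpy()
    keep = np.zeros(len(sumstats), dtype=bool)
    for r in regions:
        keep |= (chrom == r.chrom) & (pos >= r.start) & (pos <= r.end)
    return sumstats.loc[keep]


def ld_clump(records: pd.DataFrame, ld: LdMatrix, r2_threshold: float) -> pd.DataFrame:
    """Greedy LD clumping of summary-stat records.

    Records are ranked by ascending P (ties broken lexicographically by
    variant id, making the output invariant to input order); the best
    remaining record is kept and every other record with r^2 >= threshold
    against it is discarded, until the list is exhausted. The returned
    frame preserves kept order.
    """
    if records.empty:
        return records
    missing = [v for v in records["SNP"] if v not in ld]
    if missing:
        raise KeyError(f"records missing from LD matrix: {missing}")

    ranked = records.sort_values(["P", "SNP"], kind="mergesort")
    sub = ld.submatrix(list(ranked["SNP"]))
    r2 = sub.r2()
    n = len(ranked)
    alive = np.ones(n, dtype=bool)
    kept: list[int] = []
    for i in range(n):
        if not alive[i]:
            continue
        kept.append(i)
        alive &= r2[i] < r2_threshold
        alive[i] = False
    return ranked.iloc[kept]


@dataclass(frozen=True)
class HarmonizationVerdict:
    """Outcome of aligning one outcome record to the exposure orientation."""

    variant_id: str
    action: str  # keep | flip | complement | complement_flip | drop
    reason: str = ""

    @property
    def dropped(self) -> bool:
        return self.action == "drop"


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: pd.Series,
    outcome: pd.Series,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> tuple[pd.Series | None, HarmonizationVerdict]:
    """Align one outcome record to the exposure's allele orientation.

    Swapped alleles flip the outcome beta sign and complement the EAF;
    strand-flipped non-palindromic alleles are complemented then aligned.
    Palindromic variants (A/T, C/G) whose outcome EAF lies inside the
    ambiguity window are dropped: their strand cannot be resolved from
    frequency alone.
    """
    if exposure["SNP"] != outcome["SNP"]:
        raise ValueError(f"variant id mismatch: {exposure['SNP']} vs {outcome['SNP']}")
    vid = exposure["SNP"]
    e_ea, e_oa = exposure["EA"], exposure["OA"]
    o_ea, o_oa = outcome["EA"], outcome["OA"]

    if _is_palindromic(o_ea, o_oa):
        lo, hi = palindrome_eaf_window
        eaf = outcome["EAF"]
        if pd.isna(eaf) or lo <= eaf <= hi:
            return None, HarmonizationVerdict(
                vid, "drop", f"palindromic with ambiguous EAF {eaf!r} in [{lo}, {hi}]"
            )

    def flipped(rec: pd.Series) -> pd.Series:
        out = rec.copy()
        out["EA"], out["OA"] = rec["OA"], rec["EA"]
        out["BETA"] = -rec["BETA"]
        if not pd.isna(rec["EAF"]):
            out["EAF"] = 1.0 - rec["EAF"]
        return out

    if (o_ea, o_oa) == (e_ea, e_oa):
        return outcome.copy(), HarmonizationVerdict(vid, "keep")
    if (o_ea, o_oa) == (e_oa, e_ea):
        return flipped(outcome), HarmonizationVerdict(vid, "flip")

    c_ea = _COMPLEMENT.get(o_ea)
    c_oa = _COMPLEMENT.get(o_oa)
    if c_ea is not None and c_oa is not None and not _is_palindromic(o_ea, o_oa):
        comp = outcome.copy()
        comp["EA"], comp["OA"] = c_ea, c_oa
        if (c_ea, c_oa) == (e_ea, e_oa):
            return comp, HarmonizationVerdict(vid, "complement")
        if (c_ea, c_oa) == (e_oa, e_ea):
            return flipped(comp), HarmonizationVerdict(vid, "complement_flip")

    return None, HarmonizationVerdict(
        vid, "drop", f"irreconcilable alleles {o_ea}/{o_oa} vs {e_ea}/{e_oa}"
    )


def harmonize_sumstats(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, list[HarmonizationVerdict]]:
    """Align an outcome table to the exposure orientation, variant by variant.

    Returns the harmonized outcome subset (exposure order, dropped
    variants omitted) and the full list of verdicts.
    """
    out_by_id = {row["SNP"]: row for _, row in outcome.iterrows()}
    rows, verdicts = [], []
    for _, exp in exposure.iterrows():
        out = out_by_id.get(exp["SNP"])
        if out is None:
            verdicts.append(HarmonizationVerdict(exp["SNP"], "drop", "absent from outcome"))
            continue
        aligned, verdict = harmonize(exp, out)
        verdicts.append(verdict)
        if aligned is not None:
            rows.append(aligned)
    for v in verdicts:
        if v.dropped:
            logger.info("harmonization dropped %s: %s", v.variant_id, v.reason)
    aligned_df = pd.DataFrame(rows) if rows else outcome.iloc[0:0]
    return aligned_df.reset_index(drop=True), verdicts


def instrument_strength(
    beta: float, se: float, eaf: float, trait_variance: float = 1.0
) -> tuple[float, float]:
    """Per-variant F statistic and variance explained.

    F = (beta/se)^2;  R^2 = 2*eaf*(1-eaf)*beta^2 / trait_variance.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0 < eaf < 1):
        raise ValueError("eaf must lie strictly inside (0, 1)")
    f = (beta / se) ** 2
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2 / trait_variance
    return float(f), float(r2)


def select_instruments(
    sumstats: pd.DataFrame,
    regions: list[GenomicRegion] | pd.DataFrame,
    ld: LdMatrix,
    config: SelectionConfig | None = None,
    drug_class: str | None = None,
    clump: bool = True,
) -> InstrumentSet:
    """Full selection pipeline for one drug class.

    Region restriction -> pleiotropy exclusion list -> genome-wide
    significance filter -> LD clumping -> strength statistics. An empty
    result is legal and logged, not an error.
    """
    config = config or SelectionConfig()
    in_regions = filter_to_regions(sumstats, regions, drug_class=drug_class)
    kept = in_regions[~in_regions["SNP"].isin(config.exclusion_list)]
    kept = kept[kept["P"] < config.p_threshold]
    if clump and not kept.empty:
        kept = ld_clump(kept, ld, config.r2_threshold)
    kept = kept.reset_index(drop=True)

    label = drug_class if drug_class is not None else "all"
    if kept.empty:
        logger.warning("no instruments selected for drug class %s", label)
        return InstrumentSet(label, kept, LdMatrix([], np.zeros((0, 0))))

    f_stat, r2 = zip(
        *(
            instrument_strength(row.BETA, row.SE, row.EAF, config.trait_variance)
            for row in kept.itertuples()
        )
    )
    sub = ld.submatrix(list(kept["SNP"]))
    return InstrumentSet(label, kept, sub, np.asarray(f_stat), np.asarray(r2))
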