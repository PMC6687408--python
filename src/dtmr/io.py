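"""Readers and writers for the pipeline's delimited text formats.

Formats
-------
* Summary statistics: tab-delimited ``SNP CHR POS EA OA EAF BETA SE P N``;
  missing values as ``NA``.
* Regions: BED-like tab-delimited ``CHR START END NAME KIND DRUG_CLASS``;
  coordinates are 1-based inclusive, declared in a ``#`` header line.
* Genotypes: tab-delimited individual x variant dosage matrix with id
  header row/column.
* ICD diagnosis records: CSV ``person_id,vocab,code,date`` with vocab in
  {ICD9, ICD10}.
* Phecode map: CSV ``vocab,code,phecode``; phecode definitions: CSV
  ``phecode,label,category,exclude_range`` (ranges dash-separated,
  semicolon-delimited for multiples, optional ``sex`` column).
* GRS weights: tab-delimited ``SNP EA WEIGHT``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
REGION_COLUMNS = ["CHR", "START", "END", "NAME", "KIND", "DRUG_CLASS"]

_REGION_HEADER = "# coordinates: 1-based, inclusive at both ends"


def write_sumstats(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", columns=[c for c in SUMSTAT_COLUMNS if c in frame.columns])


def read_sumstats(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"SNP": str, "CHR": str})
    missing = set(SUMSTAT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns {sorted(missing)}")
    return frame


def write_regions(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_REGION_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False, columns=REGION_COLUMNS)


def read_regions(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    missing = set(REGION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"region file {path} lacks columns {sorted(missing)}")
    return frame


def write_genotypes(dosages: np.ndarray, individual_ids, variant_ids, path) -> None:
    frame = pd.DataFrame(dosages, index=individual_ids, columns=variant_ids)
    frame.to_csv(path, sep="\t", index_label="IID")


def read_genotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def write_icd_records(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=["person_id", "vocab", "code", "date"])


def read_icd_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"person_id": str, "vocab": str, "code": str})
    bad = set(frame["vocab"].unique()) - {"ICD9", "ICD10"}
    if bad:
        raise ValueError(f"unknown ICD vocabularies in {path}: {sorted(bad)}")
    return frame


def write_covariates(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"person_id": str})


def write_grs_weights(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=["SNP", "EA", "WEIGHT"])


def read_grs_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"SNP": str, "EA": str})


def write_exclusion_list(ids, path) -> None:
    with open(path, "w") as fh:
        for v in ids:
            fh.write(f"{v}\n")


def read_exclusion_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
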