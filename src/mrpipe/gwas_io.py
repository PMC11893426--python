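"""Reading, validating, and writing GWAS summary-statistics tables.

The canonical on-disk format is delimited text (tab-separated by default)
with one header row.  A :class:`ColumnMap` adapts arbitrary column dialects
(FinnGen, Olink pQTL exports and metabolite GWAS all name their columns
differently) to the canonical fields of :class:`SummaryRecord`.

Rows that violate the record invariants are dropped, never coerced: every
dropped row carries exactly one reason code in the drop log.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: p-values of exactly 0 are floored here so downstream logs are finite.
P_FLOOR = 1e-300

#: canonical field names every summary-statistics table must provide
REQUIRED_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    binary traits, SD units for continuous traits); ``eaf`` is the
    effect-allele frequency and may be NaN when the source omits it
    (only palindromic-SNP orientation needs it downstream).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class ColumnMap:
    """Mapping from canonical field names to source column headers."""

    mapping: dict[str, str]
    na_values: Sequence[str] = ("NA", "nan", ".", "")
    sep: str = "\t"

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.mapping]
        if missing:
            raise ValueError(f"ColumnMap is missing required fields: {missing}")

    @classmethod
    def identity(cls, sep: str = "\t") -> "ColumnMap":
        return cls(mapping={f: f for f in REQUIRED_FIELDS}, sep=sep)


@dataclass
class DropLogEntry:
    row: int
    snp_id: str
    reason: str


@dataclass
class ReadResult:
    records: list[SummaryRecord]
    drop_log: list[DropLogEntry] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.drop_log)


def _validate_row(row: pd.Series, idx: int) -> SummaryRecord | DropLogEntry:
    snp_id = str(row["snp_id"])
    ea = str(row["effect_allele"]).upper()
    oa = str(row["other_allele"]).upper()
    if len(ea) != 1 or len(oa) != 1 or ea not in VALID_BASES or oa not in VALID_BASES:
        return DropLogEntry(idx, snp_id, "indel_or_invalid_allele")
    if ea == oa:
        return DropLogEntry(idx, snp_id, "identical_alleles")
    try:
        pos = int(row["pos"])
        eaf = float(row["eaf"]) if pd.notna(row["eaf"]) else math.nan
        beta = float(row["beta"])
        se = float(row["se"])
        pval = float(row["pval"])
        n = float(row["n"])
    except (TypeError, ValueError):
        return DropLogEntry(idx, snp_id, "non_numeric_field")
    if not math.isfinite(beta) or not math.isfinite(se):
        return DropLogEntry(idx, snp_id, "non_numeric_field")
    if se <= 0:
        return DropLogEntry(idx, snp_id, "nonpositive_se")
    if pos < 1:
        return DropLogEntry(idx, snp_id, "invalid_position")
    if not math.isnan(eaf) and not 0.0 <= eaf <= 1.0:
        return DropLogEntry(idx, snp_id, "eaf_out_of_range")
    if not 0.0 <= pval <= 1.0:
        return DropLogEntry(idx, snp_id, "pval_out_of_range")
    if n <= 0:
        return DropLogEntry(idx, snp_id, "nonpositive_n")
    return SummaryRecord(
        snp_id=snp_id,
        chrom=str(row["chrom"]),
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=max(pval, P_FLOOR),
        n=n,
    )


def read_summary_stats(path: str | Path, colmap: ColumnMap | None = None) -> ReadResult:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    colmap:
        Column dialect; defaults to the canonical field names themselves.

    Raises
    ------
    KeyError
        if a mapped source column is absent from the file.
    ValueError
        if no row survives validation.
    """
    colmap = colmap or ColumnMap.identity()
    df = pd.read_csv(path, sep=colmap.sep, na_values=list(colmap.na_values),
                     keep_default_na=True, dtype={colmap.mapping["snp_id"]: str})
    missing = [src for src in colmap.mapping.values() if src not in df.columns]
    if missing:
        raise KeyError(f"mapped column(s) not found in {path}: {missing}")
    df = df.rename(columns={src: canon for canon, src in colmap.mapping.items()})

    records: list[SummaryRecord] = []
    drop_log: list[DropLogEntry] = []
    for idx, row in df.iterrows():
        out = _validate_row(row, int(idx))
        if isinstance(out, DropLogEntry):
            logger.info("dropping row %d (%s): %s", out.row, out.snp_id, out.reason)
            drop_log.append(out)
        else:
            records.append(out)
    if not records:
        raise ValueError(f"no valid summary-statistics rows in {path}")
    return ReadResult(records=records, drop_log=drop_log)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert a collection of dataclass records (or dicts) to a DataFrame."""
    rows = []
    for r in records:
        rows.append(dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r))
    return pd.DataFrame(rows)


def write_results_table(records, path: str | Path) -> None:
    """Write any report collection as TSV with full float precision.

    Floats are serialised with 17 significant digits so a write→read
    round-trip is the identity on numeric fields.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    if df.empty:
        raise ValueError("refusing to write an empty results table")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
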