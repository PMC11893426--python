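"""Instrument selection: p-value screening, LD clumping, strength, proxies.

Instruments are exposure-associated SNPs that are mutually independent
(greedy PLINK-style clumping at r² ≤ 0.001 within 10,000 kb by default)
and strong (per-SNP F = (beta/se)² ≥ 10 by convention, the weak-instrument
floor).  When an instrument is missing from the outcome GWAS a linkage
proxy at r² > 0.8 can stand in for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gwas_io import SummaryRecord

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0
DEFAULT_PROXY_R2 = 0.8


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise r² values over a fixed SNP id list."""

    ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match id list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r² values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def pair_r2(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} absent from LD matrix") from None

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "LDMatrix":
        """LD matrix for mutually independent SNPs (r² = 0 off-diagonal)."""
        return cls(ids=list(ids), r2=np.eye(len(ids)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], r2=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


@dataclass
class InstrumentRecord:
    """A candidate instrument with its strength and keep/drop status."""

    record: SummaryRecord
    f_stat: float
    kept: bool
    drop_reason: str = ""


@dataclass
class InstrumentSet:
    instruments: list[SummaryRecord]
    audit: list[InstrumentRecord] = field(default_factory=list)
    mean_f: float = float("nan")


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument strength, the squared Wald Z: F = (beta/se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def select_by_pvalue(
    stats: Iterable[SummaryRecord], p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[SummaryRecord]:
    """Keep exactly the records with pval strictly below the threshold."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    return [r for r in stats if r.pval < p_threshold]


def ld_clump(
    candidates: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> list[SummaryRecord]:
    """Greedy clumping: keep the best remaining SNP by p, prune its window.

    Candidates are first sorted by (p, id) so the result does not depend on
    input order.  A pruned SNP is one on the same chromosome, within
    ``window_kb`` of a kept SNP, with r² above ``r2_max`` against it.
    """
    for c in candidates:
        if c.snp_id not in ld:
            raise KeyError(f"candidate SNP {c.snp_id!r} absent from LD matrix")
    remaining = sorted(candidates, key=lambda r: (r.pval, r.snp_id))
    window_bp = window_kb * 1000
    kept: list[SummaryRecord] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == best.chrom
                and abs(r.pos - best.pos) <= window_bp
                and ld.pair_r2(best.snp_id, r.snp_id) > r2_max
            )
        ]
    return kept


def filter_by_strength(
    stats: Iterable[SummaryRecord], f_min: float = DEFAULT_F_MIN
) -> InstrumentSet:
    """Apply the per-SNP F ≥ f_min weak-instrument filter.

    Both the per-SNP decision and the mean F across candidates are
    reported, since strength rules are quoted either way in practice.
    """
    audit: list[InstrumentRecord] = []
    kept: list[SummaryRecord] = []
    fs: list[float] = []
    for r in stats:
        f = f_statistic(r.beta, r.se)
        fs.append(f)
        if f >= f_min:
            kept.append(r)
            audit.append(InstrumentRecord(r, f, True))
        else:
            audit.append(InstrumentRecord(r, f, False, "weak_instrument"))
    mean_f = float(np.mean(fs)) if fs else float("nan")
    return InstrumentSet(instruments=kept, audit=audit, mean_f=mean_f)


def select_instruments(
    stats: Sequence[SummaryRecord],
    ld: LDMatrix | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
    f_min: float | None = DEFAULT_F_MIN,
) -> InstrumentSet:
    """Full selection: p-value screen → LD clump → strength filter.

    ``ld=None`` treats the candidates as mutually independent (no clump),
    which is exact for the synthetic generator's independent SNPs.
    """
    cands = select_by_pvalue(stats, p_threshold)
    if ld is not None:
        cands = ld_clump(cands, ld, r2_max=r2_max, window_kb=window_kb)
    if f_min is None:
        return InstrumentSet(instruments=list(cands))
    out = filter_by_strength(cands, f_min)
    return out


def find_proxy(
    missing: str,
    ld: LDMatrix,
    pool: Sequence[SummaryRecord],
    r2_min: float = DEFAULT_PROXY_R2,
) -> SummaryRecord | None:
    """Best available LD proxy for a SNP absent from the outcome GWAS.

    Returns the pool SNP with the highest r² to ``missing`` among those
    with r² strictly above ``r2_min``; ties break by smaller p, then id.
    """
    if missing not in ld:
        raise KeyError(f"SNP {missing!r} absent from LD matrix")
    best: SummaryRecord | None = None
    best_key: tuple[float, float, str] | None = None
    for r in pool:
        if r.snp_id == missing or r.snp_id not in ld:
            continue
        r2 = ld.pair_r2(missing, r.snp_id)
        if r2 <= r2_min:
            continue
        key = (-r2, r.pval, r.snp_id)
        if best_key is None or key < best_key:
            best, best_key = r, key
    return best
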