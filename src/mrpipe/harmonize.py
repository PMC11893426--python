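"""Allele-specific harmonization of exposure and outcome effects.

Two GWAS can report the same SNP on different effect alleles or opposite
strands.  Harmonization rewrites the outcome effect so that it refers to
the exposure's effect allele:

* same alleles, same orientation          → unchanged
* alleles swapped                          → outcome beta sign-flipped,
                                             eaf complemented
* complementary-strand labels              → complemented, then matched
* palindromic (A/T or C/G) with either
  frequency near 0.5                       → dropped (strand unresolvable)
* palindromic with informative frequencies → oriented by the side of 0.5
* incompatible allele sets                 → dropped

Exposure fields are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

from .gwas_io import SummaryRecord
from .instruments import LDMatrix, find_proxy

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: drop palindromic SNPs whose eaf lies within this window of 0.5
DEFAULT_EAF_WINDOW = 0.08

ACTION_UNCHANGED = "unchanged"
ACTION_SIGN_FLIPPED = "sign_flipped"
ACTION_STRAND_FLIPPED = "strand_flipped"
ACTION_DROPPED = "dropped"


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class HarmonizedRecord:
    """Exposure/outcome effect pair aligned to the exposure's effect allele."""

    snp_id: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf_x: float
    eaf_y: float
    action: str
    drop_reason: str = ""
    proxy_id: str = ""

    @property
    def dropped(self) -> bool:
        return self.action == ACTION_DROPPED


@dataclass
class HarmonizedSet:
    """All non-dropped harmonized records for one exposure–outcome pair."""

    exposure: str
    outcome: str
    records: list[HarmonizedRecord]
    drop_log: list[HarmonizedRecord] = field(default_factory=list)

    @property
    def nsnp(self) -> int:
        return len(self.records)

    def arrays(self):
        import numpy as np

        bx = np.array([r.bx for r in self.records])
        sx = np.array([r.sx for r in self.records])
        by = np.array([r.by for r in self.records])
        sy = np.array([r.sy for r in self.records])
        return bx, sx, by, sy

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, keep_ids) -> "HarmonizedSet":
        keep = set(keep_ids)
        return HarmonizedSet(
            exposure=self.exposure,
            outcome=self.outcome,
            records=[r for r in self.records if r.snp_id in keep],
            drop_log=list(self.drop_log),
        )


def _dropped(exp: SummaryRecord, out: SummaryRecord, reason: str) -> HarmonizedRecord:
    return HarmonizedRecord(
        snp_id=exp.snp_id,
        bx=exp.beta,
        sx=exp.se,
        by=out.beta,
        sy=out.se,
        eaf_x=exp.eaf,
        eaf_y=out.eaf,
        action=ACTION_DROPPED,
        drop_reason=reason,
    )


def harmonize_pair(
    exp: SummaryRecord,
    out: SummaryRecord,
    eaf_window: float = DEFAULT_EAF_WINDOW,
    keep_palindromes: bool = False,
) -> HarmonizedRecord:
    """Align one outcome record to the exposure's effect allele.

    ``keep_palindromes`` disables the ambiguity drop (sensitivity reruns);
    frequency-based orientation is still applied when possible.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id!r} vs {out.snp_id!r}")

    ex_pair = {exp.effect_allele, exp.other_allele}
    out_pair = {out.effect_allele, out.other_allele}
    comp_pair = {COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]}

    by, eaf_y = out.beta, out.eaf
    action = ACTION_UNCHANGED

    if is_palindromic(exp.effect_allele, exp.other_allele):
        # For A/T and C/G SNPs the complement equals the swap, so allele
        # labels cannot identify the strand; frequency must arbitrate.
        if out_pair != ex_pair:
            return _dropped(exp, out, "allele_mismatch")
        if math.isnan(exp.eaf) or math.isnan(out.eaf):
            return _dropped(exp, out, "missing_eaf_palindrome")
        ambiguous = min(abs(exp.eaf - 0.5), abs(out.eaf - 0.5)) < eaf_window
        if ambiguous and not keep_palindromes:
            return _dropped(exp, out, "ambiguous_palindrome")
        if out.effect_allele != exp.effect_allele:
            by, eaf_y = -by, 1 - eaf_y
            action = ACTION_SIGN_FLIPPED
        # Label-aligned; if the frequencies still disagree on the minor
        # allele the outcome is on the opposite strand.
        if (exp.eaf < 0.5) != (eaf_y < 0.5):
            by, eaf_y = -by, 1 - eaf_y
            action = ACTION_STRAND_FLIPPED
        rec = HarmonizedRecord(
            snp_id=exp.snp_id, bx=exp.beta, sx=exp.se, by=by, sy=out.se,
            eaf_x=exp.eaf, eaf_y=eaf_y, action=action,
        )
        return rec

    # Non-palindromic: try direct, swapped, then strand-complement forms.
    if out.effect_allele == exp.effect_allele and out.other_allele == exp.other_allele:
        action = ACTION_UNCHANGED
    elif out.effect_allele == exp.other_allele and out.other_allele == exp.effect_allele:
        by, eaf_y = -by, 1 - eaf_y
        action = ACTION_SIGN_FLIPPED
    elif comp_pair == ex_pair:
        cea = COMPLEMENT[out.effect_allele]
        coa = COMPLEMENT[out.other_allele]
        if cea == exp.effect_allele and coa == exp.other_allele:
            action = ACTION_STRAND_FLIPPED  # same orientation on the other strand
        else:
            by, eaf_y = -by, 1 - eaf_y
            action = ACTION_STRAND_FLIPPED  # opposite strand and swapped labels
    else:
        return _dropped(exp, out, "allele_mismatch")

    return HarmonizedRecord(
        snp_id=exp.snp_id, bx=exp.beta, sx=exp.se, by=by, sy=out.se,
        eaf_x=exp.eaf, eaf_y=eaf_y, action=action,
    )


def harmonize_sets(
    exp_instruments: Sequence[SummaryRecord],
    out_stats: Sequence[SummaryRecord] | Mapping[str, SummaryRecord],
    exposure: str = "exposure",
    outcome: str = "outcome",
    eaf_window: float = DEFAULT_EAF_WINDOW,
    keep_palindromes: bool = False,
    ld: LDMatrix | None = None,
    allow_proxies: bool = False,
    proxy_r2: float = 0.8,
) -> HarmonizedSet:
    """Inner-join instruments with outcome records and harmonize per SNP.

    With ``allow_proxies`` and an LD matrix, an instrument absent from the
    outcome GWAS is replaced by its best outcome-side proxy at
    r² > ``proxy_r2`` (the exposure effect stays that of the instrument).
    """
    if not exp_instruments:
        raise ValueError("empty instrument set")
    if isinstance(out_stats, Mapping):
        out_by_id = dict(out_stats)
        out_list = list(out_stats.values())
    else:
        out_by_id = {r.snp_id: r for r in out_stats}
        out_list = list(out_stats)

    records: list[HarmonizedRecord] = []
    drop_log: list[HarmonizedRecord] = []
    for exp in exp_instruments:
        out = out_by_id.get(exp.snp_id)
        proxy_id = ""
        if out is None and allow_proxies and ld is not None and exp.snp_id in ld:
            proxy = find_proxy(exp.snp_id, ld, out_list, r2_min=proxy_r2)
            if proxy is not None:
                out, proxy_id = proxy, proxy.snp_id
                # A proxy tags the same haplotype; its alleles need not match
                # the instrument's, so align only the id for bookkeeping.
                out = SummaryRecord(
                    snp_id=exp.snp_id, chrom=out.chrom, pos=out.pos,
                    effect_allele=exp.effect_allele, other_allele=exp.other_allele,
                    eaf=out.eaf, beta=out.beta, se=out.se, pval=out.pval, n=out.n,
                )
        if out is None:
            drop_log.append(_dropped(exp, exp, "missing_in_outcome"))
            continue
        rec = harmonize_pair(exp, out, eaf_window=eaf_window,
                             keep_palindromes=keep_palindromes)
        rec.proxy_id = proxy_id
        (drop_log if rec.dropped else records).append(rec)

    if not records:
        reasons = sorted({r.drop_reason for r in drop_log})
        raise ValueError(
            f"no SNP shared between {exposure!r} instruments and {outcome!r} "
            f"after harmonization (drop reasons: {reasons})"
        )
    return HarmonizedSet(exposure=exposure, outcome=outcome,
                         records=records, drop_log=drop_log)
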