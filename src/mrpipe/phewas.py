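"""Matched-control PheWAS trait enrichment.

To test whether a set of index variants (e.g. the instruments of a
protein that screened positive) is enriched for association with specific
traits, each index SNP is matched to control SNPs on annotation criteria:
minor allele frequency within ±0.05 (absolute) and gene density, distance
to the nearest gene, and number of LD partners (r² ≥ 0.50) each within
±50% (relative).  Per trait, the frequency of nominally associated SNPs
(p < 0.01) among index vs control variants is compared with a two-sided
Fisher's exact test, and the p-values are Benjamini–Hochberg adjusted
across traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MAF_WINDOW = 0.05          # absolute
RELATIVE_WINDOW = 0.50     # ±50% on the other three criteria
DEFAULT_N_CONTROLS = 4
DEFAULT_P_NOMINAL = 0.01


@dataclass(frozen=True)
class SNPAnnotation:
    """Matching annotation for one variant."""

    snp_id: str
    maf: float
    gene_density: float
    dist_nearest_gene: float
    n_ld_partners: float

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")


@dataclass
class EnrichmentResult:
    trait: str
    k_index: int
    n_index: int
    k_control: int
    n_control: int
    fisher_or: float  # NaN when undefined (zero associated SNPs in both arms)
    fisher_p: float
    fdr_p: float = float("nan")


def _within_relative(candidate: float, index: float, frac: float) -> bool:
    if index == 0:
        return candidate == 0
    return abs(candidate - index) <= frac * abs(index)


def is_eligible_control(index: SNPAnnotation, candidate: SNPAnnotation) -> bool:
    return (
        abs(candidate.maf - index.maf) <= MAF_WINDOW
        and _within_relative(candidate.gene_density, index.gene_density, RELATIVE_WINDOW)
        and _within_relative(candidate.dist_nearest_gene, index.dist_nearest_gene, RELATIVE_WINDOW)
        and _within_relative(candidate.n_ld_partners, index.n_ld_partners, RELATIVE_WINDOW)
    )


@dataclass
class MatchResult:
    controls: list[str]
    shortfall: int = 0


def match_controls(
    index: SNPAnnotation,
    pool: Sequence[SNPAnnotation],
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int | np.random.Generator = 0,
    exclude: set[str] | None = None,
) -> MatchResult:
    """Sample matched control SNPs for one index variant.

    Eligible pool members satisfy all four matching criteria; controls are
    drawn uniformly without replacement.  When fewer than ``n_controls``
    are eligible, all of them are returned and the shortfall recorded.
    """
    exclude = exclude or set()
    exclude = exclude | {index.snp_id}
    candidates = [a for a in pool if a.snp_id not in exclude]
    if not candidates:
        raise ValueError("empty control pool after exclusions")
    eligible = [a.snp_id for a in candidates if is_eligible_control(index, a)]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if len(eligible) <= n_controls:
        return MatchResult(controls=sorted(eligible),
                           shortfall=n_controls - len(eligible))
    picks = rng.choice(len(eligible), size=n_controls, replace=False)
    return MatchResult(controls=sorted(eligible[i] for i in picks))


def match_control_set(
    index_annotations: Sequence[SNPAnnotation],
    pool: Sequence[SNPAnnotation],
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int | np.random.Generator = 0,
) -> dict[str, MatchResult]:
    """Match controls for every index SNP, never re-using a control."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    used: set[str] = {a.snp_id for a in index_annotations}
    out: dict[str, MatchResult] = {}
    for idx in index_annotations:
        res = match_controls(idx, pool, n_controls=n_controls, seed=rng, exclude=used)
        used.update(res.controls)
        out[idx.snp_id] = res
    return out


def trait_enrichment(
    assoc_table: pd.DataFrame | Mapping[tuple[str, str], float],
    index_ids: Sequence[str],
    control_ids: Sequence[str],
    p_nominal: float = DEFAULT_P_NOMINAL,
) -> list[EnrichmentResult]:
    """Per-trait Fisher enrichment of index vs control association counts.

    ``assoc_table`` is a long DataFrame with columns (snp_id, trait, p),
    a wide DataFrame (snp_id index × trait columns of p-values), or a
    mapping (snp_id, trait) → p.  Every listed SNP must be covered for
    every trait.
    """
    if isinstance(assoc_table, pd.DataFrame):
        if {"snp_id", "trait", "p"}.issubset(assoc_table.columns):
            wide = assoc_table.pivot(index="snp_id", columns="trait", values="p")
        else:
            wide = assoc_table
    else:
        long = pd.DataFrame(
            [(s, t, p) for (s, t), p in assoc_table.items()],
            columns=["snp_id", "trait", "p"],
        )
        wide = long.pivot(index="snp_id", columns="trait", values="p")
    missing = (set(index_ids) | set(control_ids)) - set(wide.index)
    if missing:
        raise ValueError(f"association table does not cover SNP(s): {sorted(missing)}")

    idx = wide.loc[list(index_ids)]
    ctl = wide.loc[list(control_ids)]
    n_index, n_control = len(index_ids), len(control_ids)
    results: list[EnrichmentResult] = []
    for trait in wide.columns:
        k_i = int((idx[trait] < p_nominal).sum())
        k_c = int((ctl[trait] < p_nominal).sum())
        degenerate = (k_i == 0 and k_c == 0) or (
            k_i == n_index and k_c == n_control
        )
        if degenerate:  # a zero margin leaves the odds ratio undefined
            orr, p = math.nan, 1.0
        else:
            table = [[k_i, n_index - k_i], [k_c, n_control - k_c]]
            orr, p = sps.fisher_exact(table, alternative="two-sided")
            orr = float(orr) if math.isfinite(orr) else math.inf
        results.append(EnrichmentResult(
            trait=str(trait), k_index=k_i, n_index=n_index,
            k_control=k_c, n_control=n_control,
            fisher_or=float(orr), fisher_p=float(p),
        ))
    pvals = [r.fisher_p for r in results]
    if pvals:
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, fdr):
            r.fdr_p = float(q)
    return results
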