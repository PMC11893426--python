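"""Synthetic GWAS summary statistics with known ground truth.

Every analysis stage in this package consumes summary-level data only, so
the generators here produce per-SNP (beta, se, p) tables with the
statistical structure the estimators assume:

* per-SNP standard errors scale as 1/sqrt(2·n·maf(1−maf)) — the
  standardized-trait approximation — so sample size and allele frequency
  enter the way they do in real GWAS;
* instruments satisfy the per-SNP F ≥ 10 strength rule by construction
  (resampled true effects), mirroring the selection applied to real data;
* a configurable share of SNPs can carry horizontal pleiotropy that is
  balanced (mean zero), directional (mean-shifted), or correlated with
  instrument strength (violating the InSIDE assumption);
* a mediator chain X→M→Y with direct effect produces three coherent
  GWAS so two-step mediation is testable end to end.

Defaults follow the study design this pipeline reproduces: an exposure
GWAS of n=14,824 (a 91-protein Olink panel), a binary-outcome GWAS of
n=73,479 (FinnGen male infertility), and a mediator GWAS of n=8,299
(plasma metabolites).  All generators are pure functions of
(scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import SummaryRecord
from .instruments import LDMatrix

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]

PLEIOTROPY_MODELS = ("none", "balanced", "directional", "inside_violating")


@dataclass
class MediatorChain:
    """True causal chain X→M→Y: M = a·X, Y = direct·X + b·M (+ noise)."""

    a: float = 0.4
    b: float = 0.3
    direct: float = 0.5
    #: when True, M is generated downstream of Y (M = a·Y) instead, so a
    #: mediator screen must reject it at step 2
    downstream_of_outcome: bool = False

    @property
    def total(self) -> float:
        return self.direct + self.a * self.b

    @property
    def true_proportion_pct(self) -> float:
        return 100.0 * self.a * self.b / self.total


@dataclass
class SimScenario:
    """Study conditions for one simulated exposure–outcome GWAS pair."""

    n_snps: int = 50
    theta: float = 0.0
    pleiotropy_model: str = "none"
    pleiotropy_sd: float = 0.05
    prop_pleiotropic: float = 0.3
    n_exposure: int = 14_824
    n_outcome: int = 73_479
    n_mediator: int = 8_299
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.05
    f_min: float = 10.0
    mediator_chain: MediatorChain | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_model not in PLEIOTROPY_MODELS:
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy_model!r}")
        if not 0 <= self.prop_pleiotropic <= 1:
            raise ValueError("prop_pleiotropic must lie in [0, 1]")
        if min(self.n_snps, self.n_exposure, self.n_outcome, self.n_mediator) <= 0:
            raise ValueError("sizes must be positive")


def _se(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def effective_n_binary(n_cases: int, n_controls: int) -> int:
    """Effective GWAS sample size of a case-control trait: 4/(1/n1+1/n0).

    Unbalanced binary outcomes (e.g. 680 infertility cases against 72,799
    controls) carry far less information than their total n suggests;
    pass this as ``n_outcome`` to emulate them.
    """
    return int(round(4.0 / (1.0 / n_cases + 1.0 / n_controls)))


def _draw_instrument_effects(
    rng: np.random.Generator, se_x: np.ndarray, effect_sd: float, f_min: float,
    max_tries: int = 100_000,
) -> np.ndarray:
    """True exposure effects resampled until every SNP has F ≥ f_min."""
    n = se_x.size
    bx = rng.normal(0.0, effect_sd, size=n)
    for _ in range(max_tries):
        weak = (bx / se_x) ** 2 < f_min
        if not weak.any():
            return bx
        bx[weak] = rng.normal(0.0, effect_sd, size=int(weak.sum()))
    raise RuntimeError(
        "could not satisfy the instrument-strength constraint; "
        "increase n_exposure or effect_sd"
    )


def _pleiotropy(
    rng: np.random.Generator, scenario: SimScenario, bx_true: np.ndarray
) -> np.ndarray:
    n = scenario.n_snps
    alpha = np.zeros(n)
    if scenario.pleiotropy_model == "none" or scenario.prop_pleiotropic == 0:
        return alpha
    mask = rng.random(n) < scenario.prop_pleiotropic
    k = int(mask.sum())
    sd = scenario.pleiotropy_sd
    if scenario.pleiotropy_model == "balanced":
        alpha[mask] = rng.normal(0.0, sd, size=k)
    elif scenario.pleiotropy_model == "directional":
        alpha[mask] = rng.normal(sd, sd, size=k)
    else:  # inside_violating: pleiotropy correlated with instrument strength
        rho = 0.5
        zx = (bx_true[mask] - bx_true.mean()) / max(bx_true.std(), 1e-12)
        alpha[mask] = sd * (rho * zx + np.sqrt(1 - rho**2) * rng.normal(size=k))
    return alpha


def _alleles(rng: np.random.Generator, n: int):
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    swap = rng.random(n) < 0.5
    ea, oa = [], []
    for i, s in zip(pair_idx, swap):
        a1, a2 = _ALLELE_PAIRS[i]
        ea.append(a2 if s else a1)
        oa.append(a1 if s else a2)
    return ea, oa


def _records(
    ids, chrom, pos, ea, oa, eaf, beta, se, n
) -> list[SummaryRecord]:
    pvals = 2 * sps.norm.sf(np.abs(beta) / se)
    return [
        SummaryRecord(
            snp_id=ids[j], chrom=str(chrom[j]), pos=int(pos[j]),
            effect_allele=ea[j], other_allele=oa[j], eaf=float(eaf[j]),
            beta=float(beta[j]), se=float(se[j]),
            pval=float(max(pvals[j], 1e-300)), n=float(n),
        )
        for j in range(len(ids))
    ]


def _positions(rng: np.random.Generator, n: int):
    """Spread SNPs across chromosomes, far apart (no residual LD)."""
    chrom = 1 + (np.arange(n) % 22)
    pos = 1_000_000 + (np.arange(n) // 22) * 20_000_000 + rng.integers(0, 1_000_000, n)
    return chrom, pos


def simulate_gwas_pair(
    scenario: SimScenario,
) -> tuple[list[SummaryRecord], list[SummaryRecord], pd.DataFrame]:
    """One exposure GWAS, one outcome GWAS, and the per-SNP ground truth.

    The outcome model is by_true = theta·bx_true + alpha with alpha set by
    the pleiotropy model; observed effects add N(0, se²) noise on each
    side.  The truth table carries every latent quantity per SNP.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_snps
    maf = rng.uniform(*scenario.maf_range, size=n)
    se_x = _se(scenario.n_exposure, maf)
    se_y = _se(scenario.n_outcome, maf)
    bx_true = _draw_instrument_effects(rng, se_x, scenario.effect_sd, scenario.f_min)
    alpha = _pleiotropy(rng, scenario, bx_true)
    by_true = scenario.theta * bx_true + alpha

    bx_obs = bx_true + rng.normal(0, se_x)
    by_obs = by_true + rng.normal(0, se_y)

    ids = [f"rs{j + 1:06d}" for j in range(n)]
    chrom, pos = _positions(rng, n)
    ea, oa = _alleles(rng, n)
    # effect-allele frequency: the minor allele is the effect allele half
    # the time, as in real exports
    eaf = np.where(rng.random(n) < 0.5, maf, 1 - maf)

    exposure = _records(ids, chrom, pos, ea, oa, eaf, bx_obs, se_x, scenario.n_exposure)
    outcome = _records(ids, chrom, pos, ea, oa, eaf, by_obs, se_y, scenario.n_outcome)
    truth = pd.DataFrame({
        "snp_id": ids, "maf": maf, "bx_true": bx_true, "alpha": alpha,
        "by_true": by_true, "se_x": se_x, "se_y": se_y,
        "theta": scenario.theta,
    })
    return exposure, outcome, truth


def simulate_mediation_triplet(
    scenario: SimScenario,
) -> tuple[list[SummaryRecord], list[SummaryRecord], list[SummaryRecord], dict]:
    """Three coherent GWAS (exposure, mediator, outcome) under a chain.

    Exposure and mediator each get their own independent instrument set;
    both sets are reported in all three GWAS.  By construction the total
    exposure→outcome effect equals direct + a·b.  With
    ``downstream_of_outcome`` the mediator is instead a consequence of
    the outcome, so its own instruments have no outcome effect.
    """
    chain = scenario.mediator_chain or MediatorChain()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_snps
    total = chain.total

    maf = rng.uniform(*scenario.maf_range, size=2 * n)
    se_x = _se(scenario.n_exposure, maf)
    se_m = _se(scenario.n_mediator, maf)
    se_y = _se(scenario.n_outcome, maf)

    # first half: exposure instruments; second half: mediator instruments
    bx_inst = _draw_instrument_effects(rng, se_x[:n], scenario.effect_sd, scenario.f_min)
    bm_inst = _draw_instrument_effects(rng, se_m[n:], scenario.effect_sd, scenario.f_min)

    bx_true = np.concatenate([bx_inst, np.zeros(n)])
    if chain.downstream_of_outcome:
        by_true = np.concatenate([chain.direct * bx_inst, np.zeros(n)])
        bm_true = chain.a * by_true + np.concatenate([np.zeros(n), bm_inst])
    else:
        bm_true = np.concatenate([chain.a * bx_inst, bm_inst])
        by_true = np.concatenate([total * bx_inst, chain.b * bm_inst])

    ids = [f"rs{j + 1:06d}" for j in range(2 * n)]
    chrom, pos = _positions(rng, 2 * n)
    ea, oa = _alleles(rng, 2 * n)
    eaf = np.where(rng.random(2 * n) < 0.5, maf, 1 - maf)

    bx_obs = bx_true + rng.normal(0, se_x)
    bm_obs = bm_true + rng.normal(0, se_m)
    by_obs = by_true + rng.normal(0, se_y)

    exposure = _records(ids, chrom, pos, ea, oa, eaf, bx_obs, se_x, scenario.n_exposure)
    mediator = _records(ids, chrom, pos, ea, oa, eaf, bm_obs, se_m, scenario.n_mediator)
    outcome = _records(ids, chrom, pos, ea, oa, eaf, by_obs, se_y, scenario.n_outcome)
    truth = {
        "a": chain.a, "b": chain.b, "direct": chain.direct, "total": total,
        "mediation_effect": chain.a * chain.b,
        "proportion_pct": chain.true_proportion_pct,
        "downstream_of_outcome": chain.downstream_of_outcome,
        "exposure_instrument_ids": ids[:n],
        "mediator_instrument_ids": ids[n:],
    }
    return exposure, mediator, outcome, truth


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class CorruptionEntry:
    snp_id: str
    swapped: bool
    strand_flipped: bool


def scramble_alleles(
    stats: Sequence[SummaryRecord], seed: int | np.random.Generator = 0,
    p_swap: float = 0.5, p_strand: float = 0.5,
) -> tuple[list[SummaryRecord], list[CorruptionEntry]]:
    """Randomly re-encode records the way discordant GWAS exports do.

    Each SNP independently gets an allele swap (beta sign flip + eaf
    complement) and/or a strand complement; the log records the truth so
    harmonization can be verified as an exact inverse.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[SummaryRecord] = []
    log: list[CorruptionEntry] = []
    for r in stats:
        swap = bool(rng.random() < p_swap)
        strand = bool(rng.random() < p_strand)
        ea, oa, beta, eaf = r.effect_allele, r.other_allele, r.beta, r.eaf
        if swap:
            ea, oa, beta, eaf = oa, ea, -beta, 1 - eaf
        if strand:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        out.append(replace(r, effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf))
        log.append(CorruptionEntry(r.snp_id, swap, strand))
    return out, log


def make_block_ld(
    ids: Sequence[str], block_size: int = 5, within_r2: float = 0.9,
) -> LDMatrix:
    """Block-diagonal LD: consecutive SNPs share r² within each block."""
    n = len(ids)
    r2 = np.eye(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r2[start:stop, start:stop] = within_r2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(ids=list(ids), r2=r2)


@dataclass
class PhewasWorld:
    index_annotations: list
    pool_annotations: list
    associations: pd.DataFrame  # wide: snp_id index × trait columns, p-values
    truth: dict = field(default_factory=dict)


def simulate_phewas_world(
    n_index: int = 4,
    n_pool: int = 2000,
    n_traits: int = 778,
    enrichment_spec: Mapping[str, float] | None = None,
    baseline_assoc: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> PhewasWorld:
    """Annotations plus a SNP×trait association table with planted signal.

    ``enrichment_spec`` maps trait name → probability that each index SNP
    is nominally associated (p < 0.01) with that trait; everywhere else
    p-values are Uniform(0, 1), giving the ``baseline_assoc`` nominal
    rate.  The pool is drawn from the same annotation distributions as
    the index SNPs so matched controls exist.
    """
    from .phewas import SNPAnnotation

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    enrichment_spec = dict(enrichment_spec or {})
    n_total = n_index + n_pool
    ids = [f"rs{j + 1:06d}" for j in range(n_total)]

    maf = rng.uniform(0.05, 0.5, size=n_total)
    gene_density = rng.integers(2, 30, size=n_total)
    dist = np.round(rng.lognormal(mean=9.2, sigma=0.6, size=n_total))
    ld_partners = rng.integers(5, 60, size=n_total)
    annotations = [
        SNPAnnotation(ids[j], float(maf[j]), float(gene_density[j]),
                      float(dist[j]), float(ld_partners[j]))
        for j in range(n_total)
    ]

    traits = [f"trait_{t + 1:03d}" for t in range(n_traits)]
    pmat = rng.uniform(0.0, 1.0, size=(n_total, n_traits))
    trait_index = {t: i for i, t in enumerate(traits)}
    for trait, prob in enrichment_spec.items():
        ti = trait_index[trait]
        hit = rng.random(n_index) < prob
        pmat[:n_index, ti] = np.where(
            hit, rng.uniform(0.0, baseline_assoc, size=n_index), pmat[:n_index, ti]
        )
    associations = pd.DataFrame(pmat, index=pd.Index(ids, name="snp_id"), columns=traits)
    return PhewasWorld(
        index_annotations=annotations[:n_index],
        pool_annotations=annotations[n_index:],
        associations=associations,
        truth={"enriched_traits": sorted(enrichment_spec),
               "baseline_assoc": baseline_assoc},
    )
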