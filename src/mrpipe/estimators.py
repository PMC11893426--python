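"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrpipe.harmonize.HarmonizedSet` whose
per-SNP pairs (bx, by) refer to the same effect allele.  The single-SNP
building block is the Wald ratio by/bx; inverse-variance weighting (IVW)
pools ratios as a weighted regression of by on bx through the origin with
weights 1/sy², which is algebraically the inverse-variance-weighted mean
of the ratios with weights bx²/sy².

MR-Egger adds an intercept: under the InSIDE assumption its slope stays
consistent in the presence of directional pleiotropy, and a non-zero
intercept is the pleiotropy diagnostic.  The weighted median is robust to
up to 50% invalid weight; the weighted mode assumes only that the largest
cluster of ratios is valid.  Cochran's Q measures ratio heterogeneity;
leave-one-out detects single-SNP leverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .harmonize import HarmonizedSet

Z95 = float(sps.norm.ppf(0.975))  # 1.959964...

METHOD_WALD = "wald"
METHOD_IVW_FIXED = "ivw_fixed"
METHOD_IVW_RANDOM = "ivw_random"
METHOD_EGGER = "egger"
METHOD_WEIGHTED_MEDIAN = "weighted_median"
METHOD_WEIGHTED_MODE = "weighted_mode"


@dataclass
class MREstimate:
    """One method's causal estimate with odds-ratio presentation.

    ``beta`` is on the scale of the outcome GWAS effect per SD of exposure
    (log-odds for binary outcomes); ``or_point`` and the CI exponentiate it.
    """

    method: str
    beta: float
    se: float
    pval: float
    or_point: float
    ci_low: float
    ci_high: float
    nsnp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, nsnp: int,
                     level: float = 0.95) -> "MREstimate":
        orp, lo, hi = or_ci(beta, se, level)
        if se > 0:
            p = 2 * sps.norm.sf(abs(beta) / se)
        else:
            p = 0.0 if beta != 0 else 1.0
        return cls(method=method, beta=float(beta), se=float(se), pval=float(p),
                   or_point=orp, ci_low=lo, ci_high=hi, nsnp=nsnp)


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class PleiotropyResult:
    egger_intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class AdjustedPValue:
    raw_p: float
    fdr_p: float
    tier: str  # significant | potential | null


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> tuple[float, float]:
    """Single-SNP causal estimate by/bx with first-order SE sy/|bx|."""
    if bx == 0:
        raise ValueError("exposure effect bx must be non-zero for a Wald ratio")
    return by / bx, sy / abs(bx)


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with normal-theory CI exp(beta ∓ z·se)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = float(sps.norm.ppf(0.5 + level / 2))
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _ratio_weights(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and first-order inverse-variance weights bx²/sy²."""
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        bad = [r.snp_id for r in hset.records if r.bx == 0]
        raise ValueError(f"zero exposure effect for SNP(s) {bad}")
    return by / bx, bx**2 / sy**2


def _oriented_arrays(hset: HarmonizedSet):
    """Arrays in the canonical bx ≥ 0 orientation (pairwise sign flips).

    Wald ratios are unchanged; bootstrap resampling becomes invariant to
    which allele each SNP happened to be reported on.
    """
    bx, sx, by, sy = hset.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    return bx * flip, sx, by * flip, sy


def cochran_q(hset: HarmonizedSet, theta: float) -> HeterogeneityResult:
    """Cochran's Q = Σ wⱼ(ratioⱼ − θ)² with wⱼ = bxⱼ²/syⱼ²; df = nsnp − 1."""
    if hset.nsnp < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    ratios, w = _ratio_weights(hset)
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = hset.nsnp - 1
    return HeterogeneityResult(Q=q, df=df, pval=float(sps.chi2.sf(q, df)))


def ivw(
    hset: HarmonizedSet, effects_model: str = "random", level: float = 0.95
) -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance-weighted estimate.

    Weighted regression of by on bx through the origin with weights 1/sy².
    The fixed-effects SE is 1/√Σ(bx²/sy²); the multiplicative
    random-effects model inflates it by max(1, √(Q/(nsnp−1))).
    A single SNP degenerates to the Wald ratio (no heterogeneity result).
    """
    if hset.nsnp == 0:
        raise ValueError("empty harmonized set")
    bx, sx, by, sy = hset.arrays()
    if hset.nsnp == 1:
        beta, se = wald_ratio(bx[0], sx[0], by[0], sy[0])
        method = METHOD_WALD
        return MREstimate.from_beta_se(method, beta, se, 1, level), None

    sxx = float(np.sum(bx**2 / sy**2))
    beta = float(np.sum(bx * by / sy**2)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    het = cochran_q(hset, beta)
    if effects_model == "random":
        scale = max(1.0, np.sqrt(het.Q / (hset.nsnp - 1)))
        se = se_fixed * scale
        method = METHOD_IVW_RANDOM
    elif effects_model == "fixed":
        se = se_fixed
        method = METHOD_IVW_FIXED
    else:
        raise ValueError(f"unknown effects model {effects_model!r}")
    return MREstimate.from_beta_se(method, beta, se, hset.nsnp, level), het


def egger(
    hset: HarmonizedSet, level: float = 0.95
) -> tuple[MREstimate, PleiotropyResult, HeterogeneityResult]:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    Effects are first oriented so every bx ≥ 0 (flipping by with bx), the
    standard convention making the intercept interpretable as average
    directional pleiotropy.  SEs use a multiplicative overdispersion scale
    max(1, √(RSS_w/(nsnp−2))).
    """
    if hset.nsnp < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    bx, sx, by, sy = hset.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x, y, w = bx * flip, by * flip, 1.0 / sy**2

    sw = np.sum(w)
    mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx == 0:
        raise ValueError("degenerate Egger fit: no spread in exposure effects")
    slope = float(np.sum(w * (x - mx) * (y - my)) / sxx)
    intercept = float(my - slope * mx)
    resid = y - intercept - slope * x
    rss_w = float(np.sum(w * resid**2))
    df = hset.nsnp - 2
    scale = max(1.0, np.sqrt(rss_w / df))
    slope_se = float(scale / np.sqrt(sxx))
    intercept_se = float(scale * np.sqrt(1.0 / sw + mx**2 / sxx))

    est = MREstimate.from_beta_se(METHOD_EGGER, slope, slope_se, hset.nsnp, level)
    intercept_p = float(2 * sps.norm.sf(abs(intercept) / intercept_se))
    pleio = PleiotropyResult(intercept, intercept_se, intercept_p)
    het = HeterogeneityResult(Q=rss_w, df=df, pval=float(sps.chi2.sf(rss_w, df)))
    return est, pleio, het


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted empirical-CDF midpoint interpolation at probability 0.5."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order] / np.sum(weights)
    cdf = np.cumsum(w) - 0.5 * w  # midpoint convention
    if 0.5 <= cdf[0]:
        return float(r[0])
    if 0.5 >= cdf[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cdf, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when SNPs carrying ≥50% of the weight are valid
    instruments.  The SE is the standard deviation of estimates recomputed
    on (bx*, by*) drawn from their sampling normals.
    """
    if hset.nsnp < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    bx, sx, by, sy = _oriented_arrays(hset)
    ratios, w = _ratio_weights(hset)
    point = _weighted_median_point(ratios, w)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        boots[i] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    return MREstimate.from_beta_se(METHOD_WEIGHTED_MEDIAN, point,
                                   float(np.std(boots, ddof=1)), hset.nsnp, level)


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    n = ratios.size
    mad = sps.median_abs_deviation(ratios, scale="normal")
    sd = np.std(ratios, ddof=1)
    s = 0.9 * min(sd, mad) * n ** (-1 / 5)
    if s <= 0:  # all ratios identical (or MAD degenerate)
        s = max(sd, 1e-12) * n ** (-1 / 5)
    return factor * s


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth: float) -> float:
    grid = np.linspace(ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / bandwidth) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    hset: HarmonizedSet, bandwidth_factor: float = 1.0, n_boot: int = 1000,
    seed: int | np.random.Generator = 0, level: float = 0.95,
) -> MREstimate:
    """Mode-based estimator: argmax of the weighted kernel density of ratios.

    The bandwidth follows the modified Silverman rule
    0.9·min(sd, MAD·1.4826)·n^(−1/5), scaled by ``bandwidth_factor``;
    the SE comes from a parametric bootstrap as for the weighted median.
    """
    if hset.nsnp < 3:
        raise ValueError("weighted mode needs at least 3 SNPs")
    bx, sx, by, sy = _oriented_arrays(hset)
    ratios, w = _ratio_weights(hset)
    wn = w / np.sum(w)
    if np.ptp(ratios) == 0:
        point = float(ratios[0])
    else:
        point = _weighted_mode_point(ratios, wn, _mode_bandwidth(ratios, bandwidth_factor))

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        r = bys / bxs
        ww = bxs**2 / sy**2
        ww = ww / np.sum(ww)
        if np.ptp(r) == 0:
            boots[i] = r[0]
        else:
            boots[i] = _weighted_mode_point(r, ww, _mode_bandwidth(r, bandwidth_factor))
    return MREstimate.from_beta_se(METHOD_WEIGHTED_MODE, point,
                                   float(np.std(boots, ddof=1)), hset.nsnp, level)


@dataclass
class LeaveOneOutRow:
    excluded: str
    estimate: MREstimate
    influential: bool


def leave_one_out(hset: HarmonizedSet, level: float = 0.95,
                  alpha: float = 0.05) -> list[LeaveOneOutRow]:
    """Random-effects IVW re-estimated with each SNP excluded in turn.

    An exclusion is flagged influential when it flips the sign of the
    estimate or moves its p-value across ``alpha`` relative to the full fit.
    """
    if hset.nsnp < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    full, _ = ivw(hset, "random", level)
    rows: list[LeaveOneOutRow] = []
    ids = hset.snp_ids
    for snp in ids:
        sub = hset.subset([s for s in ids if s != snp])
        est, _ = ivw(sub, "random", level)
        flag = (np.sign(est.beta) != np.sign(full.beta)) or (
            (full.pval < alpha) != (est.pval < alpha)
        )
        rows.append(LeaveOneOutRow(excluded=snp, estimate=est, influential=bool(flag)))
    return rows


def bh_fdr(pvals: Sequence[float], fdr_alpha: float = 0.05,
           nominal_alpha: float = 0.05) -> list[AdjustedPValue]:
    """Benjamini–Hochberg adjustment with the two-threshold tier convention.

    significant: adjusted p < ``fdr_alpha``; potential: raw p <
    ``nominal_alpha`` but adjusted p ≥ ``fdr_alpha``; otherwise null.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    out = []
    for raw, adj in zip(p, fdr):
        if adj < fdr_alpha:
            tier = "significant"
        elif raw < nominal_alpha:
            tier = "potential"
        else:
            tier = "null"
        out.append(AdjustedPValue(raw_p=float(raw), fdr_p=float(adj), tier=tier))
    return out
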