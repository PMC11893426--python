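"""MR-PRESSO: pleiotropy residual sum and outlier test by simulation.

The global test compares the observed leave-one-out weighted residual sum
of squares (RSS) against its parametric null distribution, obtained by
simulating summary statistics under the no-pleiotropy model
by*ⱼ ~ N(θ̂₋ⱼ·bxⱼ, syⱼ), bx*ⱼ ~ N(bxⱼ, sxⱼ).  The outlier test localises
the signal per SNP by comparing each observed squared residual with its
simulated counterparts; the distortion test asks whether removing the
flagged SNPs materially moves the IVW estimate compared with removing
random subsets of the same size.

p-values carry an add-one correction, so they are never exactly zero and
are bounded below by 1/(K+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ivw
from .harmonize import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    K: int
    per_snp_p: list[float] = field(default_factory=list)
    outlier_ids: list[str] = field(default_factory=list)
    beta_raw: float = float("nan")
    beta_outlier_corrected: float = float("nan")
    distortion_p: float = float("nan")
    # simulated squared residuals, kept for the outlier stage
    _resid2_obs: np.ndarray | None = None
    _resid2_sim: np.ndarray | None = None


def _loo_residuals(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Leave-one-out IVW slopes and the resulting per-SNP residuals.

    Works on 1-D arrays or on a (K, nsnp) matrix of simulated datasets.
    """
    sxy = np.sum(bx * by * w, axis=-1, keepdims=True)
    sxx = np.sum(bx * bx * w, axis=-1, keepdims=True)
    theta_loo = (sxy - bx * by * w) / (sxx - bx * bx * w)
    resid = by - theta_loo * bx
    return theta_loo, resid


def presso_global(
    hset: HarmonizedSet, K: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PressoResult:
    """Global pleiotropy test: simulation p-value for the observed RSS."""
    if hset.nsnp < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy**2
    theta_loo, resid = _loo_residuals(bx, by, w)
    rss_obs = float(np.sum(w * resid**2))

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exp_by = theta_loo.ravel() * bx
    by_sim = rng.normal(exp_by, sy, size=(K, hset.nsnp))
    bx_sim = rng.normal(bx, sx, size=(K, hset.nsnp))
    _, resid_sim = _loo_residuals(bx_sim, by_sim, w)
    rss_sim = np.sum(w * resid_sim**2, axis=1)

    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (K + 1)
    return PressoResult(
        rss_obs=rss_obs, global_p=float(global_p), K=K,
        _resid2_obs=resid**2, _resid2_sim=resid_sim**2,
    )


def presso_outlier(
    hset: HarmonizedSet, result: PressoResult, alpha: float = 0.05
) -> PressoResult:
    """Per-SNP outlier test; flags use a Bonferroni threshold alpha/nsnp."""
    if result._resid2_sim is None:
        raise ValueError("run presso_global first")
    K = result.K
    counts = np.sum(result._resid2_sim >= result._resid2_obs[None, :], axis=0)
    per_snp_p = (1 + counts) / (K + 1)
    thresh = alpha / hset.nsnp
    ids = hset.snp_ids
    result.per_snp_p = [float(p) for p in per_snp_p]
    result.outlier_ids = [s for s, p in zip(ids, per_snp_p) if p < thresh]
    return result


def presso_distortion(
    hset: HarmonizedSet, outlier_ids: list[str], n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Distortion test comparing raw and outlier-corrected IVW estimates.

    Returns (beta_raw, beta_corrected, distortion_p) where the p-value is
    the fraction of random same-size SNP subsets whose removal distorts
    the estimate at least as much as removing the flagged outliers.
    """
    if not outlier_ids:
        raise ValueError("distortion test requires at least one flagged outlier")
    ids = hset.snp_ids
    keep = [s for s in ids if s not in set(outlier_ids)]
    if not keep:
        raise ValueError("all SNPs flagged as outliers; nothing to correct against")

    beta_raw = ivw(hset, "random")[0].beta
    beta_corr = ivw(hset.subset(keep), "random")[0].beta
    d_obs = abs((beta_raw - beta_corr) / abs(beta_corr))

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_out = len(set(outlier_ids) & set(ids))
    count = 0
    for _ in range(n_boot):
        drop = set(rng.choice(len(ids), size=n_out, replace=False))
        sub = hset.subset([s for i, s in enumerate(ids) if i not in drop])
        beta_sub = ivw(sub, "random")[0].beta
        if abs((beta_raw - beta_sub) / abs(beta_sub)) >= d_obs:
            count += 1
    return float(beta_raw), float(beta_corr), count / n_boot


def run_presso(
    hset: HarmonizedSet, K: int = 1000, n_boot: int = 1000,
    seed: int | np.random.Generator = 0, alpha: float = 0.05,
) -> PressoResult:
    """Global → outlier → (if flagged) distortion, sharing one RNG stream."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    result = presso_global(hset, K=K, seed=rng)
    result = presso_outlier(hset, result, alpha=alpha)
    result.beta_raw = ivw(hset, "random")[0].beta
    if result.outlier_ids and len(result.outlier_ids) < hset.nsnp:
        raw, corr, dp = presso_distortion(hset, result.outlier_ids,
                                          n_boot=n_boot, seed=rng)
        result.beta_raw, result.beta_outlier_corrected = raw, corr
        result.distortion_p = dp
    return result
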