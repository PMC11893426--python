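"""Config-driven orchestration of the full analysis design.

The screen the pipeline reproduces: many exposures against one outcome
(forward pass with FDR tiering and a sensitivity battery), reverse-
direction reruns for the hits, a two-step mediation pass through a
mediator panel, and a matched-control PheWAS enrichment pass.

All randomness (bootstrap SEs, MR-PRESSO simulations, control matching)
derives from one root seed; per-exposure substreams are keyed by the
exposure name so results do not depend on panel order.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators, presso
from .gwas_io import ColumnMap, SummaryRecord, read_summary_stats, write_results_table
from .harmonize import harmonize_sets
from .instruments import LDMatrix, select_instruments
from .mediation import mediation_summary, screen_mediators
from .phewas import SNPAnnotation, match_control_set, trait_enrichment


@dataclass
class PipelineConfig:
    """Thresholds and seeds for every stage, with the study's defaults."""

    p_instrument: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float | None = 10.0
    proxy_r2: float = 0.8
    allow_proxies: bool = False
    eaf_window: float = 0.08
    keep_palindromes: bool = False
    fdr_alpha: float = 0.05
    nominal_alpha: float = 0.05
    phewas_p_nominal: float = 0.01
    phewas_n_controls: int = 4
    effects_model: str = "random"
    presso_k: int = 1000
    n_boot: int = 1000
    seed: int = 20240101

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _stage_rng(config: PipelineConfig, stage: str, name: str = "") -> np.random.Generator:
    """Deterministic substream keyed by (root seed, stage, name)."""
    key = [config.seed, zlib.crc32(stage.encode()), zlib.crc32(name.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


@dataclass
class ExposureResult:
    exposure: str
    outcome: str
    status: str  # analyzed | skipped
    reason: str = ""
    rows: list[dict] = field(default_factory=list)
    ivw_p: float = float("nan")


def _estimate_row(exposure: str, outcome: str, est: estimators.MREstimate) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "nsnp": est.nsnp,
        "method": est.method,
        "beta": est.beta,
        "se": est.se,
        "or": est.or_point,
        "or_ci_low": est.ci_low,
        "or_ci_high": est.ci_high,
        "pval": est.pval,
    }


def analyze_pair(
    exposure_name: str,
    exposure_stats: Sequence[SummaryRecord],
    outcome_name: str,
    outcome_stats: Sequence[SummaryRecord],
    config: PipelineConfig,
    ld: LDMatrix | None = None,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median"),
    run_sensitivity: bool = True,
) -> ExposureResult:
    """Instruments → harmonize → estimators → sensitivity for one pair."""
    inst = select_instruments(
        exposure_stats, ld=ld, p_threshold=config.p_instrument,
        r2_max=config.clump_r2, window_kb=config.clump_window_kb,
        f_min=config.f_min,
    )
    if len(inst.instruments) < 2:
        return ExposureResult(exposure_name, outcome_name, "skipped",
                              "too_few_instruments")
    try:
        hset = harmonize_sets(
            inst.instruments, outcome_stats,
            exposure=exposure_name, outcome=outcome_name,
            eaf_window=config.eaf_window,
            keep_palindromes=config.keep_palindromes,
            ld=ld, allow_proxies=config.allow_proxies, proxy_r2=config.proxy_r2,
        )
    except ValueError as exc:
        return ExposureResult(exposure_name, outcome_name, "skipped", str(exc))
    if hset.nsnp < 2:
        return ExposureResult(exposure_name, outcome_name, "skipped",
                              "too_few_harmonized_snps")

    result = ExposureResult(exposure_name, outcome_name, "analyzed")
    ivw_est, het = estimators.ivw(hset, config.effects_model)
    result.ivw_p = ivw_est.pval
    ivw_row = _estimate_row(exposure_name, outcome_name, ivw_est)
    ivw_row["Q"] = het.Q if het else math.nan
    ivw_row["Q_pval"] = het.pval if het else math.nan
    result.rows.append(ivw_row)

    if "egger" in methods and hset.nsnp >= 3:
        eg_est, pleio, _ = estimators.egger(hset)
        row = _estimate_row(exposure_name, outcome_name, eg_est)
        row["egger_intercept"] = pleio.egger_intercept
        row["egger_intercept_pval"] = pleio.intercept_pval
        result.rows.append(row)
        ivw_row["egger_pval"] = pleio.intercept_pval
    if "weighted_median" in methods and hset.nsnp >= 3:
        wm = estimators.weighted_median(
            hset, n_boot=config.n_boot,
            seed=_stage_rng(config, "weighted_median", exposure_name),
        )
        result.rows.append(_estimate_row(exposure_name, outcome_name, wm))
    if "weighted_mode" in methods and hset.nsnp >= 3:
        wmo = estimators.weighted_mode(
            hset, n_boot=config.n_boot,
            seed=_stage_rng(config, "weighted_mode", exposure_name),
        )
        result.rows.append(_estimate_row(exposure_name, outcome_name, wmo))

    if run_sensitivity and hset.nsnp >= 3:
        loo = estimators.leave_one_out(hset)
        ivw_row["n_loo_influential"] = sum(r.influential for r in loo)
    if run_sensitivity and hset.nsnp >= 4:
        pres = presso.run_presso(
            hset, K=config.presso_k, n_boot=config.n_boot,
            seed=_stage_rng(config, "presso", exposure_name),
        )
        ivw_row["global_p"] = pres.global_p
        ivw_row["n_outliers"] = len(pres.outlier_ids)
        ivw_row["beta_outlier_corrected"] = pres.beta_outlier_corrected
    return result


def run_forward(
    exposures: Mapping[str, Sequence[SummaryRecord]],
    outcome_stats: Sequence[SummaryRecord],
    config: PipelineConfig,
    ld: LDMatrix | None = None,
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Forward screen of an exposure panel against one outcome.

    Returns a long report (one row per exposure × method) with BH-FDR
    and significance tiers computed across the panel's IVW p-values —
    one FDR family per outcome, never pooled across outcomes.
    """
    results = [
        analyze_pair(name, stats, outcome_name, outcome_stats, config, ld=ld)
        for name, stats in exposures.items()
    ]
    analyzed = [r for r in results if r.status == "analyzed"]
    adj = estimators.bh_fdr(
        [r.ivw_p for r in analyzed],
        fdr_alpha=config.fdr_alpha, nominal_alpha=config.nominal_alpha,
    ) if analyzed else []
    for r, a in zip(analyzed, adj):
        for row in r.rows:
            if row["method"] in (estimators.METHOD_IVW_FIXED,
                                 estimators.METHOD_IVW_RANDOM,
                                 estimators.METHOD_WALD):
                row["fdr_p"] = a.fdr_p
                row["tier"] = a.tier

    rows: list[dict] = []
    for r in results:
        if r.status == "skipped":
            rows.append({"exposure": r.exposure, "outcome": r.outcome,
                         "method": "skipped", "reason": r.reason})
        else:
            rows.extend(r.rows)
    return pd.DataFrame(rows)


def run_bidirectional(
    outcome_stats: Sequence[SummaryRecord],
    hit_exposures: Mapping[str, Sequence[SummaryRecord]],
    config: PipelineConfig,
    ld: LDMatrix | None = None,
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Reverse-direction reruns: the outcome instruments each prior hit.

    Estimated by IVW, MR-Egger and weighted mode; a reverse IVW p < 0.05
    flags potential reverse causation.
    """
    rows: list[dict] = []
    for name, stats in hit_exposures.items():
        res = analyze_pair(
            outcome_name, outcome_stats, name, stats, config, ld=ld,
            methods=("ivw", "egger", "weighted_mode"), run_sensitivity=False,
        )
        if res.status == "skipped":
            rows.append({"exposure": outcome_name, "outcome": name,
                         "method": "skipped", "reason": res.reason})
        else:
            for row in res.rows:
                row["reverse_significant"] = bool(row["pval"] < config.nominal_alpha)
                rows.append(row)
    return pd.DataFrame(rows)


def run_mediation(
    exposure_stats: Sequence[SummaryRecord],
    mediator_panel: Mapping[str, Sequence[SummaryRecord]],
    outcome_stats: Sequence[SummaryRecord],
    config: PipelineConfig,
    ld: LDMatrix | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Two-step mediation pass producing a mediation-table-shaped report."""
    total_res = analyze_pair(
        exposure_name, exposure_stats, outcome_name, outcome_stats, config,
        ld=ld, methods=("ivw",), run_sensitivity=False,
    )
    if total_res.status == "skipped":
        raise ValueError(f"cannot estimate total effect: {total_res.reason}")
    total = next(r for r in total_res.rows if r["method"].startswith("ivw"))

    screens = screen_mediators(
        exposure_stats, mediator_panel, outcome_stats, ld=ld,
        p_instrument=config.p_instrument, p_nominal=config.nominal_alpha,
        exposure=exposure_name, outcome=outcome_name,
    )
    rows: list[dict] = []
    for s in screens:
        if not s.passed:
            continue
        med = mediation_summary(
            total["beta"], total["se"], s.a_b, s.a_se, s.b_b, s.b_se,
            exposure=exposure_name, mediator=s.mediator, outcome=outcome_name,
        )
        rows.append(asdict(med))
    columns = ["exposure", "mediator", "outcome", "total_b", "total_se",
               "a_b", "a_se", "b_b", "b_se", "med_b", "med_se", "med_p",
               "prop_pct", "prop_lo", "prop_hi", "label"]
    return pd.DataFrame(rows, columns=columns)


def run_phewas(
    index_annotations: Sequence[SNPAnnotation],
    pool_annotations: Sequence[SNPAnnotation],
    associations: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict, pd.DataFrame]:
    """Matched-control enrichment pass for the hit SNPs."""
    matches = match_control_set(
        index_annotations, pool_annotations,
        n_controls=config.phewas_n_controls,
        seed=_stage_rng(config, "phewas_matching"),
    )
    control_ids = sorted({c for m in matches.values() for c in m.controls})
    index_ids = [a.snp_id for a in index_annotations]
    enr = trait_enrichment(associations, index_ids, control_ids,
                           p_nominal=config.phewas_p_nominal)
    return matches, pd.DataFrame([asdict(e) for e in enr])


# ---------------------------------------------------------------------------
# file-based front end used by the CLI


def _load_gwas(path: str, colmap: ColumnMap | None):
    return read_summary_stats(path, colmap).records


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_from_config(config_path: str | Path, stage: str, output_dir: str | Path | None = None) -> dict:
    """Execute one pipeline stage from a YAML config; write TSV + JSON.

    The config names input tables and optional column mappings::

        seed: 20240101
        thresholds: {p_instrument: 1.0e-5, fdr_alpha: 0.05}
        columns: {snp_id: SNP, ...}      # optional dialect mapping
        exposures: {CXCL6: exposure.tsv, ...}
        outcome: {name: male_infertility, path: outcome.tsv}
        mediators: {metabolite_1: m1.tsv, ...}
        ld_matrix: ld.tsv                 # optional
        annotations: annotations.tsv      # phewas stage
        associations: associations.tsv    # phewas stage (long format)
        output_dir: results/
    """
    raw = load_config_file(config_path)
    config = PipelineConfig.from_dict({**raw.get("thresholds", {}),
                                       "seed": raw.get("seed", PipelineConfig.seed)})
    colmap = ColumnMap(mapping=raw["columns"]) if "columns" in raw else None
    outdir = Path(output_dir or raw.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    ld = LDMatrix.from_tsv(raw["ld_matrix"]) if raw.get("ld_matrix") else None

    summary: dict = {"stage": stage, "seed": config.seed}
    if stage in ("forward", "reverse"):
        exposures = {name: _load_gwas(p, colmap)
                     for name, p in raw["exposures"].items()}
        outcome = _load_gwas(raw["outcome"]["path"], colmap)
        outcome_name = raw["outcome"].get("name", "outcome")
        if stage == "forward":
            report = run_forward(exposures, outcome, config, ld=ld,
                                 outcome_name=outcome_name)
        else:
            report = run_bidirectional(outcome, exposures, config, ld=ld,
                                       outcome_name=outcome_name)
        out_path = outdir / f"{stage}_report.tsv"
        write_results_table(report, out_path)
        summary["report"] = str(out_path)
        summary["n_rows"] = int(len(report))
    elif stage == "mediation":
        (exp_name, exp_path), = raw["exposures"].items()
        exposure = _load_gwas(exp_path, colmap)
        outcome = _load_gwas(raw["outcome"]["path"], colmap)
        mediators = {name: _load_gwas(p, colmap)
                     for name, p in raw["mediators"].items()}
        report = run_mediation(exposure, mediators, outcome, config, ld=ld,
                               exposure_name=exp_name,
                               outcome_name=raw["outcome"].get("name", "outcome"))
        out_path = outdir / "mediation_report.tsv"
        if report.empty:
            report.to_csv(out_path, sep="\t", index=False)  # header-only table
        else:
            write_results_table(report, out_path)
        summary["report"] = str(out_path)
        summary["n_candidates"] = int(len(report))
    elif stage == "phewas":
        ann = pd.read_csv(raw["annotations"], sep="\t")
        annotations = [SNPAnnotation(str(r.snp_id), r.maf, r.gene_density,
                                     r.dist_nearest_gene, r.n_ld_partners)
                       for r in ann.itertuples()]
        index_ids = set(raw["index_snps"])
        index = [a for a in annotations if a.snp_id in index_ids]
        pool = [a for a in annotations if a.snp_id not in index_ids]
        assoc = pd.read_csv(raw["associations"], sep="\t")
        matches, report = run_phewas(index, pool, assoc, config)
        out_path = outdir / "phewas_report.tsv"
        write_results_table(report, out_path)
        summary["report"] = str(out_path)
        summary["matches"] = {k: v.controls for k, v in matches.items()}
    else:
        raise ValueError(f"unknown stage {stage!r}")

    with open(outdir / f"{stage}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
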