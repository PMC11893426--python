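"""Two-step mediation Mendelian randomization.

The indirect (mediation) effect of an exposure on an outcome through a
mediator is the product of coefficients a·b, where a is the IVW effect of
the exposure on the mediator (direct effect A) and b the IVW effect of
the mediator on the outcome (direct effect B).  Its standard error uses
the exact variance of a product of independent normal estimators,

    se(a·b) = sqrt(a²·se_b² + b²·se_a² + se_a²·se_b²),

i.e. the delta method including the second-order cross term.  The
mediation proportion is 100·a·b/total; an indirect effect whose sign
opposes the total effect is a suppression, not a mediation.

The proportion CI scales the Wald CI of the mediation effect by the total
effect, treating the total as fixed — a deliberate simplification (no
propagation of the total effect's SE) documented in the package docs.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .estimators import ivw
from .gwas_io import SummaryRecord
from .harmonize import harmonize_sets
from .instruments import LDMatrix, select_instruments

LABEL_MEDIATION = "mediation"
LABEL_SUPPRESSION = "suppression"


@dataclass
class MediationResult:
    """One mediator's row of a two-step mediation analysis."""

    exposure: str
    mediator: str
    outcome: str
    total_b: float
    total_se: float
    a_b: float
    a_se: float
    b_b: float
    b_se: float
    med_b: float
    med_se: float
    med_p: float
    prop_pct: float
    prop_lo: float
    prop_hi: float
    label: str


def mediation_effect(a_b: float, b_b: float) -> float:
    """Indirect effect by the product-of-coefficients rule: a·b."""
    return a_b * b_b


def delta_se(a_b: float, a_se: float, b_b: float, b_se: float) -> float:
    """Delta-method SE of a·b, exact for independent normal estimators.

    Includes the a_se²·b_se² cross term (the variance of a product of
    independent normals), not just the first-order expansion.
    """
    if a_se < 0 or b_se < 0:
        raise ValueError("standard errors must be non-negative")
    return math.sqrt(a_b**2 * b_se**2 + b_b**2 * a_se**2 + a_se**2 * b_se**2)


def mediation_summary(
    total_b: float,
    total_se: float,
    a_b: float,
    a_se: float,
    b_b: float,
    b_se: float,
    level: float = 0.95,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Full mediation row: effect, delta SE, p, proportion with CI, label."""
    if total_b == 0:
        raise ValueError("total effect must be non-zero to form a proportion")
    med_b = mediation_effect(a_b, b_b)
    med_se = delta_se(a_b, a_se, b_b, b_se)
    if med_se > 0:
        med_p = float(2 * sps.norm.sf(abs(med_b) / med_se))
    else:
        med_p = 0.0 if med_b != 0 else 1.0
    z = float(sps.norm.ppf(0.5 + level / 2))
    prop = 100.0 * med_b / total_b
    lo = 100.0 * (med_b - z * med_se) / total_b
    hi = 100.0 * (med_b + z * med_se) / total_b
    if lo > hi:  # a negative total effect reverses the bound order
        lo, hi = hi, lo
    label = LABEL_SUPPRESSION if med_b * total_b < 0 else LABEL_MEDIATION
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        total_b=total_b, total_se=total_se,
        a_b=a_b, a_se=a_se, b_b=b_b, b_se=b_se,
        med_b=med_b, med_se=med_se, med_p=med_p,
        prop_pct=prop, prop_lo=lo, prop_hi=hi, label=label,
    )


@dataclass
class MediatorScreen:
    mediator: str
    step1_p: float
    step2_p: float
    passed: bool
    reason: str = ""
    a_b: float = float("nan")
    a_se: float = float("nan")
    b_b: float = float("nan")
    b_se: float = float("nan")


def screen_mediators(
    exposure_gwas: Sequence[SummaryRecord],
    mediator_gwas: Mapping[str, Sequence[SummaryRecord]],
    outcome_gwas: Sequence[SummaryRecord],
    ld: LDMatrix | None = None,
    p_instrument: float = 1e-5,
    p_nominal: float = 0.05,
    exposure: str = "exposure",
    outcome: str = "outcome",
    exclude_exposure_instruments: bool = True,
) -> list[MediatorScreen]:
    """Two-step screen: exposure→mediator, then mediator→outcome, by IVW.

    A mediator is a candidate when both steps are nominally significant
    (p < ``p_nominal``).  Failures carry the step at which they failed.

    By default the exposure's own instrument SNPs are barred from the
    mediator's step-2 instrument set: a SNP that drives the exposure
    associates with the mediator through the exposure, so using it to
    instrument the mediator would route the exposure's direct outcome
    effect into the mediator→outcome estimate.
    """
    exp_inst = select_instruments(exposure_gwas, ld=ld, p_threshold=p_instrument)
    excluded = (
        {r.snp_id for r in exp_inst.instruments}
        if exclude_exposure_instruments else set()
    )
    results: list[MediatorScreen] = []
    for name, med_stats in mediator_gwas.items():
        # Step 1: exposure → mediator
        try:
            h1 = harmonize_sets(exp_inst.instruments, med_stats,
                                exposure=exposure, outcome=name)
            est1, _ = ivw(h1)
        except ValueError as exc:
            results.append(MediatorScreen(name, math.nan, math.nan, False,
                                          f"step1_failed: {exc}"))
            continue
        if est1.pval >= p_nominal:
            results.append(MediatorScreen(name, est1.pval, math.nan, False,
                                          "step1_not_significant",
                                          a_b=est1.beta, a_se=est1.se))
            continue
        # Step 2: mediator → outcome with the mediator's own instruments
        med_pool = [r for r in med_stats if r.snp_id not in excluded]
        med_inst = select_instruments(med_pool, ld=ld, p_threshold=p_instrument)
        try:
            h2 = harmonize_sets(med_inst.instruments, outcome_gwas,
                                exposure=name, outcome=outcome)
            est2, _ = ivw(h2)
        except ValueError as exc:
            results.append(MediatorScreen(name, est1.pval, math.nan, False,
                                          f"step2_failed: {exc}",
                                          a_b=est1.beta, a_se=est1.se))
            continue
        passed = est2.pval < p_nominal
        results.append(MediatorScreen(
            name, est1.pval, est2.pval, passed,
            "" if passed else "step2_not_significant",
            a_b=est1.beta, a_se=est1.se, b_b=est2.beta, b_se=est2.se,
        ))
    return results


def load_reference_mediation_table() -> pd.DataFrame:
    """Published mediation estimates of CXCL6 on male infertility.

    Six plasma-metabolite mediators with IVW total/direct effects and the
    delta-method mediation columns, shipped as a packaged fixture for
    validation and examples.
    """
    ref = importlib.resources.files("mrpipe").joinpath(
        "data/cxcl6_male_infertility_mediation.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
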