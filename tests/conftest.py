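import numpy as np
import pytest

from mrpipe.gwas_io import SummaryRecord
from mrpipe.harmonize import HarmonizedRecord, HarmonizedSet


def make_record(
    snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
    beta=0.1, se=0.01, pval=1e-6, n=10000,
) -> SummaryRecord:
    return SummaryRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                         effect_allele=ea, other_allele=oa, eaf=eaf,
                         beta=beta, se=se, pval=pval, n=n)


def make_hset(bx, sx, by, sy, exposure="X", outcome="Y") -> HarmonizedSet:
    records = [
        HarmonizedRecord(snp_id=f"rs{i + 1}", bx=float(bx[i]), sx=float(sx[i]),
                         by=float(by[i]), sy=float(sy[i]), eaf_x=0.3, eaf_y=0.3,
                         action="unchanged")
        for i in range(len(bx))
    ]
    return HarmonizedSet(exposure=exposure, outcome=outcome, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_snp_set():
    """Small heterogeneous set with a closed-form solvable fit."""
    return make_hset(
        bx=[0.10, 0.15, 0.08],
        sx=[0.01, 0.012, 0.009],
        by=[0.030, 0.050, 0.020],
        sy=[0.010, 0.015, 0.008],
    )


@pytest.fixture
def five_snp_set():
    return make_hset(
        bx=[0.10, 0.15, 0.08, 0.12, 0.20],
        sx=[0.01, 0.012, 0.009, 0.011, 0.015],
        by=[0.031, 0.047, 0.022, 0.041, 0.058],
        sy=[0.010, 0.015, 0.008, 0.012, 0.016],
    )
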