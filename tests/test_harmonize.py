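import math

import pytest

from conftest import make_record
from mrpipe.estimators import ivw
from mrpipe.harmonize import harmonize_pair, harmonize_sets, is_palindromic
from mrpipe.simulate import SimScenario, scramble_alleles, simulate_gwas_pair


@pytest.mark.parametrize(
    "a1, a2, expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("a", "t", True)],
)
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


class TestHarmonizePair:
    def test_same_orientation_unchanged(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="A", oa="G", beta=0.05)
        rec = harmonize_pair(exp, out)
        assert rec.action == "unchanged"
        assert rec.by == 0.05

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="G", oa="A", beta=0.05, eaf=0.3)
        rec = harmonize_pair(exp, out)
        assert rec.action == "sign_flipped"
        assert rec.by == -0.05
        assert rec.eaf_y == pytest.approx(0.7)

    def test_strand_complement_same_orientation(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="T", oa="C", beta=0.05, eaf=0.3)
        rec = harmonize_pair(exp, out)
        assert rec.action == "strand_flipped"
        assert rec.by == 0.05
        assert rec.eaf_y == pytest.approx(0.3)

    def test_strand_complement_swapped(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="C", oa="T", beta=0.05, eaf=0.3)
        rec = harmonize_pair(exp, out)
        assert rec.action == "strand_flipped"
        assert rec.by == -0.05
        assert rec.eaf_y == pytest.approx(0.7)

    def test_palindrome_near_half_frequency_dropped(self):
        exp = make_record(ea="A", oa="T", eaf=0.50)
        out = make_record(ea="A", oa="T", eaf=0.48)
        rec = harmonize_pair(exp, out)
        assert rec.dropped
        assert rec.drop_reason == "ambiguous_palindrome"

    def test_palindrome_window_boundary(self):
        exp = make_record(ea="A", oa="T", eaf=0.42)
        out = make_record(ea="A", oa="T", eaf=0.42)
        assert not harmonize_pair(exp, out, eaf_window=0.08).dropped
        assert harmonize_pair(exp, out, eaf_window=0.09).dropped

    def test_palindrome_oriented_by_frequency(self):
        # outcome reports the other strand: frequencies disagree on minor side
        exp = make_record(ea="A", oa="T", eaf=0.2, beta=0.1)
        out = make_record(ea="A", oa="T", eaf=0.8, beta=0.05)
        rec = harmonize_pair(exp, out)
        assert rec.action == "strand_flipped"
        assert rec.by == -0.05
        assert rec.eaf_y == pytest.approx(0.2)

    def test_palindrome_missing_eaf_dropped(self):
        exp = make_record(ea="A", oa="T", eaf=math.nan)
        out = make_record(ea="A", oa="T", eaf=0.2)
        assert harmonize_pair(exp, out).drop_reason == "missing_eaf_palindrome"

    def test_allele_mismatch_dropped(self):
        exp = make_record(ea="A", oa="G")
        out = make_record(ea="A", oa="C")
        assert harmonize_pair(exp, out).drop_reason == "allele_mismatch"

    def test_snp_id_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            harmonize_pair(make_record(snp_id="rs1"), make_record(snp_id="rs2"))

    def test_exposure_side_never_modified(self):
        exp = make_record(ea="A", oa="G", beta=0.1, se=0.01)
        out = make_record(ea="G", oa="A", beta=0.05)
        rec = harmonize_pair(exp, out)
        assert rec.bx == 0.1 and rec.sx == 0.01


class TestHarmonizeSets:
    def test_disjoint_snp_sets_hard_error(self):
        exp = [make_record(snp_id="rs1")]
        out = [make_record(snp_id="rs2")]
        with pytest.raises(ValueError, match="missing_in_outcome"):
            harmonize_sets(exp, out)

    def test_drop_bookkeeping_counts(self):
        exp = [make_record(snp_id=f"rs{i}", ea="A", oa="G") for i in range(8)]
        exp += [make_record(snp_id=f"pal{i}", ea="A", oa="T", eaf=0.5)
                for i in range(2)]
        out = [make_record(snp_id=r.snp_id, ea=r.effect_allele,
                           oa=r.other_allele, eaf=r.eaf, beta=0.05)
               for r in exp]
        hset = harmonize_sets(exp, out)
        assert hset.nsnp == 8
        assert len(hset.drop_log) == 2
        assert all(d.drop_reason == "ambiguous_palindrome" for d in hset.drop_log)

    def test_idempotent(self):
        scenario = SimScenario(n_snps=30, theta=0.2, seed=7)
        exp, out, _ = simulate_gwas_pair(scenario)
        h1 = harmonize_sets(exp, out)
        # re-harmonizing the already-aligned pairs changes nothing
        aligned_out = [
            make_record(snp_id=r.snp_id, ea=e.effect_allele, oa=e.other_allele,
                        eaf=r.eaf_y, beta=r.by, se=r.sy)
            for r, e in zip(h1.records, exp)
            if r.snp_id == e.snp_id
        ]
        exp_kept = [e for e in exp if e.snp_id in set(h1.snp_ids)]
        h2 = harmonize_sets(exp_kept, aligned_out)
        assert [(r.snp_id, r.by, r.eaf_y) for r in h2.records] == [
            (r.snp_id, r.by, r.eaf_y) for r in h1.records
        ]

    def test_proxy_substitution(self):
        import numpy as np

        from mrpipe.instruments import LDMatrix

        exp = [make_record(snp_id="rs1", ea="A", oa="G", pos=1000),
               make_record(snp_id="rs2", ea="A", oa="G", pos=9000)]
        out = [make_record(snp_id="rs1", ea="A", oa="G", beta=0.05),
               make_record(snp_id="proxy", ea="C", oa="T", beta=0.04, pos=9500)]
        r2 = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.95], [0.0, 0.95, 1.0]])
        ld = LDMatrix(ids=["rs1", "rs2", "proxy"], r2=r2)
        hset = harmonize_sets(exp, out, ld=ld, allow_proxies=True)
        assert hset.nsnp == 2
        by_id = {r.snp_id: r for r in hset.records}
        assert by_id["rs2"].proxy_id == "proxy"
        # without proxies the SNP is lost
        hset2 = harmonize_sets(exp, out)
        assert hset2.nsnp == 1


class TestInvolution:
    def test_scramble_then_harmonize_recovers_non_palindromic_exactly(self):
        scenario = SimScenario(n_snps=1000, theta=0.25, seed=11)
        exp, out, _ = simulate_gwas_pair(scenario)
        corrupted, log = scramble_alleles(out, seed=99)
        assert len(log) == len(out)

        clean = harmonize_sets(exp, out)
        recovered = harmonize_sets(exp, corrupted)
        clean_by_id = {r.snp_id: r for r in clean.records}
        rec_by_id = {r.snp_id: r for r in recovered.records}
        exp_by_id = {r.snp_id: r for r in exp}
        checked = 0
        for snp_id, rec in rec_by_id.items():
            if exp_by_id[snp_id].is_palindromic:
                continue
            ref = clean_by_id[snp_id]
            assert rec.by == ref.by, snp_id      # exact, not approximate
            assert rec.eaf_y == ref.eaf_y or rec.eaf_y == pytest.approx(ref.eaf_y)
            checked += 1
        assert checked > 500

    def test_downstream_estimate_invariant_to_outcome_allele_reporting(self):
        scenario = SimScenario(n_snps=40, theta=0.3, seed=3)
        exp, out, _ = simulate_gwas_pair(scenario)
        non_pal = {r.snp_id for r in exp if not r.is_palindromic}
        exp = [r for r in exp if r.snp_id in non_pal]
        out = [r for r in out if r.snp_id in non_pal]
        corrupted, _ = scramble_alleles(out, seed=5)
        est1, _ = ivw(harmonize_sets(exp, out))
        est2, _ = ivw(harmonize_sets(exp, corrupted))
        assert est2.beta == pytest.approx(est1.beta, abs=0)
        assert est2.se == pytest.approx(est1.se, abs=0)
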