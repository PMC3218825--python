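"""Genotype caller and filter cascade: oracle agreement, filter semantics,
pileup conservation and the Poisson support bound."""

import math

import numpy as np
import pysam
import pytest

from varimap import simulate as sim
from varimap.snpcall import (
    GenotypeCall,
    PileupColumn,
    build_pileup,
    call_consensus,
    call_genotype,
    classify_zygosity,
    filter_candidates,
    flank_copy_number,
    pileup_counts,
    poisson_support_fdr,
    write_vcf,
)


from oracles import brute_force_genotype


def _mkpair(chrom, start, seq, qual=30, qname="p"):
    r1 = sim.Read(chrom, start, "+", seq, qual)
    r2 = sim.Read(chrom, start + 300, "-", seq, qual)
    return sim.AlignedPair(qname, r1, r2)


class TestPileup:
    def test_single_read_columns(self, small_ref):
        pair = _mkpair("chr1", 100, "A" * 49)
        cols = list(build_pileup([pair], small_ref))
        assert [c.pos for c in cols[:49]] == list(range(100, 149))
        assert all(c.depth == 1 for c in cols[:49])

    def test_overlap_additivity(self, small_ref):
        pairs = [
            _mkpair("chr1", 100, "A" * 49, qname="a"),
            _mkpair("chr1", 139, "A" * 49, qname="b"),
        ]
        cols = {c.pos: c.depth for c in build_pileup(pairs, small_ref)}
        for pos in range(139, 149):
            assert cols[pos] == 2

    def test_depth_conservation(self, snp_bundle):
        ref, _, _, _, pairs = snp_bundle
        subset = pairs[:300]
        total_depth = sum(c.depth for c in build_pileup(subset, ref))
        expected = 0
        for p in subset:
            for read in (p.read1, p.read2):
                seg = ref.chromosomes[read.chrom][read.start : read.end]
                expected += len(seg) - seg.count("N")
        assert total_depth == expected

    def test_counts_match_columns(self, snp_bundle):
        ref, _, _, params, pairs = snp_bundle
        subset = pairs[:300]
        counts = pileup_counts(subset, ref)
        cols = {(c.chrom, c.pos): c for c in build_pileup(subset, ref)}
        for (chrom, pos), col in cols.items():
            assert counts[chrom][:, pos].sum() == col.depth

    def test_overhanging_read_rejected(self, small_ref):
        pair = sim.AlignedPair(
            "x",
            sim.Read("chr1", 99_990, "+", "A" * 44, 30),
            sim.Read("chr1", 99_000, "-", "A" * 44, 30),
        )
        cols = list(build_pileup([pair], small_ref))
        assert all(c.pos < 99_044 for c in cols)


class TestCallGenotype:
    def test_strong_hom_ref(self):
        col = PileupColumn("chr1", 0, "A", [("A", 30)] * 10)
        call = call_genotype(col)
        assert call.genotype == ("A", "A")
        assert call.cns_quality >= 40

    def test_balanced_het(self):
        col = PileupColumn("chr1", 0, "A", [("A", 30)] * 5 + [("G", 30)] * 5)
        call = call_genotype(col)
        assert call.genotype == ("A", "G")

    def test_single_low_quality_read_cannot_yield_snp(self):
        """One discordant Q5 read: the hom-ref prior wins, so the call is
        non-variant and no SNP can emerge; posterior frozen from the
        enumeration oracle."""
        col = PileupColumn("chr1", 0, "A", [("T", 5)])
        call = call_genotype(col)
        assert call.genotype == ("A", "A")
        assert classify_zygosity(call.genotype, "A") is None
        assert call.posterior == pytest.approx(0.996649, abs=1e-6)

    def test_empty_column_no_call(self):
        assert call_genotype(PileupColumn("chr1", 0, "A", [])) is None

    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive-enumeration oracle agreement on random columns."""
        for _ in range(300):
            ref_base = "ACGT"[rng.integers(4)]
            depth = int(rng.integers(1, 31))
            obs = [
                ("ACGT"[rng.integers(4)], int(rng.integers(5, 41)))
                for _ in range(depth)
            ]
            col = PileupColumn("chr1", 0, ref_base, obs)
            call = call_genotype(col)
            want_gt, want_post = brute_force_genotype(col)
            assert call.genotype == want_gt
            assert call.posterior == pytest.approx(want_post, rel=1e-9)

    def test_vectorised_matches_per_column(self, snp_bundle):
        ref, _, _, params, pairs = snp_bundle
        subset = pairs[:400]
        counts = pileup_counts(subset, ref)
        cns = call_consensus(counts, ref, base_quality=params.base_quality)
        cols = list(build_pileup(subset, ref))
        for col in cols[::7]:
            a = cns.call_at(col.chrom, col.pos)
            b = call_genotype(col)
            assert a.genotype == b.genotype
            assert a.cns_quality == b.cns_quality
            assert a.posterior == pytest.approx(b.posterior, rel=1e-9)


class TestFlankCopyNumber:
    def test_unique_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        ref = sim.Reference({"chr1": seq})
        assert flank_copy_number(ref, "chr1", 50_000) == pytest.approx(1.0)

    def test_tandem_duplication(self, rng):
        block = "".join(rng.choice(list("ACGT"), size=10_000))
        ref = sim.Reference({"chr1": block + block})
        assert flank_copy_number(ref, "chr1", 5_000) == pytest.approx(2.0)

    def test_all_n_flank_undefined(self):
        ref = sim.Reference({"chr1": "N" * 200 + "ACGT" * 100})
        assert math.isinf(flank_copy_number(ref, "chr1", 100))


def _call(pos, genotype, ref_base="A", quality=40, depths=None, chrom="chr1"):
    depths = depths or {a: 10 for a in set(genotype)}
    posterior = 1 - 10 ** (-quality / 10)
    return GenotypeCall(chrom, pos, ref_base, genotype, posterior, quality, depths)


@pytest.fixture(scope="module")
def uref():
    rng = np.random.default_rng(0)
    return sim.Reference({"chr1": "".join(rng.choice(list("ACGT"), size=50_000))})


class TestFilterCascade:
    def test_low_quality_fails_first(self, uref):
        recs = filter_candidates([_call(1000, ("A", "G"), quality=19)], uref)
        assert recs[0].filter_status == "min_cns_quality"

    def test_close_pair_both_removed(self, uref):
        calls = [_call(1000, ("A", "G")), _call(1003, ("A", "C"))]
        recs = filter_candidates(calls, uref)
        assert [r.filter_status for r in recs] == ["min_snp_spacing"] * 2

    def test_spacing_passes_at_exactly_five(self, uref):
        calls = [_call(1000, ("A", "G")), _call(1005, ("A", "C"))]
        recs = filter_candidates(calls, uref)
        assert all(r.passed for r in recs)

    def test_excess_depth_fails(self, uref):
        call = _call(1000, ("A", "G"), depths={"A": 60, "G": 41})
        recs = filter_candidates([call], uref)
        assert recs[0].filter_status == "max_depth"

    def test_het_with_weak_allele_fails(self, uref):
        call = _call(1000, ("A", "G"), depths={"A": 12, "G": 3})
        recs = filter_candidates([call], uref)
        assert recs[0].filter_status == "min_reads_per_allele"

    def test_repeat_flank_fails(self, rng):
        block = "".join(rng.choice(list("ACGT"), size=10_000))
        ref = sim.Reference({"chr1": block + block})
        recs = filter_candidates([_call(5_000, ("A", "G"))], ref)
        assert recs[0].filter_status == "max_flank_copy_number"

    def test_unsorted_input_rejected(self, uref):
        calls = [_call(2000, ("A", "G")), _call(1000, ("A", "C"))]
        with pytest.raises(ValueError):
            filter_candidates(calls, uref)

    def test_idempotence(self, uref):
        calls = [
            _call(1000, ("A", "G")),
            _call(1003, ("A", "C")),
            _call(2000, ("C", "C")),
            _call(3000, ("A", "T"), quality=19),
        ]
        first = filter_candidates(calls, uref)
        surviving = [r.call for r in first if r.passed]
        second = filter_candidates(surviving, uref)
        assert all(r.passed for r in second)
        assert [r.call.pos for r in second] == [r.call.pos for r in first if r.passed]


class TestZygosity:
    @pytest.mark.parametrize(
        "genotype,ref,expected",
        [
            (("A", "G"), "A", "het"),
            (("G", "G"), "A", "hom"),
            (("A", "A"), "A", None),
        ],
    )
    def test_definition(self, genotype, ref, expected):
        assert classify_zygosity(genotype, ref) == expected


class TestPoissonSupportFdr:
    def test_paper_operating_point(self):
        lam_eps = 11.56 * 0.01
        value = poisson_support_fdr(11.56, 0.01, 4)
        assert value <= 0.001
        # direct pmf summation oracle
        direct = 1.0 - sum(
            math.exp(-lam_eps) * lam_eps**k / math.factorial(k) for k in range(4)
        )
        assert value == pytest.approx(direct, rel=1e-9)

    def test_k_zero_is_one(self):
        assert poisson_support_fdr(5.0, 0.3, 0) == 1.0

    def test_strictly_decreasing_in_k(self):
        vals = [poisson_support_fdr(11.56, 0.01, k) for k in range(8)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestVcf:
    def test_roundtrip_positions_and_genotypes(self, tmp_path, small_ref):
        snp_ref_base = small_ref.chromosomes["chr1"][1000]
        alt = "G" if snp_ref_base != "G" else "C"
        call = _call(1000, tuple(sorted((snp_ref_base, alt))), ref_base=snp_ref_base)
        recs = filter_candidates([call], small_ref)
        path = tmp_path / "out.vcf"
        write_vcf(recs, small_ref, path)
        with pysam.VariantFile(str(path)) as vcf:
            rows = list(vcf)
        assert len(rows) == 1
        assert rows[0].pos == 1001  # 1-based emission
        assert rows[0].ref == snp_ref_base
        assert rows[0].alts == (alt,)
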