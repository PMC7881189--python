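"""VCF round-tripping and the SNP/individual filter chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgehead import (
    MISSING,
    GenotypeMatrix,
    filter_individuals,
    filter_loci,
    read_popmap,
    read_vcf,
    thin_one_snp_per_locus,
    write_popmap,
    write_vcf,
)
from bridgehead.genotypes import default_locus_frame

from conftest import random_matrix

VCF_SMALL = """\
##fileformat=VCFv4.2
##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
chr1\t10\tL1\tA\tT\t.\tPASS\tMDP=30\tGT\t0/0\t0/0
chr1\t20\tL2\tC\tG\t.\tPASS\tMDP=30\tGT\t0/1\t0|1
chr1\t30\tL3\tA\tC\t.\tPASS\tMDP=30\tGT\t1/1\t./.
"""


class TestReadVcf:
    def test_dosage_codes_and_missing(self, tmp_path):
        path = tmp_path / "small.vcf"
        path.write_text(VCF_SMALL)
        g = read_vcf(path, {"sampleA": "p1", "sampleB": "p2"})
        assert g.individuals == ["sampleA", "sampleB"]
        assert g.populations == ["p1", "p2"]
        # homozygous ref, het (phased == unphased), homozygous alt
        assert list(g.codes[0]) == [0, 1, 2]
        assert g.codes[1, 2] == MISSING
        assert list(g.loci["pos"]) == [10, 20, 30]

    def test_individual_absent_from_popmap_rejected(self, tmp_path):
        path = tmp_path / "small.vcf"
        path.write_text(VCF_SMALL)
        with pytest.raises(ValueError, match="sampleB"):
            read_vcf(path, {"sampleA": "p1"})

    def test_multiallelic_strict_raises(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(VCF_SMALL.replace("chr1\t20\tL2\tC\tG", "chr1\t20\tL2\tC\tG,T"))
        with pytest.raises(ValueError, match="multiallelic"):
            read_vcf(path, {"sampleA": "p1", "sampleB": "p2"})
        g = read_vcf(path, {"sampleA": "p1", "sampleB": "p2"},
                     strict_biallelic=False)
        assert g.n_loci == 2

    def test_round_trip_preserves_everything(self, tmp_path, rng):
        g = random_matrix(rng, {"a": 3, "b": 2}, 10, missing_rate=0.2)
        write_vcf(g, tmp_path / "rt.vcf")
        write_popmap(g, tmp_path / "rt.popmap")
        g2 = read_vcf(tmp_path / "rt.vcf", read_popmap(tmp_path / "rt.popmap"))
        assert np.array_equal(g.codes, g2.codes)
        assert g2.populations == g.populations
        assert list(g2.loci["pos"]) == list(g.loci["pos"])
        assert np.allclose(g2.loci["mean_depth"], g.loci["mean_depth"], rtol=1e-3)


class TestFilterIndividuals:
    def test_planted_missingness_fractions(self):
        # 20 individuals, 20 loci, individual i missing i fraction of loci
        fracs = np.arange(20) * 0.05  # 0.0 .. 0.95
        codes = np.ones((20, 20), dtype=np.int8)
        for i, f in enumerate(fracs):
            codes[i, : int(round(f * 20))] = MISSING
        g = GenotypeMatrix(codes, [f"i{i}" for i in range(20)], ["p"] * 20)
        out, report = filter_individuals(g, max_missing=0.30)
        assert out.n_individuals == int((fracs < 0.30).sum())
        assert report.n_removed + report.n_surviving == report.n_input

    def test_threshold_is_inclusive(self):
        codes = np.ones((2, 10), dtype=np.int8)
        codes[0, :3] = MISSING  # exactly 0.30 -> removed
        codes[1, :2] = MISSING  # 0.20 -> retained
        g = GenotypeMatrix(codes, ["x", "y"], ["p", "p"])
        out, _ = filter_individuals(g)
        assert out.individuals == ["y"]

    def test_all_removed_is_an_error(self):
        codes = np.full((2, 4), MISSING, dtype=np.int8)
        g = GenotypeMatrix(codes, ["x", "y"], ["p", "p"])
        with pytest.raises(ValueError, match="all individuals"):
            filter_individuals(g)


def _toy_filter_matrix() -> GenotypeMatrix:
    """2 populations x 4 individuals, 8 loci: 4 clean loci plus exactly one
    violation of each filter rule."""
    clean = [0, 0, 1, 1, 0, 0, 1, 1]           # maf 0.25, het 0.5
    call_rate_bad = [0, 1, 0, 1, MISSING, MISSING, MISSING, 0]  # pop2 rate 0.25
    maf_bad = [0, 0, 0, 0, 0, 0, 0, 0]         # monomorphic, maf 0 < 0.05
    het_bad = [1, 1, 1, 1, 1, 1, 1, 1]         # obs het 1.0 > 0.7
    depth_bad = clean                            # fails only on depth
    cols = [clean, clean, call_rate_bad, maf_bad, clean, het_bad, depth_bad, clean]
    codes = np.array(cols, dtype=np.int8).T
    loci = default_locus_frame(8)
    loci.loc[6, "mean_depth"] = 250.0
    return GenotypeMatrix(
        codes,
        [f"i{i}" for i in range(8)],
        ["p1"] * 4 + ["p2"] * 4,
        loci,
    )


class TestFilterLoci:
    def test_planted_violations_each_attributed_once(self):
        g = _toy_filter_matrix()
        out, report = filter_loci(g)
        assert out.n_loci == 4
        assert dict(report.stages) == {
            "call_rate": 1, "maf": 1, "heterozygosity": 1, "depth": 1
        }
        report.check_conservation()

    def test_maf_threshold_is_survival_inclusive(self, rng):
        # maf exactly 0.05 survives; below is removed
        codes = np.zeros((10, 2), dtype=np.int8)
        codes[0, 0] = 1  # 1/20 = 0.05 -> kept
        codes[:, 1] = [0, 1, 1, 0, 0, 0, 1, 0, 1, 0]  # keeps matrix polymorphic
        g = GenotypeMatrix(codes, [f"i{i}" for i in range(10)], ["p"] * 10)
        out, _ = filter_loci(g, min_call_rate_per_pop=0.0)
        assert out.n_loci == 2

    def test_all_heterozygous_removed(self):
        codes = np.ones((6, 1), dtype=np.int8)
        g = GenotypeMatrix(codes, [f"i{i}" for i in range(6)], ["p"] * 6)
        out, report = filter_loci(g)
        assert out.n_loci == 0
        assert dict(report.stages)["heterozygosity"] == 1

    def test_idempotent(self, rng):
        g = random_matrix(rng, {"a": 6, "b": 6}, 40, missing_rate=0.1)
        once, _ = filter_loci(g)
        twice, report = filter_loci(once)
        assert twice == once
        assert report.n_removed == 0

    def test_survivors_match_independent_predicates(self, rng):
        """The surviving set equals the conjunction of the four per-locus
        predicates evaluated independently (rule order only affects
        attribution)."""
        g = random_matrix(rng, {"a": 5, "b": 5}, 60, missing_rate=0.25)
        g.loci["mean_depth"] = rng.uniform(1, 250, size=60)
        out, _ = filter_loci(g)
        expected = []
        for j in range(g.n_loci):
            ok = True
            for pop in ("a", "b"):
                sub = g.codes[g.pop_indices(pop), j]
                ok &= (sub != MISSING).mean() >= 0.5
            col = g.codes[:, j]
            called = col[col != MISSING]
            p = called.sum() / (2 * len(called))
            ok &= min(p, 1 - p) >= 0.05
            ok &= (called == 1).mean() <= 0.7
            ok &= 5 <= g.loci["mean_depth"][j] <= 200
            if ok:
                expected.append(j)
        assert list(out.loci["pos"]) == [int(g.loci["pos"][j]) for j in expected]


class TestThinning:
    def _grouped(self):
        codes = np.zeros((4, 7), dtype=np.int8)
        codes[0] = 1
        loci = default_locus_frame(7)
        loci["locus_id"] = ["A", "B", "B", "B", "B", "C", "C"]
        return GenotypeMatrix(codes, list("wxyz"), ["p"] * 4, loci)

    def test_one_snp_per_locus(self):
        out = thin_one_snp_per_locus(self._grouped(), seed=1)
        assert out.n_loci == 3
        assert sorted(out.loci["locus_id"]) == ["A", "B", "C"]

    def test_deterministic_per_seed(self):
        g = self._grouped()
        a = thin_one_snp_per_locus(g, seed=42)
        b = thin_one_snp_per_locus(g, seed=42)
        assert list(a.loci["pos"]) == list(b.loci["pos"])

    def test_uniform_choice_over_seeds(self):
        codes = np.zeros((2, 2), dtype=np.int8)
        codes[0] = 1
        loci = default_locus_frame(2)
        loci["locus_id"] = ["L", "L"]
        g = GenotypeMatrix(codes, ["u", "v"], ["p", "p"], loci)
        first = sum(
            thin_one_snp_per_locus(g, seed=s).loci["pos"][0] == 1
            for s in range(1000)
        )
        assert 0.46 <= first / 1000 <= 0.54


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_ind=st.integers(2, 8),
    n_loci=st.integers(1, 30),
    seed=st.integers(0, 2**20),
)
def test_filter_reports_conserve_counts(n_ind, n_loci, seed):
    rng = np.random.default_rng(seed)
    g = random_matrix(rng, {"a": n_ind, "b": n_ind}, n_loci, missing_rate=0.3)
    try:
        out, rep = filter_individuals(g, 0.9)
    except ValueError:
        return  # everything removed: error contract, nothing to conserve
    assert rep.n_input == g.n_individuals
    assert rep.n_surviving == out.n_individuals
    out2, rep2 = filter_loci(out)
    assert rep2.n_surviving == out2.n_loci
    assert rep2.n_removed + rep2.n_surviving == rep2.n_input
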