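import io
import math
import warnings
from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import fisher_exact as scipy_fisher

from epicombo import (
    DOMINANT,
    RECESSIVE,
    PatternElement,
    SignificanceGates,
    Table2x2,
    fisher_exact_2x2,
    hwe_test,
    ld_pair,
    odds_ratio,
    read_native,
    single_variant_scan,
)

from conftest import dataset_from_counts


def fisher_p_exact_rational(t: Table2x2) -> Fraction:
    """Independent oracle: exact-rational hypergeometric enumeration."""
    row1 = t.n11 + t.n01  # carriers
    col1 = t.n11 + t.n10  # cases
    n = t.total
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    weights = {k: Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k)) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[t.n11]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestFisherExact:
    def test_small_table_closed_form(self):
        assert fisher_exact_2x2(Table2x2(3, 1, 1, 3)) == pytest.approx(34 / 70, abs=1e-12)

    def test_zero_margin_single_feasible_table(self):
        assert fisher_exact_2x2(Table2x2(0, 10, 0, 10)) == 1.0

    def test_replication_scale_table(self):
        t = Table2x2(33, 187, 8, 189)
        p = fisher_exact_2x2(t)
        assert p == pytest.approx(float(fisher_p_exact_rational(t)), abs=1e-12)
        # printed two-sided p for this contrast is of order 1e-4
        assert 1e-5 < p < 1e-3

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(Table2x2(0, 0, 0, 0))

    def test_matches_rational_enumeration_on_random_tables(self):
        # probability-mass ordering against the exact-rational oracle, N <= 60
        rng = np.random.default_rng(42)
        for _ in range(500):
            cells = rng.multinomial(int(rng.integers(1, 61)), [0.25] * 4)
            t = Table2x2(*map(int, cells))
            assert fisher_exact_2x2(t) == pytest.approx(
                float(fisher_p_exact_rational(t)), abs=1e-10
            ), cells

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cells = rng.integers(0, 40, size=4)
            if cells.sum() == 0:
                continue
            t = Table2x2(*map(int, cells))
            sp = scipy_fisher([[t.n11, t.n01], [t.n10, t.n00]])[1]
            assert fisher_exact_2x2(t) == pytest.approx(sp, rel=1e-8)


class TestOddsRatio:
    def test_replication_crp_table(self):
        r = odds_ratio(Table2x2(33, 187, 8, 189))
        assert round(r.OR, 2) == 4.17
        assert round(r.ci_low, 2) == pytest.approx(1.87, abs=0.011)
        assert round(r.ci_high, 2) == 9.26

    def test_discovery_crp_table(self):
        r = odds_ratio(Table2x2(38, 287, 8, 177))
        assert round(r.OR, 2) == 2.93
        # printed CI is 1.34-6.41; Woolf reproduces it to one unit in the last digit
        assert round(r.ci_low, 2) == pytest.approx(1.34, abs=0.011)
        assert round(r.ci_high, 2) == pytest.approx(6.41, abs=0.011)

    def test_null_table_symmetric_ci(self):
        r = odds_ratio(Table2x2(10, 10, 10, 10))
        assert r.OR == 1.0
        assert r.ci_low * r.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_row_swap_reciprocal(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = Table2x2(*(int(x) for x in rng.integers(1, 50, size=4)))
            a = odds_ratio(t, zero_correction=False)
            b = odds_ratio(t.swapped_rows(), zero_correction=False)
            assert a.OR * b.OR == pytest.approx(1.0, rel=1e-12)

    def test_zero_cell_corrected(self):
        r = odds_ratio(Table2x2(5, 0, 3, 7))
        assert r.corrected and np.isfinite(r.OR) and np.isfinite(r.ci_high)


class TestHardyWeinberg:
    def test_two_genotype_exact_enumeration(self):
        # one AA + one aa: heterozygote count 0 or 2 with probs 1/3, 2/3
        assert hwe_test(1, 0, 1).p == pytest.approx(1 / 3, abs=1e-12)

    def test_chi_square_at_exact_proportions(self):
        assert hwe_test(25, 50, 25, method="chi-square").p == 1.0

    def test_monomorphic_warns_p_one(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            res = hwe_test(50, 0, 0)
        assert res.p == 1.0 and res.monomorphic

    @pytest.mark.parametrize("counts", [(1250, 2500, 1250), (1240, 2520, 1240), (1230, 2540, 1230)])
    def test_exact_and_chi_square_converge_on_large_balanced_counts(self, counts):
        # common allele freq 0.5, total 5000: the two methods agree closely
        p_e = hwe_test(*counts).p
        p_c = hwe_test(*counts, method="chi-square").p
        assert abs(p_e - p_c) < 0.03


def _two_locus_dataset(cell_counts: np.ndarray) -> "GenotypeDataset":
    """Dataset realizing a 3x3 joint genotype count matrix (copies of A at L1, C at L2)."""
    g1 = {2: "AA", 1: "AG", 0: "GG"}
    g2 = {2: "CC", 1: "CT", 0: "TT"}
    lines = ["sample_id\tphenotype\tsex\tL1\tL2"]
    k = 0
    for i in range(3):
        for j in range(3):
            for _ in range(int(cell_counts[i, j])):
                lines.append(f"s{k}\t{k % 2}\tNA\t{g1[i]}\t{g2[j]}")
                k += 1
    return read_native(io.StringIO("\n".join(lines) + "\n"))


class TestLinkageDisequilibrium:
    def test_complete_coupling_dprime_one(self):
        counts = np.zeros((3, 3), int)
        counts[2, 2] = 25  # AA/CC (two AB haplotypes)
        counts[0, 0] = 25  # GG/TT (two ab)
        counts[1, 1] = 50  # AG/CT double het, all coupling under complete LD
        res = ld_pair(_two_locus_dataset(counts), "L1", "L2")
        assert res.Dprime == pytest.approx(1.0, abs=1e-6)
        assert res.linkage_class == "moderate"

    def test_independence_zero_d_and_lod(self):
        # genotype counts at exact independence: outer product of HWE margins at f=0.5
        m = np.array([1, 2, 1])
        counts = 4 * np.outer(m, m)  # total 64
        res = ld_pair(_two_locus_dataset(counts), "L1", "L2")
        assert res.D == pytest.approx(0.0, abs=1e-9)
        assert res.LOD == pytest.approx(0.0, abs=1e-9)
        assert res.linkage_class == "weak"

    def test_em_matches_direct_likelihood_maximization(self):
        counts = np.array([[6, 7, 2], [5, 12, 4], [1, 6, 9]])
        ds = _two_locus_dataset(counts)
        res = ld_pair(ds, "L1", "L2")
        # oracle: numerically maximize the multinomial likelihood over p_AB
        n = counts.sum()
        pA = (counts * np.arange(3)[:, None]).sum() / (2 * n)
        pB = (counts * np.arange(3)[None, :]).sum() / (2 * n)

        def negll(x):
            pAB = x[0]
            from epicombo.assoc import _ld_loglik

            hap = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
            if (hap <= 0).any():
                return 1e9
            return -_ld_loglik(counts, hap)

        best = min(
            (minimize(negll, [x0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
             for x0 in (pA * pB, 0.9 * min(pA, pB), 0.5 * max(0, pA + pB - 1) + 0.01)),
            key=lambda r: r.fun,
        )
        assert res.hap_freqs[0] == pytest.approx(best.x[0], abs=1e-6)
        assert res.LOD >= 0.0

    def test_dprime_invariant_under_allele_relabeling(self):
        counts = np.array([[10, 5, 1], [6, 20, 7], [2, 8, 11]])
        a = ld_pair(_two_locus_dataset(counts), "L1", "L2")
        b = ld_pair(_two_locus_dataset(counts[::-1, :].copy()), "L1", "L2")
        assert a.Dprime == pytest.approx(b.Dprime, abs=1e-9)

    def test_monomorphic_locus_rejected(self):
        counts = np.zeros((3, 3), int)
        counts[2, 0] = 10
        counts[2, 2] = 10
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(_two_locus_dataset(counts), "L1", "L2")


class TestSingleVariantScan:
    def test_flags_replication_crp_like_signal(self):
        ds = dataset_from_counts(33, 187, 8, 189, locus="rsCRP")
        records = single_variant_scan(ds)
        rec = next(
            r for r in records
            if r.pattern.sorted_elements[0] == PatternElement("rsCRP", RECESSIVE, "T")
        )
        assert round(rec.or_result.OR, 2) == 4.17
        assert rec.significant(SignificanceGates())
        assert rec.table == Table2x2(33, 187, 8, 189)

    def test_no_flags_when_groups_identical(self):
        text = "sample_id\tphenotype\tsex\trsA\n" + "".join(
            f"c{i}\t1\tNA\t{g}\n" for i, g in enumerate(["TT", "CT", "CC"] * 10)
        ) + "".join(f"k{i}\t0\tNA\t{g}\n" for i, g in enumerate(["TT", "CT", "CC"] * 10))
        ds = read_native(io.StringIO(text))
        records = single_variant_scan(ds)
        assert records and not any(r.significant(SignificanceGates()) for r in records)

    def test_monomorphic_locus_skipped_with_warning(self):
        text = (
            "sample_id\tphenotype\tsex\trsMono\trsPoly\n"
            + "".join(f"c{i}\t1\tNA\tTT\tCT\n" for i in range(5))
            + "".join(f"k{i}\t0\tNA\tTT\tCC\n" for i in range(5))
        )
        ds = read_native(io.StringIO(text))
        with pytest.warns(UserWarning, match="monomorphic"):
            records = single_variant_scan(ds)
        assert all(e.locus_id != "rsMono" for r in records for e in r.pattern.elements)

    def test_requires_both_groups(self, toy_dataset):
        text = "sample_id\tphenotype\tsex\trsA\ns1\t1\tM\tTT\ns2\t1\tM\tCT\n"
        ds = read_native(io.StringIO(text))
        with pytest.raises(ValueError, match="case and one control"):
            single_variant_scan(ds)
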