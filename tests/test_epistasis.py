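import itertools
import math

import numpy as np
import pytest

from epicombo import (
    DOMINANT,
    RECESSIVE,
    CarriagePattern,
    PatternElement,
    Table2x2x2,
    build_3way_table,
    conditional_null_distribution,
    evaluate_pattern,
    flint_exact_test,
    sf_flint_decision,
    sf_flint_test,
    synergy_factor,
)
from epicombo.epistasis import FlintResult, SynergyResult, table_from_indicators
from epicombo.simulate import paper_like_config, simulate_cohort

SYMMETRIC = Table2x2x2.from_cells(
    case_both=3, case_a_only=1, case_b_only=1, case_neither=3,
    ctrl_both=1, ctrl_a_only=3, ctrl_b_only=3, ctrl_neither=1,
)

MULTIPLICATIVE = Table2x2x2.from_cells(
    case_both=60, case_a_only=20, case_b_only=30, case_neither=10,
    ctrl_both=10, ctrl_a_only=10, ctrl_b_only=10, ctrl_neither=10,
)


def flint_bruteforce(table: Table2x2x2) -> float:
    """Independent oracle: enumerate the case layer outright, filter on margins.

    Given the fixed A x B margin, the control layer is determined by the case
    layer; all candidate case layers are enumerated cell by cell and kept when
    the A x outcome and B x outcome margins match, with mass prod(1/n!).
    """
    n = table.n
    m_ab = n.sum(axis=2)  # A x B margin
    m_ay = n.sum(axis=1)  # A x outcome
    m_by = n.sum(axis=0)  # B x outcome
    masses = []
    obs_mass = None
    ranges = [range(int(m_ab[a, b]) + 1) for a in (0, 1) for b in (0, 1)]
    for c00, c01, c10, c11 in itertools.product(*ranges):
        cases = np.array([[c00, c01], [c10, c11]])
        ctrls = m_ab - cases
        if (ctrls < 0).any():
            continue
        cand = np.stack([ctrls, cases], axis=2)  # n[a][b][y]
        if not np.array_equal(cand.sum(axis=1), m_ay):
            continue
        if not np.array_equal(cand.sum(axis=0), m_by):
            continue
        mass = 1.0
        for cell in cand.ravel():
            mass /= math.factorial(int(cell))
        masses.append(mass)
        if np.array_equal(cand, n):
            obs_mass = mass
    total = sum(masses)
    return sum(m for m in masses if m <= obs_mass * (1 + 1e-12)) / total


def random_table(rng, cell_max=6) -> Table2x2x2:
    return Table2x2x2(rng.integers(0, cell_max + 1, size=(2, 2, 2)))


class TestBuild3WayTable:
    def test_cell_total_conservation(self, paper_like_cohort):
        eA = PatternElement("rsIFNG", DOMINANT, "A")
        eB = PatternElement("rsPTGS1", DOMINANT, "T")
        t = build_3way_table(paper_like_cohort, eA, eB)
        assert t.total == paper_like_cohort.n_samples  # no missing data in this draw

    def test_marginal_consistency_with_2x2_evaluation(self, paper_like_cohort):
        eA = PatternElement("rsTGFB1", RECESSIVE, "T")
        eB = PatternElement("rsCRP", RECESSIVE, "T")
        t = build_3way_table(paper_like_cohort, eA, eB)
        rec_a = evaluate_pattern(paper_like_cohort, CarriagePattern.of(eA))
        rec_b = evaluate_pattern(paper_like_cohort, CarriagePattern.of(eB))
        assert t.collapse_b() == rec_a.table
        assert t.collapse_a() == rec_b.table

    def test_overlapping_loci_rejected(self, paper_like_cohort):
        eA = PatternElement("rsIFNG", DOMINANT, "A")
        with pytest.raises(ValueError, match="share loci"):
            build_3way_table(paper_like_cohort, eA, eA)


class TestConditionalNull:
    def test_all_ones_table_hand_enumeration(self):
        xs, probs = conditional_null_distribution(Table2x2x2(np.ones((2, 2, 2), int)))
        assert list(xs) == [0, 1, 2]
        assert probs == pytest.approx([1 / 18, 8 / 9, 1 / 18], abs=1e-12)

    def test_zero_margin_forces_singleton_support(self):
        t = Table2x2x2.from_cells(
            case_both=0, case_a_only=3, case_b_only=0, case_neither=2,
            ctrl_both=0, ctrl_a_only=1, ctrl_b_only=0, ctrl_neither=4,
        )  # nobody carries B: the B x anything margins pin the table
        xs, probs = conditional_null_distribution(t)
        assert len(xs) == 1 and probs[0] == pytest.approx(1.0)

    def test_masses_normalized_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            _, probs = conditional_null_distribution(random_table(rng, 8))
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestFlint:
    def test_all_ones_p_one(self):
        res = flint_exact_test(Table2x2x2(np.ones((2, 2, 2), int)))
        assert res.p == 1.0 and res.support_size == 3

    def test_symmetric_fixture(self):
        res = flint_exact_test(SYMMETRIC)
        # enumeration over x in 0..4 with weights 1/(x!^4 (4-x)!^4)
        assert res.p == pytest.approx(0.2840, abs=5e-5)
        assert res.p == pytest.approx(flint_bruteforce(SYMMETRIC), abs=1e-12)

    def test_singleton_support_p_one(self):
        t = Table2x2x2.from_cells(
            case_both=4, case_a_only=0, case_b_only=0, case_neither=0,
            ctrl_both=0, ctrl_a_only=0, ctrl_b_only=0, ctrl_neither=5,
        )
        assert flint_exact_test(t).p == 1.0

    def test_matches_bruteforce_on_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = random_table(rng, 4)
            if t.total == 0:
                continue
            assert flint_exact_test(t).p == pytest.approx(flint_bruteforce(t), abs=1e-10)

    def test_role_symmetry_smoke(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            t = random_table(rng)
            if t.total == 0:
                continue
            p0 = flint_exact_test(t).p
            for perm in itertools.permutations(range(3)):
                assert flint_exact_test(Table2x2x2(np.transpose(t.n, perm))).p == pytest.approx(
                    p0, abs=1e-12
                )


class TestSynergyFactor:
    def test_multiplicative_table_sf_exactly_one(self):
        res = synergy_factor(MULTIPLICATIVE)
        assert res.SF == 1.0 and not res.corrected

    def test_symmetric_fixture_sf_81_ci_crosses_one(self):
        res = synergy_factor(SYMMETRIC)
        assert res.SF == pytest.approx(81.0, rel=1e-12)
        assert res.ci_low < 1.0 < res.ci_high  # tiny cells, huge variance

    def test_zero_cell_correction(self):
        t = Table2x2x2.from_cells(
            case_both=5, case_a_only=0, case_b_only=3, case_neither=2,
            ctrl_both=1, ctrl_a_only=4, ctrl_b_only=2, ctrl_neither=6,
        )
        res = synergy_factor(t)
        assert res.corrected and np.isfinite(res.SF) and res.ci_low > 0

    def test_swap_factors_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = Table2x2x2(rng.integers(1, 30, size=(2, 2, 2)))
            swapped = Table2x2x2(np.transpose(t.n, (1, 0, 2)))
            assert synergy_factor(t).SF == pytest.approx(synergy_factor(swapped).SF, rel=1e-12)

    def test_sf_equals_ratio_of_subtable_odds_ratios(self):
        from epicombo import Table2x2, odds_ratio

        rng = np.random.default_rng(4)
        for _ in range(50):
            t = Table2x2x2(rng.integers(1, 30, size=(2, 2, 2)))
            n = t.n

            def or_vs_baseline(a, b):
                sub = Table2x2(
                    n11=int(n[a, b, 1]), n10=int(n[0, 0, 1]),
                    n01=int(n[a, b, 0]), n00=int(n[0, 0, 0]),
                )
                return odds_ratio(sub, zero_correction=False).OR

            expected = or_vs_baseline(1, 1) / (or_vs_baseline(1, 0) * or_vs_baseline(0, 1))
            assert synergy_factor(t).SF == pytest.approx(expected, rel=1e-10)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "sf, lo, hi, p, expected",
        [
            (5.18, 1.46, 18.4, 0.018, "synergistic"),
            (7.27, 1.72, 30.8, 0.0012, "synergistic"),
            (2.22, 0.78, 6.33, 0.18, "none"),
            (0.39, 0.086, 1.77, 0.26, "none"),
            (0.66, 0.13, 3.41, 0.67, "none"),
            (0.30, 0.10, 0.80, 0.01, "compensatory"),
            (5.0, 1.5, 20.0, 0.20, "none"),  # SF alone is not enough
            (5.0, 0.9, 20.0, 0.01, "none"),  # FLINT alone is not enough
        ],
    )
    def test_published_style_decisions(self, sf, lo, hi, p, expected):
        synergy = SynergyResult(SF=sf, ci_low=lo, ci_high=hi, alpha=0.05, corrected=False)
        flint = FlintResult(p=p, support_size=10, observed_prob=0.01)
        assert sf_flint_decision(synergy, flint).call == expected


def test_procedure_accepts_any_binary_indicators():
    # gene x sex style input: plain 0/1 vectors rather than carriage patterns
    rng = np.random.default_rng(5)
    a = rng.integers(0, 2, 300).astype(float)
    b = rng.integers(0, 2, 300).astype(float)
    y = rng.integers(0, 2, 300)
    t = table_from_indicators(a, b, y)
    assert t.total == 300
    verdict = sf_flint_decision(synergy_factor(t), flint_exact_test(t))
    assert verdict.call in ("synergistic", "compensatory", "none")


def test_planted_pair_recovers_synergistic_call_at_large_n():
    cfg = paper_like_config(n_case=2000, n_control=2000)
    ds = simulate_cohort(cfg, seed=3)
    verdict = sf_flint_test(
        ds, PatternElement("rsIFNG", DOMINANT, "A"), PatternElement("rsPTGS1", DOMINANT, "T")
    )
    assert verdict.call == "synergistic"
    assert verdict.synergy.ci_low <= 5.0 <= verdict.synergy.ci_high
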