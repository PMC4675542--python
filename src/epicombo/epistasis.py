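"""The two-statistic SF+FLINT epistasis test for 2x2x2 tables.

A candidate gene-gene interaction is summarized by a three-way table
``n[a][b][y]`` counting subjects by carriage of factor A, carriage of factor
B, and outcome (y=1 case).  Two complementary statistics are computed:

* the **synergy factor** SF — the ratio of the joint-exposure odds ratio to
  the product of the single-exposure odds ratios, all relative to the
  double-non-carrier baseline.  On the multiplicative (no-interaction) odds
  scale SF = 1; SF > 1 is synergistic, SF < 1 compensatory.  Its confidence
  interval comes from the independent-Poisson-cells model:
  var(ln SF) = sum over all 8 cells of 1/n.

* the **FLINT** exact test — an exact test of no three-way interaction that
  conditions on all three two-way margins (A x B, A x outcome, B x outcome).
  With those margins fixed the table is a one-parameter family in
  x = n[1][1][1]; the conditional null puts mass proportional to
  prod(1/n_cell!) on each feasible x, and the two-sided p-value sums the
  masses no larger than the observed one (Fisher-style probability ordering).

The combined verdict calls an interaction only when *both* statistics agree:
the SF confidence interval excludes 1 and the FLINT p-value is below its
threshold.  The machinery applies to any pair of binary indicators, e.g.
allele carriage x sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .assoc import Table2x2, table_from_carriage
from .io import CarriagePattern, GenotypeDataset, PatternElement, pattern_carriage

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class Table2x2x2:
    """Counts n[a][b][y]: carriage of A, carriage of B, outcome (1=case)."""

    n: np.ndarray  # shape (2, 2, 2), non-negative ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.n, dtype=np.int64)
        if arr.shape != (2, 2, 2):
            raise ValueError(f"expected shape (2,2,2), got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "n", arr)

    @classmethod
    def from_cells(
        cls,
        *,
        case_both: int, case_a_only: int, case_b_only: int, case_neither: int,
        ctrl_both: int, ctrl_a_only: int, ctrl_b_only: int, ctrl_neither: int,
    ) -> "Table2x2x2":
        n = np.zeros((2, 2, 2), dtype=np.int64)
        n[1, 1, 1], n[1, 0, 1], n[0, 1, 1], n[0, 0, 1] = case_both, case_a_only, case_b_only, case_neither
        n[1, 1, 0], n[1, 0, 0], n[0, 1, 0], n[0, 0, 0] = ctrl_both, ctrl_a_only, ctrl_b_only, ctrl_neither
        return cls(n)

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def collapse_a(self) -> Table2x2:
        """Marginal carriage-by-outcome table of factor B (sum over A)."""
        m = self.n.sum(axis=0)
        return Table2x2(n11=int(m[1, 1]), n10=int(m[0, 1]), n01=int(m[1, 0]), n00=int(m[0, 0]))

    def collapse_b(self) -> Table2x2:
        """Marginal carriage-by-outcome table of factor A (sum over B)."""
        m = self.n.sum(axis=1)
        return Table2x2(n11=int(m[1, 1]), n10=int(m[0, 1]), n01=int(m[1, 0]), n00=int(m[0, 0]))


@dataclass(frozen=True)
class SynergyResult:
    SF: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool  # 0.5 added to all 8 cells

    def ci_excludes_1(self) -> bool:
        return self.ci_low > 1.0 or self.ci_high < 1.0


@dataclass(frozen=True)
class FlintResult:
    p: float
    support_size: int
    observed_prob: float


@dataclass(frozen=True)
class EpistasisVerdict:
    synergy: SynergyResult
    flint: FlintResult
    call: str  # 'synergistic' | 'compensatory' | 'none'


# ---------------------------------------------------------------------------


def build_3way_table(
    dataset: GenotypeDataset,
    factor_a: PatternElement | CarriagePattern,
    factor_b: PatternElement | CarriagePattern,
) -> Table2x2x2:
    """Cross-tabulate subjects by joint carriage of two factors and outcome.

    Subjects missing any constituent genotype of either factor are excluded;
    the two factors must involve disjoint locus sets.
    """
    pa = factor_a if isinstance(factor_a, CarriagePattern) else CarriagePattern.of(factor_a)
    pb = factor_b if isinstance(factor_b, CarriagePattern) else CarriagePattern.of(factor_b)
    loci_a = {e.locus_id for e in pa.elements}
    loci_b = {e.locus_id for e in pb.elements}
    if loci_a & loci_b:
        raise ValueError(f"factors share loci: {sorted(loci_a & loci_b)}")
    ca = pattern_carriage(dataset, pa)
    cb = pattern_carriage(dataset, pb)
    return table_from_indicators(ca, cb, dataset.phenotype)


def table_from_indicators(a: np.ndarray, b: np.ndarray, y: np.ndarray) -> Table2x2x2:
    """2x2x2 counts from two 0/1/NaN indicator vectors and binary outcome."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    ai = a[ok].astype(np.int64)
    bi = b[ok].astype(np.int64)
    yi = np.asarray(y)[ok].astype(np.int64)
    n = np.zeros((2, 2, 2), dtype=np.int64)
    np.add.at(n, (ai, bi, yi), 1)
    return Table2x2x2(n)


def _support(table: Table2x2x2) -> tuple[np.ndarray, np.ndarray, int]:
    """Feasible x = n[1][1][1] values, their 8-cell tables, and observed x.

    With all three two-way margins fixed, each cell is n_obs +/- (x - x_obs);
    cells with a+b+y even move with +, odd with -.
    """
    n = table.n
    x_obs = int(n[1, 1, 1])
    a, b, y = np.indices((2, 2, 2))
    sign = np.where((a + b + y) % 2 == (1 + 1 + 1) % 2, 1, -1)  # +1 where parity matches n111
    # feasibility: n_obs + sign*(x - x_obs) >= 0 for all cells
    lo, hi = 0, table.total
    for s, c in zip(sign.ravel(), n.ravel()):
        if s == 1:
            lo = max(lo, x_obs - int(c))
        else:
            hi = min(hi, x_obs + int(c))
    xs = np.arange(lo, hi + 1)
    cells = n.ravel()[None, :] + sign.ravel()[None, :] * (xs[:, None] - x_obs)
    return xs, cells, x_obs


def conditional_null_distribution(table: Table2x2x2) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution over feasible tables given all three two-way margins.

    Returns (xs, probs): feasible values of x = n[1][1][1] and their
    normalized masses P(x) proportional to prod over cells of 1/n_cell!.
    Computed in log space via log-gamma.
    """
    xs, cells, _ = _support(table)
    if len(xs) == 0:
        raise ValueError("no feasible table for the given margins")
    logw = -gammaln(cells + 1.0).sum(axis=1)
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    return xs, probs


def flint_exact_test(table: Table2x2x2) -> FlintResult:
    """Exact Fisher-like three-way interaction test.

    p = sum of null masses no larger than the observed table's mass (with a
    1e-12 relative tie tolerance); a singleton support yields p = 1.
    """
    xs, probs = conditional_null_distribution(table)
    _, _, x_obs = _support(table)
    p_obs = probs[np.searchsorted(xs, x_obs)]
    p = float(min(1.0, probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum()))
    return FlintResult(p=p, support_size=len(xs), observed_prob=float(p_obs))


def synergy_factor(table: Table2x2x2, alpha: float = 0.05) -> SynergyResult:
    """Synergy factor with its independent-Poisson-cells confidence interval.

    With baseline (A=0, B=0): OR_ab = odds(case | a, b) / odds(case | 0, 0),
    SF = OR_11 / (OR_10 * OR_01) and var(ln SF) = sum over the 8 cells of 1/n.
    Any zero cell triggers the 0.5 continuity correction on all eight cells.
    """
    cells = table.n.astype(float)
    corrected = False
    if (cells == 0).any():
        cells = cells + 0.5
        corrected = True
    odds = cells[:, :, 1] / cells[:, :, 0]  # odds(case | a, b)
    or11 = odds[1, 1] / odds[0, 0]
    or10 = odds[1, 0] / odds[0, 0]
    or01 = odds[0, 1] / odds[0, 0]
    sf = or11 / (or10 * or01)
    se = float(np.sqrt((1.0 / cells).sum()))
    z = norm.ppf(1.0 - alpha / 2.0)
    log_sf = np.log(sf)
    return SynergyResult(
        SF=float(sf),
        ci_low=float(np.exp(log_sf - z * se)),
        ci_high=float(np.exp(log_sf + z * se)),
        alpha=alpha,
        corrected=corrected,
    )


def sf_flint_decision(
    synergy: SynergyResult,
    flint: FlintResult,
    flint_alpha: float = 0.05,
) -> EpistasisVerdict:
    """Combine the two statistics; a call requires both to be significant.

    synergistic iff SF CI lies above 1 and p_FLINT < flint_alpha;
    compensatory iff SF CI lies below 1 and p_FLINT < flint_alpha; else none.
    """
    if flint.p < flint_alpha and synergy.ci_low > 1.0:
        call = "synergistic"
    elif flint.p < flint_alpha and synergy.ci_high < 1.0:
        call = "compensatory"
    else:
        call = "none"
    return EpistasisVerdict(synergy=synergy, flint=flint, call=call)


def sf_flint_test(
    dataset: GenotypeDataset,
    factor_a: PatternElement | CarriagePattern,
    factor_b: PatternElement | CarriagePattern,
    sf_alpha: float = 0.05,
    flint_alpha: float = 0.05,
) -> EpistasisVerdict:
    """Full SF+FLINT procedure for two carriage factors on a dataset."""
    table = build_3way_table(dataset, factor_a, factor_b)
    return sf_flint_decision(
        synergy_factor(table, alpha=sf_alpha),
        flint_exact_test(table),
        flint_alpha=flint_alpha,
    )
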