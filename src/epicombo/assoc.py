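"""Exact 2x2 association statistics, Hardy-Weinberg testing, and pairwise LD.

The 2x2 table convention throughout is carriage-by-outcome::

              case      control
    carrier    n11        n01
    non-carr.  n10        n00

Fisher's exact p is two-sided by probability-mass ordering over the
hypergeometric distribution with the table's margins (the convention of R's
``fisher.test`` and SciPy).  Odds-ratio confidence intervals are Woolf
(log-Wald), with the Haldane-Anscombe 0.5 continuity correction applied to all
four cells when any cell is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .io import (
    DOMINANT,
    RECESSIVE,
    CarriagePattern,
    GenotypeDataset,
    PatternElement,
    pattern_carriage,
)

# relative tolerance for "as extreme as observed" probability comparisons
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Table2x2:
    """Carriage-by-outcome counts: (carrier, non-carrier) x (case, control)."""

    n11: int  # carrier cases
    n10: int  # non-carrier cases
    n01: int  # carrier controls
    n00: int  # non-carrier controls

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def freq_case(self) -> float:
        den = self.n11 + self.n10
        return self.n11 / den if den else float("nan")

    @property
    def freq_control(self) -> float:
        den = self.n01 + self.n00
        return self.n01 / den if den else float("nan")

    def swapped_rows(self) -> "Table2x2":
        return Table2x2(self.n10, self.n11, self.n00, self.n01)


@dataclass(frozen=True)
class OddsRatioResult:
    OR: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool = False


@dataclass(frozen=True)
class HweResult:
    p: float
    method: str
    monomorphic: bool = False


@dataclass(frozen=True)
class LDResult:
    D: float
    Dprime: float
    LOD: float
    linkage_class: str  # 'weak' (LOD <= 2) or 'moderate' (LOD > 2)
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)


# ---------------------------------------------------------------------------
# Fisher's exact test


@lru_cache(maxsize=200_000)
def _fisher_p(n11: int, row1: int, col1: int, n: int) -> float:
    """Two-sided Fisher p for a 2x2 table given margins, probability ordering."""
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(row1 + 1) - gammaln(ks + 1) - gammaln(row1 - ks + 1)
        + gammaln(n - row1 + 1) - gammaln(col1 - ks + 1) - gammaln(n - row1 - col1 + ks + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[n11 - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()))


def fisher_exact_2x2(table: Table2x2) -> float:
    """Two-sided exact Fisher p-value of the carriage-by-outcome table."""
    if table.total == 0:
        raise ValueError("all-zero 2x2 table")
    return _fisher_p(table.n11, table.n11 + table.n01, table.n11 + table.n10, table.total)


# ---------------------------------------------------------------------------
# odds ratio with Woolf CI


def odds_ratio(table: Table2x2, alpha: float = 0.05, zero_correction: bool = True) -> OddsRatioResult:
    """Cross-product OR with Woolf (log-Wald) 1-alpha CI.

    If any cell is zero and ``zero_correction`` is on, 0.5 is added to all four
    cells (Haldane-Anscombe) before computing both the OR and its CI.
    """
    cells = np.array([table.n11, table.n10, table.n01, table.n00], dtype=float)
    corrected = False
    if zero_correction and (cells == 0).any():
        cells = cells + 0.5
        corrected = True
    n11, n10, n01, n00 = cells
    or_ = (n11 * n00) / (n10 * n01)
    se = np.sqrt((1.0 / cells).sum())
    z = norm.ppf(1.0 - alpha / 2.0)
    log_or = np.log(or_)
    return OddsRatioResult(
        OR=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        alpha=alpha,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> HweResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    The exact method conditions on the allele counts and sums the
    probabilities of heterozygote counts no more likely than the observed one;
    the chi-square method is the 1-df goodness-of-fit test.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("invalid genotype counts")
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        warnings.warn("monomorphic locus: HWE p set to 1", stacklevel=2)
        return HweResult(p=1.0, method=method, monomorphic=True)
    if method == "exact":
        # heterozygote count shares the parity of the minor-allele count
        rare = min(nA, na)
        hs = np.arange(rare % 2, rare + 1, 2)
        logpmf = (
            hs * np.log(2.0)
            + gammaln(n + 1)
            - gammaln((nA - hs) / 2 + 1)
            - gammaln(hs + 1)
            - gammaln((na - hs) / 2 + 1)
        )
        pmf = np.exp(logpmf - logpmf.max())
        pmf /= pmf.sum()
        p_obs = pmf[np.searchsorted(hs, n_Aa)]
        p = float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()))
        return HweResult(p=p, method="exact")
    if method == "chi-square":
        pA = nA / (2.0 * n)
        expected = n * np.array([pA**2, 2 * pA * (1 - pA), (1 - pA) ** 2])
        observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
        stat = ((observed - expected) ** 2 / expected).sum()
        from scipy.stats import chi2

        return HweResult(p=float(chi2.sf(stat, df=1)), method="chi-square")
    raise ValueError(f"unknown HWE method {method!r}")


def hwe_scan(dataset: GenotypeDataset, group: str = "all", method: str = "exact") -> dict[str, HweResult]:
    """HWE per locus, on 'all' samples, 'case' or 'control' subsets."""
    mask = {
        "all": np.ones(dataset.n_samples, bool),
        "case": dataset.phenotype == 1,
        "control": dataset.phenotype == 0,
    }[group]
    out = {}
    for loc in dataset.loci:
        a, b = loc.alleles
        col = dataset.locus_column(loc.id)[mask]
        counts = {"AA": 0, "Aa": 0, "aa": 0}
        for g in col:
            if g is None:
                continue
            key = {a + a: "AA", "".join(sorted(a + b)): "Aa", b + b: "aa"}[g]
            counts[key] += 1
        if sum(counts.values()) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[loc.id] = hwe_test(counts["AA"], counts["Aa"], counts["aa"], method=method)
    return out


# ---------------------------------------------------------------------------
# two-locus LD: EM haplotype frequencies, D' and LOD


def _two_locus_genotype_counts(dataset: GenotypeDataset, locusA: str, locusB: str) -> np.ndarray:
    """3x3 counts of (copies of A-locus first allele) x (copies of B-locus first allele)."""
    la, lb = dataset.locus(locusA), dataset.locus(locusB)
    ca, cb = dataset.locus_column(locusA), dataset.locus_column(locusB)
    counts = np.zeros((3, 3), dtype=int)
    for ga, gb in zip(ca, cb):
        if ga is None or gb is None:
            continue
        ia = ga.count(la.alleles[0])
        ib = gb.count(lb.alleles[0])
        counts[ia, ib] += 1
    return counts


def _ld_loglik(counts: np.ndarray, hap: np.ndarray) -> float:
    """Multinomial log-likelihood of 3x3 genotype counts under random mating.

    hap = (p_AB, p_Ab, p_aB, p_ab) indexed by (first-allele at A, first-allele at B):
    index 0 <-> carries the first allele.  Genotype (i, j) = i copies of A1, j of B1.
    """
    pAB, pAb, paB, pab = hap
    P = np.empty((3, 3))
    P[2, 2] = pAB**2
    P[2, 1] = 2 * pAB * pAb
    P[2, 0] = pAb**2
    P[1, 2] = 2 * pAB * paB
    P[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    P[1, 0] = 2 * pAb * pab
    P[0, 2] = paB**2
    P[0, 1] = 2 * paB * pab
    P[0, 0] = pab**2
    with np.errstate(divide="ignore"):
        logP = np.log(P)
    mask = counts > 0
    return float((counts[mask] * logP[mask]).sum())


def ld_pair(
    dataset: GenotypeDataset,
    locusA: str,
    locusB: str,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Pairwise linkage disequilibrium: D, |D'| and LOD via EM haplotype frequencies.

    EM resolves double-heterozygote phase ambiguity starting from linkage
    equilibrium; LOD is the log10 likelihood ratio of the EM optimum against
    independent loci.  ``linkage_class`` is 'moderate' iff LOD > 2.
    """
    counts = _two_locus_genotype_counts(dataset, locusA, locusB)
    n = counts.sum()
    if n < 2:
        raise ValueError("need >=2 samples with complete genotypes at both loci")
    nA1 = (counts * np.arange(3)[:, None]).sum()
    nB1 = (counts * np.arange(3)[None, :]).sum()
    pA = nA1 / (2.0 * n)
    pB = nB1 / (2.0 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus in LD computation")

    # EM over the double-heterozygote cell
    pAB = pA * pB
    n_dh = counts[1, 1]
    ll_prev = -np.inf
    for _ in range(max_iter):
        pAb = pA - pAB
        paB = pB - pAB
        pab = 1.0 - pA - pB + pAB
        # expected coupling (AB/ab) share of double heterozygotes
        denom = pAB * pab + pAb * paB
        coupling = n_dh * (pAB * pab / denom) if denom > 0 else 0.0
        nAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + coupling
        pAB_new = nAB / (2.0 * n)
        # clamp into the feasible simplex
        pAB_new = min(max(pAB_new, max(0.0, pA + pB - 1.0) + 1e-15), min(pA, pB) - 1e-15)
        pAB = pAB_new
        ll = _ld_loglik(counts, np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB]))
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll

    hap = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    ll_mle = _ld_loglik(counts, hap)
    ll_indep = _ld_loglik(
        counts, np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    )
    lod = max(0.0, (ll_mle - ll_indep) / np.log(10.0))
    return LDResult(
        D=float(D),
        Dprime=float(min(1.0, dprime)),
        LOD=float(lod),
        linkage_class="moderate" if lod > 2 else "weak",
        hap_freqs=tuple(float(x) for x in hap),
    )


def ld_scan(dataset: GenotypeDataset) -> dict[tuple[str, str], LDResult]:
    """LD for every locus pair; monomorphic pairs are skipped with a warning."""
    out = {}
    ids = [l.id for l in dataset.loci]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            try:
                out[(ids[i], ids[j])] = ld_pair(dataset, ids[i], ids[j])
            except ValueError as exc:
                warnings.warn(f"LD {ids[i]}/{ids[j]} skipped: {exc}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# association records and the single-variant scan


@dataclass(frozen=True)
class SignificanceGates:
    """The reporting gates: CI excluding 1, p_f < 0.01 and p_perm < 0.05."""

    p_f: float = 0.01
    p_perm: float = 0.05
    require_ci_excludes_1: bool = True
    alpha: float = 0.05


@dataclass
class AssociationRecord:
    """One tested carriage pattern with its association statistics."""

    pattern: CarriagePattern
    table: Table2x2
    or_result: OddsRatioResult
    p_f: float
    p_perm: float | None = None
    minimal: bool | None = None
    degenerate: bool = False

    @property
    def freq_case(self) -> float:
        return self.table.freq_case

    @property
    def freq_control(self) -> float:
        return self.table.freq_control

    def ci_excludes_1(self) -> bool:
        return self.or_result.ci_low > 1.0 or self.or_result.ci_high < 1.0

    def significant(self, gates: SignificanceGates = SignificanceGates()) -> bool:
        ok = self.p_f < gates.p_f and not self.degenerate
        if gates.require_ci_excludes_1:
            ok = ok and self.ci_excludes_1()
        if self.p_perm is not None:
            ok = ok and self.p_perm < gates.p_perm
        return ok


def table_from_carriage(carriage: np.ndarray, phenotype: np.ndarray) -> Table2x2:
    """2x2 counts from a 0/1/NaN carriage vector, missing excluded pairwise."""
    ok = ~np.isnan(carriage)
    c = carriage[ok].astype(bool)
    y = phenotype[ok].astype(bool)
    return Table2x2(
        n11=int((c & y).sum()),
        n10=int((~c & y).sum()),
        n01=int((c & ~y).sum()),
        n00=int((~c & ~y).sum()),
    )


def evaluate_element(dataset: GenotypeDataset, element: PatternElement, alpha: float = 0.05) -> AssociationRecord:
    return evaluate_pattern_record(dataset, CarriagePattern.of(element), alpha=alpha)


def evaluate_pattern_record(
    dataset: GenotypeDataset, pattern: CarriagePattern, alpha: float = 0.05
) -> AssociationRecord:
    """Build the 2x2 table and statistics for one carriage pattern."""
    carriage = pattern_carriage(dataset, pattern)
    table = table_from_carriage(carriage, dataset.phenotype)
    if table.total == 0:
        raise ValueError(f"pattern {pattern.label}: zero complete-case samples")
    n_carrier = table.n11 + table.n01
    degenerate = n_carrier == 0 or n_carrier == table.total
    p_f = 1.0 if degenerate else fisher_exact_2x2(table)
    return AssociationRecord(
        pattern=pattern,
        table=table,
        or_result=odds_ratio(table, alpha=alpha),
        p_f=p_f,
        degenerate=degenerate,
    )


def locus_elements(locus) -> list[PatternElement]:
    """The testable elements of a biallelic locus: 2 dominant + 2 recessive."""
    a, b = locus.alleles
    return [
        PatternElement(locus.id, DOMINANT, a),
        PatternElement(locus.id, DOMINANT, b),
        PatternElement(locus.id, RECESSIVE, a),
        PatternElement(locus.id, RECESSIVE, b),
    ]


def single_variant_scan(
    dataset: GenotypeDataset,
    gates: SignificanceGates = SignificanceGates(),
) -> list[AssociationRecord]:
    """Evaluate dominant carriage of each allele and each recessive homozygote.

    Monomorphic loci (one observed allele) are skipped with a warning.
    """
    if dataset.n_case == 0 or dataset.n_control == 0:
        raise ValueError("need at least one case and one control")
    records: list[AssociationRecord] = []
    for loc in dataset.loci:
        observed: set[str] = set()
        for g in dataset.locus_column(loc.id):
            if g is not None:
                observed |= set(g)
        if len(observed) < 2:
            warnings.warn(f"monomorphic locus {loc.id} skipped", stacklevel=2)
            continue
        for element in locus_elements(loc):
            records.append(evaluate_element(dataset, element, alpha=gates.alpha))
    return records
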