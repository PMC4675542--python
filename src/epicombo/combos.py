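"""Bounded exhaustive mining of allelic-combination patterns.

For a panel of a few dozen biallelic SNPs the space of carriage conjunctions
up to order 2-3 is tiny, so patterns are enumerated exhaustively (in
deterministic lexicographic order) and each is scored with the same 2x2
statistics as single variants.  Two post-processing steps mirror the
reporting conventions of allelic-combination studies:

* the *minimality filter* keeps a multi-locus combination only if its Fisher
  p-value is strictly better than that of every sub-combination obtained by
  dropping one element;
* the *permutation adjustment* re-runs the whole search on phenotype-shuffled
  data and compares each observed p_f against the family-wise minimum p per
  permutation (the conservative reading of "same result from randomized data
  of the same dimension"), with the add-one estimator
  p_perm = (1 + #{min-p <= p_obs}) / (1 + R).

Carriage does not depend on phenotype, so each pattern's carrier column is
computed once; a permutation only moves case labels, i.e. only the
carrier-case cell of each 2x2 table changes when data are complete.  Fisher
p-values are memoized on the table margins, which makes hundreds of
permutations over hundreds of patterns cheap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import replace

import numpy as np

from .assoc import (
    AssociationRecord,
    SignificanceGates,
    Table2x2,
    _fisher_p,
    evaluate_pattern_record,
    fisher_exact_2x2,
    locus_elements,
    odds_ratio,
    table_from_carriage,
)
from .io import CarriagePattern, GenotypeDataset, pattern_carriage


def enumerate_patterns(dataset: GenotypeDataset, max_order: int = 2) -> list[CarriagePattern]:
    """All element conjunctions over distinct loci up to ``max_order``.

    Each biallelic locus contributes 4 elements (2 dominant carriages, 2
    recessive homozygotes); order is lexicographic in (order, element labels).
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if max_order > len(dataset.loci):
        warnings.warn(
            f"max_order {max_order} exceeds locus count {len(dataset.loci)}; truncated",
            stacklevel=2,
        )
        max_order = len(dataset.loci)
    per_locus = [locus_elements(loc) for loc in dataset.loci]
    patterns: list[CarriagePattern] = []
    for order in range(1, max_order + 1):
        block = []
        for locus_combo in itertools.combinations(per_locus, order):
            for elements in itertools.product(*locus_combo):
                block.append(CarriagePattern(frozenset(elements)))
        block.sort(key=lambda p: p.label)
        patterns.extend(block)
    return patterns


def evaluate_pattern(
    dataset: GenotypeDataset, pattern: CarriagePattern, alpha: float = 0.05
) -> AssociationRecord:
    """Score one pattern: conjunction carriage, 2x2 table, OR+CI, Fisher p."""
    return evaluate_pattern_record(dataset, pattern, alpha=alpha)


def evaluate_all(
    dataset: GenotypeDataset, patterns: list[CarriagePattern], alpha: float = 0.05
) -> list[AssociationRecord]:
    return [evaluate_pattern(dataset, p, alpha=alpha) for p in patterns]


def minimality_filter(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Keep combinations strictly more significant than all their sub-patterns.

    Order-1 records pass unchanged (flagged minimal).  A multi-element record
    survives iff its p_f is strictly smaller than the p_f of every pattern
    obtained by removing one element; ties are removed.
    """
    by_pattern = {r.pattern: r for r in records}
    out: list[AssociationRecord] = []
    for rec in records:
        if rec.pattern.order == 1:
            out.append(replace(rec, minimal=True))
            continue
        keep = True
        for sub in rec.pattern.subpatterns():
            if sub not in by_pattern:
                raise ValueError(
                    f"missing sub-pattern record {sub.label} for {rec.pattern.label}"
                )
            if not rec.p_f < by_pattern[sub].p_f:
                keep = False
                break
        if keep:
            out.append(replace(rec, minimal=True))
    return out


def permutation_adjust(
    dataset: GenotypeDataset,
    records: list[AssociationRecord],
    R: int = 100,
    seed: int | np.random.Generator = 0,
    scope: str = "family",
) -> list[AssociationRecord]:
    """Attach permutation p-values by re-running the search on shuffled labels.

    ``scope='family'`` (default): the null statistic per permutation is the
    minimum p_f over *all* patterns, so p_perm controls the family-wise error
    of the whole mining run.  ``scope='per_pattern'`` compares each pattern
    only against its own permuted p-values.  Both use the add-one estimator,
    so R=0 yields p_perm = 1 everywhere.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    if scope not in ("family", "per_pattern"):
        raise ValueError(f"unknown permutation scope {scope!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if R == 0:
        return [replace(r, p_perm=1.0) for r in records]

    patterns = [r.pattern for r in records]
    # carriage is label-free: precompute once
    carriage = np.stack([pattern_carriage(dataset, p) for p in patterns])  # (P, n)
    complete = (~np.isnan(carriage)).astype(np.int64)
    carrier = (np.nan_to_num(carriage) > 0).astype(np.int64)
    n_complete = complete.sum(axis=1)
    n_carrier = carrier.sum(axis=1)
    y = dataset.phenotype.astype(np.int64)

    P = len(patterns)
    obs_p = np.array([r.p_f for r in records])
    perm_p = np.empty((R, P))
    for r_i in range(R):
        perm = rng.permutation(y)
        n11 = carrier @ perm  # carrier cases per pattern
        ncase = complete @ perm  # cases among complete-case samples
        for j in range(P):
            if n_carrier[j] == 0 or n_carrier[j] == n_complete[j]:
                perm_p[r_i, j] = 1.0
            else:
                perm_p[r_i, j] = _fisher_p(
                    int(n11[j]), int(n_carrier[j]), int(ncase[j]), int(n_complete[j])
                )
    out = []
    if scope == "family":
        min_p = perm_p.min(axis=1)  # (R,)
        for j, rec in enumerate(records):
            hits = int((min_p <= obs_p[j]).sum())
            out.append(replace(rec, p_perm=(1 + hits) / (1 + R)))
    else:
        for j, rec in enumerate(records):
            hits = int((perm_p[:, j] <= obs_p[j]).sum())
            out.append(replace(rec, p_perm=(1 + hits) / (1 + R)))
    return out


def mine_combinations(
    dataset: GenotypeDataset,
    max_order: int = 2,
    R: int = 100,
    seed: int | np.random.Generator = 0,
    gates: SignificanceGates = SignificanceGates(),
    scope: str = "family",
) -> list[AssociationRecord]:
    """Full mining run: enumerate, score, permutation-adjust, minimality-filter.

    Returns every record (not only significant ones) with ``p_perm`` and
    ``minimal`` populated; callers apply ``rec.significant(gates)`` to gate.
    """
    patterns = enumerate_patterns(dataset, max_order=max_order)
    records = evaluate_all(dataset, patterns, alpha=gates.alpha)
    records = permutation_adjust(dataset, records, R=R, seed=seed, scope=scope)
    minimal = {r.pattern for r in minimality_filter(records)}
    return [replace(r, minimal=r.pattern in minimal) for r in records]
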