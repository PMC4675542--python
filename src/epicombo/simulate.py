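"""Synthetic case-control cohort generator with plantable effects.

The generator emulates the structure a candidate-gene case-control panel is
assumed to have: biallelic SNP genotypes in Hardy-Weinberg proportions
(optionally with pairwise LD via haplotype-pair sampling), a logistic
disease model on *carriage indicators*,

    logit P(case) = intercept + sum_j beta_j x_j + sum_pairs gamma x_a x_b
                    + beta_sex male + interaction terms,

and case-control ascertainment by rejection sampling until exactly n_case
cases and n_control controls are collected.  Because the planted truth is
conditional (stratum-specific) odds ratios, the synergy factor of a planted
pair is exactly exp(gamma) and each marker's conditional OR is exp(beta),
which makes parameter recovery testable in closed form; marginal (collapsed)
odds ratios are derived quantities, computed here by exact summation over the
carriage strata.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.optimize import brentq

from .io import DOMINANT, RECESSIVE, GenotypeDataset, Locus, PatternElement


@dataclass(frozen=True)
class SimLocus:
    """One simulated biallelic locus and its planted main effect."""

    id: str
    freq: float  # population frequency of the risk allele
    mode: str = DOMINANT  # carriage model of the effect element
    beta: float = 0.0  # conditional log-OR of carriage
    risk_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 < self.freq < 1.0:
            raise ValueError(f"locus {self.id}: risk-allele frequency must be in (0,1)")
        if self.mode not in (DOMINANT, RECESSIVE):
            raise ValueError(f"locus {self.id}: unknown mode {self.mode!r}")

    @property
    def carriage_prob(self) -> float:
        """Population carriage frequency under Hardy-Weinberg proportions."""
        f = self.freq
        return 1.0 - (1.0 - f) ** 2 if self.mode == DOMINANT else f**2

    @property
    def element(self) -> PatternElement:
        return PatternElement(self.id, self.mode, self.risk_allele)


@dataclass(frozen=True)
class EpistaticPair:
    locus_a: str
    locus_b: str
    gamma: float  # interaction log-OR; SF_true = exp(gamma)


@dataclass(frozen=True)
class LDPair:
    locus_a: str
    locus_b: str
    dprime: float  # planted |D'| between the two risk alleles (coupling)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dprime <= 1.0:
            raise ValueError("D' must be in [0, 1]")


@dataclass
class SimConfig:
    loci: list[SimLocus]
    n_case: int = 325
    n_control: int = 185
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    ld_pairs: list[LDPair] = field(default_factory=list)
    intercept: float | None = None  # None -> solved so that prevalence == `prevalence`
    prevalence: float = 0.1
    sex_effect: float = 0.0  # log-OR of being male
    sex_interactions: list[tuple[str, float]] = field(default_factory=list)  # (locus, extra male log-OR)
    male_frac: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("n_case and n_control must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        known = set(ids)
        for p in self.epistatic_pairs:
            if p.locus_a not in known or p.locus_b not in known:
                raise ValueError(f"epistatic pair references unknown locus: {p}")
        in_ld: set[str] = set()
        for p in self.ld_pairs:
            if p.locus_a not in known or p.locus_b not in known:
                raise ValueError(f"LD pair references unknown locus: {p}")
            if p.locus_a in in_ld or p.locus_b in in_ld:
                raise ValueError("a locus may appear in at most one LD pair")
            in_ld |= {p.locus_a, p.locus_b}

    def locus(self, lid: str) -> SimLocus:
        return next(l for l in self.loci if l.id == lid)

    def config_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(config_to_dict(self)).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# carriage strata: exact joint distribution of the carriage vector


def _hap_freqs(fa: float, fb: float, dprime: float) -> np.ndarray:
    """Two-locus haplotype frequencies (risk-allele coupling) at given |D'|."""
    dmax = min(fa * (1 - fb), (1 - fa) * fb)
    d = dprime * dmax
    return np.array(
        [fa * fb + d, fa * (1 - fb) - d, (1 - fa) * fb - d, (1 - fa) * (1 - fb) + d]
    )


def _pair_carriage_joint(la: SimLocus, lb: SimLocus, dprime: float) -> np.ndarray:
    """Joint P(x_a, x_b) for an LD pair under random union of haplotypes."""
    hap = _hap_freqs(la.freq, lb.freq, dprime)
    # allele-count pair per haplotype: (a, b) in {(1,1), (1,0), (0,1), (0,0)}
    counts = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])
    joint = np.zeros((2, 2))
    for i, pi in enumerate(hap):
        for j, pj in enumerate(hap):
            ca = counts[i, 0] + counts[j, 0]
            cb = counts[i, 1] + counts[j, 1]
            xa = int(ca >= 1) if la.mode == DOMINANT else int(ca == 2)
            xb = int(cb >= 1) if lb.mode == DOMINANT else int(cb == 2)
            joint[xa, xb] += pi * pj
    return joint


def carriage_strata(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the joint distribution of the carriage vector.

    Returns (probs, X): stratum probabilities and the (n_strata, n_loci) 0/1
    carriage matrix, loci in config order.  Loci are independent except within
    declared LD pairs.
    """
    ids = [l.id for l in config.loci]
    blocks: list[tuple[list[int], np.ndarray, np.ndarray]] = []  # (col idx, probs, states)
    paired = {p.locus_a: p for p in config.ld_pairs} | {p.locus_b: p for p in config.ld_pairs}
    done: set[str] = set()
    for j, loc in enumerate(config.loci):
        if loc.id in done:
            continue
        if loc.id in paired:
            pair = paired[loc.id]
            la, lb = config.locus(pair.locus_a), config.locus(pair.locus_b)
            joint = _pair_carriage_joint(la, lb, pair.dprime)
            states = np.array([(a, b) for a in (0, 1) for b in (0, 1)])
            probs = np.array([joint[a, b] for a, b in states])
            blocks.append(([ids.index(la.id), ids.index(lb.id)], probs, states))
            done |= {la.id, lb.id}
        else:
            c = loc.carriage_prob
            blocks.append(([j], np.array([1 - c, c]), np.array([[0], [1]])))
            done.add(loc.id)
    probs = np.array([1.0])
    X = np.zeros((1, len(ids)), dtype=int)
    for cols, bp, bs in blocks:
        probs = (probs[:, None] * bp[None, :]).ravel()
        X = np.repeat(X, len(bp), axis=0)
        tiled = np.tile(bs, (len(X) // len(bs), 1))
        X[:, cols] = tiled
    return probs, X


def _linear_predictor(config: SimConfig, X: np.ndarray, male: np.ndarray, intercept: float) -> np.ndarray:
    ids = [l.id for l in config.loci]
    lp = np.full(len(X), intercept, dtype=float)
    for j, loc in enumerate(config.loci):
        lp += loc.beta * X[:, j]
    for p in config.epistatic_pairs:
        lp += p.gamma * X[:, ids.index(p.locus_a)] * X[:, ids.index(p.locus_b)]
    lp += config.sex_effect * male
    for lid, extra in config.sex_interactions:
        lp += extra * X[:, ids.index(lid)] * male
    return lp


def solve_intercept(config: SimConfig) -> float:
    """Intercept achieving the configured population prevalence (exact strata sum)."""
    if config.intercept is not None:
        return config.intercept
    probs, X = carriage_strata(config)
    pm = config.male_frac

    def prevalence(b0: float) -> float:
        pM = 1.0 / (1.0 + np.exp(-_linear_predictor(config, X, np.ones(len(X)), b0)))
        pF = 1.0 / (1.0 + np.exp(-_linear_predictor(config, X, np.zeros(len(X)), b0)))
        return float((probs * (pm * pM + (1 - pm) * pF)).sum())

    return float(brentq(lambda b: prevalence(b) - config.prevalence, -30.0, 10.0))


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(config: SimConfig, seed: int | None = None) -> GenotypeDataset:
    """Draw a case-control cohort from the configured population model.

    Rejection sampling: population subjects are generated in vectorized
    batches and kept while the case and control quotas are unfilled; the run
    errors out after a bounded number of batches if the configured prevalence
    makes a quota unattainable.  Fully reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    b0 = solve_intercept(config)
    ids = [l.id for l in config.loci]
    paired = {(p.locus_a, p.locus_b): p for p in config.ld_pairs}
    in_ld = {l for ab in paired for l in ab}

    need_case, need_ctrl = config.n_case, config.n_control
    kept_counts: list[np.ndarray] = []
    kept_male: list[np.ndarray] = []
    kept_case: list[np.ndarray] = []
    approx_prev = max(config.prevalence, 1e-3)
    batch = int(max(2000, 1.5 * need_case / approx_prev, 1.5 * need_ctrl))
    for _attempt in range(60):
        if need_case <= 0 and need_ctrl <= 0:
            break
        m = batch
        counts = np.empty((m, len(ids)), dtype=np.int8)
        for (a_id, b_id), p in paired.items():
            la, lb = config.locus(a_id), config.locus(b_id)
            hap = _hap_freqs(la.freq, lb.freq, p.dprime)
            hap_counts = np.array([(1, 1), (1, 0), (0, 1), (0, 0)], dtype=np.int8)
            h1 = rng.choice(4, size=m, p=hap)
            h2 = rng.choice(4, size=m, p=hap)
            counts[:, ids.index(a_id)] = hap_counts[h1, 0] + hap_counts[h2, 0]
            counts[:, ids.index(b_id)] = hap_counts[h1, 1] + hap_counts[h2, 1]
        for j, loc in enumerate(config.loci):
            if loc.id not in in_ld:
                counts[:, j] = rng.binomial(2, loc.freq, size=m)
        X = np.empty((m, len(ids)), dtype=np.int8)
        for j, loc in enumerate(config.loci):
            X[:, j] = (counts[:, j] >= 1) if loc.mode == DOMINANT else (counts[:, j] == 2)
        male = (rng.random(m) < config.male_frac).astype(np.int8)
        p_case = 1.0 / (1.0 + np.exp(-_linear_predictor(config, X, male, b0)))
        is_case = rng.random(m) < p_case
        take = np.zeros(m, dtype=bool)
        case_idx = np.flatnonzero(is_case)[:max(0, need_case)]
        ctrl_idx = np.flatnonzero(~is_case)[:max(0, need_ctrl)]
        take[case_idx] = True
        take[ctrl_idx] = True
        need_case -= len(case_idx)
        need_ctrl -= len(ctrl_idx)
        kept_counts.append(counts[take])
        kept_male.append(male[take])
        kept_case.append(is_case[take])
    if need_case > 0 or need_ctrl > 0:
        raise RuntimeError(
            f"could not fill quotas after bounded attempts (missing {max(need_case,0)} "
            f"cases, {max(need_ctrl,0)} controls); prevalence too extreme?"
        )

    counts = np.concatenate(kept_counts)
    male = np.concatenate(kept_male)
    is_case = np.concatenate(kept_case)
    n = len(counts)
    geno = np.empty((n, len(ids)), dtype=object)
    for j, loc in enumerate(config.loci):
        g = ["".join(sorted(loc.other_allele * 2)),
             "".join(sorted(loc.other_allele + loc.risk_allele)),
             "".join(sorted(loc.risk_allele * 2))]
        col = np.array(g, dtype=object)[counts[:, j].astype(int)]
        geno[:, j] = col
    if config.missing_rate > 0:
        mask = rng.random((n, len(ids))) < config.missing_rate
        geno[mask] = None
    loci = [Locus(l.id, tuple(sorted((l.risk_allele, l.other_allele)))) for l in config.loci]
    return GenotypeDataset(
        samples=[f"s{i + 1:05d}" for i in range(n)],
        phenotype=is_case.astype(np.int8),
        sex=np.array(["M" if m_ else "F" for m_ in male], dtype=object),
        loci=loci,
        genotypes=geno,
    )


# ---------------------------------------------------------------------------
# analytic effect sizes (recovery oracles)


def analytic_effects(config: SimConfig) -> dict:
    """Closed-form planted effects plus exact collapsed (marginal) odds ratios.

    Conditional odds ratios are exp(beta) per marker and, for each epistatic
    pair, OR_11 = exp(beta_a + beta_b + gamma) relative to the
    double-non-carrier baseline, hence SF_true = exp(gamma).  Marginal ORs
    collapse the exact population strata (they differ from the conditional
    ones whenever other causes of the outcome vary across strata).
    """
    b0 = solve_intercept(config)
    probs, X = carriage_strata(config)
    pm = config.male_frac
    pM = 1.0 / (1.0 + np.exp(-_linear_predictor(config, X, np.ones(len(X)), b0)))
    pF = 1.0 / (1.0 + np.exp(-_linear_predictor(config, X, np.zeros(len(X)), b0)))
    p_case = pm * pM + (1 - pm) * pF

    def marginal_or(indicator: np.ndarray) -> float:
        w1 = probs[indicator == 1]
        w0 = probs[indicator == 0]
        p1 = float((w1 * p_case[indicator == 1]).sum() / w1.sum())
        p0 = float((w0 * p_case[indicator == 0]).sum() / w0.sum())
        return (p1 / (1 - p1)) / (p0 / (1 - p0))

    ids = [l.id for l in config.loci]
    out: dict = {"conditional_or": {}, "marginal_or": {}, "sf_true": {}, "pair_marginal_or": {}}
    for j, loc in enumerate(config.loci):
        out["conditional_or"][loc.id] = math.exp(loc.beta)
        out["marginal_or"][loc.id] = marginal_or(X[:, j])
    for p in config.epistatic_pairs:
        key = (p.locus_a, p.locus_b)
        out["sf_true"][key] = math.exp(p.gamma)
        joint = X[:, ids.index(p.locus_a)] * X[:, ids.index(p.locus_b)]
        out["pair_marginal_or"][key] = marginal_or(joint)
    return out


# ---------------------------------------------------------------------------
# presets and YAML round-trip


def paper_like_config(n_case: int = 325, n_control: int = 185, seed: int = 0) -> SimConfig:
    """A cohort shaped like a small inflammation/coagulation candidate panel.

    Three main-effect markers with control carriage frequencies near 0.32
    (recessive), 0.38 (dominant) and 0.04 (recessive) and conditional ORs
    1.84, 1.80 and 2.93, plus one epistatic dominant-carriage pair with weak
    main effects (OR 1.1 each), joint control carriage near 0.05, and
    SF_true = 5; prevalence 0.1, male case excess ln(2.5).
    """
    ln = math.log
    loci = [
        SimLocus("rsTGFB1", freq=math.sqrt(0.32), mode=RECESSIVE, beta=ln(1.84),
                 risk_allele="T", other_allele="C"),
        SimLocus("rsFGB", freq=1 - math.sqrt(1 - 0.38), mode=DOMINANT, beta=ln(1.80),
                 risk_allele="T", other_allele="C"),
        SimLocus("rsCRP", freq=math.sqrt(0.04), mode=RECESSIVE, beta=ln(2.93),
                 risk_allele="T", other_allele="C"),
        SimLocus("rsIFNG", freq=1 - math.sqrt(1 - 0.72), mode=DOMINANT, beta=ln(1.1),
                 risk_allele="A", other_allele="T"),
        SimLocus("rsPTGS1", freq=1 - math.sqrt(1 - 0.07), mode=DOMINANT, beta=ln(1.1),
                 risk_allele="T", other_allele="C"),
    ]
    return SimConfig(
        loci=loci,
        epistatic_pairs=[EpistaticPair("rsIFNG", "rsPTGS1", gamma=ln(5.0))],
        n_case=n_case,
        n_control=n_control,
        prevalence=0.1,
        sex_effect=ln(2.5),
        seed=seed,
    )


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["sex_interactions"] = [list(t) for t in config.sex_interactions]
    return d


def config_to_yaml(config: SimConfig) -> str:
    return yaml.safe_dump(config_to_dict(config), sort_keys=False)


def config_from_yaml(text: str) -> SimConfig:
    d = yaml.safe_load(text)
    d["loci"] = [SimLocus(**l) for l in d["loci"]]
    d["epistatic_pairs"] = [EpistaticPair(**p) for p in d.get("epistatic_pairs", [])]
    d["ld_pairs"] = [LDPair(**p) for p in d.get("ld_pairs", [])]
    d["sex_interactions"] = [tuple(t) for t in d.get("sex_interactions", [])]
    return SimConfig(**d)
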