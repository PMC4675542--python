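"""Subject-level genotype data model and file I/O.

The native on-disk dialect is a UTF-8, tab-separated table with one row per
subject::

    sample_id  phenotype  sex  rs1982073  rs1800788 ...
    s1         1          M    TT         CT
    s2         0          F    CT         NN

``phenotype`` is 1 for cases and 0 for controls; ``sex`` is ``M``/``F`` or
``NA``; genotypes are unordered two-character allele pairs (``CT`` == ``TC``),
with ``NN`` or ``--`` marking a missing call.  Restricted PED/MAP and
biallelic-SNP VCF readers are provided for interchange.

Association units are *carriage patterns*: conjunctions of per-locus elements,
each either dominant allele carriage (>=1 copy) or a recessive homozygote.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

MISSING_GENOTYPES = ("NN", "--")
MISSING_SEX = "NA"

DOMINANT = "dominant"
RECESSIVE = "recessive"


class GenotypeFormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


@dataclass(frozen=True)
class Locus:
    """A biallelic locus: an identifier and its two allele symbols."""

    id: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b:
            raise ValueError(f"locus {self.id}: alleles must be distinct, got {self.alleles}")


@dataclass(frozen=True)
class PatternElement:
    """One conjunct of a carriage pattern.

    ``mode == 'dominant'`` means carriage of >=1 copy of ``allele``;
    ``mode == 'recessive'`` means the ``allele`` homozygote.
    """

    locus_id: str
    mode: str
    allele: str

    def __post_init__(self) -> None:
        if self.mode not in (DOMINANT, RECESSIVE):
            raise ValueError(f"unknown carriage mode {self.mode!r}")

    @property
    def label(self) -> str:
        geno = self.allele if self.mode == DOMINANT else self.allele * 2
        return f"{self.locus_id}*{geno}"


@dataclass(frozen=True)
class CarriagePattern:
    """A conjunction of elements over distinct loci; order = len(elements)."""

    elements: frozenset[PatternElement]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern must contain at least one element")
        loci = [e.locus_id for e in self.elements]
        if len(set(loci)) != len(loci):
            raise ValueError("pattern elements must reference distinct loci")

    @classmethod
    def of(cls, *elements: PatternElement) -> "CarriagePattern":
        return cls(frozenset(elements))

    @property
    def order(self) -> int:
        return len(self.elements)

    @property
    def sorted_elements(self) -> tuple[PatternElement, ...]:
        return tuple(sorted(self.elements, key=lambda e: (e.locus_id, e.mode, e.allele)))

    @property
    def label(self) -> str:
        return "+".join(e.label for e in self.sorted_elements)

    def subpatterns(self) -> list["CarriagePattern"]:
        """All patterns obtained by removing exactly one element (order > 1)."""
        els = self.sorted_elements
        if len(els) == 1:
            return []
        return [CarriagePattern(frozenset(els[:i] + els[i + 1:])) for i in range(len(els))]


def canonical_genotype(g: str) -> str | None:
    """Canonicalize a two-character genotype; None for a missing code."""
    if g in MISSING_GENOTYPES:
        return None
    if len(g) != 2:
        raise GenotypeFormatError(f"genotype {g!r} is not two characters")
    return "".join(sorted(g))


@dataclass
class GenotypeDataset:
    """Subjects x biallelic loci with case/control phenotype and optional sex.

    ``genotypes`` is an (n_samples, n_loci) object array of canonicalized
    two-character strings, with ``None`` for missing calls.
    """

    samples: list[str]
    phenotype: np.ndarray
    sex: np.ndarray
    loci: list[Locus]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        n, m = len(self.samples), len(self.loci)
        if len(set(self.samples)) != n:
            raise GenotypeFormatError("duplicate sample ids")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length mismatch")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be strictly binary 0/1")
        if self.genotypes.shape != (n, m):
            raise ValueError(f"genotype matrix shape {self.genotypes.shape} != ({n}, {m})")
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != m:
            raise ValueError("duplicate locus ids")
        self._locus_index = {loc.id: j for j, loc in enumerate(self.loci)}
        for j, loc in enumerate(self.loci):
            ok = set(loc.alleles)
            for g in self.genotypes[:, j]:
                if g is not None and not set(g) <= ok:
                    raise GenotypeFormatError(
                        f"genotype {g!r} at locus {loc.id} uses alleles outside {loc.alleles}"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_case(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_control(self) -> int:
        return int((self.phenotype == 0).sum())

    def locus(self, locus_id: str) -> Locus:
        try:
            return self.loci[self._locus_index[locus_id]]
        except KeyError:
            raise KeyError(f"unknown locus {locus_id!r}") from None

    def locus_column(self, locus_id: str) -> np.ndarray:
        return self.genotypes[:, self._locus_index[locus_id]]

    def genotype_counts(self, locus_id: str) -> dict[str, int]:
        """Counts of the three genotype classes (hom-ref/het/hom-alt by symbol)."""
        col = self.locus_column(locus_id)
        out: dict[str, int] = {}
        for g in col:
            if g is not None:
                out[g] = out.get(g, 0) + 1
        return out

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.phenotype, other.phenotype)
            and list(self.sex) == list(other.sex)
            and self.loci == other.loci
            and self.genotypes.shape == other.genotypes.shape
            and all(
                a == b for a, b in zip(self.genotypes.ravel(), other.genotypes.ravel())
            )
        )


# ---------------------------------------------------------------------------
# carriage coding


def carriage_indicator(dataset: GenotypeDataset, element: PatternElement) -> np.ndarray:
    """Per-sample carriage of one element: 1.0 / 0.0 / NaN (missing genotype)."""
    locus = dataset.locus(element.locus_id)
    if element.allele not in locus.alleles:
        raise ValueError(
            f"allele {element.allele!r} not among {locus.alleles} at locus {locus.id}"
        )
    col = dataset.locus_column(element.locus_id)
    out = np.full(len(col), np.nan)
    for i, g in enumerate(col):
        if g is None:
            continue
        if element.mode == DOMINANT:
            out[i] = 1.0 if element.allele in g else 0.0
        else:
            out[i] = 1.0 if g == element.allele * 2 else 0.0
    return out


def pattern_carriage(dataset: GenotypeDataset, pattern: CarriagePattern) -> np.ndarray:
    """Conjunction (AND) of element indicators; NaN where any constituent is missing."""
    out = np.ones(dataset.n_samples)
    for element in pattern.sorted_elements:
        ind = carriage_indicator(dataset, element)
        out = out * ind  # NaN propagates
    return out


def reconstruct_counts(freq: float, n: int) -> int:
    """Carrier count implied by a printed frequency: round(freq*n), ties away from zero.

    Published tables report carriage frequencies to two decimals; this is the
    rule used to rebuild integer 2x2 tables from them.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if n <= 0:
        raise ValueError("group size must be positive")
    return int(math.floor(freq * n + 0.5))


# ---------------------------------------------------------------------------
# native TSV dialect


def read_genotype_table(stream: IO[str], dialect: str = "native", **kwargs) -> GenotypeDataset:
    """Read a genotype table. ``dialect`` is 'native', 'ped' or 'vcf'.

    'ped' requires ``map_stream=``; 'vcf' requires ``phenotype=`` (a mapping
    sample id -> 0/1) and accepts ``sex=`` (sample id -> M/F).
    """
    if dialect == "native":
        return read_native(stream)
    if dialect == "ped":
        return read_ped(stream, kwargs.pop("map_stream"))
    if dialect == "vcf":
        return read_vcf(stream, kwargs.pop("phenotype"), kwargs.pop("sex", None))
    raise ValueError(f"unknown dialect {dialect!r}")


def read_native(stream: IO[str]) -> GenotypeDataset:
    header = stream.readline().rstrip("\n")
    if not header:
        raise GenotypeFormatError("empty file: missing header")
    cols = header.split("\t")
    if cols[:3] != ["sample_id", "phenotype", "sex"]:
        raise GenotypeFormatError(
            "header must start with sample_id, phenotype, sex; got " + repr(cols[:3])
        )
    locus_ids = cols[3:]
    samples: list[str] = []
    phen: list[int] = []
    sex: list[str] = []
    rows: list[list[str | None]] = []
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise GenotypeFormatError(f"line {lineno}: expected {len(cols)} fields, got {len(fields)}")
        sid, ph, sx = fields[0], fields[1], fields[2]
        if ph not in ("0", "1"):
            raise GenotypeFormatError(f"line {lineno}: phenotype {ph!r} is not 0/1")
        if sx not in ("M", "F", MISSING_SEX):
            raise GenotypeFormatError(f"line {lineno}: sex {sx!r} is not M/F/NA")
        samples.append(sid)
        phen.append(int(ph))
        sex.append(sx)
        try:
            rows.append([canonical_genotype(g) for g in fields[3:]])
        except GenotypeFormatError as exc:
            raise GenotypeFormatError(f"line {lineno}: {exc}") from None
    return _assemble(samples, phen, sex, locus_ids, rows)


def _assemble(
    samples: list[str],
    phen: list[int],
    sex: list[str],
    locus_ids: list[str],
    rows: list[list[str | None]],
    declared_alleles: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeDataset:
    """Infer allele pairs per locus from the observed genotypes and validate."""
    n, m = len(samples), len(locus_ids)
    geno = np.empty((n, m), dtype=object)
    for i, row in enumerate(rows):
        geno[i, :] = row
    loci: list[Locus] = []
    for j, lid in enumerate(locus_ids):
        observed: set[str] = set()
        for g in geno[:, j]:
            if g is not None:
                observed |= set(g)
        if declared_alleles and lid in declared_alleles:
            alleles = declared_alleles[lid]
            if not observed <= set(alleles):
                raise GenotypeFormatError(
                    f"locus {lid}: observed alleles {sorted(observed)} exceed declared {alleles}"
                )
        else:
            if len(observed) > 2:
                raise GenotypeFormatError(
                    f"locus {lid}: >2 distinct alleles observed: {sorted(observed)}"
                )
            # pad monomorphic / all-missing loci with a placeholder second allele
            pads = [c for c in "ACGTN" if c not in observed]
            while len(observed) < 2:
                observed.add(pads.pop(0))
            alleles = tuple(sorted(observed))  # type: ignore[assignment]
        loci.append(Locus(lid, tuple(alleles)))
    return GenotypeDataset(samples, np.array(phen), np.array(sex, dtype=object), loci, geno)


def write_genotype_table(dataset: GenotypeDataset, stream: IO[str]) -> None:
    """Write the native dialect; read_native on the output is the identity."""
    stream.write("\t".join(["sample_id", "phenotype", "sex"] + [l.id for l in dataset.loci]) + "\n")
    for i, sid in enumerate(dataset.samples):
        gen = [
            g if g is not None else MISSING_GENOTYPES[0] for g in dataset.genotypes[i, :]
        ]
        stream.write(
            "\t".join([sid, str(int(dataset.phenotype[i])), str(dataset.sex[i])] + gen) + "\n"
        )


# ---------------------------------------------------------------------------
# PED/MAP subset


def read_ped(ped_stream: IO[str], map_stream: IO[str]) -> GenotypeDataset:
    """Restricted PED/MAP reader.

    PED: FID IID PAT MAT SEX PHEN then two allele columns per locus, '0' for a
    missing allele.  PHEN uses 1=control, 2=case.  MAP: chrom, locus id, cM, bp.
    """
    locus_ids = []
    for line in map_stream:
        parts = line.split()
        if len(parts) < 2:
            raise GenotypeFormatError(f"MAP line with <2 columns: {line!r}")
        locus_ids.append(parts[1])
    samples, phen, sex, rows = [], [], [], []
    for lineno, line in enumerate(ped_stream, start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6 + 2 * len(locus_ids):
            raise GenotypeFormatError(
                f"PED line {lineno}: expected {6 + 2 * len(locus_ids)} columns, got {len(parts)}"
            )
        samples.append(parts[1])
        ph = parts[5]
        if ph not in ("1", "2"):
            raise GenotypeFormatError(f"PED line {lineno}: phenotype {ph!r} not in 1/2")
        phen.append(0 if ph == "1" else 1)
        sex.append({"1": "M", "2": "F"}.get(parts[4], MISSING_SEX))
        row = []
        for j in range(len(locus_ids)):
            a, b = parts[6 + 2 * j], parts[7 + 2 * j]
            row.append(None if "0" in (a, b) else canonical_genotype(a + b))
        rows.append(row)
    return _assemble(samples, phen, sex, locus_ids, rows)


# ---------------------------------------------------------------------------
# VCF subset

_GT_RE = re.compile(r"([0-9.])[/|]([0-9.])")


def read_vcf(
    stream: IO[str],
    phenotype: Mapping[str, int],
    sex: Mapping[str, str] | None = None,
) -> GenotypeDataset:
    """Restricted VCF reader: biallelic SNP records with GT fields only.

    Phenotype (and optionally sex) come from side-channel mappings because VCF
    carries neither.  Phasing separators are ignored; the pipeline is phase-free.
    """
    samples: list[str] = []
    locus_ids: list[str] = []
    alleles_by_locus: dict[str, tuple[str, str]] = {}
    cols: list[list[str | None]] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            parts = line.split("\t")
            if len(parts) < 10:
                raise GenotypeFormatError("VCF has no sample columns")
            samples = parts[9:]
            continue
        if not samples:
            raise GenotypeFormatError("VCF data line before #CHROM header")
        parts = line.split("\t")
        chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
        if len(ref) != 1 or len(alt) != 1 or "," in alt:
            raise GenotypeFormatError(f"record {vid or chrom + ':' + pos}: not a biallelic SNP")
        lid = vid if vid not in (".", "") else f"{chrom}:{pos}"
        fmt = parts[8].split(":")
        if "GT" not in fmt:
            raise GenotypeFormatError(f"record {lid}: no GT field")
        gt_i = fmt.index("GT")
        col: list[str | None] = []
        for cell in parts[9:]:
            gt = cell.split(":")[gt_i]
            m = _GT_RE.fullmatch(gt)
            if m is None or "." in m.groups():
                col.append(None)
                continue
            a1 = ref if m.group(1) == "0" else alt
            a2 = ref if m.group(2) == "0" else alt
            col.append(canonical_genotype(a1 + a2))
        locus_ids.append(lid)
        alleles_by_locus[lid] = tuple(sorted((ref, alt)))  # type: ignore[assignment]
        cols.append(col)
    missing = [s for s in samples if s not in phenotype]
    if missing:
        raise GenotypeFormatError(f"no phenotype for samples {missing}")
    phen = [int(phenotype[s]) for s in samples]
    sx = [(sex or {}).get(s, MISSING_SEX) for s in samples]
    rows = [[cols[j][i] for j in range(len(locus_ids))] for i in range(len(samples))]
    return _assemble(samples, phen, sx, locus_ids, rows, declared_alleles=alleles_by_locus)
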