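"""Allele/genotype search space and expected peak patterns.

An allele is an (m, n) pair: m TG dinucleotide repeats followed by an
n-thymine homopolymer, total tract length 2m + n.  A genotype is an
unordered pair of alleles.  Expected peak patterns superpose the two
allele sequences with *dual alignment*: left-aligned (5') for the forward
chromatogram, right-aligned (3') for the reverse — both alleles share the
primer-proximal sequence, so their tracts coincide at the end nearest the
sequencing primer and drift out of register at the far end.

Per-position expected base sets are {T}, {G} or {T,G}; positions beyond
the shorter allele carry only the longer allele's base (flanking-sequence
contamination there is diluted signal, not modeled as expectation).
Expected relative intensities follow directly: 1/0 for a single base,
0.5/0.5 when both are expected.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySpaceError

# expected-set codes used throughout the scoring engine
SET_T, SET_G, SET_TG, SET_NONE = 0, 1, 2, 3
_CODE_FROM_SET = {frozenset("T"): SET_T, frozenset("G"): SET_G, frozenset("TG"): SET_TG}

# expected (ET, EG) per set code; "no base expected" contributes zeros
ET_OF_CODE = np.array([1.0, 0.0, 0.5, 0.0])
EG_OF_CODE = np.array([0.0, 1.0, 0.5, 0.0])

_ALLELE_RE = re.compile(r"\(TG\)(\d+)T(\d+)")


@dataclass(frozen=True, order=True)
class Allele:
    m: int  # TG dinucleotide repeat count
    n: int  # poly-T run length

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("allele requires m >= 1 and n >= 1")

    @property
    def length(self) -> int:
        return 2 * self.m + self.n

    @property
    def label(self) -> str:
        return f"(TG){self.m}T{self.n}"

    def sort_key(self):
        return (self.length, self.m)


def allele_sequence(a: Allele) -> str:
    """The tract base sequence, 'TG' * m + 'T' * n (length 2m + n)."""
    return "TG" * a.m + "T" * a.n


def parse_allele(text: str) -> Allele:
    match = _ALLELE_RE.fullmatch(text.strip())
    if not match:
        raise ValueError(f"cannot parse allele label {text!r}")
    return Allele(m=int(match.group(1)), n=int(match.group(2)))


@dataclass(frozen=True)
class Genotype:
    """Unordered allele pair in canonical order (ascending (2m+n, m))."""

    allele_a: Allele
    allele_b: Allele

    def __post_init__(self):
        a, b = self.allele_a, self.allele_b
        if a.sort_key() > b.sort_key():
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @property
    def label(self) -> str:
        return f"{self.allele_a.label}/{self.allele_b.label}"

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a == self.allele_b

    @property
    def max_length(self) -> int:
        return self.allele_b.length

    def sort_key(self):
        return (self.allele_a.sort_key() + (self.allele_a.n,),
                self.allele_b.sort_key() + (self.allele_b.n,))


def parse_genotype(text: str) -> Genotype:
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"genotype label needs two '/'-separated alleles: {text!r}")
    return Genotype(parse_allele(parts[0]), parse_allele(parts[1]))


@dataclass
class SearchSpace:
    """Allele grid searched exhaustively; defaults cover every (TG)mTn
    allele reported in the population: T3-T11 crossed with (TG)8-(TG)16."""

    min_t: int = 3
    max_t: int = 11
    min_tg: int = 8
    max_tg: int = 16

    def __post_init__(self):
        if self.min_t > self.max_t or self.min_tg > self.max_tg or self.min_t < 1 or self.min_tg < 1:
            raise EmptySpaceError(f"invalid search space {self}")

    def alleles(self) -> list[Allele]:
        return [
            Allele(m, n)
            for m in range(self.min_tg, self.max_tg + 1)
            for n in range(self.min_t, self.max_t + 1)
        ]


def enumerate_genotypes(space: SearchSpace) -> list[Genotype]:
    """All unordered allele pairs (with replacement), deterministically
    sorted by canonical genotype key: A(A+1)/2 genotypes for A alleles."""
    alleles = space.alleles()
    pairs = itertools.combinations_with_replacement(alleles, 2)
    return sorted((Genotype(a, b) for a, b in pairs), key=Genotype.sort_key)


@dataclass
class ExpectedTract:
    """Dual-aligned expected pattern for one genotype and direction.

    ``codes`` holds per-position expected-set codes (SET_T/SET_G/SET_TG);
    ``et``/``eg`` the corresponding expected relative intensities.  The
    pattern length equals the longer allele's tract length in both
    directions (mF == mR).
    """

    genotype: Genotype
    direction: str
    codes: np.ndarray
    et: np.ndarray = field(init=False)
    eg: np.ndarray = field(init=False)

    def __post_init__(self):
        self.et = ET_OF_CODE[self.codes]
        self.eg = EG_OF_CODE[self.codes]

    @property
    def length(self) -> int:
        return len(self.codes)

    def sets(self) -> list[frozenset]:
        rev = {v: k for k, v in _CODE_FROM_SET.items()}
        return [rev[int(c)] for c in self.codes]


def expected_pattern(genotype: Genotype, direction: str) -> ExpectedTract:
    """Superpose the two aligned allele sequences into an expected pattern.

    Forward: left-aligned; reverse: right-aligned, reported 5'->3' so both
    directions share the genomic-forward frame.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be forward/reverse, got {direction!r}")
    sa = allele_sequence(genotype.allele_a)
    sb = allele_sequence(genotype.allele_b)
    length = max(len(sa), len(sb))
    codes = np.empty(length, dtype=np.int8)
    for i in range(length):
        bases = set()
        for s in (sa, sb):
            j = i if direction == "forward" else i - (length - len(s))
            if 0 <= j < len(s):
                bases.add(s[j])
        codes[i] = _CODE_FROM_SET[frozenset(bases)]
    return ExpectedTract(genotype=genotype, direction=direction, codes=codes)


def informative_positions(patterns: list[ExpectedTract], direction: str) -> set[int]:
    """Positions discriminating among surviving genotypes.

    Patterns are padded to the maximum surviving length with an explicit
    "no base expected" marker — on the right for forward (left-aligned)
    patterns, on the left for reverse (right-aligned) ones — so a length
    difference itself is informative: tract signal observed beyond a
    shorter expected pattern separates it from longer candidates.  Returns
    positions in that padded alignment frame; empty for < 2 survivors.
    """
    if len(patterns) < 2:
        return set()
    if any(p.direction != direction for p in patterns):
        raise ValueError("patterns mix directions")
    length = max(p.length for p in patterns)
    padded = np.full((len(patterns), length), SET_NONE, dtype=np.int8)
    for row, p in enumerate(patterns):
        if direction == "forward":
            padded[row, : p.length] = p.codes
        else:
            padded[row, length - p.length :] = p.codes
    differs = np.any(padded != padded[0], axis=0)
    return set(np.flatnonzero(differs).tolist())
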