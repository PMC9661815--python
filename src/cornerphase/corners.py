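"""Exact two-locus phasing from empty corners of the 3x3 genotype-count table.

For two biallelic loci A/a and B/b the nine two-locus genotypes tally into a
3x3 table (rows AA/Aa/aa, columns BB/Bb/bb).  If one of the four haplotypes
AB, Ab, aB, ab is absent from the population, the three genotype cells that
require it — one of the four corners of the table — are all zero.  Detecting
an empty corner therefore identifies the missing haplotype, and with only
three haplotypes segregating the phase of every double heterozygote (AaBb)
is forced: Ab/aB when AB or ab is missing, AB/ab when Ab or aB is missing.
Every other genotype is phase-unambiguous from its allele content alone.

Corner geometry (cell indices are (row, col) with 0=hom-ref, 1=het, 2=hom-alt):

    I   = {AABB, AABb, AaBB} = {(0,0), (0,1), (1,0)}   missing AB
    II  = {AABb, AAbb, Aabb} = {(0,1), (0,2), (1,2)}   missing Ab
    III = {AaBB, aaBB, aaBb} = {(1,0), (2,0), (2,1)}   missing aB
    IV  = {Aabb, aaBb, aabb} = {(1,2), (2,1), (2,2)}   missing ab

Opposite corners are {I, IV} and {II, III}: both corners of an opposite pair
empty means two haplotypes are missing and the loci are in complete LD.  Two
*adjacent* (non-opposite) empty corners imply conflicting double-heterozygote
phases that the data cannot distinguish; the tie is broken by the precedence
order IV > III > II > I and the result is flagged ambiguous.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .io import MISSING, GenotypeMatrix, SnpMeta

logger = logging.getLogger(__name__)

__all__ = [
    "PairTable",
    "CornerStatus",
    "PhasedPair",
    "CORNER_CELLS",
    "CORNER_MISSING_HAP",
    "build_pair_table",
    "detect_corners",
    "four_gamete_test",
    "phase_pair",
    "SmallSampleWarning",
    "AmbiguousCornerWarning",
]

#: cells of each corner, as (row, col) into the 3x3 count table
CORNER_CELLS: dict[str, tuple[tuple[int, int], ...]] = {
    "I": ((0, 0), (0, 1), (1, 0)),
    "II": ((0, 1), (0, 2), (1, 2)),
    "III": ((1, 0), (2, 0), (2, 1)),
    "IV": ((1, 2), (2, 1), (2, 2)),
}

#: haplotype absent when the corner is empty
CORNER_MISSING_HAP = {"I": "AB", "II": "Ab", "III": "aB", "IV": "ab"}

OPPOSITE_CORNER = {"I": "IV", "IV": "I", "II": "III", "III": "II"}

#: tie-break precedence when adjacent corners are simultaneously empty
CORNER_PRECEDENCE = ("IV", "III", "II", "I")

#: forced phase of AaBb given the missing haplotype
_PHASE_WHEN_MISSING = {"AB": "Ab/aB", "ab": "Ab/aB", "Ab": "AB/ab", "aB": "AB/ab"}

ALL_HAPLOTYPES = ("AB", "Ab", "aB", "ab")


class SmallSampleWarning(UserWarning):
    """A corner may be empty by sampling alone when N is small."""


class AmbiguousCornerWarning(UserWarning):
    """Two adjacent corners are empty; the phase was chosen by precedence."""


class CannotPhaseError(ValueError):
    """Raised when four haplotypes segregate and no exact phase exists."""


@dataclasses.dataclass
class PairTable:
    """3x3 genotype counts for one SNP pair; the algorithm's sufficient statistic.

    ``counts[i, j]`` is the number of individuals with i copies of the alt
    allele at the left SNP and j copies at the right SNP.
    """

    counts: np.ndarray
    snp1: SnpMeta | None = None
    snp2: SnpMeta | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def locus_margins(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_AA, n_Aa, n_aa) and (n_BB, n_Bb, n_bb)."""
        return self.counts.sum(axis=1), self.counts.sum(axis=0)


@dataclasses.dataclass
class CornerStatus:
    """Outcome of corner detection for one SNP pair."""

    empty_corners: frozenset[str]
    n_haplotypes: int
    missing_haplotypes: frozenset[str]
    double_het_phase: str  # "AB/ab", "Ab/aB", or "undefined"
    ambiguous: bool = False
    monomorphic: frozenset[int] = frozenset()  # subset of {1, 2} (locus labels)

    @property
    def segregating_haplotypes(self) -> tuple[str, ...]:
        return tuple(h for h in ALL_HAPLOTYPES if h not in self.missing_haplotypes)


@dataclasses.dataclass(frozen=True)
class PhasedPair:
    """An individual's unordered pair of two-locus haplotypes (e.g. 'Ab', 'aB')."""

    sample_id: str
    hap1: str
    hap2: str

    def haplotypes(self) -> frozenset[str]:
        return frozenset((self.hap1, self.hap2))


def build_pair_table(gm: GenotypeMatrix, i: int, j: int) -> PairTable:
    """Tally the 3x3 genotype-count table for SNPs ``i`` and ``j``.

    Individuals missing at either SNP are excluded (complete-case rule).
    """
    if i == j:
        raise ValueError("a pair requires two distinct SNPs")
    d1 = gm.dosages[:, i]
    d2 = gm.dosages[:, j]
    ok = (d1 != MISSING) & (d2 != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (d1[ok], d2[ok]), 1)
    return PairTable(counts=counts, snp1=gm.snps[i], snp2=gm.snps[j])


def _monomorphic_status(table: PairTable, mono: set[int]) -> CornerStatus:
    m1, m2 = table.locus_margins()
    empty = frozenset(
        c for c, cells in CORNER_CELLS.items()
        if all(table.counts[r, q] == 0 for r, q in cells)
    )
    # alleles actually present at each locus, expressed as haplotype characters
    a1 = [c for c, n in zip("Aa", (2 * m1[0] + m1[1], 2 * m1[2] + m1[1])) if n > 0]
    a2 = [c for c, n in zip("Bb", (2 * m2[0] + m2[1], 2 * m2[2] + m2[1])) if n > 0]
    present = {x + y for x in a1 for y in a2}
    missing = frozenset(h for h in ALL_HAPLOTYPES if h not in present)
    return CornerStatus(
        empty_corners=empty,
        n_haplotypes=len(present),
        missing_haplotypes=missing,
        double_het_phase="undefined",
        ambiguous=False,
        monomorphic=frozenset(mono),
    )


def detect_corners(table: PairTable, small_sample_n: int = 50) -> CornerStatus:
    """Locate empty corners and classify the pair.

    Returns the number of segregating haplotypes (2, 3 or 4), the missing
    haplotype(s) and the forced phase of double heterozygotes.  An empty
    corner means *exactly zero* observations in all three of its cells.
    When two adjacent corners are empty the phase choice is data-equivalent;
    the precedence order IV > III > II > I decides and ``ambiguous`` is set.
    """
    N = table.n_total
    if N == 0:
        raise ValueError("empty pair table: no complete-case individuals")
    if N < small_sample_n:
        warnings.warn(
            f"N={N} < {small_sample_n}: an empty corner may reflect sampling, "
            "not a truly absent haplotype",
            SmallSampleWarning,
            stacklevel=2,
        )
    m1, m2 = table.locus_margins()
    mono = set()
    if np.count_nonzero([2 * m1[0] + m1[1], 2 * m1[2] + m1[1]]) < 2:
        mono.add(1)
    if np.count_nonzero([2 * m2[0] + m2[1], 2 * m2[2] + m2[1]]) < 2:
        mono.add(2)
    if mono:
        return _monomorphic_status(table, mono)

    empty = frozenset(
        c for c, cells in CORNER_CELLS.items()
        if all(table.counts[r, q] == 0 for r, q in cells)
    )
    if not empty:
        return CornerStatus(
            empty_corners=empty,
            n_haplotypes=4,
            missing_haplotypes=frozenset(),
            double_het_phase="undefined",
        )
    primary = next(c for c in CORNER_PRECEDENCE if c in empty)
    missing = {CORNER_MISSING_HAP[primary]}
    opposite = OPPOSITE_CORNER[primary]
    if opposite in empty:
        missing.add(CORNER_MISSING_HAP[opposite])
    ambiguous = bool(empty - {primary, opposite})
    if ambiguous:
        others = sorted(empty - {primary, opposite})
        msg = (
            f"adjacent corners {primary} and {','.join(others)} are both empty; "
            f"precedence selects {primary} (missing haplotype "
            f"{CORNER_MISSING_HAP[primary]})"
        )
        warnings.warn(msg, AmbiguousCornerWarning, stacklevel=2)
        logger.warning(msg)
    return CornerStatus(
        empty_corners=empty,
        n_haplotypes=4 - len(missing),
        missing_haplotypes=frozenset(missing),
        double_het_phase=_PHASE_WHEN_MISSING[CORNER_MISSING_HAP[primary]],
        ambiguous=ambiguous,
    )


def four_gamete_test(table: PairTable, **kwargs) -> tuple[int, CornerStatus]:
    """Number of segregating haplotypes (2, 3 or 4) for the pair.

    Four haplotypes present imply a historical recombination (or recurrent
    mutation) between the loci; fewer than four is a 'failed' test and the
    pair is exactly phaseable.
    """
    status = detect_corners(table, **kwargs)
    return status.n_haplotypes, status


def _haps_from_dosages(d1: int, d2: int, phase: str) -> tuple[str, str]:
    """Unordered haplotype pair of one individual; ``phase`` resolves AaBb."""
    if d1 == 1 and d2 == 1:
        if phase == "AB/ab":
            return ("AB", "ab")
        if phase == "Ab/aB":
            return ("Ab", "aB")
        raise CannotPhaseError("double heterozygote with undefined phase")
    a = {0: ("A", "A"), 1: ("A", "a"), 2: ("a", "a")}[d1]
    b = {0: ("B", "B"), 1: ("B", "b"), 2: ("b", "b")}[d2]
    # at most one locus is heterozygous, so the pairing is forced
    return (a[0] + b[0], a[1] + b[1])


def phase_pair(
    gm: GenotypeMatrix, i: int, j: int, status: CornerStatus
) -> list[PhasedPair]:
    """Resolve the haplotype pair of every complete-case individual.

    Requires at most three segregating haplotypes (exact phase exists).
    Double heterozygotes take the forced phase from ``status``; all other
    genotypes are phased by allele content alone.
    """
    if status.n_haplotypes >= 4:
        raise CannotPhaseError(
            "four haplotypes segregate: the four-gamete test passes and no "
            "exact phase exists"
        )
    out: list[PhasedPair] = []
    d1 = gm.dosages[:, i]
    d2 = gm.dosages[:, j]
    for k, sid in enumerate(gm.sample_ids):
        if d1[k] == MISSING or d2[k] == MISSING:
            continue
        h1, h2 = _haps_from_dosages(int(d1[k]), int(d2[k]), status.double_het_phase)
        out.append(PhasedPair(sample_id=sid, hap1=h1, hap2=h2))
    return out
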