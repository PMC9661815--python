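"""Haplotyping of recombination-free chromosomal regions.

A region in which *every* SNP pair (consecutive and nonconsecutive) fails the
four-gamete test shows no evidence of historical recombination, so each
individual's two full-length haplotypes can be reconstructed exactly: phase
every pair of heterozygous SNPs with the corner logic, chain the pairwise
phases into two strings, and fill homozygous positions on both strings.  The
assembled region then behaves as a single multi-allelic marker whose alleles
are the haplotype strings, scored by expected heterozygosity and polymorphism
information content (PIC).

The all-pairs-fail property is hereditary (any sub-interval of a valid
interval is valid), so maximal regions are found with an exact two-pointer
sweep rather than testing all intervals.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .corners import (
    CornerStatus,
    SmallSampleWarning,
    build_pair_table,
    detect_corners,
)
from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "RegionHaplotypes",
    "all_pairs_fail_4gt",
    "scan_regions",
    "assemble_haplotypes",
    "haplotype_allele_freqs",
    "heterozygosity",
    "pic",
    "regions_summary_table",
]


class PhaseConflictError(ValueError):
    """Pairwise phases contradict each other around a cycle of het SNPs."""


@dataclasses.dataclass
class Region:
    """A contiguous run of SNPs whose every pair fails the four-gamete test."""

    chrom: str
    snp_indices: list[int]
    start_pos: int
    end_pos: int
    pairwise_status: dict[tuple[int, int], CornerStatus]
    overlaps_previous: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclasses.dataclass
class RegionHaplotypes:
    """Assembled per-individual haplotype strings for one region."""

    region: Region
    haplotypes: dict[str, tuple[str, str] | None]  # sample_id -> unordered pair
    allele_table: dict[str, float]
    pic: float
    heterozygosity: float
    n_excluded: int = 0


def _pair_statuses(
    gm: GenotypeMatrix, snp_indices: list[int], small_sample_n: int = 50
) -> tuple[bool, dict[tuple[int, int], CornerStatus], tuple[int, int] | None]:
    statuses: dict[tuple[int, int], CornerStatus] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        for a in range(len(snp_indices)):
            for b in range(a + 1, len(snp_indices)):
                i, j = snp_indices[a], snp_indices[b]
                status = detect_corners(
                    build_pair_table(gm, i, j), small_sample_n=small_sample_n
                )
                statuses[(i, j)] = status
                if status.n_haplotypes >= 4:
                    return False, statuses, (i, j)
    return True, statuses, None


def all_pairs_fail_4gt(
    gm: GenotypeMatrix, snp_indices: list[int], small_sample_n: int = 50
) -> tuple[bool, dict[tuple[int, int], CornerStatus]]:
    """Check that every pair of the listed SNPs has at most three haplotypes.

    All k(k-1)/2 pairs are examined.  Genotypes must be complete across the
    region: a single missing call prevents exact phasing of that individual.
    """
    if len(snp_indices) < 2:
        raise ValueError("a region needs at least two SNPs")
    miss = np.argwhere(gm.dosages[:, snp_indices] == MISSING)
    if miss.size:
        k, m = miss[0]
        raise ValueError(
            f"missing genotype for individual {gm.sample_ids[k]!r} at SNP "
            f"{gm.snps[snp_indices[m]].id!r}: complete data are required for "
            "region phasing"
        )
    ok, statuses, offending = _pair_statuses(gm, snp_indices, small_sample_n)
    if offending is not None:
        logger.info(
            "pair (%s, %s) has four haplotypes",
            gm.snps[offending[0]].id,
            gm.snps[offending[1]].id,
        )
    return ok, statuses


def scan_regions(
    gm: GenotypeMatrix, min_snps: int = 2, small_sample_n: int = 50
) -> list[Region]:
    """Maximal per-chromosome SNP intervals in which all pairs fail the test.

    Two-pointer sweep: for each right end j the smallest left end L(j) with
    all pairs (k, j), k >= L(j) failing is maintained; L is non-decreasing
    because the property is hereditary, so the sweep is exact.  An interval is
    reported when it is not contained in the next one; maximal intervals may
    overlap at their boundaries, in which case the later one is flagged.
    """
    regions: list[Region] = []
    chrom_groups: dict[str, list[int]] = {}
    for m, s in enumerate(gm.snps):
        chrom_groups.setdefault(s.chrom, []).append(m)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        for chrom, idx in chrom_groups.items():
            pos = [gm.snps[m].pos for m in idx]
            if pos != sorted(pos):
                raise ValueError(f"SNPs on {chrom} are not sorted by position")
            n = len(idx)
            statuses: dict[tuple[int, int], CornerStatus] = {}

            def fails(a: int, b: int) -> bool:
                key = (idx[a], idx[b])
                if key not in statuses:
                    statuses[key] = detect_corners(
                        build_pair_table(gm, *key), small_sample_n=small_sample_n
                    )
                return statuses[key].n_haplotypes < 4

            left = 0
            prev_window: tuple[int, int] | None = None
            for j in range(n):
                for k in range(left, j):
                    if not fails(k, j):
                        left = k + 1
                # emit [left, j] if maximal: the next step either ends the
                # chromosome or will advance `left` past the current one
                if j == n - 1 or not all(fails(k, j + 1) for k in range(left, j + 1)):
                    if j - left + 1 >= min_snps:
                        snp_indices = idx[left : j + 1]
                        region = Region(
                            chrom=chrom,
                            snp_indices=snp_indices,
                            start_pos=gm.snps[snp_indices[0]].pos,
                            end_pos=gm.snps[snp_indices[-1]].pos,
                            pairwise_status={
                                (i, jj): statuses[(i, jj)]
                                for a, i in enumerate(snp_indices)
                                for jj in snp_indices[a + 1 :]
                            },
                            overlaps_previous=(
                                prev_window is not None and left <= prev_window[1]
                            ),
                        )
                        regions.append(region)
                        prev_window = (left, j)
    return regions


def _brute_force_region_phasings(
    het_positions: list[int],
    statuses: dict[tuple[int, int], CornerStatus],
    dosage_row: np.ndarray,
) -> list[dict[int, int]]:
    """All orientation assignments of het SNPs consistent with pairwise phases.

    Exhaustive 2^h enumeration used as the assembly oracle in tests (exposed
    here so tests and diagnostics share one implementation).  An assignment
    maps each het SNP index to 0/1: haplotype 1 carries ref (0) or alt (1).
    """
    h = len(het_positions)
    out = []
    for bits in range(2 ** h):
        assign = {m: (bits >> t) & 1 for t, m in enumerate(het_positions)}
        ok = True
        for a in range(h):
            for b in range(a + 1, h):
                i, j = het_positions[a], het_positions[b]
                status = statuses[(i, j)]
                if status.double_het_phase == "undefined":
                    continue
                cis = status.double_het_phase == "AB/ab"
                if (assign[i] == assign[j]) != cis:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(assign)
    return out


def assemble_haplotypes(
    gm: GenotypeMatrix, region: Region, allow_ambiguous: bool = False
) -> RegionHaplotypes:
    """Chain pairwise exact phases into full-length haplotype strings.

    For each individual, the SNPs that matter are the heterozygous ones: each
    het pair's forced double-heterozygote phase says whether the two SNPs'
    ref alleles ride on the same haplotype (phase AB/ab) or on opposite ones
    (Ab/aB).  These parity constraints are propagated from the first het SNP;
    every remaining constraint is then checked, and a contradiction (possible
    under genotyping error) raises :class:`PhaseConflictError`.  Homozygous
    positions are filled identically on both strings.

    Individuals needing a pair whose phase was ambiguous (adjacent-corner
    tie) are excluded from the allele table and recorded in ``n_excluded``
    unless ``allow_ambiguous`` is set.
    """
    idx = region.snp_indices
    statuses = region.pairwise_status
    haplotypes: dict[str, tuple[str, str] | None] = {}
    n_excluded = 0

    for k, sid in enumerate(gm.sample_ids):
        row = gm.dosages[k, :]
        if (row[idx] == MISSING).any():
            raise ValueError(
                f"missing genotype for individual {sid!r} inside region "
                f"{region.chrom}:{region.start_pos}-{region.end_pos}"
            )
        het = [m for m in idx if row[m] == 1]
        needed = [
            (i, j) for a, i in enumerate(het) for j in het[a + 1 :]
        ]
        if not allow_ambiguous and any(statuses[p].ambiguous for p in needed):
            haplotypes[sid] = None
            n_excluded += 1
            continue

        # parity propagation from the first het SNP
        assign: dict[int, int] = {}
        if het:
            assign[het[0]] = 0
            for m in het[1:]:
                i, j = (het[0], m)
                status = statuses[(i, j)]
                if status.double_het_phase == "undefined":
                    raise PhaseConflictError(
                        f"individual {sid!r}: no forced phase for het pair "
                        f"({gm.snps[i].id}, {gm.snps[j].id})"
                    )
                cis = status.double_het_phase == "AB/ab"
                assign[m] = assign[het[0]] if cis else 1 - assign[het[0]]
            for i, j in needed:
                status = statuses[(i, j)]
                if status.double_het_phase == "undefined":
                    continue
                cis = status.double_het_phase == "AB/ab"
                if (assign[i] == assign[j]) != cis:
                    raise PhaseConflictError(
                        f"individual {sid!r}: pairwise phases are cyclically "
                        f"inconsistent around ({gm.snps[het[0]].id}, "
                        f"{gm.snps[i].id}, {gm.snps[j].id})"
                    )

        h1 = []
        h2 = []
        for m in idx:
            s = gm.snps[m]
            if row[m] == 0:
                h1.append(s.ref_allele)
                h2.append(s.ref_allele)
            elif row[m] == 2:
                h1.append(s.alt_allele)
                h2.append(s.alt_allele)
            else:
                if assign[m] == 0:
                    h1.append(s.ref_allele)
                    h2.append(s.alt_allele)
                else:
                    h1.append(s.alt_allele)
                    h2.append(s.ref_allele)
        haplotypes[sid] = ("".join(h1), "".join(h2))

    allele_table = haplotype_allele_freqs_from_pairs(
        [p for p in haplotypes.values() if p is not None]
    )
    if n_excluded:
        logger.warning(
            "region %s:%d-%d: %d individual(s) excluded from the allele table "
            "due to ambiguous pairwise phases",
            region.chrom,
            region.start_pos,
            region.end_pos,
            n_excluded,
        )
    return RegionHaplotypes(
        region=region,
        haplotypes=haplotypes,
        allele_table=allele_table,
        pic=pic(allele_table) if allele_table else float("nan"),
        heterozygosity=heterozygosity(allele_table) if allele_table else float("nan"),
        n_excluded=n_excluded,
    )


def haplotype_allele_freqs_from_pairs(
    pairs: list[tuple[str, str]]
) -> dict[str, float]:
    counts: dict[str, int] = {}
    for h1, h2 in pairs:
        counts[h1] = counts.get(h1, 0) + 1
        counts[h2] = counts.get(h2, 0) + 1
    total = sum(counts.values())
    return {h: c / total for h, c in sorted(counts.items())} if total else {}


def haplotype_allele_freqs(rh: RegionHaplotypes) -> dict[str, float]:
    """Frequency of each distinct haplotype string over 2N gametes."""
    return haplotype_allele_freqs_from_pairs(
        [p for p in rh.haplotypes.values() if p is not None]
    )


def heterozygosity(allele_table: dict[str, float]) -> float:
    """Expected heterozygosity 1 - sum(f_i^2) of the multi-allelic locus."""
    if not allele_table:
        raise ValueError("empty allele table")
    f = np.asarray(list(allele_table.values()), dtype=float)
    return float(1.0 - np.sum(f**2))


def pic(allele_table: dict[str, float]) -> float:
    """Polymorphism information content (Botstein convention).

    PIC = 1 - sum_i f_i^2 - sum_{i<j} 2 f_i^2 f_j^2; always <= heterozygosity.
    """
    if not allele_table:
        raise ValueError("empty allele table")
    f = np.asarray(list(allele_table.values()), dtype=float)
    s2 = np.sum(f**2)
    s4 = np.sum(f**4)
    return float(1.0 - s2 - (s2**2 - s4))


def regions_summary_table(region_haps: list[RegionHaplotypes]) -> pd.DataFrame:
    """One row per region: span, SNP count, allele count, PIC, heterozygosity."""
    rows = [
        {
            "chrom": rh.region.chrom,
            "start_bp": rh.region.start_pos,
            "end_bp": rh.region.end_pos,
            "n_snps": rh.region.n_snps,
            "n_haplotype_alleles": len(rh.allele_table),
            "pic": rh.pic,
            "heterozygosity": rh.heterozygosity,
            "n_excluded": rh.n_excluded,
            "overlaps_previous": rh.region.overlaps_previous,
        }
        for rh in region_haps
    ]
    return pd.DataFrame(rows)
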