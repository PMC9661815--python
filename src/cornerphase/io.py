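"""Genotype I/O: VCF and dosage-matrix readers, QC filters, result writers.

Genotypes are stored as alt-allele dosages (0, 1, 2) with -1 for missing.
By convention the abstract alleles A and B of a two-locus system map to the
REF alleles of the left and right SNP of a pair, and a/b to the ALT alleles.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SnpMeta",
    "GenotypeMatrix",
    "read_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "apply_qc",
    "write_results",
]


class EmptyInputError(ValueError):
    """Raised when a reader or filter yields zero usable SNPs."""


@dataclasses.dataclass(frozen=True)
class SnpMeta:
    """Marker metadata: name, chromosome, 1-based position, REF/ALT alleles."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical")


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as an individuals x SNPs dosage matrix.

    ``dosages[k, m]`` counts copies of the ALT allele of SNP ``m`` carried by
    individual ``k`` (0, 1, 2), with ``MISSING`` (-1) for no-calls.
    """

    snps: list[SnpMeta]
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            k, m = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[k, m]} for sample "
                f"{self.sample_ids[k]!r} at SNP {self.snps[m].id!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        seen = set()
        for s in self.snps:
            key = (s.chrom, s.pos)
            if key in seen:
                raise ValueError(f"duplicate SNP at {s.chrom}:{s.pos}")
            seen.add(key)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, computed on non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            snps=[self.snps[m] for m in idx],
            dosages=self.dosages[:, idx].copy(),
            sample_ids=list(self.sample_ids),
        )

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for s in self.snps:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out


def read_vcf(path: str | Path, *, skip_non_biallelic_snps: bool = True) -> GenotypeMatrix:
    """Read unphased diploid genotypes from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic or non-SNP records are skipped (default) or rejected.
    ``./.`` genotypes become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snps: list[SnpMeta] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            if skip_non_biallelic_snps:
                continue
            raise ValueError(
                f"non-biallelic or non-SNP record at {var.CHROM}:{var.POS}"
            )
        d = var.gt_types.astype(np.int8)  # gts012: 0/1/2 dosage, 3 = unknown
        d[d == 3] = MISSING
        snps.append(
            SnpMeta(
                id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        rows.append(d)
    vcf.close()
    if not snps:
        raise EmptyInputError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(snps=snps, dosages=np.stack(rows, axis=1), sample_ids=sample_ids)


def read_matrix_tsv(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a TSV dosage matrix (rows = individuals, header = SNP ids).

    Cells are 0/1/2 alt-allele counts or NA.  ``map_path`` is a sidecar TSV
    with columns id, chrom, pos, ref, alt giving marker coordinates.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in ("id", "chrom", "pos", "ref", "alt") if c not in snp_map.columns]
    if missing_cols:
        raise ValueError(f"map file {map_path} lacks columns {missing_cols}")
    meta_by_id = {r.id: r for r in snp_map.itertuples()}
    snps = []
    for sid in mat.columns:
        if sid not in meta_by_id:
            raise ValueError(f"SNP {sid!r} in matrix has no entry in map file")
        r = meta_by_id[sid]
        snps.append(SnpMeta(id=sid, chrom=str(r.chrom), pos=int(r.pos),
                            ref_allele=str(r.ref), alt_allele=str(r.alt)))
    dosages = np.full(mat.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(mat.columns):
        for i, cell in enumerate(mat[col]):
            if pd.isna(cell) or cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(
                    f"invalid genotype {cell!r} at row {mat.index[i]!r}, column {col!r}"
                )
            dosages[i, j] = int(cell)
    return GenotypeMatrix(snps=snps, dosages=dosages, sample_ids=[str(s) for s in mat.index])


def write_matrix_tsv(gm: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    """Write the dosage matrix and its sidecar map; inverse of read_matrix_tsv."""
    cells = gm.dosages.astype(object)
    cells[cells == MISSING] = "NA"
    pd.DataFrame(cells, index=gm.sample_ids, columns=[s.id for s in gm.snps]).to_csv(
        path, sep="\t", index_label="sample_id"
    )
    pd.DataFrame(
        {
            "id": [s.id for s in gm.snps],
            "chrom": [s.chrom for s in gm.snps],
            "pos": [s.pos for s in gm.snps],
            "ref": [s.ref_allele for s in gm.snps],
            "alt": [s.alt_allele for s in gm.snps],
        }
    ).to_csv(map_path, sep="\t", index=False)


def apply_qc(
    gm: GenotypeMatrix, maf_min: float = 0.05, require_complete: bool = False
) -> GenotypeMatrix:
    """Drop SNPs with MAF below ``maf_min`` and, optionally, any missing call.

    Completeness matters because a single missing genotype prevents exact
    phasing of that individual across a region; requiring complete SNPs keeps
    every individual usable.  Idempotent; SNP order is preserved.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    keep = np.ones(gm.n_snps, dtype=bool)
    if maf_min > 0:
        maf = gm.maf()
        keep &= ~(maf < maf_min) & ~np.isnan(maf)
    if require_complete:
        keep &= ~(gm.dosages == MISSING).any(axis=0)
    if not keep.any():
        raise EmptyInputError("QC removed every SNP")
    if keep.all():
        return gm
    return gm.subset_snps(np.flatnonzero(keep))


def write_results(records: pd.DataFrame, path: str | Path, float_precision: int = 6) -> None:
    """Write a result table as TSV with a stable column order."""
    if records is None or len(records) == 0:
        raise ValueError(f"refusing to write an empty result table to {path}")
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g")
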