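import numpy as np
import pytest

from cornerphase import GenotypeMatrix, PairTable, SnpMeta

#: printed chr2 worked example: only AABB, AABb and AaBb observed
CHR2_COUNTS = np.array([[382, 17, 0], [0, 36, 0], [0, 0, 0]], dtype=np.int64)

#: nine-SNP region haplotype pool with its printed frequencies
TABLE5_POOL = {
    "AAAAAGAAA": 0.02183908,
    "AAAAAGGAA": 0.07701149,
    "AAGCGAAAA": 0.15632184,
    "AAGCGAAGG": 0.23218391,
    "AGAAAGAAA": 0.14712644,
    "GAGCGAAAA": 0.36551724,
}

REGION_POSITIONS = [
    309120, 477400, 705066, 712417, 768502, 771992, 887856, 1208216, 1301402,
]

SOW65_HAPLOTYPES = ("AAGCGAAGG", "GAGCGAAAA")


@pytest.fixture
def chr2_table() -> PairTable:
    snp1 = SnpMeta(id="chr2_left", chrom="2", pos=39631490, ref_allele="A", alt_allele="G")
    snp2 = SnpMeta(id="chr2_right", chrom="2", pos=39638306, ref_allele="A", alt_allele="G")
    return PairTable(counts=CHR2_COUNTS.copy(), snp1=snp1, snp2=snp2)


def make_pair_matrix(dosage_pairs, chrom="1"):
    """Two-SNP GenotypeMatrix from a list of (dosage1, dosage2) tuples."""
    snps = [
        SnpMeta(id="left", chrom=chrom, pos=100, ref_allele="A", alt_allele="G"),
        SnpMeta(id="right", chrom=chrom, pos=200, ref_allele="C", alt_allele="T"),
    ]
    d = np.array(dosage_pairs, dtype=np.int8)
    return GenotypeMatrix(
        snps=snps, dosages=d, sample_ids=[f"ind{k}" for k in range(len(d))]
    )


def matrix_from_counts(counts, chrom="1"):
    """Expand a 3x3 count table into a two-SNP GenotypeMatrix."""
    pairs = []
    for i in range(3):
        for j in range(3):
            pairs.extend([(i, j)] * int(counts[i][j]))
    return make_pair_matrix(pairs, chrom=chrom)


@pytest.fixture
def chr2_matrix() -> GenotypeMatrix:
    return matrix_from_counts(CHR2_COUNTS, chrom="2")


def write_test_vcf(path, records, samples=("s1", "s2", "s3")):
    """Write a minimal VCF 4.2 file; records are (chrom,pos,id,ref,alt,gts)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = {r[0] for r in records}
    for c in sorted(chroms):
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, vid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
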