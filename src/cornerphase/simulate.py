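"""Synthetic genotypes and phenotypes with the structure exact phasing assumes.

Individuals are random unions of two gametes drawn independently from a
haplotype pool, i.e. Hardy-Weinberg equilibrium at the haplotype level — the
regime in which the EM baseline is the natural comparator.  Every generator
is seed-deterministic and returns the simulation truth (phases, haplotype
pairs, phenotype components) alongside the observed data, so recovery tests
never re-derive it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import MISSING, GenotypeMatrix, SnpMeta
from .gwas import PhenotypeTable
from .ld import HaplotypeFrequencies

__all__ = [
    "SimSpec",
    "simulate_pair_genotypes",
    "simulate_region",
    "simulate_phenotypes",
    "add_genotyping_errors",
]

_PAIR_HAPS = ("AB", "Ab", "aB", "ab")
#: alt-dosage contribution of each two-locus haplotype at (left, right) SNP
_HAP_DOSE = {"AB": (0, 0), "Ab": (0, 1), "aB": (1, 0), "ab": (1, 1)}


@dataclasses.dataclass
class SimSpec:
    """Configuration of a synthetic dataset (YAML-loadable).

    ``pair_scenarios`` maps scenario names to {AB, Ab, aB, ab} frequency
    dicts; ``region_pool`` is a haplotype-string -> frequency map; the
    phenotype block sets the causal effect size and variance components.
    """

    n_individuals: int = 435
    pair_scenarios: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    region_pool: dict[str, float] = dataclasses.field(default_factory=dict)
    genotyping_error_rate: float = 0.0
    haplotype_effect: float = 0.0
    sigma2_a: float = 1.0
    sigma2_e: float = 1.0
    factor_levels: dict[str, list] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.genotyping_error_rate < 1:
            raise ValueError("genotyping error rate must be in [0, 1)")
        for name, freqs in self.pair_scenarios.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"scenario {name!r}: frequencies do not sum to 1")
        if self.region_pool and abs(sum(self.region_pool.values()) - 1.0) > 1e-9:
            raise ValueError("region pool frequencies do not sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _pair_snps(chrom: str = "1") -> list[SnpMeta]:
    return [
        SnpMeta(id="snp1", chrom=chrom, pos=1000, ref_allele="A", alt_allele="C"),
        SnpMeta(id="snp2", chrom=chrom, pos=2000, ref_allele="G", alt_allele="T"),
    ]


def simulate_pair_genotypes(
    freqs: HaplotypeFrequencies | dict[str, float],
    n: int,
    seed: int | np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Unphased two-SNP genotypes from n random unions of gametes.

    Returns the genotype matrix and a truth frame with each individual's two
    drawn haplotypes (the phases the estimators must recover).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(freqs, HaplotypeFrequencies):
        f = freqs.as_array()
    else:
        f = np.array([freqs.get(h, 0.0) for h in _PAIR_HAPS], dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gametes = rng.choice(4, size=(n, 2), p=f)
    dosages = np.zeros((n, 2), dtype=np.int8)
    truth = []
    for k in range(n):
        h1, h2 = _PAIR_HAPS[gametes[k, 0]], _PAIR_HAPS[gametes[k, 1]]
        d1 = _HAP_DOSE[h1]
        d2 = _HAP_DOSE[h2]
        dosages[k] = (d1[0] + d2[0], d1[1] + d2[1])
        truth.append({"sample_id": f"ind{k}", "hap1": h1, "hap2": h2})
    gm = GenotypeMatrix(
        snps=_pair_snps(),
        dosages=dosages,
        sample_ids=[f"ind{k}" for k in range(n)],
    )
    return gm, pd.DataFrame(truth)


def simulate_region(
    pool: dict[str, float],
    n: int,
    seed: int | np.random.Generator,
    chrom: str = "1",
    positions: list[int] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Unphased multi-SNP genotypes from a region haplotype pool.

    Each individual is a random pair of pool haplotypes.  Per column, the
    reference allele is the first allele character seen in the pool; a column
    with one allele across the pool becomes a monomorphic SNP.  A warning is
    printed when some SNP pair shows all four gametes in the pool (the region
    would then not pass the all-pairs test).
    """
    haps = list(pool.keys())
    f = np.array(list(pool.values()), dtype=float)
    L = len(haps[0])
    if any(len(h) != L for h in haps):
        raise ValueError("pool haplotypes must have equal length")
    for a in range(L):
        for b in range(a + 1, L):
            if len({h[a] + h[b] for h in haps}) == 4:
                import warnings

                warnings.warn(
                    f"pool columns {a} and {b} carry all four gametes; the "
                    "region will not pass the all-pairs four-gamete check",
                    stacklevel=2,
                )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if positions is None:
        positions = [1000 * (m + 1) for m in range(L)]
    # ref = first allele seen per column; any second allele is alt
    snps = []
    for m in range(L):
        alleles = []
        for h in haps:
            if h[m] not in alleles:
                alleles.append(h[m])
        ref = alleles[0]
        alt = alleles[1] if len(alleles) > 1 else ("A" if ref != "A" else "G")
        snps.append(
            SnpMeta(id=f"snp{m}", chrom=chrom, pos=positions[m], ref_allele=ref, alt_allele=alt)
        )
    draws = rng.choice(len(haps), size=(n, 2), p=f)
    dosages = np.zeros((n, L), dtype=np.int8)
    truth = []
    for k in range(n):
        h1, h2 = haps[draws[k, 0]], haps[draws[k, 1]]
        for m in range(L):
            dosages[k, m] = (h1[m] == snps[m].alt_allele) + (h2[m] == snps[m].alt_allele)
        truth.append({"sample_id": f"ind{k}", "hap1": h1, "hap2": h2})
    gm = GenotypeMatrix(snps=snps, dosages=dosages, sample_ids=[f"ind{k}" for k in range(n)])
    return gm, pd.DataFrame(truth)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    causal_dosage: np.ndarray | None,
    spec: SimSpec,
    seed: int | np.random.Generator | None = None,
    grm: np.ndarray | None = None,
    grm_chol: np.ndarray | None = None,
) -> tuple[PhenotypeTable, dict]:
    """Phenotypes y = factor effects + g * dosage + a + e.

    The polygenic term a ~ N(0, G sigma2_a) uses VanRaden's G from ``gm``
    unless a precomputed G (or its Cholesky factor) is supplied.  Returns the
    table and a components dict (truth) for recovery tests.
    """
    from .gwas import vanraden_grm

    n = gm.n_individuals
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        spec.seed if seed is None else seed
    )
    y = np.zeros(n)
    data = {"sample_id": gm.sample_ids}
    factor_effects: dict[str, dict] = {}
    for fname, levels in spec.factor_levels.items():
        assign = rng.choice(len(levels), size=n)
        effects = rng.normal(0.0, 1.0, size=len(levels))
        y += effects[assign]
        data[fname] = [levels[i] for i in assign]
        factor_effects[fname] = dict(zip(levels, effects))

    g_term = np.zeros(n)
    if causal_dosage is not None and spec.haplotype_effect != 0.0:
        g_term = spec.haplotype_effect * np.asarray(causal_dosage, dtype=float)
        y += g_term

    a = np.zeros(n)
    if spec.sigma2_a > 0:
        if grm_chol is None:
            G = vanraden_grm(gm) if grm is None else grm
            # tiny ridge keeps the factorization defined for rank-deficient G
            grm_chol = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        a = np.sqrt(spec.sigma2_a) * (grm_chol @ rng.standard_normal(n))
        y += a
    e = rng.normal(0.0, np.sqrt(spec.sigma2_e), size=n)
    y += e

    data["y"] = y
    pheno = PhenotypeTable(
        data=pd.DataFrame(data),
        trait="y",
        factors=tuple(spec.factor_levels.keys()),
    )
    components = {
        "factor_effects": factor_effects,
        "genetic_effect": g_term,
        "polygenic": a,
        "residual": e,
    }
    return pheno, components


def add_genotyping_errors(
    gm: GenotypeMatrix, rate: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Flip each non-missing genotype to a random different value with prob ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return gm
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = gm.dosages.copy()
    flip = (rng.random(d.shape) < rate) & (d != MISSING)
    for k, m in np.argwhere(flip):
        choices = [v for v in (0, 1, 2) if v != d[k, m]]
        d[k, m] = choices[rng.integers(len(choices))]
    return GenotypeMatrix(snps=list(gm.snps), dosages=d, sample_ids=list(gm.sample_ids))
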