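"""Single-marker and third-haplotype GWAS under a genomic mixed model.

For a pair of consecutive SNPs with three segregating haplotypes, the two
single-marker (SM) tests contrast only the two haplotypes tagged by an
allele; the third haplotype — the complement of the missing one — is not
contrasted against the other two by either SNP.  Exact phasing supplies each
individual's 0/1/2 copy count of that third haplotype, giving a third,
complementary association (CA) test per pair.

Model: y = W b + x g + a + e with a ~ N(0, G sigma2_a), e ~ N(0, I sigma2_e),
where W codes fixed factors (e.g. parity, season), x is the allele or
haplotype dosage, and G is VanRaden's genomic relationship matrix.  Variance
components are estimated once by REML on the null model via the spectral
decomposition of G and held fixed for all tests (the EMMAX approximation);
each test is then a single generalized-least-squares fit with a Wald p-value.

Multiple testing uses Benjamini-Hochberg with an *effective* number of tests:
SNP pairs in complete LD and the three mutually-contrasting tests of a
three-haplotype pair are redundant, so m_eff = n_snps - (pairs in full LD)/2
- (2/3)(three-haplotype pairs).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .corners import (
    CornerStatus,
    PhasedPair,
    SmallSampleWarning,
    build_pair_table,
    detect_corners,
    phase_pair,
)
from .io import MISSING, GenotypeMatrix

__all__ = [
    "PhenotypeTable",
    "LmmFit",
    "GwasRecord",
    "third_haplotype_dosage",
    "vanraden_grm",
    "fit_null_lmm",
    "association_test",
    "effective_tests",
    "bh_adjust",
    "run_gwas",
]

_COMPLEMENT = {"AB": "ab", "Ab": "aB", "aB": "Ab", "ab": "AB"}


@dataclasses.dataclass
class PhenotypeTable:
    """Trait records with optional fixed-effect factor columns."""

    data: pd.DataFrame
    trait: str = "y"
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("phenotype table needs a 'sample_id' column")
        if self.trait not in self.data.columns:
            raise ValueError(f"trait column {self.trait!r} not in phenotype table")
        for f in self.factors:
            if f not in self.data.columns:
                raise ValueError(f"factor column {f!r} not in phenotype table")

    def aligned_to(self, sample_ids: list[str]) -> "PhenotypeTable":
        df = self.data.set_index("sample_id").loc[sample_ids].reset_index()
        return PhenotypeTable(data=df, trait=self.trait, factors=self.factors)

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, W) with W = intercept + reference-coded factor dummies."""
        y = self.data[self.trait].to_numpy(dtype=float)
        cols = [np.ones(len(y))]
        for f in self.factors:
            d = pd.get_dummies(self.data[f].astype("category"), drop_first=True)
            cols.extend(d[c].to_numpy(dtype=float) for c in d.columns)
        W = np.column_stack(cols)
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("fixed-effect design matrix is rank deficient")
        return y, W


@dataclasses.dataclass
class LmmFit:
    """Null-model REML fit, caching the rotation reused by every test."""

    sigma2_a: float
    sigma2_e: float
    beta: np.ndarray
    reml_loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    y_rot: np.ndarray
    W_rot: np.ndarray

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclasses.dataclass
class GwasRecord:
    marker: str
    chrom: str
    bp: str
    test_type: str  # SM or CA
    effect: float
    se: float
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None


def third_haplotype_dosage(
    phased: list[PhasedPair], status: CornerStatus
) -> np.ndarray:
    """Copies (0/1/2) of the third haplotype carried by each phased individual.

    The third haplotype is the complement of the missing one (missing AB ->
    third ab): the one segregating haplotype not tagged by either single-SNP
    allele contrast.
    """
    if status.n_haplotypes != 3:
        raise ValueError(
            f"third-haplotype dosage requires exactly 3 segregating haplotypes, "
            f"got {status.n_haplotypes}"
        )
    (missing,) = status.missing_haplotypes
    third = _COMPLEMENT[missing]
    return np.array(
        [(pp.hap1 == third) + (pp.hap2 == third) for pp in phased], dtype=float
    )


def vanraden_grm(gm: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix G = ZZ' / (2 sum p_j (1 - p_j)).

    Z is the dosage matrix column-centered at twice the observed alt-allele
    frequency.  Requires complete genotypes (run QC first) and at least one
    polymorphic SNP.
    """
    if (gm.dosages == MISSING).any():
        raise ValueError("GRM requires complete genotypes; run apply_qc first")
    M = gm.dosages.astype(float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Z @ Z.T) / denom


def _reml_neg_loglik(
    log_lam: float, y_rot: np.ndarray, W_rot: np.ndarray, s: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Profile REML -loglik in lambda = sigma2_a / sigma2_e (constants dropped)."""
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    Wd = W_rot / w[:, None]
    A = W_rot.T @ Wd
    b = Wd.T @ y_rot
    beta = np.linalg.solve(A, b)
    r = y_rot - W_rot @ beta
    rss = float(np.sum(r * r / w))
    n, p = W_rot.shape
    sigma2_e = rss / (n - p)
    sign, logdet_A = np.linalg.slogdet(A)
    nll = 0.5 * (
        (n - p) * np.log(sigma2_e) + np.sum(np.log(w)) + logdet_A + (n - p)
    )
    return nll, sigma2_e, beta


def fit_null_lmm(
    pheno: PhenotypeTable, grm: np.ndarray, psd_epsilon: float = 1e-6
) -> LmmFit:
    """REML variance components for y = Wb + a + e via eigendecomposition of G.

    The model is profiled in lambda = sigma2_a / sigma2_e, so a single
    eigendecomposition serves the whole optimization and, afterwards, every
    association test.  Non-PSD G (possible after filtering) is stabilized by
    adding ``psd_epsilon`` to the diagonal.
    """
    y, W = pheno.design()
    n = len(y)
    if grm.shape != (n, n):
        raise ValueError(f"GRM shape {grm.shape} does not match {n} records")
    s, U = np.linalg.eigh(grm)
    if s.min() < -1e-8:
        s, U = np.linalg.eigh(grm + psd_epsilon * np.eye(n))
    s = np.clip(s, 0.0, None)
    y_rot = U.T @ y
    W_rot = U.T @ W

    res = optimize.minimize_scalar(
        lambda ll: _reml_neg_loglik(ll, y_rot, W_rot, s)[0],
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res}")
    nll, sigma2_e, beta = _reml_neg_loglik(res.x, y_rot, W_rot, s)
    lam = float(np.exp(res.x))
    # compare against the boundary sigma2_a = 0 (OLS residual variance)
    nll0, sigma2_e0, beta0 = _reml_neg_loglik(-np.inf, y_rot, W_rot, s)
    if nll0 <= nll:
        lam, nll, sigma2_e, beta = 0.0, nll0, sigma2_e0, beta0
    return LmmFit(
        sigma2_a=lam * sigma2_e,
        sigma2_e=sigma2_e,
        beta=beta,
        reml_loglik=-nll,
        eigvals=s,
        eigvecs=U,
        y_rot=y_rot,
        W_rot=W_rot,
    )


def association_test(
    dosage: np.ndarray,
    pheno: PhenotypeTable,
    null: LmmFit,
    marker: str = "",
    chrom: str = "",
    bp: str = "",
    test_type: str = "SM",
) -> GwasRecord | None:
    """GLS test of one dosage vector with variance components fixed at the null.

    V = G sigma2_a + I sigma2_e from the null fit; the dosage coefficient's
    Wald z-statistic gives the p-value.  Returns None (skipped) for a
    zero-variance dosage.
    """
    dosage = np.asarray(dosage, dtype=float)
    if np.var(dosage) == 0:
        return None
    v = null.sigma2_a * null.eigvals + null.sigma2_e
    x_rot = null.eigvecs.T @ dosage
    X = np.column_stack([null.W_rot, x_rot])
    Xv = X / v[:, None]
    A = X.T @ Xv
    beta = np.linalg.solve(A, Xv.T @ null.y_rot)
    cov = np.linalg.inv(A)
    effect = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = effect / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return GwasRecord(
        marker=marker,
        chrom=chrom,
        bp=bp,
        test_type=test_type,
        effect=effect,
        se=se,
        p_raw=max(p, np.finfo(float).tiny),
    )


def effective_tests(
    n_snps: int, n_full_ld_pairs: int, n_three_hap_pairs: int
) -> int:
    """Effective number of tests for the BH correction.

    m_eff = n_snps - n_full_ld_pairs/2 - (2/3) n_three_hap_pairs, rounded to
    the nearest integer: each full-LD pair contributes one redundant SM test,
    and the three mutually-contrasting tests of a three-haplotype pair carry
    about one test's worth of independent information each pair of them.
    """
    if min(n_snps, n_full_ld_pairs, n_three_hap_pairs) < 0:
        raise ValueError("counts must be non-negative")
    m = round(n_snps - n_full_ld_pairs / 2.0 - (2.0 / 3.0) * n_three_hap_pairs)
    if m <= 0:
        raise ValueError(f"effective number of tests is {m} <= 0")
    return int(m)


def bh_adjust(
    p_values: np.ndarray, m_eff: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up with an effective test count.

    Adjusted p-value of the i-th smallest p is min over j >= i of
    m_eff * p_(j) / j, capped at 1; a test is significant when its adjusted
    value is <= alpha.  ``m_eff`` defaults to the raw number of tests, which
    recovers standard BH; a smaller m_eff (correlated tests) is allowed.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p) if m_eff is None else int(m_eff)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    return adj, adj <= alpha


def run_gwas(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    alpha: float = 0.05,
    small_sample_n: int = 0,
) -> pd.DataFrame:
    """Full scan: SM test per SNP plus a CA test per three-haplotype pair.

    Consecutive SNP pairs (within chromosome) are classified with the corner
    logic; pairs in complete LD and three-haplotype pairs feed the effective
    test count, and all p-values are adjusted jointly.  Returns a table with
    columns Marker, Chr, bp, p-value (BH-adjusted), Testing (SM/CA), Effect,
    SE, sorted by position.
    """
    pheno = pheno.aligned_to(gm.sample_ids)
    grm = vanraden_grm(gm)
    null = fit_null_lmm(pheno, grm)

    records: list[GwasRecord] = []
    for m, snp in enumerate(gm.snps):
        rec = association_test(
            gm.dosages[:, m].astype(float),
            pheno,
            null,
            marker=snp.id,
            chrom=snp.chrom,
            bp=str(snp.pos),
            test_type="SM",
        )
        if rec is not None:
            records.append(rec)

    n_full_ld = 0
    n_three_hap = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        for m in range(gm.n_snps - 1):
            s1, s2 = gm.snps[m], gm.snps[m + 1]
            if s1.chrom != s2.chrom:
                continue
            status = detect_corners(
                build_pair_table(gm, m, m + 1), small_sample_n=small_sample_n
            )
            if status.monomorphic:
                continue
            if status.n_haplotypes == 2:
                n_full_ld += 1
            elif status.n_haplotypes == 3:
                n_three_hap += 1
                phased = phase_pair(gm, m, m + 1, status)
                if len(phased) != gm.n_individuals:
                    continue  # CA needs every individual phased
                dosage = third_haplotype_dosage(phased, status)
                rec = association_test(
                    dosage,
                    pheno,
                    null,
                    marker=s1.id,
                    chrom=s1.chrom,
                    bp=f"{s1.pos}-{s2.pos}",
                    test_type="CA",
                )
                if rec is not None:
                    records.append(rec)

    if not records:
        raise ValueError("no testable markers")
    m_eff = effective_tests(gm.n_snps, n_full_ld, n_three_hap)
    p_adj, sig = bh_adjust(np.array([r.p_raw for r in records]), m_eff, alpha)
    for r, a, s_ in zip(records, p_adj, sig):
        r.p_adj = float(a)
        r.significant = bool(s_)

    out = pd.DataFrame(
        {
            "Marker": [r.marker for r in records],
            "Chr": [r.chrom for r in records],
            "bp": [r.bp for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "Testing": [r.test_type for r in records],
            "Effect": [r.effect for r in records],
            "SE": [r.se for r in records],
            "significant": [r.significant for r in records],
        }
    )
    out["_start"] = out["bp"].str.split("-").str[0].astype(int)
    out = out.sort_values(["Chr", "_start"]).drop(columns="_start").reset_index(drop=True)
    out.attrs["m_eff"] = m_eff
    out.attrs["n_full_ld_pairs"] = n_full_ld
    out.attrs["n_three_hap_pairs"] = n_three_hap
    out.attrs["null_fit"] = null
    return out


def manhattan_plot(gwas_table: pd.DataFrame, path: str) -> None:
    """Basic Manhattan scatter of -log10 raw p by position (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = gwas_table.copy()
    df["pos"] = df["bp"].str.split("-").str[0].astype(int)
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(df.groupby("Chr", sort=False)):
        ax.scatter(
            grp["pos"] + offset,
            -np.log10(grp["p_raw"]),
            s=8,
            color=f"C{i % 2}",
            label=str(chrom),
        )
        offset += grp["pos"].max()
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
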