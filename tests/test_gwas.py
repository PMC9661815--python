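import warnings

import numpy as np
import pandas as pd
import pytest

from cornerphase import (
    GenotypeMatrix,
    PhenotypeTable,
    SimSpec,
    SnpMeta,
    association_test,
    bh_adjust,
    build_pair_table,
    detect_corners,
    effective_tests,
    fit_null_lmm,
    phase_pair,
    run_gwas,
    simulate_pair_genotypes,
    simulate_phenotypes,
    third_haplotype_dosage,
    vanraden_grm,
)


def random_genome(n=200, n_snps=150, seed=0, chrom="1"):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, n_snps)
    d = rng.binomial(2, p, size=(n, n_snps)).astype(np.int8)
    snps = [
        SnpMeta(id=f"s{m}", chrom=chrom, pos=1000 * (m + 1), ref_allele="A", alt_allele="G")
        for m in range(n_snps)
    ]
    return GenotypeMatrix(snps=snps, dosages=d, sample_ids=[f"i{k}" for k in range(n)])


def _pheno(y, sample_ids, **factor_cols):
    data = {"sample_id": sample_ids, "y": y, **factor_cols}
    return PhenotypeTable(
        data=pd.DataFrame(data), trait="y", factors=tuple(factor_cols.keys())
    )


class TestThirdHaplotypeDosage:
    def test_counts_complement_of_missing(self):
        gm, truth = simulate_pair_genotypes(
            {"AB": 0.0, "Ab": 0.5, "aB": 0.3, "ab": 0.2}, 400, seed=1
        )
        table = build_pair_table(gm, 0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            status = detect_corners(table, small_sample_n=0)
        phased = phase_pair(gm, 0, 1, status)
        dosage = third_haplotype_dosage(phased, status)
        # missing AB -> third haplotype is ab; compare with simulation truth
        true_dosage = ((truth.hap1 == "ab").to_numpy(int) + (truth.hap2 == "ab").to_numpy(int))
        np.testing.assert_array_equal(dosage, true_dosage)
        # identity: total copies = 2N * f_ab
        assert dosage.sum() == (truth[["hap1", "hap2"]] == "ab").sum().sum()

    def test_ca_dosage_complements_single_marker_tags(self):
        """With haplotypes {Ab, aB, ab}, tag dosages: SNP1 ref tags Ab, SNP2
        ref tags aB; third-hap copies = 2 - (#Ab + #aB)."""
        gm, truth = simulate_pair_genotypes(
            {"AB": 0.0, "Ab": 0.45, "aB": 0.35, "ab": 0.2}, 300, seed=2
        )
        table = build_pair_table(gm, 0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            status = detect_corners(table, small_sample_n=0)
        phased = phase_pair(gm, 0, 1, status)
        ca = third_haplotype_dosage(phased, status)
        n_Ab = np.array([(p.hap1 == "Ab") + (p.hap2 == "Ab") for p in phased])
        n_aB = np.array([(p.hap1 == "aB") + (p.hap2 == "aB") for p in phased])
        np.testing.assert_array_equal(ca, 2 - n_Ab - n_aB)

    def test_requires_three_haplotypes(self):
        gm, _ = simulate_pair_genotypes({"AB": 0.5, "ab": 0.5}, 100, seed=3)
        table = build_pair_table(gm, 0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            status = detect_corners(table, small_sample_n=0)
        phased = phase_pair(gm, 0, 1, status)
        with pytest.raises(ValueError):
            third_haplotype_dosage(phased, status)


class TestVanRadenGrm:
    def test_toy_matrix_hand_computation(self):
        d = np.array([[0, 1, 2, 1], [2, 1, 0, 0], [1, 2, 1, 1]], dtype=np.int8)
        snps = [
            SnpMeta(id=f"s{m}", chrom="1", pos=m + 1, ref_allele="A", alt_allele="G")
            for m in range(4)
        ]
        gm = GenotypeMatrix(snps=snps, dosages=d, sample_ids=["a", "b", "c"])
        p = d.mean(axis=0) / 2
        Z = d - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(vanraden_grm(gm), expected, atol=1e-12)

    def test_duplicate_individuals(self):
        d = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 0, 1]], dtype=np.int8)
        snps = [
            SnpMeta(id=f"s{m}", chrom="1", pos=m + 1, ref_allele="A", alt_allele="G")
            for m in range(3)
        ]
        gm = GenotypeMatrix(snps=snps, dosages=d, sample_ids=list("abcd"))
        G = vanraden_grm(gm)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_centering_zeroes_column_sums(self):
        gm = random_genome(50, 30, seed=4)
        d = gm.dosages.astype(float)
        Z = d - d.mean(axis=0)
        np.testing.assert_allclose(Z.sum(axis=0), 0.0, atol=1e-9)

    def test_monomorphic_only_raises(self):
        d = np.zeros((4, 3), dtype=np.int8)
        snps = [
            SnpMeta(id=f"s{m}", chrom="1", pos=m + 1, ref_allele="A", alt_allele="G")
            for m in range(3)
        ]
        gm = GenotypeMatrix(snps=snps, dosages=d, sample_ids=list("abcd"))
        with pytest.raises(ValueError):
            vanraden_grm(gm)


class TestNullLmm:
    def test_variance_component_recovery(self):
        gm = random_genome(500, 400, seed=5)
        G = vanraden_grm(gm)
        spec = SimSpec(n_individuals=500, sigma2_a=1.0, sigma2_e=1.0, seed=6)
        pheno, _ = simulate_phenotypes(gm, None, spec, grm=G)
        fit = fit_null_lmm(pheno, G)
        assert fit.sigma2_a == pytest.approx(1.0, abs=0.5)
        assert fit.sigma2_e == pytest.approx(1.0, abs=0.4)

    def test_zero_heritability_limit(self):
        gm = random_genome(300, 200, seed=7)
        G = vanraden_grm(gm)
        spec = SimSpec(n_individuals=300, sigma2_a=0.0, sigma2_e=1.0, seed=8)
        pheno, _ = simulate_phenotypes(gm, None, spec, grm=G)
        fit = fit_null_lmm(pheno, G)
        assert fit.heritability < 0.15

    def test_relabeling_invariance(self):
        gm = random_genome(120, 80, seed=9)
        G = vanraden_grm(gm)
        spec = SimSpec(n_individuals=120, sigma2_a=1.0, sigma2_e=1.0, seed=10)
        pheno, _ = simulate_phenotypes(gm, None, spec, grm=G)
        fit = fit_null_lmm(pheno, G)
        perm = np.random.default_rng(11).permutation(120)
        pheno_p = PhenotypeTable(
            data=pheno.data.iloc[perm].reset_index(drop=True), trait="y"
        )
        fit_p = fit_null_lmm(pheno_p, G[np.ix_(perm, perm)])
        assert fit_p.sigma2_a == pytest.approx(fit.sigma2_a, rel=1e-4, abs=1e-6)
        assert fit_p.sigma2_e == pytest.approx(fit.sigma2_e, rel=1e-4)


class TestAssociationTest:
    def test_zero_variance_dosage_skipped(self):
        gm = random_genome(100, 60, seed=12)
        G = vanraden_grm(gm)
        spec = SimSpec(n_individuals=100, seed=13)
        pheno, _ = simulate_phenotypes(gm, None, spec, grm=G)
        fit = fit_null_lmm(pheno, G)
        assert association_test(np.ones(100), pheno, fit) is None

    def test_effect_recovery(self):
        """Mean estimate over 60 replicates covers the simulated effect."""
        gm = random_genome(435, 300, seed=14)
        G = vanraden_grm(gm)
        chol = np.linalg.cholesky(G + 1e-8 * np.eye(435))
        spec = SimSpec(
            n_individuals=435, haplotype_effect=0.5, sigma2_a=1.0, sigma2_e=1.0
        )
        rng = np.random.default_rng(15)
        est = []
        for _ in range(60):
            gmp, truth = simulate_pair_genotypes(
                {"AB": 0.0, "Ab": 0.45, "aB": 0.35, "ab": 0.2}, 435, seed=rng
            )
            dosage = ((truth.hap1 == "ab").to_numpy(float) + (truth.hap2 == "ab").to_numpy(float))
            pheno, _ = simulate_phenotypes(gmp, dosage, spec, seed=rng, grm_chol=chol)
            fit = fit_null_lmm(pheno, G)
            est.append(association_test(dosage, pheno, fit).effect)
        est = np.array(est)
        ci = 1.96 * est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) < ci + 0.02


class TestEmmaxApproximation:
    def test_fixed_vc_agrees_with_per_test_reml(self):
        """Holding null variance components fixed (EMMAX) tracks full
        per-test REML: p-values agree within ~10% on the -log10 scale."""
        from scipy import optimize, stats

        from cornerphase.gwas import _reml_neg_loglik

        def per_test_reml_p(x, pheno, G):
            y, W = pheno.design()
            X = np.column_stack([W, x])
            s, U = np.linalg.eigh(G)
            s = np.clip(s, 0, None)
            yr, Xr = U.T @ y, U.T @ X
            res = optimize.minimize_scalar(
                lambda ll: _reml_neg_loglik(ll, yr, Xr, s)[0],
                bounds=(-12, 12),
                method="bounded",
            )
            _, s2e, _ = _reml_neg_loglik(res.x, yr, Xr, s)
            v = np.exp(res.x) * s2e * s + s2e
            Xv = Xr / v[:, None]
            A = Xr.T @ Xv
            b = np.linalg.solve(A, Xv.T @ yr)
            z = b[-1] / np.sqrt(np.linalg.inv(A)[-1, -1])
            return 2 * stats.norm.sf(abs(z))

        rng = np.random.default_rng(3)
        gaps = []
        for _ in range(20):
            gm = random_genome(200, 150, seed=rng.integers(2**31))
            G = vanraden_grm(gm)
            x = rng.binomial(2, 0.3, 200).astype(float)
            spec = SimSpec(
                n_individuals=200, haplotype_effect=0.3, sigma2_a=1.0, sigma2_e=1.0
            )
            pheno, _ = simulate_phenotypes(gm, x, spec, seed=rng, grm=G)
            fit = fit_null_lmm(pheno, G)
            l_emmax = -np.log10(association_test(x, pheno, fit).p_raw)
            l_full = -np.log10(per_test_reml_p(x, pheno, G))
            gaps.append(abs(l_emmax - l_full) / max(l_full, 0.5))
        assert float(np.median(gaps)) < 0.10


class TestEffectiveTests:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((20339, 3578, 10380), 11630),
            ((500, 0, 0), 500),
            ((100, 10, 30), 75),
        ],
    )
    def test_formula(self, args, expected):
        assert effective_tests(*args) == expected

    def test_nonpositive_result_raises(self):
        with pytest.raises(ValueError):
            effective_tests(10, 0, 100)


class TestBhAdjust:
    def test_single_p(self):
        adj, sig = bh_adjust(np.array([0.01]), m_eff=1)
        assert adj[0] == pytest.approx(0.01)
        assert sig[0]

    def test_hand_computation(self):
        adj, _ = bh_adjust(np.array([0.001, 0.02, 0.9]), m_eff=3)
        np.testing.assert_allclose(adj, [0.003, 0.03, 0.9])

    def test_reduces_to_standard_bh(self):
        """With m_eff equal to the test count our step-up equals statsmodels."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(16)
        p = rng.uniform(1e-6, 1, 50)
        adj, sig = bh_adjust(p, m_eff=None, alpha=0.05)
        _, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, adj_sm, atol=1e-12)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(1e-4, 1, 200)
        adj, _ = bh_adjust(p, m_eff=120)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_smaller_m_eff_is_less_conservative(self):
        p = np.linspace(0.001, 0.5, 20)
        adj_full, _ = bh_adjust(p, m_eff=1000)
        adj_eff, _ = bh_adjust(p, m_eff=500)
        assert (adj_eff <= adj_full + 1e-12).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([]))


@pytest.fixture(scope="module")
def causal_scan():
    """Genome with one pair whose third haplotype is causal but whose two
    tag haplotypes have equal means, hiding the signal from SM tests."""
    n = 435
    gm_bg = random_genome(n, 120, seed=19)
    gmp, truth = simulate_pair_genotypes(
        {"AB": 0.0, "Ab": 0.4, "aB": 0.4, "ab": 0.2}, n, seed=20
    )
    # splice the causal pair into the middle of the background genome
    snps = list(gm_bg.snps)
    pos = snps[60].pos + 1
    pair_snps = [
        SnpMeta(id="pairL", chrom="1", pos=pos, ref_allele="A", alt_allele="G"),
        SnpMeta(id="pairR", chrom="1", pos=pos + 1, ref_allele="A", alt_allele="G"),
    ]
    snps = snps[:61] + pair_snps + snps[61:]
    d = np.concatenate(
        [gm_bg.dosages[:, :61], gmp.dosages, gm_bg.dosages[:, 61:]], axis=1
    )
    gm = GenotypeMatrix(snps=snps, dosages=d, sample_ids=gm_bg.sample_ids)
    dosage = ((truth.hap1 == "ab").to_numpy(float) + (truth.hap2 == "ab").to_numpy(float))
    spec = SimSpec(
        n_individuals=n, haplotype_effect=0.7, sigma2_a=0.5, sigma2_e=1.0,
        factor_levels={"parity": [1, 2, 3]},
    )
    pheno, _ = simulate_phenotypes(gm, dosage, spec, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_gwas(gm, pheno, alpha=0.05)
    return result


class TestRunGwas:

    def test_causal_third_haplotype_detected(self, causal_scan):
        ca = causal_scan[(causal_scan.Testing == "CA") & (causal_scan.Marker == "pairL")]
        assert len(ca) == 1
        assert ca.iloc[0].significant
        sm = causal_scan[
            (causal_scan.Testing == "SM")
            & causal_scan.Marker.isin(["pairL", "pairR"])
        ]
        assert (sm.p_raw > ca.iloc[0].p_raw).all()

    def test_ca_bp_reports_pair_range(self, causal_scan):
        ca = causal_scan[(causal_scan.Testing == "CA") & (causal_scan.Marker == "pairL")]
        start, end = ca.iloc[0].bp.split("-")
        assert int(end) == int(start) + 1

    def test_m_eff_accounts_for_pair_classes(self, causal_scan):
        m_eff = causal_scan.attrs["m_eff"]
        expected = effective_tests(
            122,
            causal_scan.attrs["n_full_ld_pairs"],
            causal_scan.attrs["n_three_hap_pairs"],
        )
        assert m_eff == expected
        assert causal_scan.attrs["n_three_hap_pairs"] >= 1

    def test_null_genome_fdr_controlled(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = random_genome(300, 100, seed=22)
            spec = SimSpec(n_individuals=300, sigma2_a=0.5, sigma2_e=1.0, seed=23)
            pheno, _ = simulate_phenotypes(gm, None, spec)
            result = run_gwas(gm, pheno, alpha=0.05)
        assert int(result["significant"].sum()) == 0
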