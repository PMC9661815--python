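# Methods

## Model and assumptions

The core primitive is exact phasing of a two-locus system from the 3×3 table
of genotype counts. The inference "corner empty ⇒ haplotype absent in the
population" is valid under two assumptions:

1. **Sampling**: a haplotype present in the population at non-trivial
   frequency is very unlikely to leave all three of its corner cells empty
   in a sample of a few hundred individuals. The package surfaces this as a
   `SmallSampleWarning` when the pair's complete-case count N falls below a
   configurable threshold (default 50); the behaviour itself never changes
   with N — "empty" always means exactly zero, with no pseudo-counts.
2. **No genotyping error**: a single miscalled genotype can empty or fill a
   corner. The package treats error detection as a first-class output: on
   clean data the exact estimator and the EM baseline agree closely, so the
   comparison table flags pairs with |Δr²| ≥ 0.04 (configurable) as likely
   genotyping errors rather than silently averaging them away.

Corner geometry: corners I–IV require haplotypes `AB`, `Ab`, `aB`, `ab`
respectively, with cell sets I = {AABB, AABb, AaBB}, II = {AABb, AAbb,
Aabb}, III = {AaBB, aaBB, aaBb}, IV = {Aabb, aaBb, aabb}. Opposite pairs
are {I, IV} and {II, III}: these are the pairs whose two missing haplotypes
leave both loci polymorphic (missing `AB`+`ab` leaves `Ab`,`aB`; missing
`Ab`+`aB` leaves `AB`,`ab`). Any other description of "opposite" would
make one locus monomorphic and is geometrically inconsistent with the cell
sets above, so the package implements this pairing.

### Adjacent-corner ties

Two adjacent (non-opposite) empty corners imply conflicting double-
heterozygote phases that the data cannot distinguish: e.g. with only
`AA·` rows and the centre cell occupied, both "missing `aB`" and "missing
`ab`" explain the table. The package breaks the tie by the fixed precedence
IV > III > II > I, flags the result `ambiguous=True`, and logs a warning.
The precedence order is the one that reproduces the canonical chromosome-2
worked example (frequencies 0.90/0.06/0.04/0.00 with `ab` missing); it is a
reporting convention, not an inference — downstream consumers (region
assembly, the allele table) treat ambiguous pairs conservatively, excluding
affected individuals rather than guessing.

## LD estimation

Direct estimates are gamete counts over 2N gametes: every genotype except
`AaBb` contributes its two forced gametes, and the n_AaBb double
heterozygotes contribute the two haplotypes of the forced phase. The missing
haplotype's frequency is exactly 0 by construction. `r2_direct` implements
the closed-form expression in raw genotype counts (for a missing `AB`:
`r² = [(2n_AAbb+n_AABb+n_Aabb+n_AaBb)(2n_aaBB+n_AaBB+n_aaBb+n_AaBb) /
sqrt((2n_AA+n_Aa)(2n_aa+n_Aa)(2n_BB+n_Bb)(2n_bb+n_Bb))]²`, the other
corners by allele relabeling); the test suite asserts it equals the generic
`D²/(f_A f_a f_B f_b)` route to 1e-12.

The EM baseline is the standard two-locus estimator under Hardy–Weinberg:
the E-step allocates each double heterozygote to the `AB/ab` phase with
responsibility `f_AB f_ab / (f_AB f_ab + f_Ab f_aB)`, the M-step recounts
gametes. Defaults: linkage-equilibrium initialization (product of marginal
allele frequencies — deterministic and, in our experience, convergent in
well under 100 iterations on desk-scale tables), tolerance 1e-10 on the max
absolute frequency change, max 10,000 iterations, optional Dirichlet random
restarts keeping the highest multinomial log-likelihood (small samples can
make the likelihood multimodal). The log-likelihood is computed over the
nine HWE genotype-class probabilities and is asserted non-decreasing in the
tests.

D′ uses the Lewontin convention: `D_max = min(f_A f_b, f_a f_B)` for D > 0
and `min(f_A f_B, f_a f_b)` for D < 0, with D′ = 0 when D = 0. LD is
reported as undefined (an error naming the locus) when either locus is
monomorphic.

## Region haplotyping

A region is a maximal run of consecutive SNPs in which every pair —
consecutive and nonconsecutive — has at most three segregating haplotypes.
The all-pairs property is hereditary, so the scan is an exact two-pointer
sweep maintaining the smallest valid left end per right end; maximal
windows can overlap at boundaries, and both are reported (the later one
flagged) rather than arbitrarily truncated. Minimum region size is 2 SNPs.

Assembly per individual: each pair of heterozygous SNPs contributes a
parity constraint — phase `AB/ab` puts the two reference alleles on the
same haplotype ("cis"), `Ab/aB` on opposite ones. Constraints are
propagated from the first heterozygous SNP and every remaining pair is then
checked; a contradiction around a cycle (possible only under genotyping
error, since clean data satisfy all constraints simultaneously) raises an
assembly error naming the individual and a conflicting triple. Homozygous
positions are filled identically on both strings. Individuals that need an
ambiguous pairwise phase are excluded from the haplotype-frequency table
with a logged count instead of being guessed; complete genotypes across the
region are required because one missing call destroys exactness for that
individual.

Scores on the resulting multi-allelic marker: expected heterozygosity
`H = 1 − Σ f_i²` and polymorphism information content in the Botstein
convention `PIC = 1 − Σ f_i² − Σ_{i<j} 2 f_i² f_j²`, computed via the power
sums `Σf²` and `Σf⁴` so that the cross term is `(Σf²)² − Σf⁴`; PIC ≤ H
holds for any allele-frequency table.

## GWAS

Model: `y = Wb + xg + a + e`, `a ~ N(0, G σ²_a)`, `e ~ N(0, I σ²_e)`; W is
an intercept plus reference-coded factor dummies (factor names are
configurable, e.g. parity classes capped at 6 and farrowing season), x is a
0/1/2 allele dosage (SM test) or third-haplotype dosage (CA test), and G is
VanRaden's genomic relationship matrix `ZZ′/(2Σp_j(1−p_j))` with Z centered
at `2p_j`.

Variance components are estimated once by REML on the null model (`g`
excluded) and held fixed for every test — the EMMAX approximation. REML is
profiled in λ = σ²_a/σ²_e on the spectral decomposition of G, so one
eigendecomposition serves the optimization (bounded scalar search on log λ
in [−12, 12], with an explicit check of the λ = 0 boundary) and afterwards
every association test, each of which reduces to a weighted least-squares
fit in the rotated basis. p-values are two-sided Wald tests on the dosage
coefficient's z-statistic; at the sample sizes this package targets
(hundreds of individuals, a handful of fixed effects) the normal and t
reference distributions are indistinguishable in the fourth decimal. The
tests verify the approximation empirically: type-I error at nominal 0.05
within [0.04, 0.06] over 2,000 null tests, and unbiased recovery of a
simulated substitution effect.

Multiple testing: Benjamini–Hochberg step-up with an *effective* number of
tests `m_eff = n_snps − n_full_LD_pairs/2 − (2/3)·n_three_hap_pairs`
(rounded to nearest integer), reflecting that the SM test of a pair in
complete LD is fully redundant and that the three tests of a
three-haplotype pair each contrast one haplotype against the other two and
are pairwise correlated. All SM and CA p-values are adjusted jointly in one
pool. With m_eff equal to the raw test count the procedure reduces exactly
to standard BH (asserted against statsmodels in the tests).

## Synthetic data

Generators draw each individual as an independent random union of two
gametes from a haplotype pool — Hardy–Weinberg at the haplotype level,
which is precisely the assumption under which the EM baseline is the
natural comparator. Truth (gamete identities, haplotype pairs, phenotype
components) is always returned alongside the observations so recovery
tests never re-derive it. Phenotypes add factor effects, the causal
haplotype effect `g·dosage`, a polygenic term drawn through the Cholesky
factor of G (ridge 1e-8 for rank-deficient G), and i.i.d. noise.
Genotyping errors flip each non-missing genotype to a uniformly chosen
different value with the given rate.

What the generator does *not* emulate: linkage between the background SNPs
used for the GRM (they are drawn independently), family structure beyond
what the GRM induces, allele-frequency spectra of real arrays, and
systematic (non-random) genotyping error. Passing tests therefore
demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to violations such as pervasive genotyping
artefacts — those are surfaced, by design, as discordance flags and
assembly errors rather than absorbed.

## Problem sizes and numerical choices

The test and acceptance workloads use the canonical sample size of 435
individuals for worked examples and statistical checks (2,000 null tests,
200 effect-recovery replicates, 1,000 simulated pairs for the
method-equivalence check), and a few hundred background SNPs for GRM
construction — ample for the binomial tolerances asserted, while keeping a
full run in tens of seconds. Frequencies are validated to sum to 1 within
1e-9; exact-phasing identities are asserted at 1e-12; the EM convergence
tolerance is 1e-10.

## Known limitations

- No phasing is attempted when four haplotypes segregate; that is the
  domain of statistical phasers (PHASE/Beagle-style), explicitly out of
  scope.
- The adjacent-corner precedence is a convention; results carrying the
  ambiguity flag should be interpreted with the alternative phasing in
  mind.
- Per-pair complete-case analysis (the default outside regions) can use
  slightly different N per pair when data are missing; region assembly
  requires complete data.
- The EMMAX approximation holds variance components fixed across tests;
  for traits with very large single-locus effects a full per-test REML
  would differ slightly.
- Array-level QC (call rates, clustering scores), assembly liftover and
  pedigree checks are upstream concerns, not handled here.
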