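# Methods

`qkmgwas` implements the statistical core of a drought-resistance
(metabolite-)GWAS in a structured crop diversity panel: wilting-grade
phenotyping, a kinship-aware linear mixed model, locus clumping,
metabolomics differential statistics, and haplotype association — plus a
synthetic-cohort generator that reproduces the data structure those
analyses assume, with a ground-truth ledger for recovery testing.

## Phenotype scoring

Wilting rates (wilted leaves / total leaves, counted per replicate at
72, 96 and 120 h of drought) map to ordinal grades: grade 0 iff the rate
is exactly 0, then half-open bins (0, 0.25] → 1, (0.25, 0.5] → 2,
(0.5, 0.75] → 3, (0.75, 1] → 4. The bin edges are half-open because the
grade definitions are phrased in whole percent ("1% to 25%"); half-open
intervals extend them consistently to fractional rates, and 0.25 itself
stays in the lower band.

The drought-sensitivity index (DSI) averages replicates within each
timepoint first, then averages the three timepoint means. A timepoint
with no non-NA replicate makes the DSI NA; partial replicate NA is
tolerated. Replicates are graded individually and grades averaged (not
rates averaged then graded) — the two orders differ near bin edges, and
grading first matches how replicate-level grade heatmaps are built.

Extreme-group selection is a pure DSI ranking (k lowest = R, k highest =
S, ties broken by accession ID). The original screen additionally used a
subjective between-replicate consistency judgement; a deterministic
ranking is reproducible and is what the recovery tests need. An optional
replicate-SD cap could be layered on top but is off by default.

## Mixed-model association scan

The model per marker is `y = x*beta + Q*alpha + g + e` with
`g ~ N(0, sigma_g^2 K)` and `e ~ N(0, sigma_e^2 I)`. `Q` is an intercept
plus principal components of the standardized, LD-pruned dosage matrix
(default 6 PCs, mirroring the K=6 ancestry model used for the real
panel; PCs are the standard LMM structure proxy and avoid re-implementing
admixture block relaxation). `K` is the centered cross-product kinship
`Xc Xc'/m`.

Variance components: `K` is eigendecomposed once; the ratio
`delta = sigma_e^2/sigma_g^2` is profiled on the rotated data over a
100-point log grid on [1e-5, 1e5] followed by bounded Brent refinement
(deterministic), with the scale parameter in closed form. REML is the
default; ML is available. `K` is rescaled internally to unit mean
diagonal so the reported pseudo-heritability
`sigma_g^2/(sigma_g^2+sigma_e^2)` is a variance fraction. This
pseudo-h2 is a proxy for broad-sense heritability, not a replicate-based
H^2 estimate.

The scan runs generalized least squares in the eigenbasis, reusing the
null delta per SNP by default (the fast standard approximation) with an
exact per-SNP re-optimization option; the two agree to |Δlog10 p| < 0.3
on null panels. The per-SNP residual scale is re-estimated with
df = n − q − 1, so with K = I and an intercept-only design the statistic
is exactly the OLS t-square, and its chi-square(1) P-value matches the
closed-form OLS P-value — that equivalence is a test oracle. Missing
dosages are mean-imputed; monomorphic markers are flagged with beta = 0,
p = 1. Per-SNP PVE uses the conventional marginal definition
`beta^2 Var(x)/Var(y)`, clipped to [0, 1]; no formula is published for
the original analysis, so the definition is validated by recovery of
planted PVE targets instead.

Desk-scale caveat: on panels of a few hundred markers, a tested SNP's
own LD block contributes appreciably to `K` and the random effect
absorbs its signal (proximal contamination). `loco_kinship` builds `K`
from all chromosomes except the tested one; the planted-QTL recovery
scenario uses it, which is the faithful analogue of a 7.7M-SNP kinship
where any single locus is negligible.

The genome-wide threshold is `alpha / n_effective` with the effective
(LD-pruned) SNP count; 0.05 / 1,174,039 reproduces the published
4.26e-8. Genomic-control lambda is the median observed chi-square over
the chi-square(1) median (0.4549).

## Locus clumping

Significant SNPs (sorted, de-duplicated) chain by single linkage:
consecutive markers on one chromosome join a locus iff their gap is
< 1 Mb. A chained locus spanning > 30 Mb is abandoned — its member SNPs
are discarded with it, not released for re-chaining (the rule's
phrasing leaves this open; discarding is the conservative reading).
Loci with fewer than six members are dropped ("more than five" read
strictly as ≥ 6; configurable). The lead SNP is the lowest-P member,
ties broken by smallest position. Locus boundaries are the min/max
member positions. Colocalization between trait and metabolite loci is
closed-interval intersection on the same chromosome; hotspot density
counts lead SNPs in 5 Mb tiling windows.

## Genotype QC

MAF is computed on non-missing alleles; filters keep MAF ≥ 0.05 and
missingness ≤ 0.1 (no HWE filter, matching the original pipeline's
`-hwe 0.0`). LD pruning slides 50-SNP windows advancing by 5 within a
chromosome; within a window the lower-MAF member of any pair with
pairwise-complete r² > 0.2 is removed (tie: later position). Window
sweeps repeat until a full pass removes nothing, which makes pruning of
an already-pruned set a no-op. Nucleotide diversity uses the per-site
unbiased heterozygosity `2p(1-p)·2N/(2N-1)` summed over half-open 1 Mb
windows and divided by the window length in bp (the windowed-pi tool
convention), 1-based coordinates internally, BED-like 0-based output.

## Metabolomics statistics

Differential calling applies three simultaneous criteria: PLS-DA
VIP > 1.0, raw-mean fold change ≥ 1.5 or ≤ 0.67, and adjusted Student
t-test P < 0.05. Choices the source workflow leaves unstated: the
adjustment is Benjamini–Hochberg across features (the cited R package's
default; Bonferroni available), the t-test is pooled-variance Student
(Welch toggle provided) and unpaired by default (a paired option exists
since CK/DS samples share accessions), fold changes are ratios of raw
group means while tests run on log2 values, and the PLS-DA uses two
components on autoscaled log2 data with a ±1 dummy response. VIP is
`sqrt(p · Σ_a SSY_a (w_aj/||w_a||)² / Σ_a SSY_a)`, which conserves
Σ VIP² = p on every fit (an exact algebraic identity used as a test).
The PLS fit itself is scikit-learn's NIPALS `PLSRegression`; the VIP
computation is this package's.

The four-group framework compares |log2 FC| distributions of the two
induced contrasts (R_DS/R_CK, S_DS/S_CK) against the two constitutive
contrasts (R_CK/S_CK, R_DS/S_DS) with two-sided Wilcoxon rank-sum
tests. Classification formalizes the narrative categories: *inducible*
= called in the cohort-wide DS-vs-CK comparison; *constitutive
differential* = called with the same direction in R-vs-S under both
conditions but not cohort-wide induced; *both* and *neither* complete
the partition.

Sample trees binarize each feature at its cohort median (≥ median → 1)
— the source does not state how continuous abundances became
match/mismatch data, and the median split is scale-free and balanced —
then apply Saitou–Nei neighbor joining (scikit-bio) to the simple
matching distance, clamping negative branch lengths to zero. Spearman
matrices use tie-corrected ranks with BH-adjusted P-values; constant
features give NA rows.

## Haplotype association

Genotype states (hom-ref/het/hom-alt) at the chosen SNPs concatenate
into unphased haplotype classes — heterozygotes form their own state
because phasing is unavailable and single-SNP analyses in this setting
treat hets as a group. Accessions with any missing constituent are
excluded from frequencies. One-way ANOVA is followed by Fisher's
protected LSD (pairwise t on the pooled within-group mean square,
no multiplicity correction, as the procedure defines) and an
insert-and-absorb compact letter display; classes sharing no letter
differ at alpha. Allele composition per phenotype group uses Fisher's
exact test on the 2×2 allele table for two groups and a chi-square
contingency test otherwise (no general r×c exact test is available in
the stack).

## Synthetic cohort

Genotypes follow the Balding–Nichols model: ancestral frequency
p0 ~ Uniform(maf_range), subpopulation frequency
Beta(p0(1−F)/F, (1−p0)(1−F)/F) (limit p0 at F = 0). LD is first-order
Markov copying within blocks (default 20 SNPs, copy probability 0.9),
the simplest process with tunable pairwise r² for pruning tests.
Dosages are sums of two haplotypes; missingness is uniform.

Metabolites are built on the log2 scale: a baseline ~ N(14, 2) (typical
log2 LC-MS intensity), planted SNP effects with beta = sqrt(PVE) on the
standardized dosage, a polygenic term drawn through the square root of
the realized kinship and scaled to the background heritability, and
Gaussian noise filling a unit variance budget. The polygenic draw is
orthogonalized against the planted dosages so the marginal variance
fraction at each QTL equals its PVE target (without this, structure and
LD push the realized marginal R² well above target). Heritabilities are
Beta-distributed with mean 0.54 (the panel's average H²,
concentration 10). DS values share the genetic part, add the induction
log2 fold change and redraw the residual; by default ~11% of features
are induced with fold changes 1.5–5× and 89% of them up (268 up / 34
down of 302 responsive features in the real panel). Constitutive R−S
offsets are added to R-group accessions under both conditions.

Wilting liability is `effect × causal dosage + N(0, sd)`; the wilting
rate is a logistic function of liability plus an increasing per-timepoint
offset, so rates and grades are monotone in both liability and time.
Replicates share the accession liability and add their own noise (sd
0.3 by default — the within-accession replicate variance is not
published, so it is a free parameter); counts are on 45 leaves
(15 plants × 3 leaves). NA grades are injected only when configured.

Default study conditions: 246 accessions, 6 subpopulations, Fst 0.10
(not published; typical of landrace collections), MAF in [0.05, 0.5],
5% missing calls, 3 replicates. All randomness derives from one seed via
counter-based per-stage streams, so fixed (config, seed) reproduces
every matrix and file byte-identically.

What the generator does *not* emulate: realistic recombination maps or
allele-frequency spectra, mass-spectral noise and annotation ambiguity,
batch effects, or genotype-by-environment interaction beyond a single
additive induction shift. Passing recovery tests therefore show the
*methods* behave as specified under the assumed generative model, not
that real data meet those assumptions.

## Problem sizes used in validation

Validation scenarios are desk-scale by design: null calibration uses
10,000 independent markers at n = 246; QTL recovery uses 700 markers
per seed over 50 seeds with LOCO kinship; pseudo-h² recovery uses 500
markers over 25 seeds; locus-rule fuzzing uses 1,000 random inputs;
differential/classification recovery uses 40 features at n = 246 plus
1,000 null features for the FDR budget.

## Numerical choices and degenerate inputs

Delta optimization is a deterministic grid + bounded refinement;
eigenvalues are clipped at zero. Monomorphic SNPs: p = 1 and flagged in
scans, rejected in genotype-class tests, r² = 0 in pruning. Constant
features: all-zero under min-max, NA in Spearman, dropped classes warn
in ANOVA. Zero-variance/equal-mean t-tests return p = 1. PCA and PC
score signs are fixed by making each component's largest-magnitude
loading positive. Ties: LD pruning drops the later position, lead SNPs
take the smaller position, extreme-group ranking falls back to
accession ID.

## Known limitations

Pseudo-h² is a marker-based proxy, not replicate-based H². The exact
scan mode re-optimizes delta per SNP but still uses a Wald (not LRT)
test. Locus clumping assumes position-sorted biallelic SNPs; no
conditional or fine-mapping analysis is attempted. The published
cohort-level DSI summaries and π range depend on the deposited data and
are only recomputed when the supplementary grade table is supplied.
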