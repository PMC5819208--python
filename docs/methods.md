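# Methods

## The joint model

Let z_k = β_k / SE_k be the signed Wald statistic of one SNP for trait k,
k = 1..K (K = 2 or 3 here).  When the per-trait GWASs are computed on
overlapping subjects, the z_k are correlated even under the null; the
O'Brien approach treats **z** = (z_1..z_K) as multivariate normal with
covariance Σ and combines the coordinates into one statistic:

- GLS weighting (default): T = (1ᵀΣ⁻¹z)/√(1ᵀΣ⁻¹1).  This is the most
  powerful linear combination against the alternative of a shared effect of
  equal standardized size in every trait.
- Equal weighting: T = (1ᵀz)/√(1ᵀΣ1).

Both are exactly standard normal under the global null when Σ is the true
covariance.  Σ is estimated as the sample covariance of the Z matrix over
all M SNPs — valid because genuine signals occupy a vanishing fraction of
the genome; a `truncated` mode (rows with every |z| < 2) is available as a
robustness option for data with dense strong signals, at the cost of a
downward truncation bias in the off-diagonal.  The estimate is forced
symmetric positive definite by minimal diagonal inflation (eigenvalue
floor 1e-8).

A numerical remark: T as defined is *equivariant*, not invariant, to an
overall rescaling of Σ — T(cΣ) = T(Σ)/√c.  This is irrelevant in practice
because Σ estimated from Z statistics has a unit-scale diagonal, but it is
why the covariance (not correlation) matrix can be used verbatim: the two
differ only by that near-unit scale.

When both weightings are requested on an equicorrelated Σ they coincide
identically (Σ⁻¹1 ∝ 1), which is the common case for a homogeneous pair of
overlapping-cohort traits and makes discrepancies between the two runs
diagnostic of covariance-structure problems.

### Declaration rule

For a trait subset, a SNP is declared *pleiotropic* iff

    p_joint ≤ p_univ(k) / 10  for every member trait k,  and
    p_univ(k) < 0.05          for every member trait k,

and *GWS-pleiotropic* iff additionally p_joint < 5×10⁻⁸.  The
order-of-magnitude comparison is non-strict; the factor (10), nominal level
(0.05) and GWS threshold are parameters.  The rule deliberately requires
nominal support in *every* member trait, so a variant that is strong in one
trait and null in the other is not declared pleiotropic however small its
joint p.

All p-values are computed and carried in log₁₀ space.  A float64 two-sided
normal tail underflows near |z| = 38.5, so the log survival function is the
canonical representation; the scalar conversion returns an
extended-precision value in the extreme regime so p is never exactly 0 for
|z| ≤ 40 (beyond roughly |z| = 150 even extended precision underflows; the
log₁₀ p columns remain exact there).

### Diagnostics

Genomic-control λ is the median of the 1-df χ² quantiles of the observed
p-values divided by the null χ² median (≈ 0.4549); an optional region
exclusion (default APOE window chr19:44.4–46.5 Mb, GRCh37 — the region is
conventional, the coordinates are this package's choice) removes a known
strong locus before the median.  QQ tables use expected quantiles
rank/(n+1).

## Harmonization and QC

SNPs are keyed by (chrom, pos); rsIDs are annotation.  The first trait
fixes the effect-allele orientation; a trait listing the same two alleles
swapped has its β negated and frequency complemented; any other allele pair
is dropped with a count.  Strand-ambiguous (A/T, C/G) SNPs are kept and
matched by allele letters by default (`ambiguous_policy="drop"` removes
them); no strand complementing is attempted, which is the correct behaviour
when all inputs come from one imputation pipeline, as they do for both the
synthetic studies and the original meta-analyzed inputs this package
expects.  Duplicated positions (multi-allelic sites) are dropped entirely,
with a count.  QC exclusions are inclusive (≤) at MAF 0.01, imputation R²
0.4 and dosage variance 0.02, and a missing optional QC field passes its
rule — those filters were applied upstream, and absence of the column must
not erase data.  Input p-values are ignored and recomputed from β/SE so
univariate and joint p share one convention.

## Gene-based testing

A gene's SNP set is everything within `window` (default 30,000 bp,
inclusive bounds, 1-based coordinates; BED input is converted from 0-based
half-open on read) of the transcript span.  The observed statistic is
Q = Σ_j F⁻¹(1 − p_j) with F the 1-df χ² CDF, computed from log₁₀ p via the
log-scale inverse normal so arbitrarily small scan p-values contribute
correctly.  The null is simulated: z* ~ MVN(0, R) with R the Pearson
correlation of reference-panel dosages (0–2 scale), shrunk toward the
identity by the smallest intensity reaching eigenvalue 1e-8;
Q* = Σ z*²; the empirical p is (#{Q* ≥ Q} + 1)/(N + 1), which is
conservative and never zero — at N = 10⁶ the floor is ≈ 1.0×10⁻⁶.
Simulation escalates through stages (default 10³, 10⁴, 10⁶ draws) only
while fewer than 10 exceedances have been seen, so null genes resolve in
milliseconds and only genuinely extreme genes pay for the full ladder; the
stopping rule is this package's declared choice.  Per-gene streams are
spawned from one seed, so results are independent of gene order and
reproducible.  Multiple testing across genes is Bonferroni (e.g.
0.05/18,500 ≈ 2.7×10⁻⁶ at genome scale).

## Expression models

Both follow-up analyses are ordinary least squares per gene on normalized
expression — normalization (CQN for RNA-Seq counts, array pipelines for
microarray) is upstream of this package's contract, which requires
already-normalized matrices.

- DGE: expression ~ status + covariates.  Preset `mayo_rnaseq`: age at
  death, sex, RIN, tissue source, flow cell; preset `geo_microarray`: RIN,
  PMI, batch, preservation, pH, age, sex.  Both add the five cell-type
  marker genes, so a disease-driven shift in cell composition is absorbed
  by the markers instead of masquerading as differential expression of the
  target gene.  β < 0 means lower expression in AD.
- eQTL: expression ~ dosage + covariates (preset `mayo_egwas`: AD status,
  APOE-ε4 dosage, age, sex, plate, RIN, adjusted RIN), optionally within
  the AD or control stratum (status is dropped inside a stratum).  β is per
  effect-allele copy.

"Adjusted RIN" is implemented as (RIN − mean(RIN))², a centered quadratic
term.  The alternative literal reading RIN − mean(RIN)² is affine in RIN
and therefore exactly collinear with the RIN main effect — selecting
`rin_adjusted="verbatim"` surfaces that collinearity error, which is the
empirical argument for the centered-squared default.  Missing covariates
are handled by listwise deletion with the per-gene n reported; rank
deficiency raises an error naming the collinear columns.

## Synthetic data

The generator exists so every pipeline stage can be exercised against known
truth; its defaults are the study conditions, not tuning knobs.

- **Genotypes.** Two latent standard-normal haplotype fields per subject
  follow an AR(1) correlation (`rho_within`, default 0.8) inside blocks of
  `block_size` (default 50) SNPs, independent across blocks; each field is
  thresholded at the SNP's MAF (drawn uniform on (0.01, 0.5)) and the two
  allele indicators summed, giving Hardy-Weinberg dosages with blockwise
  LD.  Thresholding attenuates the latent correlation (more, the rarer the
  alleles), which is the expected behaviour of real LD on hard calls.
- **Traits.** Liabilities = standardized dosages × causal effects + MVN
  residual.  The three-trait residual correlations are *calibrated*: the
  user-facing targets (defaults NP–NFT 0.68, NP–CAA 0.56, NFT–CAA 0.40) are
  correlations of the observed discretized scores, and the latent values
  that realize them are solved by root finding on closed-form
  bivariate-normal orthant probabilities (no simulation in the
  calibration).  Cutpoints default to grade distributions skewed toward
  severe pathology, as expected in an AD-enriched autopsy series
  (NP 15/20/30/35%, NFT 10/20/35/35%, CAA 50/50%); AD status thresholds a
  liability composite at 87% cases.  Degenerate (infinite) cutpoints
  produce a single-level trait that the downstream fitter rejects — the
  generator does not.
- **Per-trait GWAS.** Ordinal traits are fit by proportional-odds logistic
  regression, CAA by logistic regression, using batched Newton solvers
  written for the genome-scale single-covariate case (tens of thousands of
  4-parameter fits per trait in seconds); standard errors come from the
  observed information, and statsmodels serves as the independent oracle in
  the tests.  Separation and non-convergence drop the SNP with a report.
  No population structure is simulated, so no ancestry principal components
  enter the fits — a documented divergence from cohort practice.
- **Scale note.** Liability effects are probit-like (Gaussian residual), so
  the fitted log-odds β for a liability effect is inflated by ≈ 1.7 and the
  cohort-level tests are about *ranks and calibration*, not β equality.
  Scale-faithful slope-recovery tests instead draw outcomes exactly from
  the proportional-odds model (logistic latent, `simulate_po_trait`).
- **Direct Z draws** (`simulate_z_direct`) provide the fast path for
  type-I/power studies: null rows MVN(0, Σ), signal rows mean-shifted on
  designated traits.
- **Expression studies** draw covariates, inject status and dosage effects,
  and optionally add a disease-driven cell-composition latent that loads on
  both the marker genes and the targets, so marker adjustment measurably
  attenuates the confound.

What passing these tests shows — and does not.  The generator emulates LD,
correlated ordinal pathology, case enrichment and cell-composition
confounding; it does not emulate population structure, imputation
uncertainty beyond a dosage-variance column, haplotype-level LD, batch
effects correlated with status, or phenotype measurement error across
centers.  Calibration and recovery on synthetic data therefore validate the
statistical machinery, not robustness to those real-data pathologies.

## Calibration experiments (desk scale)

`pleioscan.calibration` packages the standing experiments, reused by the
test suite and `scripts/acceptance.py`:

- `joint_null_calibration`: M = 10⁵ null Z rows at equicorrelation
  ρ ∈ {0, 0.4, 0.68}; type-I error at α = 0.05 and 10⁻³ within three
  binomial standard errors, λ within 1.00 ± 0.02, both weightings.
- `pleiotropy_recovery`: a cohort of n = 2,000 subjects × M = 20,000 SNPs
  with eight causal SNPs per architecture — dual (0.18 standardized
  liability effect on NP and NFT each), NP-only and NFT-only (0.18·√2, the
  same total effect).  The full pipeline runs and per-class declaration
  rates are compared at a desk-scale GWS threshold of 10⁻⁴ (with eight
  planted effects and n = 2,000, the conventional 5×10⁻⁸ would demand far
  larger cohorts).  The sizes are chosen so the per-trait dilution of the
  liability variance (24·0.18² ≈ 0.78 added variance per trait) is equal
  across NP and NFT — asymmetric dilution would bias the
  order-of-magnitude rule toward the less-diluted trait.
- `ordinal_beta_recovery`: 30 replicates of an injected log-odds 0.4 at
  MAF 0.3, n = 2,000, drawn exactly from the proportional-odds model.

## Numerical choices and degenerate inputs

- Positive-definiteness repairs (test covariance, LD matrices) use minimal
  diagonal inflation / identity shrinkage to an eigenvalue floor of 1e-8,
  with the applied intensity recorded on the object.
- The Newton solvers damp steps to max-norm 5, guard |β| at 15 (treated as
  separation), and require gradient max-norm < 1e-8·n; failures are flagged
  per SNP, never raised, because a genome scan must survive individual
  degenerate SNPs.
- Monte-Carlo gene tests draw in chunks of 10⁵ to bound memory; rank-
  deficient LD factors are handled by eigendecomposition with negative
  eigenvalues clipped at zero.
- Ties in QQ tables are kept; λ on an empty (post-exclusion) vector is an
  error rather than a NaN.
- Covariance estimation refuses fewer than 10·K rows.

## Known limitations

- The joint test is a test, not an estimator: no joint effect size is
  produced.
- The declaration rule's power is intrinsically limited for highly
  correlated traits (the GLS gain over the best univariate test shrinks as
  ρ → 1), so dual-effect variants in very correlated pairs may satisfy the
  GWS criterion yet fail the order-of-magnitude criterion.
- Gene-based results condition on the reference panel: a panel whose LD
  differs from the scanned population miscalibrates the null.
- No meta-analysis, imputation, liftover, proxy-SNP search, colocalization
  or pathway testing; normalized expression is a required input, never
  computed.
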