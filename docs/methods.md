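# Methods

## Risk model and conditional likelihood

Let G = 0, 1, 2 count risk alleles at an unmeasured causal locus and E be
the child's exposure. Population disease risk is parameterized through
genotype relative risks, log GRR_g(e) = β_g + f_g(e) for g = 1, 2, with a
baseline risk η(e) for G = 0, so that P(D=1 | G=g, E=e) = η(e) Π_{i≤g}
GRR_i(e). At a measured non-causal test locus G′ in LD with G, the same
log-linear form is fitted with per-level linear curves in e whose intercept
and slope depend on an adjustment covariate vector x:

    log GRR_g′(e, x) = β_g′ + β_g′Xᵀx + β_g′E e + β_g′EXᵀ x e,  g′ = 1, 2.

Conditioning the affected child's genotype on the parental genotypes gives
the per-trio likelihood contribution

    P(G′_c = g | G′_p, e, x, D=1)
      = m(g) Π_{i≤g} GRR_i(e, x) / Σ_g* m(g*) Π_{i≤g*} GRR_i(e, x),

where m(·) is Mendelian transmission given the parents. Two consequences
shape the implementation: η(e) cancels, so environmental main effects are
neither estimable nor needed; and trios without a heterozygous parent have
a degenerate m(·), contribute exactly zero to the log-likelihood, and are
skipped by the fitter (they are retained in datasets).

Assumptions: a diallelic test locus, G′ and E conditionally independent
given parental genotypes and x, no recombination between G and G′ within
families, and correct linearity of the log-GRR in e and x. The *codominant*
model gives each genotype level its own parameter set (2(2+2K) parameters
with K covariates); the *additive* model ties the two levels to a single
per-allele set (2+2K). The G′×E likelihood-ratio test drops all exposure
slopes: 2(K+1) df codominant, K+1 additive. It is asymptotic; no
small-sample correction is applied.

Within a population stratum the conditional model is exact for the
simulated data: haplotypes are exchangeable within strata, so the
transmitted causal allele depends only on the transmitted test-locus allele,
and the induced test-locus GRRs are those returned by
`expected_testlocus_grr` (which also exposes the population-marginal GRRs —
the spurious-interaction mechanism — when no stratum is given).

## Adjustment covariates

* **Stratum dummies** — K indicators for strata 1..K, stratum 0 (lowest
  label) baseline. Saturated in the stratum, hence the oracle benchmark.
* **EEGM** — fitted values of an intercept-included regression of E on the
  selected PC scores (linear for continuous E, logistic with fitted
  probabilities for binary E), used raw as a single covariate. Only the
  regression span of the scores matters. With two strata one scalar can
  encode the stratum effect exactly; with three or more strata a single
  linear combination generally cannot represent three distinct
  stratum-specific GRR shifts, which is why EEGM adjustment loses type-I
  control there.
* **Scaled PCs** — the selected leading score columns, each shifted and
  scaled to [0, 1], so x = 0 and x = 1 correspond to "ancestral prototype"
  individuals and covariate contrasts at 0/1 are interpretable. The same
  scaling is applied in simulations and in data analysis. PCs are computed
  on affected children only (one individual per trio), avoiding
  family-relatedness distortions.

## PCA and the number of components

Dosages are standardized per marker: centered at 2p̂ and scaled by
√(2p̂(1−p̂)); empirically monomorphic markers are dropped. The spectrum of
the individual-level covariance XXᵀ/m is obtained through the smaller Gram
matrix. Under pure noise the bulk follows Marchenko–Pastur with upper edge
(1+√(n/m))².

Three selectors of the number of informative PCs:

* **Profile-likelihood elbow** — for each split point the eigenvalues are
  modelled as two Gaussian groups with common variance; the split
  maximizing the profile likelihood is returned (≥ 1). With a dominant
  leading eigenvalue this deliberately under-selects — the behaviour it is
  included to demonstrate.
* **Low-rank threshold** (the pipeline default) — singular values are
  compared against ω(β)·s_med, the optimal hard threshold for a low-rank
  signal in Marchenko–Pastur noise of unknown level, with β the aspect
  ratio and the noise calibrated from the median singular value; the MP
  median is computed by quadrature. Returns 0 on pure noise.
* **Sequential Tracy–Widom tests** at α = 0.05 — the j-th eigenvalue is
  normalized against the remaining spectrum using effective dimensions
  obtained by moment matching (the variable dimension is the number of
  remaining eigenvalues, i.e. the smaller matrix dimension, which keeps the
  test calibrated whether individuals or markers are more numerous) and
  compared to the upper-α TW(1) quantile from a built-in table with
  interpolation; consecutive rejections from the top are counted.

Known limitation: after strong spikes are removed, the sequential TW test
is mildly anticonservative — with the default four-stratum panel it returns
one extra component in a few percent of replicates at m = 600, and more
often as m grows. The low-rank selector does not share this behaviour and
is the default.

## Trio simulator

Each candidate trio: a stratum from the configured weights; four parental
haplotypes i.i.d. from the stratum's (R1, R0, N1, N0) frequency table under
random mating; one haplotype transmitted per parent without recombination;
exposure Normal(μ_s, σ²); affection from the GRR model at the child's
*causal* genotype. Retained trios are affected with at least one
heterozygous parent at the test locus; exactly n_trios are returned and
only test-locus genotypes, exposure and the oracle stratum label are
recorded.

Affection is sampled by rejection with acceptance probability
Π_{i≤G} GRR_i(e) / max_g Π_{i≤g} GRR_i(e): any baseline depending on e
alone drops out of the child-genotype-given-(parents, E) distribution that
the likelihood models, so the per-draw normalization is unbiased for that
conditional while maximizing throughput. A configuration whose acceptance
rate falls below 10⁻⁶ raises.

Defaults are the study conditions: the four-stratum haplotype table with
implied allelic correlations (−1, 1, 0.5, −0.5); exposure means (−0.8, 0.8,
2.4, 4.0), common variance 0.36; genetic main effect β_g = log(3)/2 per
risk-allele copy; interaction β_gE = 0 (type-I error) or one of (−0.10,
−0.15, −0.20, −0.25) (power); 3,000 informative trios per dataset; stratum
splits 60/40, 50/30/20 or 40/30/20/10 for unequal sizes. Single-stratum
presets use the complete-LD stratum so the test locus carries the causal
GRRs exactly (used for parameter-recovery checks).

## Marker simulator

Marker panels are simulated independently per marker (no LD): dosage ~
Binomial(2, p_{s,j}) given the individual's stratum. Per-stratum
frequencies come either from an explicit matrix or from a hierarchical
Balding–Nichols model: ancestral frequency Uniform(0.05, 0.5), a
continental-group frequency Beta-diverged from it (group F_ST 0.45 by
default), and a stratum frequency Beta-diverged from its group's (stratum
F_ST 0.15). Divergence at each level is sampled from the Beta law truncated
to [0.05, 0.95] (by inverse-CDF), so every marker keeps MAF ≥ 0.05 in every
stratum — mirroring how genome-wide panels are constructed and keeping the
noise bulk close to Marchenko–Pastur. The default group layout (0, 1, 0, 1)
emulates four populations forming two distant continental pairs, so the
leading PC (between continents) dwarfs the within-continent PCs — the
spectrum shape that makes the scree elbow under-select while rank-based
selectors find all K components.

The divergence parameters are deliberately larger than continental-scale
F_ST estimates: stratum discriminability scales with m·F_ST, and the
desk-scale panels here (hundreds of markers) stand in for LD-pruned
genome-wide panels of tens of thousands. A real pruned panel has *both* a
dominant between-continent component *and* high per-stratum
discriminability; at a few hundred markers no single divergence setting can
deliver both, so two regimes are provided. The default configuration
preserves the spectrum shape (used wherever PC-count selectors are
compared), while `MarkerSimConfig.high_information()` (group F_ST 0.5,
stratum F_ST 0.4, 1,000 markers) matches the per-stratum information
content of a genome-wide panel and is used for the type-1-error and power
experiments, where what matters is the residual stratum variance the PC
scores fail to capture: with weakly informative panels that leakage lets
the large spurious main-effect differences bleed into the interaction
slopes and inflates the test. What the simulator does **not** emulate: LD
between markers,
admixed or continuously structured ancestry, site-frequency-spectrum shape,
genotyping error, and within-family marker transmission (each child's
markers are drawn independently given the stratum). Passing tests therefore
demonstrate the method's behaviour under clean, well-separated
stratification — not robustness to admixture or to weakly informative
panels.

## Fitting and numerics

The negative conditional log-likelihood is convex (a conditional
multinomial-logit form), and is minimized by damped Newton iteration with
analytic gradient and Hessian, started at zero (the null) or warm-started
at the null fit for the full model. Convergence: gradient sup-norm ≤ 10⁻⁶,
or a Newton decrement below 10⁻¹² of the objective scale (the attainable
improvement is then below floating-point noise). Diverging parameter norms
flag possible complete separation; non-convergence is flagged on the
result, not raised. The covariance is the inverse observed information
(exact Hessian) at the optimum; Wald intervals for modifying effects
exp(β_g′E + β_g′EXᵀx) use the delta method on the corresponding linear
combination. The LRT statistic is clipped at zero. The statistic is
invariant to affine rescaling of covariate columns and shifts of the
exposure.

## Which genetic model the experiments fit

The experiment layer fits the additive model by default. In a calibration
study with oracle stratum dummies (400 replicates, four unequal strata,
3,000 trios), the additive G'xE LRT matched its chi-square reference
(rejection rate 0.038 at the 5% level, KS p = 0.89), while the codominant
test ran above nominal (0.070): dropping eight parameters, several of which
are informed by only a few dozen genotype-2 children in the 10% stratum and
are nearly collinear with the exposure, degrades the chi-square
approximation. The same codominant test is perfectly calibrated when the
covariates are independent of the exposure, so this is a finite-sample
property of the extreme design, not of the implementation. The codominant
model remains the default for single-dataset analysis (`fit`, `lrt_gxe`,
the CLI `test` command) and is exercised by the parameter-recovery and
df checks.

## Experiments and problem sizes

Replicate r of an experiment uses a generator spawned from
SeedSequence(base_seed, spawn_key=(r,)), so reruns are bit-identical and
order-independent; per-replicate p-values and selected PC counts are
stored, so rejection rates can be re-evaluated at any level. Binomial 95%
CIs are normal-approximation by default (Wilson available). Replicate-level
fit failures are excluded only if they are under 1% of replicates,
otherwise the run errors.

The reference experiments use 5,000 replicates of 3,000 informative trios.
This package's test suite and acceptance script keep 3,000 trios per
replicate but run 100–500 replicates per cell and use panels of 600–1,000
markers for the PC pipelines — sizes chosen so the whole suite runs on a single CPU in
well under half an hour while leaving Monte-Carlo error small relative to
the effects being checked (e.g. EEGM's size inflation at three strata is
essentially 1.0 here, and power differences between PC and oracle
adjustment are an order of magnitude below the pooled MC standard error
bound). Power comparisons share each replicate's simulated trios across
adjustments (a paired design), which shrinks the variance of
between-adjustment differences.

## Design choices at genuinely open points

* The power and type-I experiments fit the codominant model (the fuller
  parameterization); the additive model is exposed everywhere, including
  the CLI, and is the natural choice for binary-exposure data analyses.
* PC scaling to [0, 1] is applied uniformly (simulations and analysis).
* Marker individuals are the affected children only. In PC-selection
  tallies, stratum labels are drawn directly from the stratum weights:
  under the default haplotype table the ascertainment filter retains every
  stratum at the same rate (the index-allele frequency is 0.5 in all
  strata), so the label distribution is unchanged and the trio layer adds
  nothing to the marker spectrum.
* For binary exposures, e enters the model as raw 0/1 (no centering), so
  exp(interaction) is the exposure's multiplicative modification of the
  GRR.
* Mendel-incompatible rows in input files are errors, not silent drops:
  they indicate data corruption and the likelihood is undefined for them.

## Limitations

Beyond the marker-simulator caveats above: missing parents or genotypes are
not handled (complete trios only); multi-allelic loci and phasing are out
of scope; the environmental main effect is structurally inestimable from
case-parent trios; EEGM's logistic regression can fail by separation when a
binary exposure is nearly deterministic in ancestry; and the sequential
Tracy–Widom selector's mild anticonservatism after strong spikes is
documented above.
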