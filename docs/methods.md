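# Methods

## Model

`mrgraph` infers the matrix **G** of *direct* causal effects among T
complex traits (entry g_ij = effect of trait j on trait i) from per-trait
GWAS summary statistics, allowing feedback loops. The underlying structural
model is the linear SEM at equilibrium,

    Y = G Y + Γ Z + ε,    equivalently    Y = (I − G)⁻¹ (Γ Z + ε),

motivated dynamically: trait values evolve in discrete time, each step
adding the propagation of the previous step's *changes* through **G**
(`network.simulate_dynamics`). When the spectral radius of **G** is below 1
the dynamics converge to the equilibrium above; with ρ(G) ≥ 1 forward
operations refuse to run. Writing W = (I − G)⁻¹:

* **B** = W Γ are the *total* SNP effects — what GWAS marginal regressions
  estimate;
* pairwise univariable MR with instruments valid for the exposure estimates
  θ_ij = w_ij / w_jj, collected in the MR-effect network
  **Θ** = W Diag(w)⁻¹ (unit diagonal);
* the map is inverted in closed form: w_jj = (Θ⁻¹)_jj,
  **G** = I − Diag(w)⁻¹ Θ⁻¹, which has an exactly zero diagonal by the
  rescaling (`network.graph_from_mr_network`);
* the total-effect network is G_tot = (I − G)⁻¹ G = W − I; its diagonal
  holds the self-loop effects created by cycles, and with no cycles
  G_tot = Θ − I.

Estimated graphs whose spectral radius reaches 1 are *flagged*
(`spectral_warning`), not rejected: the admissibility bound is a condition
of the generative model, not a constraint the estimator can enforce.

## Robust pairwise MR

For each ordered pair, the MR effect is estimated by constrained maximum
likelihood with explicit invalid-instrument selection (`uvmr`): with k
instruments allowed a free direct (pleiotropic) outcome effect r, minimize

    Σ_m (β̂_out,m − θ b_m − r_m)² / se_out,m² + (β̂_exp,m − b_m)² / se_exp,m² ,

where exactly k entries of r are nonzero. Block-coordinate descent is used
with exact updates: given θ, the optimal invalid set is the k largest
standardized profile residuals (β̂_out − θ β̂_exp)²/(se_out² + θ² se_exp²),
and b and r have closed forms; given the rest, θ is a weighted
least-squares update. Each cycle is non-increasing, convergence is declared
when the objective changes by < 1e-8, capped at 200 iterations.

The objective is non-convex in θ when instrument groups disagree, so each
fit is run from a deterministic start set — the warm start carried over
from k−1, zero, the IVW estimate, and the 10/25/50/75/90% quantiles of the
per-instrument ratios β̂_out/β̂_exp — keeping the lowest optimum. The ratio
quantiles cover the basins induced by instrument groups sharing a ratio
estimand (the role random restarts play in stock implementations) while
keeping the procedure seed-free. This matters in practice: without them
the descent never finds the contaminated-plurality solution, and the
pairwise-screening failure mode (below) silently disappears.

k is selected by BIC = 2·nll + log(min(n_exp, n_out))·k over
k = 0..⌊m/2⌋−1; the cap honors the plurality condition (a majority of
instruments stays valid). No model averaging and no analytic standard
errors: inference is entirely perturbation-based, which also absorbs the
selection uncertainty. Pairs with fewer than two instruments get θ̂ = 0
with a missingness flag.

## Instrument screening

Candidate pools per trait pair: LD-independent SNPs with p < 5e-8
(configurable) for at least one of the two traits. Association strength is
compared on r² = z²/(z² + n − 2) — a Steiger-type proxy that is comparable
across GWAS of different sample sizes, unlike raw |z|. Exact ties break to
the lower trait index and are logged.

* **pair**: a SNP significant for both traits instruments only the stronger
  one. Blind to the rest of the network: SNPs acting through a shared
  upstream trait enter as correlated-pleiotropy instruments once samples
  are large enough for their indirect associations to reach significance.
* **max**: a SNP instruments only its strongest significantly-associated
  trait across all T traits. The strength comparison is restricted to
  traits where the SNP is significant, so chance correlations with null
  traits cannot evict valid instruments. Robust but conservative.
* **aug**: starting from the max sets, a SNP excluded from pair (j → i) is
  re-admitted iff for *every* trait l that is significantly associated with
  it more strongly than j, deleting node j from a reference graph leaves no
  directed path l → i. The reference graph is the Bonferroni-thresholded
  (0.05/(T(T−1))) first-pass estimate under max screening, computed once
  from the unperturbed data and reused across bootstrap replicates (cheaper
  and keeps instrument sets stable; a per-replicate reference would add
  noise without a clear benefit). A single augmentation pass is performed;
  the procedure is not iterated.

LD pruning inside pools is greedy within blocks: SNPs ordered by smaller
p, kept while |r| < 0.1 against everything already kept — a deliberate
stand-in for external clumping tools.

## Perturbation inference

GWAS z-scores (oriented SNPs × traits) are resampled from a matrix normal
Z⁽ᵇ⁾ = Z + L_R E L_Pᵀ, with R the block-diagonal SNP LD matrix
(Cholesky per block, jitter 1e-8 before giving up) and P the trait-overlap
correlation. Each replicate re-runs screening (configurable off), the
bidirectional MR, and the closed-form recovery; G is summarized by the
element-wise replicate mean and SD, with p = 2(1 − Φ(|mean|/sd)). Replicates
with singular Θ̂ or other failures are dropped and counted (warning above
5%, error above 50%). Defaults: B = 100 perturbations for simulation
studies, 1000 recommended for data analyses.

## Synthetic data

*Three-trait individual-level design* (the package's primary validation
bed): 30 independent SNPs (MAF 0.3, Binomial(2, 0.3) genotypes, raw 0/1/2
coding — genotypes are never standardized), groups of 8/7/15 SNPs acting
exclusively on Y1/Y2/Y3 with effects uniform on ±(0.1, 0.2), residuals
MVN with AR(1) correlation 0.4 and unit variances, N = 50,000 or 200,000
individuals, marginal per-SNP OLS for the summary panel. Unit residual
variances are a modeling choice validated by the resulting genetic variance
fractions — analytically 7.1/6.0/12.8% per trait for the acyclic graph
(edges Y3→Y1 = 0.2, Y3→Y2 = 0.1) and 6.3/6.0/8.9% for the cyclic graph
(Y3→Y1 = 0.5, Y1→Y2 = 0.05, Y2→Y3 = 0.5), realistic for polygenic panels of
this size. The closed-form expectation uses E[γ²] = 7/300 for the
two-sided uniform effect law.

*Six-trait summary-level design*: summary statistics generated directly as
B̂ = (I−G)⁻¹Γ + S ⊙ E with matrix-normal E, per-SNP direct effects
N(0, 0.1²) on exactly one assigned trait (round-robin assignment by
default), standard errors synthesized as 1/√(2f(1−f)n) with per-SNP MAF
uniform on (0.05, 0.5), and block-diagonal LD with AR(1)-decaying
within-block correlation 0.5. The stock graph mirrors a cardiometabolic
network (BMI, LDL, SBP, CAD, AF, Stroke) with a CAD↔AF feedback loop; its
edge magnitudes (0.15–0.4) are synthetic, chosen in the range of
standardized effects reported for these traits, so six-trait results are
pattern-level statements (power/type-I structure), not reproductions of
any particular numeric network.

What the generators do *not* emulate: allele/strand harmonization issues,
assortative mating, population stratification, winner's-curse selection of
instruments, MAF–effect-size coupling, and sample overlap beyond the
matrix-normal P. Passing tests therefore demonstrate correctness of the
method under its own model, robustness to the modeled pleiotropy
geometries, and calibration of the bootstrap — not robustness to every
artifact of real GWAS panels.

## Study sizes and numerical choices

Replicated studies use: 200 replicates for the variance-explained
averages; 100 replicates (B = 100) for the cyclic-design power contrast of
augmented vs global-max screening at N = 50,000, Bonferroni 0.05/6; the
test suite runs reduced-size analogues (60 and 40 replicates for the
three-trait power/type-I checks, 20 replicates at 120 SNPs/60 blocks for
the six-trait pattern check) — sizes chosen as the package's own validation
budget. Power is evaluated at Bonferroni thresholds (0.05/6 three traits,
0.05/30 six traits) and type-I error at nominal 0.05.

Linear systems use LU solves with a condition-number guard (warn above
1e8, error above 1e12); Θ⁻¹ is computed explicitly in graph recovery since
its diagonal is needed, aborting if any |(Θ⁻¹)_jj| < 1e-10 (degenerate
scaling). Admissibility margin for forward computations: ρ(G) ≤ 1 − 1e-6.
All randomness flows through a single `numpy` SeedSequence tree recorded in
run manifests; fixed seed + config gives bit-identical ensembles.

## Known limitations

* The recovered graph inherits the assumptions of the pairwise estimator
  (plurality of valid instruments per pair); augmentation mitigates but
  cannot remove pleiotropy mediated by traits outside the analyzed set.
* The spectral-radius condition is not enforced during estimation; flagged
  estimates with ρ(Ĝ) ≥ 1 have no equilibrium interpretation.
* Near-singular Θ̂ replicates are dropped rather than regularized; with
  heavy drop rates the bootstrap summaries are conditional on
  non-singularity.
* Weak-instrument robustification, correlated instruments within loci, and
  analytic asymptotic covariances are out of scope.
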