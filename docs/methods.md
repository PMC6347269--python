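# Methods

## Model

For the `j`-th offspring of nuclear family `i` we observe a right-censored
time `Y_ij = min(T_ij, C_ij)` (years), an event indicator
`Δ_ij = 1{T_ij ≤ C_ij}` and optional covariates `X_ij`.  The hazard follows
a log-normal frailty model

    h_ij(t) = h0(t) exp( X_ij α + G_bi γ_b + G_wij γ_w + Q_ij ),
    Q ~ N(0, σ² A),

with `A` the block-diagonal relationship matrix over offspring
(unit diagonal; 0.5 between full sibs; zero across families).  `A` is kept
on the relationship scale — `2Φ` in kinship terms — so that `σ²` is the
per-subject polygenic variance of the log hazard and matches the scale of a
per-offspring polygenic simulation.  The baseline hazard `h0` cancels from
the partial likelihood and is never estimated.  Parents contribute
genotypes only; they never enter risk sets (the model indexes offspring
hazards).

### Genotype decomposition

Additive minor-allele scores `G ∈ {0,1,2}` split into a between-family
component and a within-family residual:

* both parents genotyped: `G_b = (G_F + G_M)/2`, the expected offspring
  score given the parents;
* neither parent genotyped: `G_b =` sibship mean (within-family `G_w` rows
  then sum to zero exactly);
* exactly one parent genotyped: the family is rejected — no half-imputation
  rule is defensible without changing the null.

`G_b + G_w` reconstructs the raw score exactly.  A family with any missing
parent/offspring call at a variant is excluded from that variant entirely
(both components missing), since the formulas assume complete data within
the family; Mendelian-impossible cells are excluded the same way with a
warning.  `E[G_w | parents] = 0` under Mendelian transmission, which is the
basis of both the stratification robustness and the gene-drop null.

### Null fit

Under `H0: γ_b = γ_w = 0` the nuisance parameters `(α, Q, σ²)` are fitted
by the standard penalized-partial-likelihood realization for Gaussian
frailties: an inner Newton maximizes the Breslow partial log-likelihood
minus `Q'A⁻¹Q/(2σ²)` jointly in `(α, Q)` (dense observed information in the
linear predictor, assembled in O(N²) from suffix sums), and an outer search
maximizes the Laplace-approximate marginal likelihood over `σ²` on a
log-spaced grid refined by bounded scalar minimization.  `σ² = 0` is an
admissible boundary solution and is compared against via the exact limit
(the plain Cox fit).  Tolerances: penalized score max-norm below
`1e-6 × N`; outer relative tolerance `1e-6`; at most 100 inner / 50 outer
iterations.  The inner fit at fixed `σ²` reproduces R `survival::coxph`
with `frailty.gaussian(theta=...)` to ~1e-6 (frozen fixture in
`tests/data/`); the `σ²`-selection criterion is Laplace maximum likelihood,
which differs from that package's REML default, so `σ²` estimation is
validated by simulation recovery instead.

Two practical caveats, both surfaced as warnings: with one offspring per
family the frailty is per-observation and `σ²` is weakly identified (the
profile typically maximizes at 0 — on trio data `θ = 1` is the honest null
fit, and the simulation drivers use it directly); and under heavy censoring
the `σ̂²` profile carries little information, giving a downward-biased,
high-variance estimate.  Ties use the Breslow convention throughout; left
truncation is not supported.

### Efficient scores

For each variant `m` and event subject `i`, with `θ` from the null fit and
risk sets `R_i = {l : Y_l ≥ Y_i}` (suffix cumulative sums after one sort):

    U_aim = a_im − Σ_{l∈R_i} a_lm θ_l / Σ_{l∈R_i} θ_l,    a ∈ {G_w, G_b}
    I_ab,m = Σ_i [ S_ab/S_0 − (S_a/S_0)(S_b/S_0) ]        (observed information)

The efficient score removes the between-family direction:

    S_wim = U_wim − (I_wb,m / I_bb,m) U_bim,

using the **aggregate** per-variant information ratio applied uniformly to
each subject's contribution.  A literal per-subject 1×1 information block
is zero or degenerate for most subjects; the aggregate ratio preserves the
textbook aggregate efficient score exactly on summation.  Where
`I_bb,m = 0` the correction vanishes.  `γ_b` is evaluated at 0, not
profiled — at its MLE the between-score would vanish and the projection
would be trivially zero.  Non-event subjects carry zero rows.  Nuisance
(`α`, `σ²`) variability is ignored in downstream variances: the test
statistics use empirical variation across offspring, per the i.i.d. CLT
argument that motivates them.

### Test statistics

With diagonal weights `W = diag(w_m)`:

* **FamBAC**: per-subject burden `b_i = Σ_m w_m S_wim`,
  `T = (Σ b_i)² / Σ b_i²`, p-value from the upper `χ²(1)` tail.  If all
  burdens vanish, `p = 1` with a warning.
* **FamKAC**: `T = Σ_m w_m² (Σ_i S_wim)²`; null distribution
  `Σ_m λ_m χ²(1)` with `λ` the eigenvalues of `n·W·Ĉ·W`, where `Ĉ` is the
  centered sample covariance (denominator `n−1`) of the rows of `S_w`.
  The symmetric form shares the spectrum of the textbook `n W² Ĉ` for
  diagonal `W` and is numerically better behaved.  Eigenvalues below
  `1e-10 × λ_max` are dropped.

Weights (computed strictly without phenotypes): `w0 = 1`;
Madsen–Browning `1/√(p(1−p))`; `Beta(p; 1, 25)` density `= 25(1−p)²⁴`.
The MAF `p` is either the population MAF carried in the variant metadata or
the sample MAF estimated from the between-family component,
`p̂ = Σ_i G_bi/(2n)`, clamped to `[ε, 1−ε]` with `ε = 1/(4n)` so the weight
functions stay finite.

### Mixture-of-chi-square tails

`P(Σ λ_m χ²(1) > q)` is computed by inverting the characteristic function
(Imhof's integral).  The head of the integral is handled by adaptive
quadrature; beyond a scale-aware breakpoint the integrand oscillates at the
fixed asymptotic frequency `q/2` and is integrated with the
Fourier-weighted infinite-range rule (QAWF), which handles the slow
algebraic decay that defeats plain quadrature at small `k`.  Agreement with
exact chi-square tails is ~1e-12 and with million-draw Monte Carlo within
2e-3 across the tested range.  If the inversion returns a non-finite or
out-of-range value, a Lugannani–Rice saddlepoint approximation is used and
flagged.

### Gene-drop permutation

The permutation null regenerates transmission randomness only, conditional
on parental genotypes and all phenotypes; the null fit and risk sets stay
fixed.  For parent-genotyped families with phased parental haplotypes
available (simulation mode), whole parental haplotypes are re-transmitted,
preserving LD across the region; with unphased real data each variant is
re-transmitted independently as Bernoulli(`g/2`) per parent — exact
marginally, but cross-variant LD within a parent is not preserved.
Parentless sibships permute offspring rows within the family; parentless
singletons cannot be permuted and keep their observed genotypes (warned).
`G_b` is invariant under the parental-mean rule, so only the within-family
score and the `I_wb` block are recomputed per permutation.  The p-value
uses the add-one rule `p = (1 + #{T_perm ≥ T_obs})/(1 + B)`; with very
sparse genotypes the permutation distribution is tie-heavy and the p-values
are valid but conservative.

## Simulation framework

### Haplotype pool

The study region is an exome-like assembly: 10 segments of 300 bp drawn
from a 100-segment (30 kb) gene, fixed once per study.  Site minor-allele
counts follow a power law `P(count = c) ∝ c^(−τ)` over `c = 1..H/2`; the
exponent is solved so the expected rare-site fraction (population
MAF < 0.01) matches a target, default 0.6 — exactly the mass the neutral
constant-size law `P ∝ 1/c` implies at `H = 20,000` haplotypes, a
reasonable stand-in for mild-growth coalescent demographies.  With ~11.5
sites per segment the region carries ~69 rare sites in expectation; the
experiment entry points re-draw the region until the realized count is
69 ± 5, matching the study design's fixed region.  Carrier sets are
partially copied between adjacent sites within a segment (reset
probability 0.3) to create short-range LD.  A plain-text pool (one 0/1
haplotype per line plus a MAF sidecar) can be supplied instead for
externally calibrated LD.

What the generator does **not** emulate: demography-calibrated site
frequency spectra, realistic recombination maps, or negative LD between
rare alleles arising from distinct coalescent backgrounds.  Consequences
observed in our own experiments: the null behavior of both statistics — in
particular how far FamKAC's mixture approximation deflates, and the exact
FamBAC size — depends visibly on the rarity spectrum of the region
(essentially on how many minor-allele carriers each site contributes), so
absolute size/power values transfer to real sequence data only
approximately, while the qualitative contrasts (FamBAC ≈ nominal; FamKAC
deflated under Davies, repaired by permutation; burden > kernel for
direction-aligned effects) are stable across the spectra we tried.

### Trio sampling

Each trio draws 4 distinct haplotypes for the parents (without replacement
within the trio, with replacement across trios) and transmits one haplotype
per parent to the offspring; Mendelian consistency holds by construction
and the phased parental haplotypes are retained for LD-preserving
gene-drop.

### Censored traits

Null: `AAO ~ N(μ_AAO = 45, V_AAO = 100)` years.  Alternative:

    AAO_i = 45 + Σ_m a_m s_m (g_im − 2 p_m) + P + E,
    a_m = sqrt(V_cv / (2 p_m (1 − p_m))),  P ~ N(0, V_p),  E ~ N(0, V_e = 75)

with `k_cv = round(P_cv · k)` causal sites drawn uniformly, `s_m = −1`
(AAO-advancing) except for a `direction_mix` fraction of `+1`, and
`V_cv = V_g/k_cv` (`fixed_Vg` mode, `V_g + V_p = 25`) or a supplied
reference value (`fixed_Vcv` mode).  Under HWE each causal variant then
contributes `V_cv` of trait variance, keeping the budget
`V_g + V_p + V_e = 100` exact.

Centering is at the population mean genotype `2p_m` (default).  A
unit-centered variant `(g − 1)` is exposed as an option but shifts the
trait mean by `Σ_m |a_m|(1 − 2p_m)` — tens of years for rare variants —
which under the fixed AAE calibration censors essentially everyone and
annihilates power; since a common shift of AAO and AAE leaves the
rank-based partial likelihood invariant, the mean-preserving form is the
faithful implementation of the intended design.

`AAE ~ N(μ_AAE, 100)` independently; `Y = min(AAO, AAE)`,
`Δ = 1{AAO ≤ AAE}`; nonpositive draws are floored at 0.01 years with a
warning.  The AAE mean is calibrated analytically from the censoring-rate
label `r`:

    μ_AAE = μ_AAO − Φ⁻¹(1 − r) · sqrt(V_AAO + V_AAE),

giving 26.88 at `r = 0.1` and 37.58 at `r = 0.3`.  Note that under this
calibration the **event** fraction equals the label (10% events at
`r = 0.1`); the realized censored fraction is `1 − r`.  The label and its
calibration formula are kept as stated above and the convention is simply
documented, rather than renaming the label.

### Experiment drivers and problem sizes

`run_type1_experiment` / `run_power_experiment` report rejection fractions
at level 0.05 with binomial standard errors; replicate `r` is seeded
`master_seed + r`, making every table bit-reproducible and restartable.
Trio cohorts carry no covariates and one offspring per family, so the null
fit is exactly `θ = 1` (see above); variants monomorphic in a replicate's
sample are dropped, mirroring cohort assembly.  The shipped checks use
1,000 replicates of 2,000 trios per experiment cell (the calibration of a
rejection probability near 0.05 has binomial SE ≈ 0.007 at that size), and
the permutation-calibration check uses 300 replicates × 300 permutations of
1,000 trios; full 10,000-replicate grids run overnight with the same
drivers.

## Numerical and design choices (summary)

* Breslow ties everywhere; risk sets via one sort + suffix sums,
  O(N log N + N k) per gene.
* Sample-MAF clamp `ε = 1/(4n)`; eigenvalue truncation `1e-10` relative;
  quadrature target 1e-9 absolute; time floor 0.01 years.
* Missing data: exclusion (family × variant), never imputation.
* `σ²` estimated once per dataset and reused across genes (the null fit
  does not involve the tested variants).
* Per-gene p-values are emitted raw; Bonferroni is available as a flag but
  off by default.

## Known limitations

* FamKAC's Davies-based p-values are conservative (deflated size), more so
  the rarer the variant spectrum; permutation p-values restore calibration
  at higher cost.  The conservatism is intrinsic to approximating the
  statistic's null by a chi-square mixture when per-variant score sums are
  driven by few carriers, so its depth depends on the pool's spectrum.
* The `σ²` profile is weakly informative for trio data and downward-biased
  under heavy censoring; treat `σ̂²` as a nuisance, not an estimand.
* Single-genotyped-parent families are rejected; X-chromosome dosages,
  multiallelic sites and multi-generation pedigrees are out of scope.
* Unphased real data gets per-variant gene-drop, which ignores cross-variant
  LD in the permutation null.
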