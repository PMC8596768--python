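# Methods

This note records the models, algorithms, numerical choices and known
limitations behind the package, in the spirit of a software methods
appendix.

## Demographic model and conventions

Models are collections of panmictic demes with diploid effective sizes
N_i (optionally exponentially growing), a matrix of scaled migration rates,
and timed events (size changes, growth changes, migration changes, and
backward joins). Conventions, stated once and used everywhere:

* **Migration is backward (ms-style).** M_ij = N_i·m_ij is the expected
  number of lineages per generation currently in deme i whose parent lived
  in deme j; m_ij = M_ij/N_i is the per-lineage backward rate. The forward
  simulator uses the matching forward fraction m̃_ij = M_ij/N_i (the
  probability that an offspring in deme i draws its parent from deme j);
  for conservative migration the two conventions agree to first order, and
  the package treats m̃ as the definition on the forward side.
* **Time** is in generations before present. An event at time t applies to
  all times ≥ t (half-open backward interval).
* **Sizes are diploid**; a sample of n individuals contributes 2n haploid
  genomes. E[pairwise coalescence time] within a constant deme is 2N
  generations.
* A **locus** is a window with one shared genealogy: recombination is free
  between loci and absent within. Positions are relative in [0, 1).

## Coalescent engine

The neutral simulator is a continuous-time exponential-race implementation
of the structured coalescent: within deme i at time t pairs coalesce at
rate 1/(2N_i(t)) and lineages migrate i→j at rate M_ij/N_i(t). Within an
epoch, growth makes all deme-i rates scale as e^{g_i u}; waiting times are
drawn by analytic integration of the cumulative hazard (closed form per
deme, root-finding via Brent only when growth is active). Events never step
over epoch boundaries: the residual exponential target is carried across.
Mutations are infinite-sites: Poisson(µ·L·total branch length), placed
uniformly on branches, derived state below the branch; positions are
uniform with collision re-draws and reported sorted. A non-coalescing model
(disconnected demes) fails explicitly at a time ceiling of 10⁹ generations
rather than truncating silently.

The engine was checked against analytic moments (E[T₂] = 2N,
E[S] = 4NµL at n = 2) and against msprime on a two-deme island model
(two-sample KS on S, p ≈ 0.9); the test suite re-runs these checks.

## Forward simulator for selected loci

Selected loci carry one biallelic site (ancestral a, derived A) embedded in
the locus and fully linked. Genotype fitnesses in the two environments are
the genotype table (1+s₁, 1, 1) and (1, 1, 1+s₂) for (AA, Aa, aa). The
published description says "dominant" beneficial alleles while printing
this table, which is advantageous only in homozygotes; the package
implements the printed table as the default and exposes
`dominance="dominant"` ((1+s, 1+s, 1)-style) as an option rather than
guessing intent. The difference matters: under the printed table a rare
beneficial allele (standing frequency 0.1) experiences very weak positive
selection and survival to the present is rare in weak-selection regimes.

The simulation scheme is an individual-based Wright-Fisher pedigree run
*forward* from the selection onset T_S:

1. **Count path (cheap stage).** Per generation and destination deme, the
   migrant group sizes are multinomial over source demes (fractions m̃),
   and the derived count within each group is binomial at the source's
   post-selection frequency p* = p·w_A(p)/w̄(p) with the marginal fitness
   w_A(p) = p·w_AA + (1−p)·w_Aa. Survival conditioning (the analogue of
   conditioning the simulation on the derived allele not being lost)
   rejection-resamples this stage until the retention rule holds at t = 0;
   a path that loses the allele aborts immediately since there is no
   recurrent mutation. The default retention rule is *not lost* (the
   derived allele is present — possibly fixed — somewhere at sampling);
   *segregating* and *none* (unconditioned) are options. Exceeding the
   resample cap (default 10⁴) raises an explicit loss-regime signal, which
   the evaluation layer reports as such (the "derived allele always lost"
   cells), never skips.
2. **Pedigree fill-in.** The accepted count path is replayed, drawing
   concrete parent indices for every one of the 2N_i haploid genomes per
   generation (uniform within the source allele class). Given the counts,
   parent assignment is exchangeable, so the two-stage scheme samples the
   same distribution as direct rejection on full pedigrees at a fraction of
   the cost.
3. **Genealogy extraction and closure.** The sampled haplotypes' ancestry
   is traced back through the pedigree; lineages that have not coalesced by
   T_S are closed with the neutral structured coalescent under the same
   model, started at T_S. Because the locus is neutral before the onset,
   this closure is the exact stationary distribution — it replaces the
   conventional long forward burn-in with something both faster and exact.
   Neutral infinite-sites mutations are then dropped on the composite
   genealogy; the selected site is inserted with the sampled allele states
   (omitted if monomorphic in the sample).

Initial conditions: standing variation assigns round(f·2N_i) derived copies
uniformly at random per deme at T_S (the allele's pre-onset age and
haplotype structure are *not* modelled — an acknowledged approximation);
de novo places a single copy in deme 1.

**Rescaling.** Forward simulation at N = 10,000 is impractical, so models
are rescaled by λ: N → N/λ, t → t/λ, s → s·λ, µ → µ·λ, m → m·λ, leaving
4Nµ, M = N·m, N·s and t/N invariant. The default λ caps rescaled deme sizes
at 1000 diploids (λ = 10 for the benchmark model). Rescaling is refused
when it would leave the diffusion regime (s·λ > 1 or m̃ > 1). A
distributional KS test (λ = 1 vs λ = 5) guards the invariance, and an
unconditioned s = 0 run is distributionally indistinguishable from the
coalescent (KS p ≈ 0.4–0.9), validating pedigree, closure and mutation
machinery together.

## Summary statistics

Per deme: S, private S (segregating here, monomorphic elsewhere), π (mean
pairwise differences per locus), Watterson's θ_W = S/a_{n−1}, Tajima's D
(standard variance constants; NaN at S = 0 or n = 2 — missing values stay
NaN and never silently become 0). Between demes: Hudson's
F_ST = 1 − mean(π_A, π_B)/π_between on per-locus quantities (clamped to
[−1, 1]; NaN when π_between = 0) and D_XY = π_between/L per site. π, θ_W, S
are per-locus window totals; D_XY is per site. The unfolded SFS is binned
into k equal frequency classes (default 4 per deme), normalized to sum 1.

The pool-sequencing emulation draws per-site depths from a negative
binomial (mean, dispersion; variance = mean + mean²/dispersion) or a fixed
depth, and derived read counts binomially at the pool frequency, pooling 2×
the requested diploids in haploid genomes. Pooled statistics are
frequency plug-ins with both the depth (d/(d−1)) and pool-size (n/(n−1))
small-sample corrections; private sites require ≥ 2 supporting reads by
default (anti-singleton noise); zero-depth sites are missing and shrink the
effective locus length.

## ABC-GLM posteriors

* **Scaling.** Count-like statistics (S, private S, π, θ_W, D_XY) enter the
  transform as log1p; bounded statistics (Tajima's D, F_ST, SFS bins) stay
  linear. Under the seven-decade migration priors the raw counts span
  10¹–10⁵, and without this fixed scaling both the PLS projection and the
  retention distance are dominated by the low-migration tail. (A
  consequence: the distance is affine-invariant in the linear-scaled
  statistics only; the log-scaled ones are counts with fixed units.)
* **PLS.** After standardization, a k-component PLS regression of the focal
  parameters on the statistics (default k = 8) defines the reduced space;
  retention is Euclidean there, ties broken by row index. Defaults retain
  max(1000, 1% of the table) simulations (the 1%-of-250,000 convention with
  a floor suited to 50,000-row desk tables).
* **GLM.** Ordinary least squares of the retained PLS scores on the focal
  parameters gives s = c₀ + Bθ + ε with ridge-regularized residual
  covariance Σ (+10⁻⁸·scale·I). The grid posterior is
  prior(θ)·N(s_obs; c₀ + Bθ, Σ) at the 33 × 33 cell centers of the prior
  box (uniform prior on the log₁₀ scale), normalized in log space with a
  10⁻³⁰⁰ density floor — all-zero output is impossible.
* **Truncated prior.** The GLM likelihood is a *local* linear model; 
  evaluated across the whole prior box it can assign spurious density to
  parameter regions no retained simulation supports (the statistics depend
  non-monotonically on the migration-rate difference, so a plane fitted
  across the retained cloud is nearly flat along that direction).
  Following the truncated-prior construction of the GLM algorithm, the
  per-locus posterior is additionally weighted by a Gaussian-kernel density
  (Scott's bandwidth) of the retained parameter draws. With this factor the
  product-of-posteriors estimate recovers the true neutral point to within
  one grid cell at desk scale; without it the estimate can drift to a prior
  corner.

Simulation-based calibration (rank of the true log₁₀M12 in its marginal
posterior over prior draws) is uniform at χ², α = 0.001, and the pure GLM
grid matches the conjugate-normal closed form to total variation < 0.01 on
a 1-parameter problem.

## Scan statistics

θ̂ maximizes the summed log posterior mass over the designated neutral loci;
each locus's log mass is max-normalized before summation (an
argmax-preserving constant that keeps 200-locus sums inside floating range)
and the per-cell sum is floored at log(10⁻³⁰⁰); ties break to the smallest
flat cell index. h_l counts only cells *strictly* denser than the θ̂ cell,
which makes flat posteriors give p_l = 1 — the conservative direction, and
the reason the neutral p_l distribution is stochastically above uniform
rather than exactly uniform. σ_l integrates mass below the neutral ratio
line with boundary cells contributing half (the continuum integral puts
zero mass on the boundary; the grid needs an explicit symmetric rule);
a = ln(σ/(1−σ)) uses the natural log with σ clamped to [10⁻⁶, 1−10⁻⁶]. The
HPD is computed on the joint 2-D grid, not on marginals.

## Validation design and what it shows

The benchmark study is a two-deme IM model with N₁ = N₂ = 10,000 diploids
(a package choice — the supplementary parameter tables of the original
study are not available here), µ = 5 × 10⁻⁷/bp/gen, 5-kb loci, and 20
haploid genomes sampled per deme (also a package choice of a typical
resequencing sample). Desk-scale runs use a 50,000-row reference table and
pseudogenomes of 200 neutral + 50 selected loci; the full-scale design
(1000 + 50 loci, 250,000 simulations) is reachable by configuration. Power
(Mann-Whitney AUC of 1 − p_l, midrank ties, equal to the trapezoidal ROC
area) at M = 5, s₁ = s₂ = 0.1, T_S = 40,000 is ≈ 1.0; neutral p_l are
strongly conservative; θ̂ recovery is within one grid cell; contaminating
the neutral set with 20% selected loci moves the AUC by far less than 0.05
(the product estimate follows the majority).

The generator emulates the published validation conditions, not real data:
no within-locus recombination, free recombination between loci, a single
selected site per locus, no sequencing error on the haplotype path, equal
deme sizes, and known ancestral states. Passing tests therefore demonstrate
the *method's* behaviour under its own model class; robustness to model
misspecification beyond the neutral-set contamination experiment (and to
LD, error or polygenic architectures) is out of scope.

Under the printed (recessive-advantage) fitness table, weak-selection
regimes (s = 0.001) at intermediate and high migration lose the derived
allele in the vast majority of attempts; survivors carry little signal.
This reproduces the published observation that power concentrates at
intermediate migration for moderate-to-strong selection, while at low
migration long regimes of weak selection remain (marginally) detectable.

## Known limitations

* The pre-onset age/haplotype background of standing variants is not
  modelled (random assignment at T_S).
* Joins (population splits) inside the selection window are not supported
  by the forward simulator.
* The GLM posterior is a local linear-Gaussian approximation; its absolute
  credible levels inherit the conservativeness of the HPD tie rule and
  should be read as calibrated p-values only through the coverage property.
* Statistics assume known ancestral alleles (unfolded SFS); folding is not
  implemented.
* The genotype-likelihood (low-coverage) data path is not implemented; the
  pooled path assumes mid-to-high coverage.
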