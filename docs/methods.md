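# Methods

This note records the modeling assumptions, parameter choices, numerical
conventions and known limitations behind `nicheflow`. The package's claim
is not that model food webs have any particular indirectness value, but
that the whole chain — structure generation, bioenergetic dynamics, environ
accounting, statistics — is specified precisely enough to be rerun and
audited.

## Web generation (niche model)

Species live on a one-dimensional niche axis. For target size S and
connectance C (defined throughout as the fraction of possible *directed*
links, C = L/S²):

- niche values n_i ~ Uniform(0, 1);
- range widths r_i = n_i·b_i with b_i ~ Beta(α = 1, β = (1−2C)/(2C)), so
  E[b] = 2C and, with E[n] = 1/2, E[r] = C;
- range centers c_i ~ Uniform(r_i/2, n_i);
- species i consumes every j (possibly itself) with n_j ∈ [c_i ± r_i/2].

C must lie in (0, 0.5): at C ≥ 0.5 the beta shape parameter is
nonpositive. Candidates are rejection-sampled until the web has at least
one producer (an all-zero row of the adjacency) and exactly one connected
component. The component count is computed the way the rest of the
pipeline's linear algebra is: as the multiplicity of the zero eigenvalue of
the Laplacian of the undirected, self-loop-free graph, with eigenvalues
|λ| < 10⁻⁹·S counted as zero (Laplacian eigenvalues are O(S)); tests pin
this against a graph-search oracle.

Calibration caveat: candidate draws hit the target connectance in
expectation, but *conditioning on validity biases small accepted webs
upward* (measured mean realized C ≈ 0.227 at S = 10, C = 0.2, versus 0.202
at S = 30). This is a property of the model's own acceptance tests, not of
the generator, and the tests assert calibration on candidates.

## Trophic levels and parameters

A species' trophic level is the mean of two topological quantities, both 1
for producers: (a) one plus the shortest consumer→prey hop count to a
basal species and (b) the flow-based position TL = 1 + Σ_j TL_j·p_ji under
equal diet fractions, solved as a linear system (residual < 10⁻¹⁰).

Cannibalistic self-links are excluded from both computations. This is
deliberate: a pure self-feeder would make the linear system singular
(TL = 1 + TL), and self-loops carry no information about trophic height. A
species whose only prey is itself is assigned level 1 while remaining a
consumer dynamically (no intrinsic growth, so it starves). Webs containing
a multi-species consumer cycle with no directed path to any producer have
no defined flow-based levels; they raise a trophic-assignment error and
the scan records the realization as failed. Their frequency rises with
connectance (from <1% of valid webs at C = 0.10 to ~14% at C = 0.48); no
published treatment of this corner exists for this parametrization, and
silently assigning pseudo-levels seemed worse than flagging.

Body masses follow m = 10^(TL−1); metabolic rates are 0.138 (producers)
and 0.314·m^(−1/4) (consumers); maximum consumption relative to metabolism
y = 8; conversion efficiencies 0.45/0.85 by prey type; functional-response
constants q = 1, c = 1, B0 = 0.5; producer growth r = 1 at carrying
capacity K = 1. The producer metabolic rate is carried in the data model
but exerts no force in the producer ODE, whose growth term is logistic and
net.

## Dynamics

State variables are species energy contents B_i. The consumer response is
Holling type III with predator interference,

    F_ij = B_j^(1+q) / (B0^(1+q) + c·B_i·B0^(1+q) + Σ_{k∈prey(i)} B_k^(1+q)),

i.e. search rate proportional to prey abundance to the power 1+q, with the
interference term scaled by the consumer's own biomass. Producers follow
logistic growth minus predation; consumers gain x_i·y·B_i·F_ij from each
prey and lose the pre-assimilation amount (gain/e) to each predator, plus
metabolism. Cannibals carry both a gain and a loss term.

Integration is classic fixed-step RK4 at dt = 0.01 (dt must divide one
time unit). The protocol draws B(0) ~ Uniform(0.5, 1), runs 1000 time
units, removes species with B < 10⁻⁶ exactly once, and runs the reduced
web for 1000 more units; the second phase is what DEA sees. After 1000
units small webs sit at steady state to ~10⁻¹⁰–10⁻¹⁵ in max |dB/dt|;
halving dt moves integer-time biomasses by far less than 10⁻⁶. The
extinction threshold is configurable; 10⁻⁶ is an order of magnitude below
any biomass that matters dynamically while catching exponential decliners.
A run is flagged degenerate (excluded from aggregates, never silently
dropped) if no producer survives, everything dies, or the removals split
the web into more components than it started with. Non-finite states flag
the run as failed. The RK4 inner loop is JIT-compiled over a CSR encoding
of the prey lists; a vectorized reference derivative is kept and the two
are cross-checked to machine precision in the tests.

## Environ accounting and DEA

The bioenergetic equations are not conservative as written (predators
assimilate less than prey lose), so snapshots rebuild a balanced
stock-and-flow network at each integer time:

- internal flow f_ij = x_i·y·B_i·F_ij, the assimilated gain;
- the prey's additional loss (1/e − 1)·f_ij is a boundary output of the
  prey (unassimilated food);
- consumer metabolism x·B is a boundary output;
- producer net growth r·B·(1−B/K) is the boundary input; when negative
  (B > K) its magnitude is booked as an output instead;
- by default producers also respire: an output x·B balanced by a
  gross-production input r·B·(1−B/K) + x·B. This choice turns out to be
  *provably immaterial* for ratio-form indirectness — producers receive no
  internal inflows, so a producer column only ever forms the first step of
  a path and any rescaling of it cancels in (N−G)/N — but it fixes the
  G-matrix values themselves; a flag disables it.

Every snapshot satisfies dB_j/dt = z_j + Σ_k f_jk − t_out_j against the
ODE right-hand side to 10⁻⁹ (tested). Normalizing columns by total outflow
gives G (g_ij = f_ij/t_out_j, diagonal forced to zero; a cannibal's
self-flow stays in its t_out but not in G).

Integral flow over a window of m steps is the time-ordered product series
N = I + Σ_{k=1..m} G(t0)···G(t0+k−1): paths up to length m, the truncated
Neumann series when G is constant. The window is m = 20 and t0 is placed
at the end of the run (t0 = T − 20), where steady state is best
approximated; at steady state the 21 G matrices in the window are
identical to ~10⁻⁷ and the placement is irrelevant.

### Two FI definitions

Per link, indirectness can be expressed two ways, and the package computes
both for every run:

- **ratio** (default): FI_ij = (N_ij − G_ij)/N_ij ∈ [0, 1], the *fraction*
  of integral flow on the link that is indirect;
- **difference**: FI_ij = N_ij − G_ij ≥ 0, the *absolute intensity* of
  indirect flow per unit input at the prey.

Web-level FI averages over ordered pairs with a realized link, i ≠ j and
N_ij > 0. A result is valid only if every off-diagonal FI lies in [0, 1]:
automatic for the ratio under nonnegative flows (violations indicate
integration failure), substantive for the difference (strong cycling can
push N − G above 1). The diagonal is always 0 by convention — under the
difference reading N_ii ≥ 1 always, so self-cycles *must* be excluded by
fiat.

The two definitions tell different stories, and the difference between
them is itself a finding of this implementation. Under the ratio, mean FI
is essentially pinned by the bioenergetics: a surviving consumer
equilibrates where its response sums to 1/y, which fixes predation at
roughly 40–50% of its throughflow, so G column sums sit near 0.4–0.5 and
link-level FI in dense webs hovers around 0.3 *regardless of connectance*
(scaled-scan grand mean ≈ 0.18, SD ≈ 0.13, rising with S and C). Under the
difference, per-link intensities shrink as links proliferate (each g ~
1/(CS)), giving much smaller values (grand mean ≈ 0.02, SD ≈ 0.02) that
peak at intermediate connectance and track path length — the qualitative
pattern usually described for indirectness in such scans. Neither
definition is "the" right one; the ratio is the package default because it
is the dimensionless fraction the term "flow indirectness" names, and both
are recorded per realization so either can be analyzed.

## Predictor metrics

About 27 named scalars per (post-extinction) web, including: size, actual
connectance L/S², link density, undirected characteristic path length
(directed reachable-pairs mode available — the undirected version is the
default because it is the common "small-world" quantity and is defined for
every connected web), spectral radius of the adjacency with self-loops
retained (zero iff acyclic; a measure of cycling), mean/SD/max trophic
level, fractions basal/intermediate/top/cannibal/omnivore/herbivore,
mean and SD of generality and vulnerability (raw and normalized by L/S),
clustering coefficient, degree statistics, diameter. Self-links are
excluded from role counts (a cannibal is not its own predator for
basal/top classification). Metrics are computed on exactly the surviving
web DEA consumed; trophic levels are the ones assigned at parametrization,
subset to survivors — recomputing them on the pruned topology can be
undefined (a consumer can outlive all its prey within a phase), and the
assigned levels are what the dynamics actually used.

## Scan and statistics

The full design is sizes 10–50 (step 1) × connectances 0.10–0.48 (step
0.02) × 250 replicates = 205,000 runs. Each cell replicate gets its own
`SeedSequence(master_seed, spawn_key=(size_index, conn_index, replicate))`
stream, so the scan is reproducible run-for-run and order-independent.
Desk-scale work (tests, the acceptance script, the analysis drivers) thins
the grid to 5 × 5 × 8 = 200 runs, which preserves the span of both axes;
replicate-level spread of the grand mean then scales as 1/√n.

The regression tree uses scikit-learn's learner configured to the classic
complexity rule: a split must raise R² by at least 0.01, implemented
exactly as `min_impurity_decrease = 0.01·Var(y)`, followed by 10-fold
cross-validation over the cost-complexity path to pick the pruning
strength. Reported R² is the in-sample fraction of variance explained
(≥ 0 by construction; a response constant to float precision reports 0).
Predictions route a metric vector down the extracted tree: left branch
when `var < threshold`.

The path-length model is least-squares PathLen = b₁C + b₂C² with no
intercept — no other intercept is possible, since a web with no links has
no paths. Because mean path length *falls* monotonically from ~2.1 at
C = 0.10 to ~1.3 at C = 0.48, a through-origin model cannot track the mean
and the centered R² is negative; the reported R² is therefore the
uncentered convention 1 − SSR/Σy² (what standard regression software
prints for no-intercept fits, ≈ 0.93 here), with the centered value kept
as a secondary field. AIC is Gaussian with the variance profiled out; only
the quadratic-minus-linear difference is meaningful.

## What the synthetic webs do and do not emulate

The generator reproduces the gross architecture of real webs —
interval-niche diets, realistic connectance scaling, omnivory and
cannibalism — but not detritus, detritivory, parasitism, age structure or
spatial flows, and niche values are uniform rather than body-size-derived.
Cycling is therefore much weaker than in detrital ecosystem networks, and
absolute indirectness here underestimates what full ecosystem models show.
Passing tests demonstrate internal correctness of the pipeline under these
study conditions, not that real food webs have these FI values.

## Numerical conventions and edge cases

- All randomness flows from explicit `numpy` Generators; fixed seeds give
  bit-identical webs, trajectories and record tables (tested).
- Files use 1-based species IDs; memory is 0-based. Scan records are
  written at 17 significant digits so `scan` → `analyze` refits are
  bit-exact (tree pruning on small samples is sensitive at the last ulp);
  other CSVs use 10.
- Degenerate/invalid runs are retained in the record table with flags,
  never dropped, and excluded from aggregates.
- A consumer whose prey all sit at zero biomass has F = 0 (numerator
  vanishes; the denominator keeps its B0 terms).
- Problem sizes in the test suite (web sizes ≤ 50, 200-run scans, window
  20) were chosen as the smallest designs that still span both axes of
  the study grid.

## Known limitations

- Webs with basal-inaccessible consumer cycles are excluded rather than
  assigned levels by some regularization; at the highest connectances this
  trims a nontrivial slice of realizations (documented above).
- Extinctions are applied only once, between phases; species can decay to
  numerically negligible biomass *within* phase 2 and still transmit flow
  intensity (G is scale-free in biomass), which inflates indirectness
  relative to a protocol with continuous extinction events.
- The two FI definitions bracket, but do not reproduce, every published
  summary statistic for this class of experiment; see the discussion of
  definitions above.
- Fixed-step RK4 has no stiffness control; rare runs with negative
  biomass excursions are flagged invalid rather than re-integrated.
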