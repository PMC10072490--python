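# Methods

This note documents the models implemented in `mitopart`, the numerical
choices behind them, and what the test suite's synthetic experiments do and
do not establish.

## Cell, network and units

The cell is the closed unit disc; every length is in units of the cell
radius `r`. Physical units enter only through reporting helpers
(`CellGeometry.mitochondrial_area_fraction`, `spacing_um`) with defaults of
a 40 µm radius and 0.4 µm tubule width, under which the default network mass
of 50 r covers ≈16% of the cell area and an exclusion radius `l = 0.05`
corresponds to a 2 µm inter-nucleoid spacing.

Networks are grown by elongation and branching from `s` evenly spaced
perimeter seeds (first seed at a uniformly random angle). The process is a
*generator of geometries with tunable heterogeneity*, not a biophysical
model of fission/fusion: `s = 4` yields lobed, uneven structures; `s = 64`
near-uniform ones. Discretisation: time advances in unit steps; each active
tip elongates by `e = 0.01` per step and branches with probability
`1 − exp(−k)`, `k = 0.02`, spawning a tip at the same point with direction
rotated by a uniform angle in ±π/2 (symmetric, so no chirality artefact);
tips grow straight, die when they reach the boundary (final increment
clipped to the circle), and the last elongation increment is trimmed so the
total mass equals the target exactly. If every tip dies early, the perimeter
is re-seeded with a fresh random offset (capped by `max_reseeds`). The
implementation is event-driven — geometric waiting times between integer-
step branch events, fractional-step deaths and mass cut — which is exactly
the per-step process advanced whole inter-event intervals at a time; it is
compiled with numba when available (a pure-NumPy fallback implements the
same events).

Sector mass (the quantity inherited at division) is measured by subdividing
every edge into pieces no longer than the growth resolution `e` and binning
piece midpoints by polar angle; the error is O(e) per sector-boundary
crossing. Exact polyline/radius clipping was rejected as error-prone near
the origin; the discretised estimator has a testable bound and is consistent
with how molecules themselves are classified (by polar angle).

## mtDNA placement

Counts are deterministic: `w_n = p(1−h)N0` etc., rounded half away from
zero with complements by subtraction, so totals are conserved and tests are
exact. Networked molecules are placed uniformly by arc length; cytoplasmic
molecules area-uniformly (`r = sqrt(U)` sampling). Repulsive placement
inserts the networked molecules in one uniformly shuffled order over both
genotypes (sequential per-genotype insertion would bias which type wins
contested space), rejecting candidates closer than `l` (Euclidean distance,
matching the 2-D "halo" picture rather than arc distance) to any placed
molecule; after `max_attempts` (default 1000) failed candidates the best
candidate seen (largest nearest-neighbour distance) is accepted and a
relaxation event is counted. Relaxation keeps near-critical packings from
dead-ending; the count is reported so analyses can condition on clean
configurations.

## Pre-division diffusion

Fragmentation-and-mixing is modelled as `n_steps = 100` isotropic Gaussian
steps per molecule. "Step width λ" is interpreted as the RMS step length
(per-axis σ = λ/√2), so the unconfined 100-step RMS net displacement is
exactly `10λ`; a per-axis convention is available. Boundary handling
defaults to the Metropolis-style rule — a step whose endpoint leaves the
disc is discarded and the molecule waits — because that chain's stationary
law is exactly area-uniform, so strong diffusion provably erases the network
imprint; redrawing rejected steps ("resample") is available but its
equilibrium density is proportional to the local step-acceptance mass and
therefore slightly interior-weighted. Diffusion is applied to cytoplasmic
molecules as well (they are already at their stationary distribution, so
their statistics are unaffected).

## Division and ensembles

Division keeps a randomly oriented sector of angle φ; a molecule is
inherited iff its polar angle lies in the sector (a molecule exactly at the
origin — a measure-zero event — goes to the sector), and `u` is the sector's
share of network mass. Only the sector daughter is recorded by default;
`both=True` returns the complement too and is used by conservation tests.
Ensembles regrow the network every replicate, so reported variances span
network realisations; a fixed-network mode supports variance decomposition
and null-model runs where no molecule touches the network. Variances use the
unbiased (n−1) estimator; h-moments are taken over replicates with `N > 0`,
with the defined count reported. Standard errors accompany every moment (the
variance SEs use the fourth central moment), since downstream tests are
z-score comparisons against theory.

## Analytic models

All three models condition on the inherited network fraction `U`, modelled
as `Beta(α, β)` with mean `p_c`; `(α, β)` is moment-matched to the
simulated `(E(U), V(U))` per parameter cell.

* **Null**: `W ~ Bin((1−h)N0, p_c)`, `M ~ Bin(hN0, p_c)` independently.
* **Random placement**: given `U = u`, networked counts are binomial in `u`,
  cytoplasmic in `p_c`; marginally beta-binomial, with
  `Cov(W_n, M_n) = w_n m_n V(U)` from the shared `u`.
* **Repulsive placement**: given `u`, the daughter's `d = min(⌊u·S⌋, w_n+m_n)`
  spaces are filled by sampling without replacement, so
  `W_n` is hypergeometric and `M_n = d − W_n` (`Cov(W_n, M_n | u) = −V(W_n | u)`).
  The total space count `S` is explicit, with two presets: `⌊1/l⌋` (the
  literal reading of spacing on a unit of length) and `⌊U*/l⌋` (network
  capacity; 500 at `l = 0.1`). This model is qualitative by construction: it
  imposes perfectly even spacing, which the simulator only approximates, so
  it is expected to overshoot the simulated effect sizes while matching
  their signs.

Closed forms (`closed_form_copy_number`, `closed_form_heteroplasmy`) and the
component-moment/delta-method routes use the *continuous* counts
`w_n = p(1−h)N0` so that the algebraic identities hold to machine precision;
the exhaustive sum, the enumeration oracle and the simulator use the rounded
integer allocation. The first-order variance of `h = M/(W+M)` carries a
negative coefficient on `Cov(W, M)` — the mechanism by which repulsion-
induced negative coupling *raises* heteroplasmy variance in homogeneous
networks. The second-order route is the generic multivariate delta method
using exact joint central moments of `(W, M)` up to fourth order; it is an
approximation validated only against the exact sum, never assumed exact.

The exhaustive sum exploits conditional independence of `W` and `M` given
`U` to replace the four-fold sum with two discrete convolutions and a 2-D
grid contraction per `U`-node (the repulsive model's `M_n = d − W_n`
coupling is handled by summing over the hypergeometric support explicitly).
Integration over `U` uses Gauss–Jacobi quadrature, which is exact for the
beta weight and remains valid for fitted shapes below 1; 200 nodes by
default with a node-doubling convergence check (warning above 1e−8 relative
change). For the repulsive model the integrand depends on `u` only through
the integer `⌊u·S⌋`, so the integral is computed exactly from Beta CDF
masses of the intervals `[j/S, (j+1)/S)` — quadrature would converge slowly
on that piecewise-constant integrand. The `(W, M) = (0, 0)` atom (undefined
`h`) is excluded from h-moments and its mass reported, matching the
simulator's convention. An edge case worth noting: for tiny `N0` the rounded
allocation can leave zero networked molecules, where the hypergeometric pmf
degenerates to a point mass at zero (special-cased; SciPy returns NaN for an
empty population).

## Approximation behaviour worth knowing

The first-order (Taylor) normalised heteroplasmy variance is systematically
below the exact value, and the gap is resolvable at realistic ensemble
sizes: at `N0 = 100`, `p = q = 0` the exact `V'(h)` is 0.01031 against the
first-order 1/N0, and at `p_c = 0.1` it is 0.1023 against 0.09. Tests that
validate the *simulator* therefore compare it with the exact sum, not with
first-order formulas; tests of the closed forms assert their algebraic
identities or their leading-order accuracy. On the unbiased diagonal
`p = q` the first-order formula predicts a small dip below the null
(−4pV(U)/N0) that the exact routes show to be an artefact; the second-order
term corrects in the opposite direction. For strongly asymmetric division
the expansion underestimates heteroplasmy variance — both behaviours are
asserted in the suite.

## Experiment grids and defaults

`SweepSpec` defaults mirror the study conditions: an 11×11 `(p, q)` grid
over [0,1]², seed counts {4, 16, 64}, `h ∈ {0.1, 0.5}`, `N0 ∈ {100, 1000}`,
symmetric division, 2000 replicates per cell. Replicate count and grid
resolution are the package's choices (statistics per cell resolve the
corner-vs-diagonal structure at ~3σ; the diagonal's internal ~1e−5
gradations are below Monte-Carlo resolution at any practical count — see the
test docstrings). Child RNG streams are spawned per cell from
`SeedSequence([master_seed, cell_index])`, so results are independent of
execution order and bytewise reproducible. Exact-sum columns are attached
for cells with `N0 ≤ 200` in the undiffused random-placement regime, where
that theory is the matched model.

## What the synthetic experiments do not show

The generator produces plausible 2-D network geometries, not real
morphologies: no fission/fusion dynamics, no curvature, no 3-D structure,
no coupling of network state to the cell cycle, and no mtDNA turnover,
replication or selection between divisions. Genotypes are placed without
spatial correlation, so clonal clustering — which would add heteroplasmy
variance — is absent. Passing tests therefore establish internal
consistency (simulation ↔ exact theory ↔ oracles) and the qualitative
control principles (bias amplifies, homogeneity + self-avoidance
suppresses, diffusion erases), not quantitative predictions for any
particular cell type.

## Known limitations

* The repulsive analytic model's space count is a free parameter; only signs
  and orderings of its predictions are meaningful.
* Delta-method routes degrade for small `N0`, strongly asymmetric division,
  or strong coupling; use the exact sum (`N0 ≤ 5000`) in those regimes.
* Sector mass is O(e)-accurate per boundary crossing; with default
  parameters this is ~1e−2 absolute on a mass of 50, negligible relative to
  Monte-Carlo error but visible to exact assertions (tests use tolerances
  accordingly).
* With numba absent the growth loop falls back to NumPy and draws from a
  different RNG stream, so seeded outputs differ between the two builds
  (each is internally deterministic).
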