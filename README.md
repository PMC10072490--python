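# mitopart

Spatial simulation and analytic statistics of **mtDNA partitioning at cell
division under mitochondrial network structure**.

Mitochondria carry their own genomes (mtDNA), present in hundreds to
thousands of copies per cell, and a cell's mitochondria range from fully
fragmented organelles to a cell-wide fused network. When a cell divides, any
randomness in how molecules are apportioned generates cell-to-cell
variability in copy number `N` and in heteroplasmy `h = M/(W+M)` (the mutant
fraction) — variability that drives genetic bottlenecks and the segregation
of mtDNA disease mutations. `mitopart` quantifies how the *physical
arrangement* of mtDNA — inside vs. outside a reticulated network, evenly
spaced vs. randomly placed, before and after pre-division fragmentation and
diffusion — shapes the variances `V(N)` and `V'(h) = V(h)/(h(1−h))` that
daughters inherit.

It is a library for modellers of organelle genetics: the public face is the
importable API plus `examples/` scripts; a thin `mitopart` CLI wraps the
sweep machinery for shell use.

## The model

A circular cell (unit disc, lengths in cell radii `r`) contains:

* **A random network** grown by elongation (rate `e = 0.01` per step) and
  Poissonian branching (`k = 0.02`) from `s` evenly spaced perimeter seed
  points, until total length `U* = 50 r` exists. Few seeds → heterogeneous
  networks; many seeds → homogeneous ones. At a 40 µm cell radius and 0.4 µm
  tubule width this is a ~16% mitochondrial area fraction.
* **`N0` mtDNA molecules** at mother heteroplasmy `h`: a proportion `p` of
  wildtype and `q` of mutant molecules sit on the network (uniformly by arc
  length, or with a mutual-exclusion halo of radius `l`); the rest are
  area-uniform in the cytoplasm. Optionally every molecule then performs a
  confined random walk of 100 Gaussian steps of RMS length `λ` (net
  displacement ≈ `10λ`), modelling pre-division fragmentation and mixing.
* **Division** removes a randomly oriented sector of angle `φ`
  (`p_c = φ/360` of the cell; `φ = 180°` is symmetric) and records the
  daughter's `W`, `M`, `h`, and inherited network fraction `u`.

Matched statistical models predict the same quantities. With
`U ~ Beta(α, β)` the inherited network fraction (mean `p_c`, variance
`V(U)` fitted from simulation), and `κ = p(1−h) + qh` the networked mtDNA
fraction:

* binomial null (no network): `V(N) = N0 p_c (1−p_c)`,
  `V'(h) = (1−p_c)/(p_c N0)` (→ `1/N0` for symmetric division);
* random placement: `W_n ~ Bin(w_n, U)` etc., so networked counts are
  beta-binomial with `Cov(W_n, M_n) = w_n m_n V(U)`, giving
  `V(N) = N0 p_c(1−p_c) + κN0(κN0−1) V(U)` and
  `V'(h) = (1−p_c)/(p_c N0) + (V(U)/p_c²)(h(1−h)(p−q)² − (ph+q(1−h))/N0)`;
* repulsive placement: the daughter's share of the network holds
  `⌊u·S⌋` discrete spaces filled without replacement
  (hypergeometric, `M_n` determined by `W_n`) — a deliberately qualitative
  picture of mtDNA self-avoidance.

Heteroplasmy moments come from first- and second-order delta-method
expansions, from an exhaustive sum over the state variables
`(W_n, W_c, M_n, M_c)` with exact integration over `U`, and (for tiny `N0`)
from a brute-force enumeration oracle used to validate the sum.

## Worked example

`python examples/network_bias_variance.py` prints (seeded):

```
binomial null: V(N) = 25.0, V'(h) = 0.0100
(p, q) = (0, 0): V(N) =   25.0 +- 0.6, V'(h) = 0.0107 +- 0.0002
(p, q) = (1, 0): V(N) =   53.8 +- 1.2, V'(h) = 0.0227 +- 0.0005 | theory: V(N) = 53.6, V'(h) = 0.0214
```

With no network placement the simulation reproduces the binomial null
(`V(N) = N0/4 = 25`, `V'(h) ≈ 1/N0`). Putting all wildtype molecules in a
heterogeneous 4-seed network while mutants stay cytoplasmic roughly doubles
both variances: each daughter inherits a noisy share `u` of the network and
all networked wildtypes with it, while mutants partition independently —
biased network inclusion acts as a genetic bottleneck. The theory columns
are the closed forms above, evaluated with `Beta(α, β)` fitted to the
simulated `(E(U), V(U))`.

The other scripts in `examples/` each demonstrate one capability:
single-cell anatomy (`grow_and_partition.py`), agreement and disagreement of
the analytic routes (`analytic_routes.py`), sub-binomial control from
self-avoidance (`repulsive_control.py`), and diffusion washout of the
network imprint (`diffusion_washout.py`).

A grid sweep from the shell:

```
mitopart sweep --p-grid 0,0.5,1 --q-grid 0,0.5,1 --seeds-list 4,64 \
    --h-list 0.5 --n0-list 100 --reps 2000 --seed 0 --out sweep.csv
```

writes one row per grid cell (simulated moments with standard errors, the
fitted `(α, β)`, the binomial-null baseline, closed-form / Taylor /
exact-sum predictions) plus a JSON manifest sufficient to regenerate it.

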