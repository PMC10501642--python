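# Methods

## Model

The population is a weighted digraph with one haploid individual per node.
Fitness is a number in the closed domain `[f_min, f_max]` (default
`[0.1, 10]` throughout the package's study conditions), constant for an
individual's lifetime and frequency-independent.  One Moran Birth–death
step selects a reproducer fitness-proportionally among all `N` nodes,
mutates the offspring with probability `μ`, and places it on an
out-neighbour drawn from the reproducer's row of the row-normalized weight
matrix (self-loops allowed).  Time is measured in Moran steps; one update =
one step, in simulation and in every analytic time formula.

Only weight *ratios* within a row enter the dynamics, so graphs store raw
weights and all computations use the row-normalized matrix.  The node
temperature `T_j = Σ_i w_ij` (column sums of the normalized matrix)
measures how often node `j` is replaced; for sink-free graphs `Σ_j T_j = N`
exactly.  A fresh mutant arises where a replacement just happened, so
single-mutant quantities are aggregated with temperature weights
("temperature initialisation").

### Graph families and the sink convention

Built-in families: complete, cycle, star, self-looped weighted star
(Eq-style rows: center `(1−δ, δ/n, …, δ/n)`, leaves `λ` toward the center
and `1−λ` on the diagonal; defaults `λ = 1/(N−1)`, `δ = 1/(N−1)²`),
self-looped complete/cycle/star (equal outgoing weights including the
loop), directed line and self-looped directed line (root node 0; the
self-looped terminal keeps weight 1 on its loop), the "molded" directed
line (adds the link 1→0 so every node has an incoming link), and the burst
(one center with equal-weight links to its leaves) plus its "modified"
variant (adds one leaf→center link).

The plain directed line's terminal node and the burst's leaves have no
outgoing links.  We deliberately treat such *sink* nodes as sterile: a sink
selected for reproduction produces nothing and the step is a null event.
The alternative — giving sinks an implicit self-loop — would change the
science: a self-loop couples a node's replacement rate to its own fitness,
which is precisely the mechanism that pins self-looped graphs to the
domain midpoint at high mutation rates, whereas the universal balance of
loop-free graphs rests on each node's replacement rate being independent of
its own fitness (up to the shared `Σf` normalisation).  With sterile sinks
the modified burst and molded directed line join the universality class, as
the high-`μ` experiments confirm.

### Mutation kernels

`uniform`: `ζ = 1/(f_max−f_min)`, parent-independent.
`truncated_gaussian`: a Gaussian of mean `f_parent` and standard deviation
`σ`, renormalized by its mass on the domain.  Density, sampler and
detailed-balance ratio are mutually consistent: the sampler resamples
until the draw lands in the closed domain, which realises exactly the
renormalized density (no clipping, no mass at the bounds beyond the
density's own).  The ratio `ζ(a,b)/ζ(b,a)` reduces to the ratio of
truncation masses because the Gaussian exponents cancel in `|a−b|`.

## Exact two-type analytics

With `μ = 0` and two fitness values (wild-type 1, mutant `r`), the
dynamics on a symmetric family reduces to a one-dimensional Markov chain.
Fixation probabilities use the standard products of conditional transition
probabilities (log-space for large state counts).  Conditional mean
absorption times are obtained by solving the linear system satisfied by
`ψ = φ·τ` on the conditional jump chain,

    ψ_s = Σ_s' π(s→s') ψ_s' + φ_s t_s ,    ψ = 0 at both absorbing states,

where `t_s` is the mean sojourn time of state `s` (reciprocal of its total
exit probability) and `φ` is either the fixation or the extinction
probability vector.  For the star chain this is a banded sparse system in
the `2n` transient states; for birth–death chains a tridiagonal solve.
This route is algebraically equivalent to the published nested-sum
solutions but avoids their notational hazards; the test suite pins it
against (a) a dense solve of the full chain with self-transitions included,
(b) an independent implementation of the classical nested sum, and (c) the
neutral closed forms, all to ≤1e-9 relative error.

Boundary subtlety worth recording: the product formula
`φ_i• = A(1,i)/A(1,n)` for the star holds for `i ≥ 1`; the state `(•,0)`
(a lone mutant center) satisfies `φ_0• = π••·φ_1•` because its only
upward conditional move is to `(•,1)` and its downward move is extinction.

The self-looped directed line is special: only a root-seeded mutant can
fix, and then the mutant block can only grow, giving the exact
`τ₁ = Σ_k 2(kr+N−k)/r = N(N−1)(1+1/r)` for every initialisation scheme.
Its extinction time is the stated single-path approximation (growth to the
terminal node, then shrinkage from the left), valid for `r ≫ 1` and
flagged as such on the result object; the temperature weighting uses the
actual non-root temperatures (bulk 1, terminal 3/2).

### Conditional-time estimators

The analytic temperature-initialised times weight the per-initial-state
conditional times by temperature alone.  A pooled Monte-Carlo conditional
mean instead re-weights initial states by their conditional outcome
probability — a different (also legitimate) functional that can sit several
standard errors away.  The Gillespie and microscopic ensemble estimators
therefore report the scheme-weighted aggregate (per-initial-state
conditional means recombined with exact temperature weights) as `tau_T`,
keeping the pooled estimator alongside.  Initial states contributing fewer
than two conditioned events are dropped with their weight renormalized; the
induced bias is bounded by the dropped weight share times the between-state
time spread (negligible in the regimes exercised here, where the dropped
state's conditional probability is itself tiny).

### Gillespie engine

On the reduced chains most Moran steps are self-transitions.  The
event-driven sampler draws the waiting time to the next
configuration-changing event from an exponential with mean equal to the
reciprocal of the total exit probability and picks the event
proportionally to its transition probability.  The embedded jump chain is
identical in law to the microscopic one, and replacing geometric by
exponential waiting preserves every mean sojourn exactly; only
higher-order waiting-time moments differ, an O(1)-per-event effect
invisible at the `≥ N²` absorption times studied.

## Mutation–selection balance

**Low `μ`.**  The population is effectively monomorphic; fitness jumps
`f → f'` at rate `μ ζ(f',f) φᵀ(f',f)`.  Assuming detailed balance of this
jump chain (the package follows the convention of asserting it for all
families, though reversibility is only proved for the high-`μ` reference),
the stationary density is `P*(f) ∝ 1/∫df' [φᵀ(f',f)/φᵀ(f,f')]
[ζ(f',f)/ζ(f,f')]`, evaluated on a uniform grid (default 2001 points,
inclusive endpoints) by trapezoid quadrature with the ratio formed in log
space.  The two-type reduction sees fitness only through `r = f'/f`, so
star-family `φᵀ` comes from the weighted-star closed form; the complete
graph and cycle share the isothermal formula; on the self-looped directed
line `φᵀ = T_root/N` independent of fitness, so its low-`μ` balance is
exactly uniform.  For the complete graph the quadrature mean agrees with
the closed form `⟨f⟩ = N/(N+1)·(f_max^{N+1}−f_min^{N+1})/(f_max^N−f_min^N)`
to better than 1e-4 relative at the default grid.

**High `μ`.**  At `μ = 1` on the self-looped complete graph every
replacement deposits an independent kernel draw and each node is equally
likely to be hit, so with the uniform kernel the per-node marginal is flat:
population mean `(f_min+f_max)/2` for every `N`, population standard
deviation `(f_max−f_min)/√(12N)`.  Reversibility is certified through
Kolmogorov's cycle criterion.  Note a structural fact the implementation
exposes: for the full-sweep product density `T(f←f') = Π_i ζ(f_i, f'_i)`
the kernel masses telescope around any closed cycle, so the sweep-level
chain is reversible for *every* kernel; kernel-induced irreversibility
(e.g. a parent-centred Gaussian) appears only in the microscopic
single-update density, which is provided separately.

## Threshold and scalings

`1/μ_th = max_r {τᵀ(r), τ̃ᵀ(r)}` over a log-spaced grid (101 points) of
the achievable relative fitness `[f_min/f_max, f_max/f_min]`; the grid
contains `r = 1` exactly when the domain is symmetric in logs.  For the
star, complete and cycle families the maximum is the fixation branch near
neutrality; for the self-looped directed line the fixation time grows as
`r` falls, so the smallest achievable `r` dominates.  Scaling exponents
are ordinary least-squares slopes of `log τ` against `log N`, reported
together with their nearest-integer rounding (the advertised contract);
three well-separated sizes (`10³–10⁴` for the star families, `10²–10³`
for the chain sums) suppress the subleading harmonic-number terms.

## Simulation design and what the tests show

The simulator's compiled loops advance one Moran step at a time; replicate
`j` of an ensemble uses an independent stream seeded from
`SeedSequence((seed, j))` — consecutive integer seeds of the underlying
Mersenne Twister produce measurably correlated replicate streams, enough
to bias ensemble means by more than one standard error.  Ensembles start
homogeneous at the domain midpoint, discard the first half of each
trajectory for node-wise time averages, and report ensemble statistics at
the final recorded time.  Default study conditions mirror the reference
experiments: `N = 10`, uniform kernel on `[0.1, 10]`, 2000 replicates for
the high-`μ` reference check and reduced replicate counts (48–500) with
standard-error-aware assertions elsewhere; horizons are `10⁴·N` steps for
figure-level sweeps and are shortened where the relaxation time is known
to be far smaller (the `μ = 1` self-looped complete graph relaxes in
`O(N log N)` steps).  Low-`μ` runs sit at `μ_th/10`, which is inside the
plateau yet still substitutes often enough to equilibrate within the
stated horizons.

These synthetic experiments emulate exactly the model's own assumptions —
bounded frequency-independent fitness, one mutation per birth at most,
fixed graph topology.  Passing tests therefore validate the
implementation and the internal consistency of the theory at desk scale;
they say nothing about real populations with frequency-dependent
selection, environmental change, or graph rewiring, and the full-scale
published curves (2000 replicates at large `N` across whole `μ` grids)
are exercised only as scaled-down runs plus the exact analytic surfaces.

## Numerical choices and limitations

* Neutrality detection at `|r−1| < 1e-10` switches the complete-graph
  formula and the `γ`-products to their exact limits; `expm1`/log-space
  evaluation keeps fixation probabilities stable to `N = 10⁶`.
* Harmonic numbers by direct summation (exact to machine precision for
  the `n ≤ 10⁶` used).
* The star conditional-time solver is a sparse LU on a bandwidth-2 system;
  conditional times are reported as NaN where the conditioning probability
  vanishes (never as 0).
* Fixation experiments carry a hard step cap (default `10⁹`) with explicit
  truncation counting, since self-looped-star absorption grows as `N⁵`.
* Exact absorption analytics cover only the reduced families (star family,
  complete, cycle, directed line); arbitrary graphs fall back to
  simulation — the full `2^N`-state problem is out of scope.
* The burst topology is a documented convention (the family is named but
  not drawn in the source material): center→leaves only, sterile leaves;
  the modified burst adds the single leaf→center link.
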