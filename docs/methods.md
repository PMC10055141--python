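# Methods

## Model

The analysis treats regional brain activity as a linear
time-invariant system `x' = A x + B u` on a weighted, undirected,
connected structural connectome. `A` is the connectome's weight
matrix rescaled to `A_norm = A/(λmax + c) − I`. With the default
`c = 0` the dominant connectome mode is marginally stable (largest
eigenvalue of `A_norm` is exactly 0) and all other modes decay; with
`c > 0` (the package also supports the common `c = 0.01·λmax`
setting) every mode decays and the free system relaxes to zero.
`B = diag(b)` places control gains on regions: all ones for uniform
whole-brain control, or heterogeneous gains derived from annotation
maps (below).

A transition from a source activation map `x0` to a target map `xT`
over horizon `T` is scored by the finite-horizon optimal control
problem

    min_u ∫₀ᵀ (xT − x(t))ᵀ(xT − x(t)) + ρ uᵀu dt,
    s.t. x' = A_norm x + B u,  x(0) = x0,  x(T) = xT.

The integrand jointly penalizes trajectory distance from the target
(discouraging long excursions) and instantaneous input power, with
`ρ` the trade-off weight. Defaults are `T = 1`, `ρ = 1`, uniform `B`.
The reported transition energy is `E = Σₖ ∫₀ᵀ uₖ*(t)² dt`, the raw
(unweighted) input energy summed over controlled nodes; per-node
energies are retained for diagnostics.

## Solver

The Hamiltonian's stationarity condition gives
`u* = −Bᵀλ/(2ρ)`, turning optimality into a linear two-point
boundary-value problem in the stacked state/costate vector:

    d/dt [x; λ] = [[A_norm, −BBᵀ/(2ρ)], [−2I, −A_normᵀ]] [x; λ] + [0; 2 xT].

The solver computes the exponential of this 2N×2N block matrix (plus
its time-integral, obtained from one augmented exponential) and
recovers `λ(0)` from the linear system enforcing `x(T) = xT`. State
and costate are then propagated exactly at the grid times by repeated
application of the per-step exponential; the time grid (default
`n_steps = 1000` intervals) affects only the trapezoidal quadrature
of `∫ u² dt` and the resolution of the returned trajectory, not the
dynamics. The terminal state is verified to match the target within a
relative `reach_tol` (default 1e-6), and the condition number of the
boundary solve is checked (warning above 1e10; hard error when
singular, which signals an uncontrollable configuration).

The all-pairs transition-energy matrix uses the same operators with
all K² ordered source/target pairs propagated as one batched linear
recursion, so one matrix exponential per connectome serves every
pair; a unit test confirms bitwise-scale agreement with per-pair
solves. Diagonal (self-)transitions are computed, not skipped. Maps
can optionally be rescaled to unit Euclidean norm before solving.

Useful exact properties (all enforced by tests): energy is
nonnegative; scaling both boundary states by α scales energy by α²;
the dominant connectome mode is a zero-energy fixed point under
`c = 0`; raising `ρ` never increases the raw input energy (the
weighted component `ρ∫u²` never decreases); uniformly raising the
control gains never increases energy.

## Graph quantities

Effective resistance is `ω_ij = (e_i − e_j)ᵀ Q (e_i − e_j)` with `Q`
the Moore–Penrose pseudoinverse of the weighted Laplacian, computed
by eigendecomposition with a relative eigenvalue cutoff of 1e-10 for
the null space (robust for near-disconnected graphs; exactly one
null mode is expected and a deviation triggers a warning). Commute
time (`vol(G)·ω`) is provided as a cross-check against explicit
random-walk first-passage computations. The network variance of a
map is `var(p) = ½ Σ_ij p(i)p(j) ω_ij` after rescaling the map to a
distribution (shift minimum to zero, divide by the sum). Effective
resistance itself plays the role of the squared distance in this
formula — the convention of the measure's source — rather than being
squared again; this is a documented convention, not a free choice
left implicit. Nodal predictors are binary degree, strength, and the
weighted participation coefficient `P_i = 1 − Σ_m (κ_im/κ_i)²`
(weighted because the connectome is weighted; isolated nodes get
`P = 0` and a flag).

## Null models

*Degree-preserving (Maslov–Sneppen)*: repeated edge-pair swaps
rejecting self-loops and multi-edges, weights travelling with their
edges, so the binary degree sequence and the weight multiset are
preserved exactly. Default 10 accepted swaps per edge; graphs with no
valid swap (stars, complete graphs) are returned unchanged with a
warning.

*Geometry-preserving*: same swap process, but a swap is accepted only
while every distance-bin edge count stays within a fractional
tolerance (default 20%, 10 quantile bins) of the empirical edge-length
histogram; after topology randomization the original weights are
reassigned within distance bins by length rank, preserving the weight
multiset exactly and the weight–length relation approximately. Bin
count and tolerance are exposed because the underlying method is
conventionally reported without parameters.

*Spin surrogates*: a uniformly random 3D rotation is applied to the
left-hemisphere unit-sphere coordinates and its mirror image (about
the sagittal plane) to the right; each original parcel takes the
value of the nearest rotated parcel of the same hemisphere. This
preserves the value distribution (values are drawn from the original
multiset, with repeats possible) and the spatial autocorrelation,
while randomizing anatomical placement. A bijective
(assignment-problem) variant yields exact value permutations for
exactness-sensitive uses.

Null comparisons use `z = (empirical − mean(null))/SD(null)`
(sample SD) and one-sided empirical p-values with the +1 correction,
oriented in the direction of the stated hypothesis (the package
documents sidedness explicitly because conventions differ).
Domain-level asymmetry uses a label-permutation test on the median
net score.

## Input weightings

Receptor maps are min–max scaled and added to the uniform gains
(`b = 1 + scaled`, range [1, 2]); disease maps (Cohen's d of
cortical-thickness abnormality) are added directly (`b = 1 + d`,
rejected unless `d > −1`). Surrogate weightings are built by spin-
rotating the *raw* annotation map and passing it through the same
gain construction, so the gain distribution is preserved and only
placement varies. Disease scoring z-scores the mean energy-to-reach
of each target against the surrogate ensemble (negative z: the
empirical abnormality layout makes the target cheaper to reach than
random layouts). Receptor scoring counts, per (source→target,
surrogate) comparison, how often the empirical map yields strictly
lower energy, pooled within target state; the per-transition
percentage table is also emitted since the aggregation could equally
be read per transition. Both analyses default to a reduced state set
and `n_rot = 100` rotations to keep desk-scale runs fast; full
fidelity is a parameter away.

## Predictors and dominance

Each state's response is the mean energy to reach it from every other
state. Predictors are the map's mean and SD, its network variance,
and Spearman correlations with nodal architecture. Partial Spearman
correlations rank-transform all variables, residualize on the ranked
covariates by least squares, and use a t-based p-value
(df = n − 2 − k). Dominance analysis fits OLS on every non-empty
predictor subset and averages each predictor's incremental R²
stratified by model size (Budescu-style), which makes the dominances
sum exactly (to 1e-10) to the full model's unadjusted R²; a uniform
(unstratified) averaging variant and an adjusted-R² display are
available, with the caveat that the exact sum identity holds only
for unadjusted R² under size-stratified averaging.

## Synthetic study conditions

The generator emulates the signatures the analysis needs: 68 nodes on
two lateralized spherical caps (yielding Euclidean and unit-sphere
coordinates plus hemisphere labels), edges sampled with probability
∝ exp(−d/30 mm) on top of a connectivity-guaranteeing minimum
spanning tree until 27% density, and weights ∝ exp(−d/30 mm) with
lognormal scatter — giving the strong negative weight–length
correlation characteristic of consensus connectomes. State maps are
white noise diffused by the graph heat kernel `exp(−s·L_norm)`
(default smoothness s = 2; graph diffusion rather than Euclidean
smoothing so spatial structure is defined even for abstract test
graphs), then affinely rescaled to means drawn from [0.5, 2.0] and
SDs from [0.5, 1.5], mimicking the heterogeneous means/SDs of
meta-analytic activation maps. Receptor-like maps are smooth and
min–max scaled to a drawn positive range; disease-like maps are
smooth, zero-centred and clipped to [−0.6, 0.9] so `1 + d` gains stay
within the plausible positive envelope. A hub-concentrated variant
(values monotone in node strength) supports spatial-specificity
checks.

What the generator does *not* reproduce: real cortical geometry and
parcel adjacency, subject-level variability, the empirical magnitude
of connectome weights (so absolute energies are not comparable to any
particular dataset), and the specific anatomy of real receptor or
disorder maps. Passing tests therefore establish the correctness and
the directional behaviour of the machinery (e.g. geometric
connectomes outperform degree-preserving nulls; energy varies more
across targets than sources when target maps are heterogeneous), not
dataset-specific effect sizes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end study at
68 nodes with 20 maps and 50 nulls per kind, using a 200-interval
quadrature grid for null ensembles (the energy quadrature error at
that resolution is orders of magnitude below the null-to-empirical
differences being tested) and the default 1000-interval grid for
headline matrices. Ties in rank statistics use scipy's average
ranking. Self-transition energies can be tiny negative numbers from
quadrature round-off and are clamped to zero. Repeated identical
energy computations can differ at the 1e-15 level (BLAS reduction
order); degeneracy checks therefore use relative tolerances rather
than exact equality.

## Known limitations

Linear, noise-free, time-invariant dynamics; a single connectome (no
consensus construction or subject-level modelling); spin surrogates
require spherical coordinates and hemisphere labels (an error directs
users to permutation nulls otherwise); dominance analysis is
exhaustive and limited to 8 predictors; the geometry-preserving null
controls binned edge lengths, not exact per-edge lengths.
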