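# Methods

## The two-fork zipper model

A neurite shaft relocating between two fasciculated neighborhoods is
modeled as a lumped mechanical system with two moving forks: a zippering
fork where the shaft adheres progressively to the target (anterior)
neighborhood and an unzippering fork where it peels off the source
(posterior) neighborhood. At each fork, adhesion per unit length `S`
favors attachment and the tension `T` carried by the shaft opposes it,
attenuated by the geometric factor `(1 − cos θ)` where `θ` is the approach
angle of the shaft to the bundle. In the overdamped limit (friction
constant `η`) the fork velocities are

    v_zip   = [S_ant − T_ant (1 − cos θ)] / η
    v_unzip = [T_post (1 − cos θ) − S_post] / η

whose sum is the combined balance `ΔS/η − ΔT (1 − cos θ)/η`. The
per-fork split is the unique symmetric decomposition consistent with the
combined equation and with the sign conventions that adhesion favors and
tension opposes zippering; the same `η` and `θ` are used at both forks.
Both velocities are signed: a negative `v_zip` is de-adhesion from the
anterior neighborhood, a negative `v_unzip` is re-zippering onto the
posterior one.

**Assumptions.** The shaft is inextensible on the force scale considered;
forces are lumped at the forks (no continuum elasticity or bending
energy); `θ` is a parameter, optionally time-varying only through the
adhesion schedule; friction is linear. Only the ratios `S/η`, `T/η`
(μm/min) are identifiable from kinematics, so force units are arbitrary
but must be consistent.

**Integration.** Explicit forward Euler with per-step clamping:
`l_anterior` is capped below at 0 and above at the optional `midline_cap`
(a phenomenological stand-in for the force balance that stops zippering at
the dorsal midline — `equilibrium_residual` exposes the mechanistic
check); `l_posterior` is clamped at 0. With `conserve_length` the free
transit segment absorbs the difference so the total length is constant,
and a zippering step that would exhaust the free segment is truncated (and
logged). Euler is exact for piecewise-constant velocities, which is the
regime of constant parameters, and adequate for the piecewise-linear
adhesion schedules used here at the default `dt = 1 min` (the CLI default;
the synthetic generator samples at 5 min, see below). Negative-length
overshoot from aggressive parameters is clamped with a logged warning
rather than raised, since noisy inferred parameters can transiently
overshoot.

**Inverse estimation.** Under the uniform-tension assumption
(`ΔT = 0`, tension equilibrates along the shaft faster than the forks
move) the summed fork velocity equals `ΔS/η` directly. The estimator
aligns the anterior and posterior position series on their common
timestamps (intervals lacking either measurement are dropped with a log
message), forms per-interval summed forward differences
`(ΔL_a − ΔL_p)/Δt`, and aggregates by the mean. With equally spaced
samples the mean telescopes to the endpoint secant, so its sampling noise
is set by the recording span, not the cadence. The sign of the aggregate
is reported as the direction of differential adhesion. `θ` is accepted
and recorded for provenance but does not enter the `ΔT = 0` estimate.

## Kinematics

Velocities are forward differences between consecutive tracked timepoints,
matching how sparse embryonic time-lapse measurements are reported;
unzippering velocities are reported as positive magnitudes of posterior
length decrease. Percent zippered is the zippered length over the initial
relocating length × 100; values above 100% (possible with measurement
noise) warn but are not clipped, so downstream statistics see the raw
measurement. Acceleration is summarized as the ratio of late- to
early-window mean velocities — a deliberate choice over trend tests, which
would add statistics the underlying measurements do not state. Window
endpoints snap to the nearest sampled time rather than interpolating,
because embryo series are sparse and timepoint labels carry ±5 min
uncertainty.

## Connectome metrics

Contact vectors are extracted per dataset for a focal neuron over the
lexicographically sorted intersection of all datasets' neuron sets
(excluding the focal neuron), with absent contacts as zeros; the fixed
ordering makes similarity values reproducible bit-exactly. Cosine
similarity is the direct formula; it is undefined for a zero vector and
raises with guidance.

Betweenness centrality is computed on the binarized graph (edge iff
weight strictly greater than the threshold, default 0 — with `≥`, a zero
threshold would turn every non-edge into an edge; diagonal forced to 0)
with the standard interior-vertex convention (`s ≠ v ≠ t`): that is the
only reading under which the normalization `(N−1)(N−2)/2` (undirected; or
`(N−1)(N−2)` directed) bounds values to [0, 1]. Disconnected pairs
contribute zero. The graph machinery is delegated to networkx; the test
suite cross-checks it against an exhaustive all-shortest-paths enumerator
on small random graphs. Undirected is the default (membrane adjacency is
symmetric); a directed mode covers synaptic matrices. Nerve-ring-style
restriction is expressed as a user-supplied neuron subset
(`AdjacencyMatrix.subset`).

## Contact patches

Membrane juxtaposition in labeled section stacks is detected per slice by
dilating each cell mask by `k` pixels and intersecting with every other
*undilated* mask; each nonempty intersection is one directional patch
(pixels of the neighbor within reach of the dilated cell). The default
structuring element is the square (Chebyshev ball) of radius `k`: it is
separable, deterministic, and makes the gap criterion exactly statable —
two labels separated by `g` background pixels (Chebyshev) are detected iff
`k ≥ g + 1`, since dilation by `k` must cross *into* the neighbor, not
merely fill the gap. A disk element is available behind a flag. Images
are zero-padded at borders (no wraparound). By default the two
directional patches of a pair are merged per slice by pixel union; a
keep-directional mode reproduces the raw two-records-per-pair bookkeeping
of ROI-based pipelines.

"Contact area" from stacked 2-D patches is ambiguous, so summaries report
both readouts, labeled: in-plane area (pixels × pixel_size²) and slab
area (per-slice longest bounding-box extent × z-spacing, a membrane
apposition proxy). Mesh export rasterizes one pair's patches into a
binary volume scaled by (z_spacing, pixel_size, pixel_size), pads one
empty voxel so border surfaces close, and runs marching cubes at isovalue
0.5; vertices are written to OBJ in nm with origin at slice 0, pixel
(0, 0). Watertightness per component is not guaranteed.

Coordinates are 0-based (slice, row, col); the reference geometry is
4.5 nm/px in-plane and 60 nm section spacing, under which the default
9-px dilation corresponds to a ~40 nm contact criterion.

## Morphometrics

All lengths are arc lengths along user-supplied polylines; no smoothing.
`min_distance` replaces the manual "shortest perpendicular gap" selection
with the exact polyline–polyline minimum distance (shapely in 2-D; an
exact convex-quadratic segment-pair minimization in 3-D), which is the
quantity the manual procedure estimates. Background subtraction returns
`reference − region` (region mean subtracted *from* the cell-body mean);
the convention is documented on the function since the plotted sign in
scoring pipelines can differ, and callers can negate. Group-comparison
statistics (ANOVA, Fisher's exact, t-tests, effect sizes) are deliberately
out of scope: the package emits tidy values suitable for any stats
environment.

## Synthetic data

Generators are pure functions of (config, seed) and their ground truth is
sufficient to score the matched analysis exactly under zero noise.

- **Trajectories** default to the embryonic repositioning window
  485–545 min post fertilization sampled at `dt = 5 min` (light-sheet
  volumes are acquired more frequently than the reported summary
  timepoints), a 10 μm neurite split as `l_a = 2`, `l_p = 5`,
  `l_free = 3` μm, and planted `ΔS/η = 0.2 μm/min` (`v_zip = 0.15`,
  `v_unzip = 0.05` at `θ = π/2` with equal tensions), matching the
  observed 0.09–0.34 μm/min velocity scale. Position noise is additive
  Gaussian, default σ = 0.5 μm (5% of total length); starting `l_a` at
  2 μm keeps the nonnegativity clip ≳4σ away so clipping cannot bias the
  estimator. Noise choices are for realism and positivity; the source
  measurements state no noise model.
- **Label stacks** place rectangular cells in a row with exact planted
  Chebyshev gaps (random in 0–12 px by default) between consecutive
  cells; cell width 14 px guarantees non-consecutive pairs stay beyond
  the dilation radii of interest, so the planted gap list fully
  determines detectability and the per-slice merged contact pixel count
  has the closed form `2 · height · min(k − gap, width)` — an independent
  oracle for the morphology-based detector.
- **Modular connectomes** use 3 modules × 10 nodes, `p_intra = 0.6`,
  `p_inter = 0.01`, one hub wired to ⌈size/3⌉ random nodes per module.
  `p_inter < 1/module_size²` keeps the expected number of non-hub
  inter-module edges per module pair below 1, so the planted hub is the
  dominant inter-module route by construction, not by tuning. Edge
  weights are uniform in [0.5, 2.0] so binarization is exercised;
  disconnected draws are repaired with logged bridge edges.
- **Enrichment time courses** draw paired (I_a, I_p) samples per
  timepoint with multiplicative lognormal noise (default σ = 0.1, chosen
  for positivity) around a planted anterior/posterior ratio ramp
  (1.0 → 2.0 across 485–535 min).

**What passing synthetic benchmarks do and do not show.** They establish
the algebraic correctness of the model and estimators, exact recovery of
planted geometry/topology, and calibrated behavior under the stated noise
models. They do not validate segmentation, tracing, or registration of
real images (fork positions and labels are inputs here), nor the
biological noise structure of embryonic imaging, nor parameter
identifiability beyond the ratios the model exposes.

## Numerical choices and problem sizes

Tolerances: the fork-sum identity and cosine formula are checked to
1e-12 relative; length conservation to 1e-9 μm; polyline distance against
a 1e-4-step sampling oracle to 1e-6 μm. Ties in hub ranking are broken
lexicographically for determinism. The bundled verification script runs
1,000 random parameter draws for the model identity, 50 trajectory seeds
for estimator bias (alongside the Monte-Carlo standard error of that
50-seed mean, ~1.3% of truth, so individual runs scatter accordingly), 200
random graphs (N ≤ 7) against the brute-force centrality oracle in the
test suite, 50 label stacks at four dilation radii, and 100 connectome
seeds for hub recovery; the whole script completes in seconds on one CPU.

## Known limitations

- The per-fork decomposition is a modeling choice; only the summed
  velocity is observable, so any split consistent with the sum fits the
  kinematic data equally well.
- The midline cap is phenomenological; a mechanistic stop requires a
  tension/adhesion schedule that drives `equilibrium_residual` to zero.
- Whether `θ` stays constant during repositioning is not asserted; it is
  a parameter.
- Slab area is a proxy; true apposition area would need 3-D membrane
  reconstruction, which is out of scope (no slice registration, no 3-D
  dilation).
- Raw directional patch counts (keep-directional mode) depend on ROI
  bookkeeping conventions of the source pipeline and are not asserted to
  be reproducible across tools.
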