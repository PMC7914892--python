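# Methods

## Model

A polymer brush of worm-like chains (WLC) grafted on an impenetrable planar
substrate is treated in single-chain mean-field theory (SCMFT): one explicit
chain is sampled by Metropolis Monte Carlo in a fixed auxiliary field
`omega(z, u)`, the orientation-resolved density is estimated from the
recorded conformations, the field is rebuilt from the density through the
Onsager excluded-volume kernel, and the cycle repeats until the field is
stationary.

All lengths are measured in Kuhn lengths, `a = 2 l_p = 1`, so the contour
length equals the reduced polymerization `N = L/a`.  The chain is
discretized into `Nm` bonds of length `b = L/Nm` with unit tangents
`u_1..u_Nm` and nodes `r_i = r_{i-1} + b u_i`; positions and orientations
are stored together, with orientations authoritative and positions rebuilt
after every accepted move (orientations are renormalized on acceptance, and
a 1e-9 unit-norm tolerance guards against drift).

* Bending: `beta H_0 = eps * sum_i |u_{i+1} - u_i|^2`, `eps = Nm/(4N)`.
  The continuous WLC is recovered as `Nm -> inf`.
* Field term of a conformation: `(N/Nm) * sum_i omega(z_i, u_i)`, evaluated
  at **bond midpoints**.  Midpoints pair each position unambiguously with
  its bond orientation; the density estimator bins the same midpoints, so
  the sampled energy and the accumulated density refer to identical points.
* Walls: the grafting wall `z > 0` (nodes 1..Nm; the graft node sits at
  z = 0) and the optional compression wall `z < H` are enforced by
  rejection, which is exactly the infinite-potential Metropolis rule
  without infinities in arithmetic.
* Onsager coupling: `omega(z, u) = (2d/a^2) ∫ du' |u x u'| rho(z, u')`.
  For the planar brush only the combination `2daσ` is physical, so the
  grafting density is fixed at `σ = 1` internally and the kernel prefactor
  carries the whole coupling.

## Monte Carlo moves

A trial move picks a pivot monomer uniformly on `1..Nm`, an axis uniformly
on the sphere, and an angle uniformly in `(-max_angle, +max_angle]`; bonds
between the pivot and the free end rotate rigidly (Rodrigues formula).
Only the joint at the pivot changes its bending energy; the field term is
re-evaluated for the rotated tail.  `max_angle` adapts during burn-in
toward a 30-50% acceptance ratio and is frozen during recording so detailed
balance holds for the recorded ensemble.  One sweep is `Nm` proposals;
burn-in defaults to 100 sweeps (reduced to ~20 when a warm-started chain
enters a mildly changed field).

All randomness is drawn from per-stream `numpy` PCG64 generators as arrays
of uniforms consumed by the compiled kernel, so the production path and the
pure-Python reference implementation can consume identical variates — the
tests use this for exact cross-checks (e.g. rejection-vs-infinite-energy
equality).

### Azo joint

A photoswitchable joint at relative contour position `f` constrains the
angle between the two flanking tangents to `pi - alpha` (`alpha = pi`:
trans, straight; `alpha = pi/3`: cis).  A delta-constraint has zero
acceptance under unconstrained proposals, so it is preserved *by
construction*: a pivot landing exactly on the constrained joint uses the
preceding bond as its rotation axis (a cone move in the joint's azimuth);
all other pivots rotate both flanking bonds rigidly or neither.  The trans
state has zero kink and imposes no constraint, so the sampler treats a
trans-azo chain exactly — bit-for-bit — like an unmodified chain.
Isomer switching is a deterministic re-kink (cone azimuths are tried until
the walls are satisfied) followed by re-equilibration.

## Grids and the field update

* z: `Nz` uniform slabs on `[0, z_max]`, `z_max >= L`.  Field lookups
  interpolate linearly between slab centers (clamped at the ends); density
  bins are half-open `[z_k, z_{k+1})`.
* Orientation: Gauss-Legendre nodes in `cos(theta)` crossed with uniform
  midpoints in `phi`.  The weights sum to `4 pi` exactly, the second
  Legendre polynomial integrates to machine zero (a band-midpoint product
  rule leaves O(10^-3) errors there), and the grid is closed under
  `u -> -u` for even `Nphi`.  Orientation lookup is nearest-bin.
* Defaults `Nz = 120` over `[0, 1.2 L]`, `Ntheta = Nphi = 12`; all
  configurable.
* **Commensurate slabs for stiff regions.**  Near the wall of a dense brush
  the first bonds are nearly straight, so their midpoints fall at almost
  deterministic heights spaced `b` apart; a slab width that is not
  commensurate with `b` then imprints an alternating comb on the histogram.
  The bundled study protocols therefore use `dz = b` whenever
  `Nz * b >= 1.1 L` (each slab receives exactly one midpoint of a fully
  stretched chain).
* Density estimator: each of the `M * Nm` binned midpoints carries weight
  `sigma N/(M Nm)`, divided by the cell volume `dz * w_b`, which makes
  `sum rho dz dOmega = sigma N` hold to rounding by construction: the
  estimator's normalization is pinned to this physical sum rule rather
  than to any particular prefactor convention.

## Self-consistent iteration

`omega_new[k,a] = sum_b K[a,b] rho[k,b]` with
`K[a,b] = prefactor * sin(gamma_ab) * w_b`, followed by linear mixing
`omega <- (1-lam) omega + lam omega_new`.  The residual is the max-abs
field difference normalized by the max-abs field; convergence is judged on
this residual (free energies are not evaluated).

Practical points, each reported in the run trace:

* **Stability bounds the mixing.**  The linearized density response to a
  local field bump is amplified by the kernel prefactor, so the feedback
  gain grows with `2daσ`; stable simple mixing requires roughly
  `lam ~ 1/(1 + 2daσ)`.  The bundled protocols use `lam = 0.3` at
  `2daσ = 0.25`, `0.1` at `2.0`, and `0.03` at `35.0`.  Larger values do
  not diverge but settle into noise-sustained standing-wave oscillations of
  the profile.
* **Noise floor.**  With `M` finite the residual cannot fall below the
  estimator's sampling noise; the trace reports a noise proxy (field
  difference between the two half-ensembles) next to the residual so
  noise-limited convergence is visible.  `M` per iteration starts at 1/8 of
  its cap and doubles each iteration.
* **Warm starts.**  Chains and field both warm-start across iterations and
  across sweep points.  Dense brushes (`2daσ >= 10`) start from the
  strong-stretching ansatz: the Onsager field of a smoothed step density
  with its edge *inside* the reachable region (only field gradients act on
  the chain — a constant offset cancels in every energy difference, so an
  edge beyond `z = L` would be inert).
* **Trailing-window reporting** (`n_avg`): the reported density and
  observables merge the last `n_avg` iterations' sub-ensembles.  Near the
  fixed point this averages sampling noise and any residual under-damped
  field oscillation; it is a pure reduction of histograms, not a change to
  the dynamics.
* Per-iteration stream seeds derive deterministically from
  `(base_seed, iteration, stream)` via `numpy.random.SeedSequence`, so runs
  are bit-reproducible for fixed seeds and stream counts, and an
  ideal-chain SCMFT run (kernel prefactor 0) is bit-identical to plain
  grafted-chain sampling.

## Sub-ensembles

Sampling splits into `K` independently seeded streams; merging densities,
histograms and counters is a pure reduction, so the pooled result does not
depend on the split.  Scalar observables carry standard errors from the
stream-level scatter (jackknife for the non-linear tilt order).  This
realizes the communicate-only-at-field-updates parallel contract; execution
here is a single-process loop (an MPI backend would drop in at the stream
boundary, and nothing in the merge step would change).

## Observables

* `rho(z)`: orientation-integrated density; `S(z)`: per-slab second
  Legendre polynomial of `u_z` (exact per-bond accumulators; the
  density-route estimate carries the grid's theta discretization); empty
  slabs are reported missing, not zero.
* Brush height `h = 2 <z>` (first moment; exact for a step profile), with a
  98%-mass variant behind a switch.  No single height definition is
  standard for diffuse profiles; the first moment is the package default.
* Tilt order `psi = <2 cos^2 phi - 1> = <cos 2 phi>` over bonds with a
  nonvanishing horizontal projection.  Of the two readings of the printed
  definition, the bounded one (`2<cos^2 phi> - 1`) is adopted.  With no
  externally imposed axis, `phi` is measured from the emergent tilt
  direction — the principal axis of the horizontal 2-D nematic tensor —
  which makes `psi = sqrt(<cos 2phi>^2 + <sin 2phi>^2) >= 0` estimator-
  positive: its null distribution at finite sampling is Rayleigh-like, and
  the symmetry checks compare it against its jackknife error rather than
  against literal zero.
* `P1 = h_cis / h_trans` (UV on / off).
* `P2 = ∫ dz phi_end,I(z) phi_end,II(z)` for two opposing planar brushes at
  separation `D`: brush II's end distribution is mirrored (`z -> D - z`)
  onto the common grid before the discretized overlap.  When `opposing_D`
  is set, the mirrored partner density (`z -> D - z`, `u -> -u`) is added
  to the own density before the field update — the symmetric two-brush
  closure.

## Reference oracles

Every oracle is an independent code path (quadrature, closed form, or
exhaustive enumeration), never the production sampler:

* joint-angle law `~ exp(2 eps cos theta) sin theta`, with closed-form CDF
  for KS tests and `t = <cos theta> = coth(2 eps) - 1/(2 eps)`;
* discrete `<R^2> = b^2 [Nm (1+t)/(1-t) - 2t(1-t^Nm)/(1-t)^2]`, exact
  because joint angles are independent;
* continuum `<R^2> = 2 lp L - 2 lp^2 (1 - e^{-L/lp})`.  The discrete chain
  carries an O(b) persistence offset, `lp_eff = -b/ln t ~ lp - b/2`
  (a 3% effect at `L/a = 30`, `Nm = 1000`); the continuum-form check at
  `Nm = 1000` therefore uses the chain's own `lp_eff` (agreement to 0.03%),
  and the nominal-`lp` gap falls below 1% around `Nm ~ 4000`, first order
  in `b`;
* exhaustive Boltzmann enumeration of `Nm <= 3` chains over a finite
  direction set (the 26 cube directions by default), compared against a
  dedicated single-bond-redraw Metropolis sampler via total variation.
  The continuous pivot sampler cannot be restricted to a finite direction
  set — rotations leave it — hence the dedicated discrete comparison path.

## Problem sizes

Production-scale SCMFT brush studies use `Nm ~ 100-1000` and `~1e7`
conformations per field update.  The bundled protocols and the
reproduction script run `Nm = 50` (`Nm = 16` for the compression loop),
`1e5` conformations per update, `Nz = 80`, `12 x 12` orientation bins, and
1-sweep record strides, chosen so a full reproduction completes on one core
in minutes.  Consequences: profile noise of a few percent per slab (hence
the trailing-window reporting), qualitative rather than quantitative
agreement at profile edges, and a hysteresis sweep that demonstrates branch
dependence rather than maps the transition.  What passing at this scale
shows: the sampler, estimator, kernel and iteration are mutually
consistent and reproduce the known regime structure; what it does not
show: converged continuum-limit profiles (`Nm -> inf`) or the precise
location of the tilting transition.

## Compression hysteresis protocol

Stiff grafted rods (`L = 3 l_p`, `2daσ = 35`) order along the wall normal;
compressing the layer below the rod length forces tilting, and the Onsager
coupling makes the tilt azimuth a collective, spontaneously broken
direction — the transition is first order, so tilted and untilted branches
are separately metastable.  The sweep lowers the wall from `0.85 L` to
`0.45 L` and raises it back, warm-starting each solve from its
predecessor.  Because nucleation of the broken azimuth from sampling noise
is throttled by the small mixing parameter, the turning point seeds the
tilt channel with a weak azimuthal field perturbation (15% of the field
scale, shape `1 - cos 2φ`) and dwells for 40 iterations; the iteration —
not the seed — decides the branch: under strong compression the
perturbation grows into the self-consistent tilted state (`ψ ~ 0.17`),
and on relaxation it decays back to zero by `H = 0.85 L`.  The compression
branch is unseeded and stays untilted, so the branch gap
`max_H |ψ_fwd − ψ_bwd|` is the reported hysteresis indicator (≈ 0.16 at
the bundled problem size, roughly fifteen times its jackknife error).

## Degenerate and edge cases

`Nm = 2` pivots at index 1 rotate the whole chain about the graft
(allowed).  Compression with `H < L` initializes from a tilted rod under
the wall (`cos theta = 0.9 H/L`).  The first bond at the graft is
orientationally free; the hard wall restricts it implicitly.  `lam = 0`
freezes the field (useful for pure re-sampling); kernel prefactor 0 gives
ideal chains.  NaN energies raise; `+inf` (wall) never accepts.

## Known limitations

Laterally homogeneous fields only (`omega(z, u)`); no free-energy
evaluation (convergence is field-residual based, which cannot distinguish
metastable branches except through the hysteresis protocol itself); simple
linear mixing (no Anderson acceleration), so dense brushes need
`lam ~ 1/(2daσ)` and correspondingly many iterations; the tilt order is
estimator-positive under the null; single-chain mean field neglects
explicit inter-chain correlations by construction.
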