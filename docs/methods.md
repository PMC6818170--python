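# Methods

## The physical model

Immune-receptor signaling frequently proceeds through *tethered* reactions:
an enzyme bound to the unstructured cytoplasmic tail of one membrane
receptor modifies a site on the tail of another.  The receptors diffuse in
the two-dimensional membrane, but their tails explore the three-dimensional
volume proximal to it.  Modeling the tails as worm-like chains that
equilibrate quickly relative to receptor motion, the probability density
that the two reactive sites meet, given an in-membrane anchor separation
`r`, is a Gaussian set by the *molecular reach of the reaction* `L`:

    sigma_3D(r; L) = (3 / (2 pi L^2))^{3/2} exp(-3 r^2 / (2 L^2))   [nm^-3]

normalized over 3D space.  `L` combines the component reaches as
`L = sqrt(L_receptor^2 + L_enzyme^2 + L_substrate^2)`, each worm-like-chain
component contributing `sqrt(l_p l_c)` with persistence length
`l_p = 0.4 nm` and contour length `l_c = 0.4 nm x (residue count)`.  A
bimolecular modification then occurs with propensity `k_cat sigma_3D(r; L)`
(units s^-1; `k_cat` in nm^3 s^-1).  An idealized in-plane variant
`sigma_2D` (normalized over the plane, `k_cat` in nm^2 s^-1) represents the
conventional assumption that membrane reactions happen strictly in 2D.

Two biological models are built on these kernels:

* **Inhibitory receptor model** (`PD1Model`): substrate receptors are
  phosphorylated by a first-order background reaction (rate `lam`,
  default 1 s^-1, standing in for a kinase whose parameters are never
  varied) and dephosphorylated by inhibitory receptor–phosphatase complexes
  through the reach kernel (`k_cat* = 0.1 uM^-1 s^-1`, `L = 8.5 nm`
  default).  Enzyme recruitment to the receptor is not modeled; the
  inhibitor concentration denotes pre-formed complexes.
* **Push–pull model** (`PushPullModel`): the canonical
  kinase/phosphatase loop `S + E -> S* + E`, `S* + F -> S + F` with
  per-reaction reaches `L_e` (swept) and `L_f = 15 nm`, efficiencies
  0.04 / 0.01 uM^-1 s^-1 (3D kernel) or the equivalent tabulated 2D rates
  221.3736 / 55.3434 nm^2 s^-1.

Default concentrations (substrate 100 um^-2, phosphatase 112 um^-2,
inhibitor-substrate 1e-4 nm^-2) and the 300 nm periodic square follow the
published parameter tables; on that domain they give 9 substrate, 10
phosphatase and (at the default kinase density 125 um^-2) 11 kinase
molecules.  All internal computation uses nm, s and molecule counts; unit
conversions (`1 uM^-1 = 1e30 / N_A nm^3`) happen once at the configuration
boundary with `N_A = 6.023e23 mol^-1`, the convention under which the
tabulated 2D rates are reproduced to five significant figures.

## Lattice stochastic simulation

Diffusion and reaction are simulated as a continuous-time jump process on a
Cartesian mesh: each molecule hops to a neighbouring voxel at rate `D/h^2`
per direction, and molecule pairs react with a separation-dependent
propensity.  As `h -> 0` this construction converges to the spatially
continuous volume-reactivity (Doi) model.

**Voxel-averaged kernels.** Pairwise Gaussian propensities use the kernel
averaged over the source and target voxels rather than the voxel-center
value.  Because the Gaussians factorize over axes, the average is a product
of per-axis closed-form (erf) factors, tabulated once per rule with
periodic images summed.  Averaging preserves the lattice-summed total
(well-mixed) reaction rate *exactly at any resolution* — essential because
physiological reaches (down to 1 nm) are narrower than any affordable
voxel.  Tables are truncated per axis beyond `4.5 L` (propensity ratio
< 1e-13), configurable.  Indicator (Doi) interactions are evaluated at the
voxel-center minimal-image distance.  The public `pair_propensity` contract
exposes the continuum kernel; the refinement-stability test verifies that
steady-state outputs are insensitive to `h` in the regimes used.

**Two exact samplers.**  `engine="direct"` is the textbook direct-method
SSA: every hop is an event; per-rule pairwise propensity totals are updated
incrementally when a molecule moves (subtract its old-position pair sums,
add the new ones) and resynchronized from scratch every 2^16 hops to bound
floating-point drift.  `engine="uniformized"` exploits the fact that free
hopping is autonomous: each molecule's position is advanced lazily, only
when observed, by sampling the free propagator (per axis, the difference of
two Poisson variates with mean `(D/h^2) dt`); pairwise reactions fire as
candidate events at the constant per-rule bound `n_a n_b max_rate` and are
accepted by thinning with the true tabulated rate at the candidate time.
Both are statistically exact samplers of the same master equation; the
suite verifies their agreement directly.  `engine="auto"` compares the
total hop rate with the total candidate bound and picks the engine for
which the event budget is smaller — the uniformized engine wins in
reaction-limited/fast-diffusion regimes (explicit hops would dominate), the
direct engine in quenched/slow-diffusion regimes (uniform pair proposals
would be overwhelmingly rejected).

**Boundaries.**  Periodic boundaries wrap both hops and pair distances
(minimal image).  Reflecting boundaries suppress the outward hop, realized
in the direct engine as a null event (equivalent by Poisson thinning) and
in the uniformized engine by cell-centered image folding of the free walk:
the preimages of an edge voxel under folding are `0` and `-1` modulo `2n`,
so the folded walk at the edge stays put with probability 1/2 — the same
process again.

**Seeding.**  Trajectory `k` of an ensemble draws its placement and
dynamics seeds from `numpy.random.SeedSequence([base_seed, k, stream])`;
runs are reproducible bit-for-bit for a fixed base seed and ordering.

## Steady-state policy

Each trajectory is integrated to `T_end = 20 tau` and the modified fraction
is the exact time integral over the final half of the run, averaged over
trajectories (mean ± standard error across trajectories).  The relaxation
time is

    tau = 1/(r_fwd + r_bwd)
          + max over bimolecular directions of
              min( 1/r_dir , (side/2)^2 / (4 (D_a + D_b)) )

where `r_fwd`, `r_bwd` are the mean-field modification/de-modification
rates computed from the kernels' well-mixed rate constants
(`k_RL = k_cat sqrt(3/(2 pi))/L` for a 3D kernel acting in the plane,
`k_cat` itself for a 2D kernel).  The correction term covers spatially
quenched configurations: at slow diffusion a substrate whose partner for
one direction is out of reach relaxes no faster than that direction's own
rate, until the pair geometry re-randomizes diffusively; at fast diffusion
the correction vanishes and the policy reduces to the mean-field rate.
A diagnostic compares the ensemble-mean fraction over the third and fourth
quarters of the run (flagged in `SteadyStateResult.converged`).
Trajectories start with all substrates unmodified.

## Dose response and potency

Sweeping the inhibitor (or kinase) concentration yields the steady-state
modified fraction curve.  The half-maximal concentration is extracted by
projecting the mean curve onto the appropriate monotone cone (isotonic
regression — assumption-light smoothing) and interpolating the 50%-of-
baseline crossing linearly in log concentration; a two-parameter Hill fit
is provided as an independent cross-check.  With 1% additive noise on a
12-point log grid the interpolation estimator recovers a known half-max to
~2.5% on average (its single-replicate spread is ~±8%, set by the local
noise-to-slope ratio and insensitive to grid density); the Hill fit
recovers it within 5% in every replicate.  For the inhibitor model the
baseline is exactly 1 (no dephosphorylation without inhibitor).

## Two-particle theory

The potency switch is explained by a minimal model: one molecule fixed at
the origin of a disc (membrane models) or sphere of radius `R` chosen to
match the 300 nm square's area (cube's volume), one molecule diffusing, and
the Gaussian interaction replaced by an indicator `lam 1_[0,eps](r)`
moment-matched to the kernel (matching the zeroth and first radial
moments), which gives `eps = alpha L`, `alpha = 16/(3 sqrt(6 pi)) ~ 1.2284`
for the 3D kernel and `eps = mu L`, `mu = sqrt(3 pi/8) ~ 1.0854` for the 2D
kernel, with `lam` preserving total kernel mass.  The mean reaction time
`w(r)` solves

    D r^{1-d} (r^{d-1} w')' - lam 1_[0,eps] w = -1,  w'(R) = 0,  w(0) finite,

and the well-mixed MRT is its volume average.  Closed forms are implemented
for the disc (modified Bessel functions, evaluated through exponentially
scaled ratios `ive` to avoid overflow) and for the sphere (hyperbolic
functions, derived by matching `w_in = 1/lam + A sinh(qr)/r` to the
reaction-free outer solution).  For `eps >= R` both reduce to `1/lam`
(equivalently `(4/3) pi (alpha L)^3 / k_cat` on the large-reach branch).

**Numerical oracle.**  An independently discretized conservative
finite-volume solver validates the closed forms.  Accuracy to better than
1e-6 relative across the full physiological grid required four numerical
measures: the reaction coefficient is cell-averaged across the `eps`
interface (a sharp-coefficient cell otherwise degrades the scheme to first
order); the mesh is geometrically graded into the reaction boundary layer
of width `sqrt(D/lam)` (as small as 0.008 nm at slow diffusion); the system
is assembled in extended precision and the float64 banded solve is polished
by iterative refinement with extended-precision residuals (the assembled
matrix reaches condition ~1e12 when `D/h^2 >> lam`); and the resolution
ladder doubles until the second-order error estimate `|T_2n - T_n|/(3 T)`
meets tolerance.

**Asymptotics and decomposition.**  For small `rho = eps/R` the well-mixed
MRT decomposes into a reaction-limited term (`T_RL = pi R^2 / k_RL` in the
planar models, `(4/3) pi R^3 / k_cat` in 3D) plus a diffusion-limited term
(`(R^2/2D) ln(R/eps)` on the disc, `R^3/(3 D eps)` in 3D) with universal
coefficients (32/(9 pi), 1, 6/5) and an `O(R^2/D)` constant.  Only in the
2.5D configuration (planar diffusion, 3D kernel) does `T_RL` grow with the
reach — `k_RL ~ 1/L` because a volume-normalized kernel is integrated over
a plane — which is the entire switch: a longer reach shortens the diffusive
search but dilutes the contact probability, and the balance tips as
diffusion speeds up.  The expansions additionally require the reaction zone
to be weakly absorbing, `eps sqrt(lam/D) <~ 1`; at the slowest tabulated
diffusivities this fails and the exact solution approaches the
perfect-absorber limit while the expansions retain their weak-absorption
coefficients (e.g. the 3D `6/5 T_DL` arises from the `x^2/15` Taylor term
of `x coth x`), leaving 6–20% discrepancies even at `rho <= 0.05`.
`asymptotic_mrt` therefore flags validity on both `rho <= 0.2` and
`eps sqrt(lam/D) <= 1`; the exact/numeric routes serve outside that region.

## Study conditions and problem sizes

The stochastic switch experiment runs the push–pull model at a fixed kinase
count (11 molecules = 125 um^-2), reaches 1 and 70 nm, diffusivities
1.25e-6 and 0.1 um^2 s^-1 (substrate and kinase; phosphatase fixed at
6.25e-4), 500 trajectories per condition.  The 3D-kernel arms use a 128^2
mesh; the 2D-kernel arms use 32^2, where the narrow-kernel candidate bound
(~1/h^2) would otherwise dominate runtime while the voxel-averaged tables
keep the reaction-limited steady state mesh-independent (verified by the
refinement test).  The two-particle Monte-Carlo comparison uses 2000
trajectories at (D = 1.25e-3 um^2/s, L = 25 nm) and (1.25e-2, 40 nm),
chosen so the reaction-limited share of the MRT dominates; the fixed
molecule sits at the domain center, matching the origin-centered theory.
The comparison carries a small documented systematic: the simulation runs
on a reflecting square with a voxel-center-discretized trap (discrete trap
area 0.991 x pi eps^2 at L = 40 nm on the 128^2 mesh, inflating the
reaction-limited term ~0.9%), the theory on the equal-area disc.  Measured
across independent seed batches the combined offset is ~2% of the mean
reaction time at these points, so simulation-vs-theory agreement is
asserted within 3 standard errors plus a 2.5% geometry/discretization
allowance.  These sizes are desk-scale choices: published ensembles of 5e4
trajectories on 256^2 meshes sharpen the same quantities but do not change
any ordering tested here.

## What the synthetic scenarios do and do not show

The generator-driven tests exercise exactness of the samplers (exponential
waiting times, conservation, uniform stationary occupancy, MSD = 2 d D t),
agreement with the two-particle theory, and the qualitative switch.  They
do not emulate receptor clustering, crowding/steric exclusion, explicit
kinase particles, enzyme recruitment kinetics, membrane-interacting tails
(non-Gaussian kernels) or slowly relaxing tethers — passing tests therefore
support the model's internal consistency and its predictions under the
stated idealizations, not those extensions.  The free-space Gaussian kernel
is used even though the membrane restricts tails to a half space; the
half-space kernel differs only by a constant factor, which rescales
efficiencies but not the reach dependence.

## Numerical conventions and edge cases

Zero total propensity terminates a trajectory cleanly with a `stalled`
flag.  Rounding of `concentration x area` to integer molecule counts warns
above 5% relative change.  Same-voxel pairs react at the voxel-averaged
contact rate (the zero-offset table entry).  Floating-point ties between
channels are broken by rule order; simultaneous events have probability
zero in continuous time.  Engine RNG streams use numpy's legacy
`np.random.seed` inside numba with seeds reduced below 2^31.
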