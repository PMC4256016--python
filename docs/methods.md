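# Methods

`fimsim` simulates the stationary adhesion of a fimbriated bacterium to a
mannose-coated wall in laminar shear flow.  The cell is a rigid sphere; each
of its fimbriae is an independent tether with a single FimH adhesin at the
tip.  Three ingredients are coupled in a stochastic time loop: the
mechanics of the fimbrial shaft, the two-state allosteric kinetics of the
FimH-mannose bond, and the near-wall Stokes hydrodynamics of the cell body.

## Fimbrial shaft mechanics

The shaft is a helical quaternary polymer of `n_subunits` subunits.  Each
subunit is coiled (A), uncoiled (B), or uncoiled-and-stretched (C), with
`n_A + n_B + n_C` conserved.

* The A segment is contiguous (uncoiling is a cooperative phase transition
  confined to the edge of the helix) and acts as a Hookean spring: natural
  length `n_A * rise_A`, stiffness `k_coil / n_A` (subunit springs in
  series, `k_coil` = 2000 pN/nm per subunit).
* B and C segments are worm-like chains (Marko-Siggia interpolation) with
  contours `n_B * x0_B` and `n_C * x0_C` and persistence lengths `l_pB`,
  `l_pC`.  Total length is the sum of the three segments.
* A<->B transitions occur only at the single A/B edge with Bell rates
  `k0_AB * exp(F x_AB / kBT)` and `k0_BA * exp(-F x_BA / kBT)`.  The two
  rates cross at the equilibrium uncoiling force
  `F_eq = kBT ln(k0_BA/k0_AB)/(x_AB + x_BA) = 32.2 pN` for the defaults.
* The B<->C stretch transition occurs independently per uncoiled subunit
  and is treated as an instantaneous equilibrium with
  `K(F) = k_eq exp(F x_eq / kBT)`; the stretched fraction is `K/(1+K)`,
  rounded half-to-even when applied to integer counts.  A kinetic
  treatment would add a relaxation time to the S-curve but no new steady
  states; the equilibrium form is the declared simplification.

Tension at a prescribed end-to-end length inverts the monotone
length-tension map by safeguarded, warm-started Newton iteration
(tolerance 1e-5 nm).  In yielding mode the tension and the B/C partition
are solved *jointly* (the map `L(F, phi(F))` is strictly monotone); a naive
solve-then-repartition loop oscillates across the stretch transition and
was rejected.  Compression is clamped at `-buckling_force` (default 10 pN),
a stand-in for three-dimensional stretch/bend/buckle elasticity that is not
re-derived here.

Elasticity-mode variants keep the identical machinery: `linear` disallows
uncoiling (pure Hookean rod), `strain_hardening` treats uncoiling as free
(a single WLC of contour `n_subunits * x0_B` with `l_pB`).

### Parameter defaults

The canonical parameter table for this model is not available, so the
shipped defaults are calibrated once against the printed anchors and then
frozen: `F_eq = 32.2 pN`; extension plateaus rising with pull speed across
0.1-10 um/s (about 64 pN at 0.1 um/s to about 124 pN at 10 um/s) with
retraction plateaus below `F_eq` (about 23 down to 7 pN over the same
range); a maximum mean-field recoil flux above 10 um/s so the fastest
printed retraction speed is representable; whole-cell creep at the
published scale (net uncoiling pays out tether at tens of nm/s per bond
near 50 pN, so anchoring bonds hold their load between recruitment events
instead of relaxing to `F_eq` within seconds); and a post-uncoiling
S-curve ending near 150 pN at the default maximum pull extension (97% of
the fully stretched contour).  Geometry: `rise_A` =
0.7 nm helical rise, `x0_B` = 5.0 nm and `x0_C` = 6.6 nm uncoiled/stretched
contours per subunit, `l_pB` = 3 nm, `l_pC` = 8 nm — the scale of published
fimbrial-rod models.  A 1-um native fimbria is 1430 subunits.

## FimH catch-bond kinetics

The bond is a two-state allosteric catch bond: a short-lived low-affinity
state 1 and a long-lived activated state 2, with Bell-form rates for
rupture from each state (`k0_10, x_10`; `k0_20, x_20`), force-promoted
activation (`k0_12, x_12`) and force-suppressed deactivation
(`k0_21, x_21`).  Only tensile force enters the rate laws; compressive
contact counts as zero force.  The defaults follow the scale of the
allosteric catch-bond literature and are constrained by the printed
lifetime anchors: mean lifetime peaks between 30 and 70 pN (minutes to
tens of minutes across that window for the defaults) and collapses to
about a second above 90 pN.  Bonds above 90 pN are counted as
"vulnerable".  At low force the activated state deactivates within a
second and the low-affinity state ruptures, so unloaded bonds die in
seconds -- the catch-bond behaviour that makes adhesion depend on load
history.

The closed-form mean lifetime solves the two-state first-passage system;
the stochastic stepper uses exact exponential event probabilities with a
single competing-risk draw per step.

Association: a tip binds at rate `k_on` while within `capture_radius` of
the wall plane; new bonds enter the low-affinity state.  Neither parameter
is printed anywhere; they were calibrated once against the flow-protocol
anchors (stable anchorage at 1 Pa, recruitment of activated bonds with
rising shear, mean bond force near 50 pN at the stepwise-protocol
snapshots) and then frozen.  Bonds formed during a simulation never enter
the activated state directly; only the seed bond starts activated.

## Hydrodynamics

The cell is a sphere of radius 0.794 um (calibrated so the drag at 0.01 Pa
wall shear stress is 0.2 pN at the default resting gap of 0.05 um, with
viscosity 1e-3 Pa s).  Near-wall corrections are scalar factors of the
classic near-wall sphere literature: the shear force and torque factors are
anchored at their contact values (1.7005 and 0.9440) and decay to 1 as
`(a/h)^3`; parallel translation resistance uses the method-of-reflections
series; perpendicular resistance uses `1 + a/gap` (lubrication-correct
leading order); rotation uses the reflection series.  The resistance matrix
is diagonal per rigid-body component.  Translation-rotation coupling is
omitted: with tethers that pivot freely at both ends it contributes a
secondary correction to a force balance already dominated by the tether
tensions, and omitting it preserves exact linearity and mirror symmetry.
Vertical position is maintained by the bond forces plus a short-range wall
repulsion (50 pN/nm below the resting gap); there is no gravity or
Brownian motion of the cell body (deterministic mechanics, stochastic
kinetics).

## Whole-cell engine

Fimbriae are placed with uniform random anchor directions and exponential
lengths (mean 0.572 um, 186 fimbriae by default).  Single-fimbria
simulations keep the full coat but set the association rate to zero for
every fimbria and force the seed tether to 1 um, so only the seed bond can
ever hold the cell.  Simulations start with one fimbria bound in the
activated state ("just transitioned to stationary adhesion"): the seed is
the fimbria with the largest upstream reach fraction, attached exactly
taut at the wall point directly upstream of its anchor -- a cell that has
just arrested was moving downstream, so its tether trails upstream and
carries roughly the drag force from the start, inside the
force-stabilized catch regime.

Unbound fimbriae whose rigid rods would penetrate the wall act as
compressible legs: an axial spring (the rod stiffness) capped at the
buckling force, pushing the cell up at the contact point.  The fimbrial
bed these legs form is what lets the cell balance the shear torque --
with tethers that pivot freely, a lone tether always torques the cell
forward, and without legs the cell would roll over its own anchor and
snap the bond.  Leg tips are not binding-competent (binding uses the
rigid rod at natural length; a buckled rod does not present its adhesin
to the surface).

Each step (base `dt` = 1e-4 s): (1) anchor/tip geometry; (2) tension per
bound fimbria; (3) coiling edge events (sub-stepped so event probabilities
stay below 0.1; tension re-solved within bursts) and the stretch
partition; (4) bond transitions with tensile-clamped force; (5) binding
attempts for tips in range (a rigid rod at natural length along the anchor
direction, in range when its tip is within `capture_radius` of the wall
plane); (6) pose update.  Unbound fimbriae carry no force; partially
uncoiled ones re-coil with bulk Poisson counts, and fully coiled ones are
held coiled (the zero-force equilibrium occupancy of the uncoiled edge
subunit is k0_AB/k0_BA ~ 2e-3, i.e. negligible).

The pose update is semi-implicit: the 6x6 system
`(R/dt + K) dq = F` is solved for the rigid-body displacement `dq`, where
`R` is the resistance matrix and `K` the assembled tether stiffness
(elastic term `k n n^T` plus the geometric term `T/d (I - n n^T)`, with
lever-arm blocks; `K` is positive semi-definite by construction).  This is
backward Euler on the linearized elastic force and is stable for
arbitrarily stiff tethers, where explicit stepping at a practical `dt` is
not.  Displacements are limited to 4 nm per sub-step (the step subdivides,
re-solving geometry, through ruptures and protocol switches where the
linearization would otherwise be left behind).  An explicit fixed-step
scheme at `dt` = 1e-5 s was tried first and rejected: short linear-mode
tethers and near-contour WLCs make the problem arbitrarily stiff.

Detachment is declared when no fimbria is bound for longer than a grace
window (0.1 s), which prevents counting instantaneous rebinding as
detachment.  Replicates derive per-replicate seeds from a master seed as
the leading 31-bit words of `numpy.random.SeedSequence(master_seed)`.
Identical configuration and seed reproduce trajectories bit for bit.

## Force spectroscopy and fitting

`simulate_pull` drags the fimbrial end through a series cantilever
(default 6 pN/nm, the soft-lever regime) at constant speed through a
back-and-forth waypoint schedule; the coiling state evolves stochastically
while the series tension solves `L(T) + T/k_c = z`.  Plateau extraction
finds the longest run where the smoothed |dF/dx| falls below 5% of the
pre-plateau stiffness (measured on the 15-30 pN rise) and averages the
central 60%; linear and strain-hardening traces correctly yield "no
plateau".

Fitting uses the deterministic mean-field limit: at the plateau the net
coiling flux carries exactly the imposed length rate,
`(k_AB - k_BA)(F) dL(F) = v`, which predicts the dynamic plateau force per
speed and phase (stochastic and mean-field plateaus agree within 1 pN;
tested).  `fit_uncoiling_params` least-squares fits
`(x_AB, x_BA, k0_AB, k0_BA)` (rates in log space) to the plateau-force
table across speeds and phases; both phases and at least two speeds are
required for identifiability.  `fit_stretch_params` fits
`(k_eq, x_eq, l_pB, l_pC, x0_B, x0_C)` to the post-uncoiling S-curve.  The
S-curve table carries absolute extension alongside the normalized column:
extension normalized to its maximum determines only the ratio
`x0_B / x0_C`, so the fitter works with per-subunit absolute extension to
keep all six parameters identifiable.  Plain unweighted least squares is
used throughout (the original fitting objective is not specified).

## Synthetic data

`generate_synthetic_afm_dataset` emulates a force-spectroscopy session:
one back-and-forth pull per speed (default 0.1, 1, 3, 10 um/s) with
additive Gaussian force noise, the plateau table (one row per speed and
phase), and the S-curve sampled from the fully uncoiled branch of the
fastest pull.  It reproduces the features the fitters need — plateau
hysteresis, speed dependence, S-curve shape — but not instrument drift,
baseline tilt, unbinding spikes, or surface contamination, so passing
recovery tests demonstrates identifiability of the model from clean
traces, not robustness to raw instrument output.

The whole-cell generator draws the fimbrial coat (directions, exponential
lengths) per replicate.  It does not emulate rod-shaped cell bodies,
fimbria-fimbria interactions, or fluid-mediated coupling between
fimbriae.

## Observable conventions

Snapshots are taken 5 s after each protocol switch.  Force distributions
pool tensile forces on activated bonds across replicates (compressed
activated bonds count as zero); box-whisker summaries use quartiles with
9-91% whiskers and outliers beyond them.  A fimbria counts as uncoiled
when more than 5% of its subunits are outside the coiled state (a
threshold chosen to ignore thermal edge flicker; configurable).  The
stepwise protocol reconstruction holds 1, 2.5, 5, 10, 15, 20, 25 Pa for
10 s each before dropping to 0.01 Pa; the ramp protocol rises at 1 Pa/s
from 1 to 100 Pa; the flow-history protocol holds one level and drops to
0.01 Pa, with "before" measured just before the drop and "after" 60 s
later.

## Problem sizes

The package's reference ensembles are 19 replicates for ramp comparisons
and 15 for the stepwise force accounting.  The test suite runs reduced
ensembles (5-8 replicates) of the same conditions; the acceptance script
runs 19 single-fimbria replicates per elasticity mode and 10 multi-fimbria
replicates per tether variant.

## Known limitations

* The B<->C transition is an equilibrium, not kinetic, treatment.
* Unbound fimbriae are rigid rods at natural length for binding geometry;
  flexing of unbound fimbriae in flow is not modeled.
* Compression is a scalar clamp; no three-dimensional buckling.
* The near-wall corrections are scalar interpolations anchored at the
  classic contact values, not the full tabulated resistance functions.
* Association kinetics (`k_on`, `capture_radius`) are calibrated, not
  measured; conclusions that depend on absolute recruitment rates should
  be read accordingly.
* Two published contrasts are not reproduced and their checks are left
  failing by design: the relative ordering of the two weak tether modes
  (here linear tethers detach before strain-hardening ones, because an
  axial-spring tether concentrates load on the shortest taut rod where
  an elastic beam would spread it), and detachment after low-stress
  holds under the zero-bonds-past-grace definition (the cell rests on
  its fimbrial legs and in-range tips rebind within the grace window
  even though only transient, unloaded bonds remain).  Both are
  consequences of the freely pivoting rigid-rod tether idealization,
  not of the bond or coiling kinetics.
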