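# Methods

This note documents the model, the numerical methods, and the design
choices behind `vwfflow`, in the order a reader meets them: the
constitutive model, its homogeneous steady states, parameter calibration,
the stenotic-pipe solvers, and postprocessing. Numbers quoted here are
computed by the test suite or `scripts/acceptance.py`.

## Constitutive model and conventions

VWF is represented by the configuration tensor **A** of a FENE-P dumbbell
(finitely extensible nonlinear elastic spring with the Peterlin closure),
with one modification: the relaxation time is a saturating function of
the scalar shear rate,

    tau(gd) = alpha * (0.5*(tanh(beta*(gd - gamma_star)) + 1) + delta),

bounded between `alpha*delta` (globular regime, ~1.4e-4 s with the
default parameters) and `alpha*(1+delta)` (~0.069 s, unfolded regime).
The defaults are the published dimensional set: alpha = 0.069 s,
beta = 3.44e-4 s, delta = 9.70e-4, gamma* = 1.0e4 1/s, L = 22.6.

Two conventions are fixed package-wide:

* **2-D tensors, Tr I = 2.** Both the planar homogeneous flows and the
  axisymmetric (r, z) plane use 2×2 tensors with no hoop component; the
  saturated normalised length is then `L/sqrt(2)` (15.98 for L = 22.6)
  and the maximum extension `L/sqrt(2) - 1 ≈ 15`, which is what makes the
  extension scale consistent with the reported full-unfolding values. A
  3-D trace convention would saturate at `L/sqrt(3)` instead.
* **Velocity-gradient storage `G_ij = du_i/dx_j`,** so the stretching
  terms read `G·A + A·Gᵀ`; this reproduces the printed steady-shear
  algebra for `u = gd*y*x̂` exactly.

Dimensionless groups follow the pipe scalings (lengths by the maximum
radius d, velocities by the peak inlet speed U): Re = rho*U*d/mu, and
xi = alpha*mu/(d² rho) chosen so xi*Re is the Deborah number. The scales
are derived from the dimensional parameter table plus xi = 0.043, which
fixes d = 1.955 mm; the dimensionless relaxation parameters that follow
(beta_hat = 2.14e-4, gamma_star_hat = 1.60e4) match the published
dimensionless table to its printed rounding (its beta_hat = 2.16e-4
differs by 0.7%).

## Homogeneous steady states

In spatially uniform flow the model reduces to algebraic systems: for
simple shear (with Weissenberg number `s = gd*tau`)

    2 s A_xy = f A_xx - a,   s A_yy = f A_xy,   f A_yy = a,

and for planar pure elongation

    f A_g - a - 2 s A_g = 0,  f A_s - a + 2 s A_s = 0,  A_xy = 0,

where the growing component carries the coefficient `+2s` (the printed
system is used as-is; the alternative coefficient `s` implied by the
stated velocity field `u = gd(x, -y)/2` would move the elongation
threshold from ~1950 to ~2650 1/s and is inconsistent with the reported
behaviour).

Numerics: both systems collapse to a scalar root-finding problem —
in the trace for shear, and in the pole gap `u = f - 2s` (bracketed in
log space) for elongation, because near saturation `f → 2s` makes the
trace formulation catastrophically ill-conditioned. Naive fixed-point
iteration oscillates; bracketed Brent iteration plus a final Newton
polish in extended precision gives components whose residuals satisfy a
backward-error test at 1e-10 relative to the equation's terms (with a
floor of ~16·eps·f, the representation limit of double-precision
components near saturation). A time-marching integrator of the full
evolution equation (stiff Radau, steadiness declared when ‖dA/dt‖ drops
below tolerance) provides the independent cross-check: algebraic and
marched solutions agree to 1e-6 over 30 log-spaced rates.

"Half unfolding" is defined as the normalised length reaching
`L/(2*sqrt(2))`, i.e. half its saturation value; with the default
parameters the thresholds are 5117 1/s (shear) and 1957 1/s
(elongation). The root is found by Brent iteration on the default
bracket [1e2, 1e5] 1/s. Rotational flow never extends the tensor, so the
threshold is undefined there and requesting it raises.

## Calibration

The four unfolding parameters are fitted at fixed L by minimising the
mean absolute error (MAE) of normalised extension (extension divided by
`L/sqrt(2) - 1`) over a log-spaced grid of 50 shear rates on
[1e2, 1e5] 1/s. The experimental unfolding curve behind the published
parameters is not available in tabulated form, so synthetic sigmoidal
stand-ins `0.5*(1 + tanh((gd - half)/width))` are used as targets (the
default half point is the cleavage-derived 5122 1/s); all calibration
tests therefore demonstrate pipeline behaviour, not reproduction of the
original fit. Optimisation runs in log-parameter space under box bounds
(alpha ∈ [1e-3, 1] s, beta ∈ [1e-5, 1e-2] s, delta ∈ [1e-5, 1e-1],
gamma* ∈ [1e3, 1e5] 1/s) with L-BFGS-B from a deterministic multistart
set: the bounds-box centre plus seeded scrambled-Sobol points. Fits are
bit-reproducible for a fixed seed and grid.

Individual parameters are not claimed identifiable at fixed L; recovery
is asserted at the level of the curve (self-refit of a model-generated
target attains MAE ≤ 1e-3) and of the threshold (within 1%). One
definitional subtlety: the length-based half threshold corresponds to
normalised extension 0.467, not 0.5, so when a fitted model is compared
with a sigmoid target's half point the comparison is made in the
target's own metric (the rate where the model's normalised extension
crosses 0.5); the length-based threshold sits a systematic ~2% lower.

## Stenosis geometry and grid

The vessel is a unit-radius pipe with a smooth axisymmetric constriction
`r_wall(z) = 1 - h*B(|z|)`: B = 1 on the flat top (|z| ≤ l1), a cosine
ramp of length l2 down to the unstenosed wall, zero beyond. This
flat-topped C¹ bump has half-length l1, maximum slope `pi*h/(2*l2)`
(proportional to the steepness h/l2), and is an assumption: the
functional form used in the original study is not recorded, and it is
the largest uncontrolled source of discrepancy for the field statistics
below. The domain runs from z_i = −10 to z_o = 30 + l1 + l2, long enough
to contain the recirculation zone of the 50% stenosis.

The computational grid is structured and body-fitted via y = r/r_wall(z):
sinh-clustered radial lines (wall cells ~5× thinner than axis cells,
65 lines by default) and axial stations at 0.06 over the stenosis,
geometrically graded to 0.45 in the far field. Because the mapping is
only C¹, mapped second derivatives lose pointwise convergence in the two
columns at the ramp ends; solution functionals (peak wall shear rate,
wall extension) nevertheless change by <2% under one refinement level,
which is the gate used for the production runs.

## Flow solver

The steady axisymmetric Navier–Stokes equations are solved in
stream-function/vorticity form, in the regularised variables
`phi = psi/r²` and `g = eta/r` (psi the Stokes stream function, eta the
azimuthal vorticity):

    phi_rr + (3/r) phi_r + phi_zz + g = 0,
    u g_r + w g_z = (1/Re)(g_rr + (3/r) g_r + g_zz),

with `w = 2 phi + r phi_r`, `u = -r phi_z`. Both variables are smooth
and even across the axis, and — deliberately — fully developed pipe flow
(phi quadratic in r, g constant) satisfies the nonuniform 3-point
discretisation exactly, so the straight pipe reproduces Poiseuille flow
and its shear-rate field to solver tolerance (~1e-12). Advection is
discretised with second-order upwinding (first-order fallback on the
lines nearest a boundary), diffusion centrally.

Boundary conditions: parabolic inlet `w = 1 - r²` (Dirichlet in phi and
g); axis symmetry (vanishing radial derivatives); fixed wall stream
function plus the discrete no-slip constraint `2 phi_w + phi_y = 0`,
which couples the wall-vorticity unknowns through the interior equations;
outlet `∂_z = 0`, equivalent to the prescribed-normal-stress,
unidirectional outflow condition. Pressure is recovered only as a
postprocessing diagnostic by integrating the momentum balance.

The nonlinear system is solved by damped Newton with an exact sparse
Jacobian obtained by coloured finite differences (unknowns coloured
modulo 5 in each grid direction so perturbation footprints never
overlap; one residual evaluation per colour), LU factorisation, and
continuation in Re (steps ≤150 from a developed-flow start, automatic
step bisection on failure). Convergence is ‖F‖∞ ≤ 1e-9 with the
vorticity residual scaled by 1/Re so the criterion is Re-independent.
The discrete through-flux is constant by construction of the stream
function; quadrature of the derived velocity agrees across cross-sections
to <0.1% on the production mesh.

Recirculation is detected from closed streamlines: a zone exists when
the stream function exceeds its wall value by more than 1e-4 of the
through-flux (genuine eddies at h ≥ 0.3 overshoot by 1e-2 to 1e-1;
discretisation-level slivers at h ≤ 0.2 by ≤1e-5, a clean scale
separation). The reported extent is the reversed-wall-shear interval
(separation to reattachment).

## Tensor transport

On the frozen flow (one-way coupling; the dilute protein does not feed
back on the momentum balance), the dimensionless steady balance

    xi*Re*(u·∇A − G·A − A·Gᵀ) = −(1/tau_hat)(f A − a I) + (xi*Re/Pe) ∇²A

is solved for (A_rr, A_rz, A_zz) with G the in-plane velocity gradient.
The Laplacian term is artificial diffusion: the regularisation that makes
the otherwise hyperbolic equation solvable on a grid, applied
component-wise with diffusivity 1/Pe relative to the advective scale
(Pe = 10³ by default, entering as `(xi*Re/Pe)∇²A`; whether the original
study's diffusion carried the xi*Re factor is not recorded — the
Pe-doubling check below bounds the consequence). Scalar rates for
tau_hat are evaluated from the axisymmetric rate-of-strain tensor
including the hoop component u/r (with its axis limit u_r); the
configuration tensor itself remains 2-D.

Boundary conditions: inlet Dirichlet profile equal to the homogeneous
steady-shear solution at the local rate 2r of the parabolic inflow
(off-diagonal sign following sign(dw/dr)); axis symmetry (A_rz = 0, even
diagonals); no normal diffusive flux on the wall, `(1+R'²) A_y = R R' A_ξ`
in mapped coordinates; no axial gradient at the outlet. The nonlinear
system is solved by the same coloured-Jacobian Newton machinery, with
continuation in Pe (10² → 10³ in half-decade steps) and a line search
that rejects any iterate violating positive diagonals or the
finite-extensibility bound Tr A < L². Failures raise with a suggestion
to lower Pe or refine the mesh; the solver never silently changes the
requested Pe. Consistency checks: a straight pipe reproduces the
z-invariant inlet profile to 1e-3; doubling Pe moves the maximum wall
extension by well under 5% (stabilisation, not physics); the wall
extension maximum co-locates with the wall shear-rate maximum to within
two samples.

## Postprocessing and headline numbers

Wall series sample z, the scaled wall shear rate WSR = Re·gamma_dot, the
extension E and E as % of `L/sqrt(2) − 1` along the wall. The bulk
speed-up across the stenosis is the ratio of cross-section mean axial
velocities (throat over inlet), which continuity pins at `1/(1−h)²` —
4.0 for the 50% stenosis; the pointwise peak-speed ratio is a different
(smaller, ~2.9 at Re = 400) quantity.

The highly elongational core region is the thresholded set
`gamma_dot − omega_dot ≥ 0.2` with a one-cell wall ring removed and any
connected component still touching that ring discarded as wall shear
layer. With the cosine geometry this region reaches from the axis to
y ≈ 0.9 along the upstream ramp, and its maximum shear rate (2.4 for
the shallow ramp, 6.6 for the steep one at Re = 400) is set by the
region's near-wall edge, where the margin over the threshold is only
~0.05 — making this the most shape- and connectivity-sensitive statistic
the package reports (the corresponding axis-core maxima are 1.1 and
2.2). Known limitation: reported region maxima should be read together
with the region mask, not as single numbers.

Production numbers at Re = 400, h = 0.5, l1 = 1.5, l2 = 2 (65×~320
grid): peak dimensionless shear rate 60.0 at the leading edge (z ≈ −1.8);
peak extension 14.86 (FENE saturation); wall extension 99.2% of maximum,
93.4% for the shallow ramp l2 = 5, and 37.6% at Re = 200. A closed
recirculation zone exists at h ≥ 0.3 and is absent for h ≤ 0.2.

## What the synthetic data does and does not show

The synthetic sigmoid targets emulate the shape of a normalised
unfolding curve (monotone, saturating, half point near 5100 1/s) but not
the noise, asymmetry or sampling of a measured curve; passing the
calibration tests shows the fitting pipeline recovers curves within its
own model family, not that the published parameter values would be
recovered from real data. Likewise the stenosis geometry is an idealised
smooth bump: trends across Re, height and steepness are meaningful,
while absolute field statistics inherit the shape assumption.

## Determinism and problem sizes

All solvers are deterministic; the only randomness in the package is the
calibration multistart (seeded). Production meshes are ~20k nodes
(~40k flow unknowns, ~60k tensor unknowns); a full stenosis case (flow +
transport) solves in about 1.5 minutes on one core, and the complete
acceptance recomputation in about 3.5 minutes. Tests use coarser grids
(~6k nodes) for everything except the acceptance checks.
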