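# Methods

`aneuflow` is a desk-scale computational-hemodynamics pipeline for studying
why some intracranial aneurysm sacs accumulate atherosclerotic wall change
while neighbouring sacs in the same host do not. The working hypothesis it
operationalizes is hemodynamic: sacs exposed to slow, disturbed, poorly
renewed blood (low wall shear stress, long relative residence time, old
blood) are the atherosclerosis-prone ones. The package builds synthetic 2D
vessel-plus-sac geometries, drives them with a pulsatile carotid-like inflow,
solves the incompressible Navier-Stokes equations under Newtonian or
Herschel-Bulkley rheology, and computes the discriminating diagnostics: wall
maps (TAWSS, OSI, RRT), washout metrics (neck inflow volume, exchange rate,
mean sac velocity) and the Eulerian age-of-blood field.

## Synthetic geometries and the 2D convention

Patient lumens are replaced by a straight parent channel of width *W*
(default 4 mm) on a uniform Cartesian grid with stair-stepped walls, carrying
one or more circular sidewall pockets. Each pocket of diameter *D* opens onto
the channel wall through a chord of length *w* (the neck); requiring
*w* < *D* makes the pocket deeper than a half-disc and guarantees that the
grid-aligned neck plane separates every sac cell from the parent vessel. A
resolution guard rejects any neck resolved by fewer than 8 grid faces.
Geometry construction is deterministic: identical parameters give
bit-identical masks.

Two dimensional-reduction conventions matter:

* **Volumes** are areas times a 1 mm unit depth, reported in mm³, so
  volume/inflow/exchange-rate columns keep their familiar units. The
  exchange rate b/a is independent of the depth choice.
* **Flow rates**: a printed volumetric flow Q (mL/min) is converted to a
  planar flux through an equivalent circular lumen of diameter *W*:
  U(t) = Q(t)/(πW²/4), q₂D(t) = U(t)·W. This keeps the mean velocity,
  Reynolds number (≈ 430 at 271.7 mL/min in a 4 mm vessel) and Womersley
  number (≈ 2.8 at 63 bpm) at the physiological values the printed flows
  imply, which the wall-shear and washout scales inherit.

The inlet waveform is a truncated Fourier series (4 harmonics by default)
with exact period T = 60/heart-rate and exact cycle mean; clinical flow
reports print only the mean flow and heart rate, so the shape is a
configurable model. The default "ica" preset is a single-systolic-peak shape
(peak at 0.15 T, peak/mean ≈ 1.8) with strictly positive flow.

## Rheology

Blood density is 1050 kg/m³ and the Newtonian viscosity 0.0035 kg/(m s).
The non-Newtonian setting uses the Herschel-Bulkley apparent viscosity
μ(γ̇) = k·γ̇ⁿ⁻¹ + τ₀/γ̇, which captures shear thinning (n < 1) and yield
stress (τ₀ > 0) but diverges as γ̇ → 0; it is regularized by flooring γ̇ at
γ̇_min (default 0.1 s⁻¹) and capping μ at μ_max (default 1.0 kg/(m s)),
keeping the law finite, positive and continuous. The default coefficients
(k = 0.0089 Pa·sⁿ, n = 0.8, τ₀ = 0.0175 Pa) are literature-typical
stand-ins for whole blood, intended to be overridden per case when measured
values are available; every verification in the test battery is independent
of this choice. With (k = μ, n = 1, τ₀ = 0) the Herschel-Bulkley branch
reproduces the Newtonian solve exactly.

## Flow solver

A fractional-step (projection) method on a staggered (MAC) grid:

* explicit upwind advection (first-order by default; a second-order upwind
  variant is available but the monotone first-order form is preferred for
  robustness in recirculating pockets — its numerical diffusion is the main
  accuracy cost of the default configuration);
* explicit variable-viscosity diffusion in the form ∇·(μ∇u), with the
  apparent viscosity lagged one step (Picard) from the previous strain
  rate; walls enter tangential fluxes at their true half-cell distance;
* a pressure Poisson solve by a prefactorized sparse LU, so stored fields
  are discretely divergence-free to round-off (~1e-15 scaled).

Boundary conditions: quasi-steady parabolic inlet profile scaled to Q(t)
(discretely normalized, so the inlet flux matches the waveform exactly);
zero-gradient outflow with an additive correction that pins each outlet to
exactly its Murray-law (d³) share of the instantaneous inlet flux; rigid
no-slip stair-step walls. Womersley inlet profiles are deliberately out of
scope.

The fixed time step honours both an advective Courant bound (CFL ≤ 0.35 on
a conservative velocity estimate, monitored at run time and aborted above
0.95) and the explicit viscous limit computed from the largest viscosity
the regularized rheology can produce. Each case runs 3 warm-up cardiac
cycles before one cycle is stored (200 snapshots) for post-processing —
the standard establish-then-analyse protocol. The initial state seeds the
parabolic profile along the channel, so the warm-up only has to establish
the sac recirculation, not the mean flow.

Verification: steady flow reproduces plane Poiseuille (centerline within
2%, error order ≈ 1.9 under grid halving), a 2:1-diameter bifurcation
splits flux 8:1 to within round-off, and inlet/outlet fluxes balance
exactly at every stored step.

## Wall parameters

In 2D the wall shear is a signed tangential scalar τ_w = μ_wall ∂u_t/∂n per
stair-step wall face, from a one-sided two-point difference that uses the
no-slip wall value (exact for parabolic profiles; single-point fallback at
under-resolved corners). From the stored cycle, by trapezoid quadrature:
TAWSS = ⟨|τ_w|⟩, OSI = ½(1 − |⟨τ_w⟩|/⟨|τ_w|⟩) (He-Ku form, defined 0 when
the shear never acts), RRT = 1/((1 − 2·OSI)·TAWSS) (Himburg form). RRT is
capped at 10⁶ Pa⁻¹ with a flag so tabulated output stays finite. Per-sac
extrema (max RRT, min TAWSS, max OSI) are searched independently — they
generally occur at different faces. Steady flow gives OSI = 0 and
RRT·TAWSS = 1 to 1e-10.

## Age of blood

The Eulerian age a(x, t) obeys ∂a/∂t + ∇·(u a) = 1 with zero age on the
inlet, zero normal gradient at outlets and no flux through walls. The
stored periodic flow cycle is replayed (linear interpolation in time, which
preserves discrete divergence-freedom) for 5 cycles by default, starting
from a = 0 everywhere; co-integrating flow and age over all 8 cycles would
cost ~4x more for the same diagnostics under cycle-periodic flow. The
conservative donor-cell scheme is monotone: age stays non-negative and
never exceeds elapsed time. A bound-limited QUICK variant is available;
monotonicity is worth more than formal order here because the unit source
makes over/undershoots compound. On a sealed cavity the age equals elapsed
time to round-off; on steady plug flow it converges (first order) to the
transit time x/U, with the donor-cell inlet closure contributing an O(h)
near-inlet offset.

Per sac, the pipeline records the spatial mean and maximum age at every
stored sample, the least-squares slope of max age versus time over the last
3 of 5 cycles (trailing window excludes the fill-in transient; the fitting
protocol is a package choice), and a phase diagnostic: the circular
cross-correlation lag between the sac mean-age series and the inlet
waveform over the final cycle, after removing a linear trend fitted over
the final two cycles (an integer number of periods, so the periodic
component is untouched). A lag in [0.35 T, 0.65 T] sets an "antiphase"
flag.

## Bundled study conditions

The standard battery case (`two_sac_comparison`) drives a 4 mm x 40 mm
channel at 271.7 mL/min and 63 bpm (T = 0.952 s) with two sacs on the same
wall: **stagnant** (D = 8 mm behind a 3.2 mm neck; deep, narrow-neck, the
atherosclerosis-prone archetype) and **washed** (D = 4.2 mm behind a 4 mm
neck; small and open, echoing the clinical pairing of a small well-washed
sac with a larger stagnant one in the same patient). At the default 0.4 mm
grid the case has ~1500 fluid cells and ~10,800 steps per cycle and runs in
about 1.5 minutes on one CPU — the problem size used throughout the tests
and the acceptance script.

On this case the pipeline reproduces the qualitative signature of
disturbed-sac hemodynamics: the stagnant sac simultaneously shows larger
max RRT, smaller min TAWSS, smaller exchange rate, smaller mean velocity
and larger max age than the washed sac, its intra-sac speed is ~2% of the
parent-channel mean, and its max-age slope is 1.00 — the trapped-core
"inclination of unity" signature — while the washed sac's slope decays
toward zero as it saturates.

## What the synthetic model does and does not show

The generator emulates pulsatile channel flow past sidewall pockets with
rigid walls and Murray-split outlets. It does **not** emulate: 3D geometry
and secondary/swirling flow, real (jet-driven) neck impingement, elastic
walls, or measured waveform shapes. Two consequences are worth stating
plainly:

* **Washout is slower than in patient-specific 3D studies.** 2D shear-driven
  cavity exchange gives per-cycle exchange rates of order 0.1-1, versus the
  5-60 per cycle that 3D jet-driven sacs show; correspondingly the washed
  sac's mean age needs ~9 replayed cycles (not 5) before its cycle-to-cycle
  drift falls below 2%. The *orderings* between sacs — the actual
  discriminant — are insensitive to this scale difference.
* **The antiphase flag is conservative.** The sac mean age does dip after
  systole and recover through diastole (opposite in phase with inflow in
  the visual sense), but the neck transport delay places the measured
  cross-correlation lag at ~0.1-0.3 T, below the strict [0.35 T, 0.65 T]
  window, so the flag stays unset for the bundled cases. The lag itself is
  reported and the constructed antiphase/in-phase limits behave exactly as
  defined.

Passing tests therefore demonstrate internal correctness (conservation,
analytic limits, monotone transport, deterministic reports) and the
qualitative stagnant-versus-washed discriminant — not quantitative
agreement with any patient-specific 3D result.

## Numerical choices and degenerate inputs

* Divergence acceptance: scaled residual max|∇·u|·h/U_ref ≤ 1e-8 (direct
  solves leave ~1e-15).
* RRT cap 1/ε with ε = 1e-6 Pa; capped faces flagged in all outputs.
* OSI defined 0 at zero-shear faces; clipped to [0, 0.5] against round-off.
* Ranking ties in comparison tables break in stable aneurysm-name order.
* A sealed box (no inlet/outlet) is a valid geometry for transport fixtures
  but is rejected by the flow solver.
* One printed per-sac table row is internally inconsistent (266.6/4.38 =
  60.9, not the printed 60.1); the recomputed value is used wherever that
  row appears.

## Known limitations

Stair-step walls make wall-shear extrema first-order accurate on curved sac
walls; the first-order advection default is diffusive (sharp shear layers
at the neck are smeared over a few cells, which inflates sac-channel
momentum exchange somewhat); the lagged-viscosity Picard coupling assumes
viscosity varies slowly over a time step; and with 2 aneurysm archetypes the
disturbed-flow flag is a transparent threshold rule, not a fitted
classifier.
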