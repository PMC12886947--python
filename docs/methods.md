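# Methods

This note documents the models, numerical choices and validation strategy
behind `laflow`. All internal computation is in SI units (m/s, m³, s);
presentation layers convert to the clinical units (ml/s, mm, mJ, mW).

## Data model and conventions

A `FlowDataset` holds the velocity field indexed `(phase, z, y, x,
component)` in m/s and the scanner magnitude image on the same grid. World
coordinates follow the VTK image convention: `world = origin +
index * spacing`, axes ordered (x, y, z), 0-based voxel indices, velocity
components along the world axes. Cardiac phases are uniformly spaced over
the RR interval; phase `k` occurs at `k * T / N`. The RR interval is taken
from the dataset's JSON sidecar or from the loader's `cycle_duration`
argument — file formats carry no reliable cardiac timing, so absent both
the loader raises rather than guessing.

Input velocities declared in cm/s (the acquisition convention; VENC is
typically 150–160 cm/s) are converted to m/s on load. Masking zeroes all
velocities outside the chosen segmentation label at every phase and is
idempotent; the magnitude image is never modified.

## PC-MRA

The time-averaged angiogram is `mean_t M(t) * (|V(t)|²)^γ`. The exponent
γ = 0.4 (default) boosts the low-speed voxels typical of the atrium; since
γ ≠ 0.5 the output depends on the velocity unit inside the power term, so
that unit is an explicit parameter (default cm/s, matching acquisition
convention). The magnitude image is passed through raw — any scanner-side
normalization is the caller's concern; the index is linear in M, so a
global magnitude scale only rescales the output. A γ-sweep helper exists
for tuning figures.

## Velocity-gradient machinery

All tensor indices (dissipation, vorticity, Q-criterion) share one masked
finite-difference kernel. For each voxel inside the region: central
differences where both axis neighbors are inside; one-sided differences
where only one is; zero with a reduced-accuracy flag where neither is.
Velocities outside the segmentation are zeroed and untrustworthy, so they
never enter a stencil. The flagged-voxel fraction is logged.

A consequence worth noting: one-sided differences are *exact* for fields
that are linear in space. On a rigid rotation (a linear field), every
region voxel — boundary included — obtains the exact gradient, so the
Q-criterion equals Ω_z² everywhere and the Q>500 s⁻² voxel fraction is
exactly 1.0, not just the interior fraction. The tests exploit this as a
calibration oracle (Ω_z = 30 s⁻¹ → Q = 900 s⁻², |ω| = 60 s⁻¹).

## Hemodynamic indices

* **Kinetic energy** `KE(t) = ½ ρ Σ_i |v_i|² Vol_i` with ρ = 1060 kg/m³
  (whole-blood density; configurable). Reported in mJ, and per unit region
  volume in µJ/ml (numerically equal to J/m³).
* **Viscous energy loss** uses the standard incompressible-flow dissipation
  function with the bracketed deviatoric term *squared*:
  `Φ_v = ½ Σ_ij [(∂v_i/∂x_j + ∂v_j/∂x_i) − ⅔(∇·v)δ_ij]²` and
  `EL(t) = μ Σ_i Φ_v,i Vol_i`, μ = 0.0035 Pa·s. Without the square the
  expression can be negative and fails the Poiseuille closed form
  `EL = 2πμLv₀²`; with it, simple shear `v_x = k·y` gives exactly `μk²V`
  and rigid rotation dissipates nothing. The `⅔∇·v` term is kept even for
  nominally incompressible blood because measured MRI fields are never
  discretely divergence-free.
* **Vorticity** ω = ∇×v; the scalar summary is the region-mean |ω|
  (equivalently Σ|ω|Vol / V_region for uniform voxels), which normalizes
  away atrial dilation.
* **Q-criterion** `Q = ½(‖Ω‖_F² − ‖S‖_F²)` with Frobenius norms of the
  antisymmetric/symmetric gradient parts; with this convention rigid
  rotation gives Q = Ω_z², the calibration value. The scalar summary is the
  fraction of region voxels with Q above a threshold, 500 s⁻² by default.
* The 3×3×3 **median filter** used before Q-criterion rendering replicates
  the nearest edge voxel at borders.

Scaling laws (checked on a Lamb–Oseen vortex): vorticity is 1-homogeneous
in velocity amplitude; Q, KE and EL are 2-homogeneous; KE/EL is invariant.
On grids ≤12³ all three indices match naive per-voxel loop implementations
to 1e-10.

Accuracy note: the dissipation of a Poiseuille profile concentrates at the
tube wall, where masked one-sided stencils under-read the gradient; the
measured EL converges to the closed form from below (−70% at 2.4 mm,
−27% at 1.2 mm, −7% at 0.6 mm, −1.5% at 0.3 mm for R = 5 mm). Closed-form
dissipation checks therefore run at 0.3 mm spacing; clinical-resolution
dissipation values should be read as lower bounds with a resolution-dependent
bias, which cohort comparisons at fixed protocol largely cancel.

## Cross-sections and flow rates

Each vessel is located by a named sample sphere (RS/RI/LS/LI pulmonary
veins, MV). The plane normal is the dominant flow direction: per-phase mean
velocity over in-sphere voxels (voxel centers inside the radius), phases
ranked by that mean's magnitude, top-5 phase means summed and normalized.
The plane through the sphere center is sampled on a uniform grid with step
= half the smallest voxel spacing and half-extent 3× the seed radius —
enough to resolve ~5 mm vessels on 1.2–2.4 mm grids. A sample is lumen when
the linearly interpolated binary label ≥ 0.5, restricted to the connected
component containing the center; the reported lumen *area* additionally
integrates the fractional label coverage over a 2-sample dilation ring,
which removes the ~half-voxel dilation bias of the 0.5-threshold rule
(thresholded area overestimates a 5 mm-radius disc by ~11% at 1 mm spacing;
the fractional area is within ~2%).

Flow rate is `Q(t) = Σ_lumen v·n̂ ΔA` with trilinear velocity interpolation;
1 (m/s)·mm² = 1 ml/s. The normal is flipped, when needed, so the
cycle-integrated flow is positive — venous and mitral curves then plot
inflow-dominant, the clinical convention.

### Wave features

The wave-detection windows are operational choices (all configurable),
since clinical practice names the waves but does not define detectors:

* **PV curves**: the systolic window runs from the cycle start until the
  subject's mitral flow first exceeds 10% of its maximum (valve opening).
  S = max in the window, D = max after it, Ar = min within the last 30% of
  the cycle (flagged "no reversal" when non-negative), S/D from the peaks.
* **MV curve**: E is the global maximum and A the last local maximum after
  it; when no local maximum follows the global peak but one precedes it,
  the amplitudes are reversed (advanced diastolic dysfunction) and the
  earlier peak is E. The E–A split is the flow minimum between the peaks;
  passive volume integrates (trapezoid, negative lobes clipped) from the
  last upward 10%-of-E crossing to the split, active volume from the split
  to the first downward 10%-of-A crossing. E/A is reported both by peak and
  by volume. A trough above 20% of the E peak sets the fusion flag.

Peak detection reads values on the sampled time grid; features are accurate
to the phase spacing (T/N).

## Volumetrics, agreement, mask metrics

LA volume is voxel count × voxel volume. LAVi divides by the DuBois body
surface area `0.007184·W^0.425·H^0.725` (W kg, H cm). The 2D comparator is
biplane disk summation `V = (π/4) Σ a_i b_i (L/N)` with diameters taken at
disk centers (midpoint rule); 2D cine image analysis itself is out of
scope — the function consumes pre-measured diameters. Method agreement uses
Pearson r with a Fisher-z 95% CI and Bland–Altman bias ± 1.96·SD limits
(sample SD). Dice is `2|A∩B|/(|A|+|B|)` (both-empty defined as 1 with a
warning); HD95 is the 95th percentile (linear interpolation) of pooled
bidirectional nearest-surface distances between the voxel shells of the two
regions, in mm — the pooled definition keeps it symmetric.

Surface meshes come from marching cubes at the 0.5 iso-level of the
binarized label (zero-padded so edge-touching regions still close), no
smoothing by default; optional Taubin smoothing removes the staircase area
inflation (~+9% for a 10 mm digitized sphere at 1 mm; ~2% after smoothing)
while preserving volume to <0.5%. Tetrahedral meshes split each voxel into
6 tetrahedra, so the mesh volume equals voxel count × voxel volume exactly.
Scalar upsampling uses tensor-product natural cubic splines per spatial
axis (time untouched): new spacing = old/factor, original samples are
preserved, and affine fields are reproduced exactly (natural boundary
conditions extrapolate linearly, so no boundary ringing on ramps).

## Pathlines

Classical RK4 with trilinear interpolation in space, linear in time, cyclic
over the cycle (the last phase wraps to the first). Default 4 substeps per
phase. Particles leaving the grid or the segmentation terminate with a
flag. Emission sites reuse the cross-section lumen geometry; each particle
keeps a speed attribute and the exporter writes legacy ASCII VTK polylines
with a configurable 6-step trail for rendering. On a rigid rotation the
orbit radius is conserved to <1e-6% over one revolution at 400 steps, and
halving the step shrinks the endpoint error by roughly the 4th-order
factor.

## Cohort statistics

Features are compared with a homogeneous-slopes ANCOVA, `value ~ group +
age` (no group×age interaction), implemented as two least-squares fits; the
group F-test compares against `value ~ age`, and partial η² =
SS_group/(SS_group + SS_residual). Post hoc (only when p < 0.05):
Tukey–Kramer on the covariate-adjusted group means using the ANCOVA
residual mean square and the studentized-range distribution; Cohen's d on
raw values with the pooled SD (reported as the raw-value convention, not
covariate-adjusted); Benjamini–Hochberg step-up correction across the
pairwise p-values of one feature (the BH family is all pairwise contrasts
within a feature). The implementation is cross-checked in the tests against
pingouin's ANCOVA and statsmodels' BH correction, and calibrated by
simulation: type-I error 0.05 ± 0.02 over 1000 null tables, power > 0.99
for a 3σ group shift at n = 20/group.

## The synthetic phantom

`la_phantom` emulates the *geometry and plumbing* of an LA acquisition: a
64³ grid at 2 mm isotropic spacing, 30 phases over a 1 s cycle, an
ellipsoidal atrium (semi-axes 26/24/22 mm), four pulmonary-vein tubes
(radius 6 mm) entering the roof and a mitral tube (radius 12 mm) leaving
the floor. Tubes carry Poiseuille profiles scaled by Gaussian-pulse
waveforms: per vein S/D/Ar amplitudes 50/40/−15 ml/s at 0.20/0.60/0.90 of
the cycle; the mitral E/A pulses (raw 200/120 ml/s at 0.60/0.90) are scaled
so the mitral cycle volume equals the summed venous inflow — mass balance
holds by construction. Pulse centers sit on the 30-phase sampling grid so
the prescribed peak is observable at a sample instant and peak-recovery
tests measure flux accuracy rather than temporal sampling. A Lamb–Oseen
vortex (Γ = 0.012 m²/s, core 8 mm) gated to the S and D windows fills the
chamber interior, making the kinetic-energy curve triphasic with peaks in
the S, E and A windows. Peak velocities stay under the 150 cm/s VENC.
Gaussian velocity noise can be added (`add_noise`, seeded); the phantom
default is noise-free so discretization error and noise are separable in
tests.

What the phantom does *not* emulate: MR physics (k-space, partial volume,
VENC aliasing, eddy currents), a globally divergence-free chamber flow
(tube/ellipsoid junctions are not mass-consistent voxel by voxel; chamber
energy indices are therefore validated on the analytic fields, while the
phantom validates geometry, flux and waveform plumbing), wall motion, and
anatomical shape variability. Passing phantom tests demonstrates correct
measurement plumbing at clinical resolution, not robustness to scanner
artifacts.

## Problem sizes used in validation

Analytic-field checks run on 24³–96³ grids chosen so the relevant feature
is resolved by ≥4 voxels (warned otherwise); the dissipation closed form
uses 0.3 mm spacing as discussed above; the phantom runs at its default
64³ × 30 phases; statistical calibration uses 1000 null simulations
(n = 15/group) and 200 power simulations (n = 20/group); agreement recovery
uses 200 pairs per replicate. These sizes were chosen to keep each check
comfortably converged.

## Known limitations

* Dissipation at clinical resolution is biased low near walls (see above).
* The static mask means no time-resolved LA emptying function; only the
  maximal-volume estimate is produced.
* Wave detectors assume one cardiac cycle starting in systole; curves with
  waves wrapping the cycle boundary need re-phasing first.
* DICOM ingestion, phase unwrapping, background-offset and eddy-current
  correction are out of scope; inputs are assumed preprocessed.
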