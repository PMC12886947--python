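# laflow

Quantitative analysis of 4D flow MRI in the left atrium (LA).

4D flow MRI acquires all three blood-velocity components over a volume,
time-resolved across the cardiac cycle. The LA is a hard target for it: the
chamber velocities are low, the spatial resolution is coarse (1–2.4 mm), and
most analysis tooling is built for the aorta or the left ventricle. `laflow`
implements the post-segmentation half of an LA analysis pipeline: given the
velocity + magnitude volumes and a static LA segmentation mask, it computes
the angiogram used for segmentation, the advanced hemodynamic indices, the
pulmonary-vein (PV) and mitral-valve (MV) flow waveforms and their clinical
wave features, LA volumetrics with the 2D biplane comparator, and the
age-adjusted cohort statistics. Everything is validated against analytic
flow fields and a synthetic LA phantom, so the whole pipeline is testable
without patient data.

## What it computes

**PC-MRA** (phase-contrast MR angiogram), time-averaged:

    PC-MRA = (1/N) Σ_t M(t) · (Vx² + Vy² + Vz²)^γ,   γ = 0.4 by default

**Kinetic energy** over the masked region (ρ = 1060 kg/m³):

    KE(t) = ½ ρ Σ_i |v_i|² Vol_i            [reported in mJ]

**Viscous energy loss** from the Navier–Stokes dissipation function
(μ = 0.0035 Pa·s):

    Φ_v = ½ Σ_ij [ (∂v_i/∂x_j + ∂v_j/∂x_i) − ⅔ (∇·v) δ_ij ]²
    EL(t) = μ Σ_i Φ_v,i Vol_i               [reported in mW]

**Vorticity** ω = ∇×v, volume-averaged over the LA (|ω_LA|, s⁻¹), and the
**Q-criterion** Q = ½(‖Ω‖² − ‖S‖²) with the vortex-core burden
Q-crit₅₀₀ = fraction of LA voxels with Q > 500 s⁻².

**Flow rates** through sphere-seeded vessel cross-sections (four PVs + MV),
with S/D/Ar and E/A wave features, including E/A both by peak flow and by
integrated filling volume.

**Volumetrics**: LA volume from the mask, LAVi indexed to DuBois body
surface area, the biplane disk-summation comparator, Pearson/Bland–Altman
agreement, and Dice/HD95 mask-overlap metrics.

**Statistics**: ANCOVA (value ~ group + age) with partial η², Tukey–Kramer
post hoc on adjusted means, Cohen's d, Benjamini–Hochberg correction.

**Pathlines**: RK4 particle advection in the time-resolved field for vortex
visualization (exported as VTK polylines).

## Worked example

The synthetic phantom is an ellipsoidal LA fed by four PV tubes and drained
by an MV tube, each carrying Poiseuille profiles scaled by prescribed
Gaussian-pulse waveforms, plus a decaying interior vortex:

```python
import laflow

ds, mask, seeds, truth = laflow.la_phantom()
ds = laflow.apply_mask(ds, mask, "LA")

ke, _ = laflow.kinetic_energy(ds, mask)
mv_seed = next(s for s in seeds if s.name == "MV")
normal = laflow.plane_normal_from_flow(ds, mv_seed)
cs = laflow.extract_cross_section(mask, "LA", mv_seed, normal)
waves = laflow.detect_mv_waves(laflow.flow_rate(ds, cs))
```

Printing the extracted numbers (volume, indexed volume, curve peaks and the
mitral wave features) gives:

```
LA volume: 101.2 ml
LAVi (70 kg, 170 cm): 55.9 ml/m^2
peak KE: 7.85 mJ at t = 0.60 s
peak VEL: 3.259 mW
peak |omega_LA|: 62.77 1/s
peak Q-crit500 ratio: 0.019
MV E peak: 257.0 ml/s, A peak: 154.2 ml/s, E/A = 1.67
E/A by volume: 2.46 (truth 2.38)
```

The LA volume (101 ml, ellipsoid + vessel stumps) and LAVi (56 ml/m²)
describe a mildly dilated atrium; the kinetic-energy curve peaks at early
diastolic filling (t = 0.6 s, the E wave); the mitral E/A of 1.67 matches
the prescribed 200:120 pulse amplitudes after mass-balance scaling, and the
measured E/A-by-volume (2.46) recovers the generator truth (2.38) to ~3%,
the discretization level of the 2 mm phantom grid.

A full per-subject run (masking → PC-MRA → indices → flow rates → volumes →
pathlines) is one call, or one shell command:

```sh
laflow phantom --out subj/
laflow run --config subject.json --out report/
```

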