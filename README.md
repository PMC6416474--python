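# photodose

Voxel Monte Carlo light transport coupled to singlet-oxygen photokinetics
for photodynamic-therapy (PDT) dosimetry — with the tumor-regrowth outcome
analysis that shows *why* this matters: the reacted singlet-oxygen dose
predicts treatment outcome where the conventional light dose does not.

## The problem

Type-II PDT kills tumor cells through singlet oxygen (¹O₂) generated when a
light-activated photosensitizer transfers energy to tissue oxygen. Clinics
mostly prescribe the *incident light dose* (fluence, J/cm²), but identical
light doses produce wildly different outcomes because the effect also
depends on the in-tissue fluence-rate distribution, the photosensitizer
concentration, photobleaching, and oxygen depletion/resupply. A better dose
metric is the cumulative *reacted singlet-oxygen concentration* [¹O₂]rx,
which can be computed but not directly measured.

`photodose` computes it in two stages:

1. **Transport** (`photodose.mc`): voxel-based Monte Carlo — packets from a
   collimated disc source, Henyey–Greenstein scattering, continuous
   absorption-weight deposition per traversed voxel, unpolarized Fresnel
   treatment of the air–tissue interface and exterior faces, Russian-roulette
   termination — yielding the 3-D fluence-rate map φ (mW/cm²), the diffuse
   reflectance Rd and an exact energy balance.
2. **Kinetics** (`photodose.kinetics`): per-voxel integration of the
   macroscopic three-state system for the sensitizer [S0], ground-state
   oxygen [O₂] and reacted singlet oxygen [O₂rx],

       d[S0]/dt   = −ξσφ([S0]+δ)·([O₂]/([O₂]+β))·[S0]
       d[O₂]/dt   = −ξφ[S0]·([O₂]/([O₂]+β)) + g(1 − [O₂]/[O₂]₀)
       d[O₂rx]/dt = +ξφ[S0]·([O₂]/([O₂]+β))

   by an adaptive embedded Runge–Kutta 5(4) with a non-negativity guard.
   Defaults are the benzoporphyrin-derivative (BPD/Visudyne) constants.

Around these sit a 1-D analytic centreline model (two-exponential decay with
a subsurface build-up factor, fittable to MC profiles), the outcome layer
(tumor volume V = πa²b/6, exponential regrowth rate k, cure index
CI = 1 − k/k_ctr, logistic dose–response CI = A/(1+B·e^(−c·dose))), and a
session/pipeline driver with the built-in 15-group BPD mouse-study table.

## Worked example

Group 1 of the built-in study table: 50 mW/cm² for 600 s from a 10-mm disc,
0.53 μM BPD, tumor optics μa = 0.69 cm⁻¹, μs′ = 11 cm⁻¹, n = 1.4:

```python
from photodose import run_mc, dose_map, dose_at_depth, session_for_group

sess = session_for_group(1)                 # 100^3 grid of 0.5-mm voxels
fl = run_mc(sess.grid(), sess.source, 2_000_000, seed=1)
print(f"Rd = {fl.energy_balance.diffuse_reflected:.4f}")
print(f"peak phi = {fl.values.max():.1f} mW/cm^2 "
      f"({fl.values.max()/50:.2f}x incident)")

dm = dose_map(fl, S0_init=sess.BPD_pre, T=sess.time)
print(f"dose at 3 mm = {dose_at_depth(dm, 0.3):.4f} mM")
print(f"peak dose    = {dm.values.max()*1000:.0f} uM")
```

prints (seed 1):

```
Rd = 0.3234
peak phi = 169.3 mW/cm^2 (3.39x incident)
dose at 3 mm = 0.4045 mM
peak dose    = 713 uM
```

Reading: backscattering raises the subsurface fluence rate to ~3.4× the
incident value — the light dose *inside* the tissue is not the light dose
you prescribed. After 600 s the beam-centre voxel column has accumulated
0.40 mM of reacted singlet oxygen at the 3-mm tumor base, far below the
~1.3 mM the logistic dose–response (`photodose.logistic_ci`) associates with
a full cure (CI = 1) — and indeed this group's observed CI was 0.04. The
cured groups in the table all sit at ≈1.3 mM.

The same from the shell:

```bash
photodose pipeline --config examples/group01.yaml --out out/
photodose batch --groups 1,4,9,14 --photons 2000000
photodose eq5fit --profile out/centerline.csv
```

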