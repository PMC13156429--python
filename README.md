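# mcdip

Motion-compensated diffusion imaging with phase-contrast (MC-DIP): absolute
regional cerebral blood flow (rCBF) from non-contrast MRI.

## The problem

Intravoxel incoherent motion (IVIM) analysis of multi-b-value
diffusion-weighted imaging sees capillary blood flow as a fast
pseudo-diffusion compartment superimposed on tissue diffusion:

    S(b) = S0 · [ F · exp(−b·D*) + (1 − F) · exp(−b·D) ]

where `D` (mm²/s) is the tissue diffusion coefficient, `D*` the
perfusion-related pseudo-diffusion coefficient, and `F` the perfusion signal
fraction. The product `F·D*` is a *relative* blood-flow surrogate — useful,
but not in physiologic units. The DIP idea makes it absolute: measure total
cerebral blood flow (tCBF) through the two internal carotid and two
vertebral arteries with phase-contrast MRI, normalize by brain mass
(volume × 1.06 g/mL), and scale the `F·D*` map so its brain mean equals
that normalized tCBF. The result is an rCBF map in mL/100 g/min without
contrast agents.

The catch is bulk motion: brain pulsation adds phase dispersion to the
diffusion-encoded signal, which masquerades as extra perfusion and corrupts
the biexponential fit — most severely in deep white matter. Diffusion
gradients with nulled first and second gradient moments (velocity- and
acceleration-compensated, "2nd-MC") are insensitive to this; first-order
compensation ("1st-MC") removes only the velocity term, and uncompensated
gradients ("non-MC") see both.

`mcdip` implements the full analysis — stepwise biexponential fitting,
pulsatility-based vessel segmentation and flow quantification, FD*→rCBF
calibration, an ASL kinetic-model reference, and the comparison metrics
(nRMSE, Jensen–Shannon divergence, Bland–Altman, Spearman) — together with
a seeded synthetic phantom that emulates the three gradient schemes'
motion sensitivity, so every stage can be validated against ground truth.

It is aimed at researchers in quantitative perfusion MRI who want a tested,
scriptable reference implementation of the DIP calibration chain and a
phantom for method development.

## Worked example

```python
import numpy as np
from mcdip import (
    BValueScheme, GradientScheme, make_phantom, synthesize_dwi, synthesize_pc,
    make_brain_mask, fit_ivim_map, brain_volume,
    segment_lumen, vessel_flow, total_cbf, normalize_tcbf, calibrate_rcbf,
)

truth = make_phantom(shape=(24, 24, 12), seed=7)
scheme = BValueScheme(scheme=GradientScheme.SECOND_ORDER_MC)
dwi = synthesize_dwi(truth, scheme, noise_sigma=0.0, seed=8)

mask = make_brain_mask(dwi.b0)
params = fit_ivim_map(dwi, mask)

planes = synthesize_pc(truth, seed=9)
flows = [vessel_flow(p.cine, segment_lumen(p.cine, p.seed_point)) for p in planes]
tcbf = total_cbf(flows)
tcbf_norm = normalize_tcbf(tcbf, brain_volume(mask, dwi.voxel_dims))
rcbf, calib = calibrate_rcbf(params.fd_star, mask, tcbf_norm,
                             valid=params.valid_mask)

print(f"tCBF = {tcbf:.1f} mL/min -> {tcbf_norm:.1f} mL/100g/min")
print(f"conversion factor = {calib.conversion_factor:.1f}")
print(f"brain-mean rCBF  = {rcbf.values[rcbf.valid_mask].mean():.1f} mL/100g/min")
gm = truth.tissue_probs['gm'] >= 0.9
print(f"GM mean rCBF     = {rcbf.values[gm & rcbf.valid_mask].mean():.1f}"
      f" (truth {truth.true_rcbf.values[gm].mean():.1f})")
```

Output:

```
tCBF = 33.2 mL/min -> 50.0 mL/100g/min
conversion factor = 64869.5
brain-mean rCBF  = 50.0 mL/100g/min
GM mean rCBF     = 76.5 (truth 76.5)
```

The desk-scale phantom brain (~63 mL) carries a total inflow of 33 mL/min,
i.e. exactly the configured 50 mL/100 g/min once normalized by brain mass;
with noise-free data and second-order motion compensation the calibrated
gray-matter mean reproduces the ground truth to a fraction of a percent.
The conversion factor is large because FD* is numerically tiny
(~0.8×10⁻³ mm²/s on brain average).

A CLI mirrors the library:

```bash
mcdip simulate --seed 1 --out subj/           # synthetic subject on disk
mcdip fit --dwi subj/dwi_2nd_mc.nii.gz --bvals subj/dwi_2nd_mc.bval \
          --scheme 2nd-mc --out maps/
mcdip run --config pipeline.yaml              # full chain + JSON report
```

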