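# neodmri

Protocol design, image-formation simulation and quality assurance for
**post-mortem neonatal diffusion MRI at 7T**.

Diffusion imaging of unfixed post-mortem infant brains trades the usual
in-vivo constraints for new ones: tissue diffusivities collapse roughly
five-fold (cold, ischemic tissue, ADC ≈ 0.07–0.3 μm²/ms), so very high
b-values (3000/6000/9000 s/mm²) are needed for contrast; overnight scan
sessions make RF heating (SAR) and gradient duty cycle limiting factors;
and sub-millimetre resolution at 7T forces readout-segmented EPI with
multiband and in-plane (GRAPPA) acceleration, whose blurring, distortion
and noise-amplification trade-offs must be quantified before a protocol is
committed — piloting on recruited subjects is not an option.

`neodmri` packages those design computations as a tested toolkit, exercised
entirely on synthetic phantoms:

| module | what it does |
| --- | --- |
| `phantom_forge` | labelled neonatal head phantom, B0 field maps with calibrated percentile, 16-channel coil sensitivities, kurtosis-model DWI volumes with Rician noise and ADC drift, segmented multi-coil k-space; NIfTI + FSL bval/bvec I/O |
| `epi_geometry` | echo-train timing; PSF blurring FWHM `|DFT{exp(-t/T2*)}|`; off-resonance voxel shift `f·T_train`, percentile summaries |
| `parallel_recon` | split slice-GRAPPA slice separation, in-plane GRAPPA, NRMSE, analytic SENSE g-factor `g_j = √([(SᴴS)⁻¹]ⱼⱼ[SᴴS]ⱼⱼ)` and pseudo-multiple-replica check |
| `protocol_planner` | TR/SAR/scan-time feasibility over the MB×R grid, b-shell subset partitioning, duty-cycle interleaved scheduling, electrostatic-repulsion direction sets |
| `signal_forecast` | linear field scaling of R2=1/T2, Speedy–Angell water-diffusivity temperature law `D = D₀((T/Tₛ)−1)^γ`, relative signal/SNR forecasts with assumption echo |
| `shellwise_qa` | shell-wise ADC and attenuation per tissue, sub-group ADC stability (CoV), diffusion kurtosis fit (tensor + scalar MK, iterated WLLS), BIC selection of a fixed axial diffusivity |

## Worked example

```python
import numpy as np
from neodmri import epi_geometry as epi, phantom_forge as pf, protocol_planner as plan

geom = epi.AcquisitionGeometry()           # 188x188x130, 0.4 ms esp, 0.8 mm
for R in (1, 2, 3, 4):
    g = geom.with_acceleration(R=R)
    width = epi.fwhm(epi.psf_profile(83.0, g))          # T2* = 83 ms
    fm = pf.make_fieldmap(pf.make_phantom(seed=0), 35.9, seed=0)
    shift = epi.shift_percentile(epi.distortion_map(fm, g), 90)
    print(f"R={R}  FWHM {width:.3f} vox   q90 shift {shift:.2f} mm")
```

prints

```
R=1  FWHM 1.245 vox   q90 shift 2.16 mm
R=2  FWHM 1.216 vox   q90 shift 1.08 mm
R=3  FWHM 1.211 vox   q90 shift 0.72 mm
R=4  FWHM 1.209 vox   q90 shift 0.54 mm
```

i.e. in-plane acceleration buys a four-fold reduction of off-resonance
distortion (largest step from R=1 to 2) but only marginal de-blurring —
the quantitative basis for choosing R=2.  The scheduling side:

```python
budget = plan.per_volume_budget(7 * 3600, 301)       # 83 s per volume
sched, scheme = plan.build_schedule(seed=0)          # 301 volumes, 17 subsets
```

partitions the 64/88/128-direction shells into 4/5/8 subsets, interleaves
them so no two b=9000 subsets run back to back, and opens each subset with
a forward-PE b=0 (plus 4 reversed-PE b=0s at the end).

A `neodmri` console script exposes the same operations
(`phantom`, `psf`, `distortion`, `recon`, `plan`, `schedule`, `forecast`,
`qa`); try `neodmri plan` or `neodmri psf`.

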