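# carotidfr

Free-running 4D carotid MR angiography, end to end and at desk scale:
simulate a continuously acquired 3D radial ("spiral phyllotaxis")
acquisition of a pulsating two-vessel neck phantom, sort the readouts
into cardiac bins from pulse-oximeter triggers, reconstruct the
cardiac-resolved image by compressed sensing with temporal total
variation, contour the lumen by the full-width-at-half-maximum rule,
process parallel synthetic M-mode ultrasound traces, and derive the
five standard carotid stiffness indices with scan-rescan repeatability
statistics.

It is aimed at people developing or validating dynamic vascular MRI
analysis: every stage is a tested library function with a known-truth
synthetic data generator in front of it, so the whole chain doubles as
a parameter-recovery benchmark.

## The model

The cardiac-resolved image solves

    x_hat = argmin_x  || F C x - y ||_2^2  +  lambda_c || grad_c x ||_1

where `F` is the per-bin non-uniform Fourier transform along radial
spokes, `C` the coil sensitivities, `y` the binned raw k-space, and
`grad_c` the cyclic first-order finite difference across cardiac
phases.  The problem is solved by ADMM (10 iterations; inner conjugate
gradient; complex soft-thresholding), with `lambda_c = 0.01` under the
normalization convention described in `docs/methods.md`.

From the per-phase lumen diameters (FWHM contour -> triangulated area
-> effective diameter `D = 2 sqrt(A/pi)`) and the brachial pressures,
the stiffness panel is

    RDC  = (D_s - D_d)/D_d x 100          relative diameter change [%]
    beta = ln(P_s/P_d) / (RDC/100)        stiffness index [-]
    AC   = pi (D_s^2 - D_d^2)/(4 dP)      arterial compliance [mm^2/kPa]
    PWV  = sqrt(beta P_s / (2 rho))       local pulse wave velocity [m/s]
    E    = dP / (RDC/100)                 pressure-strain modulus [kPa]

with blood density rho = 1050 kg/m^3.

## Worked example

```python
import numpy as np
from carotidfr import (ExperimentConfig, stiffness_panel,
                       simulate_pressures, analyze_mmode,
                       make_diameter_waveform, simulate_mmode)
from carotidfr.pipeline import simulate_subject_mra, reconstruct_and_measure

cfg = ExperimentConfig()          # 64^3 phantom, 2-min scan, 80-ms bins
raw = simulate_subject_mra(cfg, seed=1)
series, image, info = reconstruct_and_measure(cfg, raw)
d_s = np.mean([series[v].d_s for v in series])
d_d = np.mean([series[v].d_d for v in series])
print(f"MRA: D_s {d_s:.2f} mm, D_d {d_d:.2f} mm "
      f"(truth {cfg.d_s_mm}/{cfg.d_d_mm})")

be = analyze_mmode(simulate_mmode(cfg.waveform(), 5, 0.1, 0.05,
                                  imt_mm=0.6, seed=2))
print(f"US:  D_s {be.d_s:.2f} mm, D_d {be.d_d:.2f} mm")

panel = stiffness_panel(6.4, 5.5, simulate_pressures(113, 63, 0.0, 0))
print({k: round(v, 3) for k, v in panel.as_dict().items()})
```

prints (the MRA line takes a few minutes of reconstruction):

```
MRA: D_s 6.14 mm, D_d 5.40 mm (truth 6.4/5.5)
US:  D_s 6.44 mm, D_d 5.48 mm
{'rdc_percent': 16.364, 'beta': 3.57, 'ac_mm2_per_kpa': 1.262, 'pwv_m_per_s': 5.061, 'e_kpa': 40.737}
```

The MRA diameters land within half a voxel (0.3 mm) of the ground
truth: the residual shortfall is the physics of 80-ms cardiac binning
(motion states are averaged within a bin) plus mild regularization.
The stiffness line evaluates the panel at the healthy-young magnitudes
D 5.5->6.4 mm and 63/113 mmHg: a relative diameter change of ~16%, a
stiffness index of ~3.6, a compliance of ~1.3 mm^2/kPa, a local pulse
wave velocity of ~5 m/s and an elastic modulus of ~41 kPa.

A `carotidfr` command-line tool exposes the same stages
(`simulate`, `bin`, `recon`, `measure-mra`, `measure-us`, `stiffness`,
`cohort`, `sweep-binwidth`, `sweep-lambda`); run `carotidfr --help`.

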