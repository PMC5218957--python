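# luquant

Accuracy of absolute ¹⁷⁷Lu activity quantification in SPECT, measured by
parameter recovery on digital phantoms.

Targeted radionuclide therapy with ¹⁷⁷Lu needs patient-specific dosimetry,
which in turn needs SPECT images whose voxel values are trustworthy
activities (MBq), not just counts. Whether the MIRD-style workflow —
OSEM reconstruction with attenuation correction, resolution recovery and
triple-energy-window (TEW) scatter handling, a camera normalization
factor (CNF) to convert counts to activity, and a segmentation step to
read off each object — actually recovers known activities is an
empirical question. `luquant` answers it in simulation: it builds
voxelized bench phantoms (Jaszczak spheres and bottles in air, cold and
radioactive background, a thorax body, bottles on the camera bed),
simulates three-energy-window acquisitions with scatter and Poisson
noise, runs the full reconstruction-calibration-segmentation chain, and
tabulates signed percent quantification errors per insert.

The package is aimed at physicists and imaging scientists who want a
controlled, fully scriptable testbed for quantitative-SPECT corrections
and segmentation strategies.

## The model in brief

OSEM iterates the multiplicative update

    X_j ← X_j / Σ_i C_ij · Σ_i C_ij · Y_i / (Σ_k C_ik X_k + S_i + H_i)

over 10 angle-interleaved subsets of the 90 views, 6 iterations; `C` is a
rotation-based projector with depth-dependent Gaussian detector response
σ(d) = σ₀ + s·d and Beer–Lambert attenuation, and `S + H` (self-scatter
plus high-energy downscatter) enters the denominator as a per-bin
estimate. TEW estimates it from the flanking windows of Table-style
settings (LSW 153.0–187.0, PW 187.2–228.8, USW 229.5–280.2 keV):

    C_s = (C_ls / w_ls + C_us / w_us) · w_pw / 2 .

Counts become activity through a CNF (counts per MBq per second),
measured from a planar point-source scan (with or without TEW
subtraction: "method 2" / "method 1") or from a tomographic phantom
reconstruction, C_rec / (A · t_p · n_p). Segmentation is a fixed
fractional threshold (0.1% in air, 1% in cold water, 40% clinical
reference), the CT-derived true geometry, or iterative adaptive dual
thresholding (IADT) whose two threshold-vs-SBR curves are learned from
multi-SBR calibration scans. `docs/methods.md` has the full account.

## Worked example

`examples/03_camera_calibration.py` determines the CNF three ways from
simulated scans of a camera with a true sensitivity of 10 counts/(MBq·s):

```
$ python examples/03_camera_calibration.py
planar method 1 (no scatter correction): 10.787 counts/(MBq s)
planar method 2 (TEW corrected):         9.953 counts/(MBq s)
tomographic (TEW-corrected OSEM):        9.959 counts/(MBq s)
```

Method 1 reads ~8% high — exactly the self-scatter plus high-energy
downscatter fraction contaminating the photopeak window — while the
TEW-corrected planar value and the tomographic value agree with the true
sensitivity to within about 1%, which is why planar point-source scans
with scatter correction suffice for camera calibration.

The other examples build phantoms (`01`), reconstruct a noisy
acquisition with TEW / ideal / no scatter correction (`02`), compare the
three segmentation methods in warm background (`04`), and run the whole
study matrix (`05`), each printing the quantities it computes and what
they mean.

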