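# fiberorient

Quantifying how astrocyte processes and axons are oriented along the mouse
optic nerve, from serial-section fluorescence microscopy.

In coronal sections of white matter, Gfap-labeled astrocyte processes appear
either as small round cross-sections (fibers running *along* the nerve) or as
elongated in-plane profiles whose angle against the image horizontal can be
measured. This package implements the full measurement chain for that kind of
study:

- **Subpixel ridge detection** (Steger's method): Gaussian-derivative Hessian,
  line points where the directional derivative along the Hessian eigenvector
  vanishes within the pixel, hysteresis linking — with the published
  parameterization (`sigma = 1.2`, thresholds `0 / 3.74`, minimum line length
  2 px, at most 200 contours) as the default profile.
- **Axial angle statistics**: per-contour chord angle in [0°, 180°),
  length-weighted section means (arithmetic, per the original procedure, and a
  doubled-angle axial estimator), slide-placement correction, and the
  polarization statistic — the SD of segment angles referenced to vertical.
- **Fiber-class analysis**: Bernsen local thresholding (radius 3), 8-connected
  particles, the inclusive 25 µm² longitudinal/transverse cutoff, and the
  per-section class-area ratio.
- **Orientation profile**: per-section means on the normalized nerve axis
  (0 = scleral end, 1 = chiasm–tract transition), an ordinary-least-squares
  degree-7 polynomial fit, critical and interior inflection points (5%
  edge margin), and matching of inflections against a map of positions where
  the tissue surrounding the nerve changes — scored as mean |Δz| in % of
  nerve length.
- **Paired-channel polarization**: per-image dispersion of astrocyte and axon
  channels inside the convex hull of labeled tissue, astro-on-axon regression
  R², and region-wise one-way ANOVA with Tukey HSD (D'Agostino–Pearson
  normality reported).
- **Synthetic phantoms**: serial-section fiber phantoms and coupled
  two-channel images with exact ground truth (axial von Mises angles around a
  position-dependent mean θ(z), position-dependent longitudinal fraction,
  analytic painted areas), so every stage is validated end to end without
  tissue.

## Worked example

The numbered scripts under `analysis/` run the whole study on phantoms:

```sh
python analysis/01_simulate_phantoms.py   # 60 coronal sections + truth
python analysis/02_orientation_profile.py # ridges -> angles -> degree-7 fit
python analysis/03_fiber_classes.py       # Bernsen -> particles -> ratio
python analysis/04_polarization.py        # paired-channel dispersion
```

which prints, for the default seed:

```
recovered inflections: [0.236, 0.499, 0.762]
true inflections:      [0.25, 0.5, 0.75]
mean |inflection - transition| = 0.89% +/- 0.70% of nerve length

longitudinal/transverse ratio rises from 0.006 (proximal) to 0.343 (chiasm end)
Spearman rho vs ground truth: 0.973 over 60 sections

astro vs axon dispersion: R^2 = 0.8979 (SD pairing), R^2 = 0.8891 (mean-angle pairing), n = 40
region ANOVA: F = 269.2, p = 3.71e-20
  Tukey chiasm vs distal: adjusted p = 1.22e-15
```

Reading these: the degree-7 fit of the oscillating per-section mean angle
recovers all three inflection points of the generating orientation field to
about 1% of nerve length; the small-particle area fraction tracks the imposed
proximal-to-distal rise of longitudinal fibers; and when the two channels of
a field share an orientation distribution, their dispersion statistics
correlate strongly while a chiasm-like low-concentration group separates
cleanly from every nerve-proper group.

The same stages are scriptable through the CLI (`fiberorient synth|preprocess|
ridges|angles|particles|profile|match|polarization|pipeline`), with a single
TOML config driving a fully reproducible `pipeline` run whose manifest
content-hashes every artifact.

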