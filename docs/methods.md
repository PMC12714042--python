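# Methods

This note records the models, parameter choices, and numerical conventions
behind `dsfa_spri`, and what the synthetic tests do and do not demonstrate
about real instruments.

## Forward optical model

All spectra live on a uniform wavelength grid, by default 550–610 nm at
0.1 nm — fine enough to sub-resolve the 4–5 nm filter edges and the SPR dip.

**Filters.** Each band-pass filter is a smooth-edged rectangle: plateau
transmittance `peak` (default 0.85, consistent with the >80 % plateau of the
fabricated filters), raised-cosine edges parameterized so that the span
between the 50 % and 0.005 % transmission points equals `edge_width`
(default 4.5 nm — the steepness metric quoted for the real devices). The
transmittance is exactly `peak/2` at the nominal cut-on/cut-off. The true
lineshape of the fabricated filters is not published; the raised cosine
matches the published steepness metric while staying C¹-smooth. Defaults:
A = 583–598 nm, AB = 562–598 nm, with A nested inside AB (`T_A ≤ T_AB`
pointwise is enforced).

**SPR resonance.** The chip reflectance is a phenomenological Gaussian dip

```
R(λ; n) = baseline − depth · exp(−(λ − λ_dip(n))² / (2 w²)),
λ_dip(n) = λ₀ + S_λ · (n − n₀)
```

with defaults `w = 8 nm`, `depth = 0.5`, `baseline = 0.9`, `n₀ = 1.333`,
`S_λ = 244.7 nm/RIU` (the measured dispersion of the real chip). Rigorous
electromagnetics of the gold-coated grating is out of scope; the Gaussian is
the same surrogate the experimental analysis itself fits to the measured SPR
curve.

**Dip placement (a deliberate design choice).** For a *symmetric dip* in
reflectance integrated through *nested* filters, placing the dip at the
band-1/band-2 boundary (the A cut-on, 583 nm) makes γ **decrease** under a
red shift: the dip moves into band 1 and removes intensity from I_A. The
positive γ response that the method exhibits experimentally corresponds, in
this model, to operating on the long-wavelength shoulder where the dip exits
the common A/AB cut-off as n grows (centers ≳ 592.5 nm; I_A recovers faster
than I_AB). The default is therefore `λ₀ = 593.5 nm`: γ(n) is strictly
increasing over the whole calibration range 1.333–1.3495 (the dip center
stays ≤ 597.5 nm, inside the AB band), with a forward slope of
≈ +3.1 a.u./RIU — the same order as the measured 2.25 a.u./RIU. Real SPR
lineshapes are asymmetric (Fano-like) and sit on sloped baselines, which can
produce a positive response in other alignments; a symmetric Gaussian cannot,
and this package documents the operating point it actually uses rather than
an alignment statement it cannot reproduce.

**Band intensities and γ.** `I_A` and `I_AB` are trapezoidal integrals of
reflectance × filter × illumination over the grid (illumination defaults to
flat; a CSV spectrum can be supplied). γ = (2 I_A − I_AB)/I_AB. Sanity
anchors: equal band halves give γ = 0, all intensity in band 1 gives γ = 1,
and γ is invariant under any common intensity rescaling.

## Thin-film transfer-matrix module

Standard 2×2 characteristic matrices (phase δ = 2π n d cosθ/λ, tilted
admittances per polarization), with `T = 4 η₀ Re(η_s) / |η₀B + C|²`. Material
indices default to non-dispersive SiO₂ = 1.46 and Ta₂O₅ = 2.10; the published
design gives only total stack thicknesses, so the module ships a generic
quarter-wave/bandpass builder and makes no claim to reproduce the proprietary
A/AB layer sequences. The etch-stop property is checked as published: SiO₂
overlayers up to 220 nm on a 10-pair quarter-wave reflector move the
transmittance-weighted stopband centroid by well under 2 nm. The centroid
(not an argmax) is used as the feature position because it is robust to
stopband ripple.

## Synthetic DBSI generator

Each tile of an `n_tiles × n_tiles` checkerboard (tile class by the parity
rule `(i + j + parity) mod 2`) is filled with `gain × band intensity` for its
filter; `gain` is chosen so the two classes average ≈ 2000 counts — mid-scale
on the 12-bit camera model. The camera pixel pitch is folded into an integer
`tile_px = 4` px per 10 µm filter unit so demosaicing is exact; resampling of
real, non-integer-pitch sensors is out of scope.

**Grid artifacts.** Boundary pixels (width 1 px by default) take a fixed
mixture `(1−f)·own + f·other` of the two tile-class values, `f = 0.5`. This
reproduces the contrast-diluting boundary grid seen in real DBSI frames
without modeling diffraction.

**Noise.** Optional Poisson shot noise on the signal plus Gaussian read noise
(default σ = 10 counts), seeded; identical seeds reproduce frames bitwise.
These defaults were set to emulate the error magnitudes reported for the real
instrument: the simulated spectrometer channel (0.5 nm sampling, additive
reflectance noise σ = 0.001) yields raw-minimum wavelength scatter of
0.15–0.45 nm per state, matching the 0.15–0.46 nm reported; the imaging
channel yields full-frame γ scatter ≈ 1.3×10⁻³ at 64×64 px. The real camera
frame has ~5000× more pixels, so its γ noise (reported 6.8×10⁻⁵–1.2×10⁻⁴) is
correspondingly lower; γ noise scales ≈ 1/√(averaged pixels), verified
empirically in the suite. Consequently the *ordering* LOD_γ < LOD_shift is
reproduced at this scaled-down frame size (factor ~4 here rather than the
~two orders of magnitude available at full frame size).

**Protocols.** Step staircases (default: five states, 1.333 → 1.3495) and
pseudo-first-order Langmuir kinetics — association
`n₀ + Δn_max(1 − e^(−k_obs t))`, wash as exponential relaxation toward a
configurable residual — serve as binding-transient stand-ins; the source
experiments publish no kinetic model, so `k_obs` and `Δn_max` are user
parameters. Every rendered sequence carries a ground-truth table (t, n, I_A,
I_AB, γ) used as the oracle in parameter-recovery tests.

## Demosaicing

Tiles one pitch away (±`tile_px` along either axis) always carry the opposite
filter class. Each foreign pixel is filled with the mean of its in-bounds
shifted neighbors, combined pairwise (vertical pair, horizontal pair, then
the two means) so the fill is bit-exact when all neighbors agree — which
makes the noiseless round trip exact, and halves the fill noise otherwise. A
single fixed shift is available (`mode="shift"`) since the original
description does not state a combination rule. The output is cropped by one
tile on each side by default so every pixel has a full neighbor set. Parity
is auto-detected from phase means (the narrowband phase is darker), with a
configurable ambiguity floor.

## γ pipeline

Pixels with `I_AB` at or below 1 % of full scale are masked, not propagated.
Smoothing is a mask-aware normalized Gaussian (`scipy.ndimage`, symmetric
boundary): on a fully valid frame the operator is doubly stochastic, so the
spatial mean is preserved to machine precision; at σ = `tile_px`/2 the
tile-frequency FFT amplitude of the boundary-grid artifact drops well over
5-fold. ROI statistics default to the full valid frame; calibration uses the
tile-interior mask (1 px erosion per tile) so boundary-artifact pixels — whose
γ barely responds to n and which dilute the measured sensitivity roughly
threefold, the effect the real experiment also reports — stay out of the
sensitivity estimate.

## Calibration

Sensitivities are unweighted OLS slopes (no weights are published for the
original fits). Baseline noise is the sample standard deviation (n−1) per
state; the LOD noise figure takes the maximum across states by default
(configurable to mean/pooled), and `LOD = noise / |S|`. The published
phrasing inverts this ratio, but the published numeric values
(0.46/244.7 = 1.88×10⁻³; 1.23×10⁻⁴/2.25 ≈ 5.5×10⁻⁵) fix the convention
implemented here.

**Dip-wavelength readout.** The per-spectrum stability series uses the raw
in-band minimum — the conventional spectrometer readout, whose scatter on a
0.5 nm grid is dominated by sampling quantization. For the *sensitivity fit*
the per-state wavelength is instead estimated by a Gaussian fit to the
state-averaged spectrum: on a coarse grid the raw minimum carries ~0.15 nm of
quantization scatter per state, which would leave a five-point slope estimate
statistically unstable, while the Gaussian fit (the same functional form the
theoretical-sensitivity procedure uses) localizes the center to ~0.01 nm.
Both localizers are available (`localizer="gauss"|"min"`).

**Theoretical sensitivity.** The Gaussian-redshift procedure shifts the
fitted dip by `S_λ(n − n₀)`, integrates through the filter curves, and fits
γ(n) by OLS. Over a small n-interval this equals the chain rule
`dγ/dλ × S_λ` evaluated at the interval midpoint (the OLS secant matches the
midpoint derivative to second order). The published theoretical value
(6.89 a.u./RIU) used the *measured* filter spectra, which are not published;
with this package's nominal filters and default dip the procedure yields
≈ 3.1 a.u./RIU, and no attempt is made to match the unpublishable number.

**Concentration LOD.** Dose–response end points are extrapolated to the
concentration whose response equals k·noise (k = 3 by default, the usual 3σ
convention; the original estimation method is unstated), fitting either
`Δγ = a·log₁₀C + b` or a through-origin linear response. Results below the
lowest measured concentration are flagged as extrapolated.

## Problem sizes and determinism

The default acceptance scenario uses a 16×16-tile, 4 px/tile checkerboard
(64×64 px), 5 refractive-index states × 30 frames, and 10 spectrometer
spectra per state — sizes chosen so the full staircase simulation,
demosaicing, and both calibrations complete in about a second while keeping
every estimator comfortably inside its statistical tolerance. All stochastic
components draw from `numpy.random.default_rng` generators seeded from a
single run seed; identical config + seed reproduce every CSV/JSON product
byte-for-byte (frame stacks are quantized to uint16 only on write; in-memory
analysis keeps float64 precision).

## Known limitations

* The Gaussian dip is symmetric; Fano asymmetry, sloped baselines, and
  dispersion of the real chip are not modeled, and the sign analysis above is
  specific to the symmetric-dip surrogate.
* No optical PSF, defocus, or flow-cell physics; tiles are ideal squares with
  a 1 px mixing band as the only spatial nonideality.
* Non-integer tile pitch (real 2.4 µm pixels under 10 µm tiles) is rejected
  rather than resampled.
* The transfer-matrix module is qualitative for the fabricated filters: layer
  sequences are unpublished, so only generic quarter-wave behavior and the
  etch-stop insensitivity are asserted.
* Passing tests on synthetic data demonstrates the correctness of the
  algorithms and their statistical behavior under the modeled noise, not the
  performance of any physical instrument.
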