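# dsfa-spri

Simulation and analysis tools for **snapshot dual-band surface-plasmon-resonance
imaging (SPRi)** with a checkerboard spectral filter array.

## The problem

A label-free SPR biosensor reports binding events as a red shift of a resonance
dip in the reflectance spectrum of a metal-coated chip. Conventional readout
tracks the dip wavelength with a spectrometer — precise, but not imaging, and
limited by the wavelength resolution of the instrument. An alternative puts a
**dual-band spectral filter array (DSFA)** into the illumination path: a
checkerboard of 10×10 µm filter units alternating between a narrow band-pass
filter A (583–598 nm) and a wide filter AB (562–598 nm) that contains it. A
monochrome camera then records a checkerboard **dual-band spectral image
(DBSI)** in a single snapshot: dark tiles saw the chip through A, bright tiles
through AB.

Per pixel, after separating the two bands, the **spectral contrast response**

```
γ = (I_A − I_B) / (I_A + I_B) = (2·I_A − I_AB) / I_AB ,   I_B = I_AB − I_A
```

is a dimensionless, intensity-scale-invariant statistic whose value tracks
where the resonance dip sits relative to the two bands. As the refractive
index n at the chip surface rises, the dip red-shifts at a rate S_λ (nm/RIU)
and γ changes at a rate S_γ (a.u./RIU). Because γ averages over many camera
pixels instead of locating a minimum on a coarse wavelength grid, its baseline
noise is far lower, and the **limit of detection**

```
LOD = baseline noise / |sensitivity|        (in refractive-index units, RIU)
```

improves by orders of magnitude over spectral-shift readout on the same scene.

This package implements the complete computational chain as a tested library
plus CLI:

| module | contents |
|---|---|
| `dsfa_spri.spectral` | wavelength grid, filter passbands, Gaussian SPR dip model, band integrals, γ, dip localization, Gaussian dip fitting |
| `dsfa_spri.tmm` | transfer-matrix optics for the SiO₂/Ta₂O₅ multilayer filters (quarter-wave stacks, transmittance, etch-stop overlayer scans) |
| `dsfa_spri.simulate` | synthetic DBSI frame/sequence generator: mosaics, refractive-index protocols (staircase, Langmuir binding), camera noise, grid-boundary artifacts, ground-truth sidecars |
| `dsfa_spri.demosaic` | checkerboard parity detection and pixel-shift demosaicing into co-registered A/AB band images |
| `dsfa_spri.pipeline` | per-pixel γ maps with dark-pixel masking, mask-aware Gaussian smoothing (grid-artifact suppression), ROI sensorgrams, stabilized-state difference images |
| `dsfa_spri.calibration` | sensitivity fits, baseline noise, LOD, the Gaussian-redshift theoretical-sensitivity procedure, concentration-LOD extrapolation |
| `dsfa_spri.config` / `dsfa_spri.cli` | YAML run configs, reproducible simulate/analyze entry points, `dsfa-spri` CLI |

## Worked example

Run the built-in staircase scenario — five sugar-solution refractive-index
states from 1.333 to 1.3495, a 16×16-tile checkerboard at 4 px per tile,
Poisson + read noise — and calibrate both readout modes:

```bash
dsfa-spri demo --seed 1 --out demo/
```

```json
{
  "forward_model_gamma_slope_au_per_riu": 3.0745010232218886,
  "gamma": {
    "baseline_noise": 0.0013184129341798003,
    "lod_riu": 0.0004236695689448802,
    "sensitivity": 3.111889620638123,
    "sensitivity_units": "a.u./RIU"
  },
  "spectral_shift": {
    "baseline_noise": 0.43779751788545657,
    "lod_riu": 0.0017894414400325216,
    "sensitivity": 244.65596252062878,
    "sensitivity_units": "nm/RIU"
  }
}
```

(abridged; the command prints the full calibration records). Reading the
numbers: the spectrometer channel recovers the generating dip sensitivity of
244.7 nm/RIU almost exactly, with ~0.44 nm of raw-minimum wavelength scatter,
giving LOD ≈ 1.8×10⁻³ RIU. The imaging channel recovers the forward model's γ
slope (3.07 a.u./RIU) within ~1 % and — because γ is averaged over the whole
tile-interior region of the frame — reaches LOD ≈ 4×10⁻⁴ RIU, several times
better on this deliberately small synthetic frame (the gap grows with pixel
count). `demo/` additionally contains the rendered 16-bit TIFF stack, the
ground-truth CSV, the mean γ map, and a hashed manifest for reproducibility.

The same steps are available individually (`simulate`, `demosaic`, `gamma`,
`calibrate`, `tmm`); see `dsfa-spri COMMAND --help`.

## Library snippet

```python
from dsfa_spri import SceneOptics, build_mosaic, render_frame, demosaic_frame, gamma_map

optics = SceneOptics()                      # default dip + A/AB filters
frame = render_frame(build_mosaic(16, 16, 4), 1.341, optics)
bands = demosaic_frame(frame)               # pixel-shift band separation
gamma = gamma_map(bands)                    # per-pixel spectral contrast
print(gamma.mean(), optics.gamma(1.341))    # recovered vs forward-model γ
```

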