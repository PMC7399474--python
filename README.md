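# sfdikit

A toolkit for spatial frequency domain imaging (SFDI) of turbid media:
from spatially modulated 8-bit camera frames to per-pixel maps of the
absorption coefficient (μa) and reduced scattering coefficient (μs′) in
five RGB-derived spectral bands — three primary bands plus two
cross-channel bands obtained from the spectral overlap between one LED
colour and a different camera colour filter.

A synthetic instrument (gamma-distorting projector, band responsivities,
noisy quantising camera) replaces the physical hardware, so the entire
pipeline is testable end to end at desk scale, including a 16-phantom
validation study with linear-regression agreement statistics.

## What's inside

| Module | Purpose |
| --- | --- |
| `sfdikit.forward_model` | White Monte Carlo photon transport (semi-infinite medium, Fresnel boundary, Henyey–Greenstein scattering), Beer–Lambert absorption rescaling, zeroth-order Hankel transform to Rd(fx), diffusion-approximation oracle, tabulation and bilinear log-space lookup |
| `sfdikit.spectral_bands` | LED×filter band construction (nine combinations), weighted-average centre and FWHM, cross-channel selection, two-line wavelength calibration, band-averaged emulation of continuous spectra |
| `sfdikit.sfdi_core` | Sinusoidal pattern generation with gamma pre-compensation, three-phase demodulation to the AC amplitude, reference-phantom calibration to diffuse reflectance |
| `sfdikit.inversion` | Per-pixel Nelder–Mead recovery of (μa, μs′) from Rd(fx) with the tabulated forward model |
| `sfdikit.synthetic_instrument` | Full optical-chain simulator, the 4×4 scattering/absorption phantom grid, an idealised spectrally continuous counterpart for band-emulation comparisons |
| `sfdikit.validation` | End-to-end 16-phantom study: imaging estimates vs band-emulated spectroscopy ground truth, R²/RMSE regression statistics, comparison plots |
| `sfdikit.io_utils`, `sfdikit.config`, `sfdikit.cli` | 8-bit BMP/PNG frames, CSV spectra and manifests, float TIFF maps, strict YAML config, command-line interface |
| `sfdikit.demo` | Analytic stand-ins for the measured projector/camera spectral curves |

## CLI

```bash
# build a Monte Carlo reflectance table
sfdikit mc-table --seed 1 --out table.npz

# characterise the nine LED x filter bands from CSV spectra
sfdikit characterize-bands \
    --led B led_b.csv --led G led_g.csv --led R led_r.csv \
    --filter B fil_b.csv --filter G fil_g.csv --filter R fil_r.csv \
    --out-table bands.csv

# synthesise acquisition frames (BMP + manifest CSV)
sfdikit simulate --table table.npz --phantom-grid --seed 1 --out-dir frames/

# demodulate, calibrate and invert a manifest
sfdikit process --manifest frames/manifest.csv --table table.npz --out-dir out/

# full 16-phantom validation study with plot
sfdikit validate --seed 1 --out-dir study/
```

Exit codes distinguish configuration (2), I/O (3) and numerical (4)
failures. Units everywhere: spatial frequencies in mm⁻¹ at the sample
plane, lengths in mm, wavelengths in nm.

## Method summary

Sinusoidal patterns at spatial frequencies fx ∈ {0, 0.0333, 0.05, 0.1} mm⁻¹
are projected at three spatial phases (0°, 120°, 240°). The per-pixel AC
amplitude is

    MAC = (√2/3) · √[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²],

and the ratio against a reference phantom of known reflectance cancels the
source intensity and instrument transfer function:

    Rd,tissue = (MAC / MAC,ref) · Rd,ref.

A white Monte Carlo simulation (run once at μs′ = 1 mm⁻¹ and rescaled by
similarity, or independently per μs′ on request) provides Rd(μa, μs′, fx)
via pathlength rescaling and a Hankel transform; a Nelder–Mead simplex
search then recovers (μa, μs′) per pixel and per band.
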