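"""Synthetic optical chain: projector, sample, camera.

Replaces the physical instrument so the whole pipeline is testable at desk
scale: sinusoidal patterns pass through a gamma-distorting projector, the
sample modulates the DC and AC components by its diffuse reflectance at
fx = 0 and fx respectively (evaluated at each band's centre wavelength via
the forward table), and a noisy 8-bit camera records the frames.

Also builds the 4 x 4 scattering/absorption phantom grid used for
validation, and an idealised spectrally continuous counterpart of the same
samples for band-emulation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward_model import OpticalProperties, ReflectanceTable, lookup_rd
from .inversion import InversionConfig, fit_pixel
from .sfdi_core import (
    PHASES_DEG,
    GammaCurve,
    PatternSpec,
    estimate_gamma,
    make_pattern,
    pregamma,
)
from .spectral_bands import SpectrumCurve, band_stats

__all__ = [
    "PhantomSpec",
    "InstrumentModel",
    "AcquisitionSet",
    "make_phantom_grid",
    "phantom_properties",
    "simulate_acquisition",
    "simulate_sfds_spectrum",
    "power_law_gamma_curve",
    "DEFAULT_FX_LIST",
    "SFDS_FX_LIST",
]

#: Acquisition spatial frequencies, 1/mm.
DEFAULT_FX_LIST = (0.0, 0.0333, 0.05, 0.1)
#: Spectroscopic-system spatial frequencies, 1/mm.
SFDS_FX_LIST = (0.0, 0.05, 0.1, 0.15, 0.2)

_LAMBDA_MIN, _LAMBDA_MAX = 380.0, 720.0
_ANCHOR_NM = 625.0


@dataclass(frozen=True)
class PhantomSpec:
    """Homogeneous liquid phantom: power-law scattering, scaled absorber.

    mu_s'(lambda) = a * lambda**-b, anchored so that
    mu_s'(625 nm) = ``mus_prime_at_anchor``; mu_a(lambda) follows the
    absorber template (flat by default, i.e. a neutral ink) anchored so
    that mu_a(625 nm) = ``mua_at_anchor``.
    """

    name: str
    mus_prime_at_anchor: float   # 1/mm at 625 nm
    mua_at_anchor: float         # 1/mm at 625 nm
    scatter_exponent: float = 1.2
    absorber_template: SpectrumCurve | None = None  # None = flat
    scattering_level: int = 0    # grid labels (0-based)
    absorption_level: int = 0
    # reserved: split depth (mm) for a two-layer variant; accepted but not
    # simulated — layered samples are outside the validation path
    layer_split_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mus_prime_at_anchor <= 0:
            raise ValueError("mus_prime_at_anchor must be > 0")
        if self.mua_at_anchor < 0:
            raise ValueError("mua_at_anchor must be >= 0")
        if self.absorber_template is not None:
            if self.absorber_template(_ANCHOR_NM) <= 0:
                raise ValueError("absorber template must be > 0 at 625 nm")

    def mu_s_prime(self, lam) -> np.ndarray | float:
        lam = np.asarray(lam, dtype=np.float64)
        out = self.mus_prime_at_anchor * (lam / _ANCHOR_NM) ** (-self.scatter_exponent)
        return float(out) if out.ndim == 0 else out

    def mu_a(self, lam) -> np.ndarray | float:
        lam = np.asarray(lam, dtype=np.float64)
        if self.absorber_template is None:
            out = np.full_like(lam, self.mua_at_anchor, dtype=np.float64)
        else:
            out = self.mua_at_anchor * (
                self.absorber_template(lam) / self.absorber_template(_ANCHOR_NM)
            )
        return float(out) if out.ndim == 0 else out


#: Nominal scattering-agent concentrations (%) and absorber loads (mg/L).
INTRALIPID_CONCENTRATIONS = (0.5, 1.0, 1.5, 2.0)
INK_CONCENTRATIONS = (13.0, 27.0, 40.0, 53.0)
#: Measured anchor ranges spanned by those concentrations, 1/mm at 625 nm.
MUS_PRIME_RANGE = (0.5, 2.5)
MUA_RANGE = (0.025, 0.25)


def make_phantom_grid(
    scatter_exponent: float = 1.2,
    absorber_template: SpectrumCurve | None = None,
) -> list[PhantomSpec]:
    """The 16-phantom validation grid: 4 scattering x 4 absorption levels.

    Anchor values at 625 nm interpolate linearly in nominal concentration
    between the measured range endpoints: mu_s' spans 0.5-2.5 /mm over
    0.5-2 % scatterer, mu_a spans 0.025-0.25 /mm over 13-53 mg/L absorber.
    """
    il = np.asarray(INTRALIPID_CONCENTRATIONS)
    ink = np.asarray(INK_CONCENTRATIONS)
    mus = MUS_PRIME_RANGE[0] + (il - il[0]) / (il[-1] - il[0]) * (
        MUS_PRIME_RANGE[1] - MUS_PRIME_RANGE[0]
    )
    mua = MUA_RANGE[0] + (ink - ink[0]) / (ink[-1] - ink[0]) * (
        MUA_RANGE[1] - MUA_RANGE[0]
    )
    grid = []
    for i, ms in enumerate(mus):
        for j, ma in enumerate(mua):
            grid.append(
                PhantomSpec(
                    name=f"P_s{i}_a{j}",
                    mus_prime_at_anchor=float(ms),
                    mua_at_anchor=float(ma),
                    scatter_exponent=scatter_exponent,
                    absorber_template=absorber_template,
                    scattering_level=i,
                    absorption_level=j,
                )
            )
    return grid


def phantom_properties(
    spec: PhantomSpec, lambda0: float, g: float = 0.8, n: float = 1.4
) -> OpticalProperties:
    """Optical properties of a phantom at one wavelength (nm)."""
    if not _LAMBDA_MIN <= lambda0 <= _LAMBDA_MAX:
        raise ValueError(
            f"lambda0={lambda0} nm outside supported range "
            f"[{_LAMBDA_MIN}, {_LAMBDA_MAX}] nm"
        )
    return OpticalProperties(
        mu_a=float(spec.mu_a(lambda0)),
        mu_s_prime=float(spec.mu_s_prime(lambda0)),
        g=g,
        n=n,
    )


def power_law_gamma_curve(gamma: float, n_levels: int = 256) -> GammaCurve:
    """Idealised projector response: output = (level/255)**gamma."""
    levels = np.arange(n_levels) * (255.0 / (n_levels - 1))
    return estimate_gamma(levels, (levels / 255.0) ** gamma)


@dataclass(frozen=True)
class InstrumentModel:
    """Synthetic projector + camera configuration."""

    bands: tuple                    # selected BandResponsivity objects
    projector_gamma: float = 2.2
    camera_noise_sigma: float = 1.0  # additive Gaussian, 8-bit counts
    noise_fraction: float = 0.0      # multiplicative (shot-like) noise
    pixel_pitch: float = 0.5         # mm per projected pixel
    frame_shape: tuple = (64, 64)    # (height, width)
    exposure: float | None = None    # counts at unit reflectance; None = auto
    target_peak: float = 245.0       # auto-exposure headroom, counts
    bit_depth: int = 8
    quantize: bool = True
    dc_level: float = 0.5
    ac_level: float = 0.5
    apply_pregamma: bool = True
    #: "delta" evaluates the sample at each band's centre wavelength;
    #: "full" weights Rd(lambda) by the band responsivity (for studying
    #: band-averaging bias)
    band_integration: str = "delta"

    def __post_init__(self) -> None:
        if self.band_integration not in ("delta", "full"):
            raise ValueError('band_integration must be "delta" or "full"')
        if self.projector_gamma <= 0:
            raise ValueError("projector gamma must be > 0")
        if self.camera_noise_sigma < 0 or self.noise_fraction < 0:
            raise ValueError("noise levels must be >= 0")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit cameras are modelled")
        if not self.bands:
            raise ValueError("at least one band is required")

    @property
    def band_centres(self) -> dict[str, float]:
        return {b.name: band_stats(b).lambda0 for b in self.bands}


@dataclass
class AcquisitionSet:
    """Complete factorial acquisition: bands x fx x phases for one sample."""

    sample: str
    manifest: list = field(default_factory=list)  # dicts: band, fx_index, ...
    frames: dict = field(default_factory=dict)    # (band, fx_i, phase_i) -> array
    exposures: dict = field(default_factory=dict)  # band -> counts/reflectance
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.manifest)

    def projected_images_per_fx(self) -> int:
        """Patterns physically projected per spatial frequency:
        one per LED colour per phase."""
        colours = {row["band"][0] for row in self.manifest}
        phases = {row["phase_index"] for row in self.manifest}
        return len(colours) * len(phases)

    def triplet_arrays(self, band: str, fx_index: int):
        return tuple(self.frames[(band, fx_index, p)] for p in range(3))


def _projected_pattern(
    spec: PatternSpec, gamma_curve: GammaCurve, apply_pre: bool
) -> tuple[np.ndarray, float]:
    """Pattern after the projector, plus its DC component.

    With pre-compensation the projector output is linear in the request
    (up to 8-bit quantisation).  Without it the sinusoid is distorted by
    the gamma curve; the DC term is then computed analytically over one
    spatial period of the distorted waveform.
    """
    ideal = make_pattern(spec)
    if apply_pre:
        levels = pregamma(ideal, gamma_curve)
        projected = gamma_curve.forward(levels.astype(np.float64))
        dc = spec.dc_level
    else:
        levels = np.clip(np.rint(ideal * 255.0), 0, 255)
        projected = gamma_curve.forward(levels)
        phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        wave = spec.dc_level + spec.ac_level * np.cos(phi)
        dc = float(gamma_curve.forward(np.clip(np.rint(wave * 255), 0, 255)).mean())
    return projected, dc


def _band_rd(
    sample: PhantomSpec,
    band,
    table: ReflectanceTable,
    fx_values,
    mode: str,
) -> dict:
    """Per-band Rd at the requested spatial frequencies.

    "delta": evaluate at the band centre wavelength.  "full": weight
    Rd(lambda, fx) by the band responsivity over its effective support
    (2-nm subsampling), exposing the band-averaging bias of broad bands.
    """
    fx_values = tuple(dict.fromkeys(float(f) for f in fx_values))
    if mode == "delta":
        props = phantom_properties(sample, band_stats(band).lambda0)
        vals = lookup_rd(table, props, list(fx_values))
        return dict(zip(fx_values, (float(v) for v in vals)))
    wl = band.curve.wavelengths
    resp = band.curve.values
    sel = resp >= 1e-3 * resp.max()
    wl_s, w_s = wl[sel][::2], resp[sel][::2]
    acc = np.zeros(len(fx_values))
    for lam, w in zip(wl_s, w_s):
        props = phantom_properties(sample, float(lam))
        acc += w * lookup_rd(table, props, list(fx_values))
    acc /= w_s.sum()
    return dict(zip(fx_values, (float(v) for v in acc)))


def simulate_acquisition(
    sample: PhantomSpec,
    instrument: InstrumentModel,
    table: ReflectanceTable,
    fx_list=DEFAULT_FX_LIST,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> AcquisitionSet:
    """Simulate the full acquisition of one sample.

    For each (band, fx, phase): generate the pattern, pass it through the
    projector (gamma pre-compensated by default), scale the DC component
    by Rd(0) and the AC component by Rd(fx) at the band's centre
    wavelength, add camera noise, quantise to 8 bits, and optionally write
    the frame to disk as grayscale BMP.  Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    h, w = instrument.frame_shape
    gamma_curve = power_law_gamma_curve(instrument.projector_gamma)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    acq = AcquisitionSet(
        sample=sample.name,
        seed=seed,
        config={
            "fx_list": list(fx_list),
            "phases_deg": list(PHASES_DEG),
            "bands": [b.name for b in instrument.bands],
            "pixel_pitch": instrument.pixel_pitch,
            "projector_gamma": instrument.projector_gamma,
            "camera_noise_sigma": instrument.camera_noise_sigma,
            "noise_fraction": instrument.noise_fraction,
            "quantize": instrument.quantize,
        },
    )

    for band in instrument.bands:
        lam0 = band_stats(band).lambda0
        try:
            rd_all = _band_rd(
                sample, band, table, (0.0, *fx_list), instrument.band_integration
            )
        except ValueError as exc:
            props = phantom_properties(sample, lam0)
            raise ValueError(
                f"forward table cannot cover band {band.name!r} "
                f"(lambda0={lam0:.1f} nm, mu_a={props.mu_a:.4g}, "
                f"mu_s'={props.mu_s_prime:.4g}): {exc}"
            ) from exc
        rd0 = rd_all[0.0]
        rd_fx = {fx: rd_all[fx] for fx in fx_list}
        if instrument.exposure is None:
            # fill the camera's dynamic range, as a manual exposure
            # adjustment on the physical instrument would
            exposure = instrument.target_peak / (
                rd0 * (instrument.dc_level + instrument.ac_level)
            )
        else:
            exposure = instrument.exposure
        acq.exposures[band.name] = exposure
        for fx_i, fx in enumerate(fx_list):
            for phase_i, phase in enumerate(PHASES_DEG):
                spec = PatternSpec(
                    fx=fx,
                    phase=phase,
                    width=w,
                    height=h,
                    pixel_pitch=instrument.pixel_pitch,
                    dc_level=instrument.dc_level,
                    ac_level=instrument.ac_level,
                )
                projected, dc = _projected_pattern(
                    spec, gamma_curve, instrument.apply_pregamma
                )
                image = exposure * (
                    dc * rd0 + (projected - dc) * rd_fx[fx]
                )
                if instrument.noise_fraction > 0:
                    image = image * (
                        1.0 + instrument.noise_fraction * rng.standard_normal(image.shape)
                    )
                if instrument.camera_noise_sigma > 0:
                    image = image + instrument.camera_noise_sigma * rng.standard_normal(
                        image.shape
                    )
                if instrument.quantize:
                    frame = np.clip(np.rint(image), 0, 255).astype(np.uint8)
                else:
                    frame = np.clip(image, 0.0, 255.0)
                acq.frames[(band.name, fx_i, phase_i)] = frame
                path = ""
                if out_dir is not None:
                    from .io_utils import write_frame

                    fname = f"{sample.name}_{band.name}_{fx_i}_{phase_i}.bmp"
                    path = str(out_dir / fname)
                    write_frame(path, np.clip(np.rint(frame), 0, 255).astype(np.uint8))
                acq.manifest.append(
                    {
                        "sample": sample.name,
                        "band": band.name,
                        "fx_index": fx_i,
                        "phase_index": phase_i,
                        "path": path,
                        "exposure": exposure,
                    }
                )
    return acq


def simulate_sfds_spectrum(
    sample: PhantomSpec,
    table: ReflectanceTable,
    fx_list=SFDS_FX_LIST,
    wavelengths=None,
    refit: bool = False,
    inversion_config: InversionConfig | None = None,
    g: float = 0.8,
    n: float = 1.4,
):
    """Idealised spectrally continuous counterpart of one sample.

    Returns a dict with the 1-nm wavelength grid (400-700 nm by default),
    the noise-free Rd(fx, lambda) surface from the forward table, and the
    (mu_a, mu_s') spectra.  With ``refit=False`` (the noise-free default)
    the property spectra are the generating curves themselves; with
    ``refit=True`` they are re-estimated from the Rd surface per
    wavelength with the standard inverse solver.
    """
    if wavelengths is None:
        wavelengths = np.arange(400.0, 701.0, 1.0)
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    rd = np.empty((len(fx_list), len(wavelengths)))
    for j, lam in enumerate(wavelengths):
        props = phantom_properties(sample, float(lam), g=g, n=n)
        rd[:, j] = lookup_rd(table, props, list(fx_list))

    mu_a = np.asarray(sample.mu_a(wavelengths), dtype=np.float64)
    mu_s_prime = np.asarray(sample.mu_s_prime(wavelengths), dtype=np.float64)
    if refit:
        cfg = inversion_config or InversionConfig(g=g, n=n)
        mu_a = np.empty(len(wavelengths))
        mu_s_prime = np.empty(len(wavelengths))
        for j in range(len(wavelengths)):
            props, _, _ = fit_pixel(rd[:, j], list(fx_list), table, cfg)
            mu_a[j] = props.mu_a
            mu_s_prime[j] = props.mu_s_prime
    return {
        "wavelengths": wavelengths,
        "fx_list": np.asarray(fx_list, dtype=np.float64),
        "rd": rd,
        "mu_a": mu_a,
        "mu_s_prime": mu_s_prime,
    }
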