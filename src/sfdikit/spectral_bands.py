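"""Spectral band construction for an RGB projector/camera pair.

Multiplying each LED emission spectrum by each camera colour-filter
transmission yields nine band responsivities: three primary bands (the
diagonal, e.g. "GG") and six cross-channel bands from spectral overlap
between a LED and a different colour filter (e.g. "GR": green LED seen
through the red filter).  Band centres and widths are computed as
intensity-weighted statistics rather than Gaussian fits, since the
cross-channel shapes can be strongly asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "COMMON_GRID",
    "SpectrumCurve",
    "BandResponsivity",
    "BandStats",
    "WavelengthCalibration",
    "BAND_NAMES",
    "PRIMARY_BANDS",
    "cross_channel_product",
    "build_all_bands",
    "band_stats",
    "select_bands",
    "wavelength_calibrate",
    "emulate_band_values",
]

#: Default common wavelength grid, nm.
COMMON_GRID = np.arange(380.0, 721.0, 1.0)

BAND_NAMES = ("BB", "BG", "BR", "GB", "GG", "GR", "RB", "RG", "RR")
PRIMARY_BANDS = ("BB", "GG", "RR")


@dataclass(frozen=True)
class SpectrumCurve:
    """Sampled spectrum: relative intensity or transmission vs wavelength."""

    wavelengths: np.ndarray  # nm, strictly ascending
    values: np.ndarray       # >= 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if wl.ndim != 1 or len(wl) < 2:
            raise ValueError("need at least 2 wavelength samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if v.shape != wl.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(v < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def resample(self, grid: Sequence[float]) -> "SpectrumCurve":
        """Linear resampling onto ``grid``; zero outside the support."""
        grid = np.asarray(grid, dtype=np.float64)
        vals = np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)
        return SpectrumCurve(grid, vals)

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.wavelengths))

    def __call__(self, lam) -> np.ndarray:
        return np.interp(lam, self.wavelengths, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class BandResponsivity:
    """LED x filter spectral sensitivity for one named band."""

    name: str
    curve: SpectrumCurve
    relative_strength: float | None = None  # band integral / strongest band

    def __post_init__(self) -> None:
        if self.name not in BAND_NAMES:
            raise ValueError(f"band name must be one of {BAND_NAMES}, got {self.name!r}")
        if self.relative_strength is not None and not 0 <= self.relative_strength <= 1:
            raise ValueError("relative_strength must be in [0, 1]")

    @property
    def is_primary(self) -> bool:
        return self.name in PRIMARY_BANDS


@dataclass(frozen=True)
class BandStats:
    lambda0: float  # nm, intensity-weighted centre
    fwhm: float     # nm, outermost half-maximum crossings

    def format(self) -> str:
        """Render as centre +/- half-width, the usual reporting convention."""
        return f"{self.lambda0:.0f}±{0.5 * self.fwhm:.0f} nm"


@dataclass(frozen=True)
class WavelengthCalibration:
    """Two-point linear pixel -> wavelength map."""

    slope: float      # nm per pixel
    intercept: float  # nm
    reference_lines: tuple  # ((pixel, nm), (pixel, nm))

    def __call__(self, pixels) -> np.ndarray:
        return self.slope * np.asarray(pixels, dtype=np.float64) + self.intercept


def cross_channel_product(
    led: SpectrumCurve, filt: SpectrumCurve, name: str
) -> BandResponsivity:
    """Pointwise product of an LED spectrum and a filter transmission.

    Both curves must already share one wavelength grid; ``relative_strength``
    is left unset here and is filled in by :func:`build_all_bands` once all
    nine products exist.
    """
    if not np.array_equal(led.wavelengths, filt.wavelengths):
        raise ValueError(
            "LED and filter curves are sampled on different wavelength grids; "
            "resample both onto a common grid first (SpectrumCurve.resample)"
        )
    prod = SpectrumCurve(led.wavelengths, led.values * filt.values)
    return BandResponsivity(name, prod)


def build_all_bands(
    leds: dict[str, SpectrumCurve],
    filters: dict[str, SpectrumCurve],
    grid: Sequence[float] | None = None,
) -> list[BandResponsivity]:
    """All nine LED x filter combinations with relative strengths.

    ``leds`` and ``filters`` map single letters "B"/"G"/"R" to curves.
    Each set is normalised to its own global maximum (preserving the
    relative intensity ratios within the set); band strengths are the
    band integrals normalised to the strongest band.
    """
    if grid is None:
        grid = COMMON_GRID
    if set(leds) != {"B", "G", "R"} or set(filters) != {"B", "G", "R"}:
        raise ValueError('leds and filters must have keys {"B", "G", "R"}')

    led_rs = {k: c.resample(grid) for k, c in leds.items()}
    fil_rs = {k: c.resample(grid) for k, c in filters.items()}
    led_max = max(c.values.max() for c in led_rs.values())
    fil_max = max(c.values.max() for c in fil_rs.values())
    if led_max == 0 or fil_max == 0:
        raise ValueError("all-zero LED or filter set")
    led_rs = {k: SpectrumCurve(c.wavelengths, c.values / led_max) for k, c in led_rs.items()}
    fil_rs = {k: SpectrumCurve(c.wavelengths, c.values / fil_max) for k, c in fil_rs.items()}

    raw = [
        cross_channel_product(led_rs[l], fil_rs[f], l + f)
        for l in "BGR"
        for f in "BGR"
    ]
    integrals = np.array([b.curve.integral() for b in raw])
    strongest = integrals.max()
    if strongest == 0:
        raise ValueError("all nine bands are zero; no spectral overlap at all")
    return [
        BandResponsivity(b.name, b.curve, float(i / strongest))
        for b, i in zip(raw, integrals)
    ]


def band_stats(band: BandResponsivity) -> BandStats:
    """Weighted-average centre and outermost half-maximum width.

    lambda0 is the intensity-weighted mean wavelength.  FWHM is the
    distance between the first and last crossings of half the peak value,
    linearly interpolated between grid samples (robust for multi-lobed
    band shapes).
    """
    wl = band.curve.wavelengths
    v = band.curve.values
    total = v.sum()
    if total == 0:
        raise ValueError(f"unusable band {band.name!r}: responsivity is all zero")
    lambda0 = float((wl * v).sum() / total)

    half = v.max() / 2.0
    above = v >= half
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    # interpolate the outermost crossings
    if i0 == 0:
        left = wl[0]
    else:
        left = wl[i0 - 1] + (half - v[i0 - 1]) / (v[i0] - v[i0 - 1]) * (
            wl[i0] - wl[i0 - 1]
        )
    if i1 == len(v) - 1:
        right = wl[-1]
    else:
        right = wl[i1] + (v[i1] - half) / (v[i1] - v[i1 + 1]) * (wl[i1 + 1] - wl[i1])
    return BandStats(lambda0=lambda0, fwhm=float(right - left))


def _default_exclusion(band: BandResponsivity, stats: BandStats) -> bool:
    """Reject cross-channels centred below 500 nm (strong blue absorption
    in tissue degrades their effective SNR)."""
    return stats.lambda0 < 500.0


def select_bands(
    bands: Iterable[BandResponsivity],
    strength_threshold: float = 0.05,
    exclusion_rules: Sequence[Callable[[BandResponsivity, BandStats], bool]] | None = (
        _default_exclusion,
    ),
) -> list[str]:
    """Usable band names, ordered by centre wavelength.

    Primary bands (BB, GG, RR) are always retained.  A cross-channel is
    retained when its relative strength reaches ``strength_threshold`` and
    no exclusion rule fires.  Rules receive (band, stats) and return True
    to exclude.
    """
    rules = tuple(exclusion_rules) if exclusion_rules else ()
    chosen: list[tuple[float, str]] = []
    for band in bands:
        if band.curve.values.sum() == 0:
            if band.is_primary:
                raise ValueError(f"primary band {band.name!r} is all zero")
            continue
        stats = band_stats(band)
        if band.is_primary:
            chosen.append((stats.lambda0, band.name))
            continue
        strength = band.relative_strength
        if strength is None:
            raise ValueError(f"band {band.name!r} has no relative_strength set")
        if strength < strength_threshold:
            continue
        if any(rule(band, stats) for rule in rules):
            continue
        chosen.append((stats.lambda0, band.name))
    chosen.sort()
    return [name for _, name in chosen]


def wavelength_calibrate(
    line_pixels: Sequence[float], line_nm: Sequence[float]
) -> WavelengthCalibration:
    """Two-point linear wavelength calibration from two reference lines."""
    (p1, p2) = (float(line_pixels[0]), float(line_pixels[1]))
    (l1, l2) = (float(line_nm[0]), float(line_nm[1]))
    if p1 == p2:
        raise ValueError("reference lines must be at distinct pixels")
    if l1 == l2:
        raise ValueError("reference lines must have distinct wavelengths")
    slope = (l2 - l1) / (p2 - p1)
    intercept = l1 - slope * p1
    return WavelengthCalibration(slope, intercept, ((p1, l1), (p2, l2)))


def emulate_band_values(
    spectrum: SpectrumCurve, bands: Sequence[BandResponsivity]
) -> np.ndarray:
    """Responsivity-weighted average of a continuous spectrum per band.

    Emulates what each broad band would report for a spectrally resolved
    measurement: value_b = sum(s * resp_b) / sum(resp_b).  Linear in the
    spectrum; maps constants to constants.
    """
    out = np.empty(len(bands))
    for i, band in enumerate(bands):
        wl = band.curve.wavelengths
        resp = band.curve.values
        if resp.max() == 0:
            raise ValueError(f"band {band.name!r} has empty support")
        # effective support: negligible tails (< 1e-4 of peak) are ignored
        support = resp >= 1e-4 * resp.max()
        lo, hi = wl[support][0], wl[support][-1]
        if lo < spectrum.wavelengths[0] or hi > spectrum.wavelengths[-1]:
            raise ValueError(
                f"spectrum grid [{spectrum.wavelengths[0]}, "
                f"{spectrum.wavelengths[-1]}] nm does not cover band "
                f"{band.name!r} support [{lo}, {hi}] nm"
            )
        s_on_band = np.interp(wl[support], spectrum.wavelengths, spectrum.values)
        out[i] = (s_on_band * resp[support]).sum() / resp[support].sum()
    return out
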