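"""Synthetic RGB projector/camera spectral curves.

Analytic stand-ins for a measured consumer-grade LED projector and colour
CMOS camera: narrow blue and red LEDs, a wide green LED, and broad
flat-topped colour filters with substantial overlap.  The shapes are tuned
so that the green LED leaks usefully into the blue and red filters (strong
GB and GR cross-channels), the blue LED leaks into the green filter (a BG
band that is then rejected on wavelength grounds), and the remaining
cross-channels are negligible.
"""

from __future__ import annotations

import numpy as np

from .spectral_bands import COMMON_GRID, SpectrumCurve

__all__ = ["demo_led_spectra", "demo_filter_curves"]


def _gaussian(grid: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / sigma) ** 2)


def _flat_top(grid: np.ndarray, centre: float, width: float, order: int = 4) -> np.ndarray:
    return np.exp(-(((grid - centre) / width) ** (2 * order)))


def demo_led_spectra(grid=None) -> dict[str, SpectrumCurve]:
    """Relative emission of the three projector LEDs."""
    g = COMMON_GRID if grid is None else np.asarray(grid, dtype=float)
    return {
        "B": SpectrumCurve(g, 0.95 * _gaussian(g, 458.0, 11.0)),
        "G": SpectrumCurve(g, 1.00 * _gaussian(g, 537.0, 30.0)),
        "R": SpectrumCurve(g, 0.90 * _gaussian(g, 626.0, 9.0)),
    }


def demo_filter_curves(grid=None) -> dict[str, SpectrumCurve]:
    """Relative transmission of the camera's Bayer colour filters."""
    g = COMMON_GRID if grid is None else np.asarray(grid, dtype=float)
    return {
        "B": SpectrumCurve(g, 0.92 * _flat_top(g, 474.0, 58.0)),
        "G": SpectrumCurve(g, 1.00 * _flat_top(g, 528.0, 62.0)),
        "R": SpectrumCurve(g, 0.95 * _flat_top(g, 604.0, 58.0)),
    }
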