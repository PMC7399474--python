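"""Pattern generation, three-phase demodulation and reference calibration.

The measurement model: sinusoidal patterns at spatial frequency fx are
projected at three spatial phases (0/120/240 deg); the per-pixel AC
amplitude is recovered from the three frames, and the ratio against a
reference phantom of known reflectance cancels the source intensity and
the instrument transfer function, yielding calibrated diffuse reflectance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES_DEG",
    "PatternSpec",
    "GammaCurve",
    "PhaseTriplet",
    "DemodulatedMap",
    "CalibrationReference",
    "CalibratedMap",
    "make_pattern",
    "estimate_gamma",
    "pregamma",
    "demodulate",
    "calibrate",
]

PHASES_DEG = (0.0, 120.0, 240.0)


@dataclass(frozen=True)
class PatternSpec:
    """One projected sinusoid: fx in 1/mm at the sample plane.

    The modulation axis is the image x axis (origin at the top-left
    pixel, x increasing rightward).
    """

    fx: float
    phase: float  # degrees, one of 0/120/240
    width: int
    height: int
    pixel_pitch: float        # mm per projected pixel at the sample plane
    dc_level: float = 0.5
    ac_level: float = 0.5

    def __post_init__(self) -> None:
        if self.fx < 0:
            raise ValueError(f"fx must be >= 0, got {self.fx}")
        if self.phase not in PHASES_DEG:
            raise ValueError(f"phase must be one of {PHASES_DEG}, got {self.phase}")
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.dc_level < 0 or self.ac_level < 0:
            raise ValueError("dc_level and ac_level must be >= 0")
        if self.dc_level + self.ac_level > 1.0 + 1e-12:
            raise ValueError(
                f"dc_level + ac_level = {self.dc_level + self.ac_level} > 1 "
                "would clip the sinusoid"
            )
        if self.fx * self.pixel_pitch >= 0.5:
            raise ValueError(
                f"fx * pixel_pitch = {self.fx * self.pixel_pitch} violates "
                "the Nyquist limit of 0.5 cycles per pixel"
            )


def make_pattern(spec: PatternSpec) -> np.ndarray:
    """Sinusoidal pattern in [0, 1]: dc + ac*cos(2*pi*fx*x + phase).

    For fx = 0 this is a uniform field at dc + ac*cos(phase), so the same
    three-phase demodulation applies unchanged at zero frequency.
    """
    x_mm = np.arange(spec.width) * spec.pixel_pitch
    row = spec.dc_level + spec.ac_level * np.cos(
        2.0 * np.pi * spec.fx * x_mm + np.deg2rad(spec.phase)
    )
    return np.tile(row, (spec.height, 1))


@dataclass(frozen=True)
class GammaCurve:
    """Measured projector level -> output intensity curve (monotone)."""

    input_levels: np.ndarray     # ascending device levels (0..255)
    measured_output: np.ndarray  # non-decreasing relative intensity

    def __post_init__(self) -> None:
        lv = np.asarray(self.input_levels, dtype=np.float64)
        out = np.asarray(self.measured_output, dtype=np.float64)
        if len(lv) < 2 or np.any(np.diff(lv) <= 0):
            raise ValueError("input_levels must be strictly ascending, >= 2 points")
        if out.shape != lv.shape:
            raise ValueError("input_levels and measured_output length mismatch")
        if np.any(np.diff(out) < 0):
            raise ValueError("measured_output must be non-decreasing")
        object.__setattr__(self, "input_levels", lv)
        object.__setattr__(self, "measured_output", out)

    def forward(self, levels) -> np.ndarray:
        """Device output intensity at the given input levels."""
        return np.interp(levels, self.input_levels, self.measured_output)

    def inverse(self, intensity) -> np.ndarray:
        """Input level producing the requested output intensity (clipped)."""
        # interp needs strictly increasing x: compress flat runs
        out = self.measured_output
        lv = self.input_levels
        keep = np.concatenate(([True], np.diff(out) > 0))
        return np.interp(intensity, out[keep], lv[keep])


def _pool_adjacent_violators(y: np.ndarray) -> np.ndarray:
    """Isotonic (non-decreasing) regression, L2, pool-adjacent-violators."""
    y = np.asarray(y, dtype=np.float64)
    vals = y.copy()
    wts = np.ones_like(y)
    n = 0
    for i in range(len(y)):
        vals[n] = y[i]
        wts[n] = 1.0
        n += 1
        while n > 1 and vals[n - 2] > vals[n - 1]:
            pooled = (vals[n - 2] * wts[n - 2] + vals[n - 1] * wts[n - 1]) / (
                wts[n - 2] + wts[n - 1]
            )
            wts[n - 2] += wts[n - 1]
            vals[n - 2] = pooled
            n -= 1
    out = np.empty_like(y)
    j = 0
    for k in range(n):
        m = int(wts[k])
        out[j : j + m] = vals[k]
        j += m
    return out


def estimate_gamma(levels, measured) -> GammaCurve:
    """Monotone lookup curve from a projector characterisation sweep.

    Non-monotone measurements (noise) are isotonically regularised.
    """
    lv = np.asarray(levels, dtype=np.float64)
    ms = np.asarray(measured, dtype=np.float64)
    if lv.shape != ms.shape:
        raise ValueError("levels and measured must have equal length")
    if np.any(ms < 0):
        raise ValueError("measured intensities must be non-negative")
    order = np.argsort(lv)
    lv, ms = lv[order], ms[order]
    if len(np.unique(lv)) < 2:
        raise ValueError("need at least 2 distinct device levels")
    iso = _pool_adjacent_violators(ms)
    return GammaCurve(lv, iso)


def pregamma(pattern: np.ndarray, curve: GammaCurve) -> np.ndarray:
    """Pre-compensate a [0, 1] pattern for the projector gamma.

    Returns quantised 8-bit device levels such that the projected output
    is linear in the requested pattern.  Requested intensities outside the
    measured output range are clipped with a logged warning.
    """
    pattern = np.asarray(pattern, dtype=np.float64)
    lo, hi = curve.measured_output[0], curve.measured_output[-1]
    target = lo + pattern * (hi - lo)
    n_clip = int(np.sum((target < lo) | (target > hi)))
    if n_clip:
        logger.warning("pregamma: clipping %d pixels outside measured range", n_clip)
        target = np.clip(target, lo, hi)
    levels = curve.inverse(target)
    return np.clip(np.rint(levels), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class PhaseTriplet:
    """Three co-registered linear-intensity frames at 0/120/240 deg."""

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    fx: float
    band: str

    def __post_init__(self) -> None:
        a1 = np.asarray(self.i1, dtype=np.float64)
        a2 = np.asarray(self.i2, dtype=np.float64)
        a3 = np.asarray(self.i3, dtype=np.float64)
        if not (a1.shape == a2.shape == a3.shape):
            raise ValueError(
                f"frame shapes differ: {a1.shape}, {a2.shape}, {a3.shape}"
            )
        if min(a1.min(), a2.min(), a3.min()) < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "i1", a1)
        object.__setattr__(self, "i2", a2)
        object.__setattr__(self, "i3", a3)


@dataclass(frozen=True)
class DemodulatedMap:
    mac: np.ndarray  # per-pixel AC amplitude, >= 0
    fx: float
    band: str


def demodulate(triplet: PhaseTriplet) -> DemodulatedMap:
    """Per-pixel three-phase AC amplitude.

    MAC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2),
    invariant to a common offset and to a global phase shift.
    No smoothing, no windowing.
    """
    d12 = triplet.i1 - triplet.i2
    d23 = triplet.i2 - triplet.i3
    d31 = triplet.i3 - triplet.i1
    mac = (np.sqrt(2.0) / 3.0) * np.sqrt(d12**2 + d23**2 + d31**2)
    return DemodulatedMap(mac=mac, fx=triplet.fx, band=triplet.band)


@dataclass
class CalibrationReference:
    """Demodulated reference acquisition plus its theoretical reflectance.

    ``mac_ref`` and ``rd_ref`` are keyed by (fx, band).  The source
    intensity and instrument transfer function are never represented:
    they cancel in the MAC ratio by construction.  ``smooth`` optionally
    median-filters the reference MAC (k x k) before division to suppress
    reference speckle; default off so that self-calibration is exact.
    """

    mac_ref: dict = field(default_factory=dict)   # (fx, band) -> 2-D array
    rd_ref: dict = field(default_factory=dict)    # (fx, band) -> float in (0, 1)
    smooth: int = 0

    def add(self, demod: DemodulatedMap, rd_ref: float) -> None:
        if not 0 < rd_ref < 1:
            raise ValueError(f"rd_ref must be in (0, 1), got {rd_ref}")
        mac = demod.mac
        if self.smooth:
            mac = median_filter(mac, size=self.smooth)
        self.mac_ref[(demod.fx, demod.band)] = mac
        self.rd_ref[(demod.fx, demod.band)] = float(rd_ref)


@dataclass(frozen=True)
class CalibratedMap:
    rd: np.ndarray             # clipped to [0, 1.5]
    out_of_range: np.ndarray   # bool mask of clipped pixels
    fx: float
    band: str


def calibrate(mac_tissue: DemodulatedMap, ref: CalibrationReference) -> CalibratedMap:
    """Rd_tissue = (MAC / MAC_ref) * Rd_ref, per pixel, per (fx, band)."""
    key = (mac_tissue.fx, mac_tissue.band)
    if key not in ref.mac_ref:
        raise KeyError(
            f"(fx={mac_tissue.fx}, band={mac_tissue.band!r}) absent from the "
            f"calibration reference (have: {sorted(ref.mac_ref)})"
        )
    mac_ref = ref.mac_ref[key]
    if mac_tissue.mac.shape != mac_ref.shape:
        raise ValueError(
            f"tissue MAC shape {mac_tissue.mac.shape} != reference "
            f"{mac_ref.shape}"
        )
    if np.any(mac_ref <= 0):
        raise ValueError("reference MAC must be > 0 wherever calibration applies")
    rd = mac_tissue.mac / mac_ref * ref.rd_ref[key]
    out_of_range = (rd < 0) | (rd > 1.5)
    return CalibratedMap(
        rd=np.clip(rd, 0.0, 1.5),
        out_of_range=out_of_range,
        fx=mac_tissue.fx,
        band=mac_tissue.band,
    )
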