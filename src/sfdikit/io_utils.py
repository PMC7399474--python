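"""File I/O: 8-bit grayscale frames, CSV spectra, manifests, float TIFFs."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .spectral_bands import SpectrumCurve

__all__ = [
    "UnsupportedFormatError",
    "read_frame",
    "write_frame",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "FrameManifest",
    "write_property_maps_tiff",
    "file_sha256",
]


class UnsupportedFormatError(ValueError):
    """Raised for frames that are not 8-bit single-channel images."""


def read_frame(path) -> np.ndarray:
    """Read an 8-bit grayscale BMP or PNG frame; values 0-255, unscaled."""
    with Image.open(path) as img:
        if img.format not in ("BMP", "PNG"):
            raise UnsupportedFormatError(
                f"{path}: unsupported container {img.format!r} (need BMP or PNG)"
            )
        if img.mode != "L":
            raise UnsupportedFormatError(
                f"{path}: mode {img.mode!r} is not 8-bit grayscale; convert "
                "explicitly rather than relying on silent conversion"
            )
        return np.asarray(img, dtype=np.uint8)


def write_frame(path, frame: np.ndarray) -> None:
    """Write an 8-bit grayscale frame (BMP or PNG chosen by extension)."""
    frame = np.asarray(frame)
    if frame.dtype != np.uint8 or frame.ndim != 2:
        raise UnsupportedFormatError("frame must be a 2-D uint8 array")
    Image.fromarray(frame, mode="L").save(path)


def read_spectrum_csv(path) -> SpectrumCurve:
    """Two-column CSV with header: wavelength_nm, value."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (wavelength_nm, value)")
    return SpectrumCurve(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_spectrum_csv(path, curve: SpectrumCurve) -> None:
    pd.DataFrame(
        {"wavelength_nm": curve.wavelengths, "value": curve.values}
    ).to_csv(path, index=False)


class FrameManifest:
    """CSV manifest of acquisition frames.

    Columns: sample, band, fx_index, phase_index, path, role
    (role in {sample, reference}).
    """

    COLUMNS = ("sample", "band", "fx_index", "phase_index", "path", "role")

    def __init__(self, rows: pd.DataFrame):
        missing = set(self.COLUMNS) - set(rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        bad_roles = set(rows["role"].unique()) - {"sample", "reference"}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        self.rows = rows.reset_index(drop=True)

    @classmethod
    def load(cls, path) -> "FrameManifest":
        return cls(pd.read_csv(path))

    def save(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def validate(self, base_dir=None) -> None:
        """Check referenced files exist and coverage is factorial."""
        base = Path(base_dir) if base_dir else Path(".")
        for p in self.rows["path"]:
            if not (base / p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        for sample, grp in self.rows.groupby("sample"):
            n_b = grp["band"].nunique()
            n_f = grp["fx_index"].nunique()
            n_p = grp["phase_index"].nunique()
            if len(grp) != n_b * n_f * n_p:
                raise ValueError(
                    f"sample {sample!r}: {len(grp)} frames, expected full "
                    f"factorial {n_b} bands x {n_f} fx x {n_p} phases = "
                    f"{n_b * n_f * n_p}"
                )

    def triplet_paths(self, sample: str, band: str, fx_index: int) -> list[str]:
        sel = self.rows[
            (self.rows["sample"] == sample)
            & (self.rows["band"] == band)
            & (self.rows["fx_index"] == fx_index)
        ].sort_values("phase_index")
        if len(sel) != 3:
            raise ValueError(
                f"expected 3 phases for ({sample}, {band}, fx {fx_index}), "
                f"found {len(sel)}"
            )
        return sel["path"].tolist()


def write_property_maps_tiff(path, maps: dict) -> None:
    """Multi-page 32-bit float TIFF, one page per named map."""
    import tifffile

    pages = np.stack([np.asarray(m, dtype=np.float32) for m in maps.values()])
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        metadata={"labels": list(maps.keys())},
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
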