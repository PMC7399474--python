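"""End-to-end phantom study: imaging pipeline vs band-emulated spectroscopy.

Simulates the 16-phantom validation grid and a calibration reference,
runs the full pipeline (simulate -> demodulate -> calibrate -> fit), and
compares the field-of-view mean optical properties per band against the
band-emulated values of the spectrally continuous ground truth, with
linear-regression agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .forward_model import MCSettings, ReflectanceTable, build_table, lookup_rd
from .inversion import InversionConfig, fit_image
from .sfdi_core import CalibrationReference, PhaseTriplet, calibrate, demodulate
from .spectral_bands import (
    SpectrumCurve,
    band_stats,
    build_all_bands,
    select_bands,
)
from .synthetic_instrument import (
    DEFAULT_FX_LIST,
    InstrumentModel,
    PhantomSpec,
    make_phantom_grid,
    phantom_properties,
    simulate_acquisition,
    simulate_sfds_spectrum,
)

__all__ = [
    "RegressionResult",
    "PhantomStudyResult",
    "regression_stats",
    "run_phantom_study",
    "default_reference_phantom",
    "default_table_grids",
]

#: Shared fx subset for imaging/spectroscopy comparison, 1/mm.
COMPARISON_FX = (0.0, 0.05, 0.1)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmse: float  # about the identity line y = x unless stated otherwise

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def regression_stats(pairs, rmse_about: str = "identity") -> RegressionResult:
    """Ordinary least squares of y on x with an agreement RMSE.

    ``rmse_about`` selects the RMSE reference: "identity" (residuals about
    y = x, an agreement metric) or "fit" (residuals about the regression
    line).
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; regression is degenerate")
    res = sps.linregress(x, y)
    if rmse_about == "identity":
        rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    elif rmse_about == "fit":
        rmse = float(np.sqrt(np.mean((y - (res.slope * x + res.intercept)) ** 2)))
    else:
        raise ValueError('rmse_about must be "identity" or "fit"')
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse=rmse,
    )


@dataclass
class PhantomStudyResult:
    comparison: pd.DataFrame  # long table, one row per (phantom, band, property)
    regressions: dict         # property -> RegressionResult
    seed: int

    def cluster_sizes(self, property_name: str, by: str = "absorption_level"):
        sub = self.comparison[self.comparison["property"] == property_name]
        return sub.groupby(by).size()

    def to_csv(self, path) -> None:
        self.comparison.to_csv(path, index=False)

    def plot(self, path) -> None:
        """Fig.-6-style scatter: imaging vs spectroscopy values, with the
        regression and unity lines, one panel per property."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
        for ax, prop, unit in zip(
            axes, ("mu_a", "mu_s_prime"), ("1/mm", "1/mm")
        ):
            sub = self.comparison[self.comparison["property"] == prop]
            level = "absorption_level" if prop == "mu_a" else "scattering_level"
            for lvl, grp in sub.groupby(level):
                ax.scatter(
                    grp["value_reference"],
                    grp["value_sfdi"],
                    s=18,
                    label=f"level {lvl}",
                )
            reg = self.regressions[prop]
            lims = [sub["value_reference"].min(), sub["value_reference"].max()]
            xs = np.linspace(lims[0], lims[1], 2)
            ax.plot(xs, reg.slope * xs + reg.intercept, "k--", lw=1)
            ax.plot(xs, xs, "k:", lw=1)
            ax.set_xlabel(f"reference {prop} ({unit})")
            ax.set_ylabel(f"imaging {prop} ({unit})")
            ax.set_title(f"R²={reg.r_squared:.3f}, RMSE={reg.rmse:.3g}")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def default_reference_phantom() -> PhantomSpec:
    """Calibration reference: mid-range scattering, low flat absorption."""
    return PhantomSpec(
        name="reference",
        mus_prime_at_anchor=1.0,
        mua_at_anchor=0.05,
        scatter_exponent=1.2,
    )


def default_table_grids():
    """Grids covering the phantom validation range with margin."""
    mu_a_grid = np.geomspace(0.005, 0.5, 28)
    mu_s_prime_grid = np.geomspace(0.3, 5.0, 20)
    fx_grid = np.array([0.0, 0.0333, 0.05, 0.1, 0.15, 0.2, 0.3])
    return mu_a_grid, mu_s_prime_grid, fx_grid


def _default_bands():
    from .demo import demo_filter_curves, demo_led_spectra

    bands = build_all_bands(demo_led_spectra(), demo_filter_curves())
    names = select_bands(bands)
    by_name = {b.name: b for b in bands}
    return tuple(by_name[n] for n in names)


def run_phantom_study(
    seed: int = 0,
    noise_fraction: float = 0.0,
    camera_noise_sigma: float = 0.0,
    fx_subset=COMPARISON_FX,
    table: ReflectanceTable | None = None,
    mc_photons: int = 150_000,
    frame_shape=(32, 32),
    quantize: bool = True,
    bands=None,
    rmse_about: str = "identity",
) -> PhantomStudyResult:
    """Full synthetic replication of the 16-phantom validation study.

    Returns the per-(phantom, band, property) comparison table and the
    per-property regression statistics.  Deterministic for a fixed seed.
    """
    if table is None:
        mu_a_grid, musp_grid, fx_grid = default_table_grids()
        table = build_table(
            mu_a_grid, musp_grid, fx_grid, MCSettings(n_photons=mc_photons, seed=seed)
        )
    if bands is None:
        bands = _default_bands()
    band_centres = {b.name: band_stats(b).lambda0 for b in bands}

    instrument = InstrumentModel(
        bands=tuple(bands),
        camera_noise_sigma=camera_noise_sigma,
        noise_fraction=noise_fraction,
        frame_shape=tuple(frame_shape),
        quantize=quantize,
    )
    fx_list = tuple(sorted(set(DEFAULT_FX_LIST) | set(fx_subset)))
    fx_idx = {fx: i for i, fx in enumerate(fx_list)}

    # Reference acquisition and its theoretical reflectance.
    ref_spec = default_reference_phantom()
    ref_acq = simulate_acquisition(
        ref_spec, instrument, table, fx_list=fx_list, seed=seed + 10_000
    )
    reference = CalibrationReference()
    for b in bands:
        props = phantom_properties(ref_spec, band_centres[b.name])
        exp_ref = ref_acq.exposures[b.name]
        for fx in fx_subset:
            i1, i2, i3 = (
                a.astype(np.float64) / exp_ref
                for a in ref_acq.triplet_arrays(b.name, fx_idx[fx])
            )
            demod = demodulate(
                PhaseTriplet(i1, i2, i3, fx=fx, band=b.name)
            )
            rd_theory = float(lookup_rd(table, props, [fx])[0])
            reference.add(demod, rd_theory)

    config = InversionConfig()
    phantoms = make_phantom_grid()
    rows = []
    for k, ph in enumerate(phantoms):
        acq = simulate_acquisition(
            ph, instrument, table, fx_list=fx_list, seed=seed + k
        )
        sfds = simulate_sfds_spectrum(ph, table, refit=False)
        spectrum_mu_a = SpectrumCurve(sfds["wavelengths"], sfds["mu_a"])
        spectrum_musp = SpectrumCurve(sfds["wavelengths"], sfds["mu_s_prime"])
        for b in bands:
            rd_stack = []
            exp_b = acq.exposures[b.name]
            for fx in fx_subset:
                i1, i2, i3 = (
                    a.astype(np.float64) / exp_b
                    for a in acq.triplet_arrays(b.name, fx_idx[fx])
                )
                demod = demodulate(PhaseTriplet(i1, i2, i3, fx=fx, band=b.name))
                rd_stack.append(calibrate(demod, reference).rd)
            pmap = fit_image(
                np.stack(rd_stack), list(fx_subset), table, config, band=b.name
            )
            mua_hat, musp_hat = pmap.fov_mean
            from .spectral_bands import emulate_band_values

            mua_ref = float(emulate_band_values(spectrum_mu_a, [b])[0])
            musp_ref = float(emulate_band_values(spectrum_musp, [b])[0])
            common = {
                "phantom": ph.name,
                "band": b.name,
                "lambda0": band_centres[b.name],
                "absorption_level": ph.absorption_level,
                "scattering_level": ph.scattering_level,
            }
            rows.append(
                {**common, "property": "mu_a", "value_sfdi": mua_hat,
                 "value_reference": mua_ref}
            )
            rows.append(
                {**common, "property": "mu_s_prime", "value_sfdi": musp_hat,
                 "value_reference": musp_ref}
            )

    comparison = pd.DataFrame(rows)
    regressions = {}
    for prop in ("mu_a", "mu_s_prime"):
        sub = comparison[comparison["property"] == prop]
        regressions[prop] = regression_stats(
            np.column_stack([sub["value_reference"], sub["value_sfdi"]]),
            rmse_about=rmse_about,
        )
    return PhantomStudyResult(comparison=comparison, regressions=regressions, seed=seed)
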