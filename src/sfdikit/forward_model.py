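"""Forward model of spatially modulated diffuse reflectance.

A white (absorption-free) Monte Carlo simulation of photon transport in a
homogeneous semi-infinite turbid medium records, for every photon packet
that crosses the top surface, its exit radius, cumulative path length and
residual weight.  Absorption is applied afterwards by Beer-Lambert
rescaling of the recorded path lengths, the radially resolved reflectance
is transformed to the spatial-frequency domain with a zeroth-order Hankel
transform, and the results are tabulated over an (mu_a, mu_s', fx) grid
for fast interpolated lookup by the inverse solver.

A closed-form diffusion-approximation expression for Rd(fx) is provided as
an independent cross-check of the Monte Carlo results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import j0

__all__ = [
    "OpticalProperties",
    "PhotonExitRecord",
    "ExitRecords",
    "RadialReflectance",
    "ReflectanceTable",
    "MCSettings",
    "run_white_mc",
    "apply_absorption",
    "hankel_to_fx",
    "diffusion_rd",
    "build_table",
    "lookup_rd",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair with phase-function constants.

    All lengths in mm; ``mu_a`` and ``mu_s_prime`` in 1/mm.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.8
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not 0 <= self.g < 1:
            raise ValueError(f"g must be in [0, 1), got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s' / (1 - g), 1/mm."""
        return self.mu_s_prime / (1.0 - self.g)


class PhotonExitRecord(NamedTuple):
    exit_radius: float  # mm
    path_length: float  # mm
    weight: float       # residual packet weight in (0, 1]


class ExitRecords:
    """Column store of photon exit events (list-like of PhotonExitRecord).

    Keeping the three columns as contiguous arrays keeps absorption
    rescaling and binning vectorised; indexing still yields individual
    PhotonExitRecord tuples.
    """

    __slots__ = ("exit_radius", "path_length", "weight", "n_launched")

    def __init__(self, exit_radius, path_length, weight, n_launched: int):
        self.exit_radius = np.asarray(exit_radius, dtype=np.float64)
        self.path_length = np.asarray(path_length, dtype=np.float64)
        self.weight = np.asarray(weight, dtype=np.float64)
        self.n_launched = int(n_launched)
        if not (len(self.exit_radius) == len(self.path_length) == len(self.weight)):
            raise ValueError("record columns must have equal length")

    def __len__(self) -> int:
        return len(self.weight)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return PhotonExitRecord(
                float(self.exit_radius[i]),
                float(self.path_length[i]),
                float(self.weight[i]),
            )
        return ExitRecords(
            self.exit_radius[i], self.path_length[i], self.weight[i], self.n_launched
        )

    def __iter__(self):
        for r, l, w in zip(self.exit_radius, self.path_length, self.weight):
            yield PhotonExitRecord(float(r), float(l), float(w))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExitRecords):
            return NotImplemented
        return (
            self.n_launched == other.n_launched
            and np.array_equal(self.exit_radius, other.exit_radius)
            and np.array_equal(self.path_length, other.path_length)
            and np.array_equal(self.weight, other.weight)
        )

    def rescaled(self, factor: float) -> "ExitRecords":
        """Similarity-rescaled copy: all lengths multiplied by ``factor``.

        A white MC run in a semi-infinite medium has no intrinsic length
        scale other than 1/mu_s, so a run at mu_s' = 1 rescaled by
        1/mu_s' is an exact run at mu_s'.
        """
        return ExitRecords(
            self.exit_radius * factor,
            self.path_length * factor,
            self.weight.copy(),
            self.n_launched,
        )


@dataclass(frozen=True)
class RadialReflectance:
    """Radially binned diffuse reflectance per unit area (1/mm^2)."""

    bin_edges: np.ndarray        # mm, ascending, starting at 0
    rd_per_area: np.ndarray      # 1/mm^2 per annulus
    n_photons_launched: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        vals = np.asarray(self.rd_per_area, dtype=np.float64)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be ascending with >= 2 entries")
        if edges[0] != 0:
            raise ValueError("bin_edges must start at 0")
        if len(vals) != len(edges) - 1:
            raise ValueError("rd_per_area must have len(bin_edges) - 1 entries")
        if np.any(vals < 0):
            raise ValueError("rd_per_area must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "rd_per_area", vals)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def annulus_areas(self) -> np.ndarray:
        return np.pi * (self.bin_edges[1:] ** 2 - self.bin_edges[:-1] ** 2)

    @property
    def total_reflectance(self) -> float:
        return float(np.sum(self.rd_per_area * self.annulus_areas))


def _fresnel_reflectance(cos_i: np.ndarray, n: float) -> np.ndarray:
    """Unpolarised Fresnel reflectance, internal medium n -> external 1.

    Total internal reflection beyond the critical angle.
    """
    if n == 1.0:
        return np.zeros_like(cos_i)
    sin_i = np.sqrt(np.clip(1.0 - cos_i**2, 0.0, 1.0))
    sin_t = n * sin_i
    tir = sin_t >= 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t**2, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n * cos_i - cos_t) / (n * cos_i + cos_t)
        rp = (cos_i - n * cos_t) / (cos_i + n * cos_t)
        r = 0.5 * (rs**2 + rp**2)
    r = np.where(tir, 1.0, r)
    return np.clip(r, 0.0, 1.0)


try:  # optional compiled kernel; the numpy path below is the reference
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _numba = None
    _HAVE_NUMBA = False


def run_white_mc(
    mu_s_prime: float,
    g: float = 0.0,
    n: float = 1.0,
    n_photons: int = 1_000_000,
    seed: int = 0,
    max_path: float = 4000.0,
    roulette_weight: float = 1e-4,
) -> ExitRecords:
    """White Monte Carlo in a semi-infinite medium (mu_a = 0).

    Pencil beam enters at the origin along +z (specular entry excluded,
    matching cross-polarised acquisition).  Photons crossing z = 0 deposit
    the Fresnel-transmitted fraction of their weight as an exit record and
    continue internally reflected.  Photons whose cumulative path exceeds
    ``max_path`` are terminated unrecorded; Russian roulette is played
    below ``roulette_weight``.

    Deterministic for a fixed seed (per backend: the compiled kernel is
    used when numba is importable, the vectorised numpy path otherwise).
    """
    if mu_s_prime <= 0:
        raise ValueError(f"mu_s_prime must be > 0, got {mu_s_prime}")
    if not 0 <= g < 1:
        raise ValueError(f"g must be in [0, 1), got {g}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if max_path <= 0:
        raise ValueError("max_path must be > 0")

    mu_s = mu_s_prime / (1.0 - g)
    if _HAVE_NUMBA:
        r, l, ww = _mc_kernel_numba(
            mu_s, g, n, int(n_photons), int(seed), max_path, roulette_weight
        )
        return ExitRecords(r, l, ww, n_photons)
    return _run_white_mc_numpy(
        mu_s, g, n, int(n_photons), seed, max_path, roulette_weight
    )


def _run_white_mc_numpy(
    mu_s: float,
    g: float,
    n: float,
    n_photons: int,
    seed: int,
    max_path: float,
    roulette_weight: float,
) -> ExitRecords:
    rng = np.random.default_rng(seed)

    m = int(n_photons)
    x = np.zeros(m)
    y = np.zeros(m)
    z = np.zeros(m)
    ux = np.zeros(m)
    uy = np.zeros(m)
    uz = np.ones(m)
    w = np.ones(m)
    path = np.zeros(m)

    out_r: list[np.ndarray] = []
    out_l: list[np.ndarray] = []
    out_w: list[np.ndarray] = []

    while m > 0:
        s = rng.exponential(1.0 / mu_s, size=m)

        # Distance to the z=0 plane along the current direction.
        up = uz < 0
        with np.errstate(divide="ignore"):
            d_b = np.where(up, -z / np.where(up, uz, -1.0), np.inf)
        hit = d_b < s

        # Photons that reach the surface within this step.
        if np.any(hit):
            db_h = d_b[hit]
            xh = x[hit] + ux[hit] * db_h
            yh = y[hit] + uy[hit] * db_h
            path_h = path[hit] + db_h
            cos_i = -uz[hit]
            refl = _fresnel_reflectance(cos_i, n)
            w_exit = w[hit] * (1.0 - refl)
            ok = (w_exit > 0) & (path_h <= max_path)
            if np.any(ok):
                out_r.append(np.hypot(xh[ok], yh[ok]))
                out_l.append(path_h[ok])
                out_w.append(w_exit[ok])
            # Internally reflected remainder finishes the step mirrored.
            rem = s[hit] - db_h
            x[hit] = xh + ux[hit] * rem
            y[hit] = yh + uy[hit] * rem
            z[hit] = rem * cos_i  # uz flips sign at the boundary
            uz[hit] = cos_i
            w[hit] = w[hit] * refl

        nh = ~hit
        x[nh] += ux[nh] * s[nh]
        y[nh] += uy[nh] * s[nh]
        z[nh] += uz[nh] * s[nh]
        path += s

        alive = (w > 0) & (path <= max_path)

        # Russian roulette on low-weight packets.
        low = alive & (w < roulette_weight)
        if np.any(low):
            u = rng.random(int(low.sum()))
            survive = u < 0.1
            wl = w[low]
            wl = np.where(survive, wl * 10.0, 0.0)
            w[low] = wl
            alive = (w > 0) & (path <= max_path)

        if not np.all(alive):
            x, y, z = x[alive], y[alive], z[alive]
            ux, uy, uz = ux[alive], uy[alive], uz[alive]
            w, path = w[alive], path[alive]
            m = len(w)
            if m == 0:
                break

        # Henyey-Greenstein scattering.
        u1 = rng.random(m)
        if g == 0.0:
            cost = 2.0 * u1 - 1.0
        else:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
            cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            cost = np.clip(cost, -1.0, 1.0)
        sint = np.sqrt(1.0 - cost**2)
        phi = 2.0 * np.pi * rng.random(m)
        cosp = np.cos(phi)
        sinp = np.sin(phi)

        near_vert = np.abs(uz) > 0.99999
        denom = np.sqrt(np.clip(1.0 - uz**2, 1e-30, None))
        ux_n = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
        uy_n = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
        uz_n = -denom * sint * cosp + uz * cost
        ux_v = sint * cosp
        uy_v = sint * sinp
        uz_v = np.sign(uz) * cost
        ux = np.where(near_vert, ux_v, ux_n)
        uy = np.where(near_vert, uy_v, uy_n)
        uz = np.where(near_vert, uz_v, uz_n)
        norm = np.sqrt(ux**2 + uy**2 + uz**2)
        ux /= norm
        uy /= norm
        uz /= norm

    if out_r:
        r = np.concatenate(out_r)
        l = np.concatenate(out_l)
        ww = np.concatenate(out_w)
    else:
        r = np.empty(0)
        l = np.empty(0)
        ww = np.empty(0)
    return ExitRecords(r, l, ww, n_photons)


if _HAVE_NUMBA:

    @_numba.njit(cache=True, fastmath=False)
    def _mc_kernel_numba(mu_s, g, n, n_photons, seed, max_path, roulette_weight):
        np.random.seed(seed)
        cap = n_photons * 8
        rec_r = np.empty(cap)
        rec_l = np.empty(cap)
        rec_w = np.empty(cap)
        cnt = 0
        for _ in range(n_photons):
            x = 0.0
            y = 0.0
            z = 0.0
            ux = 0.0
            uy = 0.0
            uz = 1.0
            w = 1.0
            path = 0.0
            alive = True
            while alive:
                s = -np.log(np.random.random()) / mu_s
                if uz < 0.0:
                    d_b = -z / uz
                    if d_b < s:
                        # advance to the surface
                        x += ux * d_b
                        y += uy * d_b
                        path += d_b
                        cos_i = -uz
                        if n == 1.0:
                            refl = 0.0
                        else:
                            sin_i2 = 1.0 - cos_i * cos_i
                            if sin_i2 < 0.0:
                                sin_i2 = 0.0
                            sin_t2 = n * n * sin_i2
                            if sin_t2 >= 1.0:
                                refl = 1.0
                            else:
                                cos_t = np.sqrt(1.0 - sin_t2)
                                rs = (n * cos_i - cos_t) / (n * cos_i + cos_t)
                                rp = (cos_i - n * cos_t) / (cos_i + n * cos_t)
                                refl = 0.5 * (rs * rs + rp * rp)
                        w_exit = w * (1.0 - refl)
                        if w_exit > 0.0 and path <= max_path and cnt < cap:
                            rec_r[cnt] = np.sqrt(x * x + y * y)
                            rec_l[cnt] = path
                            rec_w[cnt] = w_exit
                            cnt += 1
                        w *= refl
                        if w <= 0.0:
                            break
                        uz = cos_i
                        rem = s - d_b
                        x += ux * rem
                        y += uy * rem
                        z = rem * uz
                        path += rem
                    else:
                        x += ux * s
                        y += uy * s
                        z += uz * s
                        path += s
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    path += s
                if path > max_path:
                    break
                if w < roulette_weight:
                    if np.random.random() < 0.1:
                        w *= 10.0
                    else:
                        break
                # Henyey-Greenstein scatter
                u1 = np.random.random()
                if g == 0.0:
                    cost = 2.0 * u1 - 1.0
                else:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                sint = np.sqrt(1.0 - cost * cost)
                phi = 2.0 * np.pi * np.random.random()
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    denom = np.sqrt(1.0 - uz * uz)
                    ux_n = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                    uy_n = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                    uz_n = -denom * sint * cosp + uz * cost
                    ux = ux_n
                    uy = uy_n
                    uz = uz_n
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
        return rec_r[:cnt], rec_l[:cnt], rec_w[:cnt]


def apply_absorption(
    records: ExitRecords, mu_a: float, bin_edges: Sequence[float]
) -> RadialReflectance:
    """Beer-Lambert pathlength rescaling of white-MC exit records.

    Each record contributes ``weight * exp(-mu_a * path_length)`` to its
    radial annulus, normalised per launched photon and per annulus area.
    Records beyond the last edge are folded into the outermost bin so the
    total reflectance is conserved exactly.
    """
    if mu_a < 0:
        raise ValueError(f"mu_a must be >= 0, got {mu_a}")
    if len(records) == 0:
        raise ValueError("no exit records: run the white Monte Carlo first")
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be ascending with >= 2 entries")

    w = records.weight * np.exp(-mu_a * records.path_length)
    idx = np.searchsorted(edges, records.exit_radius, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=w, minlength=len(edges) - 1)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rd = sums / (records.n_launched * areas)
    return RadialReflectance(edges, rd, records.n_launched)


def hankel_to_fx(radial: RadialReflectance, fx_list: Sequence[float]) -> np.ndarray:
    """Zeroth-order Hankel transform of a radial reflectance profile.

    Rd(fx) = 2*pi * sum_i rd(r_i) * J0(2*pi*fx*r_i) * r_i * dr_i at bin
    centres.  With midpoint centres, Rd(0) equals the annulus-weighted
    total exactly.
    """
    fx = np.asarray(fx_list, dtype=np.float64)
    if np.any(fx < 0):
        raise ValueError("spatial frequencies must be >= 0")
    rc = radial.bin_centers
    dr = np.diff(radial.bin_edges)
    kernel = radial.rd_per_area * rc * dr
    return 2.0 * np.pi * (j0(2.0 * np.pi * np.outer(fx, rc)) @ kernel)


def _internal_reflection_parameter(n: float) -> float:
    # Groenhuis/Haskell effective-reflection approximation.
    r_eff = 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


def diffusion_rd(props: OpticalProperties, fx) -> np.ndarray | float:
    """Diffusion-approximation Rd(fx) for a semi-infinite medium.

    Independent closed-form oracle for the Monte Carlo table.  Valid in
    the diffusive regime (mu_s' / mu_a >~ 10); computed regardless.
    """
    fx_arr = np.asarray(fx, dtype=np.float64)
    mu_tr = props.mu_a + props.mu_s_prime
    a_prime = props.mu_s_prime / mu_tr
    mu_eff = np.sqrt(3.0 * props.mu_a * mu_tr)
    mu_eff_p = np.sqrt(mu_eff**2 + (2.0 * np.pi * fx_arr) ** 2)
    big_a = _internal_reflection_parameter(props.n)
    rd = (3.0 * big_a * a_prime) / (
        (mu_eff_p / mu_tr + 1.0) * (mu_eff_p / mu_tr + 3.0 * big_a)
    )
    if np.isscalar(fx):
        return float(rd)
    return rd


@dataclass(frozen=True)
class MCSettings:
    """White Monte Carlo run configuration for table building."""

    n_photons: int = 1_000_000
    seed: int = 0
    g: float = 0.0
    n: float = 1.4
    max_path: float = 4000.0
    roulette_weight: float = 1e-4
    n_bins: int = 512
    dr: float = 0.1
    independent_runs: bool = False

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.dr


@dataclass
class ReflectanceTable:
    """Tabulated Rd over (mu_a, mu_s', fx), with build metadata."""

    mu_a_grid: np.ndarray
    mu_s_prime_grid: np.ndarray
    fx_grid: np.ndarray
    rd: np.ndarray  # shape (n_mu_a, n_mu_s_prime, n_fx)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu_a_grid = np.asarray(self.mu_a_grid, dtype=np.float64)
        self.mu_s_prime_grid = np.asarray(self.mu_s_prime_grid, dtype=np.float64)
        self.fx_grid = np.asarray(self.fx_grid, dtype=np.float64)
        self.rd = np.asarray(self.rd, dtype=np.float64)
        for name, grid in (
            ("mu_a_grid", self.mu_a_grid),
            ("mu_s_prime_grid", self.mu_s_prime_grid),
            ("fx_grid", self.fx_grid),
        ):
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        expected = (len(self.mu_a_grid), len(self.mu_s_prime_grid), len(self.fx_grid))
        if self.rd.shape != expected:
            raise ValueError(f"rd shape {self.rd.shape} != grids {expected}")
        if self.fx_grid[0] < 0:
            raise ValueError("fx_grid must start at >= 0")
        if np.any(self.rd < 0) or np.any(self.rd > 1):
            raise ValueError("rd entries must lie in [0, 1]")

    def fx_index(self, fx: float, atol: float = 1e-9) -> int:
        i = int(np.argmin(np.abs(self.fx_grid - fx)))
        if abs(self.fx_grid[i] - fx) > atol:
            raise ValueError(
                f"fx={fx} is not a tabulated spatial frequency "
                f"(grid: {self.fx_grid.tolist()})"
            )
        return i

    def save(self, path) -> None:
        """Single-file .npz container with explicit grids and metadata."""
        np.savez(
            path,
            mu_a_grid=self.mu_a_grid,
            mu_s_prime_grid=self.mu_s_prime_grid,
            fx_grid=self.fx_grid,
            rd=self.rd,
            metadata_json=np.array(json.dumps(self.metadata)),
        )

    @classmethod
    def load(cls, path) -> "ReflectanceTable":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["metadata_json"]))
            return cls(
                npz["mu_a_grid"],
                npz["mu_s_prime_grid"],
                npz["fx_grid"],
                npz["rd"],
                meta,
            )

    def fx_slice_csv(self, fx: float, path) -> None:
        """Export one fx slice as CSV (rows mu_a, columns mu_s')."""
        import pandas as pd

        k = self.fx_index(fx)
        df = pd.DataFrame(
            self.rd[:, :, k],
            index=self.mu_a_grid,
            columns=self.mu_s_prime_grid,
        )
        df.index.name = "mu_a"
        df.to_csv(path)


def build_table(
    mu_a_grid: Sequence[float],
    mu_s_prime_grid: Sequence[float],
    fx_grid: Sequence[float],
    settings: MCSettings,
) -> ReflectanceTable:
    """Tabulate Rd(mu_a, mu_s', fx) from white Monte Carlo runs.

    By default a single run at mu_s' = 1/mm is similarity-rescaled to each
    grid value (exact for a semi-infinite homogeneous medium, which has no
    length scale other than 1/mu_s); set ``independent_runs=True`` in the
    settings to simulate each mu_s' value separately.
    """
    mu_a_grid = np.asarray(mu_a_grid, dtype=np.float64)
    mu_s_prime_grid = np.asarray(mu_s_prime_grid, dtype=np.float64)
    fx_grid = np.asarray(fx_grid, dtype=np.float64)
    edges = settings.bin_edges

    base = None
    if not settings.independent_runs:
        base = run_white_mc(
            1.0,
            g=settings.g,
            n=settings.n,
            n_photons=settings.n_photons,
            seed=settings.seed,
            max_path=settings.max_path,
            roulette_weight=settings.roulette_weight,
        )

    rd = np.empty((len(mu_a_grid), len(mu_s_prime_grid), len(fx_grid)))
    for j, musp in enumerate(mu_s_prime_grid):
        if settings.independent_runs:
            records = run_white_mc(
                float(musp),
                g=settings.g,
                n=settings.n,
                n_photons=settings.n_photons,
                seed=settings.seed + j,
                max_path=settings.max_path,
                roulette_weight=settings.roulette_weight,
            )
        else:
            records = base.rescaled(1.0 / float(musp))
        for i, mua in enumerate(mu_a_grid):
            radial = apply_absorption(records, float(mua), edges)
            rd[i, j, :] = hankel_to_fx(radial, fx_grid)

    rd = np.clip(rd, 0.0, 1.0)
    meta = {
        "n_photons": settings.n_photons,
        "seed": settings.seed,
        "g": settings.g,
        "n": settings.n,
        "max_path": settings.max_path,
        "n_bins": settings.n_bins,
        "dr": settings.dr,
        "independent_runs": settings.independent_runs,
    }
    return ReflectanceTable(mu_a_grid, mu_s_prime_grid, fx_grid, rd, meta)


def _bilinear_log(table: ReflectanceTable, mu_a: float, mu_s_prime: float) -> tuple:
    """Bracketing indices and weights in (log mu_a, log mu_s')."""
    ag = table.mu_a_grid
    sg = table.mu_s_prime_grid
    if not ag[0] <= mu_a <= ag[-1]:
        raise ValueError(
            f"mu_a={mu_a} outside table range [{ag[0]}, {ag[-1]}] (axis mu_a)"
        )
    if not sg[0] <= mu_s_prime <= sg[-1]:
        raise ValueError(
            f"mu_s_prime={mu_s_prime} outside table range "
            f"[{sg[0]}, {sg[-1]}] (axis mu_s_prime)"
        )
    ia = min(int(np.searchsorted(ag, mu_a, side="right")) - 1, len(ag) - 2)
    ia = max(ia, 0)
    js = min(int(np.searchsorted(sg, mu_s_prime, side="right")) - 1, len(sg) - 2)
    js = max(js, 0)
    la = np.log(max(mu_a, 1e-300))
    ta = (la - np.log(ag[ia])) / (np.log(ag[ia + 1]) - np.log(ag[ia]))
    ts = (np.log(mu_s_prime) - np.log(sg[js])) / (
        np.log(sg[js + 1]) - np.log(sg[js])
    )
    if mu_a == ag[ia]:
        ta = 0.0
    return ia, js, float(np.clip(ta, 0.0, 1.0)), float(np.clip(ts, 0.0, 1.0))


def lookup_rd(
    table: ReflectanceTable, props: OpticalProperties, fx_list: Sequence[float]
) -> np.ndarray:
    """Interpolated Rd at the requested properties and tabulated fx values.

    Bilinear in (log mu_a, log mu_s'); exact at grid nodes.  Raises a
    range error naming the offending axis for out-of-bounds queries.
    """
    ia, js, ta, ts = _bilinear_log(table, props.mu_a, props.mu_s_prime)
    ks = [table.fx_index(f) for f in np.atleast_1d(np.asarray(fx_list, dtype=float))]
    sub = table.rd[ia : ia + 2, js : js + 2, :][:, :, ks]
    top = sub[0, 0] * (1 - ts) + sub[0, 1] * ts
    bot = sub[1, 0] * (1 - ts) + sub[1, 1] * ts
    return top * (1 - ta) + bot * ta
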