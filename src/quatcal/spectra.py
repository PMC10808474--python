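"""Synthetic UV absorption spectra for the four-component mixture.

Pure-component curves are parametric stand-ins built from Gaussian bands
plus a short-wavelength exponential end-absorption term; they are tuned so
the four components overlap severely on the shared analysis window, the
regime the real mixture presents.  Mixtures follow Beer-Lambert additivity
at 1 cm path length with additive homoscedastic Gaussian noise.

All analysis grids use an exclusive upper endpoint, so the 210-300 nm
window at 1.0 nm spacing holds 90 variables and 210-340 nm holds 130.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ANALYTES

__all__ = [
    "WavelengthGrid",
    "BandSpec",
    "PureSpectrum",
    "SpectralDataset",
    "make_grid",
    "pure_spectrum",
    "default_library",
    "simulate_mixtures",
    "restrict",
    "write_spectra_csv",
    "read_spectra_csv",
    "DEFAULT_NOISE_SD",
    "FULL_SCAN",
    "ANALYSIS_WINDOWS",
]

#: Default additive noise standard deviation, absorbance units.
DEFAULT_NOISE_SD = 0.002

#: Full instrument scan: 200-400 nm at 0.2 nm, endpoints included.
FULL_SCAN = (200.0, 400.0, 0.2)

#: Per-analyte analysis windows (nm), exclusive upper endpoint at 1.0 nm.
ANALYSIS_WINDOWS: dict[str, tuple[float, float]] = {
    "CAF": (210.0, 300.0),
    "COD": (210.0, 300.0),
    "PAR": (210.0, 300.0),
    "PAP": (210.0, 340.0),
}


@dataclass(frozen=True)
class WavelengthGrid:
    start: float
    stop: float
    step: float
    endpoint_mode: str = "exclusive"
    points: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_points(self) -> int:
        return len(self.points)


def make_grid(start: float, stop: float, step: float,
              endpoint_mode: str = "exclusive") -> WavelengthGrid:
    """Uniform wavelength grid.

    ``exclusive`` mode yields floor((stop-start)/step) points starting at
    ``start``; ``inclusive`` adds the upper endpoint.
    """
    if step <= 0:
        raise ValueError("invalid-grid: step must be positive")
    if stop <= start:
        raise ValueError("invalid-grid: stop must exceed start")
    if endpoint_mode not in ("inclusive", "exclusive"):
        raise ValueError("invalid-grid: endpoint_mode must be inclusive or exclusive")
    span = round((stop - start) / step, 9)
    n = int(np.floor(span + 1e-9))
    if endpoint_mode == "inclusive":
        n += 1
    pts = start + step * np.arange(n)
    pts.setflags(write=False)
    return WavelengthGrid(start, stop, step, endpoint_mode, pts)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``amplitude`` is the specific absorbance at the band centre, in AU per
    (µg/mL) at 1 cm path; ``width`` is the Gaussian sigma in nm.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("invalid-band: width must be positive")
        if self.amplitude < 0:
            raise ValueError("invalid-band: amplitude must be non-negative")


@dataclass(frozen=True)
class PureSpectrum:
    """Per-wavelength specific absorbance of one component (AU·mL·µg⁻¹)."""

    analyte: str
    grid: WavelengthGrid
    curve: np.ndarray
    bands: tuple[BandSpec, ...]
    end_absorption: tuple[float, float]  # (amplitude AU·mL·µg⁻¹, decay nm)


def pure_spectrum(bands, end_absorption: tuple[float, float],
                  grid: WavelengthGrid, analyte: str = "") -> PureSpectrum:
    """Evaluate Gaussian bands + exponential end absorption on a grid.

    curve(λ) = Σ_b amp·exp(−(λ−center)²/(2·width²))
             + end_amp·exp(−(λ−grid.start)/decay)
    """
    bands = tuple(bands)
    lam = grid.points
    curve = np.zeros_like(lam)
    for b in bands:
        if b.width <= 0:
            raise ValueError("invalid-band: width must be positive")
        curve = curve + b.amplitude * np.exp(-((lam - b.center) ** 2) / (2.0 * b.width ** 2))
    end_amp, decay = end_absorption
    if end_amp != 0.0:
        curve = curve + end_amp * np.exp(-(lam - grid.start) / decay)
    curve.setflags(write=False)
    return PureSpectrum(analyte, grid, curve, bands, (float(end_amp), float(decay)))


# Synthetic band libraries; parameters are package constants chosen so the
# four curves overlap severely on 210-300 nm (pairwise cosine >= 0.5) while
# PAP alone retains signal out to ~320 nm and none absorbs past 340 nm.
_LIBRARY_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    # (center nm, sigma nm, amplitude AU·mL·µg⁻¹)
    "CAF": ((273.0, 14.0, 0.100), (225.0, 10.0, 0.035)),
    "COD": ((284.0, 12.0, 0.050), (240.0, 14.0, 0.020)),
    "PAR": ((243.0, 16.0, 0.125), (280.0, 12.0, 0.020)),
    "PAP": ((230.0, 12.0, 0.095), (298.0, 12.0, 0.080)),
}

_LIBRARY_END: dict[str, tuple[float, float]] = {
    # (amplitude at 200 nm, decay constant nm): strong sub-210 end absorption
    "CAF": (0.60, 11.0),
    "COD": (0.80, 12.0),
    "PAR": (0.55, 11.0),
    "PAP": (0.50, 10.0),
}


def default_library(grid: WavelengthGrid) -> tuple[PureSpectrum, ...]:
    """The four synthetic pure spectra (CAF, COD, PAR, PAP) on ``grid``."""
    if grid.points[0] > 210.0 or grid.points[-1] < 339.0:
        raise ValueError("invalid-grid: library grid must span at least 210-340 nm")
    return tuple(
        pure_spectrum(
            [BandSpec(*b) for b in _LIBRARY_BANDS[a]],
            _LIBRARY_END[a],
            grid,
            analyte=a,
        )
        for a in ANALYTES
    )


@dataclass(frozen=True)
class SpectralDataset:
    """Absorbance matrix (samples x wavelengths) with its concentrations."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    concentrations: np.ndarray
    noise_sd: float
    seed: int | None
    sample_ids: tuple = ()

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.points

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]


def simulate_mixtures(
    concentrations: np.ndarray,
    library: tuple[PureSpectrum, ...],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    sample_ids: tuple = (),
) -> SpectralDataset:
    """Beer-Lambert mixture spectra with additive Gaussian noise.

    absorbance = concentrations · pure-curves + N(0, noise_sd²) i.i.d.
    """
    conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if conc.shape[1] != len(library):
        raise ValueError("invalid-input: one concentration column per library entry required")
    if np.any(conc < 0):
        raise ValueError("invalid-input: concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("invalid-input: noise_sd must be non-negative")
    grid = library[0].grid
    for s in library:
        if s.grid.n_points != grid.n_points or not np.array_equal(s.grid.points, grid.points):
            raise ValueError("invalid-input: library spectra must share one grid")
    S = np.vstack([s.curve for s in library])          # 4 x p
    A = conc @ S
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    A.setflags(write=False)
    if not sample_ids:
        sample_ids = tuple(range(1, conc.shape[0] + 1))
    return SpectralDataset(grid, A, conc.copy(), float(noise_sd), seed, tuple(sample_ids))


def restrict(dataset: SpectralDataset, window: tuple[float, float]) -> SpectralDataset:
    """Restrict a dataset to an analysis window on the 1.0 nm exclusive grid.

    The target wavelengths start..stop-1 nm must all be present in the
    dataset's grid (subsampling a finer scan is the usual case).
    """
    start, stop = window
    target = make_grid(start, stop, 1.0, "exclusive")
    have = dataset.grid.points
    idx = []
    for lam in target.points:
        j = np.argmin(np.abs(have - lam))
        if abs(have[j] - lam) > 1e-6:
            raise ValueError(f"invalid-window: wavelength {lam} nm not on the dataset grid")
        idx.append(j)
    idx = np.asarray(idx)
    A = dataset.absorbance[:, idx].copy()
    A.setflags(write=False)
    return SpectralDataset(
        target, A, dataset.concentrations, dataset.noise_sd, dataset.seed,
        dataset.sample_ids,
    )


def write_spectra_csv(dataset: SpectralDataset, path) -> None:
    """CSV layout: first column wavelength_nm, one column per sample."""
    cols = {"wavelength_nm": dataset.grid.points}
    for i, sid in enumerate(dataset.sample_ids):
        cols[str(sid)] = dataset.absorbance[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectra_csv(path, concentrations: np.ndarray | None = None) -> SpectralDataset:
    """Read spectra written by :func:`write_spectra_csv`."""
    df = pd.read_csv(path)
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    step = float(np.round(np.diff(lam).mean(), 9)) if len(lam) > 1 else 1.0
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), step, "inclusive", lam)
    sample_cols = [c for c in df.columns if c != "wavelength_nm"]
    A = df[sample_cols].to_numpy(dtype=float).T
    if concentrations is None:
        concentrations = np.full((len(sample_cols), len(ANALYTES)), np.nan)
    return SpectralDataset(grid, A, np.asarray(concentrations, dtype=float),
                           np.nan, None, tuple(sample_cols))
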