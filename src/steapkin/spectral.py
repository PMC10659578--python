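"""Absorption spectra of redox species and Beer-Lambert mixture composition.

Heme and flavin species are represented on a common wavelength grid as sums
of Gaussian bands (center, FWHM, peak molar absorptivity).  Ferric b-type
heme shows a Soret band at 413 nm and a broad Q band near 550 nm; on
reduction the Soret shifts to 427 nm and sharp alpha/beta bands appear at
560 and 532 nm.  These landmarks parameterize the reference library used by
the synthetic-data generators; the absolute extinction scale is a
placeholder (flagged in metadata) because only band positions, not
coefficients, are constrained.

Units throughout: wavelength nm, concentration uM, pathlength cm,
molar absorptivity mM^-1 cm^-1, absorbance AU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GaussianBand",
    "SpeciesSpectrum",
    "SpeciesLibrary",
    "build_species_spectrum",
    "compose_absorbance",
    "find_isosbestic",
    "default_grid",
    "reference_library",
]

#: 4 ln 2 — converts FWHM to the Gaussian exponent denominator.
_FOUR_LN2 = 4.0 * np.log(2.0)

REDOX_STATES = frozenset(
    {"ferric", "ferrous", "oxidized_flavin", "reduced_flavin", "other"}
)


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band.

    Parameters
    ----------
    center_nm : float
        Band center, nm; must lie in the visible/near-UV window [300, 800].
    fwhm_nm : float
        Full width at half maximum, nm (> 0).
    peak_epsilon : float
        Molar absorptivity at the center, mM^-1 cm^-1 (>= 0).
    """

    center_nm: float
    fwhm_nm: float
    peak_epsilon: float

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise ValueError(f"fwhm_nm must be > 0, got {self.fwhm_nm}")
        if self.peak_epsilon < 0:
            raise ValueError(f"peak_epsilon must be >= 0, got {self.peak_epsilon}")
        if not 300.0 <= self.center_nm <= 800.0:
            raise ValueError(
                f"center_nm must be within [300, 800] nm, got {self.center_nm}"
            )

    def epsilon(self, grid_nm: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavelength grid."""
        d = np.asarray(grid_nm, dtype=float) - self.center_nm
        return self.peak_epsilon * np.exp(-_FOUR_LN2 * d * d / self.fwhm_nm**2)


def _validate_grid(grid_nm: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid_nm, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wavelength grid must be a nonempty 1-D array")
    if grid.size > 1:
        steps = np.diff(grid)
        if np.any(steps <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("wavelength grid must be uniformly spaced")
    return grid


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Molar absorptivity of one redox species on a uniform wavelength grid."""

    name: str
    redox_state: str
    grid_nm: np.ndarray
    epsilon: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        grid = _validate_grid(self.grid_nm)
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != grid.shape:
            raise ValueError(
                f"epsilon length {eps.size} != grid length {grid.size}"
            )
        if np.any(eps < 0):
            raise ValueError("epsilon must be nonnegative everywhere")
        if self.redox_state not in REDOX_STATES:
            raise ValueError(
                f"redox_state {self.redox_state!r} not in {sorted(REDOX_STATES)}"
            )
        object.__setattr__(self, "grid_nm", grid)
        object.__setattr__(self, "epsilon", eps)

    def peak_wavelength(self) -> float:
        """Wavelength of maximum absorptivity, nm."""
        return float(self.grid_nm[int(np.argmax(self.epsilon))])


class SpeciesLibrary:
    """Named set of species spectra sharing one wavelength grid."""

    def __init__(self, entries: Iterable[SpeciesSpectrum] = ()) -> None:
        self._entries: dict[str, SpeciesSpectrum] = {}
        for spec in entries:
            self.add(spec)

    def add(self, spec: SpeciesSpectrum) -> None:
        if spec.name in self._entries:
            raise ValueError(f"duplicate species name {spec.name!r}")
        if self._entries:
            ref = next(iter(self._entries.values()))
            if not np.array_equal(ref.grid_nm, spec.grid_nm):
                raise ValueError(
                    f"species {spec.name!r} grid differs from library grid"
                )
        self._entries[spec.name] = spec

    def __getitem__(self, name: str) -> SpeciesSpectrum:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def grid_nm(self) -> np.ndarray:
        if not self._entries:
            raise ValueError("empty library has no grid")
        return next(iter(self._entries.values())).grid_nm

    def epsilon_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_wavelengths, n_species) absorptivity matrix, column order `names`."""
        names = list(names) if names is not None else self.names
        missing = [n for n in names if n not in self._entries]
        if missing:
            raise KeyError(f"species not in library: {missing}")
        return np.column_stack([self._entries[n].epsilon for n in names])


def default_grid(start_nm: float = 350.0, stop_nm: float = 700.0,
                 step_nm: float = 1.0) -> np.ndarray:
    """Default wavelength grid: 350-700 nm at 1 nm spacing."""
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


def build_species_spectrum(bands: Sequence[GaussianBand], grid_nm,
                           name: str, redox_state: str = "other",
                           meta: dict | None = None) -> SpeciesSpectrum:
    """Sum Gaussian bands into a species spectrum on `grid_nm`.

    An empty band list yields an all-zero spectrum.  Band centers must lie
    within the grid range.
    """
    grid = _validate_grid(grid_nm)
    eps = np.zeros_like(grid)
    # summation in a canonical band order makes the result exactly
    # independent of the order bands were supplied in
    key = lambda b: (b.center_nm, b.fwhm_nm, b.peak_epsilon)
    for band in sorted(bands, key=key):
        if not grid[0] <= band.center_nm <= grid[-1]:
            raise ValueError(
                f"band center {band.center_nm} nm outside grid "
                f"[{grid[0]}, {grid[-1]}] nm"
            )
        eps += band.epsilon(grid)
    return SpeciesSpectrum(name=name, redox_state=redox_state, grid_nm=grid,
                           epsilon=eps, meta=dict(meta or {}))


def compose_absorbance(library: SpeciesLibrary,
                       concentrations: Mapping[str, float],
                       pathlength_cm: float = 1.0) -> np.ndarray:
    """Beer-Lambert absorbance of a mixture: A(l) = sum_i eps_i(l) c_i d.

    Concentrations are in uM; epsilon is per mM, so c is divided by 1000.
    Linear and homogeneous in every concentration.
    """
    if pathlength_cm <= 0:
        raise ValueError("pathlength_cm must be positive")
    absorbance = np.zeros_like(library.grid_nm, dtype=float)
    for name, c_uM in concentrations.items():
        if name not in library:
            raise KeyError(f"unknown species {name!r}")
        if c_uM < 0:
            raise ValueError(f"negative concentration for {name!r}: {c_uM}")
        absorbance += library[name].epsilon * (c_uM / 1000.0) * pathlength_cm
    return absorbance


def find_isosbestic(spec_a: SpeciesSpectrum, spec_b: SpeciesSpectrum,
                    tol: float = 1e-6) -> np.ndarray:
    """Wavelengths where two species have (near-)equal absorptivity.

    Returns grid points with |eps_a - eps_b| < tol plus linearly
    interpolated sign-change crossings between adjacent grid points.  At an
    isosbestic wavelength the total absorbance of a closed two-species
    interconversion is time-invariant.
    """
    if not np.array_equal(spec_a.grid_nm, spec_b.grid_nm):
        raise ValueError("spectra must share one wavelength grid")
    grid = spec_a.grid_nm
    diff = spec_a.epsilon - spec_b.epsilon
    points = list(grid[np.abs(diff) < tol])
    # interpolated zero crossings strictly between grid points
    s = np.sign(diff)
    for i in np.flatnonzero(s[:-1] * s[1:] < 0):
        lam = grid[i] + (grid[i + 1] - grid[i]) * diff[i] / (diff[i] - diff[i + 1])
        points.append(float(lam))
    return np.unique(np.asarray(points, dtype=float))


# --- reference species library -------------------------------------------

# Band positions follow the ferric/ferrous landmarks of STEAP hemes (Soret
# 413 -> 427 nm; broad ferric Q ~550 nm; ferrous alpha/beta 560/532 nm) and
# generic oxidized-flavin bands (~375/450 nm).  Peak extinction values are
# placeholders on a plausible b-type-heme scale, flagged in metadata.
_PLACEHOLDER = {"epsilon_source": "placeholder"}

_REFERENCE_BANDS: dict[str, tuple[str, list[GaussianBand]]] = {
    "ferric_heme": ("ferric", [
        GaussianBand(413.0, 30.0, 100.0),
        GaussianBand(550.0, 100.0, 10.0),
    ]),
    "ferrous_heme": ("ferrous", [
        GaussianBand(427.0, 22.0, 100.0),
        GaussianBand(560.0, 14.0, 18.0),
        GaussianBand(532.0, 18.0, 12.0),
    ]),
    "fad_ox": ("oxidized_flavin", [
        GaussianBand(450.0, 45.0, 11.3),
        GaussianBand(375.0, 40.0, 9.6),
    ]),
    "fadh_red": ("reduced_flavin", [
        GaussianBand(400.0, 80.0, 2.0),
    ]),
    "b5r_ox": ("oxidized_flavin", [
        GaussianBand(461.0, 45.0, 10.2),
        GaussianBand(390.0, 40.0, 9.0),
    ]),
    "b5r_red": ("reduced_flavin", [
        GaussianBand(420.0, 70.0, 1.8),
    ]),
}


def reference_library(grid_nm: np.ndarray | None = None) -> SpeciesLibrary:
    """Library of heme/flavin species used by the synthetic fixtures."""
    grid = default_grid() if grid_nm is None else _validate_grid(grid_nm)
    lib = SpeciesLibrary()
    for name, (state, bands) in _REFERENCE_BANDS.items():
        lib.add(build_species_spectrum(bands, grid, name, state,
                                       meta=dict(_PLACEHOLDER)))
    return lib
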