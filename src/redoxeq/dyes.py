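"""Redox species and the indicator-dye registry.

An optical redox titration pairs the protein of interest with an indicator
(mediator) dye: a chromophoric couple of known midpoint potential that
equilibrates with the protein in bulk solution and whose colour change in the
500-700 nm region reports the solution potential.  This module defines the
:class:`RedoxSpecies` container used for both partners and a small,
user-extensible registry of dyes.

The three registered dyes and their potentials (mV vs NHE, pH 7):

========================================  ======  ===
toluidine blue O                             +34    2
2,6-dichlorophenolindophenol (DCPIP)        +217    2
Nile blue                                   -116    2
========================================  ======  ===

The electron numbers are the conventional two-electron/two-proton couples of
these phenothiazine/indophenol/phenoxazine chromophores.  They are explicit,
per-run-overridable configuration, never a silent assumption: a wrong n shows
up directly in the free-slope Nernst-plot diagnostic.

Dye spectra here are synthetic: a single Gaussian absorption band of the
oxidized (coloured) form centred in the 500-700 nm window, with a colourless
reduced (leuco) form.  Band centres/widths are package constants chosen to be
typical of these dye families, not measured values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ValidationError

#: synthetic peak extinction of registered dye bands, AU µM^-1 cm^-1
#: (0.08 AU/µM == 80 mM^-1 cm^-1, typical of strongly coloured redox dyes)
DYE_PEAK_EPS = 0.08

Spectrum = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: centre (nm), sigma (nm), peak ε (AU/µM)."""

    center_nm: float
    sigma_nm: float
    eps_peak: float

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        z = (wl - self.center_nm) / self.sigma_nm
        return self.eps_peak * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class BandSpectrum:
    """Sum of Gaussian bands; callable ε(λ) in AU µM⁻¹ (1 cm path)."""

    bands: tuple[GaussianBand, ...]

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for band in self.bands:
            out += band(wl)
        return out


ZERO_SPECTRUM = BandSpectrum(bands=())


@dataclass(frozen=True)
class RedoxSpecies:
    """One redox couple (protein or dye) and its optical signatures.

    Parameters
    ----------
    name
        Species name as reported.
    E_m_mV
        Midpoint potential in mV vs NHE.
    n
        Electrons transferred per couple (positive integer).
    concentration_uM
        Concentration in µM; 0 marks a registry template that has not yet
        been dosed into a simulated cuvette.
    spectrum_ox, spectrum_red
        Molar absorptivity ε(λ) of the oxidized / reduced forms, callables
        returning AU µM⁻¹ per cm of path on any wavelength grid.
    """

    name: str
    E_m_mV: float
    n: int
    concentration_uM: float = 0.0
    spectrum_ox: Spectrum = ZERO_SPECTRUM
    spectrum_red: Spectrum = ZERO_SPECTRUM

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValidationError(
                f"{self.name}: electron number n must be a positive integer, "
                f"got {self.n!r}"
            )
        if self.concentration_uM < 0:
            raise ValidationError(
                f"{self.name}: concentration must be >= 0 µM"
            )
        if not np.isfinite(self.E_m_mV):
            raise ValidationError(f"{self.name}: E_m must be finite")

    @property
    def capacity_uM_electrons(self) -> float:
        """Electron capacity n·C of the couple, µM electrons."""
        return self.n * self.concentration_uM

    def with_concentration(self, concentration_uM: float) -> "RedoxSpecies":
        return replace(self, concentration_uM=concentration_uM)

    def validate_on_grid(self, wavelengths: np.ndarray) -> None:
        """Check both spectra evaluate finite and non-negative on a grid."""
        for label, spec in (("ox", self.spectrum_ox), ("red", self.spectrum_red)):
            eps = np.asarray(spec(wavelengths), dtype=float)
            if eps.shape != np.shape(wavelengths):
                raise ValidationError(
                    f"{self.name}: {label} spectrum not defined on the "
                    "requested wavelength grid"
                )
            if not np.all(np.isfinite(eps)) or np.any(eps < 0):
                raise ValidationError(
                    f"{self.name}: {label} spectrum must be finite and "
                    "non-negative"
                )


@dataclass(frozen=True)
class _DyeRecord:
    name: str
    synonyms: tuple[str, ...]
    E_m_mV: float
    n: int
    band_center_nm: float
    band_width_nm: float

    def to_species(self) -> RedoxSpecies:
        band = GaussianBand(self.band_center_nm, self.band_width_nm, DYE_PEAK_EPS)
        return RedoxSpecies(
            name=self.name,
            E_m_mV=self.E_m_mV,
            n=self.n,
            concentration_uM=0.0,
            spectrum_ox=BandSpectrum(bands=(band,)),
            spectrum_red=ZERO_SPECTRUM,  # leuco (colourless) reduced form
        )


class DyeRegistry:
    """Case-insensitive name/synonym lookup of indicator dyes."""

    def __init__(self) -> None:
        self._records: dict[str, _DyeRecord] = {}
        self._index: dict[str, str] = {}  # lowercase name/synonym -> canonical

    def load_table(self, path: str | Path, overwrite: bool = True) -> None:
        """Load dyes from a CSV table.

        Columns: ``name, synonyms, E_m_mV, n, band_center_nm, band_width_nm``
        with synonyms separated by semicolons.
        """
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                record = _DyeRecord(
                    name=row["name"].strip(),
                    synonyms=tuple(
                        s.strip() for s in row["synonyms"].split(";") if s.strip()
                    ),
                    E_m_mV=float(row["E_m_mV"]),
                    n=int(row["n"]),
                    band_center_nm=float(row["band_center_nm"]),
                    band_width_nm=float(row["band_width_nm"]),
                )
                self._add(record, overwrite=overwrite)

    def _add(self, record: _DyeRecord, overwrite: bool) -> None:
        key = record.name.lower()
        if key in self._index and not overwrite:
            raise ValidationError(
                f"dye {record.name!r} already registered "
                "(pass overwrite=True to replace)"
            )
        self._records[record.name] = record
        for alias in (record.name, *record.synonyms):
            self._index[alias.lower()] = record.name

    def register(self, species: RedoxSpecies, *, band_center_nm: float = 630.0,
                 band_width_nm: float = 30.0, synonyms: tuple[str, ...] = (),
                 overwrite: bool = False) -> None:
        """Register a dye template from a :class:`RedoxSpecies`."""
        record = _DyeRecord(
            name=species.name,
            synonyms=synonyms,
            E_m_mV=species.E_m_mV,
            n=species.n,
            band_center_nm=band_center_nm,
            band_width_nm=band_width_nm,
        )
        self._add(record, overwrite=overwrite)

    def names(self) -> list[str]:
        return sorted(self._records)

    def get(self, name: str) -> RedoxSpecies:
        key = name.strip().lower()
        if key not in self._index:
            raise ValidationError(
                f"unknown dye {name!r}; registered dyes: "
                + ", ".join(self.names())
            )
        return self._records[self._index[key]].to_species()


def _load_default_registry() -> DyeRegistry:
    registry = DyeRegistry()
    with resources.as_file(
        resources.files("redoxeq").joinpath("data/dyes.csv")
    ) as path:
        registry.load_table(path)
    return registry


_DEFAULT_REGISTRY: DyeRegistry | None = None


def default_registry() -> DyeRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = _load_default_registry()
    return _DEFAULT_REGISTRY


def get_dye(name: str) -> RedoxSpecies:
    """Look up a dye template (zero concentration) in the default registry.

    Lookup is case-insensitive and accepts listed synonyms (e.g. ``DCPIP``).
    Unknown names raise an error listing the registered dyes.
    """
    return default_registry().get(name)


def register_dye(species: RedoxSpecies, *, band_center_nm: float = 630.0,
                 band_width_nm: float = 30.0, synonyms: tuple[str, ...] = (),
                 overwrite: bool = False) -> None:
    """Add a dye to the default registry so later :func:`get_dye` calls see it."""
    default_registry().register(
        species,
        band_center_nm=band_center_nm,
        band_width_nm=band_width_nm,
        synonyms=synonyms,
        overwrite=overwrite,
    )
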