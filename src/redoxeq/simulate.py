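"""Forward model of a dye-equilibration redox titration.

The experiment being emulated: a cuvette holds a ferric heme protein and an
indicator dye in anaerobic buffer; xanthine oxidase slowly injects electrons
(two per xanthine oxidised to uric acid) into the solution, and both couples
co-reduce while UV-vis spectra are scanned every minute.  Once the spectra are
stable, excess sodium dithionite fully reduces everything, giving the
fully-reduced endpoint reference.

The model is a quasi-equilibrium one: electron exchange between protein and
dye in bulk solution is fast compared with enzymatic injection, so at every
scan both couples share a single solution potential E.  Given the cumulative
injected electrons e(t), that potential is the unique root of the electron
balance

    sum_i  n_i * C_i * f_red_i(E)  =  e(t),
    f_red_i(E) = 1 / (1 + exp(n_i * F * (E - E_m_i) / (R T))),

which is monotone in E and solved by bracketed 1-D root finding.  Spectra are
then rendered by Beer-Lambert mixing of the oxidized and reduced basis
spectra of each species, plus iid Gaussian instrument noise.

No enzyme kinetics are modelled: the electron source is an abstract injection
profile (constant-rate by default, approximating zero-order turnover at
saturating xanthine).  Oxygen scavenging chemistry is outside the model; the
simulated cuvette is anaerobic by construction.  All heme and dye band shapes
are synthetic package constants (the emulated instrument is not calibrated
against any real extinction coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.constants import R as GAS_CONSTANT  # J mol^-1 K^-1
from scipy.constants import physical_constants
from scipy.optimize import brentq
from scipy.special import expit

from .dyes import BandSpectrum, GaussianBand, RedoxSpecies
from .errors import ValidationError
from .spectra_io import (
    PHASE_DITHIONITE,
    PHASE_TITRATION,
    ExperimentMeta,
    SpectralTimeSeries,
)

FARADAY = physical_constants["Faraday constant"][0]  # C mol^-1

#: default analysis wavelength grid, nm (UV-vis instrument convention)
DEFAULT_GRID = np.arange(350.0, 751.0, 1.0)

# Synthetic heme basis spectra (AU µM^-1 cm^-1).  Ferric: Soret at 413 nm
# with a weak visible band at 533 nm; ferrous: Soret shifted to 430 nm with
# increased amplitude and a visible band at 556 nm.  Peak positions follow
# the ferric maxima reported for heme-reconstituted PAS-A domains; widths and
# amplitudes are fixed package constants in the range typical of b-type hemes.
HEME_OX_BANDS = (
    GaussianBand(center_nm=413.0, sigma_nm=11.0, eps_peak=0.150),
    GaussianBand(center_nm=533.0, sigma_nm=10.0, eps_peak=0.011),
)
HEME_RED_BANDS = (
    GaussianBand(center_nm=430.0, sigma_nm=12.0, eps_peak=0.170),
    GaussianBand(center_nm=556.0, sigma_nm=12.0, eps_peak=0.012),
)

HEME_SPECTRUM_OX = BandSpectrum(bands=HEME_OX_BANDS)
HEME_SPECTRUM_RED = BandSpectrum(bands=HEME_RED_BANDS)


def default_heme_spectra(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic ferric/ferrous heme spectra evaluated on a wavelength grid.

    The grid must cover at least 380-600 nm so that both Soret forms and the
    visible bands are represented.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] > 380.0 or grid[-1] < 600.0:
        raise ValidationError(
            "wavelength grid must cover 380-600 nm for heme basis spectra"
        )
    return HEME_SPECTRUM_OX(grid), HEME_SPECTRUM_RED(grid)


def heme_protein(
    name: str,
    E_m_mV: float,
    n: int = 1,
    concentration_uM: float = 4.0,
) -> RedoxSpecies:
    """A heme protein species with the package's synthetic basis spectra.

    Defaults: one-electron Fe(III)/Fe(II) couple, 4 µM protein (absorbance in
    the 0.1-1.0 range at the Soret maximum for a 1 cm path).
    """
    return RedoxSpecies(
        name=name,
        E_m_mV=E_m_mV,
        n=n,
        concentration_uM=concentration_uM,
        spectrum_ox=HEME_SPECTRUM_OX,
        spectrum_red=HEME_SPECTRUM_RED,
    )


# ---------------------------------------------------------------------------
# equilibrium partition
# ---------------------------------------------------------------------------


def _beta_per_mV(temperature_K: float) -> float:
    """F/(RT) expressed per millivolt."""
    if not temperature_K > 0:
        raise ValidationError(f"temperature must be > 0 K, got {temperature_K}")
    return FARADAY / (1000.0 * GAS_CONSTANT * temperature_K)


def reduced_fraction(
    E_mV: float | np.ndarray,
    E_m_mV: float,
    n: int,
    temperature_K: float,
) -> np.ndarray:
    """Nernstian reduced fraction of a couple at solution potential E."""
    beta = _beta_per_mV(temperature_K)
    return expit(-n * beta * (np.asarray(E_mV, dtype=float) - E_m_mV))


def equilibrium_partition(
    e_total_uM: float,
    species: Sequence[RedoxSpecies],
    temperature_K: float = 298.15,
) -> tuple[float, np.ndarray]:
    """Partition a pool of injected electrons among co-equilibrated couples.

    Returns the unique solution potential E (mV vs NHE) at which the summed
    reduced-electron content of all couples equals ``e_total_uM``, together
    with the per-species reduced fractions at that potential.  Electron
    conservation holds to better than 1e-9 µM.

    The boundary cases ``e_total = 0`` and ``e_total = capacity`` have no
    finite potential; they return ``+inf`` / ``-inf`` with fractions exactly
    0 / 1.
    """
    caps = np.array([s.capacity_uM_electrons for s in species], dtype=float)
    capacity = caps.sum()
    if capacity <= 0:
        raise ValidationError(
            "equilibrium partition needs at least one species with C > 0"
        )
    if not (-1e-9 <= e_total_uM <= capacity + 1e-9):
        raise ValidationError(
            f"e_total={e_total_uM} µM outside [0, capacity={capacity}] µM"
        )
    if e_total_uM <= 0:
        return np.inf, np.zeros(len(species))
    if e_total_uM >= capacity:
        return -np.inf, np.ones(len(species))

    beta = _beta_per_mV(temperature_K)
    E_ms = np.array([s.E_m_mV for s in species], dtype=float)
    ns = np.array([s.n for s in species], dtype=float)

    def balance(E: float) -> float:
        return float(np.sum(caps * expit(-ns * beta * (E - E_ms)))) - e_total_uM

    # balance() is strictly decreasing in E; expand the bracket until it
    # straddles the root.
    margin = 500.0
    lo, hi = E_ms.min() - margin, E_ms.max() + margin
    while balance(lo) < 0:
        lo -= margin
    while balance(hi) > 0:
        hi += margin
    E = brentq(balance, lo, hi, xtol=1e-10, rtol=8.9e-16)
    fractions = expit(-ns * beta * (E - E_ms))
    return float(E), fractions


# ---------------------------------------------------------------------------
# injection profiles
# ---------------------------------------------------------------------------

INJECTION_PROFILES = ("constant", "exponential_approach")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated titration run.

    ``injection_rate_uM_per_min`` and ``electron_budget_uM`` may be left as
    ``None``; :meth:`resolved` fills them (budget = total couple capacity;
    rate such that the budget is delivered over the first three quarters of
    the titration, leaving a stable tail that satisfies the 10-minute
    constancy criterion).  A dye template with zero concentration is
    auto-titrated so its band maximum matches the protein's Soret maximum,
    mirroring the bench procedure of matching dye and protein absorbances.
    """

    protein: RedoxSpecies
    dye: RedoxSpecies
    temperature_K: float = 298.15
    scan_interval_min: float = 1.0
    n_scans: int = 40
    injection_rate_uM_per_min: float | None = None
    injection_profile: str = "constant"
    electron_budget_uM: float | None = None
    noise_sd_AU: float = 0.002
    endpoint_scans: int = 10
    path_length_cm: float = 1.0
    seed: int | None = None
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self) -> None:
        if self.n_scans < 4:
            raise ValidationError("n_scans must be >= 4")
        if self.endpoint_scans < 1:
            raise ValidationError(
                "endpoint_scans must be >= 1 (the dithionite endpoint block "
                "is required by endpoint-based analysis)"
            )
        if self.scan_interval_min <= 0:
            raise ValidationError("scan_interval_min must be > 0")
        if self.noise_sd_AU < 0:
            raise ValidationError("noise_sd_AU must be >= 0")
        if self.path_length_cm <= 0:
            raise ValidationError("path_length_cm must be > 0")
        if self.injection_profile not in INJECTION_PROFILES:
            raise ValidationError(
                f"injection_profile must be one of {INJECTION_PROFILES}"
            )
        if self.noise_sd_AU > 0 and self.seed is None:
            raise ValidationError(
                "a seed is mandatory for stochastic simulations "
                "(noise_sd_AU > 0)"
            )
        if (
            self.injection_rate_uM_per_min is not None
            and self.injection_rate_uM_per_min < 0
        ):
            raise ValidationError("injection_rate_uM_per_min must be >= 0")
        if self.electron_budget_uM is not None and self.electron_budget_uM < 0:
            raise ValidationError("electron_budget_uM must be >= 0")
        if not self.temperature_K > 0:
            raise ValidationError("temperature_K must be > 0")

    def resolved(self) -> "SimulationConfig":
        """Fill derived defaults (dye dose, electron budget, injection rate)."""
        grid = np.asarray(self.wavelengths, dtype=float)
        protein = self.protein
        protein.validate_on_grid(grid)
        dye = self.dye
        if dye.concentration_uM == 0.0:
            dye_peak = float(np.max(dye.spectrum_ox(grid)))
            if dye_peak <= 0:
                raise ValidationError(
                    f"cannot auto-titrate dye {dye.name!r}: its oxidized "
                    "spectrum has no absorbance on the grid"
                )
            protein_peak = float(
                np.max(protein.spectrum_ox(grid)) * protein.concentration_uM
            )
            dye = dye.with_concentration(protein_peak / dye_peak)
        dye.validate_on_grid(grid)
        capacity = protein.capacity_uM_electrons + dye.capacity_uM_electrons
        budget = self.electron_budget_uM
        if budget is None:
            budget = capacity
        rate = self.injection_rate_uM_per_min
        if rate is None:
            titration_span = self.n_scans * self.scan_interval_min
            rate = budget / (0.75 * titration_span)
        return replace(
            self,
            dye=dye,
            electron_budget_uM=budget,
            injection_rate_uM_per_min=rate,
        )


def injected_electrons(t_min: float, config: SimulationConfig) -> float:
    """Cumulative injected electrons (µM) at time t.

    Non-decreasing in t; capped at the electron budget and at the total
    couple capacity.  The constant profile is ``rate * t`` (zero-order
    enzymatic turnover); ``exponential_approach`` is
    ``budget * (1 - exp(-rate * t / budget))`` (substrate depletion).
    """
    if t_min < 0:
        raise ValidationError("time must be >= 0")
    cfg = config
    if cfg.injection_rate_uM_per_min is None or cfg.electron_budget_uM is None:
        cfg = config.resolved()
    rate = cfg.injection_rate_uM_per_min
    budget = cfg.electron_budget_uM
    capacity = (
        cfg.protein.capacity_uM_electrons + cfg.dye.capacity_uM_electrons
    )
    if cfg.injection_profile == "constant":
        e = rate * t_min
    else:  # exponential_approach
        e = budget * -np.expm1(-rate * t_min / budget) if budget > 0 else 0.0
    return float(min(e, budget, capacity))


# ---------------------------------------------------------------------------
# spectral rendering
# ---------------------------------------------------------------------------


def render_spectrum(
    fractions_red: Sequence[float],
    species: Sequence[RedoxSpecies],
    wavelengths: np.ndarray,
    path_length_cm: float = 1.0,
) -> np.ndarray:
    """Beer-Lambert mixture spectrum for given per-species reduced fractions.

    ``A(λ) = path * Σ_i C_i [(1 - f_i) ε_ox,i(λ) + f_i ε_red,i(λ)]`` —
    linear in every fraction.
    """
    grid = np.asarray(wavelengths, dtype=float)
    fr = np.asarray(fractions_red, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValidationError("reduced fractions must lie in [0, 1]")
    A = np.zeros_like(grid)
    for f, sp in zip(fr, species, strict=True):
        sp.validate_on_grid(grid)
        A += sp.concentration_uM * (
            (1.0 - f) * np.asarray(sp.spectrum_ox(grid))
            + f * np.asarray(sp.spectrum_red(grid))
        )
    return path_length_cm * A


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """The simulator's hidden state: what an analysis should recover."""

    times: np.ndarray
    phase_labels: np.ndarray
    potential_mV: np.ndarray
    f_red_protein: np.ndarray
    f_red_dye: np.ndarray
    injected_uM: np.ndarray
    config: SimulationConfig


def simulate_run(
    config: SimulationConfig,
) -> tuple[SpectralTimeSeries, GroundTruth]:
    """Run the forward model: titration scans, then a dithionite block.

    Every titration scan evaluates the injection profile, solves the shared
    potential, renders the mixture spectrum and adds iid Gaussian noise.
    The dithionite block renders both species fully reduced (excess chemical
    reductant) with the same noise model, continuing the same time axis.
    Returns the noisy observable series and the noiseless ground truth.
    """
    cfg = config.resolved()
    grid = np.asarray(cfg.wavelengths, dtype=float)
    species = (cfg.protein, cfg.dye)

    t_titr = np.arange(cfg.n_scans) * cfg.scan_interval_min
    t_endp = (cfg.n_scans + np.arange(cfg.endpoint_scans)) * cfg.scan_interval_min
    times = np.concatenate([t_titr, t_endp])
    phases = np.array(
        [PHASE_TITRATION] * cfg.n_scans + [PHASE_DITHIONITE] * cfg.endpoint_scans,
        dtype=object,
    )

    potentials = np.empty(times.size)
    f_protein = np.empty(times.size)
    f_dye = np.empty(times.size)
    injected = np.empty(times.size)
    A = np.empty((grid.size, times.size))

    for j, t in enumerate(t_titr):
        e = injected_electrons(t, cfg)
        E, fr = equilibrium_partition(e, species, cfg.temperature_K)
        injected[j] = e
        potentials[j] = E
        f_protein[j], f_dye[j] = fr
        A[:, j] = render_spectrum(fr, species, grid, cfg.path_length_cm)

    reduced_spectrum = render_spectrum(
        (1.0, 1.0), species, grid, cfg.path_length_cm
    )
    for k in range(cfg.endpoint_scans):
        j = cfg.n_scans + k
        injected[j] = np.nan  # dithionite electrons are not metered
        potentials[j] = -np.inf
        f_protein[j] = f_dye[j] = 1.0
        A[:, j] = reduced_spectrum

    if cfg.noise_sd_AU > 0:
        rng = np.random.default_rng(cfg.seed)
        A = A + rng.normal(0.0, cfg.noise_sd_AU, size=A.shape)

    ts = SpectralTimeSeries(
        wavelengths=grid,
        times=times,
        absorbance=A,
        phase_labels=phases,
        meta=ExperimentMeta(
            temperature_K=cfg.temperature_K,
            pH=7.0,
            dye_name=cfg.dye.name,
            protein_name=cfg.protein.name,
        ),
    )
    truth = GroundTruth(
        times=times,
        phase_labels=phases,
        potential_mV=potentials,
        f_red_protein=f_protein,
        f_red_dye=f_dye,
        injected_uM=injected,
        config=cfg,
    )
    return ts, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as ``# key: value`` front matter plus a table.

    Kept in a separate file from the observable spectra so that analysis code
    can never read the answer by accident.
    """
    cfg = truth.config
    fmt = "{:.12g}".format
    lines = [
        f"# protein_name: {cfg.protein.name}",
        f"# protein_E_m_mV: {fmt(cfg.protein.E_m_mV)}",
        f"# protein_n: {cfg.protein.n}",
        f"# protein_concentration_uM: {fmt(cfg.protein.concentration_uM)}",
        f"# dye_name: {cfg.dye.name}",
        f"# dye_E_m_mV: {fmt(cfg.dye.E_m_mV)}",
        f"# dye_n: {cfg.dye.n}",
        f"# dye_concentration_uM: {fmt(cfg.dye.concentration_uM)}",
        f"# temperature_K: {fmt(cfg.temperature_K)}",
        f"# injection_profile: {cfg.injection_profile}",
        f"# injection_rate_uM_per_min: {fmt(cfg.injection_rate_uM_per_min)}",
        f"# electron_budget_uM: {fmt(cfg.electron_budget_uM)}",
        f"# noise_sd_AU: {fmt(cfg.noise_sd_AU)}",
        f"# seed: {cfg.seed}",
        "time_min,phase,potential_mV,f_red_protein,f_red_dye,injected_uM",
    ]
    for j in range(truth.times.size):
        lines.append(
            ",".join(
                [
                    fmt(truth.times[j]),
                    str(truth.phase_labels[j]),
                    fmt(truth.potential_mV[j]),
                    fmt(truth.f_red_protein[j]),
                    fmt(truth.f_red_dye[j]),
                    fmt(truth.injected_uM[j]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
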