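"""Spectral time-series containers and delimited-text I/O.

The central record of a dye-equilibration redox titration is an absorbance
matrix A(lambda, t): rows are wavelengths in nm, columns are scans at times in
minutes measured from the addition of xanthine oxidase (the electron-injection
start).  Each scan carries a phase label: ``titration`` while electrons are
being injected enzymatically, ``dithionite`` for the excess-reductant endpoint
block recorded after the titration has stabilised.  The dithionite block is the
fully-reduced absorbance reference that endpoint-fraction analysis requires.

Two delimited-text dialects are supported:

* ``wide`` (default) — one column per scan, a ``phase`` row under the header::

      # temperature_K: 298.15
      # pH: 7.0
      wavelength_nm,t=0.0,t=1.0,...
      phase,titration,titration,...,dithionite
      350.0,0.0123,...

* ``long`` — one row per cell, columns
  ``wavelength_nm,time_min,absorbance,phase``.

Metadata travels as a front-matter block of ``# key: value`` comment lines.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ParseError, ValidationError

PHASE_TITRATION = "titration"
PHASE_DITHIONITE = "dithionite"
_PHASES = (PHASE_TITRATION, PHASE_DITHIONITE)

#: numeric formatting used for all written floats; round-trips < 1e-9 AU
_FLOAT_FMT = "{:.12g}"


@dataclass(frozen=True)
class ExperimentMeta:
    """Experimental metadata attached to a spectral time series.

    Potentials downstream are always reported against the normal hydrogen
    electrode; the ``reference_electrode`` field exists so that files are
    self-describing, and any other value is rejected.
    """

    temperature_K: float = 298.15
    pH: float = 7.0
    dye_name: str = ""
    protein_name: str = ""
    reference_electrode: str = "NHE"

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValidationError(
                f"temperature must be positive kelvin, got {self.temperature_K}"
            )
        if self.reference_electrode != "NHE":
            raise ValidationError(
                "reference_electrode must be 'NHE' "
                f"(got {self.reference_electrode!r}); potentials in this "
                "package are defined versus the normal hydrogen electrode"
            )


@dataclass
class SpectralTimeSeries:
    """Absorbance matrix over (wavelength, time) with per-scan phase labels.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    times
        Strictly increasing scan times in minutes from xanthine-oxidase
        addition; dithionite-phase scans continue the same clock.
    absorbance
        Matrix of shape ``(len(wavelengths), len(times))`` in absorbance
        units (AU).
    phase_labels
        Per-scan tags, each ``"titration"`` or ``"dithionite"``.
    meta
        Experiment metadata.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    absorbance: np.ndarray
    phase_labels: np.ndarray
    meta: ExperimentMeta = field(default_factory=ExperimentMeta)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels, dtype=object)
        if self.wavelengths.ndim != 1 or self.times.ndim != 1:
            raise ValidationError("wavelengths and times must be 1-D")
        if self.absorbance.shape != (self.wavelengths.size, self.times.size):
            raise ValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{self.wavelengths.size} wavelengths x {self.times.size} times"
            )
        if self.phase_labels.shape != self.times.shape:
            raise ValidationError("one phase label per scan time is required")
        unknown = set(self.phase_labels) - set(_PHASES)
        if unknown:
            raise ValidationError(f"unknown phase labels: {sorted(unknown)}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance matrix contains non-finite values")
        if np.any(self.wavelengths < 0) or np.any(self.times < 0):
            raise ValidationError("wavelengths and times must be non-negative")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    # -- phase helpers ---------------------------------------------------
    @property
    def titration_mask(self) -> np.ndarray:
        return self.phase_labels == PHASE_TITRATION

    @property
    def dithionite_mask(self) -> np.ndarray:
        return self.phase_labels == PHASE_DITHIONITE

    def require_dithionite(self) -> None:
        """Raise unless at least one dithionite-phase scan is present."""
        if not np.any(self.dithionite_mask):
            raise ValidationError(
                "endpoint-based analysis requires at least one scan tagged "
                "'dithionite' (fully reduced reference); none found"
            )


@dataclass(frozen=True)
class Trace:
    """A single-wavelength absorbance time course extracted from a series."""

    times: np.ndarray
    absorbance: np.ndarray
    phase_labels: np.ndarray
    wavelength_requested: float
    wavelength_used: float


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_META_FIELDS = {
    "temperature_K": float,
    "pH": float,
    "dye_name": str,
    "protein_name": str,
    "reference_electrode": str,
}


def _meta_lines(meta: ExperimentMeta) -> list[str]:
    out = []
    for name in _META_FIELDS:
        value = getattr(meta, name)
        if isinstance(value, float):
            value = _FLOAT_FMT.format(value)
        out.append(f"# {name}: {value}")
    return out


def _parse_front_matter(lines: list[str]) -> tuple[ExperimentMeta, int]:
    """Consume leading ``# key: value`` lines; return (meta, n_consumed)."""
    kwargs: dict[str, object] = {}
    n = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n += 1
        body = line.lstrip("#").strip()
        if not body:
            continue
        if ":" not in body:
            raise ParseError(f"malformed metadata line {n}: {line!r}")
        key, _, value = body.partition(":")
        key = key.strip()
        value = value.strip()
        if key not in _META_FIELDS:
            continue  # unknown metadata keys are carried over silently
        caster = _META_FIELDS[key]
        try:
            kwargs[key] = caster(value)
        except ValueError as exc:
            raise ParseError(
                f"metadata line {n}: cannot parse {key}={value!r}"
            ) from exc
    return ExperimentMeta(**kwargs), n


def _parse_cell(text: str, row: int, col: int) -> float:
    text = text.strip()
    if text == "":
        raise ParseError(f"blank absorbance cell at row {row}, column {col}")
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(
            f"non-numeric cell {text!r} at row {row}, column {col}"
        ) from exc


def _sort_by_time(
    times: np.ndarray, absorbance: np.ndarray, phases: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(times, kind="stable")
    times = times[order]
    if np.any(np.diff(times) == 0):
        dup = times[np.flatnonzero(np.diff(times) == 0)[0]]
        raise ParseError(f"duplicate scan time {dup} min")
    return times, absorbance[:, order], phases[order]


def read_timeseries(path: str | Path, dialect: str = "wide") -> SpectralTimeSeries:
    """Read a delimited-text spectral time series.

    Times are sorted on read (columns permuted consistently); duplicate
    (wavelength, time) cells are an error.  Malformed headers, blank or
    non-numeric cells raise :class:`ParseError` naming the offending cell.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, n_meta = _parse_front_matter(lines)
    body = lines[n_meta:]
    if not body:
        raise ParseError(f"{path}: no data after front matter")
    if dialect == "wide":
        return _read_wide(body, meta, n_meta)
    if dialect == "long":
        return _read_long(body, meta, n_meta)
    raise ValidationError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")


def _read_wide(
    body: list[str], meta: ExperimentMeta, offset: int
) -> SpectralTimeSeries:
    rows = list(csv.reader(io.StringIO("\n".join(body))))
    header = rows[0]
    if not header or header[0].strip() != "wavelength_nm":
        raise ParseError(
            f"wide header row {offset + 1}: first column must be "
            f"'wavelength_nm', got {header[:1]!r}"
        )
    times = []
    for j, cell in enumerate(header[1:], start=2):
        cell = cell.strip()
        if not cell.startswith("t="):
            raise ParseError(
                f"wide header column {j}: expected 't=<minutes>', got {cell!r}"
            )
        times.append(_parse_cell(cell[2:], offset + 1, j))
    if len(rows) < 2 or not rows[1] or rows[1][0].strip() != "phase":
        raise ParseError(
            f"row {offset + 2}: missing 'phase' row with per-scan phase labels"
        )
    phases = [c.strip() for c in rows[1][1:]]
    if len(phases) != len(times):
        raise ParseError(
            f"row {offset + 2}: {len(phases)} phase labels for "
            f"{len(times)} scan columns"
        )
    wavelengths = []
    matrix = []
    for i, row in enumerate(rows[2:], start=offset + 3):
        if not row:
            continue
        if len(row) != len(times) + 1:
            raise ParseError(
                f"row {i}: expected {len(times) + 1} cells, got {len(row)}"
            )
        wavelengths.append(_parse_cell(row[0], i, 1))
        matrix.append([_parse_cell(c, i, j) for j, c in enumerate(row[1:], 2)])
    times_a, absorb, phases_a = _sort_by_time(
        np.array(times, dtype=float),
        np.array(matrix, dtype=float),
        np.array(phases, dtype=object),
    )
    return SpectralTimeSeries(
        wavelengths=np.array(wavelengths, dtype=float),
        times=times_a,
        absorbance=absorb,
        phase_labels=phases_a,
        meta=meta,
    )


def _read_long(
    body: list[str], meta: ExperimentMeta, offset: int
) -> SpectralTimeSeries:
    rows = list(csv.reader(io.StringIO("\n".join(body))))
    expected = ["wavelength_nm", "time_min", "absorbance", "phase"]
    if [c.strip() for c in rows[0]] != expected:
        raise ParseError(
            f"long header row {offset + 1}: expected {expected}, got {rows[0]}"
        )
    cells: dict[tuple[float, float], float] = {}
    phase_of: dict[float, str] = {}
    for i, row in enumerate(rows[1:], start=offset + 2):
        if not row:
            continue
        if len(row) != 4:
            raise ParseError(f"row {i}: expected 4 cells, got {len(row)}")
        wl = _parse_cell(row[0], i, 1)
        t = _parse_cell(row[1], i, 2)
        a = _parse_cell(row[2], i, 3)
        phase = row[3].strip()
        if phase == "":
            raise ParseError(f"missing phase label at row {i}, column 4")
        if (wl, t) in cells:
            raise ParseError(
                f"row {i}: duplicate (wavelength, time) cell ({wl}, {t})"
            )
        if t in phase_of and phase_of[t] != phase:
            raise ParseError(
                f"row {i}: conflicting phase labels for time {t} min"
            )
        cells[(wl, t)] = a
        phase_of[t] = phase
    wavelengths = np.array(sorted({wl for wl, _ in cells}), dtype=float)
    times = np.array(sorted({t for _, t in cells}), dtype=float)
    absorb = np.empty((wavelengths.size, times.size))
    for i, wl in enumerate(wavelengths):
        for j, t in enumerate(times):
            if (wl, t) not in cells:
                raise ParseError(
                    f"missing cell for wavelength {wl} nm, time {t} min"
                )
            absorb[i, j] = cells[(wl, t)]
    phases = np.array([phase_of[t] for t in times], dtype=object)
    return SpectralTimeSeries(
        wavelengths=wavelengths,
        times=times,
        absorbance=absorb,
        phase_labels=phases,
        meta=meta,
    )


def write_timeseries(
    ts: SpectralTimeSeries, path: str | Path, dialect: str = "wide"
) -> None:
    """Write a spectral time series; output is byte-stable for fixed inputs."""
    path = Path(path)
    lines = _meta_lines(ts.meta)
    f = _FLOAT_FMT.format
    if dialect == "wide":
        lines.append(
            "wavelength_nm," + ",".join(f"t={f(t)}" for t in ts.times)
        )
        lines.append("phase," + ",".join(str(p) for p in ts.phase_labels))
        for i, wl in enumerate(ts.wavelengths):
            lines.append(
                f(wl) + "," + ",".join(f(a) for a in ts.absorbance[i])
            )
    elif dialect == "long":
        lines.append("wavelength_nm,time_min,absorbance,phase")
        for i, wl in enumerate(ts.wavelengths):
            for j, t in enumerate(ts.times):
                lines.append(
                    f"{f(wl)},{f(t)},{f(ts.absorbance[i, j])},"
                    f"{ts.phase_labels[j]}"
                )
    else:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# trace extraction and stability
# ---------------------------------------------------------------------------


def extract_trace(ts: SpectralTimeSeries, wavelength: float) -> Trace:
    """Return the absorbance time course at the grid point nearest a request.

    No interpolation is performed: the returned trace is an exact column of
    the stored matrix, which keeps analyses reproducible.  A midpoint tie
    between two grid wavelengths resolves to the lower wavelength.  Requests
    outside the recorded wavelength range are an error.
    """
    wl = ts.wavelengths
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ValidationError(
            f"wavelength {wavelength} nm outside recorded range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    dist = np.abs(wl - wavelength)
    idx = int(np.argmin(dist))  # argmin takes the first (lower-λ) minimum
    return Trace(
        times=ts.times.copy(),
        absorbance=ts.absorbance[idx].copy(),
        phase_labels=ts.phase_labels.copy(),
        wavelength_requested=float(wavelength),
        wavelength_used=float(wl[idx]),
    )


def assess_stability(
    times: np.ndarray | Iterable[float],
    values: np.ndarray | Iterable[float],
    window: float = 10.0,
    tol: float = 0.002,
) -> float | None:
    """Earliest time from which a trace stays within ``tol`` to its end.

    Emulates the experimental rule "spectra remained constant for at least
    *window* minutes": returns the earliest t0 such that the trace over
    [t0, end] spans at least ``window`` minutes and its max-min range does
    not exceed ``tol`` AU.  Returns ``None`` when no such t0 exists.
    """
    times = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                       dtype=float)
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                        dtype=float)
    if times.size == 0:
        raise ValidationError("empty trace")
    if times.size != values.size:
        raise ValidationError("times and values must have the same length")
    span = times[-1] - times[0]
    if window > span:
        raise ValidationError(
            f"stability window {window} min exceeds trace span {span} min"
        )
    # suffix running extrema: range of values[i:] for each i
    suff_max = np.maximum.accumulate(values[::-1])[::-1]
    suff_min = np.minimum.accumulate(values[::-1])[::-1]
    ok = (suff_max - suff_min <= tol) & (times[-1] - times >= window)
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return None
    return float(times[hits[0]])


def to_frame(ts: SpectralTimeSeries):
    """Long-format :class:`pandas.DataFrame` view (for plotting/inspection)."""
    import pandas as pd

    wl, t = np.meshgrid(ts.wavelengths, ts.times, indexing="ij")
    return pd.DataFrame(
        {
            "wavelength_nm": wl.ravel(),
            "time_min": t.ravel(),
            "absorbance": ts.absorbance.ravel(),
            "phase": np.repeat(
                ts.phase_labels[np.newaxis, :], ts.wavelengths.size, axis=0
            ).ravel(),
        }
    )


def copy_with(ts: SpectralTimeSeries, **updates) -> SpectralTimeSeries:
    """Return a validated copy of ``ts`` with fields replaced."""
    fields = dict(
        wavelengths=ts.wavelengths,
        times=ts.times,
        absorbance=ts.absorbance,
        phase_labels=ts.phase_labels,
        meta=ts.meta,
    )
    fields.update(updates)
    return SpectralTimeSeries(**fields)
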