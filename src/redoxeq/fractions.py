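"""From absorbance traces to oxidized-fraction time series.

The analysis follows the single-wavelength endpoint procedure: the heme is
followed at a wavelength where the dye contribution is negligible (typically
400-420 nm, on the Soret band), the dye in the 500-700 nm region where its
absorbance change dominates.  With A_ox the fully-oxidized reference (the
first scan, before significant enzymatic reduction) and A_red the
fully-reduced dithionite endpoint, the oxidized fraction at each scan is

    f_ox(t) = (A(t) - A_red) / (A_ox - A_red).

Raw (unclipped) fractions are retained throughout; a [0, 1]-clipped copy
exists for display only.  The log-ratio filter for the Nernst plot operates
on the raw values, dropping (never clipping) points outside the fraction
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AnalysisError, StabilityError, ValidationError
from .nernst import NernstDataset
from .spectra_io import (
    SpectralTimeSeries,
    Trace,
    assess_stability,
    extract_trace,
)

#: default fraction window retained for log-ratio analysis
DEFAULT_FRACTION_WINDOW = (0.1, 0.9)

#: default wavelength search windows (nm): heme Soret region / dye region
DEFAULT_PROTEIN_WINDOW = (400.0, 420.0)
DEFAULT_DYE_WINDOW = (500.0, 700.0)


@dataclass(frozen=True)
class RedoxFractionSeries:
    """Per-time oxidized fraction of one species during the titration phase."""

    times: np.ndarray
    f_ox: np.ndarray          # clipped to [0, 1], for display
    raw_f_ox: np.ndarray      # unclipped, used for filtering and fitting
    species: str
    wavelength_nm: float
    A_ox: float
    A_red: float

    def to_csv(self, path: str | Path) -> None:
        fmt = "{:.12g}".format
        lines = ["time_min,f_ox_raw,f_ox,species,wavelength_nm"]
        for j in range(self.times.size):
            lines.append(
                f"{fmt(self.times[j])},{fmt(self.raw_f_ox[j])},"
                f"{fmt(self.f_ox[j])},{self.species},{fmt(self.wavelength_nm)}"
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _robust_noise_scale(values: np.ndarray) -> float:
    """Noise scale from median absolute successive differences (MAD-style).

    Successive differencing removes slow titration drift; the 1.4826/sqrt(2)
    factor calibrates the estimator to the Gaussian standard deviation.
    """
    diffs = np.diff(np.asarray(values, dtype=float))
    if diffs.size == 0:
        return 0.0
    return float(np.median(np.abs(diffs)) * 1.4826 / np.sqrt(2.0))


def _rms_diff_noise(values: np.ndarray) -> float:
    """Noise scale from root-mean-square successive differences.

    Less robust to outliers than the median version but far less variable on
    short blocks, and positively correlated with the block's range — which
    makes range-versus-tolerance stability checks well behaved on as few as
    ten scans.
    """
    diffs = np.diff(np.asarray(values, dtype=float))
    if diffs.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(diffs**2) / 2.0))


def endpoint_fractions(
    trace: Trace,
    A_ox: float,
    A_red: float,
    species: str = "",
    noise_scale: float | None = None,
) -> RedoxFractionSeries:
    """Convert a titration-phase trace to oxidized fractions via endpoints.

    Requires a usable dynamic range: |A_ox - A_red| must exceed five times
    the noise scale (estimated from the trace itself when not supplied).
    Only titration-phase scans enter the returned series.
    """
    span = A_ox - A_red
    if noise_scale is None:
        noise_scale = _robust_noise_scale(trace.absorbance)
    if abs(span) <= 5.0 * noise_scale or span == 0.0:
        raise AnalysisError(
            f"degenerate endpoints for {species or 'trace'} at "
            f"{trace.wavelength_used:g} nm: |A_ox - A_red| = {abs(span):.4g} "
            f"AU is within 5x the noise scale ({noise_scale:.4g} AU)"
        )
    titr = trace.phase_labels == "titration"
    raw = (trace.absorbance[titr] - A_red) / span
    return RedoxFractionSeries(
        times=trace.times[titr],
        f_ox=np.clip(raw, 0.0, 1.0),
        raw_f_ox=raw,
        species=species,
        wavelength_nm=trace.wavelength_used,
        A_ox=float(A_ox),
        A_red=float(A_red),
    )


@dataclass(frozen=True)
class EndpointEstimate:
    """Endpoint absorbances with their standard errors and averaging counts."""

    A_ox: float
    A_red: float
    se_ox: float
    se_red: float
    n_ox: int
    n_red: int
    noise_sd_AU: float  # per-scan noise estimate at this wavelength


def estimate_endpoints(
    ts: SpectralTimeSeries,
    wavelength: float,
    k_ox: int = 1,
    stability_window_min: float = 5.0,
    stability_tol_AU: float | None = None,
) -> EndpointEstimate:
    """Endpoint absorbances plus uncertainty bookkeeping at one wavelength.

    A_ox is the mean of the first ``k_ox`` titration scans (k_ox=1 by
    default; raise it for noisy data).  A_red is the mean of the stable tail
    of the dithionite phase: the post-dithionite spectra must hold constant
    for at least ``stability_window_min`` minutes within
    ``stability_tol_AU``, mirroring the bench endpoint criterion.

    ``stability_tol_AU=None`` (default) sets the tolerance to eight times a
    robust noise estimate from the dithionite trace itself: the stability
    test compares the *range* of the block, and the range of ~10 noisy scans
    routinely reaches several standard deviations even when the chemistry is
    at rest.  A noiseless trace gets a zero tolerance and must be exactly
    constant.
    """
    ts.require_dithionite()
    trace = extract_trace(ts, wavelength)
    titr = trace.phase_labels == "titration"
    dith = trace.phase_labels == "dithionite"
    if not np.any(titr):
        raise ValidationError("time series has no titration-phase scans")
    if k_ox < 1:
        raise ValidationError("k_ox must be >= 1")
    A_ox = float(np.mean(trace.absorbance[titr][:k_ox]))

    t_d = trace.times[dith]
    a_d = trace.absorbance[dith]
    if stability_tol_AU is None:
        stability_tol_AU = 8.0 * _rms_diff_noise(a_d)
    window = min(stability_window_min, t_d[-1] - t_d[0]) if t_d.size > 1 else 0.0
    t0 = assess_stability(t_d, a_d, window=window, tol=stability_tol_AU)
    if t0 is None:
        raise StabilityError(
            f"dithionite phase never stable within {stability_tol_AU} AU "
            f"over {window} min at {trace.wavelength_used:g} nm; consider "
            "increasing stability_tol_AU"
        )
    tail = a_d[t_d >= t0]
    A_red = float(np.mean(tail))
    sigma = _rms_diff_noise(a_d)
    return EndpointEstimate(
        A_ox=A_ox,
        A_red=A_red,
        se_ox=sigma / np.sqrt(k_ox),
        se_red=sigma / np.sqrt(tail.size),
        n_ox=int(min(k_ox, np.count_nonzero(titr))),
        n_red=int(tail.size),
        noise_sd_AU=sigma,
    )


def pick_endpoints(
    ts: SpectralTimeSeries,
    wavelength: float,
    k_ox: int = 1,
    stability_window_min: float = 5.0,
    stability_tol_AU: float | None = None,
) -> tuple[float, float]:
    """Oxidized and reduced endpoint absorbances (see :func:`estimate_endpoints`)."""
    est = estimate_endpoints(
        ts,
        wavelength,
        k_ox=k_ox,
        stability_window_min=stability_window_min,
        stability_tol_AU=stability_tol_AU,
    )
    return est.A_ox, est.A_red


def choose_wavelengths(
    ts: SpectralTimeSeries,
    protein_window: tuple[float, float] = DEFAULT_PROTEIN_WINDOW,
    dye_window: tuple[float, float] = DEFAULT_DYE_WINDOW,
) -> tuple[float, float]:
    """Analysis wavelengths maximizing the oxidized-to-reduced change.

    Within each window the wavelength with the largest
    |A(λ, first titration scan) - A(λ, dithionite endpoint)| is chosen, the
    dithionite endpoint being the mean over the endpoint block (robust to
    scan noise).  Ties resolve to the lower wavelength.  Windows given in
    reversed order are normalized.
    """
    ts.require_dithionite()
    first = np.flatnonzero(ts.titration_mask)
    if first.size == 0:
        raise ValidationError("time series has no titration-phase scans")
    a_first = ts.absorbance[:, first[0]]
    a_red = ts.absorbance[:, ts.dithionite_mask].mean(axis=1)
    change = np.abs(a_first - a_red)

    def pick(window: tuple[float, float], label: str) -> float:
        lo, hi = sorted(window)
        mask = (ts.wavelengths >= lo) & (ts.wavelengths <= hi)
        if not np.any(mask):
            raise ValidationError(
                f"empty {label} window [{lo}, {hi}] nm on grid "
                f"[{ts.wavelengths[0]}, {ts.wavelengths[-1]}] nm"
            )
        idx = np.flatnonzero(mask)
        return float(ts.wavelengths[idx[np.argmax(change[idx])]])

    return pick(protein_window, "protein"), pick(dye_window, "dye")


def pair_fractions(
    protein: RedoxFractionSeries,
    dye: RedoxFractionSeries,
    window: tuple[float, float] = DEFAULT_FRACTION_WINDOW,
) -> NernstDataset:
    """Pair protein and dye fractions into Nernst-plot coordinates.

    Keeps titration times at which BOTH raw oxidized fractions lie inside
    the window (default [0.1, 0.9]; log-ratios amplify endpoint noise
    without bound outside it), then emits x = log10(f_ox/(1-f_ox)) for the
    dye and y for the protein.  Fewer than 4 surviving points means the
    titration never swept the overlap region of the two couples.
    """
    lo, hi = sorted(window)
    if not (0.0 < lo < hi < 1.0):
        raise ValidationError(
            f"fraction window must satisfy 0 < lo < hi < 1, got ({lo}, {hi})"
        )
    if protein.times.shape != dye.times.shape or not np.allclose(
        protein.times, dye.times
    ):
        raise ValidationError(
            "protein and dye fraction series must share one time grid"
        )
    fp = protein.raw_f_ox
    fd = dye.raw_f_ox
    keep = (fp >= lo) & (fp <= hi) & (fd >= lo) & (fd <= hi)
    if np.count_nonzero(keep) < 4:
        from .errors import InsufficientCoverageError

        raise InsufficientCoverageError(
            f"insufficient titration coverage: only {np.count_nonzero(keep)} "
            f"scans have both fractions inside [{lo}, {hi}] (need >= 4); "
            "the dye and protein potentials may be too far apart or the "
            "titration too fast"
        )
    logit10 = lambda f: np.log10(f / (1.0 - f))  # noqa: E731
    return NernstDataset(
        x=logit10(fd[keep]),
        y=logit10(fp[keep]),
        times=protein.times[keep],
        protein_wavelength_nm=protein.wavelength_nm,
        dye_wavelength_nm=dye.wavelength_nm,
        fraction_window=(lo, hi),
    )
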