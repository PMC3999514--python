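"""Nernst-plot fitting: from paired log-ratios to a midpoint potential.

Each couple obeys the Nernst equation at the shared solution potential E:

    E = E_m,p + (k / n_p) * log10([ox]_p / [red]_p)
    E = E_m,d + (k / n_d) * log10([ox]_d / [red]_d)

with k = RT ln(10) / F the Nernst slope factor (59.16 mV per decade at
298.15 K).  Eliminating E between the two couples makes the protein
log-ratio y linear in the dye log-ratio x:

    y = (n_p / n_d) * x + n_p * (E_m,d - E_m,p) / k

so the slope is the electron-number ratio and the intercept b carries the
potential difference; the protein midpoint potential is recovered as

    E_m,p = E_m,d - b * k / n_p   (mV vs NHE).

By default the slope is FIXED at the theoretical ratio n_p/n_d (electron
counts are known chemistry) and only b is estimated; the free-slope fit is
retained as a stoichiometry diagnostic — a fitted slope far from n_p/n_d
flags a wrong electron-number assumption.  Fitting both parameters on the
narrow log-ratio range of a typical titration destabilizes E_m, which is why
free mode is diagnostic rather than default.

Uncertainty is reported two ways, since the error treatment behind the
conventional "±2 mV" of bench reports is method-dependent: a residual-based
standard error on the intercept propagated to E_m, and a nonparametric
case-resampling bootstrap percentile interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants

from .errors import AnalysisError, ValidationError

FARADAY = physical_constants["Faraday constant"][0]


def nernst_slope_factor(temperature_K: float) -> float:
    """RT ln(10)/F in mV per decade (per electron).

    59.16 mV/decade at 298.15 K; linear in absolute temperature.
    """
    if not temperature_K > 0:
        raise ValidationError(
            f"temperature must be > 0 K, got {temperature_K}"
        )
    return 1000.0 * GAS_CONSTANT * temperature_K * np.log(10.0) / FARADAY


@dataclass(frozen=True)
class NernstDataset:
    """Paired, filtered log-ratio points: dye on x, protein on y."""

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    protein_wavelength_nm: float = float("nan")
    dye_wavelength_nm: float = float("nan")
    fraction_window: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.x.shape != self.y.shape or self.x.shape != self.times.shape:
            raise ValidationError("x, y and times must have equal length")
        if self.x.size < 4:
            raise ValidationError(
                f"a Nernst dataset needs at least 4 points, got {self.x.size}"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("log-ratio coordinates must be finite")


@dataclass(frozen=True)
class NernstFit:
    """Result of a Nernst-plot fit, all potentials in mV vs NHE."""

    slope: float
    intercept: float
    slope_mode: str                  # "fixed" or "free"
    E_m_mV: float
    E_m_se_mV: float
    E_m_ci95_mV: tuple[float, float]
    r_squared: float
    n_points: int
    temperature_K: float
    dye_E_m_mV: float
    n_protein: int
    n_dye: int
    slope_se: float = float("nan")   # populated in free mode
    slope_theory: float = float("nan")


def _intercept_to_Em(
    intercept: float, dye_E_m_mV: float, n_protein: int, temperature_K: float
) -> float:
    k = nernst_slope_factor(temperature_K)
    return dye_E_m_mV - intercept * k / n_protein


def fit_nernst(
    data: NernstDataset,
    dye_E_m_mV: float,
    n_protein: int = 1,
    n_dye: int = 2,
    temperature_K: float = 298.15,
    slope_mode: str = "fixed",
) -> NernstFit:
    """Fit y = s·x + b and convert the intercept to the protein's E_m.

    ``slope_mode="fixed"`` (default) pins s at the theoretical n_p/n_d and
    estimates b by least squares; ``"free"`` fits both by ordinary least
    squares and reports the fitted slope against the theoretical ratio.
    The intercept's residual-based standard error is propagated to
    ``E_m_se_mV`` and a Student-t 95% interval.
    """
    if slope_mode not in ("fixed", "free"):
        raise ValidationError("slope_mode must be 'fixed' or 'free'")
    if n_protein < 1 or n_dye < 1:
        raise ValidationError("electron numbers must be positive integers")
    x, y = data.x, data.y
    n = x.size
    s_theory = n_protein / n_dye
    k = nernst_slope_factor(temperature_K)

    if slope_mode == "fixed":
        s = s_theory
        b = float(np.mean(y - s * x))
        resid = y - s * x - b
        dof = n - 1
        se_b = float(np.std(resid, ddof=1) / np.sqrt(n))
        slope_se = float("nan")
    else:
        if np.ptp(x) == 0.0:
            raise AnalysisError(
                "free-slope fit impossible: zero variance in dye log-ratios"
            )
        res = stats.linregress(x, y)
        s, b = float(res.slope), float(res.intercept)
        resid = y - s * x - b
        dof = n - 2
        se_b = float(res.intercept_stderr)
        slope_se = float(res.stderr)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    E_m = _intercept_to_Em(b, dye_E_m_mV, n_protein, temperature_K)
    E_se = se_b * k / n_protein
    t_crit = float(stats.t.ppf(0.975, dof)) if dof > 0 else float("inf")
    ci = (E_m - t_crit * E_se, E_m + t_crit * E_se)

    return NernstFit(
        slope=float(s),
        intercept=b,
        slope_mode=slope_mode,
        E_m_mV=float(E_m),
        E_m_se_mV=float(E_se),
        E_m_ci95_mV=(float(ci[0]), float(ci[1])),
        r_squared=float(r2),
        n_points=int(n),
        temperature_K=float(temperature_K),
        dye_E_m_mV=float(dye_E_m_mV),
        n_protein=int(n_protein),
        n_dye=int(n_dye),
        slope_se=slope_se,
        slope_theory=float(s_theory),
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile confidence interval for E_m from bootstrap resampling."""

    ci95_mV: tuple[float, float]
    B: int
    n_failed: int
    widened: bool  # True when > 10% of resamples failed to fit
    seed: int


@dataclass(frozen=True)
class EndpointNoise:
    """Endpoint uncertainty of one species' fraction scale.

    ``delta_A`` is the dynamic range A_ox - A_red (AU); ``se_ox`` and
    ``se_red`` are the standard errors of the two endpoint absorbances.
    Endpoint errors rescale and shift ALL fractions of a replicate
    coherently — a shared error that resampling of (x, y) pairs alone is
    blind to, which is why the pipeline's bootstrap draws them explicitly.
    """

    delta_A: float
    se_ox: float
    se_red: float


def _perturb_logratio(
    X: np.ndarray, noise: EndpointNoise, rng: np.random.Generator
) -> np.ndarray:
    """Re-derive log-ratios after drawing one endpoint error per resample.

    Inverts x = log10(f/(1-f)) to the fraction f, applies the endpoint
    perturbation f' = (f*dA - e_red) / (dA + e_ox - e_red), and returns the
    perturbed log-ratio.  Fractions pushed outside (0, 1) become NaN and are
    treated as failed resamples by the caller.
    """
    B = X.shape[0]
    e_ox = rng.normal(0.0, noise.se_ox, size=(B, 1))
    e_red = rng.normal(0.0, noise.se_red, size=(B, 1))
    f = 1.0 / (1.0 + 10.0 ** (-X))
    f2 = (f * noise.delta_A - e_red) / (noise.delta_A + e_ox - e_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((f2 > 0.0) & (f2 < 1.0), f2, np.nan)
        return np.log10(out / (1.0 - out))


def bootstrap_ci(
    data: NernstDataset,
    dye_E_m_mV: float,
    n_protein: int = 1,
    n_dye: int = 2,
    temperature_K: float = 298.15,
    slope_mode: str = "fixed",
    B: int = 1000,
    seed: int | None = None,
    endpoint_noise: tuple[EndpointNoise, EndpointNoise] | None = None,
) -> BootstrapResult:
    """Bootstrap 95% percentile interval for the recovered E_m.

    Nonparametric case resampling of (x, y) pairs, ``B`` resamples
    (B >= 200), refitting each and taking the 2.5/97.5 percentiles of the
    recovered midpoint potentials.  Seeded and reproducible.

    When ``endpoint_noise`` is supplied as ``(protein, dye)``
    :class:`EndpointNoise` terms, each resample additionally draws one
    endpoint-error realisation per species and re-derives the log-ratios
    before refitting.  Endpoint errors act coherently on every point of a
    replicate, so pure pair resampling systematically understates the E_m
    uncertainty; the endpoint component restores honest interval coverage
    and is enabled by the analysis pipeline.

    If more than 10% of resamples cannot be fitted (zero x-variance draws in
    free mode, endpoint draws pushing fractions out of (0, 1)) a warning is
    emitted and the ``widened`` flag is set.
    """
    if B < 200:
        raise ValidationError("bootstrap needs B >= 200 resamples")
    if seed is None:
        raise ValidationError("bootstrap requires an explicit seed")
    x, y = data.x, data.y
    n = x.size
    k = nernst_slope_factor(temperature_K)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    X, Y = x[idx], y[idx]
    if endpoint_noise is not None:
        protein_noise, dye_noise = endpoint_noise
        Y = _perturb_logratio(Y, protein_noise, rng)
        X = _perturb_logratio(X, dye_noise, rng)

    finite = np.all(np.isfinite(X) & np.isfinite(Y), axis=1)
    if slope_mode == "fixed":
        s = n_protein / n_dye
        with np.errstate(invalid="ignore"):
            b = (Y - s * X).mean(axis=1)
        ok = finite
    else:
        with np.errstate(invalid="ignore"):
            xm = X.mean(axis=1, keepdims=True)
            ym = Y.mean(axis=1, keepdims=True)
            sxx = ((X - xm) ** 2).sum(axis=1)
            sxy = ((X - xm) * (Y - ym)).sum(axis=1)
            ok = finite & (sxx > 1e-12 * max(1.0, float(np.var(x)) * n))
            slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
            b = ym.ravel() - slope * xm.ravel()

    n_failed = int(B - ok.sum())
    if n_failed == B:
        raise AnalysisError("all bootstrap resamples failed to fit")
    widened = n_failed > 0.1 * B
    if widened:
        warnings.warn(
            f"{n_failed}/{B} bootstrap resamples failed to fit; the "
            "percentile interval is computed from the remainder and should "
            "be treated as wider than nominal",
            stacklevel=2,
        )
    Em_b = dye_E_m_mV - b[ok] * k / n_protein
    lo, hi = np.percentile(Em_b, [2.5, 97.5])
    return BootstrapResult(
        ci95_mV=(float(lo), float(hi)),
        B=B,
        n_failed=n_failed,
        widened=widened,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def write_summary(
    fit: NernstFit,
    path: str | Path,
    protein_name: str = "",
    dye_name: str = "",
    bootstrap: BootstrapResult | None = None,
) -> None:
    """Machine-readable ``# key: value`` summary of a fit."""
    fmt = "{:.6g}".format
    lines = [
        f"# protein: {protein_name}",
        f"# dye: {dye_name}",
        f"# E_m_mV: {fmt(fit.E_m_mV)}",
        f"# E_m_se_mV: {fmt(fit.E_m_se_mV)}",
        f"# ci95_lo_mV: {fmt(fit.E_m_ci95_mV[0])}",
        f"# ci95_hi_mV: {fmt(fit.E_m_ci95_mV[1])}",
        f"# slope: {fmt(fit.slope)}",
        f"# slope_theory: {fmt(fit.slope_theory)}",
        f"# intercept: {fmt(fit.intercept)}",
        f"# r2: {fmt(fit.r_squared)}",
        f"# n_points: {fit.n_points}",
        f"# temperature_K: {fmt(fit.temperature_K)}",
        f"# dye_E_m_mV: {fmt(fit.dye_E_m_mV)}",
        f"# n_protein: {fit.n_protein}",
        f"# n_dye: {fit.n_dye}",
        f"# slope_mode: {fit.slope_mode}",
        f"# reference_electrode: NHE",
    ]
    if bootstrap is not None:
        lines += [
            f"# bootstrap_ci95_lo_mV: {fmt(bootstrap.ci95_mV[0])}",
            f"# bootstrap_ci95_hi_mV: {fmt(bootstrap.ci95_mV[1])}",
            f"# bootstrap_B: {bootstrap.B}",
            f"# bootstrap_failed: {bootstrap.n_failed}",
            f"# bootstrap_widened: {bootstrap.widened}",
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_summary(path: str | Path) -> dict[str, str]:
    """Parse a ``# key: value`` summary file back into a dict of strings."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            out[key.strip()] = value.strip()
    return out


def report(
    fit: NernstFit,
    data: NernstDataset,
    out_dir: str | Path,
    spectra=None,
    protein_name: str = "",
    dye_name: str = "",
    bootstrap: BootstrapResult | None = None,
) -> dict[str, Path]:
    """Write the run report: a two-panel figure and a key-value summary.

    Panel A overlays the recorded spectra (time-coloured titration scans and
    the dithionite endpoint); panel B is the Nernst plot with the fitted
    line.  The figure uses a fixed style and embeds no timestamps, so
    regenerating it from the same inputs reproduces the same file.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    two_panel = spectra is not None
    fig = Figure(figsize=(9.0, 3.6) if two_panel else (4.5, 3.6), dpi=150)
    FigureCanvasAgg(fig)
    if two_panel:
        ax_a, ax_b = fig.subplots(1, 2)
        titr = np.flatnonzero(spectra.titration_mask)
        cmap = matplotlib.colormaps["viridis"]
        for rank, j in enumerate(titr):
            ax_a.plot(
                spectra.wavelengths,
                spectra.absorbance[:, j],
                color=cmap(rank / max(1, titr.size - 1)),
                lw=0.6,
            )
        dith = np.flatnonzero(spectra.dithionite_mask)
        if dith.size:
            ax_a.plot(
                spectra.wavelengths,
                spectra.absorbance[:, dith].mean(axis=1),
                color="crimson",
                lw=1.2,
                label="dithionite endpoint",
            )
            ax_a.legend(frameon=False, fontsize=8)
        ax_a.set_xlabel("wavelength (nm)")
        ax_a.set_ylabel("absorbance (AU)")
        ax_a.set_title("A  spectral time course", loc="left", fontsize=10)
    else:
        ax_b = fig.subplots()

    ax_b.scatter(data.x, data.y, s=18, color="k", zorder=3)
    xx = np.linspace(data.x.min(), data.x.max(), 50)
    ax_b.plot(xx, fit.slope * xx + fit.intercept, color="crimson", lw=1.2)
    ax_b.set_xlabel(r"log$_{10}$([ox]/[red]) dye")
    ax_b.set_ylabel(r"log$_{10}$([ox]/[red]) protein")
    label = f"$E_m$ = {fit.E_m_mV:.0f} mV vs NHE"
    ax_b.set_title(
        ("B  " if two_panel else "") + "Nernst plot", loc="left", fontsize=10
    )
    ax_b.text(
        0.04, 0.92, label, transform=ax_b.transAxes, fontsize=9, va="top"
    )
    fig.tight_layout()

    plot_path = out_dir / "nernst_plot.png"
    fig.savefig(plot_path, metadata={"Software": "redoxeq"})
    summary_path = out_dir / "summary.txt"
    write_summary(
        fit,
        summary_path,
        protein_name=protein_name,
        dye_name=dye_name,
        bootstrap=bootstrap,
    )
    return {"plot": plot_path, "summary": summary_path}
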