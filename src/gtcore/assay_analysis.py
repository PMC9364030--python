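"""Michaelis–Menten kinetics and thermal-shift melt-curve analysis.

Saturation series (rate vs. substrate concentration) are fit to
v = Vmax·[S]/(Km + [S]) by unweighted nonlinear least squares, with
duplicate wells averaged before fitting.  Catalytic efficiency is
kcat/Km when the enzyme molar concentration is known, else Vmax/Km in
signal units; mutant-vs-wt efficiency fold changes propagate the fit
standard errors in quadrature.

Melting temperatures come from ThermoFluor-style melt curves: Tm is the
temperature of the maximum of the smoothed first derivative dF/dT inside
an analysis window (e.g. 40–70 °C for the enzyme transition), with
out-of-window secondary transitions (a GFP tag near 88 °C, say) reported
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

logger = logging.getLogger(__name__)


@dataclass
class SaturationSeries:
    """One substrate-saturation experiment (other substrate held saturating)."""

    concentrations: np.ndarray  # mM
    rates: np.ndarray  # signal units / time
    substrate: str = "acceptor"
    enzyme_molar: float | None = None  # enzyme concentration, same time base

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise ValueError("concentrations and rates must have the same length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")

    def averaged(self) -> "SaturationSeries":
        """Mean rate per distinct concentration (duplicate-well averaging)."""
        df = pd.DataFrame({"c": self.concentrations, "v": self.rates})
        g = df.groupby("c", sort=True)["v"].mean()
        return SaturationSeries(
            concentrations=g.index.to_numpy(), rates=g.to_numpy(),
            substrate=self.substrate, enzyme_molar=self.enzyme_molar,
        )


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


@dataclass
class KineticFit:
    km: float
    vmax: float
    km_se: float
    vmax_se: float
    converged: bool
    substrate: str = ""
    kcat: float | None = None
    kcat_se: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def efficiency(self) -> float:
        """kcat/Km when kcat is known, else Vmax/Km (signal units)."""
        num = self.kcat if self.kcat is not None else self.vmax
        return num / self.km

    @property
    def efficiency_se(self) -> float:
        num, num_se = (
            (self.kcat, self.kcat_se) if self.kcat is not None else (self.vmax, self.vmax_se)
        )
        rel = np.sqrt((num_se / num) ** 2 + (self.km_se / self.km) ** 2)
        return float(abs(self.efficiency) * rel)

    def to_dict(self) -> dict:
        return {
            "substrate": self.substrate,
            "Km_mM": self.km, "Km_se": self.km_se,
            "Vmax": self.vmax, "Vmax_se": self.vmax_se,
            "kcat_per_s": self.kcat, "kcat_se": self.kcat_se,
            "efficiency": self.efficiency, "efficiency_se": self.efficiency_se,
            "efficiency_units": "kcat/Km" if self.kcat is not None else "Vmax/Km (signal)",
            "converged": self.converged,
            **self.diagnostics,
        }


def fit_mm(series: SaturationSeries) -> KineticFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    Initialization: Vmax0 = max rate, Km0 = concentration nearest half-max.
    Non-convergence and degenerate (flat) data return a flagged failure
    rather than raising.
    """
    avg = series.averaged()
    c, v = avg.concentrations, avg.rates
    if len(c) < 4:
        raise ValueError("need at least 4 distinct concentration points")
    vmax0 = float(v.max())
    if vmax0 <= 0 or np.allclose(v, v[0]):
        logger.warning("fit_mm: degenerate rates (flat or non-positive); fit flagged")
        return KineticFit(
            km=float("nan"), vmax=float("nan"), km_se=float("nan"),
            vmax_se=float("nan"), converged=False, substrate=series.substrate,
            diagnostics={"reason": "degenerate_rates"},
        )
    km0 = float(c[np.argmin(np.abs(v - vmax0 / 2))])
    span_warn = not (c.min() < km0 < c.max())
    try:
        popt, pcov = curve_fit(
            michaelis_menten, c, v, p0=(vmax0, km0),
            bounds=((0, 0), (np.inf, np.inf)), maxfev=10000,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except RuntimeError as exc:
        logger.warning("fit_mm failed to converge: %s", exc)
        return KineticFit(
            km=float("nan"), vmax=float("nan"), km_se=float("nan"),
            vmax_se=float("nan"), converged=False, substrate=series.substrate,
            diagnostics={"reason": str(exc)},
        )
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    if km <= c.min() / 4:
        logger.warning(
            "fit_mm: Km (%.3g) at/under the concentration range floor; "
            "data may be saturated everywhere", km,
        )
    kcat = kcat_se = None
    if series.enzyme_molar:
        kcat = vmax / series.enzyme_molar
        kcat_se = float(se[0]) / series.enzyme_molar
    return KineticFit(
        km=km, vmax=vmax, km_se=float(se[1]), vmax_se=float(se[0]),
        converged=True, substrate=series.substrate, kcat=kcat, kcat_se=kcat_se,
        diagnostics={"range_warning": bool(span_warn)},
    )


def efficiency_fold_change(mutant: KineticFit, wt: KineticFit) -> tuple[float, float]:
    """(kcat/Km)_mutant / (kcat/Km)_wt with quadrature-propagated error."""
    if not (mutant.converged and wt.converged):
        raise ValueError("both fits must have converged")
    if wt.efficiency == 0:
        raise ValueError("wild-type efficiency is zero")
    ratio = mutant.efficiency / wt.efficiency
    rel = np.sqrt(
        (mutant.efficiency_se / mutant.efficiency) ** 2
        + (wt.efficiency_se / wt.efficiency) ** 2
    )
    return float(ratio), float(abs(ratio) * rel)


# ---------------------------------------------------------------------------
# thermal shift


@dataclass
class MeltCurve:
    temperatures: np.ndarray  # °C, increasing
    fluorescence: np.ndarray
    window: tuple[float, float] = (40.0, 70.0)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperatures and fluorescence must have the same length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        lo, hi = self.window
        if ((self.temperatures >= lo) & (self.temperatures <= hi)).sum() < 10:
            raise ValueError("need >= 10 points inside the analysis window")


@dataclass
class MeltResult:
    tm: float | None
    converged: bool
    secondary_tms: list[float] = field(default_factory=list)
    window: tuple[float, float] = (40.0, 70.0)

    def to_dict(self) -> dict:
        return {
            "Tm_C": self.tm, "converged": self.converged,
            "secondary_Tm_C": self.secondary_tms, "window_C": list(self.window),
        }


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid peak position by parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + delta * (x[i + 1] - x[i - 1]) / 2)


def melt_tm(curve: MeltCurve, smooth_window: int = 5) -> MeltResult:
    """Tm = argmax of the smoothed dF/dT inside the window.

    Savitzky–Golay smoothing (order 2, ``smooth_window`` points) of the
    finite-difference derivative, with parabolic sub-grid refinement.
    Derivative peaks outside the window are reported as secondary
    transitions.  No positive slope in-window → flagged failure.
    """
    t, f = curve.temperatures, curve.fluorescence
    dfdt = np.gradient(f, t)
    if smooth_window >= 3 and len(dfdt) > smooth_window:
        dfdt = savgol_filter(dfdt, smooth_window | 1, polyorder=2)
    lo, hi = curve.window
    inside = (t >= lo) & (t <= hi)
    secondary = []
    peaks, _ = find_peaks(dfdt, height=0.05 * dfdt.max() if dfdt.max() > 0 else None)
    for p in peaks:
        if not inside[p]:
            secondary.append(_parabolic_refine(t, dfdt, int(p)))
    if not np.any(inside) or dfdt[inside].max() <= 0:
        logger.warning("melt_tm: no positive-slope region inside window")
        return MeltResult(tm=None, converged=False, secondary_tms=secondary,
                          window=curve.window)
    idx_inside = np.where(inside)[0]
    i = int(idx_inside[np.argmax(dfdt[inside])])
    return MeltResult(
        tm=_parabolic_refine(t, dfdt, i), converged=True,
        secondary_tms=secondary, window=curve.window,
    )


def read_saturation_csv(path, substrate="acceptor", enzyme_molar=None) -> SaturationSeries:
    df = pd.read_csv(path)
    return SaturationSeries(
        concentrations=df["concentration_mM"].to_numpy(),
        rates=df["rate"].to_numpy(),
        substrate=substrate, enzyme_molar=enzyme_molar,
    )


def read_melt_csv(path, window=(40.0, 70.0)) -> MeltCurve:
    df = pd.read_csv(path)
    return MeltCurve(
        temperatures=df["temperature_C"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        window=tuple(window),
    )
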