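"""Exchange thermodynamics built on fitted populations and rates.

Conventions: the equilibrium constant is K = p_b / p_a (minor over
major), so the free-energy difference of the minor state,
dG = -R T ln K, is positive whenever p_b < 0.5. The van't Hoff analysis
comes in a linear form (dH, dS constant) and a non-linear form with a
constant heat-capacity change:

    dH(T) = dH0 + dCp (T - T0)
    dS(T) = dS0 + dCp ln(T/T0)
    ln K(T) = -(dH(T) - T dS(T)) / (R T)

Activation barriers follow transition-state theory (Eyring, unit
transmission coefficient): dG_act = -R T ln(k h / (k_B T)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import R, h, k as k_B
from scipy.optimize import curve_fit

__all__ = [
    "TemperatureSeries",
    "ThermoResult",
    "delta_g",
    "pb_from_delta_g",
    "pb_from_dw",
    "rates_from_kex",
    "eyring_dg_activation",
    "vant_hoff",
    "energy_landscape",
]


@dataclass
class TemperatureSeries:
    """Equilibrium data over temperature for van't Hoff analysis.

    ``values`` are minor-state populations (``kind='pb'``) or
    equilibrium constants K = p_b/p_a (``kind='keq'``). ``t0`` is the
    reference temperature of the non-linear model (K).
    """

    temperatures: np.ndarray
    values: np.ndarray
    kind: str = "pb"
    t0: float = 298.0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("pb", "keq"):
            raise ValueError("kind must be 'pb' or 'keq'")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive (kelvin)")
        if len(set(self.temperatures.tolist())) != self.temperatures.size:
            raise ValueError("temperatures must be distinct")

    @property
    def keq(self) -> np.ndarray:
        if self.kind == "keq":
            return self.values
        pb = self.values
        if np.any((pb <= 0) | (pb >= 1)):
            raise ValueError("populations must lie strictly in (0, 1)")
        return pb / (1.0 - pb)


@dataclass
class ThermoResult:
    dg: float | None = None  # J/mol at the evaluation temperature
    dh: float | None = None  # J/mol
    ds: float | None = None  # J/(mol K)
    dcp: float | None = None  # J/(mol K), non-linear fit only
    dg_activation: float | None = None  # J/mol
    t_eval: float | None = None  # K


def delta_g(pb: float, temperature: float) -> float:
    """Free energy of the minor state relative to the major, J/mol."""
    if not 0.0 < pb < 1.0:
        raise ValueError("pb must lie strictly between 0 and 1")
    return -R * temperature * math.log(pb / (1.0 - pb))


def pb_from_delta_g(dg: float, temperature: float) -> float:
    """Inverse of :func:`delta_g`: pb = 1/(1 + exp(dG/RT))."""
    return 1.0 / (1.0 + math.exp(dg / (R * temperature)))


def pb_from_dw(phi: float, dw_known: float) -> float:
    """Minor population from a fast-limit amplitude and a known dw.

    Solves ``p (1 - p) = phi / dw^2`` for the smaller root; the product
    cannot exceed 1/4, so larger ratios have no physical solution.
    """
    if phi <= 0 or dw_known <= 0:
        raise ValueError("phi and dw must be positive")
    q = phi / dw_known**2
    if q > 0.25 + 1e-12:
        raise ValueError(f"phi/dw^2 = {q:.4g} > 1/4: no physical population")
    return 0.5 * (1.0 - math.sqrt(max(1.0 - 4.0 * q, 0.0)))


def rates_from_kex(kex: float, pb: float):
    """Forward/backward rates from kex = k_ab + k_ba and detailed balance.

    k_ab = pb * kex (major -> minor), k_ba = (1 - pb) * kex.
    """
    if kex <= 0 or not 0.0 < pb < 1.0:
        raise ValueError("kex must be positive and pb in (0, 1)")
    return pb * kex, (1.0 - pb) * kex


def eyring_dg_activation(rate: float, temperature: float) -> float:
    """Activation free energy (J/mol) of a rate constant, Eyring form."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return -R * temperature * math.log(rate * h / (k_B * temperature))


def _lnk_nonlinear(T, dh0, ds0, dcp, t0):
    dh = dh0 + dcp * (T - t0)
    ds = ds0 + dcp * np.log(T / t0)
    return -(dh - T * ds) / (R * T)


def vant_hoff(series: TemperatureSeries, mode: str = "linear") -> ThermoResult:
    """Extract dH and dS (and dCp in non-linear mode) from K(T).

    Linear mode regresses ln K on 1/T (slope = -dH/R, intercept =
    dS/R) and needs >= 2 temperatures; the non-linear mode fits the
    constant-dCp extension and needs >= 4. The returned dG is evaluated
    at ``series.t0``.
    """
    T = series.temperatures
    lnk = np.log(series.keq)
    if mode == "linear":
        if T.size < 2:
            raise ValueError("linear van't Hoff needs >= 2 temperatures")
        slope, intercept = np.polyfit(1.0 / T, lnk, 1)
        dh = -slope * R
        ds = intercept * R
        return ThermoResult(
            dg=dh - series.t0 * ds, dh=dh, ds=ds, t_eval=series.t0
        )
    if mode != "nonlinear":
        raise ValueError("mode must be 'linear' or 'nonlinear'")
    if T.size < 4:
        raise ValueError("non-linear van't Hoff needs >= 4 temperatures")
    # linear fit seeds the non-linear optimization
    slope, intercept = np.polyfit(1.0 / T, lnk, 1)
    p0 = (-slope * R, intercept * R, 0.0)
    popt, _ = curve_fit(
        lambda t, dh0, ds0, dcp: _lnk_nonlinear(t, dh0, ds0, dcp, series.t0),
        T,
        lnk,
        p0=p0,
        maxfev=10000,
    )
    dh0, ds0, dcp = map(float, popt)
    return ThermoResult(
        dg=dh0 - series.t0 * ds0, dh=dh0, ds=ds0, dcp=dcp, t_eval=series.t0
    )


def energy_landscape(kex: float, pb: float, temperature: float) -> dict:
    """Two-state landscape: dG plus forward/backward barriers (J/mol).

    Satisfies dG_act_fwd - dG_act_bwd = dG exactly (both barriers from
    the same Eyring prefactor).
    """
    k_ab, k_ba = rates_from_kex(kex, pb)
    return {
        "dG": delta_g(pb, temperature),
        "dG_act_forward": eyring_dg_activation(k_ab, temperature),
        "dG_act_backward": eyring_dg_activation(k_ba, temperature),
    }
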