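"""Closed-form two-site exchange models for CPMG relaxation dispersion.

Three nested descriptions of the effective transverse relaxation rate
R2eff(nu_CPMG) are provided:

* model 1 — no exchange: a flat baseline, ``R2eff = R2_0``.
* model 2 — fast-limit two-site exchange (kex >> delta-omega), the
  Luz-Meiboom form parameterized by the composite amplitude
  ``Phi = p_a * p_b * dw**2``.
* model 3 — slow-limit two-site exchange (kex << delta-omega), the
  Carver-Richards equation parameterized by the minor population ``p_b``
  and the chemical shift difference ``dw`` (rad/s).

All rates are 1/s, frequencies nu_CPMG in Hz, shift differences in rad/s.
The chemical shift difference scales linearly with the static field; the
package stores ``dw`` at a declared reference field and produces per-field
values with :func:`scale_dw`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FieldContext",
    "ModelParams",
    "N_PARAMS",
    "model1_r2eff",
    "model2_r2eff",
    "model3_r2eff",
    "r2eff_fast",
    "r2eff_slow",
    "compute_rex",
    "scale_dw",
]

logger = logging.getLogger(__name__)

#: free parameters per model for a single residue at a single field
N_PARAMS = {1: 1, 2: 3, 3: 4}


@dataclass(frozen=True)
class FieldContext:
    """Static-field context of one experiment.

    Parameters
    ----------
    frequency_mhz : float
        Proton spectrometer frequency in MHz.
    reference_mhz : float, optional
        Frequency at which field-dependent parameters (``dw``, ``phi``)
        are stored. Defaults to ``frequency_mhz`` (scaling factor 1).
    temperature_k : float
        Sample temperature in kelvin.
    """

    frequency_mhz: float
    reference_mhz: float | None = None
    temperature_k: float = 298.0

    def __post_init__(self) -> None:
        if self.frequency_mhz <= 0:
            raise ValueError("spectrometer frequency must be positive")
        if self.reference_mhz is None:
            object.__setattr__(self, "reference_mhz", self.frequency_mhz)
        if self.reference_mhz <= 0:
            raise ValueError("reference frequency must be positive")

    @property
    def scaling(self) -> float:
        """Field ratio applied to ``dw`` (linear) and ``phi`` (squared)."""
        return self.frequency_mhz / self.reference_mhz


@dataclass
class ModelParams:
    """Parameter set of one dispersion model.

    ``r20`` is the exchange-free transverse rate (one value, or one per
    field for global fits). ``kex = k_ab + k_ba`` is the total exchange
    rate. Model 2 carries the composite amplitude ``phi`` ((rad/s)^2);
    model 3 carries the minor population ``pb`` and the shift difference
    ``dw`` (rad/s, at the reference field).
    """

    model_id: int
    r20: float | np.ndarray
    kex: float | None = None
    phi: float | None = None
    pb: float | None = None
    dw: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError(f"unknown model id {self.model_id}")
        if np.any(np.asarray(self.r20) <= 0):
            raise ValueError("r20 must be positive")
        if self.model_id in (2, 3):
            if self.kex is None or self.kex <= 0:
                raise ValueError("kex must be positive for exchange models")
        if self.model_id == 2:
            if self.phi is None or self.phi < 0:
                raise ValueError("model 2 requires phi >= 0")
        if self.model_id == 3:
            if self.pb is None or not 0 <= self.pb < 0.5:
                raise ValueError("model 3 requires 0 <= pb < 0.5 (minor state)")
            if self.dw is None or self.dw < 0:
                raise ValueError("model 3 requires dw >= 0")

    @property
    def pa(self) -> float | None:
        """Major-state population, ``1 - pb``."""
        return None if self.pb is None else 1.0 - self.pb

    def _scalar_r20(self) -> float:
        r20 = np.atleast_1d(np.asarray(self.r20, dtype=float))
        if r20.size != 1:
            raise ValueError(
                "per-field r20 supplied; select one field before evaluating"
            )
        return float(r20[0])


def r2eff_fast(nu_cpmg, r20: float, kex: float, phi: float):
    """Fast-limit (Luz-Meiboom) dispersion curve.

    ``R2eff = R2_0 + (Phi/kex) * [1 - (4 nu/kex) * tanh(kex/(4 nu))]``
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    x = 4.0 * nu / kex
    out = r20 + (phi / kex) * (1.0 - x * np.tanh(1.0 / x))
    return out if out.shape else float(out)


def r2eff_slow(nu_cpmg, r20: float, kex: float, pb: float, dw: float):
    """Slow-limit (Carver-Richards) dispersion curve.

    Implements

    ``R2eff = R2_0 + kex/2 - nu * acosh(D+ cosh(eta+) - D- cos(eta-))``

    with ``Psi = kex^2 - dw^2``, ``xi = -2 dw kex (p_a - p_b)``,
    ``D± = (±1 + (Psi + 2 dw^2)/sqrt(Psi^2 + xi^2)) / 2`` and
    ``eta± = sqrt(±Psi + sqrt(Psi^2 + xi^2)) / (2 sqrt(2) nu)``.

    The acosh argument is clamped to 1 to absorb floating-point
    undershoot near the no-exchange limit; for large ``eta+`` the
    asymptotic form ``acosh(D+ cosh eta+) ≈ eta+ + log(D+)`` is used to
    avoid overflow of ``cosh``.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    if dw == 0.0 or pb == 0.0:
        # exchange contribution vanishes identically
        out = np.full_like(nu, r20)
        return out if out.shape else float(r20)

    pa = 1.0 - pb
    psi = kex * kex - dw * dw
    xi = -2.0 * dw * (pa * kex - pb * kex)
    root = math.hypot(psi, xi)
    dplus = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    dminus = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    # root >= |psi|, so both sqrt arguments are non-negative
    eta_plus = np.sqrt(max(root + psi, 0.0)) / (2.0 * math.sqrt(2.0) * nu)
    eta_minus = np.sqrt(max(root - psi, 0.0)) / (2.0 * math.sqrt(2.0) * nu)

    big = eta_plus > 30.0
    acosh_term = np.empty_like(nu)
    with np.errstate(over="ignore", invalid="ignore"):
        arg = dplus * np.cosh(np.where(big, 0.0, eta_plus)) - dminus * np.cos(
            eta_minus
        )
        if np.any(arg < 1.0):
            logger.debug("clamping acosh argument below 1 (min %.3e)", arg.min())
            arg = np.maximum(arg, 1.0)
        acosh_term[~big] = np.arccosh(arg[~big])
    # cosh(eta) ~ exp(eta)/2 and the D- term is exponentially negligible
    acosh_term[big] = eta_plus[big] + math.log(dplus)

    out = r20 + kex / 2.0 - nu * acosh_term
    return out if out.shape else float(out)


def model1_r2eff(params: ModelParams, nu_cpmg):
    """No-exchange model: R2eff equals the baseline for every nu_CPMG."""
    if params.model_id != 1:
        raise ValueError("model1_r2eff requires model_id == 1")
    nu = np.asarray(nu_cpmg, dtype=float)
    out = np.full_like(nu, params._scalar_r20())
    return out if out.shape else float(out)


def model2_r2eff(params: ModelParams, nu_cpmg):
    """Fast-limit dispersion curve from a :class:`ModelParams`."""
    if params.model_id != 2:
        raise ValueError("model2_r2eff requires model_id == 2")
    return r2eff_fast(nu_cpmg, params._scalar_r20(), params.kex, params.phi)


def model3_r2eff(params: ModelParams, nu_cpmg):
    """Slow-limit dispersion curve from a :class:`ModelParams`."""
    if params.model_id != 3:
        raise ValueError("model3_r2eff requires model_id == 3")
    return r2eff_slow(
        nu_cpmg, params._scalar_r20(), params.kex, params.pb, params.dw
    )


def evaluate(params: ModelParams, nu_cpmg):
    """Dispatch to the model curve matching ``params.model_id``."""
    return {1: model1_r2eff, 2: model2_r2eff, 3: model3_r2eff}[params.model_id](
        params, nu_cpmg
    )


def compute_rex(params: ModelParams) -> float:
    """Exchange contribution to transverse relaxation (1/s).

    Fast limit: ``Rex = Phi / kex``. Slow limit:
    ``Rex = p_a p_b kex / (1 + (kex/dw)^2)``. Model 1 carries no
    exchange, ``Rex = 0``.
    """
    if params.model_id == 1:
        return 0.0
    if params.model_id == 2:
        return params.phi / params.kex
    if params.dw == 0.0:
        return 0.0
    return params.pa * params.pb * params.kex / (1.0 + (params.kex / params.dw) ** 2)


def scale_dw(dw_ref: float, ctx: FieldContext) -> float:
    """Chemical shift difference at ``ctx``'s field from its reference value.

    ``dw`` is proportional to the static field, e.g.
    ``dw(600 MHz) = (600/800) * dw(800 MHz)``.
    """
    return dw_ref * ctx.scaling
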