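"""Synthetic dispersion data generator.

Produces R2eff profiles from the exact model equations, optionally
perturbed with multiplicative Gaussian noise (a "percent error"
reading): R2eff -> R2eff * (1 + eps) with eps ~ N(0, (p/100)^2)
truncated at +-3 SD. The attached sigma_R2eff is the nominal noise
level, (p/100) * mean(R2eff); noiseless profiles carry unit weights
(sigma = 1) so chi-square stays defined.

The default nu_CPMG grid is a typical constant-time CPMG acquisition
list of 14 frequencies between 25 and 2000 Hz, without replicates; it
is fully configurable. Generating ("truth") parameters travel alongside
every simulation and can be written to a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FieldContext, ModelParams, evaluate
from .rates import CPMGSchedule, DispersionProfile, SchedulePoint

__all__ = [
    "DEFAULT_NU_GRID",
    "SimulationSpec",
    "simulate_profile",
    "simulate_multifield",
    "simulate_cluster",
    "to_peak_table",
    "write_truth",
    "read_truth",
]

#: default CPMG frequency list (Hz): 14 points, 25-2000 Hz
DEFAULT_NU_GRID = (
    25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0,
    500.0, 600.0, 700.0, 900.0, 1000.0, 1500.0, 2000.0,
)


@dataclass
class SimulationSpec:
    """One synthetic experiment: generating parameters, grid, noise, seed.

    ``params`` holds the generating :class:`ModelParams` (a list for
    cluster simulations), expressed at the reference field. Noise is a
    percentage of each R2eff value.
    """

    params: ModelParams | list
    seed: int
    noise_percent: float = 0.0
    nu_grid: tuple = DEFAULT_NU_GRID
    fields: tuple = (FieldContext(800.0),)

    def __post_init__(self) -> None:
        if self.noise_percent < 0:
            raise ValueError("noise_percent must be >= 0")
        if len(self.nu_grid) < 6:
            raise ValueError("nu grid needs at least 6 points")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed is mandatory and must be an integer")

    @property
    def param_list(self) -> list:
        return self.params if isinstance(self.params, list) else [self.params]

    @property
    def model_id(self) -> int:
        return self.param_list[0].model_id


def _reference_mhz(fields) -> float:
    declared = {f.reference_mhz for f in fields if f.reference_mhz != f.frequency_mhz}
    if len(declared) > 1:
        raise ValueError("fields declare conflicting reference frequencies")
    if declared:
        return declared.pop()
    return max(f.frequency_mhz for f in fields)


def _field_params(p: ModelParams, scale: float) -> ModelParams:
    """Generating parameters at a field a factor ``scale`` from the
    reference: dw scales linearly, phi quadratically."""
    if p.model_id == 1:
        return p
    if p.model_id == 2:
        return ModelParams(2, r20=p.r20, kex=p.kex, phi=p.phi * scale**2)
    return ModelParams(3, r20=p.r20, kex=p.kex, pb=p.pb, dw=p.dw * scale)


def _noisy_profile(
    residue, params: ModelParams, fctx: FieldContext, nu_grid,
    noise_percent: float, rng: np.random.Generator,
) -> DispersionProfile:
    nu = np.asarray(nu_grid, dtype=float)
    curve = np.asarray(evaluate(params, nu), dtype=float)
    frac = noise_percent / 100.0
    if frac > 0:
        eps = np.clip(rng.normal(0.0, frac, size=nu.shape), -3 * frac, 3 * frac)
        y = curve * (1.0 + eps)
        sigma = frac * float(np.mean(curve))
    else:
        y = curve.copy()
        sigma = 1.0
    return DispersionProfile(
        residue=residue, field=fctx, nu_cpmg=nu, r2eff=y, sigma=sigma
    )


def simulate_profile(spec: SimulationSpec) -> DispersionProfile:
    """Single residue, single field. Identity with the exact model curve
    at 0% noise; bit-reproducible under a fixed seed."""
    if len(spec.param_list) != 1 or len(spec.fields) != 1:
        raise ValueError("simulate_profile expects one residue and one field")
    rng = np.random.default_rng(spec.seed)
    fctx = spec.fields[0]
    return _noisy_profile(
        1, spec.param_list[0], fctx, spec.nu_grid, spec.noise_percent, rng
    )


def simulate_multifield(spec: SimulationSpec) -> dict:
    """One residue at several fields -> {field_MHz: profile}.

    The generating ``dw`` (``phi``) is scaled by the field ratio
    (squared) relative to the reference field — by default the highest
    field in ``spec.fields``. Noise is drawn independently per field.
    """
    if len(spec.param_list) != 1:
        raise ValueError("simulate_multifield expects a single residue")
    rng = np.random.default_rng(spec.seed)
    ref = _reference_mhz(spec.fields)
    p0 = spec.param_list[0]
    out = {}
    for f in spec.fields:
        scale = f.frequency_mhz / ref
        fctx = FieldContext(f.frequency_mhz, reference_mhz=ref,
                            temperature_k=f.temperature_k)
        out[f.frequency_mhz] = _noisy_profile(
            1, _field_params(p0, scale), fctx, spec.nu_grid,
            spec.noise_percent, rng,
        )
    return out


def simulate_cluster(spec: SimulationSpec) -> list:
    """Several residues (one profile per residue per field), independent
    noise per residue; shared exchange parameters live in ``spec``."""
    rng = np.random.default_rng(spec.seed)
    ref = _reference_mhz(spec.fields)
    profiles = []
    for i, p in enumerate(spec.param_list, start=1):
        for f in spec.fields:
            scale = f.frequency_mhz / ref
            fctx = FieldContext(f.frequency_mhz, reference_mhz=ref,
                                temperature_k=f.temperature_k)
            profiles.append(
                _noisy_profile(
                    i, _field_params(p, scale), fctx, spec.nu_grid,
                    spec.noise_percent, rng,
                )
            )
    return profiles


def to_peak_table(
    profiles: list, t_cpmg: float = 0.08, i0: float = 1e6,
    n_references: int = 1,
):
    """Invert the intensity relation to emit a peak table + schedule.

    ``I(nu) = I(0) * exp(-R2eff * T_CPMG)``; re-importing through the
    rates module reproduces the profiles' R2eff exactly.
    """
    fields = {p.field.frequency_mhz for p in profiles}
    if len(fields) != 1:
        raise ValueError("one peak table per field; split profiles first")
    nu_grid = profiles[0].nu_cpmg
    points = [SchedulePoint(f"ref_{j}", None) for j in range(n_references)]
    points += [SchedulePoint(f"s{i}", float(nu)) for i, nu in enumerate(nu_grid)]
    schedule = CPMGSchedule(t_cpmg=t_cpmg, points=points, field=profiles[0].field)

    rows = {}
    for p in profiles:
        if not np.array_equal(p.nu_cpmg, nu_grid):
            raise ValueError("all profiles must share one nu grid")
        row = {f"ref_{j}": i0 for j in range(n_references)}
        for i, r in enumerate(p.r2eff):
            row[f"s{i}"] = i0 * np.exp(-r * t_cpmg)
        rows[p.residue] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "residue"
    return table, schedule


def _params_dict(p: ModelParams) -> dict:
    d = {"model_id": p.model_id, "r20": np.asarray(p.r20).tolist()}
    for k in ("kex", "phi", "pb", "dw"):
        v = getattr(p, k)
        if v is not None:
            d[k] = v
    return d


def write_truth(spec: SimulationSpec, path) -> None:
    """JSON sidecar with the generating parameters and simulation setup."""
    payload = {
        "seed": int(spec.seed),
        "noise_percent": spec.noise_percent,
        "nu_grid": list(spec.nu_grid),
        "fields_mhz": [f.frequency_mhz for f in spec.fields],
        "params": [_params_dict(p) for p in spec.param_list],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
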