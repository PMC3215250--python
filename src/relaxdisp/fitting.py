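"""Chi-square minimization of dispersion models.

One joint machinery covers the three fit modes:

* per-residue fit — one R2eff profile, all parameters free;
* global fit — one residue at several static fields, sharing ``kex``
  and the exchange amplitude (``dw`` scaling linearly, ``phi``
  quadratically with the field ratio) with one ``r20`` per field;
* cluster fit — several residues sharing ``kex`` (and ``pb``), with
  per-residue baselines and amplitudes.

The target function is the sigma-normalized chi-square

    chi2 = sum_n (R2eff_calc(nu_n) - R2eff_n)^2 / sigma_R2eff^2

minimized with bounded least squares (Levenberg-Marquardt/trust-region)
from a deterministic multi-start grid; the best start wins, ties broken
by grid order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import least_squares

from .models import ModelParams, N_PARAMS, evaluate, r2eff_fast, r2eff_slow
from .rates import DispersionProfile

__all__ = [
    "ClusterSpec",
    "FitResult",
    "chi2",
    "fit_residue",
    "fit_global",
    "fit_cluster",
    "KEX_STARTS",
    "PB_STARTS",
    "BOUNDS",
]

#: deterministic multi-start grid for the exchange rate (1/s)
KEX_STARTS = (100.0, 500.0, 1000.0, 3000.0, 8000.0)
#: multi-start grid for the minor population (model 3)
PB_STARTS = (0.01, 0.05, 0.1, 0.3)

#: box constraints enforced by bounded least squares
BOUNDS = {
    "r20": (1e-6, 200.0),
    "kex": (1e-3, 1e6),
    "pb": (1e-4, 0.5),
    "dw": (0.0, 1e5),
    "phi": (0.0, 1e9),
}

_FTOL = 1e-10
_MAX_NFEV = 2000


@dataclass
class ClusterSpec:
    """Residues fitted jointly: shared ``kex`` (and ``pb`` for model 3),
    individual ``r20`` and ``dw``/``phi`` per residue."""

    residue_ids: list

    def __post_init__(self) -> None:
        if len(self.residue_ids) < 1:
            raise ValueError("cluster needs at least one residue")


@dataclass
class _Series:
    """One residue at one field: the unit of the joint residual vector."""

    nu: np.ndarray
    y: np.ndarray
    sigma: float
    scale: float  # field / reference-field ratio
    group: int  # residue index within the joint fit
    residue: object = None
    field_mhz: float | None = None


@dataclass
class FitResult:
    """Optimized parameters of one model for one residue (or one member
    of a cluster).

    ``chi2`` is the full (joint, for global/cluster fits) chi-square;
    ``partial_chi2`` is this residue's own contribution. ``k_params``
    and ``n_points`` count the whole joint problem and feed AIC/AICc.
    ``param_errors`` is filled by the Monte Carlo uncertainty module.
    """

    model_id: int
    residue: object
    params: ModelParams
    chi2: float
    n_points: int
    k_params: int
    converged: bool
    n_restarts_used: int
    partial_chi2: float | None = None
    param_errors: dict | None = None
    aic: float | None = None
    aicc: float | None = None
    fields_mhz: list | None = None
    mc_n_failed: int | None = None
    selected: bool = False
    _series: list = dc_field(default=None, repr=False)
    _theta: np.ndarray = dc_field(default=None, repr=False)


def chi2(profile: DispersionProfile, params: ModelParams) -> float:
    """Chi-square of ``params`` against one profile (sigma-normalized)."""
    if profile.sigma is None or profile.sigma <= 0:
        raise ValueError("profile sigma must be available and positive")
    calc = evaluate(params, profile.nu_cpmg)
    resid = (calc - profile.r2eff) / profile.sigma
    return float(np.dot(resid, resid))


# ---------------------------------------------------------------------------
# joint parameter vector:  [r20 per series] + [kex] + [pb] + [amp per group]
# amp is phi (model 2, scales with field ratio squared) or dw (model 3,
# scales linearly), stored at the reference field.
# ---------------------------------------------------------------------------


def _n_groups(series: list[_Series]) -> int:
    return max(s.group for s in series) + 1


def _curves(theta: np.ndarray, series: list[_Series], model_id: int):
    ns = len(series)
    if model_id == 1:
        return [np.full(s.nu.shape, theta[i]) for i, s in enumerate(series)]
    kex = theta[ns]
    if model_id == 2:
        amps = theta[ns + 1 :]
        return [
            r2eff_fast(s.nu, theta[i], kex, amps[s.group] * s.scale**2)
            for i, s in enumerate(series)
        ]
    pb = theta[ns + 1]
    amps = theta[ns + 2 :]
    return [
        r2eff_slow(s.nu, theta[i], kex, pb, amps[s.group] * s.scale)
        for i, s in enumerate(series)
    ]


def _residuals(theta: np.ndarray, series: list[_Series], model_id: int):
    curves = _curves(theta, series, model_id)
    return np.concatenate(
        [(c - s.y) / s.sigma for c, s in zip(curves, series)]
    )


def _bounds(series: list[_Series], model_id: int):
    ns, ng = len(series), _n_groups(series)
    lo = [BOUNDS["r20"][0]] * ns
    hi = [BOUNDS["r20"][1]] * ns
    if model_id >= 2:
        lo.append(BOUNDS["kex"][0])
        hi.append(BOUNDS["kex"][1])
    if model_id == 3:
        lo.append(BOUNDS["pb"][0])
        hi.append(BOUNDS["pb"][1])
    if model_id >= 2:
        amp = "phi" if model_id == 2 else "dw"
        lo.extend([BOUNDS[amp][0]] * ng)
        hi.extend([BOUNDS[amp][1]] * ng)
    return np.array(lo), np.array(hi)


def _amplitude_guess(series: list[_Series]) -> np.ndarray:
    """Per-group dispersion amplitude (low-nu minus high-nu R2eff)."""
    ng = _n_groups(series)
    delta = np.zeros(ng)
    for s in series:
        order = np.argsort(s.nu)
        d = s.y[order[0]] - s.y[order[-1]]
        delta[s.group] = max(delta[s.group], d / max(s.scale, 1e-9) ** 2)
    return np.maximum(delta, 1e-3)


def _starts(series: list[_Series], model_id: int):
    """Deterministic multi-start grid, ordered."""
    ns, ng = len(series), _n_groups(series)
    r20_0 = [
        float(np.clip(s.y[np.argmax(s.nu)], 0.1, BOUNDS["r20"][1] - 1e-6))
        for s in series
    ]
    if model_id == 1:
        return [np.array(r20_0)]
    delta = _amplitude_guess(series)
    starts = []
    if model_id == 2:
        for kex0 in KEX_STARTS:
            phi0 = np.clip(delta * kex0, 1.0, BOUNDS["phi"][1] - 1.0)
            starts.append(np.concatenate([r20_0, [kex0], phi0]))
    else:
        for kex0 in KEX_STARTS:
            for pb0 in PB_STARTS:
                dw0 = np.sqrt(delta * kex0 / (pb0 * (1.0 - pb0)))
                dw0 = np.clip(dw0, 1.0, BOUNDS["dw"][1] - 1.0)
                starts.append(np.concatenate([r20_0, [kex0, pb0], dw0]))
    return starts


def _optimize(series: list[_Series], model_id: int, starts=None):
    """Run every start, keep the strictly best chi-square (grid order
    breaks ties). Returns (theta, chi2, converged, n_starts)."""
    if starts is None:
        starts = _starts(series, model_id)
    lo, hi = _bounds(series, model_id)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                _residuals,
                x0,
                bounds=(lo, hi),
                args=(series, model_id),
                method="trf",
                ftol=_FTOL,
                xtol=_FTOL,
                gtol=_FTOL,
                max_nfev=_MAX_NFEV,
            )
        except Exception:
            continue
        cost = 2.0 * res.cost
        if best is None or cost < best[1]:
            best = (res.x, cost, res.status > 0)
    if best is None:
        return np.clip(np.asarray(starts[0]), lo, hi), np.inf, False, len(starts)
    return best[0], best[1], best[2], len(starts)


def _refit(series: list[_Series], model_id: int, theta0: np.ndarray):
    """Single-start refit (used by Monte Carlo simulations)."""
    return _optimize(series, model_id, starts=[np.array(theta0)])


def _params_from_theta(
    theta: np.ndarray, series: list[_Series], model_id: int, group: int
) -> ModelParams:
    ns = len(series)
    own = [i for i, s in enumerate(series) if s.group == group]
    r20 = theta[own[0]] if len(own) == 1 else np.array([theta[i] for i in own])
    if model_id == 1:
        return ModelParams(1, r20=r20)
    kex = float(theta[ns])
    if model_id == 2:
        return ModelParams(2, r20=r20, kex=kex, phi=float(theta[ns + 1 + group]))
    return ModelParams(
        3,
        r20=r20,
        kex=kex,
        pb=float(theta[ns + 1]),
        dw=float(theta[ns + 2 + group]),
    )


def _partial_chi2(theta, series, model_id, group) -> float:
    curves = _curves(theta, series, model_id)
    tot = 0.0
    for c, s in zip(curves, series):
        if s.group == group:
            r = (c - s.y) / s.sigma
            tot += float(np.dot(r, r))
    return tot


def _check_points(n_points: int, model_id: int, k: int) -> None:
    if n_points < k + 2:
        raise ValueError(
            f"model {model_id} with {k} parameters needs at least {k + 2} "
            f"points, got {n_points}"
        )


def fit_residue(profile: DispersionProfile, model_id: int) -> FitResult:
    """Fit one model to one residue's single-field profile."""
    k = N_PARAMS[model_id]
    _check_points(profile.n_points, model_id, k)
    series = [
        _Series(
            nu=profile.nu_cpmg,
            y=profile.r2eff,
            sigma=profile.sigma,
            scale=profile.field.scaling,
            group=0,
            residue=profile.residue,
            field_mhz=profile.field.frequency_mhz,
        )
    ]
    theta, cost, conv, nstarts = _optimize(series, model_id)
    return FitResult(
        model_id=model_id,
        residue=profile.residue,
        params=_params_from_theta(theta, series, model_id, 0),
        chi2=cost,
        n_points=profile.n_points,
        k_params=len(theta),
        converged=conv,
        n_restarts_used=nstarts,
        partial_chi2=cost,
        fields_mhz=[profile.field.frequency_mhz],
        _series=series,
        _theta=theta,
    )


def _as_profile_list(profiles_by_field) -> list[DispersionProfile]:
    if isinstance(profiles_by_field, dict):
        return [profiles_by_field[k] for k in sorted(profiles_by_field)]
    return list(profiles_by_field)


def _series_for(profiles: list[DispersionProfile], groups: list[int]):
    """Build series with consistent field scaling. If no profile declares
    a distinct reference field, the highest frequency becomes the
    reference."""
    declared = any(
        p.field.reference_mhz != p.field.frequency_mhz for p in profiles
    )
    ref = (
        None if declared else max(p.field.frequency_mhz for p in profiles)
    )
    series = []
    for p, g in zip(profiles, groups):
        scale = (
            p.field.scaling if declared else p.field.frequency_mhz / ref
        )
        series.append(
            _Series(
                nu=p.nu_cpmg,
                y=p.r2eff,
                sigma=p.sigma,
                scale=scale,
                group=g,
                residue=p.residue,
                field_mhz=p.field.frequency_mhz,
            )
        )
    return series


def fit_global(profiles_by_field, model_id: int) -> FitResult:
    """Fit one residue jointly across static fields.

    Shares ``kex`` (and ``pb``) plus the reference-field exchange
    amplitude; ``dw`` scales linearly and ``phi`` quadratically with the
    field ratio. One ``r20`` is fitted per field.
    """
    profiles = _as_profile_list(profiles_by_field)
    temps = {p.field.temperature_k for p in profiles}
    if len(temps) > 1:
        warnings.warn(f"inconsistent temperatures across fields: {sorted(temps)}")
    series = _series_for(profiles, [0] * len(profiles))
    n_points = sum(p.n_points for p in profiles)
    k = N_PARAMS[model_id] + (len(profiles) - 1)
    _check_points(n_points, model_id, k)
    theta, cost, conv, nstarts = _optimize(series, model_id)
    return FitResult(
        model_id=model_id,
        residue=profiles[0].residue,
        params=_params_from_theta(theta, series, model_id, 0),
        chi2=cost,
        n_points=n_points,
        k_params=len(theta),
        converged=conv,
        n_restarts_used=nstarts,
        partial_chi2=cost,
        fields_mhz=[p.field.frequency_mhz for p in profiles],
        _series=series,
        _theta=theta,
    )


def fit_cluster(
    profiles: list[DispersionProfile], spec: ClusterSpec, model_id: int
) -> list[FitResult]:
    """Fit several residues jointly, sharing ``kex`` (and ``pb``).

    ``profiles`` may contain several fields per residue. Residues with
    too few points for their individual parameters are dropped with a
    warning. Each returned result carries the shared parameters, its own
    ``r20``/amplitude, the joint chi-square and its own partial
    chi-square.
    """
    by_res = {rid: [p for p in profiles if p.residue == rid] for rid in spec.residue_ids}
    k_indiv = N_PARAMS[model_id] - (0 if model_id == 1 else (1 if model_id == 2 else 2))
    usable = []
    for rid, plist in by_res.items():
        n = sum(p.n_points for p in plist)
        k_own = max(len(plist), 1) + (0 if model_id == 1 else 1)
        if not plist or n < k_own + 2:
            warnings.warn(f"residue {rid}: insufficient data; dropped from cluster")
            continue
        usable.append(rid)
    if not usable:
        raise ValueError("no residue in the cluster has usable data")

    flat, groups = [], []
    for g, rid in enumerate(usable):
        for p in by_res[rid]:
            flat.append(p)
            groups.append(g)
    series = _series_for(flat, groups)
    theta, cost, conv, nstarts = _optimize(series, model_id)
    n_points = sum(p.n_points for p in flat)
    results = []
    for g, rid in enumerate(usable):
        results.append(
            FitResult(
                model_id=model_id,
                residue=rid,
                params=_params_from_theta(theta, series, model_id, g),
                chi2=cost,
                n_points=n_points,
                k_params=len(theta),
                converged=conv,
                n_restarts_used=nstarts,
                partial_chi2=_partial_chi2(theta, series, model_id, g),
                fields_mhz=sorted({p.field.frequency_mhz for p in by_res[rid]}),
                _series=series,
                _theta=theta,
            )
        )
    return results
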