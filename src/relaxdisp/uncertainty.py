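"""Monte Carlo estimation of parameter standard errors.

Parametric Monte Carlo around the best-fit curve: each simulation adds
Gaussian noise with standard deviation sigma_R2eff to the fitted curve
at every point (jointly over all fields and residues of a global or
cluster fit), refits starting from the best-fit parameters, and the
parameter errors are the standard deviations over the converged
simulations. The default of 500 simulations is user-controlled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, _Series, _curves, _optimize, _refit, _starts

__all__ = ["MonteCarloConfig", "monte_carlo_errors", "cluster_member_errors"]


@dataclass
class MonteCarloConfig:
    n_sims: int = 500
    seed: int = 0
    full_grid: bool = False  # restart from the full multi-start grid per sim

    def __post_init__(self) -> None:
        if self.n_sims < 2:
            raise ValueError("n_sims must be at least 2")


def cluster_member_errors(results: list, cfg: MonteCarloConfig | None = None) -> dict:
    """One joint Monte Carlo run over a fitted cluster, with errors
    distributed to every member.

    All simulations perturb every residue's points jointly; the shared
    parameters (kex, pb) get one error value, copied onto each member,
    while each member receives its own baseline and amplitude errors.
    Returns the joint (flat) error dictionary.
    """
    joint = monte_carlo_errors(results[0], cfg)
    series = results[0]._series
    for g, fit in enumerate(results):
        own = [i for i, s in enumerate(series) if s.group == g]
        errs: dict[str, float] = {}
        if len(own) == 1:
            errs["r20"] = joint.get("r20", joint.get(f"r20_{own[0]}"))
        else:
            for j, i in enumerate(own):
                errs[f"r20_{j}"] = joint[f"r20_{i}"]
        for key in ("kex", "pb"):
            if key in joint:
                errs[key] = joint[key]
        for base in ("dw", "phi"):
            key = base if base in joint else f"{base}_{g}"
            if key in joint:
                errs[base] = joint[key]
        fit.param_errors = errs
        fit.mc_n_failed = results[0].mc_n_failed
    return joint


def monte_carlo_errors(fit: FitResult, cfg: MonteCarloConfig | None = None) -> dict:
    """Standard errors of every fitted parameter of ``fit``.

    The fit must have converged and carry its internal series (any
    result from ``fit_residue``/``fit_global``/``fit_cluster`` does).
    Errors are attached to ``fit.param_errors`` (keyed r20[_i], kex, pb,
    dw/phi — cluster amplitudes as dw_g/phi_g per residue group) and
    returned. Simulations that fail to converge are dropped from the
    standard deviation and counted in ``fit.mc_n_failed``; if more than
    half fail the errors are flagged unreliable with a warning.
    """
    cfg = cfg or MonteCarloConfig()
    if not fit.converged:
        raise ValueError("Monte Carlo errors require a converged fit")
    series, theta = fit._series, fit._theta
    if series is None or theta is None:
        raise ValueError("fit carries no data series; refit before Monte Carlo")

    rng = np.random.default_rng(cfg.seed)
    best_curves = _curves(theta, series, fit.model_id)
    draws, n_failed = [], 0
    for _ in range(cfg.n_sims):
        sim_series = [
            _Series(
                nu=s.nu,
                y=c + rng.normal(0.0, s.sigma, size=s.nu.shape),
                sigma=s.sigma,
                scale=s.scale,
                group=s.group,
            )
            for s, c in zip(series, best_curves)
        ]
        if cfg.full_grid:
            th, cost, conv, _ = _optimize(sim_series, fit.model_id)
        else:
            th, cost, conv, _ = _refit(sim_series, fit.model_id, theta)
        if conv and np.isfinite(cost):
            draws.append(th)
        else:
            n_failed += 1

    fit.mc_n_failed = n_failed
    if n_failed > cfg.n_sims // 2:
        warnings.warn(
            f"{n_failed}/{cfg.n_sims} Monte Carlo refits failed to converge; "
            "errors are unreliable"
        )
    sds = (
        np.std(np.array(draws), axis=0, ddof=1)
        if len(draws) >= 2
        else np.full(theta.shape, np.nan)
    )

    ns = len(series)
    errors: dict[str, float] = {}
    for i in range(ns):
        key = "r20" if ns == 1 else f"r20_{i}"
        errors[key] = float(sds[i])
    if fit.model_id >= 2:
        errors["kex"] = float(sds[ns])
    if fit.model_id == 3:
        errors["pb"] = float(sds[ns + 1])
    n_groups = max(s.group for s in series) + 1
    amp0 = ns + (1 if fit.model_id == 2 else 2)
    if fit.model_id == 2:
        for g in range(n_groups):
            errors["phi" if n_groups == 1 else f"phi_{g}"] = float(sds[amp0 + g])
    elif fit.model_id == 3:
        for g in range(n_groups):
            errors["dw" if n_groups == 1 else f"dw_{g}"] = float(sds[amp0 + g])
    fit.param_errors = errors
    return errors
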