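"""Scikit-learn-style estimators over the dispersion-fitting core.

``DispersionRegressor`` fits one residue (optionally at several static
fields); ``ClusterDispersionRegressor`` fits several residues jointly
with shared exchange parameters. Both follow the sklearn contract:
constructor parameters are hyperparameters, ``fit`` consumes arrays,
fitted attributes carry a trailing underscore, and ``predict`` returns
the model curve, so they compose with sklearn model selection and
pipelines. The thin functional wrappers in :mod:`relaxdisp.fitting`
(``fit_residue`` and friends) remain the profile-object interface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .fitting import (
    KEX_STARTS,
    PB_STARTS,
    _optimize,
    _params_from_theta,
    _Series,
)
from .models import N_PARAMS, r2eff_fast, r2eff_slow

__all__ = ["DispersionRegressor", "ClusterDispersionRegressor"]


def _split_series(X, y, sigma, field_col, group_col=None):
    """Group rows of (nu[, field][, residue]) into fitting series."""
    nu = X[:, 0]
    fields = X[:, field_col] if field_col is not None else np.zeros(len(X))
    groups = X[:, group_col] if group_col is not None else np.zeros(len(X))
    if sigma is None:
        sigma = np.ones_like(y, dtype=float)
    else:
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape)
    ref = fields.max() if field_col is not None and fields.max() > 0 else None
    group_ids = sorted(set(groups.tolist()))
    series, index = [], []
    for g, gid in enumerate(group_ids):
        for f in sorted(set(fields[groups == gid].tolist())):
            mask = (groups == gid) & (fields == f)
            series.append(
                _Series(
                    nu=nu[mask],
                    y=np.asarray(y, dtype=float)[mask],
                    sigma=float(sigma[mask][0]),
                    scale=1.0 if ref is None else f / ref,
                    group=g,
                    residue=gid,
                    field_mhz=f if field_col is not None else None,
                )
            )
            index.append((gid, f, mask))
    return series, index, group_ids, ref


class DispersionRegressor(RegressorMixin, BaseEstimator):
    """Fit one residue's R2eff(nu_CPMG) dispersion curve.

    Parameters
    ----------
    model : int
        1 (no exchange), 2 (fast-limit) or 3 (slow-limit Carver-
        Richards).
    kex_starts, pb_starts : sequence
        Deterministic multi-start grids for the exchange parameters.

    ``X`` has one column (nu_CPMG in Hz) or two (nu_CPMG, field in
    MHz); with two, one ``r20_`` is fitted per field and the exchange
    amplitude is shared at the highest (reference) field. Per-point
    uncertainties enter through ``fit``'s ``sigma`` argument (constant
    within each field).
    """

    def __init__(self, model: int = 2, kex_starts=KEX_STARTS, pb_starts=PB_STARTS):
        self.model = model
        self.kex_starts = kex_starts
        self.pb_starts = pb_starts

    def _more_tags(self):
        return {"poor_score": True}

    def fit(self, X, y, sigma=None):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if self.model not in (1, 2, 3):
            raise ValueError(f"model must be 1, 2 or 3, got {self.model}")
        field_col = 1 if X.shape[1] >= 2 else None
        series, index, _, ref = _split_series(X, y, sigma, field_col)
        theta, cost, conv, nstarts = _optimize(series, self.model)
        self.n_features_in_ = X.shape[1]
        self._series_ = series
        self._index_ = index
        self.reference_mhz_ = ref
        self.theta_ = theta
        self.chi2_ = cost
        self.converged_ = conv
        self.n_restarts_ = nstarts
        self.k_params_ = len(theta)
        params = _params_from_theta(theta, series, self.model, 0)
        self.r20_ = np.array([theta[i] for i in range(len(series))])
        self.kex_ = params.kex
        self.pb_ = params.pb
        self.dw_ = params.dw
        self.phi_ = params.phi
        self.params_ = params
        return self

    def _curve(self, nu, r20, scale):
        if self.model == 1:
            return np.full(nu.shape, r20)
        if self.model == 2:
            return r2eff_fast(nu, r20, self.kex_, self.phi_ * scale**2)
        return r2eff_slow(nu, r20, self.kex_, self.pb_, self.dw_ * scale)

    def predict(self, X):
        check_is_fitted(self, "theta_")
        X = check_array(X)
        nu = X[:, 0]
        out = np.empty(len(X), dtype=float)
        if self.n_features_in_ == 1 or self.reference_mhz_ is None:
            out[:] = self._curve(nu, self.r20_[0], self._series_[0].scale)
            return out
        fitted_fields = {s.field_mhz: i for i, s in enumerate(self._series_)}
        for f in np.unique(X[:, 1]):
            mask = X[:, 1] == f
            if f in fitted_fields:
                i = fitted_fields[f]
                r20, scale = self.r20_[i], self._series_[i].scale
            else:  # unseen field: nearest fitted r20, exact dw scaling
                i = min(fitted_fields.values(),
                        key=lambda j: abs(self._series_[j].field_mhz - f))
                r20, scale = self.r20_[i], f / self.reference_mhz_
            out[mask] = self._curve(nu[mask], r20, scale)
        return out


class ClusterDispersionRegressor(RegressorMixin, BaseEstimator):
    """Joint fit of clustered residues sharing kex (and pb).

    ``X`` columns: nu_CPMG (Hz), residue id, and optionally field
    (MHz). Each residue gets its own baseline(s) and exchange amplitude
    (phi or dw); ``kex_`` (and ``pb_``) are single shared values.
    """

    def __init__(self, model: int = 3, kex_starts=KEX_STARTS, pb_starts=PB_STARTS):
        self.model = model
        self.kex_starts = kex_starts
        self.pb_starts = pb_starts

    def fit(self, X, y, sigma=None):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if X.shape[1] < 2:
            raise ValueError("X needs (nu_cpmg, residue[, field]) columns")
        field_col = 2 if X.shape[1] >= 3 else None
        series, index, group_ids, ref = _split_series(
            X, y, sigma, field_col, group_col=1
        )
        theta, cost, conv, nstarts = _optimize(series, self.model)
        self.n_features_in_ = X.shape[1]
        self._series_ = series
        self.residues_ = group_ids
        self.reference_mhz_ = ref
        self.theta_ = theta
        self.chi2_ = cost
        self.converged_ = conv
        self.k_params_ = len(theta)
        ns = len(series)
        self.r20_ = theta[:ns].copy()
        if self.model >= 2:
            self.kex_ = float(theta[ns])
        if self.model == 3:
            self.pb_ = float(theta[ns + 1])
            self.dw_ = theta[ns + 2 :].copy()
        elif self.model == 2:
            self.phi_ = theta[ns + 1 :].copy()
        return self

    def predict(self, X):
        check_is_fitted(self, "theta_")
        X = check_array(X)
        out = np.empty(len(X), dtype=float)
        lookup = {
            (s.residue, s.field_mhz): i for i, s in enumerate(self._series_)
        }
        for i, row in enumerate(X):
            nu, gid = row[0], row[1]
            f = row[2] if self.n_features_in_ >= 3 else None
            j = lookup.get((gid, f))
            if j is None:
                raise ValueError(f"unseen residue/field combination {(gid, f)}")
            s = self._series_[j]
            if self.model == 1:
                out[i] = self.r20_[j]
            elif self.model == 2:
                out[i] = r2eff_fast(
                    nu, self.r20_[j], self.kex_, self.phi_[s.group] * s.scale**2
                )
            else:
                out[i] = r2eff_slow(
                    nu, self.r20_[j], self.kex_, self.pb_, self.dw_[s.group] * s.scale
                )
        return out
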