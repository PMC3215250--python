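"""Model ranking by AICc (default), AIC, or F-test.

Information criteria use the chi-square form (score = chi2 + penalty),
appropriate for weighted least-squares fits with known per-point
uncertainties:

    AIC  = chi2 + 2k
    AICc = chi2 + 2k + 2k(k+1)/(n - k - 1)

Lower scores win; ties (within 1e-9) favor the simpler model. The
F-test compares models along the chain 1 -> 2 -> winner vs 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import f as f_dist

from .fitting import FitResult
from .models import compute_rex

__all__ = ["aic", "aicc", "f_test", "select_model", "SelectionReport"]

_TIE_TOL = 1e-9


@dataclass
class SelectionReport:
    """Per-residue outcome of model selection."""

    residue: object
    criterion: str
    scores: dict  # model_id -> (chi2, score or p-value)
    selected_model: int | None
    rex: float | None = None
    kex: float | None = None


def aic(chi2: float, k: int) -> float:
    """Akaike information criterion, chi-square form."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return chi2 + 2.0 * k


def aicc(chi2: float, k: int, n: int) -> float:
    """AIC with the second-order small-sample correction."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n}, k={k} (n must exceed k+1); use AIC"
        )
    return chi2 + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def f_test(simple: FitResult, complex: FitResult, alpha: float = 0.05):
    """F-test between nested fits: returns (choose_complex, p_value).

    F = ((chi2_s - chi2_c)/(k_c - k_s)) / (chi2_c/(n - k_c)); the more
    complex model is kept iff p < alpha.
    """
    if complex.k_params <= simple.k_params:
        raise ValueError("complex model must have more parameters")
    if complex.n_points != simple.n_points:
        raise ValueError("fits must share the same data points")
    n, ks, kc = simple.n_points, simple.k_params, complex.k_params
    if complex.chi2 == 0.0:
        warnings.warn("degenerate (chi2 = 0) complex fit; F-test trivially accepts")
        return True, 0.0
    F = ((simple.chi2 - complex.chi2) / (kc - ks)) / (complex.chi2 / (n - kc))
    if F <= 0:
        return False, 1.0
    p = float(f_dist.sf(F, kc - ks, n - kc))
    return p < alpha, p


def _score(fit: FitResult, criterion: str) -> float:
    if criterion == "aic":
        return aic(fit.chi2, fit.k_params)
    return aicc(fit.chi2, fit.k_params, fit.n_points)


def select_model(
    fits: list[FitResult], criterion: str = "aicc", alpha: float = 0.05
) -> SelectionReport:
    """Pick the best model for one residue from its competing fits.

    AIC/AICc: lowest score wins, simpler model on ties. F-test: chain
    model 1 vs 2, then the winner vs model 3. The winning fit gets its
    ``selected`` flag, ``aic``/``aicc`` fields are filled on every fit,
    and the exchange contribution Rex of the winner is reported.
    """
    if criterion not in ("aicc", "aic", "ftest"):
        raise ValueError(f"unknown criterion {criterion!r}")
    fits = sorted(fits, key=lambda f: f.model_id)
    residue = fits[0].residue
    converged = [f for f in fits if f.converged]
    for f in fits:
        f.aic = aic(f.chi2, f.k_params)
        try:
            f.aicc = aicc(f.chi2, f.k_params, f.n_points)
        except ValueError:
            f.aicc = None
    if not converged:
        return SelectionReport(residue, criterion, {}, None)

    if criterion in ("aicc", "aic"):
        scores = {f.model_id: (f.chi2, _score(f, criterion)) for f in converged}
        best = min(converged, key=lambda f: (_score(f, criterion), f.model_id))
        # prefer the simpler model on (near-)ties
        for f in converged:
            if (
                f.model_id < best.model_id
                and _score(f, criterion) - _score(best, criterion) <= _TIE_TOL
            ):
                best = f
    else:
        by_id = {f.model_id: f for f in converged}
        winner = by_id[min(by_id)]
        scores = {}
        chain = sorted(by_id)
        for mid in chain[1:]:
            choose, p = f_test(winner, by_id[mid], alpha=alpha)
            scores[mid] = (by_id[mid].chi2, p)
            if choose:
                winner = by_id[mid]
        scores.setdefault(chain[0], (by_id[chain[0]].chi2, None))
        best = winner

    for f in fits:
        f.selected = f is best
    rex = compute_rex(best.params) if best.model_id in (2, 3) else 0.0
    return SelectionReport(
        residue=residue,
        criterion=criterion,
        scores=scores,
        selected_model=best.model_id,
        rex=rex,
        kex=best.params.kex,
    )
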