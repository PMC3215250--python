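"""Basic dispersion-curve and correlation plots (PNG/SVG)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import evaluate

__all__ = ["plot_dispersion", "plot_correlation"]


def plot_dispersion(profile, fits=None, path=None):
    """Dispersion profile with optional fitted model curves overlaid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(
        profile.nu_cpmg,
        profile.r2eff,
        yerr=profile.sigma,
        fmt="o",
        ms=4,
        capsize=2,
        label=f"residue {profile.residue}",
    )
    if fits:
        grid = np.linspace(profile.nu_cpmg.min(), profile.nu_cpmg.max(), 200)
        for fit in fits:
            ax.plot(grid, evaluate(fit.params, grid), label=f"model {fit.model_id}")
    ax.set_xlabel(r"$\nu_\mathrm{CPMG}$ (Hz)")
    ax.set_ylabel(r"$R_2^\mathrm{eff}$ (1/s)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation(true_values, fitted_values, label, path=None):
    """Fitted-versus-generating parameter correlation (cluster checks)."""
    t = np.asarray(true_values, dtype=float)
    f = np.asarray(fitted_values, dtype=float)
    fig, ax = plt.subplots(figsize=(3.8, 3.8))
    ax.scatter(t, f, s=18)
    lo, hi = min(t.min(), f.min()), max(t.max(), f.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlabel(f"generating {label}")
    ax.set_ylabel(f"fitted {label}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
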