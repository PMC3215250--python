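"""Peak intensities -> R2eff dispersion profiles with pooled-variance errors.

The effective transverse relaxation rate at one refocusing frequency is

    R2eff = (1/T_CPMG) * ln(I(0) / I(nu_CPMG))

where ``T_CPMG`` is the constant relaxation period, ``I(0)`` the peak
intensity in the reference spectrum and ``I(nu_CPMG)`` the intensity in
the spectrum recorded with CPMG frequency ``nu_CPMG``. The per-residue
uncertainty ``sigma_R2eff`` is estimated from replicated spectra via the
pooled variance

    sigma^2 = sum_j s_j^2 (n_j - 1) / sum_j (n_j - 1)

over replicate groups j, and is held constant within a residue (per
field).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FieldContext

__all__ = [
    "REFERENCE",
    "SchedulePoint",
    "CPMGSchedule",
    "DispersionProfile",
    "compute_r2eff",
    "pooled_sigma",
    "build_profiles",
]

logger = logging.getLogger(__name__)

#: marker for a reference (nu_CPMG absent) spectrum in a schedule
REFERENCE = None

#: two nu_CPMG values closer than this (Hz) form one replicate group
REPLICATE_TOL_HZ = 0.5

#: floor applied to degenerate (zero) pooled sigma, 1/s
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class SchedulePoint:
    spectrum_id: str
    nu_cpmg: float | None  # None marks a reference spectrum

    @property
    def is_reference(self) -> bool:
        return self.nu_cpmg is None


@dataclass
class CPMGSchedule:
    """Experiment definition: which spectrum was recorded at which nu_CPMG.

    ``t_cpmg`` is the constant CPMG period in seconds. ``points`` lists
    every spectrum, including replicates and at least one reference.
    """

    t_cpmg: float
    points: list[SchedulePoint]
    field: FieldContext

    def __post_init__(self) -> None:
        if self.t_cpmg <= 0:
            raise ValueError("t_cpmg must be positive")
        if not any(p.is_reference for p in self.points):
            raise ValueError("schedule needs at least one reference spectrum")
        for p in self.points:
            if p.nu_cpmg is not None and p.nu_cpmg <= 0:
                raise ValueError(f"nu_cpmg must be positive ({p.spectrum_id})")

    @property
    def reference_ids(self) -> list[str]:
        return [p.spectrum_id for p in self.points if p.is_reference]

    @property
    def cpmg_points(self) -> list[SchedulePoint]:
        return [p for p in self.points if not p.is_reference]


@dataclass
class DispersionProfile:
    """Per-residue R2eff versus nu_CPMG at a single static field.

    ``sigma`` is the single pooled uncertainty shared by every point of
    the profile. ``negative`` flags points where I(nu) exceeded I(0).
    """

    residue: int | str
    field: FieldContext
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: float
    negative: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.nu_cpmg.shape != self.r2eff.shape:
            raise ValueError("nu_cpmg and r2eff must have equal length")
        order = np.argsort(self.nu_cpmg, kind="stable")
        self.nu_cpmg = self.nu_cpmg[order]
        self.r2eff = self.r2eff[order]
        if self.negative is not None:
            self.negative = np.asarray(self.negative, dtype=bool)[order]
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def n_points(self) -> int:
        return int(self.nu_cpmg.size)


def compute_r2eff(i0: float, i_nu: float, t_cpmg: float) -> float:
    """R2eff (1/s) from one intensity ratio over the constant CPMG time.

    Negative values (``i_nu > i0``) are returned as-is; callers decide
    whether to keep or drop them. Non-positive intensities have no
    defined rate and raise ``ValueError``.
    """
    if t_cpmg <= 0:
        raise ValueError("t_cpmg must be positive")
    if i0 <= 0 or i_nu <= 0:
        raise ValueError("intensities must be positive to extract R2eff")
    return math.log(i0 / i_nu) / t_cpmg


def pooled_sigma(replicate_groups) -> float:
    """Pooled standard deviation over replicate groups ``(n_j, s_j)``.

    Groups with ``n_j < 2`` carry no degrees of freedom and are ignored.
    A degenerate zero result is floored at ``SIGMA_FLOOR`` with a
    warning so chi-square stays finite.
    """
    num = 0.0
    den = 0
    for n_j, s_j in replicate_groups:
        if n_j >= 2:
            num += s_j * s_j * (n_j - 1)
            den += n_j - 1
    if den == 0:
        raise ValueError("pooled_sigma needs at least one group with n >= 2")
    sigma = math.sqrt(num / den)
    if sigma == 0.0:
        warnings.warn(
            "zero pooled variance; applying sigma floor "
            f"{SIGMA_FLOOR} 1/s"
        )
        sigma = SIGMA_FLOOR
    return sigma


def _group_replicates(nus: np.ndarray) -> list[np.ndarray]:
    """Index groups of nu values closer than ``REPLICATE_TOL_HZ``."""
    order = np.argsort(nus, kind="stable")
    groups: list[list[int]] = []
    for idx in order:
        if groups and nus[idx] - nus[groups[-1][0]] < REPLICATE_TOL_HZ:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return [np.array(g) for g in groups]


def build_profiles(
    peaks: pd.DataFrame,
    schedule: CPMGSchedule,
    default_rel_sigma: float = 0.02,
    drop_negative: bool = False,
) -> list[DispersionProfile]:
    """Convert a peak table into one dispersion profile per residue.

    ``peaks`` is indexed by residue with one column per spectrum_id;
    missing intensities (NaN) propagate to missing points. Multiple
    reference spectra are averaged into I(0). Replicated nu_CPMG values
    yield separate points and feed the pooled-variance error; residues
    without any replicates fall back to ``default_rel_sigma`` times
    their median R2eff (with a warning).
    """
    missing = [
        p.spectrum_id for p in schedule.points if p.spectrum_id not in peaks.columns
    ]
    if missing:
        raise KeyError(f"schedule spectra missing from peak table: {missing}")

    profiles = []
    for residue, row in peaks.iterrows():
        refs = [
            row[s]
            for s in schedule.reference_ids
            if pd.notna(row[s]) and row[s] > 0
        ]
        if not refs:
            warnings.warn(f"residue {residue}: no usable reference intensity; skipped")
            continue
        i0 = float(np.mean(refs))

        nus, rates, neg = [], [], []
        for p in schedule.cpmg_points:
            val = row[p.spectrum_id]
            if pd.isna(val) or val <= 0:
                if pd.notna(val):
                    warnings.warn(
                        f"residue {residue}, spectrum {p.spectrum_id}: "
                        "non-positive intensity; point dropped"
                    )
                continue
            r = compute_r2eff(i0, float(val), schedule.t_cpmg)
            if r < 0:
                warnings.warn(
                    f"residue {residue}, nu={p.nu_cpmg} Hz: negative R2eff "
                    f"({r:.3g} 1/s)"
                )
                if drop_negative:
                    continue
            nus.append(p.nu_cpmg)
            rates.append(r)
            neg.append(r < 0)
        if len(nus) < 2:
            warnings.warn(f"residue {residue}: fewer than 2 usable points; skipped")
            continue

        nus_arr = np.array(nus)
        rates_arr = np.array(rates)
        groups = [
            (len(g), float(np.std(rates_arr[g], ddof=1)))
            for g in _group_replicates(nus_arr)
            if len(g) >= 2
        ]
        if groups:
            sigma = pooled_sigma(groups)
        else:
            sigma = default_rel_sigma * abs(float(np.median(rates_arr)))
            sigma = max(sigma, SIGMA_FLOOR)
            warnings.warn(
                f"residue {residue}: no replicated nu_CPMG points; "
                f"sigma_R2eff defaulted to {default_rel_sigma:.0%} of the "
                f"median R2eff ({sigma:.4g} 1/s)"
            )
        profiles.append(
            DispersionProfile(
                residue=residue,
                field=schedule.field,
                nu_cpmg=nus_arr,
                r2eff=rates_arr,
                sigma=sigma,
                negative=np.array(neg),
            )
        )
    return profiles


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tidy frame of profiles (residue, field_MHz, nu_cpmg_Hz, r2eff, sigma)."""
    rows = []
    for p in profiles:
        for nu, r in zip(p.nu_cpmg, p.r2eff):
            rows.append(
                {
                    "residue": p.residue,
                    "field_MHz": p.field.frequency_mhz,
                    "nu_cpmg_Hz": nu,
                    "r2eff": r,
                    "sigma": p.sigma,
                }
            )
    return pd.DataFrame(rows)
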