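"""Readers and writers for the external text formats.

Inputs: peak lists (generic two-column TSV, Sparky-like, or NMRView-like
tables), Bruker vd/vc lists for the CPMG schedule, protein sequences
(FASTA, plain string, or PDB), and a YAML project configuration.
Outputs: deterministic results/profile CSV files and PyMOL coloring
macros. All writers render floats with 6 significant figures and a
fixed row order so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .models import FieldContext, compute_rex
from .rates import CPMGSchedule, SchedulePoint, profiles_to_frame

__all__ = [
    "read_peak_list",
    "read_vd_list",
    "schedule_from_vd",
    "read_sequence",
    "write_profiles_csv",
    "write_results_csv",
    "write_pymol_macro",
    "ProjectConfig",
]

_RESIDUE_RE = re.compile(r"(\d+)")

#: fixed colors for the model-selection macro
_MODEL_COLORS = {1: "skyblue", 2: "green", 3: "red"}


def _parse_residue(token: str) -> int | None:
    """Residue number from assignment strings like '24Trp', 'W24', '24'."""
    m = _RESIDUE_RE.search(token)
    return int(m.group(1)) if m else None


def read_peak_list(path, dialect: str = "generic_tsv") -> pd.Series:
    """One spectrum's residue -> intensity mapping.

    Dialects: ``generic_tsv`` (two whitespace/tab-separated columns,
    '#' comments), ``sparky_like`` (assignment first, intensity last,
    optional 'Assignment' header), ``nmrview_table`` (header row naming
    a residue-like and an intensity-like column). Unparseable lines are
    skipped with a line-numbered warning; a file yielding zero rows is
    a hard error.
    """
    if dialect not in ("generic_tsv", "sparky_like", "nmrview_table"):
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.readlines()

    data: dict[int, float] = {}
    if dialect == "nmrview_table":
        header = None
        for lineno, raw in enumerate(lines, 1):
            tokens = raw.split()
            if not tokens or raw.lstrip().startswith("#"):
                continue
            if header is None:
                header = [t.lower() for t in tokens]
                res_col = _find_column(header, ("residue", "label", "assign", "res"))
                int_col = _find_column(header, ("intensity", "height", "int", "volume"))
                if res_col is None or int_col is None:
                    raise ValueError(
                        f"{path}: NMRView-style header must name residue and "
                        "intensity columns"
                    )
                continue
            _ingest(tokens, res_col, int_col, data, path, lineno)
        if header is None:
            raise ValueError(f"{path}: empty NMRView-style table")
    else:
        for lineno, raw in enumerate(lines, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if dialect == "sparky_like" and tokens[0].lower() == "assignment":
                continue
            _ingest(tokens, 0, -1, data, path, lineno)

    if not data:
        raise ValueError(f"{path}: no peak intensities parsed")
    name = os.path.splitext(os.path.basename(str(path)))[0]
    return pd.Series(data, name=name).sort_index()


def _find_column(header: list, candidates) -> int | None:
    for cand in candidates:
        for i, name in enumerate(header):
            if cand in name:
                return i
    return None


def _ingest(tokens, res_col, int_col, data, path, lineno) -> None:
    try:
        residue = _parse_residue(tokens[res_col])
        intensity = float(tokens[int_col])
    except (ValueError, IndexError):
        residue = None
        intensity = None
    if residue is None or intensity is None:
        warnings.warn(f"{path}:{lineno}: unparseable peak line skipped")
        return
    data[residue] = intensity


def read_vd_list(path, t_cpmg: float, mode: str = "frequency_hz") -> list:
    """Bruker vd/vc list -> ordered nu_CPMG values (None = reference).

    ``frequency_hz``: values are CPMG frequencies directly.
    ``loop_count``: values are CPMG loop counts; nu = count / T_CPMG.
    Zero or blank entries mark reference spectra; negatives are a hard
    error.
    """
    if mode not in ("frequency_hz", "loop_count"):
        raise ValueError(f"unknown vd-list mode {mode!r}")
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vd entry") from exc
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative vd entry")
            if v == 0:
                values.append(None)
            elif mode == "frequency_hz":
                values.append(v)
            else:
                values.append(v / t_cpmg)
    if not values:
        raise ValueError(f"{path}: empty vd list")
    return values


def schedule_from_vd(
    path, t_cpmg: float, field: FieldContext, mode: str = "frequency_hz"
) -> CPMGSchedule:
    """Schedule whose spectrum ids are 'spec_0', 'spec_1', ... in vd order."""
    nus = read_vd_list(path, t_cpmg, mode=mode)
    points = [SchedulePoint(f"spec_{i}", nu) for i, nu in enumerate(nus)]
    return CPMGSchedule(t_cpmg=t_cpmg, points=points, field=field)


def read_sequence(source) -> dict:
    """Residue-number -> one-letter amino acid map.

    ``source`` is a FASTA file, a PDB file (SEQRES if present, else the
    ATOM records of the first chain, keeping author numbering), a file
    holding a plain sequence, or the plain sequence string itself.
    FASTA/plain sequences are numbered from 1.
    """
    text = None
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
        if re.search(r"^(ATOM|SEQRES|HEADER)", text, re.MULTILINE):
            return _sequence_from_pdb(str(source))
    else:
        text = str(source)
    seq = _plain_from_text(text)
    if not seq:
        raise ValueError("empty sequence")
    return {i: aa for i, aa in enumerate(seq, start=1)}


def _plain_from_text(text: str) -> str:
    seq = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith((">", ";", "#")):
            continue
        if not re.fullmatch(r"[A-Za-z*\-]+", line):
            raise ValueError(f"not a sequence line: {line!r}")
        seq.append(line.replace("*", "").replace("-", "").upper())
    return "".join(seq)


def _sequence_from_pdb(path: str) -> dict:
    from Bio import SeqIO
    from Bio.PDB import PDBParser
    from Bio.SeqUtils import seq1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seqres = list(SeqIO.parse(path, "pdb-seqres"))
    if seqres:
        return {i: aa for i, aa in enumerate(str(seqres[0].seq), start=1)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", path)
    chain = next(structure[0].get_chains())
    mapping = {}
    for res in chain:
        if res.id[0] != " ":
            continue
        mapping[res.id[1]] = seq1(res.get_resname())
    if not mapping:
        raise ValueError(f"{path}: no amino-acid residues found")
    return mapping


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.6g}"


def write_profiles_csv(profiles, path) -> None:
    """Tidy CSV: residue, field_MHz, nu_cpmg_Hz, r2eff, sigma."""
    frame = profiles_to_frame(profiles)
    frame = frame.sort_values(["residue", "field_MHz", "nu_cpmg_Hz"])
    frame.to_csv(path, index=False, float_format="%.6g")


_RESULT_COLUMNS = [
    "residue", "model", "selected", "r20", "r20_err", "kex", "kex_err",
    "pb", "pb_err", "dw", "dw_err", "phi", "rex", "chi2", "aic", "aicc",
]


def write_results_csv(results, path) -> None:
    """One row per residue x model with parameters, errors and scores.

    Deterministic ordering (residue, then model id); 6 significant
    figures throughout so reruns are byte-identical.
    """
    if not results:
        raise ValueError("no results to write")
    rows = []
    for fit in results:
        p = fit.params
        err = fit.param_errors or {}
        r20 = np.atleast_1d(np.asarray(p.r20, dtype=float))
        rows.append(
            {
                "residue": fit.residue,
                "model": fit.model_id,
                "selected": int(fit.selected),
                "r20": _fmt(float(r20[0])),
                "r20_err": _fmt(err.get("r20", err.get("r20_0"))),
                "kex": _fmt(p.kex),
                "kex_err": _fmt(err.get("kex")),
                "pb": _fmt(p.pb),
                "pb_err": _fmt(err.get("pb")),
                "dw": _fmt(p.dw),
                "dw_err": _fmt(err.get("dw")),
                "phi": _fmt(p.phi),
                "rex": _fmt(compute_rex(p)),
                "chi2": _fmt(fit.chi2),
                "aic": _fmt(fit.aic),
                "aicc": _fmt(fit.aicc),
            }
        )
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    frame = frame.sort_values(["residue", "model"], kind="stable")
    frame.to_csv(path, index=False)


def write_pymol_macro(values: dict, mode: str, path, pdb_residues=None) -> None:
    """PyMOL macro coloring analyzed residues on a structure.

    ``mode='model'`` colors by selected model id (fixed palette);
    ``mode='kex'``/``'rex'`` ramp from yellow to red over the observed
    value range and scale the stick radius with the value. Everything
    without data stays black. Residues absent from ``pdb_residues``
    (when given) are skipped with a warning.
    """
    if mode not in ("model", "kex", "rex"):
        raise ValueError(f"unknown macro mode {mode!r}")
    usable = {}
    for res, val in values.items():
        if pdb_residues is not None and res not in pdb_residues:
            warnings.warn(f"residue {res} absent from the structure; skipped")
            continue
        usable[res] = val
    if not usable:
        warnings.warn("no residues to color; macro contains only the default")

    lines = [
        f"# dispersion {mode} coloring",
        "bg_color white",
        "hide everything",
        "show cartoon",
        "color black, polymer",
    ]
    if mode == "model":
        for res in sorted(usable):
            color = _MODEL_COLORS.get(int(usable[res]), "grey50")
            lines.append(f"color {color}, resi {res}")
    else:
        vals = {r: float(v) for r, v in usable.items()}
        if vals:
            vmin, vmax = min(vals.values()), max(vals.values())
            span = vmax - vmin
            for res in sorted(vals):
                t = 1.0 if span == 0 else (vals[res] - vmin) / span
                lines.append(
                    f"set_color disp_c{res}, [1.000, {1.0 - t:.3f}, 0.000]"
                )
                lines.append(f"color disp_c{res}, resi {res}")
                lines.append(f"show sticks, resi {res}")
                lines.append(
                    f"set_bond stick_radius, {0.2 + 0.6 * t:.3f}, resi {res}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class ProjectConfig:
    """YAML-backed project description for the CLI ``fit`` pipeline."""

    t_cpmg: float
    fields: list  # [{frequency_mhz, reference_mhz?, temperature_k?, vd_list, vd_mode?, peak_lists: [...]}]
    output_dir: str = "."
    models: tuple = (1, 2, 3)
    criterion: str = "aicc"
    mc_sims: int = 500
    seed: int = 0
    sequence: str | None = None
    pdb: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "fields" not in raw or "t_cpmg" not in raw:
            raise ValueError(f"{path}: config must define t_cpmg and fields")
        known = {k: raw[k] for k in cls.__dataclass_fields__ if k in raw}
        cfg = cls(**known)
        for fdef in cfg.fields:
            if "vd_list" not in fdef or "peak_lists" not in fdef:
                raise ValueError("each field needs vd_list and peak_lists")
            if len(fdef["peak_lists"]) == 0:
                raise ValueError("each field needs at least one peak list")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.__dict__.items()
                },
                fh,
                sort_keys=True,
            )
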