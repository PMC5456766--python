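"""Curve-file and configuration I/O.

Extraction curves travel as plain delimited text: ``#``-prefixed metadata
comment lines, a header row naming the abscissa (``t_min`` or ``q_kgkg``)
and the yield column ``e_kgkg``, then whitespace-delimited numeric rows.
Writing then reading reproduces the points exactly as decimal text.

Run configuration is YAML with nested blocks (``bed``, ``equilibrium``,
``transport``, ``initial``, ``simulation``, ``fit``); keys carry explicit
unit suffixes (``N_kg``, ``Q_kg_per_min``, ...).  Cross-field constraints
are delegated to the module validators.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import yaml

from .bed import BedSpec, flow_derived
from .equilibrium import EquilibriumParams
from .lumped import ModelParams
from .synthetic import ExtractionCurve

__all__ = [
    "read_curve",
    "write_curve",
    "load_config",
    "bed_from_config",
    "equilibrium_from_config",
    "model_from_config",
]

_ABSCISSA_COLUMNS = {"t_min": "t", "q_kgkg": "q"}
_KIND_TO_COLUMN = {"t": "t_min", "q": "q_kgkg"}


class CurveParseError(ValueError):
    """Malformed curve file; the message names the offending line."""


def write_curve(curve: ExtractionCurve, path) -> None:
    """Write a curve as delimited text with ``#`` metadata comments."""
    path = Path(path)
    lines = []
    for key, value in curve.metadata.items():
        if key == "comments":
            continue
        lines.append(f"# {key}: {value}")
    lines.extend(curve.metadata.get("comments", []))
    lines.append(f"{_KIND_TO_COLUMN[curve.abscissa_kind]}\te_kgkg")
    for v, e in zip(curve.values, curve.yields):
        lines.append(f"{float(v)!r}\t{float(e)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_curve(path) -> ExtractionCurve:
    """Read a curve file written by :func:`write_curve` (or by hand).

    Raises :class:`CurveParseError` naming the line for malformed rows or
    a non-increasing abscissa.
    """
    path = Path(path)
    comments: list[str] = []
    meta: dict = {}
    header: list[str] | None = None
    values: list[float] = []
    yields: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(raw)
            m = re.match(r"#\s*([\w.]+)\s*:\s*(.*)$", line)
            if m:
                key, val = m.group(1), m.group(2).strip()
                try:
                    meta[key] = int(val)
                except ValueError:
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = None if val == "None" else val
            continue
        fields = re.split(r"[\t,;]+|\s+", line)
        if header is None:
            if len(fields) < 2 or fields[0] not in _ABSCISSA_COLUMNS:
                raise CurveParseError(
                    f"{path}:{lineno}: expected header '<t_min|q_kgkg> e_kgkg', got {line!r}"
                )
            header = fields
            continue
        if len(fields) != len(header):
            raise CurveParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            v, e = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise CurveParseError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
        if values and v <= values[-1]:
            raise CurveParseError(
                f"{path}:{lineno}: abscissa not strictly increasing "
                f"({v!r} after {values[-1]!r})"
            )
        values.append(v)
        yields.append(e)
    if header is None:
        raise CurveParseError(f"{path}: no header row found")
    if not values:
        raise CurveParseError(f"{path}: no data rows found")
    meta["comments"] = comments
    return ExtractionCurve(
        _ABSCISSA_COLUMNS[header[0]], np.array(values), np.array(yields), meta
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def bed_from_config(cfg: dict) -> BedSpec:
    """Build a :class:`BedSpec` from the ``bed`` config block."""
    b = cfg.get("bed", cfg)
    try:
        return BedSpec(
            N=float(b["N_kg"]),
            Qp=float(b["Q_kg_per_min"]),
            rho_f=float(b["rho_f_kg_m3"]),
            eps=float(b["eps"]) if "eps" in b else None,
            rho_s=float(b.get("rho_s_kg_m3", 950.0)),
            V=float(b["V_m3"]) if "V_m3" in b else None,
            with_beads=bool(b.get("with_beads", False)),
            dp=float(b["dp_m"]) if "dp_m" in b else None,
            SE=float(b["SE_m2"]) if "SE_m2" in b else None,
        )
    except KeyError as exc:
        raise ValueError(f"bed block missing required key {exc}") from exc


def equilibrium_from_config(cfg: dict) -> EquilibriumParams:
    """Build :class:`EquilibriumParams` from the ``equilibrium`` block."""
    e = cfg.get("equilibrium", cfg)
    try:
        eq = EquilibriumParams(ys=float(e["ys"]), xt=float(e["xt"]), K=float(e["K"]))
    except KeyError as exc:
        raise ValueError(f"equilibrium block missing required key {exc}") from exc
    return eq.require_valid()


def model_from_config(cfg: dict) -> tuple[ModelParams, BedSpec]:
    """Assemble the full simulation parameter set from a run config."""
    bed = bed_from_config(cfg)
    eq = equilibrium_from_config(cfg)
    fd = flow_derived(bed)
    tb = cfg.get("transport", {})
    if "tc_min" in tb:
        tc = float(tb["tc_min"])
    elif "tf_min" in tb:
        tc = float(tb["tf_min"]) + float(tb.get("ti_min", 0.0))
    else:
        raise ValueError("transport block must give tc_min or tf_min (+ ti_min)")
    init = cfg.get("initial", {})
    params = ModelParams(
        eq=eq,
        xu=float(cfg["xu"]),
        tc=tc,
        tr=fd.tr,
        gamma=fd.gamma,
        y0=float(init.get("y0", 0.0)),
        x0=float(init["x0"]) if "x0" in init else None,
    )
    return params, bed
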