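"""File formats and run configuration.

The lingua franca between the experimental and back-calculated sides is a
rates CSV with columns residue, r1, r1_err, noe, noe_err, eta_xy,
eta_xy_err. Empty cells mean "not measured" and are kept as missing — a
residue is never zero-filled. Author residue numbering is preserved as-is.

A minimal NMR-STAR reader is included for ingesting archive relaxation
loops; it maps tags by name within each loop rather than by position, and
only reads — deposition tooling is out of scope.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model_free import ResidueRates
from .spin import InteractionConstants

__all__ = [
    "RunConfig",
    "RATES_COLUMNS",
    "read_relaxation_table",
    "write_relaxation_table",
    "read_intensity_csv",
    "read_nmrstar_rates",
]

RATES_COLUMNS = (
    "residue", "r1", "r1_err", "noe", "noe_err", "eta_xy", "eta_xy_err",
)


@dataclass
class RunConfig:
    """Resolved analysis configuration, embedded in outputs for provenance."""

    field_mhz: float = 600.13
    r_nh_angstrom: float = 1.023
    delta_sigma_ppm: float = -166.0
    delta_sigma_p2_ppm: float = -145.0
    tau_c_ns: float = 14.7
    s2_threshold: float = 0.8
    max_rel_err: float = 0.10
    rigid_ranges: list[tuple[int, int]] = field(default_factory=lambda: [
        (131, 152), (162, 193), (204, 265), (296, 342),
        (351, 366), (383, 392),
    ])
    segment_window_ns: float = 500.0
    sd_max: float = 0.3
    jump_max: float = 1.0
    equilibration_ns: float = 700.0
    lag_max_factor: float = 7.0       # lag_max = factor * tau_c
    n_boot: int = 100
    seed: int = 0
    eta_xy_j_zero: bool = True
    ct_exponent_factor: float = 4.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.rigid_ranges = [tuple(r) for r in cfg.rigid_ranges]
        return cfg

    def constants(self) -> InteractionConstants:
        return InteractionConstants(
            proton_freq_mhz=self.field_mhz,
            r_nh_angstrom=self.r_nh_angstrom,
            delta_sigma_ppm=self.delta_sigma_ppm,
            delta_sigma_p2_ppm=self.delta_sigma_p2_ppm,
        )

    def provenance(self) -> dict:
        from . import __version__
        return {"package": "relaxsel", "version": __version__,
                "config": asdict(self)}


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_relaxation_table(path: str | Path,
                          format: str = "csv") -> list[ResidueRates]:
    """Read a per-residue rates table (CSV/TSV, or a NMR-STAR file)."""
    if format == "nmrstar":
        return read_nmrstar_rates(path)
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format: {format}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(RATES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing columns {sorted(missing)}; "
            f"expected {', '.join(RATES_COLUMNS)}"
        )
    bad = df["residue"].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()   # 1-based + header
        raise ValueError(f"{path}: malformed residue ids on lines {lines}")
    out = []
    for _, row in df.iterrows():
        out.append(ResidueRates(
            residue=int(row["residue"]),
            r1=_opt(row["r1"]), r1_err=_opt(row["r1_err"]),
            noe=_opt(row["noe"]), noe_err=_opt(row["noe_err"]),
            eta_xy=_opt(row["eta_xy"]), eta_xy_err=_opt(row["eta_xy_err"]),
        ))
    return out


def write_relaxation_table(table: Sequence[ResidueRates],
                           path: str | Path) -> None:
    rows = [{
        "residue": r.residue,
        "r1": r.r1, "r1_err": r.r1_err,
        "noe": r.noe, "noe_err": r.noe_err,
        "eta_xy": r.eta_xy, "eta_xy_err": r.eta_xy_err,
    } for r in table]
    pd.DataFrame(rows, columns=list(RATES_COLUMNS)).to_csv(path, index=False)


def read_intensity_csv(path: str | Path) -> dict[int, "pd.DataFrame"]:
    """Intensity series grouped by residue; columns residue, delay,
    intensity and optionally noise."""
    df = pd.read_csv(path)
    required = {"residue", "delay", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return {int(res): g.sort_values("delay").reset_index(drop=True)
            for res, g in df.groupby("residue")}


# ---------------------------------------------------------------------------
# minimal NMR-STAR relaxation-loop reader

_RATE_LOOP_HINTS = {
    "heteronucl_t1_relaxation": ("r1", "r1_err"),
    "t1": ("r1", "r1_err"),
    "heteronucl_noe": ("noe", "noe_err"),
    "noe": ("noe", "noe_err"),
    "cross_correlation": ("eta_xy", "eta_xy_err"),
    "eta_xy": ("eta_xy", "eta_xy_err"),
}


def _star_loops(text: str):
    """Yield (tags, rows) for each loop_ ... stop_ block."""
    for block in re.findall(r"loop_(.*?)stop_", text, re.S):
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        tags = [ln for ln in lines if ln.startswith("_")]
        data_lines = [ln for ln in lines if not ln.startswith("_")
                      and not ln.startswith("#")]
        rows = []
        for ln in data_lines:
            rows.append(ln.split())
        yield tags, rows


def _tag_index(tags: list[str], *names: str) -> int | None:
    lowered = [t.lower().split(".")[-1] for t in tags]
    for name in names:
        if name in lowered:
            return lowered.index(name)
    return None


def read_nmrstar_rates(path: str | Path) -> list[ResidueRates]:
    """Relaxation rates from NMR-STAR loops, mapped by tag name.

    Recognizes loops whose tag frame mentions a T1/R1, heteronuclear NOE,
    or cross-correlation category; within a loop, residue number, value
    and error columns are located by tag name (Seq_ID/Comp_index_ID, Val,
    Val_err), never by position.
    """
    text = Path(path).read_text()
    records: dict[int, ResidueRates] = {}
    for tags, rows in _star_loops(text):
        joined = " ".join(tags).lower()
        param = None
        for hint, (val_name, err_name) in _RATE_LOOP_HINTS.items():
            if hint in joined:
                param, err_param = val_name, err_name
                break
        if param is None:
            continue
        i_res = _tag_index(tags, "seq_id", "comp_index_id", "residue")
        i_val = _tag_index(tags, "val", "value", "t1_val", "noe_val")
        i_err = _tag_index(tags, "val_err", "value_err", "t1_val_err",
                           "noe_val_err")
        if i_res is None or i_val is None:
            continue
        for row in rows:
            if len(row) <= max(i_res, i_val):
                continue
            try:
                resid = int(row[i_res])
                val = float(row[i_val]) if row[i_val] not in (".", "?") else None
            except ValueError:
                continue
            err = None
            if i_err is not None and len(row) > i_err and \
                    row[i_err] not in (".", "?"):
                err = abs(float(row[i_err]))
            rec = records.setdefault(resid, ResidueRates(residue=resid))
            setattr(rec, param, val)
            setattr(rec, err_param, err)
            if val is not None:
                rec.flags.discard("missing")
    if not records:
        raise ValueError(f"{path}: no relaxation loops recognized")
    out = []
    for resid in sorted(records):
        rec = records[resid]
        rec.__post_init__()     # re-derive missing flag after filling
        out.append(rec)
    return out


def write_json_report(payload: dict, path: str | Path,
                      config: RunConfig | None = None) -> None:
    if config is not None:
        payload = {**payload, "provenance": config.provenance()}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
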