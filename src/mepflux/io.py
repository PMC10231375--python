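"""CSV readers/writers for all package interfaces.

One CSV dialect only: comma separator, dot decimal, mandatory header,
UTF-8.  Malformed inputs are rejected with a SchemaError rather than
guessed at, so test fixtures stay bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .enzyme_kinetics import MMKinetics, ProgressCurve
from .exceptions import SchemaError
from .label_model import LabelTimeCourse
from .pool_estimation import METABOLITE_ORDER, MetabolitePoolRecord

__all__ = [
    "read_timecourse",
    "read_pool_table",
    "read_assay",
    "read_profile",
    "write_results",
]

_SPLIT_RTOL = 1e-6


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_timecourse(path: str | Path) -> LabelTimeCourse:
    """Read `time_min,fraction[,sd]`; rows sorted by time, duplicates rejected."""
    df = _read_csv(path, {"time_min", "fraction"})
    df = df.sort_values("time_min")
    times = df["time_min"].to_numpy(dtype=float)
    fractions = df["fraction"].to_numpy(dtype=float)
    if np.any(np.diff(times) == 0):
        raise SchemaError(f"{path}: duplicate time values")
    if np.any((fractions < 0) | (fractions > 1)):
        raise SchemaError(f"{path}: fraction outside [0, 1]")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    try:
        return LabelTimeCourse(times=times, fractions=fractions, sd=sd)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_pool_table(path: str | Path) -> tuple[list[MetabolitePoolRecord], float | None]:
    """Read `metabolite,total_pool_nmol_per_gfw,final_fraction`.

    A row named `isoprene` (pool column may be empty) supplies the
    reference plateau; returns (records, isoprene_final_fraction or None).
    """
    df = _read_csv(path, {"metabolite", "total_pool_nmol_per_gfw", "final_fraction"})
    records: list[MetabolitePoolRecord] = []
    isoprene_fraction: float | None = None
    for _, row in df.iterrows():
        name = str(row["metabolite"]).strip()
        if name.lower() == "isoprene":
            isoprene_fraction = float(row["final_fraction"])
            continue
        if name not in METABOLITE_ORDER:
            raise SchemaError(f"{path}: unknown metabolite {name!r}")
        try:
            records.append(
                MetabolitePoolRecord(
                    name=name,
                    total_pool=float(row["total_pool_nmol_per_gfw"]),
                    final_fraction=float(row["final_fraction"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return records, isoprene_fraction


def read_assay(path: str | Path) -> list[ProgressCurve]:
    """Read `substrate_uM,time_min,product_uM[,dmadp_uM,idp_uM]`.

    Returns one ProgressCurve per distinct substrate level.  When the split
    columns are present their sum must match the combined product to within
    1e-6 relative.
    """
    df = _read_csv(path, {"substrate_uM", "time_min", "product_uM"})
    has_split = {"dmadp_uM", "idp_uM"} <= set(df.columns)
    if has_split:
        total = df["dmadp_uM"] + df["idp_uM"]
        scale = np.maximum(np.abs(df["product_uM"]), 1e-300)
        bad = np.abs(total - df["product_uM"]) / scale > _SPLIT_RTOL
        # rows with zero product and zero split are trivially consistent
        bad &= ~((df["product_uM"] == 0) & (total == 0))
        if bad.any():
            raise SchemaError(
                f"{path}: dmadp_uM + idp_uM deviates from product_uM on "
                f"{int(bad.sum())} row(s)"
            )
    curves = []
    for s_level, group in df.groupby("substrate_uM", sort=True):
        group = group.sort_values("time_min")
        try:
            curves.append(
                ProgressCurve(
                    times=group["time_min"].to_numpy(dtype=float),
                    product=group["product_uM"].to_numpy(dtype=float),
                    substrate_conc=float(s_level),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path} (S={s_level}): {exc}") from exc
    return curves


def read_profile(path: str | Path) -> dict[str, float]:
    """Read a terpenoid product profile `class,moles`."""
    df = _read_csv(path, {"class", "moles"})
    return {str(row["class"]): float(row["moles"]) for _, row in df.iterrows()}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _round_sig(value: Any, sig: int = 6) -> Any:
    if isinstance(value, float) and np.isfinite(value) and value != 0:
        return float(f"{value:.{sig}g}")
    return value


def write_results(
    result: Any,
    path: str | Path,
    fmt: str = "json",
    provenance: dict | None = None,
) -> None:
    """Write a result object as JSON or a flat CSV row, with provenance.

    Numbers are rendered at 6 significant digits; the JSON payload records
    the package version and any provenance the caller supplies (inputs,
    seed, options).
    """
    path = Path(path)
    payload = _to_plain(result)
    if isinstance(result, MMKinetics):
        payload["efficiency"] = result.efficiency
    meta = {"package_version": __version__, **(provenance or {})}
    if fmt == "json":
        doc = {"result": payload, "provenance": meta}

        def _walk(node):
            if isinstance(node, dict):
                return {k: _walk(v) for k, v in node.items()}
            if isinstance(node, list):
                return [_walk(v) for v in node]
            return _round_sig(node)

        with open(path, "w") as fh:
            json.dump(_walk(doc), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        flat = {
            k: _round_sig(v)
            for k, v in payload.items()
            if not isinstance(v, (list, dict))
        }
        flat.update({f"provenance_{k}": v for k, v in meta.items()})
        pd.DataFrame([flat]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'json' or 'csv'")
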