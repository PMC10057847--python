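"""Reading and writing raw dose-response tables.

The raw-curve schema has one row per (variant, replicate, ligand
concentration): columns ``variant, mutation_codes, clone, IPTG,
geo_mean, geo_mean_err, date_plate, row``.  ``IPTG`` is the inducer
concentration in umol/L and ``geo_mean`` the calibrated (MEF)
geometric-mean fluorescence; ``clone``, ``date_plate`` and ``row``
jointly identify a biological/technical replicate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hill import DoseResponseCurve

__all__ = ["S1_COLUMNS", "read_curves", "write_curves"]

S1_COLUMNS = [
    "variant",
    "mutation_codes",
    "clone",
    "IPTG",
    "geo_mean",
    "geo_mean_err",
    "date_plate",
    "row",
]


def read_curves(path) -> dict[str, list[DoseResponseCurve]]:
    """Load raw curves grouped by variant, one curve per replicate."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in S1_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["IPTG"] = pd.to_numeric(df["IPTG"])
    df["geo_mean"] = pd.to_numeric(df["geo_mean"])
    df["geo_mean_err"] = pd.to_numeric(df["geo_mean_err"])
    out: dict[str, list[DoseResponseCurve]] = {}
    for (variant, clone, date_plate, row), grp in df.groupby(
        ["variant", "clone", "date_plate", "row"], sort=False
    ):
        rep_id = f"{clone}/{date_plate}/{row}"
        curve = DoseResponseCurve(
            ligand=grp["IPTG"].to_numpy(float),
            geo_mean=grp["geo_mean"].to_numpy(float),
            geo_mean_err=grp["geo_mean_err"].to_numpy(float),
            replicate_id=rep_id,
        )
        out.setdefault(str(variant), []).append(curve)
    return out


def write_curves(
    path,
    curves_by_variant: dict[str, list[DoseResponseCurve]],
    mutation_codes: dict[str, str] | None = None,
) -> None:
    """Write raw curves in the S1-style schema (one row per point)."""
    mutation_codes = mutation_codes or {}
    rows = []
    for variant, curves in curves_by_variant.items():
        codes = mutation_codes.get(variant, "")
        for curve in curves:
            parts = (curve.replicate_id or "c1/d1/A").split("/")
            clone, date_plate, row_lab = (parts + ["c1", "d1", "A"])[:3]
            for L, gm, ge in zip(curve.ligand, curve.geo_mean, curve.geo_mean_err):
                rows.append(
                    {
                        "variant": variant,
                        "mutation_codes": codes,
                        "clone": clone,
                        "IPTG": L,
                        "geo_mean": gm,
                        "geo_mean_err": ge,
                        "date_plate": date_plate,
                        "row": row_lab,
                    }
                )
    pd.DataFrame(rows, columns=S1_COLUMNS).to_csv(Path(path), index=False)
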