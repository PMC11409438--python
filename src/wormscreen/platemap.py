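"""Plate-map reading and validation.

A plate map is a CSV assigning each well a compound, concentration and role.
Required columns: ``plate, well, compound, conc_um, role``; optional:
``experiment`` (default "E1") and ``genotype`` (default "reporter"). Roles
are ``negative_control`` (vehicle, concentration 0), ``positive_control``
and ``test``. One schema serves the primary screen, validation and
counter-screen runs, so reporter and lin-1 plates flow through identical
machinery.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ["plate", "well", "compound", "conc_um", "role"]
OPTIONAL_DEFAULTS = {"experiment": "E1", "genotype": "reporter"}
VALID_ROLES = ("negative_control", "positive_control", "test")
WELL_RE = re.compile(r"^[A-P]\d{2}$")


def validate_plate_map(pm: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in pm.columns]
    if missing:
        raise ValueError(f"plate map missing required columns: {missing}")
    pm = pm.copy()
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in pm.columns:
            pm[col] = default
    pm["conc_um"] = pd.to_numeric(pm["conc_um"], errors="coerce")

    for i, row in pm.iterrows():
        where = f"row {i + 2}"  # 1-based + header line, as in the file
        if "_" in str(row["plate"]):
            raise ValueError(
                f"{where}: plate id {row['plate']!r} may not contain '_' "
                "(reserved by the image naming convention)"
            )
        if not WELL_RE.match(str(row["well"])):
            raise ValueError(f"{where}: malformed well id {row['well']!r} (expected e.g. B07)")
        if row["role"] not in VALID_ROLES:
            raise ValueError(
                f"{where}: unknown role {row['role']!r}; valid roles are {VALID_ROLES}"
            )
        if pd.isna(row["conc_um"]) or row["conc_um"] < 0:
            raise ValueError(f"{where}: concentration must be a number >= 0, got {row['conc_um']!r}")
        if row["role"] == "negative_control" and row["conc_um"] != 0:
            raise ValueError(
                f"{where}: negative-control well {row['well']} must have concentration 0 "
                f"(vehicle), got {row['conc_um']}"
            )

    dup = pm.duplicated(subset=["plate", "well"])
    if dup.any():
        dupes = pm.loc[dup, ["plate", "well"]].values.tolist()
        raise ValueError(f"duplicate (plate, well) entries: {dupes}")
    return pm.reset_index(drop=True)


def read_plate_map(path: Path) -> pd.DataFrame:
    """Read and validate a plate-map CSV; errors name the offending row."""
    pm = pd.read_csv(path, dtype={"plate": str, "well": str, "compound": str, "role": str})
    return validate_plate_map(pm)
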