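"""Run configuration, per-well simulation parameter assembly, run metadata.

A simulation config YAML mirrors :class:`~wormscreen.simulate.WellSimParams`
field names under ``defaults``, with optional per-role overrides under
``roles`` and per-compound overrides under ``compounds``::

    defaults:      {adult_fraction: 0.8, vulva_rate_adult: 1.0, ...}
    roles:
      positive_control: {vulva_rate_adult: 0.0}
    compounds:
      CMP-0007:         {vulva_rate_adult: 0.05}

Per-well parameters are defaults <- role override <- compound override, and
every well gets its own seed derived from the top-level seed and the well's
identity (so adding wells never perturbs existing wells' draws).

Every CLI command writes a run-metadata JSON next to its outputs recording
the package version, seed, every threshold that affected a decision, and
SHA-256 digests of the inputs — enough to regenerate any output byte-
identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

import wormscreen
from wormscreen.simulate import WellSimParams, well_seed

_TUPLE_FIELDS = {f.name for f in dataclasses.fields(WellSimParams) if "tuple" in str(f.type)}


def _coerce(d: Mapping) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v
    return out


def load_sim_config(path: Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - {"defaults", "roles", "compounds"}
    if unknown:
        raise ValueError(f"unknown simulation config sections: {sorted(unknown)}")
    return cfg


def build_well_params(
    plate_map: pd.DataFrame, sim_config: Mapping, seed: int
) -> dict[tuple[str, str], WellSimParams]:
    """Resolve per-well simulation parameters from a layered config."""
    defaults = _coerce(sim_config.get("defaults", {}))
    roles = {k: _coerce(v) for k, v in sim_config.get("roles", {}).items()}
    compounds = {k: _coerce(v) for k, v in sim_config.get("compounds", {}).items()}
    params: dict[tuple[str, str], WellSimParams] = {}
    for _, row in plate_map.iterrows():
        layered = dict(defaults)
        layered.update(roles.get(row["role"], {}))
        layered.update(compounds.get(row["compound"], {}))
        layered["seed"] = well_seed(seed, row["plate"], row["well"])
        p = WellSimParams(**layered)
        p.validate()
        params[(row["plate"], row["well"])] = p
    return params


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_metadata(
    path: Path,
    command: str,
    seed: int | None,
    configs: Mapping[str, Mapping] | None = None,
    inputs: Mapping[str, Path] | None = None,
) -> None:
    """Write the run-metadata JSON accompanying every CLI output.

    Deliberately timestamp-free: reruns from identical inputs and seed must
    reproduce every output file byte-identically.
    """
    meta = {
        "package": "wormscreen",
        "version": wormscreen.__version__,
        "command": command,
        "seed": seed,
        "configs": {k: dict(v) for k, v in (configs or {}).items()},
        "inputs": {
            k: {"path": str(p), "sha256": sha256_file(p)} for k, p in (inputs or {}).items()
        },
    }
    blob = json.dumps(meta, indent=2, sort_keys=True)
    meta["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
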