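"""Well-level phenotype scores: vulvae per adult and percent larvae.

The two readouts condense the three object classes counted per well:

* ``vulvae_per_adult`` = n_vulvae / n_adults — the MAPK/ERK pathway-activity
  score (about 1 in wild type, about 0 under pathway inhibition, above 2 in
  multivulva genotypes). Undefined when a well has no adults; the undefined
  marker (NaN) propagates through aggregation instead of being coerced to 0.
* ``pct_larvae`` = 100 * n_larvae / (n_adults + n_larvae) — the toxicity
  proxy (worms that failed to reach adulthood). The denominator counts
  worm-classified objects only; rejected objects and vulvae are not animals.

Wells averaging more than 1.5 vulvae per adult are *flagged* as outliers
(the signature of fluorescent confounders) but never silently removed;
dropping them is an explicit, separate step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from wormscreen.detect import DetectedObject

OUTLIER_VA_THRESHOLD = 1.5

SCORE_CSV_COLUMNS = [
    "plate",
    "well",
    "compound",
    "conc_um",
    "role",
    "experiment",
    "genotype",
    "n_vulvae",
    "n_adults",
    "n_larvae",
    "vulvae_per_adult",
    "pct_larvae",
    "outlier_flag",
    "notes",
]


@dataclass
class WellScore:
    """Counts and derived statistics for one well."""

    well_id: str
    n_vulvae: int
    n_adults: int
    n_larvae: int
    vulvae_per_adult: float  # NaN when n_adults == 0
    pct_larvae: float  # NaN when no worms
    outlier_flag: bool
    notes: str = ""


def score_counts(
    n_vulvae: int, n_adults: int, n_larvae: int, well_id: str = ""
) -> WellScore:
    """Pure reduction of per-well class counts to the two assay readouts."""
    notes = []
    if n_adults > 0:
        va = n_vulvae / n_adults
    else:
        va = math.nan
        notes.append("no adults: vulvae_per_adult undefined")
    n_worms = n_adults + n_larvae
    if n_worms > 0:
        pct_larvae = 100.0 * n_larvae / n_worms
    else:
        pct_larvae = math.nan
        notes.append("no worms: pct_larvae undefined")
    outlier = (not math.isnan(va)) and va > OUTLIER_VA_THRESHOLD
    if outlier:
        notes.append(f"outlier: vulvae/adult {va:.2f} > {OUTLIER_VA_THRESHOLD}")
    return WellScore(
        well_id=well_id,
        n_vulvae=int(n_vulvae),
        n_adults=int(n_adults),
        n_larvae=int(n_larvae),
        vulvae_per_adult=va,
        pct_larvae=pct_larvae,
        outlier_flag=outlier,
        notes="; ".join(notes),
    )


def score_well(objects: Iterable[DetectedObject], well_id: str = "") -> WellScore:
    """Score one well from its labeled objects (summed over all fields)."""
    n_v = n_a = n_l = 0
    for obj in objects:
        if obj.label == "vulva":
            n_v += 1
        elif obj.label == "adult_pharynx":
            n_a += 1
        elif obj.label == "larval_pharynx":
            n_l += 1
        elif obj.label is None:
            raise ValueError("score_well requires labeled objects (run classify_objects first)")
    return score_counts(n_v, n_a, n_l, well_id=well_id)


def score_plate(
    objects_df: pd.DataFrame,
    plate_map: pd.DataFrame,
    muv_df: pd.DataFrame | None = None,
    drop_outliers: bool = False,
) -> pd.DataFrame:
    """Score every well of a plate map from a per-object table.

    Every (plate, well) in ``objects_df`` must appear in the plate map
    (hard error otherwise); plate-map wells without any detected object are
    scored as empty. The result has one row per plate-map well, deterministic
    (plate, well) order, joined to compound/concentration/role metadata.
    """
    pm = plate_map.copy()
    key_cols = ["plate", "well"]
    dup = pm.duplicated(subset=key_cols)
    if dup.any():
        raise ValueError(
            f"duplicate wells in plate map: {pm.loc[dup, key_cols].values.tolist()}"
        )
    map_keys = set(map(tuple, pm[key_cols].values))
    obj_keys = set(map(tuple, objects_df[key_cols].values)) if len(objects_df) else set()
    orphans = sorted(obj_keys - map_keys)
    if orphans:
        raise ValueError(f"wells scored but missing from plate map: {orphans}")

    if len(objects_df):
        counts = (
            objects_df.groupby(key_cols + ["label"]).size().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame()
    rows = []
    for _, mrow in pm.iterrows():
        key = (mrow["plate"], mrow["well"])
        if key in counts.index:
            c = counts.loc[key]
            n_v = int(c.get("vulva", 0))
            n_a = int(c.get("adult_pharynx", 0))
            n_l = int(c.get("larval_pharynx", 0))
        else:
            n_v = n_a = n_l = 0
        ws = score_counts(n_v, n_a, n_l, well_id=mrow["well"])
        rows.append(
            {
                "plate": mrow["plate"],
                "well": mrow["well"],
                "compound": mrow.get("compound", ""),
                "conc_um": mrow.get("conc_um", float("nan")),
                "role": mrow.get("role", "test"),
                "experiment": mrow.get("experiment", "E1"),
                "genotype": mrow.get("genotype", "reporter"),
                "n_vulvae": ws.n_vulvae,
                "n_adults": ws.n_adults,
                "n_larvae": ws.n_larvae,
                "vulvae_per_adult": ws.vulvae_per_adult,
                "pct_larvae": ws.pct_larvae,
                "outlier_flag": ws.outlier_flag,
                "notes": ws.notes,
            }
        )
    out = pd.DataFrame(rows, columns=SCORE_CSV_COLUMNS)
    if muv_df is not None and len(muv_df):
        out = out.merge(muv_df, on=key_cols, how="left")
    out = out.sort_values(key_cols, kind="mergesort").reset_index(drop=True)
    if drop_outliers:
        out = out[~out["outlier_flag"]].reset_index(drop=True)
    return out


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    """Serialise a score table with missing values as empty cells."""
    scores.to_csv(path, index=False, float_format="%.6g", na_rep="")
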