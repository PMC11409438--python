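"""Screen decision layer: exclusion criteria, hit calling, counter-screen.

The primary screen is single-datapoint and threshold-based. Per compound,
three criteria are applied in order (all strict inequalities; boundary
values never trigger):

(i)   artifact exclusion — vulva-class count > 2x the number of adults in
      the positive control (fluorescent speckles from progeny, bacteria or
      drugs inflate the focus count);
(ii)  toxicity exclusion — adult count < 30% of the positive-control adult
      count (severely reduced larval growth);
(iii) hit threshold — remaining compounds with vulvae/adult < 0.4 are
      primary hits.

"The number of adults in the positive control" is operationalised as the
mean adult count over the positive-control wells of the same plate.

Validation reapplies (i)-(ii) per well, then keeps a compound only if at
least one concentration shows a mean (over experiments) vulvae/adult <= 0.4
— i.e. compounds above 0.4 at *all* concentrations are removed.

The counter-screen reruns validated hits in a lin-1 loss-of-function
background whose multivulva (Muv) phenotype arises downstream of the drugged
kinases. Classification order per compound: retarded growth (adult count
below 30% of the untreated lin-1 control) is indeterminate; Muv fraction
suppressed below half the control's classifies the compound as acting
downstream of / parallel to the ELK1-family transcription factor; otherwise
it is an on-pathway hit. The 0.5 suppression threshold is a package
convention (configurable, echoed into the output), not a literature value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

STATUSES = ("excluded_artifact", "excluded_toxic", "primary_hit", "non_hit")
COUNTER_CLASSES = ("on_pathway_hit", "downstream_or_parallel", "indeterminate_growth")


@dataclass
class ScreenConfig:
    """Decision thresholds for hit calling and counter-screening."""

    artifact_vulvae_multiplier: float = 2.0
    min_adult_fraction_of_pos: float = 0.30
    primary_hit_va_threshold: float = 0.4
    counter_muv_suppression_threshold: float = 0.5
    counter_min_adult_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.artifact_vulvae_multiplier <= 0 or self.primary_hit_va_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        for name in (
            "min_adult_fraction_of_pos",
            "counter_muv_suppression_threshold",
            "counter_min_adult_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: Path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class HitCall:
    compound: str
    status: str  # one of STATUSES
    value: float  # vulvae/adult driving the call (NaN if excluded before computing)
    reason: str

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if math.isnan(d["value"]):
            d["value"] = None  # strict-JSON friendly undefined marker
        return d


@dataclass(frozen=True)
class CounterScreenCall:
    compound: str
    klass: str  # one of COUNTER_CLASSES
    reporter_va: float
    lin1_muv_fraction: float
    lin1_adult_fraction_of_control: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class"] = d.pop("klass")
        for k, v in d.items():
            if isinstance(v, float) and math.isnan(v):
                d[k] = None
        return d


def _positive_control_adult_means(scores: pd.DataFrame) -> dict[str, float]:
    """Per-plate mean adult count over positive-control wells."""
    pos = scores[scores["role"] == "positive_control"]
    if pos.empty:
        raise ValueError(
            "no positive-control wells: exclusion criteria are defined relative to them"
        )
    means = pos.groupby("plate")["n_adults"].mean().to_dict()
    missing = sorted(set(scores["plate"]) - set(means))
    if missing:
        raise ValueError(f"plates without positive-control wells: {missing}")
    return means


def call_primary_hits(
    scores: pd.DataFrame, config: ScreenConfig
) -> tuple[list[HitCall], dict]:
    """Apply the three screen criteria to every test compound.

    ``scores`` is a score-module table (one row per well). Compounds with
    several wells are averaged before the criteria are applied. Returns the
    per-compound calls plus a summary with status counts and the thresholds
    used.
    """
    pos_means = _positive_control_adult_means(scores)
    test = scores[scores["role"] == "test"]
    calls: list[HitCall] = []
    for compound, group in test.groupby("compound", sort=True):
        n_vulvae = float(group["n_vulvae"].mean())
        n_adults = float(group["n_adults"].mean())
        pos_adults = float(
            sum(pos_means[p] for p in group["plate"]) / len(group)
        )  # plate-matched reference
        artifact_cut = config.artifact_vulvae_multiplier * pos_adults
        toxic_cut = config.min_adult_fraction_of_pos * pos_adults
        if n_vulvae > artifact_cut:
            calls.append(
                HitCall(
                    compound,
                    "excluded_artifact",
                    value=math.nan,
                    reason=f"vulvae {n_vulvae:g} > {config.artifact_vulvae_multiplier:g}x "
                    f"positive-control adults ({pos_adults:g})",
                )
            )
            continue
        if n_adults < toxic_cut:
            calls.append(
                HitCall(
                    compound,
                    "excluded_toxic",
                    value=math.nan,
                    reason=f"adults {n_adults:g} < {config.min_adult_fraction_of_pos:.0%} "
                    f"of positive-control adults ({pos_adults:g})",
                )
            )
            continue
        va = n_vulvae / n_adults if n_adults > 0 else math.nan
        if not math.isnan(va) and va < config.primary_hit_va_threshold:
            calls.append(
                HitCall(
                    compound,
                    "primary_hit",
                    value=va,
                    reason=f"vulvae/adult {va:.3g} < {config.primary_hit_va_threshold:g}",
                )
            )
        else:
            calls.append(
                HitCall(
                    compound,
                    "non_hit",
                    value=va,
                    reason=f"vulvae/adult {va:.3g} >= {config.primary_hit_va_threshold:g}",
                )
            )
    counts = {s: 0 for s in STATUSES}
    for c in calls:
        counts[c.status] += 1
    summary = {
        "n_compounds": len(calls),
        "status_counts": counts,
        "positive_control_adult_mean_by_plate": {k: float(v) for k, v in pos_means.items()},
        "thresholds": config.to_dict(),
    }
    return calls, summary


def _well_excluded(row, pos_adults: float, config: ScreenConfig) -> str | None:
    if row["n_vulvae"] > config.artifact_vulvae_multiplier * pos_adults:
        return "artifact"
    if row["n_adults"] < config.min_adult_fraction_of_pos * pos_adults:
        return "toxic"
    return None


def validate_hits(
    validation_scores: pd.DataFrame, config: ScreenConfig
) -> tuple[list[str], list[dict]]:
    """Filter primary hits using the validation-round score table.

    Per-well exclusions (criteria i-ii, against the validation run's own
    positive controls) are applied first; a compound then survives iff at
    least one concentration has a mean-over-experiments vulvae/adult <= the
    hit threshold. Returns (surviving compounds, removed records with the
    failing rule).
    """
    pos_means = _positive_control_adult_means(validation_scores)
    test = validation_scores[validation_scores["role"] == "test"]
    surviving: list[str] = []
    removed: list[dict] = []
    for compound, group in test.groupby("compound", sort=True):
        kept = group[
        	group.apply(lambda r: _well_excluded(r, pos_means[r["plate"]], config) is None, axis=1)
        ]
        if kept.empty:
            removed.append({"compound": compound, "reason": "no evaluable wells"})
            continue
        conc_means = []
        for conc, cgroup in kept.groupby("conc_um"):
            exp_means = [
                float(e["vulvae_per_adult"].dropna().mean())
                for _, e in cgroup.groupby("experiment")
                if e["vulvae_per_adult"].notna().any()
            ]
            if exp_means:
                conc_means.append((conc, sum(exp_means) / len(exp_means)))
        if not conc_means:
            removed.append({"compound": compound, "reason": "no evaluable wells"})
        elif any(m <= config.primary_hit_va_threshold for _, m in conc_means):
            surviving.append(compound)
        else:
            detail = ", ".join(f"{c:g}uM: {m:.3g}" for c, m in conc_means)
            removed.append(
                {
                    "compound": compound,
                    "reason": f"vulvae/adult > {config.primary_hit_va_threshold:g} "
                    f"at all concentrations ({detail})",
                }
            )
    return surviving, removed


def counter_screen_classify(
    validated_compounds: Sequence[str],
    reporter_va: Mapping[str, float],
    lin1_scores: pd.DataFrame,
    config: ScreenConfig,
) -> list[CounterScreenCall]:
    """Classify validated hits against the lin-1 mutant counter-screen.

    ``lin1_scores`` must contain ``muv_fraction`` and ``n_adults`` per well,
    with negative-control (untreated) wells providing the reference Muv
    fraction (expected ~1.0 in this genotype) and adult count.
    """
    if "muv_fraction" not in lin1_scores.columns:
        raise ValueError("lin-1 score table lacks muv_fraction (score with body detection)")
    ctrl = lin1_scores[lin1_scores["role"] == "negative_control"]
    if ctrl.empty:
        raise ValueError("missing untreated lin-1 control wells")
    ctrl_muv = float(ctrl["muv_fraction"].dropna().mean())
    ctrl_adults = float(ctrl["n_adults"].mean())
    if not (ctrl_muv > 0):
        raise ValueError(f"lin-1 control Muv fraction must be > 0, got {ctrl_muv}")
    if not (ctrl_adults > 0):
        raise ValueError("lin-1 control wells contain no adults")
    test = lin1_scores[lin1_scores["role"] == "test"]
    calls = []
    for compound in validated_compounds:
        rows = test[test["compound"] == compound]
        if rows.empty:
            raise ValueError(f"validated compound {compound!r} missing from lin-1 scores")
        adults = float(rows["n_adults"].mean())
        muv = float(rows["muv_fraction"].dropna().mean()) if rows["muv_fraction"].notna().any() else math.nan
        adult_frac = adults / ctrl_adults
        if adult_frac < config.counter_min_adult_fraction:
            klass = "indeterminate_growth"
        elif not math.isnan(muv) and muv / ctrl_muv < config.counter_muv_suppression_threshold:
            klass = "downstream_or_parallel"
        else:
            klass = "on_pathway_hit"
        calls.append(
            CounterScreenCall(
                compound=compound,
                klass=klass,
                reporter_va=float(reporter_va.get(compound, math.nan)),
                lin1_muv_fraction=muv,
                lin1_adult_fraction_of_control=adult_frac,
            )
        )
    return calls
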