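"""Assay-quality and aggregation statistics.

Z-factor
--------
For negative-control scores (mean mu_n, sample SD sigma_n) and
positive-control scores (mu_p, sigma_p), the assay-quality statistic is

    Z = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

with the n-1 (sample) SD convention throughout — the convention matters for
the small control groups (6 wells per plate) typical of this assay. Z is at
most 1; Z in [0.5, 1] indicates a screen-worthy assay, [0, 0.5) a marginal
one, and negative values an unusable one. Z-factors here are computed on
vulvae-per-adult well scores.

Dose-response aggregation is experiment-first: replicate wells are averaged
within each independent experiment, then cells report the mean and SD of the
experiment means. Undefined well scores (no adults) are dropped, with the
dropped count reported, never imputed.

The regression comparison (ordinary least squares of one scoring pipeline on
another, paired by condition) reports slope, intercept and R^2 = 1 -
SS_res/SS_tot; it is used to benchmark the automated pipeline against
ground truth or against an alternative scorer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ControlStats:
    group: str  # "negative" | "positive"
    n_wells: int
    mean: float
    sd: float
    n_dropped: int = 0  # undefined scores excluded (e.g. zero-adult wells)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_wells": self.n_wells,
            "mean": self.mean,
            "sd": self.sd,
            "n_dropped": self.n_dropped,
        }


@dataclass(frozen=True)
class ZFactorResult:
    z: float
    neg: ControlStats
    pos: ControlStats
    interpretation: str  # "excellent" | "marginal" | "unusable"

    def to_dict(self) -> dict:
        return {
            "z": self.z,
            "interpretation": self.interpretation,
            "neg": self.neg.to_dict(),
            "pos": self.pos.to_dict(),
        }


def _interpret(z: float) -> str:
    if z >= 0.5:
        return "excellent"
    if z >= 0.0:
        return "marginal"
    return "unusable"


def _group_stats(values: Sequence[float], group: str) -> ControlStats:
    arr = np.asarray(values, dtype=float)
    kept = arr[np.isfinite(arr)]
    n_dropped = arr.size - kept.size
    if kept.size < 2:
        raise ValueError(
            f"{group} control group needs >= 2 defined scores, got {kept.size}"
        )
    return ControlStats(
        group=group,
        n_wells=int(kept.size),
        mean=float(kept.mean()),
        sd=float(kept.std(ddof=1)),
        n_dropped=int(n_dropped),
    )


def zfactor(neg_scores: Sequence[float], pos_scores: Sequence[float]) -> ZFactorResult:
    """Z-factor of an assay from its control-well scores.

    Undefined (NaN) scores are excluded with their count recorded. Raises if
    either group has fewer than two defined values or the group means are
    equal (Z undefined).
    """
    neg = _group_stats(neg_scores, "negative")
    pos = _group_stats(pos_scores, "positive")
    sep = abs(pos.mean - neg.mean)
    if sep == 0:
        raise ValueError("control means are equal: Z-factor undefined")
    z = 1.0 - 3.0 * (pos.sd + neg.sd) / sep
    return ZFactorResult(z=float(z), neg=neg, pos=pos, interpretation=_interpret(z))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def compare_scorings(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> RegressionResult:
    """OLS of pipeline A scores on pipeline B scores, paired by condition."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired score vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError(f"need >= 3 paired points, got {a.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("scores must be finite")
    var_b = b.var()
    if var_b == 0:
        raise ValueError("zero variance in predictor: regression undefined")
    slope = float(np.cov(a, b, ddof=1)[0, 1] / b.var(ddof=1))
    intercept = float(a.mean() - slope * b.mean())
    resid = a - (slope * b + intercept)
    ss_tot = float(((a - a.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2, n_points=int(a.size))


DOSE_RESPONSE_COLUMNS = [
    "compound",
    "conc_um",
    "mean_va",
    "sd_va",
    "mean_pct_larvae",
    "n_wells",
    "n_dropped",
    "n_experiments",
]


def aggregate_dose_response(scores: pd.DataFrame) -> pd.DataFrame:
    """Two-level aggregation of well scores into dose-response cells.

    Within each (compound, conc_um, experiment): mean over replicate wells,
    dropping undefined vulvae-per-adult values (dropped count reported).
    Across experiments: mean and SD of the experiment means (SD is NaN for a
    single experiment). Cells where every well is undefined are emitted with
    NaN means so downstream rendering can mark them distinctly.
    """
    required = {"compound", "conc_um", "experiment", "vulvae_per_adult", "pct_larvae"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    rows = []
    for (compound, conc), group in scores.groupby(["compound", "conc_um"], sort=True):
        exp_means_va = []
        exp_means_pl = []
        n_wells = len(group)
        n_dropped = int(group["vulvae_per_adult"].isna().sum())
        for _, exp_group in group.groupby("experiment"):
            va = exp_group["vulvae_per_adult"].dropna()
            if len(va):
                exp_means_va.append(float(va.mean()))
            pl = exp_group["pct_larvae"].dropna()
            if len(pl):
                exp_means_pl.append(float(pl.mean()))
        rows.append(
            {
                "compound": compound,
                "conc_um": conc,
                "mean_va": float(np.mean(exp_means_va)) if exp_means_va else math.nan,
                "sd_va": float(np.std(exp_means_va, ddof=1)) if len(exp_means_va) > 1 else math.nan,
                "mean_pct_larvae": float(np.mean(exp_means_pl)) if exp_means_pl else math.nan,
                "n_wells": n_wells,
                "n_dropped": n_dropped,
                "n_experiments": len(exp_means_va),
            }
        )
    return pd.DataFrame(rows, columns=DOSE_RESPONSE_COLUMNS)


HEATMAP_METRICS = ("mean_va", "sd_va", "mean_pct_larvae")


def heatmap_export(
    dose_response: pd.DataFrame,
    metric: str,
    out_csv: Path,
    out_figure: Path | None = None,
) -> pd.DataFrame:
    """Pivot a dose-response table into a drugs x concentrations matrix.

    The matrix CSV is always written; a figure (PNG/SVG, missing cells drawn
    hatched-grey) is optional. Returns the pivoted matrix.
    """
    if metric not in HEATMAP_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {HEATMAP_METRICS}")
    if dose_response.empty:
        raise ValueError("dose-response table is empty")
    matrix = dose_response.pivot(index="compound", columns="conc_um", values=metric)
    matrix = matrix.sort_index()
    matrix.to_csv(out_csv, float_format="%.6g", na_rep="")
    if out_figure is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.35 * matrix.shape[0])
        )
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("lightgrey")
        im = ax.imshow(np.ma.masked_invalid(matrix.to_numpy()), aspect="auto", cmap=cmap)
        ax.set_xticks(range(matrix.shape[1]), [f"{c:g}" for c in matrix.columns])
        ax.set_yticks(range(matrix.shape[0]), matrix.index)
        ax.set_xlabel("concentration (umol/L)")
        fig.colorbar(im, ax=ax, label=metric)
        fig.tight_layout()
        fig.savefig(out_figure)
        plt.close(fig)
    return matrix
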