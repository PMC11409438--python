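"""Reference screen layouts for benchmarking the pipeline on synthetic data.

Two standard layouts are defined programmatically (no stored fixtures):

* a *calibration plate*: one 96-well plate spanning vulva rates from full
  suppression to a mild multivulva regime, with default noise and two
  confounder speckles per field — used to measure per-class count errors and
  the pipeline-vs-ground-truth regression;
* a *planted validation screen*: 433 test compounds across five 96-well
  plates (8 control wells per plate), with planted strong suppressors,
  speckle-storm artifact wells and toxic growth-retarded wells, whose known
  classes the decision layer must recover.

Planted wells use a fixed nominal worm load (25 worms; positive controls 30
all-adult worms) so that the planted classes are separated from the decision
thresholds by construction rather than by luck of the density draw; filler
compounds and negative controls draw the usual truncated-normal worm count.
"""

from __future__ import annotations

import pandas as pd

ROWS = "ABCDEFGH"
N_TEST_COMPOUNDS = 433
N_SUPPRESSORS = 7
N_ARTIFACT = 20
N_TOXIC = 15

#: speckle-storm override emulating fluorescent precipitates / progeny
STORM_OVERRIDE = {
    "speckle_rate": 40.0,
    "speckle_radius_range": [3.2, 5.5],
    "speckle_peak_range": [32000.0, 48000.0],
    "n_worms": 25,
}


def calibration_plate_map(plate_id: str = "CAL1") -> pd.DataFrame:
    """96-well plate: column 1 controls, columns 2-12 a vulva-rate gradient.

    Test wells in column c (2..12) share vulva rate 2.0 * (c - 2) / 10, i.e.
    0 .. 2 vulvae per adult across the plate — a wide dynamic range for
    regression against ground truth.
    """
    rows = []
    for r in range(8):
        well = f"{ROWS[r]}01"
        if r < 4:
            rows.append((plate_id, well, "DMSO", 0.0, "negative_control"))
        else:
            rows.append((plate_id, well, "trametinib", 7.0, "positive_control"))
    for c in range(2, 13):
        for r in range(8):
            rows.append(
                (plate_id, f"{ROWS[r]}{c:02d}", f"GRAD-{c - 2:02d}", 10.0, "test")
            )
    return pd.DataFrame(rows, columns=["plate", "well", "compound", "conc_um", "role"])


def calibration_sim_config() -> dict:
    compounds = {
        f"GRAD-{i:02d}": {"vulva_rate_adult": 2.0 * i / 10, "n_worms": 25}
        for i in range(11)
    }
    return {
        "defaults": {"adult_fraction": 0.8, "vulva_rate_adult": 1.0, "speckle_rate": 2.0},
        "roles": {
            "positive_control": {"vulva_rate_adult": 0.0, "n_worms": 30, "adult_fraction": 1.0},
        },
        "compounds": compounds,
    }


def planted_compound_classes() -> dict[str, str]:
    """Compound name -> planted class for the validation screen."""
    classes: dict[str, str] = {}
    for i in range(1, N_SUPPRESSORS + 1):
        classes[f"SUP-{i:02d}"] = "suppressor"
    for i in range(1, N_ARTIFACT + 1):
        classes[f"ART-{i:02d}"] = "artifact"
    for i in range(1, N_TOXIC + 1):
        classes[f"TOX-{i:02d}"] = "toxic"
    for i in range(1, N_TEST_COMPOUNDS - N_SUPPRESSORS - N_ARTIFACT - N_TOXIC + 1):
        classes[f"CMP-{i:03d}"] = "inactive"
    return classes


def planted_screen_plate_map() -> pd.DataFrame:
    """433-compound screen over five plates; column 1 holds the controls.

    Planted compounds are interleaved deterministically across plates (every
    13th slot cycles through the planted lists) so no plate is all-planted.
    """
    classes = planted_compound_classes()
    planted = [c for c, k in classes.items() if k != "inactive"]
    fillers = [c for c, k in classes.items() if k == "inactive"]
    order: list[str] = []
    pi = fi = 0
    for slot in range(N_TEST_COMPOUNDS):
        planted_turn = (slot % 13 == 3 and pi < len(planted)) or fi >= len(fillers)
        if planted_turn and pi < len(planted):
            order.append(planted[pi])
            pi += 1
        else:
            order.append(fillers[fi])
            fi += 1

    rows = []
    idx = 0
    for p in range(1, 6):
        plate = f"VS{p}"
        for r in range(8):
            well = f"{ROWS[r]}01"
            if r < 4:
                rows.append((plate, well, "DMSO", 0.0, "negative_control"))
            else:
                rows.append((plate, well, "trametinib", 7.0, "positive_control"))
        for c in range(2, 13):
            for r in range(8):
                if idx < len(order):
                    rows.append((plate, f"{ROWS[r]}{c:02d}", order[idx], 10.0, "test"))
                    idx += 1
    return pd.DataFrame(rows, columns=["plate", "well", "compound", "conc_um", "role"])


def planted_screen_sim_config() -> dict:
    compounds: dict[str, dict] = {}
    for name, klass in planted_compound_classes().items():
        if klass == "suppressor":
            compounds[name] = {"vulva_rate_adult": 0.05, "n_worms": 25}
        elif klass == "artifact":
            compounds[name] = dict(STORM_OVERRIDE)
        elif klass == "toxic":
            compounds[name] = {"adult_fraction": 0.05, "n_worms": 25}
    return {
        "defaults": {"adult_fraction": 0.8, "vulva_rate_adult": 1.0, "speckle_rate": 1.0},
        "roles": {
            "positive_control": {"vulva_rate_adult": 0.0, "n_worms": 30, "adult_fraction": 1.0},
        },
        "compounds": compounds,
    }
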