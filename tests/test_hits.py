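"""Screen decision layer: exclusion criteria, validation, counter-screen."""

import math

import pandas as pd
import pytest

from wormscreen import (
    ScreenConfig,
    call_primary_hits,
    counter_screen_classify,
    validate_hits,
)


def _screen_table(test_wells, pos_adults=(10, 10), neg=((10, 10),), plate="P1"):
    """Build a minimal score table: test_wells is {compound: (vulvae, adults)}."""
    rows = []
    for i, a in enumerate(pos_adults):
        rows.append((plate, f"H{i+1:02d}", "trametinib", 7.0, "positive_control", 1, a))
    for i, (v, a) in enumerate(neg):
        rows.append((plate, f"G{i+1:02d}", "DMSO", 0.0, "negative_control", v, a))
    for i, (cmp_, (v, a)) in enumerate(test_wells.items()):
        rows.append((plate, f"A{i+1:02d}", cmp_, 10.0, "test", v, a))
    df = pd.DataFrame(
        rows, columns=["plate", "well", "compound", "conc_um", "role", "n_vulvae", "n_adults"]
    )
    df["vulvae_per_adult"] = df["n_vulvae"] / df["n_adults"].where(df["n_adults"] > 0)
    df["experiment"] = "E1"
    return df


class TestCallPrimaryHits:
    def test_worked_four_well_example(self):
        # positive-control adult mean 10: A is artifact (25 > 2x10), B toxic
        # (2 < 3), C hit (0.3 < 0.4), D non-hit (0.8)
        table = _screen_table({"A": (25, 10), "B": (1, 2), "C": (3, 10), "D": (8, 10)})
        calls, summary = call_primary_hits(table, ScreenConfig())
        statuses = {c.compound: c.status for c in calls}
        assert statuses == {
            "A": "excluded_artifact",
            "B": "excluded_toxic",
            "C": "primary_hit",
            "D": "non_hit",
        }
        assert summary["status_counts"] == {
            "excluded_artifact": 1, "excluded_toxic": 1, "primary_hit": 1, "non_hit": 1,
        }
        assert summary["positive_control_adult_mean_by_plate"]["P1"] == 10

    @pytest.mark.parametrize(
        "well,expected",
        [
            ({"X": (4, 10)}, "non_hit"),       # exactly 0.4: strict < means no hit
            ({"X": (20, 10)}, "non_hit"),      # vulvae exactly 2x pos adults: no exclusion
            ({"X": (3, 3)}, "non_hit"),        # adults exactly 30% of pos: no exclusion
        ],
    )
    def test_printed_strict_inequalities_at_boundaries(self, well, expected):
        calls, _ = call_primary_hits(_screen_table(well), ScreenConfig())
        assert calls[0].status == expected

    def test_empty_test_set(self):
        calls, summary = call_primary_hits(_screen_table({}), ScreenConfig())
        assert calls == []
        assert summary["n_compounds"] == 0

    def test_missing_positive_controls_hard_error(self):
        table = _screen_table({"X": (1, 10)})
        table = table[table["role"] != "positive_control"]
        with pytest.raises(ValueError, match="positive-control"):
            call_primary_hits(table, ScreenConfig())

    def test_partition_and_threshold_monotonicity(self):
        wells = {f"C{i}": (i, 10) for i in range(0, 25)}
        table = _screen_table(wells)
        calls, summary = call_primary_hits(table, ScreenConfig())
        assert sum(summary["status_counts"].values()) == len(wells)
        hits_04 = {c.compound for c in calls if c.status == "primary_hit"}
        calls_02, _ = call_primary_hits(table, ScreenConfig(primary_hit_va_threshold=0.2))
        hits_02 = {c.compound for c in calls_02 if c.status == "primary_hit"}
        assert hits_02 <= hits_04

    def test_replicate_wells_averaged(self):
        table = _screen_table({"X": (2, 10)})
        extra = table[table["compound"] == "X"].assign(well="A09", n_vulvae=6)
        table = pd.concat([table, extra], ignore_index=True)
        calls, _ = call_primary_hits(table, ScreenConfig())
        assert calls[0].value == pytest.approx(0.4)  # mean (2+6)/2 / 10
        assert calls[0].status == "non_hit"


def _validation_table(conc_scores, pos_adults=10, plate="V1"):
    """conc_scores: {compound: {conc: [(vulvae, adults), ...]}} over 2 experiments."""
    rows = [
        (plate, "H01", "trametinib", 7.0, "positive_control", 1, pos_adults, "E1"),
        (plate, "H02", "trametinib", 7.0, "positive_control", 1, pos_adults, "E2"),
    ]
    i = 0
    for cmp_, concs in conc_scores.items():
        for conc, wells in concs.items():
            for j, (v, a) in enumerate(wells):
                rows.append((plate, f"A{i+1:02d}", cmp_, conc, "test", v, a, f"E{j+1}"))
                i += 1
    df = pd.DataFrame(
        rows,
        columns=["plate", "well", "compound", "conc_um", "role", "n_vulvae", "n_adults", "experiment"],
    )
    df["vulvae_per_adult"] = df["n_vulvae"] / df["n_adults"].where(df["n_adults"] > 0)
    return df


class TestValidateHits:
    def test_one_effective_concentration_suffices(self):
        table = _validation_table({"X": {5.0: [(6, 10)], 10.0: [(3, 10)], 20.0: [(2, 10)]}})
        surviving, removed = validate_hits(table, ScreenConfig())
        assert surviving == ["X"]
        assert removed == []

    def test_above_threshold_at_all_concentrations_removed(self):
        table = _validation_table({"X": {5.0: [(5, 10)], 10.0: [(45, 100)], 20.0: [(41, 100)]}})
        surviving, removed = validate_hits(table, ScreenConfig())
        assert surviving == []
        assert removed[0]["compound"] == "X"
        assert "all concentrations" in removed[0]["reason"]

    def test_all_wells_excluded_removed_with_reason(self):
        # every well is a speckle storm (vulvae way above 2x pos adults)
        table = _validation_table({"X": {10.0: [(500, 10), (480, 10)]}})
        surviving, removed = validate_hits(table, ScreenConfig())
        assert surviving == []
        assert removed[0]["reason"] == "no evaluable wells"

    def test_boundary_survives_at_exactly_threshold(self):
        # mean exactly 0.4 at one concentration: <= keeps the compound
        table = _validation_table({"X": {10.0: [(4, 10), (4, 10)]}})
        surviving, _ = validate_hits(table, ScreenConfig())
        assert surviving == ["X"]


def _lin1_table(test_rows, ctrl_muv=1.0, ctrl_adults=20):
    rows = [
        ("L1", "G01", "DMSO", 0.0, "negative_control", ctrl_adults, ctrl_muv),
        ("L1", "G02", "DMSO", 0.0, "negative_control", ctrl_adults, ctrl_muv),
    ]
    for i, (cmp_, adults, muv) in enumerate(test_rows):
        rows.append(("L1", f"A{i+1:02d}", cmp_, 10.0, "test", adults, muv))
    return pd.DataFrame(
        rows, columns=["plate", "well", "compound", "conc_um", "role", "n_adults", "muv_fraction"]
    )


class TestCounterScreen:
    def test_three_way_classification(self):
        table = _lin1_table(
            [
                ("ON", 20, 0.95),      # Muv retained -> acts upstream (on-pathway)
                ("DOWN", 20, 0.2),     # Muv suppressed -> downstream/parallel
                ("SLOW", 2, 1.0),      # growth retarded -> indeterminate
            ]
        )
        calls = counter_screen_classify(
            ["ON", "DOWN", "SLOW"], {"ON": 0.1, "DOWN": 0.1, "SLOW": 0.1}, table, ScreenConfig()
        )
        classes = {c.compound: c.klass for c in calls}
        assert classes == {
            "ON": "on_pathway_hit",
            "DOWN": "downstream_or_parallel",
            "SLOW": "indeterminate_growth",
        }
        on = next(c for c in calls if c.compound == "ON")
        assert on.lin1_adult_fraction_of_control == pytest.approx(1.0)
        assert on.reporter_va == pytest.approx(0.1)

    def test_each_compound_gets_exactly_one_class(self):
        table = _lin1_table([(f"C{i}", 20, 0.1 * i) for i in range(10)])
        calls = counter_screen_classify([f"C{i}" for i in range(10)], {}, table, ScreenConfig())
        assert len(calls) == 10
        assert all(c.klass in ("on_pathway_hit", "downstream_or_parallel", "indeterminate_growth") for c in calls)

    def test_growth_check_precedes_muv_check(self):
        # both criteria would fire; growth must win (analysis precluded)
        table = _lin1_table([("X", 1, 0.1)])
        (call,) = counter_screen_classify(["X"], {}, table, ScreenConfig())
        assert call.klass == "indeterminate_growth"

    def test_missing_control_is_error(self):
        table = _lin1_table([("X", 20, 0.5)])
        table = table[table["role"] != "negative_control"]
        with pytest.raises(ValueError, match="control"):
            counter_screen_classify(["X"], {}, table, ScreenConfig())

    def test_missing_muv_column_is_error(self):
        table = _lin1_table([("X", 20, 0.5)]).drop(columns=["muv_fraction"])
        with pytest.raises(ValueError, match="muv_fraction"):
            counter_screen_classify(["X"], {}, table, ScreenConfig())


class TestScreenConfig:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(primary_hit_va_threshold=0.0)
        with pytest.raises(ValueError):
            ScreenConfig(min_adult_fraction_of_pos=1.5)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = ScreenConfig(primary_hit_va_threshold=0.3)
        path = tmp_path / "screen.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert ScreenConfig.from_yaml(path) == cfg
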