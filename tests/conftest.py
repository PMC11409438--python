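"""Shared fixtures: small, fast synthetic wells and detection helpers."""

from collections import Counter

import pandas as pd
import pytest

from wormscreen import DetectionConfig, WellSimParams


@pytest.fixture
def det_config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def quick_params():
    """Factory for small noise-free wells (256 px fields, few worms)."""

    def make(**kwargs) -> WellSimParams:
        defaults = dict(
            field_size=(256, 256),
            n_worms=6,
            adult_fraction=0.7,
            vulva_rate_adult=1.0,
            speckle_rate=0.0,
            noise_sd=0.0,
            seed=0,
        )
        defaults.update(kwargs)
        return WellSimParams(**defaults)

    return make


def gfp_fields(image):
    return [f["gfp"] for f in image.fields]


def label_counts(objects) -> tuple[int, int, int]:
    """(adult, larva, vulva) counts from labeled objects."""
    c = Counter(o.label for o in objects)
    return c["adult_pharynx"], c["larval_pharynx"], c["vulva"]


def objects_to_df(objects, plate: str, well: str) -> pd.DataFrame:
    rows = [
        {
            "plate": plate,
            "well": well,
            "field": o.field_index,
            "label": o.label,
            "x": o.centroid[0],
            "y": o.centroid[1],
            "area": o.area,
            "peak": o.peak_intensity,
            "mean": o.mean_intensity,
            "eccentricity": o.eccentricity,
        }
        for o in objects
    ]
    return pd.DataFrame(
        rows,
        columns=["plate", "well", "field", "label", "x", "y", "area", "peak", "mean", "eccentricity"],
    )
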