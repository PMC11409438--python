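"""GFP object segmentation and three-class size/intensity gating.

The detector re-implements, as explicit operators, the focus-counting stage
of an automated vulva-screening pipeline: smooth -> threshold -> connected
components -> feature extraction -> gate-based classification into

* ``vulva``           — compact, very bright mid-body focus,
* ``adult_pharynx``   — large pharyngeal plateau (adult-sized),
* ``larval_pharynx``  — smaller, dimmer pharyngeal plateau,
* ``rejected``        — anything that fits no gate.

Gates are (area_min, area_max, peak_min) triples applied in a declared
precedence order (vulva first, mirroring the "large, intense" qualifier that
resolves the area overlap between vulval foci and larval pharynges). The
object *area* feature is the full-width-at-half-maximum support — pixels of
the component at or above background + half the background-subtracted
smoothed peak — which for plateau-shaped objects measures the geometric
footprint independently of the global threshold level.

An optional body-segmentation pass recovers the dim autofluorescent worm
silhouettes so vulval foci can be assigned to individual worms; an adult
body carrying two or more assigned foci is flagged multivulva (Muv), the
automated proxy for manual Muv scoring in the lin-1 counter-screen.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage import measure

from wormscreen.simulate import CHANNELS, N_FIELDS

OBJECT_CSV_COLUMNS = [
    "plate",
    "well",
    "field",
    "label",
    "x",
    "y",
    "area",
    "peak",
    "mean",
    "eccentricity",
]

TIFF_PATTERN = re.compile(
    r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})_f(?P<field>\d)_(?P<channel>gfp|bf)\.tif$"
)

CLASS_LABELS = ("vulva", "adult_pharynx", "larval_pharynx")


@dataclass(frozen=True)
class ClassGate:
    """Area/intensity gate for one object class."""

    area_min: float
    area_max: float
    peak_min: float

    def __post_init__(self) -> None:
        if not (self.area_min < self.area_max):
            raise ValueError(f"invalid gate: area_min {self.area_min} >= area_max {self.area_max}")

    def matches(self, area: float, peak: float) -> bool:
        return self.area_min <= area <= self.area_max and peak >= self.peak_min


@dataclass
class DetectionConfig:
    """Segmentation threshold, size gates and focus-assignment settings.

    The default threshold mode is background-relative: background median plus
    ``max(mad_multiplier * MAD, min_offset)`` of the smoothed field, where the
    fixed offset floor keeps dim body autofluorescence out of the GFP object
    mask even in noise-free images.
    """

    threshold_mode: str = "background_relative"  # or "absolute"
    gfp_threshold: float = 6.0  # MAD multiplier, or absolute intensity
    min_offset: float = 4000.0  # floor above background median (relative mode)
    smoothing_sigma: float = 2.0
    min_object_area: int = 15  # px, on the thresholded component
    gates: dict[str, ClassGate] = field(
        default_factory=lambda: {
            "vulva": ClassGate(30.0, 120.0, 30000.0),
            "adult_pharynx": ClassGate(250.0, 900.0, 8000.0),
            "larval_pharynx": ClassGate(40.0, 220.0, 6000.0),
        }
    )
    precedence: tuple[str, ...] = ("vulva", "adult_pharynx", "larval_pharynx")
    body_detection: bool = False
    body_threshold_offset: float = 1000.0  # above background median
    min_body_area: int = 300  # px; drops noise blobs and sub-larval fragments
    assignment_radius: float = 20.0  # px, focus-to-body snap distance

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.threshold_mode not in ("background_relative", "absolute"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if set(self.precedence) != set(self.gates):
            raise ValueError(
                "gate precedence must be a total order over the configured classes: "
                f"precedence {self.precedence} vs gates {tuple(self.gates)}"
            )
        if len(set(self.precedence)) != len(self.precedence):
            raise ValueError(f"duplicate labels in precedence {self.precedence}")
        if self.min_object_area <= 0:
            raise ValueError("min_object_area must be positive")

    # -- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gates"] = {k: dataclasses.asdict(g) for k, g in self.gates.items()}
        d["precedence"] = list(self.precedence)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        d = dict(d)
        if "gates" in d:
            d["gates"] = {k: ClassGate(**v) for k, v in d["gates"].items()}
        if "precedence" in d:
            d["precedence"] = tuple(d["precedence"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "DetectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class DetectedObject:
    """One segmented GFP object with its measured features."""

    field_index: int
    centroid: tuple[float, float]  # (x, y) in field pixel coordinates
    area: float  # px^2, FWHM support (see module docstring)
    n_pixels: int  # raw thresholded-component size
    peak_intensity: float  # max of original intensities over the component
    mean_intensity: float
    eccentricity: float
    label: str | None = None  # set by classify_objects


def _check_raster(raster: np.ndarray) -> np.ndarray:
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("raster contains non-finite pixels")
    return arr


def _threshold(smoothed: np.ndarray, config: DetectionConfig) -> tuple[float, float]:
    """Return (background_median, threshold) for a smoothed field."""
    med = float(np.median(smoothed))
    if config.threshold_mode == "absolute":
        return med, float(config.gfp_threshold)
    mad = float(np.median(np.abs(smoothed - med)))
    return med, med + max(config.gfp_threshold * mad, config.min_offset)


def segment_gfp(
    field_raster: np.ndarray,
    config: DetectionConfig,
    field_index: int = 1,
) -> list[DetectedObject]:
    """Segment one GFP field into unlabeled objects.

    Objects are connected components of the thresholded (smoothed) raster
    with at least ``min_object_area`` pixels; intensity features are computed
    from the original raster.
    """
    raw = _check_raster(field_raster)
    smoothed = ndimage.gaussian_filter(raw, config.smoothing_sigma) if config.smoothing_sigma > 0 else raw
    bg, thr = _threshold(smoothed, config)
    mask = smoothed > thr
    labels = measure.label(mask, connectivity=2)
    objects: list[DetectedObject] = []
    for region in measure.regionprops(labels, intensity_image=raw):
        if region.num_pixels < config.min_object_area:
            continue
        comp = labels[region.slice] == region.label
        sm_patch = smoothed[region.slice]
        peak_sm = float(sm_patch[comp].max())
        half_level = bg + 0.5 * (peak_sm - bg)
        area = float(np.count_nonzero(comp & (sm_patch >= half_level)))
        cy, cx = region.centroid
        objects.append(
            DetectedObject(
                field_index=field_index,
                centroid=(float(cx), float(cy)),
                area=area,
                n_pixels=int(region.num_pixels),
                peak_intensity=float(region.image_intensity[region.image].max()),
                mean_intensity=float(region.image_intensity[region.image].mean()),
                eccentricity=float(region.eccentricity),
            )
        )
    return objects


def classify_objects(
    objects: Iterable[DetectedObject],
    config: DetectionConfig,
) -> list[DetectedObject]:
    """Label objects by the first matching gate in precedence order.

    Objects matching no gate are labeled ``rejected``. Each object receives
    exactly one label.
    """
    labeled = []
    for obj in objects:
        label = "rejected"
        for name in config.precedence:
            if config.gates[name].matches(obj.area, obj.peak_intensity):
                label = name
                break
        labeled.append(dataclasses.replace(obj, label=label))
    return labeled


def segment_bodies(field_raster: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Segment autofluorescent worm bodies; returns a labeled int array.

    Bodies are thresholded just above background so the full silhouette
    (body + pharynx + vulva) forms one component per worm; components below
    ``min_body_area`` (noise, debris) are dropped.
    """
    raw = _check_raster(field_raster)
    smoothed = ndimage.gaussian_filter(raw, config.smoothing_sigma)
    med = float(np.median(smoothed))
    mask = smoothed > med + config.body_threshold_offset
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < config.min_body_area)
    mask2 = ~np.isin(labels, small)
    mask2 &= labels > 0
    return measure.label(mask2, connectivity=2)


@dataclass
class BodyRecord:
    """Per-worm focus assignment result."""

    field_index: int
    body_label: int
    is_adult: bool
    n_foci: int
    muv: bool


@dataclass
class FocusAssignment:
    """Result of assigning vulva-class foci to segmented bodies in one well."""

    bodies: list[BodyRecord]
    n_unassigned: int

    @property
    def n_adults(self) -> int:
        return sum(1 for b in self.bodies if b.is_adult)

    @property
    def n_muv_adults(self) -> int:
        return sum(1 for b in self.bodies if b.is_adult and b.muv)

    @property
    def muv_fraction(self) -> float:
        """Fraction of adult bodies with >= 2 assigned vulval foci (NaN if no adults)."""
        return self.n_muv_adults / self.n_adults if self.n_adults else float("nan")


def assign_foci_to_bodies(
    gfp_objects: Sequence[DetectedObject],
    body_labels_per_field: Sequence[np.ndarray],
    config: DetectionConfig,
) -> FocusAssignment:
    """Assign each vulva-class focus to the body containing it, else to the
    nearest body within ``assignment_radius``; foci farther than that stay
    unassigned (still counted in well totals, but no worm's Muv status
    changes).

    A body is called adult if it contains an adult_pharynx-class object
    centroid. Raises if body detection is disabled in the config.
    """
    if not config.body_detection:
        raise RuntimeError("body detection is disabled; enable DetectionConfig.body_detection")
    bodies: dict[tuple[int, int], BodyRecord] = {}
    nearest: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for fi, lbl in enumerate(body_labels_per_field, start=1):
        for b in np.unique(lbl):
            if b > 0:
                bodies[(fi, int(b))] = BodyRecord(fi, int(b), False, 0, False)
        dist, (iy, ix) = ndimage.distance_transform_edt(lbl == 0, return_indices=True)
        nearest[fi] = (dist, iy, ix)

    def body_at(fi: int, x: float, y: float, radius: float) -> int | None:
        lbl = body_labels_per_field[fi - 1]
        r, c = int(round(y)), int(round(x))
        r = min(max(r, 0), lbl.shape[0] - 1)
        c = min(max(c, 0), lbl.shape[1] - 1)
        if lbl[r, c] > 0:
            return int(lbl[r, c])
        dist, iy, ix = nearest[fi]
        if dist[r, c] <= radius:
            return int(lbl[iy[r, c], ix[r, c]])
        return None

    for obj in gfp_objects:
        if obj.label == "adult_pharynx":
            b = body_at(obj.field_index, *obj.centroid, radius=config.assignment_radius)
            if b is not None:
                bodies[(obj.field_index, b)].is_adult = True

    n_unassigned = 0
    for obj in gfp_objects:
        if obj.label != "vulva":
            continue
        b = body_at(obj.field_index, *obj.centroid, radius=config.assignment_radius)
        if b is None:
            n_unassigned += 1
            continue
        rec = bodies[(obj.field_index, b)]
        rec.n_foci += 1
        rec.muv = rec.is_adult and rec.n_foci >= 2
    return FocusAssignment(bodies=list(bodies.values()), n_unassigned=n_unassigned)


# ---------------------------------------------------------------------------
# well- and directory-level drivers
# ---------------------------------------------------------------------------


def detect_well(
    gfp_fields: Sequence[np.ndarray],
    config: DetectionConfig,
) -> list[DetectedObject]:
    """Segment and classify all fields of one well (counts sum per well;
    fields are processed independently, matching non-overlapping acquisition)."""
    objects: list[DetectedObject] = []
    for fi, raster in enumerate(gfp_fields, start=1):
        objects.extend(segment_gfp(raster, config, field_index=fi))
    return classify_objects(objects, config)


def scan_image_dir(image_dir: Path) -> pd.DataFrame:
    """Index TIFFs following ``<plate>_<well>_f<field#>_<channel>.tif``."""
    rows = []
    for p in sorted(Path(image_dir).glob("*.tif")):
        m = TIFF_PATTERN.match(p.name)
        if m:
            rows.append(
                {
                    "plate": m["plate"],
                    "well": m["well"],
                    "field": int(m["field"]),
                    "channel": m["channel"],
                    "path": str(p),
                }
            )
    return pd.DataFrame(rows, columns=["plate", "well", "field", "channel", "path"])


def load_well_gfp(index: pd.DataFrame, plate: str, well: str) -> list[np.ndarray]:
    sel = index[(index["plate"] == plate) & (index["well"] == well) & (index["channel"] == "gfp")]
    sel = sel.sort_values("field")
    if len(sel) != N_FIELDS:
        raise ValueError(
            f"well {plate}/{well}: expected {N_FIELDS} GFP fields, found {len(sel)}"
        )
    return [tifffile.imread(p) for p in sel["path"]]


def detect_image_dir(
    image_dir: Path,
    wells: Sequence[tuple[str, str]],
    config: DetectionConfig,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Run detection for every (plate, well) in ``wells``.

    Returns (objects table, muv table or None). The muv table (one row per
    well, with adult-body and Muv counts) is produced only when
    ``config.body_detection`` is enabled.
    """
    index = scan_image_dir(image_dir)
    obj_rows: list[dict] = []
    muv_rows: list[dict] = []
    for plate, well in wells:
        rasters = load_well_gfp(index, plate, well)
        objects = detect_well(rasters, config)
        for o in objects:
            obj_rows.append(
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
            )
        if config.body_detection:
            body_labels = [segment_bodies(r, config) for r in rasters]
            fa = assign_foci_to_bodies(objects, body_labels, config)
            muv_rows.append(
                {
                    "plate": plate,
                    "well": well,
                    "n_adult_bodies": fa.n_adults,
                    "n_muv_adults": fa.n_muv_adults,
                    "muv_fraction": fa.muv_fraction,
                    "n_unassigned_foci": fa.n_unassigned,
                }
            )
    objects_df = pd.DataFrame(obj_rows, columns=OBJECT_CSV_COLUMNS)
    muv_df = pd.DataFrame(muv_rows) if config.body_detection else None
    return objects_df, muv_df


def match_vulva_false_positives(
    objects_df: pd.DataFrame,
    gt_objects: pd.DataFrame,
    radius: float = 8.0,
) -> int:
    """Count detected vulva-class objects attributable to simulated speckles.

    A detected vulva focus is speckle-attributed if its centroid lies within
    ``radius`` px of a ground-truth speckle centroid in the same field. Used
    to report confounder-driven false positives separately from genuine
    vulva-count errors.
    """
    n = 0
    sp = gt_objects[gt_objects["class"] == "speckle"]
    det = objects_df[objects_df["label"] == "vulva"]
    for (plate, well, fi), group in det.groupby(["plate", "well", "field"]):
        ref = sp[(sp["plate"] == plate) & (sp["well"] == well) & (sp["field"] == fi)]
        if ref.empty:
            continue
        rx = ref["x"].to_numpy()
        ry = ref["y"].to_numpy()
        for _, row in group.iterrows():
            d2 = (rx - row["x"]) ** 2 + (ry - row["y"]) ** 2
            if d2.size and d2.min() <= radius * radius:
                n += 1
    return n
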