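"""Seeded synthetic plate-image generator with exact ground truth.

Each well is rendered as four non-overlapping image fields (2x2 tile layout)
in two channels: ``gfp`` and ``bf`` (brightfield). A well contains a
configurable number of worms (default drawn from a truncated normal with mean
25.5, SD 7.4, clipped to [5, 66], matching per-well animal counts typical of
the liquid-culture assay). Every worm is rendered as

* a dim, elongated autofluorescent body (a capsule of constant intensity),
* a bright pharynx plateau (a convex ellipse) at one body end, whose area
  discriminates adults from larvae,
* zero or more intense, compact, circular vulval GFP foci at mid-body
  (adults only; multivulva worms carry two or more).

Confounder "speckles" — compact bright foci whose footprint overlaps the
vulva size gate — emulate fluorescence from progeny, bacteria and drug
precipitates, the dominant failure mode of focus counting.

All shapes are constant-intensity plateaus softened by a small Gaussian blur,
so in noise-free mode the pixel-area and peak-intensity distributions of the
three object classes are disjoint by construction and a correctly gated
detector recovers ground truth exactly. Intensities are arbitrary units on a
16-bit scale with strict ordering

    vulval focus > adult pharynx > larval pharynx > body > background.

Determinism contract: identical parameters (including ``seed``) produce
byte-identical images and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from numpy.random import Generator, SeedSequence, default_rng
from scipy import ndimage

CHANNELS = ("gfp", "bf")
N_FIELDS = 4
UINT16_MAX = 65535

#: Default intensity plateaus (arbitrary units on the 16-bit scale).
DEFAULT_BACKGROUND = 400.0
DEFAULT_BODY_AMP = 2000.0
DEFAULT_LARVAL_PHARYNX_AMP = 12000.0
DEFAULT_ADULT_PHARYNX_AMP = 20000.0
DEFAULT_VULVA_AMP = 40000.0

#: Brightfield rendering levels (silhouettes only).
BF_BACKGROUND = 30000.0
BF_BODY = 20000.0

GROUND_TRUTH_WELL_COLUMNS = [
    "plate",
    "well",
    "n_adults",
    "n_larvae",
    "n_vulvae",
    "n_speckles",
]
GROUND_TRUTH_OBJECT_COLUMNS = [
    "plate",
    "well",
    "field",
    "class",
    "x",
    "y",
    "area",
    "peak",
]


class PlacementError(RuntimeError):
    """Raised when worms cannot be placed without overlap at the requested density."""


@dataclass(frozen=True)
class WormSpec:
    """Ground-truth record for one simulated worm.

    Positions and orientation refer to the worm's assigned image field;
    ``position`` is the body centroid as (x, y) pixel coordinates.
    """

    stage: str  # "adult" | "larva"
    body_length: float  # px, tip to tip
    body_width: float  # px
    pharynx_area: float  # px^2, rasterised pharynx footprint
    n_vulvae: int
    position: tuple[float, float]
    orientation: float  # radians
    field_index: int  # 1..4


@dataclass(frozen=True)
class SpeckleSpec:
    """Ground-truth record for one confounder focus."""

    field_index: int
    x: float
    y: float
    radius: float
    peak: float
    area: float


@dataclass
class WellSimParams:
    """Simulation parameters for a single well.

    Parameters
    ----------
    n_worms
        Exact worm count, or None to draw round(Normal(n_worms_mean,
        n_worms_sd)) clipped to ``n_worms_range``.
    adult_fraction
        Per-worm probability of being an adult at analysis time. Low values
        emulate toxic growth retardation.
    vulva_rate_adult
        Expected vulvae per adult. Values <= 1 draw Bernoulli(rate) per adult
        (a wild-type adult has at most one vulva; pathway inhibition removes
        it). Values > 1 put adults in the multivulva (Muv) regime:
        2 + Poisson(rate - 2), truncated at ``max_vulvae``.
    vulva_dist
        "auto" (the behaviour above) or "fixed" (every adult gets exactly
        round(vulva_rate_adult) foci).
    muv_fraction
        Optional mixture for counter-screen genotypes: each adult is Muv with
        this probability (receiving the Muv draw above) and otherwise carries
        a single vulva. None disables the mixture.
    speckle_rate
        Expected confounder foci per field (Poisson).
    noise_sd
        Additive Gaussian pixel noise SD. The default equals 10% of the
        default vulval plateau.
    """

    n_worms: int | None = None
    n_worms_mean: float = 25.5
    n_worms_sd: float = 7.4
    n_worms_range: tuple[int, int] = (5, 66)
    adult_fraction: float = 0.8
    vulva_rate_adult: float = 1.0
    vulva_dist: str = "auto"
    muv_fraction: float | None = None
    max_vulvae: int = 4
    speckle_rate: float = 0.0
    noise_sd: float = 4000.0
    background_level: float = DEFAULT_BACKGROUND
    seed: int = 0

    # --- optics / geometry (px at pixel_size_um per pixel) ---
    field_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.5
    adult_length_range: tuple[float, float] = (120.0, 160.0)
    adult_width_range: tuple[float, float] = (9.0, 13.0)
    larva_length_range: tuple[float, float] = (40.0, 65.0)
    larva_width_range: tuple[float, float] = (4.0, 6.0)
    #: pharynx footprint targets: inside the detection gates with a margin
    adult_pharynx_area_range: tuple[float, float] = (300.0, 700.0)
    larva_pharynx_area_range: tuple[float, float] = (60.0, 180.0)
    vulva_area_range: tuple[float, float] = (45.0, 85.0)
    speckle_radius_range: tuple[float, float] = (1.8, 3.4)
    speckle_peak_range: tuple[float, float] = (15000.0, 45000.0)

    body_amp: float = DEFAULT_BODY_AMP
    larval_pharynx_amp: float = DEFAULT_LARVAL_PHARYNX_AMP
    adult_pharynx_amp: float = DEFAULT_ADULT_PHARYNX_AMP
    vulva_amp: float = DEFAULT_VULVA_AMP

    render_sigma: float = 1.0  # optical blur of the rendered plateaus
    clearance: float = 5.0  # min px between rendered objects (pre-blur)
    max_place_tries: int = 500

    def validate(self) -> None:
        if not (0.0 <= self.adult_fraction <= 1.0):
            raise ValueError(f"adult_fraction must be in [0,1], got {self.adult_fraction}")
        if self.muv_fraction is not None and not (0.0 <= self.muv_fraction <= 1.0):
            raise ValueError(f"muv_fraction must be in [0,1], got {self.muv_fraction}")
        if self.vulva_rate_adult < 0 or self.speckle_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.vulva_dist not in ("auto", "fixed"):
            raise ValueError(f"unknown vulva_dist {self.vulva_dist!r}")
        h, w = self.field_size
        if h <= 0 or w <= 0:
            raise ValueError(f"non-positive field dimensions {self.field_size}")
        reach = 2 * (self.adult_length_range[1] / 2 + 16)
        if self.n_worms != 0 and (h < reach or w < reach):
            raise ValueError(
                f"field {self.field_size} too small to hold an adult worm "
                f"(needs >= {reach:.0f} px per side)"
            )
        if self.n_worms is not None and self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")

    def replace(self, **kwargs) -> "WellSimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class WellImage:
    """Two-channel, four-field pixel data for one well."""

    plate_id: str
    well_id: str
    fields: list[dict[str, np.ndarray]]  # 4 entries, each {"gfp": ..., "bf": ...}
    pixel_size_um: float

    def __post_init__(self) -> None:
        if len(self.fields) != N_FIELDS:
            raise ValueError(f"expected {N_FIELDS} fields, got {len(self.fields)}")
        shapes = {f[ch].shape for f in self.fields for ch in CHANNELS}
        if len(shapes) != 1:
            raise ValueError(f"field rasters do not share dimensions: {shapes}")


@dataclass
class GroundTruth:
    """Exact simulator output for one well (the downstream test oracle)."""

    plate_id: str
    well_id: str
    worms: list[WormSpec]
    speckles: list[SpeckleSpec]

    @property
    def n_adults(self) -> int:
        return sum(1 for w in self.worms if w.stage == "adult")

    @property
    def n_larvae(self) -> int:
        return sum(1 for w in self.worms if w.stage == "larva")

    @property
    def n_vulvae(self) -> int:
        return sum(w.n_vulvae for w in self.worms)

    @property
    def n_speckles(self) -> int:
        return len(self.speckles)

    @property
    def true_counts(self) -> tuple[int, int, int, int]:
        return (self.n_adults, self.n_larvae, self.n_vulvae, self.n_speckles)

    def well_record(self) -> dict:
        return {
            "plate": self.plate_id,
            "well": self.well_id,
            "n_adults": self.n_adults,
            "n_larvae": self.n_larvae,
            "n_vulvae": self.n_vulvae,
            "n_speckles": self.n_speckles,
        }

    # object_table is filled in during rendering (per-object class/centroid/
    # area/peak); kept as plain records so it serialises straight to CSV.
    object_table: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _patch(shape: tuple[int, int], cx: float, cy: float, reach: float):
    """Integer bbox (slices) of radius ``reach`` around (cx, cy), clipped to shape."""
    h, w = shape
    x0 = max(0, int(math.floor(cx - reach)))
    x1 = min(w, int(math.ceil(cx + reach)) + 1)
    y0 = max(0, int(math.floor(cy - reach)))
    y1 = min(h, int(math.ceil(cy + reach)) + 1)
    return slice(y0, y1), slice(x0, x1)


def _grid(sy: slice, sx: slice):
    yy, xx = np.mgrid[sy, sx]
    return xx.astype(float), yy.astype(float)


def _capsule_mask(xx, yy, p0, p1, halfwidth) -> np.ndarray:
    """Pixels within ``halfwidth`` of the segment p0-p1."""
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        d2 = (xx - p0[0]) ** 2 + (yy - p0[1]) ** 2
    else:
        t = ((xx - p0[0]) * dx + (yy - p0[1]) * dy) / seg2
        t = np.clip(t, 0.0, 1.0)
        d2 = (xx - (p0[0] + t * dx)) ** 2 + (yy - (p0[1] + t * dy)) ** 2
    return d2 <= halfwidth * halfwidth


def _ellipse_mask(xx, yy, center, a, b, theta) -> np.ndarray:
    """Rotated ellipse with semi-axes a (along theta) and b."""
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - center[0]) * ct + (yy - center[1]) * st
    v = -(xx - center[0]) * st + (yy - center[1]) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_mask(xx, yy, center, r) -> np.ndarray:
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r * r


@dataclass
class _WormGeometry:
    """Resolved render geometry for one worm, in field coordinates."""

    stage: str
    length: float
    width: float
    center: tuple[float, float]
    theta: float
    pharynx_center: tuple[float, float]
    pharynx_a: float
    pharynx_b: float
    vulva_centers: list[tuple[float, float]]
    vulva_radius: float

    @property
    def reach(self) -> float:
        return self.length / 2 + max(self.pharynx_b, self.width) + 4


def _make_geometry(
    rng: Generator,
    stage: str,
    n_vulvae: int,
    params: WellSimParams,
    cx: float,
    cy: float,
    theta: float,
) -> _WormGeometry:
    if stage == "adult":
        length = rng.uniform(*params.adult_length_range)
        width = rng.uniform(*params.adult_width_range)
        ph_area = rng.uniform(*params.adult_pharynx_area_range)
    else:
        length = rng.uniform(*params.larva_length_range)
        width = rng.uniform(*params.larva_width_range)
        ph_area = rng.uniform(*params.larva_pharynx_area_range)
    aspect = 1.4  # pharynx ellipse elongation along the body axis
    b = math.sqrt(ph_area / (math.pi * aspect))
    a = aspect * b
    u = (math.cos(theta), math.sin(theta))
    half_seg = (length - width) / 2  # capsule segment half-length
    # pharynx sits at the head end, slightly inset so it stays on the body axis
    ph_center = (cx + (half_seg + width / 2 - a) * u[0], cy + (half_seg + width / 2 - a) * u[1])

    v_r = math.sqrt(rng.uniform(*params.vulva_area_range) / math.pi)
    centers: list[tuple[float, float]] = []
    if n_vulvae > 0:
        # axial interval for foci: clear of the tail tip, and separated from
        # the pharynx near edge by a fixed gap so foci never fuse with it
        pharynx_gap = 12.0
        lo = -(half_seg - v_r - 2.0)
        hi = half_seg + width / 2 - 2 * a - pharynx_gap - v_r
        hi = max(hi, lo)
        if n_vulvae == 1:
            mid = (lo + hi) / 2
            alongs = [mid + rng.uniform(-0.1, 0.1) * (hi - lo)]
        else:
            # even spacing maximises focus separation (no jitter: short worms
            # with large pharynges leave little room)
            alongs = list(np.linspace(lo, hi, n_vulvae))
        n = (-u[1], u[0])  # ventral offset, normal to the body axis
        side = 1.0 if rng.random() < 0.5 else -1.0
        for along in alongs:
            centers.append(
                (
                    cx + along * u[0] + side * 0.6 * (width / 2) * n[0],
                    cy + along * u[1] + side * 0.6 * (width / 2) * n[1],
                )
            )
    return _WormGeometry(
        stage=stage,
        length=length,
        width=width,
        center=(cx, cy),
        theta=theta,
        pharynx_center=ph_center,
        pharynx_a=a,
        pharynx_b=b,
        vulva_centers=centers,
        vulva_radius=v_r,
    )


def _worm_masks(geom: _WormGeometry, shape):
    """Rasterise body/pharynx/vulva masks of one worm inside its patch."""
    sy, sx = _patch(shape, geom.center[0], geom.center[1], geom.reach)
    xx, yy = _grid(sy, sx)
    u = (math.cos(geom.theta), math.sin(geom.theta))
    half_seg = (geom.length - geom.width) / 2
    p0 = (geom.center[0] - half_seg * u[0], geom.center[1] - half_seg * u[1])
    p1 = (geom.center[0] + half_seg * u[0], geom.center[1] + half_seg * u[1])
    body = _capsule_mask(xx, yy, p0, p1, geom.width / 2)
    pharynx = _ellipse_mask(xx, yy, geom.pharynx_center, geom.pharynx_a, geom.pharynx_b, geom.theta)
    vulvae = [_disk_mask(xx, yy, c, geom.vulva_radius) for c in geom.vulva_centers]
    return (sy, sx), body, pharynx, vulvae


def _place_worm(
    rng: Generator,
    geom_factory,
    occupancy: list[np.ndarray],
    field_order: list[int],
    params: WellSimParams,
):
    """Rejection-sample a non-overlapping placement across candidate fields.

    Returns (field_index_0based, geometry, masks) or raises PlacementError.
    """
    h, w = params.field_size
    pad = params.clearance + 4  # clearance + blur skirt
    for fi in field_order:
        occ = occupancy[fi]
        for _ in range(params.max_place_tries):
            theta = rng.uniform(0.0, 2 * math.pi)
            probe = geom_factory(rng, w / 2, h / 2, theta)
            # oriented half-extents keep the whole worm inside the field
            # without wasting placement area on a circumradius bound
            lat = max(probe.width / 2, probe.pharynx_b, 0.6 * probe.width / 2 + probe.vulva_radius)
            c, s = abs(math.cos(theta)), abs(math.sin(theta))
            ex = c * probe.length / 2 + s * lat + pad
            ey = s * probe.length / 2 + c * lat + pad
            if 2 * ex >= w or 2 * ey >= h:
                raise PlacementError(
                    f"worm extent ({ex:.0f}, {ey:.0f})px exceeds field {params.field_size}"
                )
            cx = rng.uniform(ex, w - ex)
            cy = rng.uniform(ey, h - ey)
            geom = dataclasses.replace(
                probe,
                center=(cx, cy),
                pharynx_center=(
                    probe.pharynx_center[0] + cx - w / 2,
                    probe.pharynx_center[1] + cy - h / 2,
                ),
                vulva_centers=[
                    (x + cx - w / 2, y + cy - h / 2) for x, y in probe.vulva_centers
                ],
            )
            (sy, sx), body, pharynx, vulvae = _worm_masks(geom, (h, w))
            footprint = body | pharynx
            for vm in vulvae:
                footprint |= vm
            if (occ[sy, sx] & footprint).any():  # cheap reject before the EDT
                continue
            dilated = ndimage.distance_transform_edt(~footprint) <= params.clearance
            if not (occ[sy, sx] & dilated).any():
                occ[sy, sx] |= dilated
                return fi, geom, ((sy, sx), body, pharynx, vulvae)
    raise PlacementError(
        f"could not place worm after {params.max_place_tries} tries per field "
        f"(density too high for non-overlapping placement)"
    )


def _draw_n_vulvae(rng: Generator, params: WellSimParams) -> int:
    rate = params.vulva_rate_adult
    if params.vulva_dist == "fixed":
        return min(int(round(rate)), params.max_vulvae)
    if params.muv_fraction is not None:
        if rng.random() < params.muv_fraction:
            return _muv_draw(rng, max(rate, 2.0), params.max_vulvae)
        return 1
    if rate <= 1.0:
        return int(rng.random() < rate)
    return _muv_draw(rng, rate, params.max_vulvae)


def _muv_draw(rng: Generator, rate: float, max_vulvae: int) -> int:
    return min(2 + int(rng.poisson(max(rate - 2.0, 0.0))), max_vulvae)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_well(
    params: WellSimParams,
    plate_id: str = "SIM",
    well_id: str = "A01",
) -> tuple[WellImage, GroundTruth]:
    """Render one well and return its image stack plus exact ground truth.

    Raises
    ------
    ValueError
        On invalid parameters.
    PlacementError
        If the requested worm count cannot be placed without overlap
        (never silently truncated).
    """
    params.validate()
    rng = default_rng(SeedSequence([int(params.seed) & 0x7FFFFFFF]))
    h, w = params.field_size

    if params.n_worms is not None:
        n_worms = int(params.n_worms)
    else:
        lo, hi = params.n_worms_range
        n_worms = int(np.clip(round(rng.normal(params.n_worms_mean, params.n_worms_sd)), lo, hi))

    stages = ["adult" if rng.random() < params.adult_fraction else "larva" for _ in range(n_worms)]
    vulva_counts = [
        _draw_n_vulvae(rng, params) if s == "adult" else 0 for s in stages
    ]
    # place large worms first: improves packing at high densities without
    # changing the sampled phenotypes
    order = sorted(range(n_worms), key=lambda i: (stages[i] != "adult", i))

    gfp = [np.full((h, w), params.background_level, dtype=float) for _ in range(N_FIELDS)]
    bf = [np.full((h, w), BF_BACKGROUND, dtype=float) for _ in range(N_FIELDS)]
    occupancy = [np.zeros((h, w), dtype=bool) for _ in range(N_FIELDS)]

    gt = GroundTruth(plate_id=plate_id, well_id=well_id, worms=[], speckles=[])

    for i in order:
        stage, n_v = stages[i], vulva_counts[i]
        start_field = int(rng.integers(0, N_FIELDS))
        field_order = [(start_field + k) % N_FIELDS for k in range(N_FIELDS)]

        def factory(r, cx, cy, theta, _stage=stage, _nv=n_v):
            return _make_geometry(r, _stage, _nv, params, cx, cy, theta)

        fi, geom, ((sy, sx), body, pharynx, vulvae) = _place_worm(
            rng, factory, occupancy, field_order, params
        )
        ph_amp = params.adult_pharynx_amp if stage == "adult" else params.larval_pharynx_amp
        g = gfp[fi]
        g[sy, sx][body] = params.background_level + params.body_amp
        g[sy, sx][pharynx] = params.background_level + ph_amp
        for vm in vulvae:
            g[sy, sx][vm] = params.background_level + params.vulva_amp
        bf[fi][sy, sx][body | pharynx] = BF_BODY

        ph_px = int(np.count_nonzero(pharynx))
        gt.worms.append(
            WormSpec(
                stage=stage,
                body_length=geom.length,
                body_width=geom.width,
                pharynx_area=float(ph_px),
                n_vulvae=n_v,
                position=geom.center,
                orientation=geom.theta,
                field_index=fi + 1,
            )
        )
        label = "adult_pharynx" if stage == "adult" else "larval_pharynx"
        gt.object_table.append(
            {
                "plate": plate_id,
                "well": well_id,
                "field": fi + 1,
                "class": label,
                "x": geom.pharynx_center[0],
                "y": geom.pharynx_center[1],
                "area": float(ph_px),
                "peak": params.background_level + ph_amp,
            }
        )
        for c in geom.vulva_centers:
            gt.object_table.append(
                {
                    "plate": plate_id,
                    "well": well_id,
                    "field": fi + 1,
                    "class": "vulva",
                    "x": c[0],
                    "y": c[1],
                    "area": float(math.pi * geom.vulva_radius**2),
                    "peak": params.background_level + params.vulva_amp,
                }
            )

    # confounder speckles: off-worm compact bright foci, Poisson per field
    for fi in range(N_FIELDS):
        n_speckles = int(rng.poisson(params.speckle_rate))
        placed = 0
        tries = 0
        while placed < n_speckles and tries < params.max_place_tries * max(n_speckles, 1):
            tries += 1
            r = rng.uniform(*params.speckle_radius_range)
            amp = rng.uniform(*params.speckle_peak_range)
            margin = r + params.clearance + 3
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            sy, sx = _patch((h, w), cx, cy, r + params.clearance + 1)
            xx, yy = _grid(sy, sx)
            disk = _disk_mask(xx, yy, (cx, cy), r)
            dilated = _disk_mask(xx, yy, (cx, cy), r + params.clearance)
            if (occupancy[fi][sy, sx] & dilated).any():
                continue
            occupancy[fi][sy, sx] |= dilated
            gfp[fi][sy, sx][disk] = params.background_level + amp
            area = float(np.count_nonzero(disk))
            gt.speckles.append(
                SpeckleSpec(field_index=fi + 1, x=cx, y=cy, radius=r, peak=amp, area=area)
            )
            gt.object_table.append(
                {
                    "plate": plate_id,
                    "well": well_id,
                    "field": fi + 1,
                    "class": "speckle",
                    "x": cx,
                    "y": cy,
                    "area": area,
                    "peak": params.background_level + amp,
                }
            )
            placed += 1
        if placed < n_speckles:
            raise PlacementError("could not place requested speckles without overlap")

    fields: list[dict[str, np.ndarray]] = []
    for fi in range(N_FIELDS):
        g, b = gfp[fi], bf[fi]
        if params.render_sigma > 0:
            g = ndimage.gaussian_filter(g, params.render_sigma)
            b = ndimage.gaussian_filter(b, params.render_sigma)
        if params.noise_sd > 0:
            g = g + rng.normal(0.0, params.noise_sd, size=g.shape)
            b = b + rng.normal(0.0, params.noise_sd, size=b.shape)
        fields.append(
            {
                "gfp": np.clip(np.rint(g), 0, UINT16_MAX).astype(np.uint16),
                "bf": np.clip(np.rint(b), 0, UINT16_MAX).astype(np.uint16),
            }
        )

    image = WellImage(
        plate_id=plate_id, well_id=well_id, fields=fields, pixel_size_um=params.pixel_size_um
    )
    return image, gt


def well_seed(base_seed: int, plate_id: str, well_id: str) -> int:
    """Stable per-well seed: adding wells never perturbs other wells' draws."""
    ss = SeedSequence(
        [int(base_seed) & 0x7FFFFFFF, zlib.crc32(plate_id.encode()), zlib.crc32(well_id.encode())]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def tiff_name(plate: str, well: str, field_index: int, channel: str) -> str:
    return f"{plate}_{well}_f{field_index}_{channel}.tif"


def write_well_tiffs(image: WellImage, out_dir: Path) -> list[str]:
    """Write one 16-bit grayscale TIFF per (field, channel); returns filenames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for fi, f in enumerate(image.fields, start=1):
        for ch in CHANNELS:
            name = tiff_name(image.plate_id, image.well_id, fi, ch)
            tifffile.imwrite(out_dir / name, f[ch])
            names.append(name)
    return names


def render_plate(
    plate_map: pd.DataFrame,
    per_well_params: Mapping[tuple[str, str], WellSimParams],
    out_dir: Path,
) -> dict:
    """Render every well of a plate map and write TIFFs + ground-truth CSVs.

    ``plate_map`` needs columns ``plate`` and ``well``; ``per_well_params``
    maps (plate, well) to the simulation parameters for that well. Returns a
    manifest dict listing all written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys = list(zip(plate_map["plate"], plate_map["well"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate wells in plate map: {dupes}")
    missing = [k for k in keys if k not in per_well_params]
    if missing:
        raise ValueError(f"no simulation parameters for wells: {missing[:5]}")

    image_files: list[str] = []
    well_records: list[dict] = []
    object_records: list[dict] = []
    for plate, well in keys:
        image, gt = render_well(per_well_params[(plate, well)], plate_id=plate, well_id=well)
        image_files.extend(write_well_tiffs(image, out_dir))
        well_records.append(gt.well_record())
        object_records.extend(gt.object_table)

    gt_wells = pd.DataFrame(well_records, columns=GROUND_TRUTH_WELL_COLUMNS)
    gt_wells = gt_wells.sort_values(["plate", "well"], kind="mergesort").reset_index(drop=True)
    gt_wells.to_csv(out_dir / "ground_truth_wells.csv", index=False)
    gt_objects = pd.DataFrame(object_records, columns=GROUND_TRUTH_OBJECT_COLUMNS)
    gt_objects.to_csv(out_dir / "ground_truth_objects.csv", index=False, float_format="%.3f")

    manifest = {
        "n_wells": len(keys),
        "images": sorted(image_files),
        "ground_truth_wells": "ground_truth_wells.csv",
        "ground_truth_objects": "ground_truth_objects.csv",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
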