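"""Stained-area-fraction quantification of region-of-interest (ROI) areas.

The measurement follows bright-field DAB-Ni conventions: the chromogen is a
dark grey deposit on a lighter background, so all detection happens on the
*inverted* intensity scale (``1 - I``), where larger means more stain.  A
pixel inside an ROI counts as stained when its inverted intensity exceeds a
robust per-ROI background estimate (median) by ``k`` scaled median absolute
deviations (MAD, normal-consistent, i.e. ``k`` is in sigma-like units).
The per-ROI quantity is the stained-area fraction::

    fraction = stained pixel area / total ROI pixel area

and ROIs belonging to the same animal x region (different sides or
sections) are pooled area-weighted: sum of stained areas over sum of total
areas, never a mean of ratios.

Blinding support: :func:`blind_order` returns a seeded random presentation
order that exposes only opaque blinded IDs and image references; the
mapping back to animal and group is emitted as a separate sealed key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "SectionImage",
    "RegionROI",
    "StainMeasurement",
    "BackgroundEstimate",
    "rasterize_polygon",
    "blind_order",
    "estimate_background",
    "stain_mask",
    "measure_roi",
    "aggregate_animal",
    "measure_records",
    "quantify_cohort_dir",
    "load_image",
]

#: Default threshold multiplier: stained iff inverted intensity exceeds the
#: ROI median by more than 5 scaled MADs.
DEFAULT_K: float = 5.0


@dataclass
class SectionImage:
    """One scanned section: single-channel intensity raster in [0, 1].

    ``resolution_um`` is the physical pixel pitch in micrometres (the
    study's slide scanner operated at 1.6 um/px).
    """

    data: np.ndarray
    resolution_um: float = 1.6
    section_index: int = 0
    source: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"section image must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("section image contains non-finite intensities")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("section image intensities must lie in [0, 1]")
        if self.resolution_um <= 0:
            raise ValueError("resolution_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def load_image(path: str | Path, resolution_um: float = 1.6,
               section_index: int = 0) -> SectionImage:
    """Read a single-channel TIFF and rescale by its declared bit depth."""
    raw = tifffile.imread(str(path))
    if raw.dtype == np.uint8:
        data = raw / 255.0
    elif raw.dtype == np.uint16:
        data = raw / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        data = np.asarray(raw, dtype=float)
    else:
        raise ValueError(f"unsupported TIFF dtype {raw.dtype} for {path}")
    return SectionImage(data, resolution_um=resolution_um,
                        section_index=section_index, source=str(path))


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall strictly inside the polygon.

    Coordinates are 0-based pixel indices: pixel ``(row r, col c)`` has its
    center at point ``(x=c, y=r)``.  Pixels with centers exactly on the
    boundary are excluded, which makes rasterization bit-reproducible.
    A polygon extending beyond the image raster is a hard error.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n>=3, 2) array of (x, y) vertices")
    h, w = shape
    geom = Polygon(poly)
    if not geom.is_valid:
        raise ValueError("polygon must be simple (non-self-intersecting) and closed")
    minx, miny, maxx, maxy = geom.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ValueError(
            f"ROI polygon bounds {geom.bounds} fall outside image raster {shape}")
    c0, c1 = max(int(math.floor(minx)), 0), min(int(math.ceil(maxx)), w - 1)
    r0, r1 = max(int(math.floor(miny)), 0), min(int(math.ceil(maxy)), h - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    xs, ys = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel())
    mask[r0:r1 + 1, c0:c1 + 1] = inside.reshape(xs.shape)
    return mask


@dataclass
class RegionROI:
    """A segmented area on one section.

    Exactly one of ``polygon`` (pixel-coordinate vertices) or ``mask``
    (boolean raster congruent with the image) must describe the geometry;
    a polygon is rasterized by the pixel-center-inside rule.
    """

    region: str
    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None
    side: str = "NA"
    animal_id: str | None = None
    blinded_id: str | None = None
    _cached_mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.polygon is None and self.mask is None:
            raise ValueError("RegionROI needs a polygon or a mask")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """ROI raster for an image of ``shape``; errors on empty ROI."""
        if self._cached_mask is not None and self._cached_mask.shape == shape:
            return self._cached_mask
        if self.mask is not None:
            if self.mask.shape != shape:
                raise ValueError(
                    f"ROI mask shape {self.mask.shape} != image shape {shape}")
            m = self.mask.astype(bool)
        else:
            m = rasterize_polygon(self.polygon, shape)
        if not m.any():
            raise ValueError(f"ROI '{self.region}' has zero pixel area")
        self._cached_mask = m
        return m


@dataclass(frozen=True)
class StainMeasurement:
    """Stained and total areas for one ROI or one pooled animal x region."""

    stained_area_px: float
    total_area_px: float
    stained_area_um2: float
    total_area_um2: float
    fraction: float
    threshold_used: float
    level: str = "roi"  # "roi" | "animal_region"

    def __post_init__(self) -> None:
        if self.total_area_px <= 0:
            raise ValueError("total area must be positive")
        if not 0 <= self.stained_area_px <= self.total_area_px:
            raise ValueError("stained area must lie in [0, total area]")


class BackgroundEstimate(NamedTuple):
    level: float  # median inverted intensity within the ROI
    mad: float    # normal-consistent scaled MAD of inverted intensity


_MAD_SCALE = 1.4826  # normal-consistency factor


def estimate_background(image: SectionImage, roi: RegionROI) -> BackgroundEstimate:
    """Robust background level of an ROI on the inverted-intensity scale.

    The median tolerates the stained minority of pixels; the scaled MAD
    captures the spread of the unspecific background staining plus noise.
    """
    m = roi.pixel_mask(image.shape)
    inv = 1.0 - image.data[m]
    med = float(np.median(inv))
    mad = _MAD_SCALE * float(np.median(np.abs(inv - med)))
    return BackgroundEstimate(med, mad)


def stain_mask(image: SectionImage, roi: RegionROI, k: float = DEFAULT_K,
               background: BackgroundEstimate | None = None) -> np.ndarray:
    """Binary stained-pixel mask: inverted intensity > background + k * MAD.

    The background defaults to the ROI's own robust estimate, which assumes
    stain covers a minority of the ROI; for near-saturated ROIs pass a
    ``background`` measured on a stain-free reference area instead.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    m = roi.pixel_mask(image.shape)
    bg = background if background is not None else estimate_background(image, roi)
    inv = 1.0 - image.data
    return m & (inv > bg.level + k * bg.mad)


def measure_roi(image: SectionImage, roi: RegionROI, k: float = DEFAULT_K,
                background: BackgroundEstimate | None = None) -> StainMeasurement:
    """Stained-area fraction of one ROI, with areas in px and um^2."""
    if k <= 0:
        raise ValueError("k must be positive")
    m = roi.pixel_mask(image.shape)
    bg = background if background is not None else estimate_background(image, roi)
    inv = 1.0 - image.data
    threshold = bg.level + k * bg.mad
    stained = int((m & (inv > threshold)).sum())
    total = int(m.sum())
    px_area = image.resolution_um ** 2
    return StainMeasurement(
        stained_area_px=stained,
        total_area_px=total,
        stained_area_um2=stained * px_area,
        total_area_um2=total * px_area,
        fraction=stained / total,
        threshold_used=threshold,
        level="roi",
    )


def aggregate_animal(measurements: Sequence[StainMeasurement]) -> StainMeasurement:
    """Pool ROI measurements of one animal x region, area-weighted.

    The pooled fraction is sum(stained) / sum(total) over sides and
    sections — equivalent to measuring all the segmented area at once —
    not the mean of the per-ROI ratios.
    """
    if not measurements:
        raise ValueError("cannot aggregate an empty set of measurements")
    stained_px = sum(m.stained_area_px for m in measurements)
    total_px = sum(m.total_area_px for m in measurements)
    stained_um2 = sum(m.stained_area_um2 for m in measurements)
    total_um2 = sum(m.total_area_um2 for m in measurements)
    return StainMeasurement(
        stained_area_px=stained_px,
        total_area_px=total_px,
        stained_area_um2=stained_um2,
        total_area_um2=total_um2,
        fraction=stained_px / total_px,
        threshold_used=float("nan"),
        level="animal_region",
    )


# ---------------------------------------------------------------------------
# blinding
# ---------------------------------------------------------------------------

_PRESENTED_COLUMNS = ["position", "blinded_id", "image_path"]
_KEY_COLUMNS = ["blinded_id", "roi_id", "animal_id", "group", "region",
                "side", "section_index"]


def blind_order(roi_records: pd.DataFrame | Iterable[dict],
                seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random presentation order for blind scoring.

    Returns ``(presentation, key)``: the presentation frame exposes only a
    running position, the blinded ID and the image reference — never group,
    animal or region — while the sealed key maps blinded IDs back to their
    full identity for post-hoc unblinding.
    """
    df = pd.DataFrame(roi_records)
    if df.empty:
        return (pd.DataFrame(columns=_PRESENTED_COLUMNS),
                pd.DataFrame(columns=_KEY_COLUMNS))
    if "blinded_id" not in df.columns:
        raise ValueError("records must carry a blinded_id column")
    if df["blinded_id"].duplicated().any():
        dupes = df.loc[df["blinded_id"].duplicated(), "blinded_id"].tolist()
        raise ValueError(f"duplicate blinded_ids: {dupes}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    shuffled = df.iloc[order].reset_index(drop=True)
    presentation = pd.DataFrame({
        "position": np.arange(len(shuffled)),
        "blinded_id": shuffled["blinded_id"],
        "image_path": shuffled.get("image_path", pd.Series([""] * len(shuffled))),
    })
    key_cols = [c for c in _KEY_COLUMNS if c in df.columns]
    key = df[key_cols].sort_values("blinded_id").reset_index(drop=True)
    return presentation, key


# ---------------------------------------------------------------------------
# batch quantification
# ---------------------------------------------------------------------------

_ROI_MEAS_COLUMNS = ["roi_id", "animal_id", "group", "region", "side",
                     "section_index", "blinded_id", "stained_px", "total_px",
                     "stained_um2", "total_um2", "fraction", "threshold"]
MEASUREMENT_COLUMNS = ["animal_id", "group", "region", "n_rois",
                       "stained_um2", "total_um2", "fraction"]


def measure_records(records: Iterable, k: float = DEFAULT_K,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure an iterable of cohort ROI records.

    Each record must provide ``image`` (a :class:`SectionImage` or a path),
    ``roi`` (:class:`RegionROI`) and the identity fields.  Returns
    ``(roi_level, pooled)`` data frames; ``pooled`` has one row per
    animal x region with the area-weighted fraction (the measurements CSV
    contract).
    """
    rows = []
    for rec in records:
        image = rec.image if isinstance(rec.image, SectionImage) else load_image(
            rec.image, resolution_um=rec.resolution_um)
        meas = measure_roi(image, rec.roi, k=k)
        rows.append({
            "roi_id": rec.roi_id, "animal_id": rec.animal_id,
            "group": rec.group, "region": rec.region, "side": rec.side,
            "section_index": rec.section_index, "blinded_id": rec.blinded_id,
            "stained_px": meas.stained_area_px, "total_px": meas.total_area_px,
            "stained_um2": meas.stained_area_um2,
            "total_um2": meas.total_area_um2,
            "fraction": meas.fraction, "threshold": meas.threshold_used,
        })
    roi_df = pd.DataFrame(rows, columns=_ROI_MEAS_COLUMNS)
    if roi_df.empty:
        return roi_df, pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    grouped = roi_df.groupby(["animal_id", "group", "region"], sort=True)
    pooled = grouped.agg(
        n_rois=("roi_id", "size"),
        stained_um2=("stained_um2", "sum"),
        total_um2=("total_um2", "sum"),
        stained_px=("stained_px", "sum"),
        total_px=("total_px", "sum"),
    ).reset_index()
    pooled["fraction"] = pooled["stained_px"] / pooled["total_px"]
    return roi_df, pooled[MEASUREMENT_COLUMNS]


def quantify_cohort_dir(cohort_dir: str | Path, k: float = DEFAULT_K,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a cohort previously written to disk (TIFF/JSON/CSV contract)."""
    from .synthetic import load_cohort  # deferred: synthetic imports this module

    cohort = load_cohort(cohort_dir)
    return measure_records(cohort.records, k=k)
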