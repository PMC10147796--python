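"""Seeded synthetic immunohistochemistry sections with known ground truth.

The study's raw section scans are not publicly deposited, so this module
generates the kind of data the quantification pipeline consumes, with exact
per-pixel ground truth: bright-field-like fields in which activated neurons
appear as dark stained cytoplasmic annuli (the nucleus stays unstained, as
do dendrites and axons), on a light background carrying a slight smooth
unspecific staining plus sensor noise.

Model, per section:

* cell centers — homogeneous Poisson process with intensity
  ``cell_density`` (cells per mm^2); overlapping cells merge by mask union;
* each cell — annulus between an inner (nucleus) and outer (soma) radius;
  radii are drawn per cell with 10% relative spread around the means, the
  nucleus scaling proportionally;
* stain — the annulus pixels are depressed by ``stain_level`` below the
  local background; the ground-truth mask marks exactly those pixels;
* unspecific background — a zero-mean low-frequency field (coarse Gaussian
  grid, smoothly upsampled) with standard deviation ``background_stain_sd``
  added to ``background_level``; it never enters the ground-truth mask;
* noise — i.i.d. additive Gaussian, then clipping to [0, 1].

All geometry is specified in micrometres and converted through
``resolution_um`` (default 1.6 um/px, the study's scanner pitch).  The same
spec and seed always reproduce the same bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

from .quantify import RegionROI, SectionImage, rasterize_polygon
from .regions import CONTROL_GROUP, GROUPS, REGIONS

__all__ = [
    "StainFieldSpec",
    "CohortSpec",
    "GroundTruth",
    "CohortRecord",
    "Cohort",
    "generate_section",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

_COARSE_PX = 32  # grid spacing (px) of the low-frequency background field
_ROI_MARGIN_PX = 5.5  # inset of the rectangular ROI polygon from the frame edge


@dataclass(frozen=True)
class StainFieldSpec:
    """Parameters of one synthetic section field.

    Intensities live in [0, 1]; geometry in micrometres.  Defaults give a
    light background (0.85) with dark stained annuli (depressed by 0.35),
    ~3% baseline stained-area fraction at 350 cells/mm^2, and mild
    unspecific background staining and noise.
    """

    image_shape: tuple[int, int] = (192, 192)
    resolution_um: float = 1.6
    background_level: float = 0.85
    background_stain_sd: float = 0.02
    cell_density: float = 350.0
    cell_radius_um: float = 6.0
    nucleus_radius_um: float = 3.0
    stain_level: float = 0.35
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image dimensions must be positive")
        if self.resolution_um <= 0:
            raise ValueError("resolution_um must be positive")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level must lie in [0, 1]")
        if not 0 <= self.stain_level <= 1:
            raise ValueError("stain_level must lie in [0, 1]")
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus radius must be smaller than cell radius")
        if min(self.background_stain_sd, self.noise_sd, self.cell_density,
               self.nucleus_radius_um) < 0:
            raise ValueError("densities, radii and sd parameters must be >= 0")

    def with_(self, **kwargs) -> "StainFieldSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Exact stained-pixel mask of one generated section."""

    mask: np.ndarray

    def fraction(self, roi_mask: np.ndarray | None = None) -> float:
        """True stained fraction, optionally restricted to an ROI raster."""
        if roi_mask is None:
            return float(self.mask.mean())
        if roi_mask.shape != self.mask.shape:
            raise ValueError("ROI mask not congruent with section")
        total = int(roi_mask.sum())
        if total == 0:
            raise ValueError("empty ROI mask")
        return int((self.mask & roi_mask).sum()) / total


def _smooth_background(rng: np.random.Generator, shape: tuple[int, int],
                       sd: float) -> np.ndarray:
    """Zero-mean low-frequency field with standard deviation ``sd``."""
    h, w = shape
    gh = max(2, math.ceil(h / _COARSE_PX) + 1)
    gw = max(2, math.ceil(w / _COARSE_PX) + 1)
    coarse = rng.normal(0.0, 1.0, size=(gh, gw))
    fine = resize(coarse, shape, order=3, mode="reflect", anti_aliasing=False)
    fine -= fine.mean()
    s = fine.std()
    if s > 0:
        fine *= sd / s
    return fine


def generate_section(spec: StainFieldSpec) -> tuple[SectionImage, GroundTruth]:
    """Render one synthetic section and its exact stained-pixel mask."""
    h, w = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    px = spec.resolution_um

    area_mm2 = h * w * px * px / 1e6
    n_cells = int(rng.poisson(spec.cell_density * area_mm2))
    mask = np.zeros((h, w), dtype=bool)
    if n_cells > 0:
        cx = rng.uniform(0, w, n_cells)
        cy = rng.uniform(0, h, n_cells)
        r_out_um = rng.normal(spec.cell_radius_um, 0.1 * spec.cell_radius_um,
                              n_cells)
        r_out_um = np.clip(r_out_um, 0.3 * spec.cell_radius_um, None)
        ratio = spec.nucleus_radius_um / spec.cell_radius_um
        for x, y, ro_um in zip(cx, cy, r_out_um):
            ro = ro_um / px
            ri = ro * ratio
            c0, c1 = max(int(x - ro) - 1, 0), min(int(x + ro) + 2, w)
            r0, r1 = max(int(y - ro) - 1, 0), min(int(y + ro) + 2, h)
            if c1 <= c0 or r1 <= r0:
                continue
            yy, xx = np.ogrid[r0:r1, c0:c1]
            d2 = (xx - x) ** 2 + (yy - y) ** 2
            mask[r0:r1, c0:c1] |= (d2 <= ro * ro) & (d2 > ri * ri)

    img = np.full((h, w), spec.background_level, dtype=float)
    if spec.background_stain_sd > 0:
        img += _smooth_background(rng, (h, w), spec.background_stain_sd)
    img[mask] -= spec.stain_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    np.clip(img, 0.0, 1.0, out=img)
    return SectionImage(img, resolution_um=px), GroundTruth(mask)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group study layout with known per-ROI ground truth.

    Defaults mirror the study conditions: 19 brain regions, four groups
    (control, avoidance, trained, novelty) of 10 animals, and 4 ROIs per
    animal x region (both brain sides over two sections), i.e. 3040 ROIs.
    ``activation_multiplier`` maps ``(group, region)`` to a positive factor
    applied to the cell density; unspecified cells default to 1.0 and the
    control group is pinned to 1.0.
    """

    regions: tuple[str, ...] = REGIONS
    groups: tuple[str, ...] = GROUPS
    n_per_group: int | Mapping[str, int] = 10
    rois_per_region: int = 4
    activation_multiplier: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    base_field: StainFieldSpec = field(default_factory=StainFieldSpec)
    control_group: str = CONTROL_GROUP
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region labels must be unique")
        if self.rois_per_region < 1:
            raise ValueError("rois_per_region must be >= 1")
        for (g, r), m in self.activation_multiplier.items():
            if g not in self.groups:
                raise ValueError(f"unknown group {g!r} in multiplier map")
            if r not in self.regions:
                raise ValueError(f"unknown region {r!r} in multiplier map")
            if not m > 0:
                raise ValueError(f"multiplier for {(g, r)} must be > 0")
            if g == self.control_group and m != 1.0:
                raise ValueError("control-group multipliers must equal 1.0")

    def group_size(self, group: str) -> int:
        if isinstance(self.n_per_group, Mapping):
            return int(self.n_per_group[group])
        return int(self.n_per_group)

    def multiplier(self, group: str, region: str) -> float:
        return float(self.activation_multiplier.get((group, region), 1.0))


@dataclass
class CohortRecord:
    """One generated ROI: image (in memory or on disk), geometry and truth."""

    roi_id: str
    animal_id: str
    group: str
    region: str
    side: str
    section_index: int
    blinded_id: str
    roi: RegionROI
    resolution_um: float
    true_fraction: float
    true_stained_px: int
    roi_total_px: int
    image: SectionImage | str  # SectionImage when in memory, path when on disk
    truth_mask: np.ndarray | None = None
    field_seed: int = 0
    image_rel: str = ""  # path relative to the cohort dir, for portable metadata

    @property
    def image_path(self) -> str:
        if self.image_rel:
            return self.image_rel
        return self.image if isinstance(self.image, str) else ""


@dataclass
class Cohort:
    """Bundle of generated ROI records plus tabular views."""

    spec: CohortSpec
    records: list[CohortRecord]
    out_dir: Path | None = None

    def metadata(self) -> pd.DataFrame:
        cols = ["animal_id", "group", "region", "side", "section_index",
                "roi_id", "blinded_id", "image_path"]
        rows = [{c: getattr(r, c) if c != "image_path" else r.image_path
                 for c in cols} for r in self.records]
        return pd.DataFrame(rows, columns=cols)

    def ground_truth(self) -> pd.DataFrame:
        cols = ["roi_id", "animal_id", "group", "region", "true_stained_px",
                "roi_total_px", "true_fraction"]
        rows = [{c: getattr(r, c) for c in cols} for r in self.records]
        return pd.DataFrame(rows, columns=cols)


def _roi_polygon(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    m = _ROI_MARGIN_PX
    if w - 2 * m <= 1 or h - 2 * m <= 1:
        raise ValueError(f"image shape {shape} too small for an inset ROI")
    return np.array([(m, m), (w - 1 - m, m), (w - 1 - m, h - 1 - m),
                     (m, h - 1 - m)], dtype=float)


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None,
                    ) -> Cohort:
    """Generate every ROI of the cohort.

    With ``out_dir`` set, images are streamed to ``images/*.tif`` (16-bit
    TIFF) as they are produced and only geometry, metadata and ground truth
    are kept in memory; the standard file contract (metadata.csv,
    rois.json, ground_truth.csv) is written as well.  Without it, full
    pixel data stays on the records (suitable for small cohorts and
    simulation harnesses).
    """
    roster: list[tuple[str, str]] = []  # (group, animal_id)
    for g in spec.groups:
        for a in range(spec.group_size(g)):
            roster.append((g, f"{g}{a + 1:02d}"))

    layout: list[tuple[str, str, str, int]] = []  # (group, animal, region, j)
    for g, animal in roster:
        for region in spec.regions:
            for j in range(spec.rois_per_region):
                layout.append((g, animal, region, j))

    ss = np.random.SeedSequence(spec.seed)
    blind_child, *roi_children = ss.spawn(len(layout) + 1)
    blind_rng = np.random.default_rng(blind_child)
    codes = blind_rng.permutation(len(layout))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    records: list[CohortRecord] = []
    roi_mask_cache: dict[tuple[int, int], np.ndarray] = {}
    for i, (g, animal, region, j) in enumerate(layout):
        field_seed = int(roi_children[i].generate_state(1)[0] % (2 ** 31))
        mult = spec.multiplier(g, region)
        fspec = spec.base_field.with_(
            cell_density=spec.base_field.cell_density * mult, seed=field_seed)
        image, truth = generate_section(fspec)
        shape = image.shape
        if shape not in roi_mask_cache:
            roi_mask_cache[shape] = rasterize_polygon(_roi_polygon(shape), shape)
        roi_mask = roi_mask_cache[shape]
        total_px = int(roi_mask.sum())
        stained_px = int((truth.mask & roi_mask).sum())
        roi_id = f"{animal}_{region}_{j}"
        roi = RegionROI(region=region, polygon=_roi_polygon(shape),
                        side="L" if j % 2 == 0 else "R", animal_id=animal,
                        blinded_id=f"B{codes[i] + 1:04d}")
        roi._cached_mask = roi_mask
        if out_path is not None:
            rel = f"images/{roi_id}.tif"
            tifffile.imwrite(out_path / rel,
                             np.round(image.data * 65535).astype(np.uint16))
            stored_image: SectionImage | str = str(out_path / rel)
            truth_mask = None
            image_rel = rel
        else:
            stored_image = image
            truth_mask = truth.mask
            image_rel = ""
        records.append(CohortRecord(
            roi_id=roi_id, animal_id=animal, group=g, region=region,
            side=roi.side, section_index=j // 2,
            blinded_id=roi.blinded_id, roi=roi,
            resolution_um=fspec.resolution_um,
            true_fraction=stained_px / total_px,
            true_stained_px=stained_px, roi_total_px=total_px,
            image=stored_image, truth_mask=truth_mask, field_seed=field_seed,
            image_rel=image_rel))

    cohort = Cohort(spec=spec, records=records, out_dir=out_path)
    if out_path is not None:
        write_cohort(cohort, out_path, write_images=False)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 write_images: bool = True) -> Path:
    """Write the standard cohort file contract (TIFF + JSON + CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_images:
        (out / "images").mkdir(exist_ok=True)
        for rec in cohort.records:
            if isinstance(rec.image, SectionImage):
                rel = f"images/{rec.roi_id}.tif"
                tifffile.imwrite(out / rel,
                                 np.round(rec.image.data * 65535).astype(np.uint16))
                rec.image = str(out / rel)
                rec.image_rel = rel
    cohort.metadata().to_csv(out / "metadata.csv", index=False)
    cohort.ground_truth().to_csv(out / "ground_truth.csv", index=False)
    rois = [{
        "roi_id": rec.roi_id,
        "region": rec.region,
        "side": rec.side,
        "image_path": rec.image_path or f"images/{rec.roi_id}.tif",
        "resolution_um": rec.resolution_um,
        "bit_depth": 16,
        "polygon": np.asarray(rec.roi.polygon).tolist(),
    } for rec in cohort.records]
    (out / "rois.json").write_text(json.dumps({"rois": rois}, indent=1,
                                              sort_keys=True))
    return out


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a written cohort for quantification (images stay on disk)."""
    out = Path(cohort_dir)
    meta = pd.read_csv(out / "metadata.csv")
    roi_info = {r["roi_id"]: r
                for r in json.loads((out / "rois.json").read_text())["rois"]}
    records: list[CohortRecord] = []
    for row in meta.itertuples(index=False):
        info = roi_info[row.roi_id]
        path = Path(info["image_path"])
        rel = "" if path.is_absolute() else str(path)
        if not path.is_absolute():
            path = out / path
        roi = RegionROI(region=info["region"],
                        polygon=np.asarray(info["polygon"], dtype=float),
                        side=info["side"], animal_id=row.animal_id,
                        blinded_id=row.blinded_id)
        records.append(CohortRecord(
            roi_id=row.roi_id, animal_id=row.animal_id, group=row.group,
            region=row.region, side=row.side,
            section_index=int(row.section_index), blinded_id=row.blinded_id,
            roi=roi, resolution_um=float(info["resolution_um"]),
            true_fraction=float("nan"), true_stained_px=-1, roi_total_px=-1,
            image=str(path), image_rel=rel))
    spec = CohortSpec(regions=tuple(pd.unique(meta["region"])),
                      groups=tuple(pd.unique(meta["group"])),
                      n_per_group=0, rois_per_region=1) if len(meta) else CohortSpec()
    return Cohort(spec=spec, records=records, out_dir=out)
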