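"""CD34+ vessel objects, marker phenotypes, tissue areas and densities.

A vessel is one connected component of the refined CD34 mask.  An
auxiliary marker (ACKR1, CD36, KDR, LAMB1, MADCAM1) is called positive
for a vessel when its refined mask covers strictly more than 5% of the
vessel's area.  The core area comes from the union of all channel masks
(plus DAPI) after closing; the epithelial area from the KRT mask; the
stromal area is core minus epithelial.  Densities are vessels per mm^2
of core area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from vesselphen.morphometry import FEATURE_NAMES, compute_features
from vesselphen.preprocess import MARKERS, BinaryMask, ChannelStack, disk_closing

#: The nine per-case vessel-density variables (/mm^2 of core area).
DENSITY_VARS = (
    "overall",
    "collapsed",
    "micro",
    "patent",
    "ACKR1",
    "CD36",
    "KDR",
    "LAMB1",
    "MADCAM1",
)

#: Morphology classes with a dedicated density variable; "irregular"
#: contributes to "overall" and is reported as an extra column.
CLASS_DENSITY_VARS = ("collapsed", "micro", "patent", "irregular")


@dataclass
class PhenotypingConfig:
    marker_area_fraction_threshold: float = 0.05  # strict >
    connectivity: int = 2  # skimage convention: 2 = 8-connected
    min_vessel_area_px: int = 12  # 3 um^2 at 0.5 um/px
    tissue_closing_radius_px: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.marker_area_fraction_threshold < 1:
            raise ValueError("marker threshold must be in (0,1)")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if self.min_vessel_area_px < 1:
            raise ValueError("min vessel area must be >= 1 px")


@dataclass
class VesselObject:
    """One connected CD34+ component."""

    vessel_id: int
    core_id: str
    rows: np.ndarray  # 0-based pixel coordinates, grid frame
    cols: np.ndarray
    centroid_um: tuple[float, float]
    area_px: int
    marker_flags: dict[str, bool] = field(default_factory=dict)
    features: dict[str, float] = field(default_factory=dict)
    class_label: str | None = None

    def mask_slices(self) -> tuple[slice, slice]:
        return (
            slice(int(self.rows.min()), int(self.rows.max()) + 1),
            slice(int(self.cols.min()), int(self.cols.max()) + 1),
        )

    def local_mask(self) -> np.ndarray:
        sl = self.mask_slices()
        m = np.zeros(
            (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start), dtype=bool
        )
        m[self.rows - sl[0].start, self.cols - sl[1].start] = True
        return m


@dataclass
class CoreRecord:
    core_id: str
    case_id: str
    core_area_mm2: float
    epithelial_area_mm2: float
    stromal_area_mm2: float
    vessels: list[VesselObject] = field(default_factory=list)
    qc_passed: bool = True

    def __post_init__(self) -> None:
        if min(self.core_area_mm2, self.epithelial_area_mm2, self.stromal_area_mm2) < 0:
            raise ValueError("areas must be non-negative")


def build_tissue_mask(
    masks: dict[str, BinaryMask | np.ndarray],
    closing_radius_px: float = 40.0,
) -> np.ndarray:
    """Tissue = closing of the union of all channel masks (incl. DAPI)."""
    union = None
    for m in masks.values():
        data = m.data if isinstance(m, BinaryMask) else np.asarray(m, bool)
        union = data.copy() if union is None else (union | data)
    if union is None:
        raise ValueError("no masks given")
    return disk_closing(union, closing_radius_px)


def compute_core_areas(
    tissue_mask: np.ndarray,
    krt_mask: np.ndarray,
    pixel_size_um: float = 0.5,
) -> tuple[float, float, float]:
    """(core, epithelial, stromal) areas in mm^2.

    The epithelial mask is intersected with the tissue mask; stromal =
    core - epithelial exactly.
    """
    tissue_mask = np.asarray(tissue_mask, bool)
    krt_mask = np.asarray(krt_mask, bool)
    if tissue_mask.shape != krt_mask.shape:
        raise ValueError("masks must share dimensions")
    px_mm2 = pixel_size_um**2 / 1e6
    core = float(tissue_mask.sum()) * px_mm2
    epithelial = float((krt_mask & tissue_mask).sum()) * px_mm2
    return core, epithelial, core - epithelial


def extract_vessels(
    cd34_mask: BinaryMask | np.ndarray,
    config: PhenotypingConfig | None = None,
    core_id: str = "",
    pixel_size_um: float = 0.5,
    compute_morphometry: bool = True,
) -> list[VesselObject]:
    """Connected components of the refined CD34 mask as vessel objects.

    Components smaller than ``min_vessel_area_px`` are discarded.  IDs
    follow the row-major position of each component's first pixel, so
    the ordering is deterministic.
    """
    config = config or PhenotypingConfig()
    data = cd34_mask.data if isinstance(cd34_mask, BinaryMask) else np.asarray(cd34_mask, bool)
    labeled = label(data, connectivity=config.connectivity)
    vessels: list[VesselObject] = []
    for p in regionprops(labeled):  # regionprops orders labels ascending
        if p.area < config.min_vessel_area_px:
            continue
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        v = VesselObject(
            vessel_id=len(vessels),
            core_id=core_id,
            rows=rows,
            cols=cols,
            centroid_um=(p.centroid[0] * pixel_size_um, p.centroid[1] * pixel_size_um),
            area_px=int(p.area),
        )
        if compute_morphometry:
            v.features = compute_features(v.local_mask())
        vessels.append(v)
    # skimage labels in row-major order of first encounter already;
    # re-sort defensively by first pixel to pin the contract
    vessels.sort(key=lambda v: (int(v.rows.min()), int(v.cols[np.argmin(v.rows)])))
    for i, v in enumerate(vessels):
        v.vessel_id = i
    return vessels


def assign_marker_flags(
    vessel: VesselObject,
    marker_masks: dict[str, BinaryMask | np.ndarray],
    config: PhenotypingConfig | None = None,
) -> dict[str, bool]:
    """Strict >5%-area marker positivity for one vessel."""
    config = config or PhenotypingConfig()
    flags: dict[str, bool] = {}
    for name in MARKERS:
        m = marker_masks[name]
        data = m.data if isinstance(m, BinaryMask) else np.asarray(m, bool)
        overlap = int(np.count_nonzero(data[vessel.rows, vessel.cols]))
        flags[name] = (overlap / vessel.area_px) > config.marker_area_fraction_threshold
    vessel.marker_flags = flags
    return flags


def vessel_counts(vessels: list[VesselObject]) -> dict[str, int]:
    counts = {"overall": len(vessels)}
    for cls in CLASS_DENSITY_VARS:
        counts[cls] = sum(1 for v in vessels if v.class_label == cls)
    for m in MARKERS:
        counts[m] = sum(1 for v in vessels if v.marker_flags.get(m, False))
    return counts


def vessel_densities(core: CoreRecord) -> dict[str, float]:
    """Per-core densities (/mm^2 of core area) for the nine variables
    plus the irregular morphology class."""
    if not core.qc_passed:
        raise ValueError(f"core {core.core_id} failed QC; densities undefined")
    if core.core_area_mm2 <= 0:
        raise ValueError(f"core {core.core_id} has zero area; densities undefined")
    counts = vessel_counts(core.vessels)
    return {k: c / core.core_area_mm2 for k, c in counts.items()}


def vessels_to_table(vessels: list[VesselObject]) -> pd.DataFrame:
    """Per-vessel table: ids, centroid, area, marker flags, features."""
    rows = []
    for v in vessels:
        row: dict = {
            "vessel_id": v.vessel_id,
            "core_id": v.core_id,
            "centroid_row_um": v.centroid_um[0],
            "centroid_col_um": v.centroid_um[1],
            "area_px": v.area_px,
            "class_label": v.class_label,
        }
        for m in MARKERS:
            row[f"{m}_pos"] = v.marker_flags.get(m, False)
        row.update(v.features)
        rows.append(row)
    cols = (
        ["vessel_id", "core_id", "centroid_row_um", "centroid_col_um", "area_px", "class_label"]
        + [f"{m}_pos" for m in MARKERS]
        + list(FEATURE_NAMES)
    )
    return pd.DataFrame(rows, columns=cols)
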