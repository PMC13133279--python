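"""Standardized channel preprocessing for multiplex IF core images.

Every marker channel goes through the same chain: a 9x9 averaging filter
to suppress pixel noise, Otsu binarization to separate signal from
background, and morphological refinement (closing then opening with a
circular structuring element) to fill narrow lumens/gaps and remove
specks.  Core-level QC rejects cores with too little tissue, saturation
artifacts, or manual exclusion-list membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

#: Fixed channel order, matching the multi-page TIFF page order.
CHANNELS = ("DAPI", "ACKR1", "CD34", "CD36", "KDR", "LAMB1", "MADCAM1", "KRT")

#: Auxiliary endothelial markers scored per CD34+ vessel.
MARKERS = ("ACKR1", "CD36", "KDR", "LAMB1", "MADCAM1")


@dataclass
class ChannelStack:
    """One core's named channel images plus pixel-size metadata."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.5  # um per pixel side
    core_id: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"missing required channels: {missing}")
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size**2


@dataclass
class BinaryMask:
    """Boolean grid plus a record of the processing chain that produced it."""

    data: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)


@dataclass
class QCResult:
    core_id: str
    reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return len(self.reasons) == 0


@dataclass
class QCRules:
    """Thresholds for automatic core QC.

    min_tissue_fraction: minimum fraction of pixels called foreground in
        the union of all binarized channels.
    max_saturated_fraction: maximum fraction of pixels at the dtype
        ceiling in any channel (acquisition artifact proxy).
    """

    min_tissue_fraction: float = 0.05
    max_saturated_fraction: float = 0.2
    saturation_value: float = 65535.0
    exclusion_list: frozenset[str] = field(default_factory=frozenset)


def smooth_channel(image: np.ndarray, size: int = 9) -> np.ndarray:
    """Mean filter with a size x size window, reflected at borders.

    Each output pixel is the arithmetic mean of the window centered on
    it; dimensions are unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if min(image.shape) < size:
        raise ValueError(
            f"image {image.shape} smaller than the {size}x{size} filter window"
        )
    return ndi.uniform_filter(image, size=size, mode="reflect")


def otsu_threshold(image: np.ndarray, max_levels: int = 4096) -> float:
    """Otsu threshold maximizing between-class variance.

    The histogram is taken over the exact observed intensity levels when
    there are at most ``max_levels`` distinct values (so the result is
    exact on discrete images); denser float images are binned to
    ``max_levels`` equal-width bins first.  The returned threshold is an
    observed level; foreground is strictly above it.
    """
    values = np.asarray(image).ravel()
    levels, counts = np.unique(values, return_counts=True)
    if levels.size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    if levels.size > max_levels:
        counts, edges = np.histogram(values, bins=max_levels)
        levels = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        levels, counts = levels[keep], counts[keep]

    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * levels)
    mean_all = cum_m[-1] / total
    # candidate thresholds: split after each level except the last
    w0 = cum_w[:-1] / total
    m0 = cum_m[:-1] / cum_w[:-1]
    w1 = 1.0 - w0
    m1 = (cum_m[-1] - cum_m[:-1]) / (cum_w[-1] - cum_w[:-1])
    between = w0 * (m0 - mean_all) ** 2 + w1 * (m1 - mean_all) ** 2
    return float(levels[int(np.argmax(between))])


def binarize_otsu(image: np.ndarray, max_levels: int = 4096) -> BinaryMask:
    """Binarize an intensity image at the Otsu threshold (strict >).

    A constant image yields an all-background mask with a warning.
    """
    image = np.asarray(image)
    try:
        t = otsu_threshold(image, max_levels=max_levels)
    except ValueError:
        warnings.warn(
            "constant image: Otsu threshold undefined, returning empty mask",
            stacklevel=2,
        )
        return BinaryMask(np.zeros(image.shape, bool), ("otsu[constant]",))
    return BinaryMask(image > t, (f"otsu[t={t:.6g}]",))


def disk_footprint(radius: float) -> np.ndarray:
    """Discrete Euclidean disk: pixels within ``radius`` of the center."""
    r = int(np.floor(radius))
    y, x = np.mgrid[-r: r + 1, -r: r + 1]
    return (x**2 + y**2) <= radius**2


def _disk_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation by a Euclidean disk (distance <= radius from center)."""
    if not mask.any():
        return mask.copy()
    if radius <= 8:
        return ndi.binary_dilation(mask, structure=disk_footprint(radius))
    # large disks: the distance transform is much faster than direct
    # correlation and realizes the exact same Euclidean footprint
    return ndi.distance_transform_edt(~mask) <= radius


def _disk_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erosion by a Euclidean disk; out-of-frame treated as foreground."""
    if mask.all():
        return mask.copy()
    if radius <= 8:
        return ndi.binary_erosion(
            mask, structure=disk_footprint(radius), border_value=1
        )
    return ndi.distance_transform_edt(mask) > radius


def disk_closing(mask: np.ndarray, radius: float) -> np.ndarray:
    return _disk_erode(_disk_dilate(mask, radius), radius)


def disk_opening(mask: np.ndarray, radius: float) -> np.ndarray:
    return _disk_dilate(_disk_erode(mask, radius), radius)


def morph_refine(mask: BinaryMask | np.ndarray, radius: float = 2) -> BinaryMask:
    """Closing then opening with a discrete Euclidean disk.

    Fills gaps and lumens narrower than the disk, then removes specks
    smaller than it.  The disk contains every pixel whose center lies
    within ``radius`` of the element center; pixels beyond the image
    border are treated as background for dilation and foreground for
    erosion, so tissue touching the frame edge is not eaten away.
    """
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    if isinstance(mask, BinaryMask):
        data, prov = mask.data, mask.provenance
    else:
        data, prov = np.asarray(mask, bool), ()
    refined = disk_opening(disk_closing(data, radius), radius)
    return BinaryMask(refined, prov + (f"close-open[r={radius}]",))


def preprocess_channel(
    image: np.ndarray, *, filter_size: int = 9, se_radius: float = 2
) -> BinaryMask:
    """The full standard chain: smooth -> Otsu -> close/open refine."""
    smoothed = smooth_channel(image, size=filter_size)
    mask = binarize_otsu(smoothed)
    refined = morph_refine(mask, radius=se_radius)
    return BinaryMask(refined.data, (f"mean[{filter_size}x{filter_size}]",) + refined.provenance)


def preprocess_stack(
    stack: ChannelStack, *, filter_size: int = 9, se_radius: float = 2
) -> dict[str, BinaryMask]:
    """Apply the standard chain independently to every channel."""
    return {
        name: preprocess_channel(img, filter_size=filter_size, se_radius=se_radius)
        for name, img in stack.channels.items()
    }


def qc_core(
    stack: ChannelStack,
    rules: QCRules | None = None,
    exclusion_list: frozenset[str] | set[str] | None = None,
) -> QCResult:
    """Automatic core QC plus the manual-review exclusion list.

    Fails when tissue coverage is too low, any channel has too many
    saturated pixels, or the core id is on the exclusion list.
    """
    rules = rules or QCRules()
    excluded = set(rules.exclusion_list)
    if exclusion_list:
        excluded |= set(exclusion_list)
    reasons: list[str] = []
    if stack.core_id in excluded:
        reasons.append("on manual exclusion list")

    union = np.zeros(stack.shape, bool)
    for img in stack.channels.values():
        img = np.asarray(img)
        if img.max() > img.min():
            union |= img > otsu_threshold(img)
    tissue_fraction = union.mean()
    if tissue_fraction < rules.min_tissue_fraction:
        reasons.append(
            f"low tissue area (fraction {tissue_fraction:.3f} < "
            f"{rules.min_tissue_fraction})"
        )
    for name, img in stack.channels.items():
        sat = float(np.mean(np.asarray(img) >= rules.saturation_value))
        if sat > rules.max_saturated_fraction:
            reasons.append(f"saturation in {name} (fraction {sat:.3f})")
    return QCResult(stack.core_id, tuple(reasons))


def batch_intensity_report(
    stacks: list[ChannelStack], *, fold_change: float = 2.0
) -> pd.DataFrame:
    """Per-batch per-channel median intensities with deviation flags.

    A staining-consistency check across TMA sections: batches whose
    median intensity deviates from the grand median by more than
    ``fold_change`` in either direction are flagged.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    rows = []
    for s in stacks:
        for name, img in s.channels.items():
            rows.append(
                {"batch_id": s.batch_id, "channel": name, "median": float(np.median(img))}
            )
    per_core = pd.DataFrame(rows)
    report = (
        per_core.groupby(["batch_id", "channel"])["median"]
        .agg(median="median", dispersion="std")
        .reset_index()
    )
    # grand median over cores (not batch summaries), so one deviant
    # batch cannot drag the reference toward itself
    grand = per_core.groupby("channel")["median"].median().rename("grand_median")
    report = report.merge(grand, on="channel")
    ratio = report["median"] / report["grand_median"]
    report["flagged"] = (ratio > fold_change) | (ratio < 1.0 / fold_change)
    return report
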