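"""Ground-truthed synthetic multiplex-IF TMA core images.

One simulated core is an 8-channel 16-bit stack (DAPI, ACKR1, CD34,
CD36, KDR, LAMB1, MADCAM1, KRT) at 0.5 um/px.  Vessels of the four
morphological archetypes are placed without overlap in the stromal
(non-KRT) compartment at a planted overall density; each auxiliary
marker is painted on a vessel per an independent Bernoulli draw of the
planted positivity rate, covering well over 5% of the vessel area when
positive and exactly 0% when negative.  Signal sits ~10x above the
uniform background so Otsu binarization has a clear valley; optional
Gaussian noise exercises the smoothing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from vesselphen.preprocess import CHANNELS, MARKERS, ChannelStack, morph_refine
from vesselphen.morphometry import features_table
from vesselphen.simulate.shapes import CLASSES, ShapeParams, generate_vessel_shape

#: Default class mixture over (micro, collapsed, patent, irregular).
#: The published rounded proportions (18/49/14/18%) sum to 99%, so they
#: are renormalized proportionally to a proper mixture.
DEFAULT_CLASS_MIXTURE = {
    "collapsed": 18 / 99,
    "micro": 49 / 99,
    "patent": 14 / 99,
    "irregular": 18 / 99,
}

#: Default per-marker vessel-positivity rates.
DEFAULT_MARKER_RATES = {
    "ACKR1": 0.042,
    "CD36": 0.067,
    "KDR": 0.14,
    "LAMB1": 0.068,
    "MADCAM1": 0.014,
}


@dataclass
class ImageSimConfig:
    image_size: int = 1600  # pixels per side
    pixel_size: float = 0.5  # um per pixel side
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    marker_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_RATES)
    )
    target_density: float = 197.0  # overall vessels per mm^2 of core
    epithelial_fraction: float = 0.4
    noise_sd: float = 0.0
    background_level: float = 500.0
    signal_level: float = 5000.0
    nuclei_per_mm2: float = 5000.0
    nucleus_radius_px: float = 2.5
    seed: int | None = None
    shape_params: ShapeParams = field(default_factory=ShapeParams)

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.pixel_size <= 0:
            raise ValueError("image_size and pixel_size must be positive")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if set(self.class_mixture) != set(CLASSES):
            raise ValueError(f"class_mixture must cover exactly {CLASSES}")
        for m, r in self.marker_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"marker rate for {m} outside [0,1]")
        if set(self.marker_rates) != set(MARKERS):
            raise ValueError(f"marker_rates must cover exactly {MARKERS}")
        if self.target_density < 0:
            raise ValueError("target_density must be non-negative")
        if not 0.0 <= self.epithelial_fraction < 1.0:
            raise ValueError("epithelial_fraction must be in [0,1)")
        self.shape_params.validate()

    @property
    def frame_area_mm2(self) -> float:
        return (self.image_size * self.pixel_size) ** 2 / 1e6


@dataclass
class TrueVessel:
    vessel_id: int  # 1-based; matches the ground-truth label image
    class_label: str
    marker_flags: dict[str, bool]
    bbox: tuple[int, int, int, int]  # r0, c0, r1, c1 (exclusive)
    mask: np.ndarray  # local boolean mask inside bbox


@dataclass
class GroundTruth:
    """Everything the generator planted for one core."""

    vessels: list[TrueVessel]
    label_image: np.ndarray  # int32 vessel ids, 0 = background
    epithelial_mask: np.ndarray
    config: ImageSimConfig

    def __post_init__(self) -> None:
        for v in self.vessels:
            if v.class_label not in CLASSES:
                raise ValueError(f"invalid true class {v.class_label!r}")

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for v in self.vessels:
            counts[v.class_label] += 1
        return counts

    def marker_counts(self) -> dict[str, int]:
        return {
            m: sum(1 for v in self.vessels if v.marker_flags[m]) for m in MARKERS
        }


def _epithelial_field(
    size: int, fraction: float, rng: np.random.Generator, sigma: float = 80.0
) -> np.ndarray:
    """Smooth random field thresholded at a quantile -> KRT+ blobs."""
    if fraction <= 0:
        return np.zeros((size, size), bool)
    # the field is smooth at scale sigma >> 4 px, so generate it on a
    # 4x-coarser grid and upsample -- same statistics, ~16x cheaper
    step = 4
    coarse = max(size // step + 1, 2)
    field_ = ndi.gaussian_filter(
        rng.standard_normal((coarse, coarse)), sigma / step
    )
    field_ = ndi.zoom(field_, step, order=1)[:size, :size]
    return field_ > np.quantile(field_, 1.0 - fraction)


def _nuclei_mask(
    size: int,
    pixel_size: float,
    per_mm2: float,
    radius_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    area_mm2 = (size * pixel_size) ** 2 / 1e6
    n = rng.poisson(per_mm2 * area_mm2)
    centers = np.zeros((size, size), bool)
    if n > 0:
        rr = rng.integers(0, size, size=n)
        cc = rng.integers(0, size, size=n)
        centers[rr, cc] = True
    if not centers.any():
        return centers
    return ndi.distance_transform_edt(~centers) <= radius_px


def _marker_patch(
    local_mask: np.ndarray, rng: np.random.Generator, min_px: int = 80
) -> np.ndarray:
    """A compact painted subregion covering >=50% of the vessel.

    The patch grows as a Euclidean ball (clipped to the vessel) around
    an interior seed pixel, so it always contains a disk thick enough to
    survive the refinement opening.  Vessels too small to host a
    ``min_px`` patch are painted entirely.
    """
    area = int(local_mask.sum())
    target = max(int(np.ceil(rng.uniform(0.5, 1.0) * area)), min_px)
    if target >= area:
        return local_mask.copy()
    interior = ndi.distance_transform_edt(local_mask) >= 2.0
    pool = interior if interior.any() else local_mask
    rows, cols = np.nonzero(pool)
    k = rng.integers(len(rows))
    seed_r, seed_c = rows[k], cols[k]
    vr, vc = np.nonzero(local_mask)
    dist = np.hypot(vr - seed_r, vc - seed_c)
    order = np.argsort(dist, kind="stable")[:target]
    patch = np.zeros_like(local_mask)
    patch[vr[order], vc[order]] = True
    return patch


def generate_core_image(
    config: ImageSimConfig | None = None,
    rng: np.random.Generator | None = None,
    core_id: str = "core-0",
    batch_id: str = "batch-0",
) -> tuple[ChannelStack, GroundTruth]:
    """Simulate one core: 8-channel stack plus full ground truth.

    The vessel count is Poisson(target_density x frame area in mm^2);
    placement rejection-samples positions in the stromal compartment
    with a 3-px guard band so no two vessels touch or merge under the
    default refinement.  Raises if the requested density cannot fit.
    """
    config = config or ImageSimConfig()
    rng = rng or np.random.default_rng(config.seed)
    size = config.image_size

    epithelial = _epithelial_field(size, config.epithelial_fraction, rng)
    paint = {name: np.zeros((size, size), bool) for name in CHANNELS}
    paint["KRT"] = epithelial
    paint["DAPI"] = _nuclei_mask(
        size, config.pixel_size, config.nuclei_per_mm2, config.nucleus_radius_px, rng
    )

    n_vessels = rng.poisson(config.target_density * config.frame_area_mm2)
    class_names = list(config.class_mixture)
    class_probs = np.array([config.class_mixture[c] for c in class_names])
    guard = 3.0

    occupancy = np.zeros((size, size), bool)
    label_image = np.zeros((size, size), np.int32)
    vessels: list[TrueVessel] = []
    for vid in range(1, n_vessels + 1):
        cls = class_names[rng.choice(len(class_names), p=class_probs)]
        shape = generate_vessel_shape(cls, rng, config.shape_params)
        pad = int(np.ceil(guard)) + 1
        shape_dil = (
            ndi.distance_transform_edt(~np.pad(shape, pad)) <= guard
        )
        h, w = shape_dil.shape
        if h >= size or w >= size:
            raise RuntimeError("vessel archetype larger than the frame")
        placed = False
        for _ in range(500):
            r0 = rng.integers(0, size - h)
            c0 = rng.integers(0, size - w)
            win = (slice(r0, r0 + h), slice(c0, c0 + w))
            if (occupancy[win] & shape_dil).any():
                continue
            core_win = (slice(r0 + pad, r0 + pad + shape.shape[0]),
                        slice(c0 + pad, c0 + pad + shape.shape[1]))
            if (epithelial[core_win] & shape).any():
                continue
            occupancy[win] |= shape_dil
            paint["CD34"][core_win] |= shape
            label_image[core_win][shape] = vid
            flags = {
                m: bool(rng.random() < config.marker_rates[m]) for m in MARKERS
            }
            for m in MARKERS:
                if flags[m]:
                    patch = _marker_patch(shape, rng)
                    paint[m][core_win] |= patch
            vessels.append(
                TrueVessel(
                    vessel_id=vid,
                    class_label=cls,
                    marker_flags=flags,
                    bbox=(core_win[0].start, core_win[1].start,
                          core_win[0].stop, core_win[1].stop),
                    mask=shape,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place vessel {vid}/{n_vessels}: target density "
                f"{config.target_density}/mm^2 does not fit in the frame"
            )

    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        img = np.full((size, size), config.background_level, dtype=float)
        img[paint[name]] += config.signal_level
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, img.shape)
        channels[name] = np.clip(img, 0, 65535).astype(np.uint16)

    stack = ChannelStack(
        channels=channels,
        pixel_size=config.pixel_size,
        core_id=core_id,
        batch_id=batch_id,
    )
    truth = GroundTruth(
        vessels=vessels,
        label_image=label_image,
        epithelial_mask=epithelial,
        config=config,
    )
    return stack, truth


def simulate_labeled_vessels(
    n_per_class: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    shape_params: ShapeParams | None = None,
    refine_radius: float = 2.0,
    label_noise: float = 0.0,
):
    """A labeled vessel set: refined archetype masks with features.

    Masks go through the same closing/opening refinement as the imaging
    pipeline (so patent lumens are filled) before feature computation.
    ``label_noise`` relabels that fraction of vessels with a uniformly
    random other class, emulating rater disagreement.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(seed)
    rows = []
    for cls in CLASSES:
        for _ in range(n_per_class):
            shape = generate_vessel_shape(cls, rng, shape_params)
            pad = int(np.ceil(refine_radius)) + 1
            refined = morph_refine(np.pad(shape, pad), radius=refine_radius).data
            label = cls
            if label_noise > 0 and rng.random() < label_noise:
                label = rng.choice([c for c in CLASSES if c != cls])
            rows.append((refined, label))
    table = features_table([m for m, _ in rows])
    table["class_label"] = [lab for _, lab in rows]
    return table
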