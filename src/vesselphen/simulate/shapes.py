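"""Binary masks for the four vessel morphological archetypes.

* micro -- small filled near-circular blob (indistinct lumen);
* collapsed -- thin elongated ribbon (lumen obstructed by compression);
* patent -- thick-walled disk with a small central lumen (the lumen is
  narrower than the refinement closing disk, so downstream processing
  fills it and the vessel reads as a large round object);
* irregular -- union of several overlapping elongated lobes (complex,
  bent and/or branched vessels).

Sizes are in pixels at the default 0.5 um/px scale.  The ranges are
chosen for geometric class separability, not measured vessel-size
distributions, and every archetype is wide enough (>= 5 px) to survive
opening with the default radius-2 disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fixed class order (also the classifier's tie-break order).
CLASSES = ("micro", "collapsed", "patent", "irregular")


@dataclass
class ShapeParams:
    """Per-class size ranges (px). All ranges are (low, high) inclusive."""

    micro_radius: tuple[float, float] = (3.0, 8.0)
    micro_axis_ratio: tuple[float, float] = (1.0, 1.25)
    collapsed_width: tuple[float, float] = (5.0, 8.0)
    collapsed_length: tuple[float, float] = (40.0, 90.0)
    patent_outer_radius: tuple[float, float] = (9.5, 16.0)
    patent_lumen_radius: float = 1.0  # below the closing radius -> filled later
    irregular_n_lobes: tuple[int, int] = (2, 4)
    irregular_lobe_width: tuple[float, float] = (5.0, 8.0)
    irregular_lobe_length: tuple[float, float] = (22.0, 50.0)

    def validate(self) -> None:
        for name in (
            "micro_radius",
            "micro_axis_ratio",
            "collapsed_width",
            "collapsed_length",
            "patent_outer_radius",
            "irregular_lobe_width",
            "irregular_lobe_length",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid size range {name}={lo, hi}")
        if self.patent_lumen_radius < 0:
            raise ValueError("lumen radius must be non-negative")


def _grid(half: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.arange(-half, half + 1, dtype=float)
    return np.meshgrid(c, c, indexing="ij")


def _trim(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return mask[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]


def _ellipse(a: float, b: float, theta: float) -> np.ndarray:
    half = int(np.ceil(max(a, b))) + 1
    y, x = _grid(half)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    return _trim((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)


def _stadium_dist(
    y: np.ndarray, x: np.ndarray, cy: float, cx: float, h: float, theta: float
) -> np.ndarray:
    """Distance from grid points to a segment of half-length h at angle theta."""
    ux, uy = np.cos(theta), np.sin(theta)
    px, py = x - cx, y - cy
    t = np.clip(px * ux + py * uy, -h, h)
    return np.hypot(px - t * ux, py - t * uy)


def _stadium(length: float, width: float, theta: float) -> np.ndarray:
    half = int(np.ceil(length / 2 + width)) + 1
    y, x = _grid(half)
    h = max(length / 2 - width / 2, 0.0)
    return _trim(_stadium_dist(y, x, 0.0, 0.0, h, theta) <= width / 2)


def generate_vessel_shape(
    class_label: str,
    rng: np.random.Generator,
    size_params: ShapeParams | None = None,
) -> np.ndarray:
    """Draw one connected binary mask for the given morphology class."""
    params = size_params or ShapeParams()
    params.validate()
    if class_label == "micro":
        # accept-reject so every draw honors the archetype contract
        # (Solidity > 0.9, Eccentricity < 0.7) despite rasterization
        # artifacts on the smallest blobs
        from vesselphen.morphometry import compute_features

        for _ in range(200):
            r = rng.uniform(*params.micro_radius)
            ratio = rng.uniform(*params.micro_axis_ratio)
            a = r * np.sqrt(ratio)
            b = r / np.sqrt(ratio)
            mask = _ellipse(a, b, rng.uniform(0, np.pi))
            f = compute_features(mask)
            if f["Solidity"] > 0.905 and f["Eccentricity"] < 0.69:
                return mask
        raise RuntimeError("could not draw a compliant micro-vessel shape")
    if class_label == "collapsed":
        w = rng.uniform(*params.collapsed_width)
        length = rng.uniform(*params.collapsed_length)
        return _stadium(length, w, rng.uniform(0, np.pi))
    if class_label == "patent":
        r_out = rng.uniform(*params.patent_outer_radius)
        # near-circular outer contour with a tiny central lumen
        ratio = rng.uniform(1.0, 1.05)
        theta = rng.uniform(0, np.pi)
        half = int(np.ceil(r_out * np.sqrt(ratio))) + 1
        y, x = _grid(half)
        xr = x * np.cos(theta) + y * np.sin(theta)
        yr = -x * np.sin(theta) + y * np.cos(theta)
        a, b = r_out * np.sqrt(ratio), r_out / np.sqrt(ratio)
        outer = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        lumen = x**2 + y**2 <= params.patent_lumen_radius**2
        return _trim(outer & ~lumen)
    if class_label == "irregular":
        n = rng.integers(params.irregular_n_lobes[0], params.irregular_n_lobes[1] + 1)
        lengths = rng.uniform(*params.irregular_lobe_length, size=n)
        widths = rng.uniform(*params.irregular_lobe_width, size=n)
        # lobes at clearly distinct angles, so a 2-lobe vessel reads as
        # bent/branched rather than as a single collapsed ribbon
        base = rng.uniform(0, np.pi)
        thetas = base + np.cumsum(rng.uniform(0.6, np.pi - 0.6, size=n))
        half = int(np.ceil(lengths.max() / 2 + widths.max())) + 4
        y, x = _grid(half)
        mask = np.zeros_like(y, dtype=bool)
        for length, w, theta in zip(lengths, widths, thetas):
            # small center offsets keep the lobes overlapping (connected)
            cy, cx = rng.uniform(-2.0, 2.0, size=2)
            h = max(length / 2 - w / 2, 0.0)
            mask |= _stadium_dist(y, x, cy, cx, h, theta) <= w / 2
        return _trim(mask)
    raise ValueError(
        f"unknown vessel class {class_label!r}; expected one of {CLASSES}"
    )
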