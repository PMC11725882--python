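"""Synthetic binary shape images with ground-truth label masks.

Emulates the two- and three-shape benchmark images used to evaluate the
segmentation pipeline: 32x32 rasters containing a triangle and a square (plus
a 180-degree-rotated triangle in the three-object case) at uniformly random
positions.  Variants with partial overlap and with a reduced intensity on the
second object support the overlap experiments.

Conventions: object 1 is the triangle at intensity 1; object 2 the square at
intensity ``1 - intensity_delta``; when overlap is allowed, overlapping pixels
take object 1's id and intensity and the overlap region is recorded in
``meta['overlap']``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ShapeImage",
    "PlacementError",
    "make_shapes",
    "make_overlapping_pair",
    "load_image",
    "save_shape_image",
    "load_shape_image",
    "SHAPE_SIZE",
]

#: bounding-box side of every generated shape, in pixels
SHAPE_SIZE = 8

#: rejection-sampling budget for disjoint placement
_MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """No disjoint placement found within the rejection-sampling budget."""


@dataclass
class ShapeImage:
    """A grayscale raster with (optional) integer ground-truth labels.

    ``labels`` uses 0 for background and 1..M for objects; ``meta`` carries
    shape kinds, positions, intensities, the generator seed and, for
    overlapping images, the list of overlap pixel coordinates.
    """

    pixels: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pixels.shape != self.labels.shape:
            raise ValueError("pixels and labels must have identical shape")
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("image must be a square 2-D grid")

    @property
    def n_side(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def overlap_mask(self) -> np.ndarray:
        """Boolean grid of pixels covered by more than one object."""
        mask = np.zeros_like(self.labels, dtype=bool)
        for r, c in self.meta.get("overlap", []):
            mask[r, c] = True
        return mask


def _triangle_mask(flipped: bool = False) -> np.ndarray:
    """Isosceles triangle filling an 8x8 box: row i holds i+1 centred pixels."""
    mask = np.zeros((SHAPE_SIZE, SHAPE_SIZE), dtype=bool)
    for i in range(SHAPE_SIZE):
        width = i + 1
        start = (SHAPE_SIZE - width) // 2
        mask[i, start : start + width] = True
    return mask[::-1].copy() if flipped else mask


def _square_mask() -> np.ndarray:
    return np.ones((SHAPE_SIZE, SHAPE_SIZE), dtype=bool)


#: drawing order; the triangle is object 1 (keeps full intensity under
#: intensity_delta and wins overlapping pixels)
_SHAPE_KINDS = ("triangle", "square", "triangle_flipped")

_SHAPE_MASKS = {
    "triangle": _triangle_mask(),
    "square": _square_mask(),
    "triangle_flipped": _triangle_mask(flipped=True),
}


def _place(rng: np.random.Generator, size: int) -> tuple[int, int]:
    top = int(rng.integers(0, size - SHAPE_SIZE + 1))
    left = int(rng.integers(0, size - SHAPE_SIZE + 1))
    return top, left

def _stamp(size: int, kind: str, top: int, left: int) -> np.ndarray:
    grid = np.zeros((size, size), dtype=bool)
    grid[top : top + SHAPE_SIZE, left : left + SHAPE_SIZE] = _SHAPE_MASKS[kind]
    return grid


def make_shapes(
    n_objects: int,
    size: int = 32,
    allow_overlap: bool = False,
    intensity_delta: float = 0.0,
    seed: int = 0,
) -> ShapeImage:
    """Generate a shape image with ground-truth labels.

    Two objects give a triangle and a square; three add a second triangle
    rotated 180 degrees.  Positions are uniform over all placements that keep
    each shape's bounding box inside the image.  Without ``allow_overlap``,
    disjoint placements are rejection-sampled (bounded attempts).  With
    ``intensity_delta > 0`` the square's intensity drops to
    ``1 - intensity_delta`` while the triangle keeps intensity 1; overlap
    pixels take the triangle's id and intensity.
    """
    if n_objects not in (2, 3):
        raise ValueError(f"n_objects must be 2 or 3, got {n_objects}")
    if not 0.0 <= intensity_delta < 1.0:
        raise ValueError("intensity_delta must lie in [0, 1)")
    if size < 2 * SHAPE_SIZE and not allow_overlap:
        raise ValueError(
            f"size {size} too small to place {n_objects} disjoint "
            f"{SHAPE_SIZE}x{SHAPE_SIZE} shapes"
        )
    if size < SHAPE_SIZE:
        raise ValueError(f"size must be >= {SHAPE_SIZE}")

    rng = np.random.default_rng(seed)
    kinds = _SHAPE_KINDS[:n_objects]
    intensities = [1.0] * n_objects
    if intensity_delta > 0:
        intensities[1] = 1.0 - intensity_delta

    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        positions = [_place(rng, size) for _ in kinds]
        masks = [_stamp(size, k, *pos) for k, pos in zip(kinds, positions)]
        coverage = np.sum(masks, axis=0)
        if allow_overlap or coverage.max() <= 1:
            break
    else:
        raise PlacementError(
            f"no disjoint placement of {n_objects} shapes on a {size}x{size} "
            f"grid within {_MAX_PLACEMENT_ATTEMPTS} attempts"
        )

    pixels = np.zeros((size, size))
    labels = np.zeros((size, size), dtype=int)
    # paint back-to-front so earlier objects win contested pixels
    for obj_id in range(n_objects, 0, -1):
        mask = masks[obj_id - 1]
        pixels[mask] = intensities[obj_id - 1]
        labels[mask] = obj_id
    overlap = np.argwhere(coverage > 1)

    meta = {
        "kinds": list(kinds),
        "positions": [list(p) for p in positions],
        "intensities": intensities,
        "seed": int(seed),
        "allow_overlap": bool(allow_overlap),
        "intensity_delta": float(intensity_delta),
        "overlap": [list(map(int, rc)) for rc in overlap],
    }
    return ShapeImage(pixels=pixels, labels=labels, meta=meta)


def make_overlapping_pair(
    seed: int,
    size: int = 32,
    intensity_delta: float = 0.0,
    min_overlap: int = 4,
    max_overlap_frac: float = 0.5,
) -> ShapeImage:
    """Triangle-square pair guaranteed to partially (never mostly) overlap.

    Deterministically scans sub-seeds derived from ``seed`` until the two
    shapes share at least ``min_overlap`` pixels but no more than
    ``max_overlap_frac`` of the smaller object's area, so each object keeps a
    clear majority of its own pixels (complete or near-complete overlap is not
    a segmentable case).
    """
    areas = [int(_SHAPE_MASKS[k].sum()) for k in _SHAPE_KINDS[:2]]
    max_overlap = int(max_overlap_frac * min(areas))
    for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
        img = make_shapes(
            2,
            size=size,
            allow_overlap=True,
            intensity_delta=intensity_delta,
            seed=seed * _MAX_PLACEMENT_ATTEMPTS + attempt,
        )
        n_overlap = len(img.meta["overlap"])
        if min_overlap <= n_overlap <= max_overlap:
            return img
    raise PlacementError("no partially overlapping placement found")


def load_image(path, zscore: bool = False) -> ShapeImage:
    """Load a grayscale raster (PNG/PGM/...) or plain numeric grid as input.

    Returned labels are all zero (no ground truth).  With ``zscore`` the
    pixels are standardised to zero mean and unit variance before use as an
    input drive; a constant image maps to an all-zero drive with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".txt", ".csv", ".dat"}:
        delimiter = "," if path.suffix.lower() == ".csv" else None
        pixels = np.loadtxt(path, delimiter=delimiter, dtype=float)
    else:
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("F"), dtype=float)
        if pixels.max() > 1.0:
            pixels = pixels / 255.0
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected a square grayscale image, got {pixels.shape}")
    if zscore:
        std = pixels.std()
        # ptp, not std: the std of a constant array can round to ~1e-17
        if np.ptp(pixels) == 0:
            warnings.warn(
                "zero-variance image: z-scored drive is identically zero",
                stacklevel=2,
            )
            pixels = np.zeros_like(pixels)
        else:
            pixels = (pixels - pixels.mean()) / std
    return ShapeImage(
        pixels=pixels,
        labels=np.zeros(pixels.shape, dtype=int),
        meta={"source": str(path), "zscore": bool(zscore)},
    )


def save_shape_image(image: ShapeImage, basepath) -> dict:
    """Write pixels (PNG), labels (CSV) and metadata (JSON) beside ``basepath``."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "pixels": base.with_suffix(".png"),
        "labels": base.with_name(base.name + "_labels.csv"),
        "meta": base.with_name(base.name + "_meta.json"),
    }
    lo, hi = image.pixels.min(), image.pixels.max()
    scaled = (image.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(image.pixels)
    Image.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(
        paths["pixels"]
    )
    np.savetxt(paths["labels"], image.labels, fmt="%d", delimiter=",")
    meta = dict(image.meta)
    meta["pixel_range"] = [float(lo), float(hi)]
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def load_shape_image(basepath) -> ShapeImage:
    """Inverse of :func:`save_shape_image` (pixel values restored from meta)."""
    base = Path(basepath)
    meta = json.loads(base.with_name(base.name + "_meta.json").read_text())
    with Image.open(base.with_suffix(".png")) as im:
        scaled = np.asarray(im, dtype=float) / 255.0
    lo, hi = meta.pop("pixel_range", [0.0, 1.0])
    pixels = lo + scaled * (hi - lo)
    labels = np.loadtxt(
        base.with_name(base.name + "_labels.csv"), delimiter=",", dtype=int
    )
    return ShapeImage(pixels=pixels, labels=labels, meta=meta)
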