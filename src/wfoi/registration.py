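"""Landmark alignment, brain masking and uniform-illumination removal.

Cross-session and cross-animal comparison requires a common orientation.
Bregma and lambda (skull suture landmarks) are annotated once per session;
a similarity transform (rotation + translation, optional uniform scale)
then maps bregma onto a configured reference pixel with the bregma-lambda
axis vertical, lambda caudal (toward increasing row).

Coordinates are 0-based ``(row, col)``; after alignment row increases
caudally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label

from .errors import DegenerateLandmarksError, EmptyMaskError, InvalidArgumentError

__all__ = [
    "LandmarkAnnotation",
    "AlignmentTransform",
    "fit_alignment",
    "warp",
    "mask_from_polygon",
    "mask_from_threshold",
    "global_mean_subtract",
]


@dataclass(frozen=True)
class LandmarkAnnotation:
    """Manually annotated bregma and lambda positions, (row, col) pixels."""

    bregma_px: tuple[float, float]
    lambda_px: tuple[float, float]

    def __post_init__(self):
        b = tuple(float(v) for v in self.bregma_px)
        l = tuple(float(v) for v in self.lambda_px)
        if b == l:
            raise DegenerateLandmarksError("bregma and lambda coincide")
        object.__setattr__(self, "bregma_px", b)
        object.__setattr__(self, "lambda_px", l)


@dataclass(frozen=True)
class AlignmentTransform:
    """Similarity transform ``p' = scale * R(rotation) @ (p - pivot) + offset``.

    ``rotation`` is radians (positive = row axis toward column axis, i.e.
    counter-clockwise in image display convention), applied about
    ``pivot``; ``offset`` is the target position of the pivot.
    """

    rotation: float
    scale: float
    pivot: tuple[float, float]
    offset: tuple[float, float]

    def __post_init__(self):
        if not (self.scale > 0):
            raise InvalidArgumentError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        """Map (row, col) points forward through the transform."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - np.asarray(self.pivot)) @ self.matrix.T + np.asarray(self.offset)
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse_apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.matrix)
        out = (p - np.asarray(self.offset)) @ inv.T + np.asarray(self.pivot)
        return out[0] if np.asarray(points).ndim == 1 else out

    @property
    def is_identity(self) -> bool:
        return (self.rotation == 0.0 and self.scale == 1.0
                and tuple(self.pivot) == tuple(self.offset))


def fit_alignment(landmarks: LandmarkAnnotation,
                  bregma_ref: tuple[float, float],
                  axis_length_px: float | None = None) -> AlignmentTransform:
    """Fit the similarity transform that standardises orientation.

    The transform maps bregma exactly onto ``bregma_ref`` and rotates the
    bregma->lambda vector onto the +row direction (lambda caudal, below
    bregma).  If ``axis_length_px`` is given, a uniform scale makes the
    mapped bregma-lambda distance equal to it; otherwise scale = 1.
    """
    b = np.asarray(landmarks.bregma_px, dtype=float)
    l = np.asarray(landmarks.lambda_px, dtype=float)
    v = l - b
    norm = float(np.hypot(*v))
    # angle of v relative to the +row axis; rotating by -angle aligns it
    angle = float(np.arctan2(v[1], v[0]))
    scale = 1.0 if axis_length_px is None else float(axis_length_px) / norm
    return AlignmentTransform(rotation=-angle, scale=scale,
                              pivot=tuple(b), offset=tuple(bregma_ref))


def warp(stack, transform: AlignmentTransform, interpolation: str = "bilinear",
         fill_value: float = np.nan) -> np.ndarray:
    """Resample every frame of a ``(t, h, w)`` stack through the transform.

    Out-of-bounds pixels are filled with ``fill_value`` (NaN by default)
    so they can be excluded from masks.  An exact identity transform with
    nearest interpolation returns a bit-identical copy.
    """
    data = np.asarray(stack)
    single = data.ndim == 2
    if single:
        data = data[None]
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise InvalidArgumentError(f"unknown interpolation {interpolation!r}")
    if transform.is_identity:
        return data[0].copy() if single else data.copy()

    h, w = data.shape[1:]
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    src = transform.inverse_apply(np.column_stack([rr.ravel(), cc.ravel()]))
    coords = [src[:, 0].reshape(h, w), src[:, 1].reshape(h, w)]
    out = np.empty(data.shape, dtype=float)
    for i, frame in enumerate(data):
        out[i] = ndimage.map_coordinates(frame.astype(float), coords,
                                         order=order, mode="constant",
                                         cval=fill_value, prefilter=False)
    return out[0] if single else out


def mask_from_polygon(vertices, shape) -> np.ndarray:
    """Rasterise a polygon (list of (row, col) vertices) into a boolean mask.

    Uses the pixel-centre-inside rule; vertex orientation is irrelevant.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise InvalidArgumentError("polygon needs >= 3 (row, col) vertices")
    mask = polygon2mask(shape, verts)
    if not mask.any():
        raise EmptyMaskError("polygon rasterises to an empty mask")
    return mask


def mask_from_threshold(image, quantile: float) -> np.ndarray:
    """Threshold at an intensity quantile; keep the largest component."""
    if not (0.0 < quantile < 1.0):
        raise InvalidArgumentError("quantile must be in (0, 1)")
    img = np.asarray(image, dtype=float)
    level = np.quantile(img, quantile)
    above = img > level
    if not above.any():
        raise EmptyMaskError(f"no pixels above the {quantile} quantile")
    labels = cc_label(above)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def global_mean_subtract(stack, mask) -> np.ndarray:
    """Subtract each frame's in-mask spatial mean from all its pixels.

    Removes spatially uniform illumination fluctuations.  This is an
    explicit, logged preprocessing choice — not global signal regression
    in the functional-connectivity sense — and results should be reported
    with and without it when correlation structure is analysed.
    """
    data = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("brain mask is empty")
    if mask.shape != data.shape[-2:]:
        raise InvalidArgumentError(
            f"mask shape {mask.shape} != frame shape {data.shape[-2:]}")
    means = data[..., mask].mean(axis=-1)
    return data - means[..., None, None]
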