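"""Nuclear segmentation and per-cell measurement.

The built-in segmenter is deterministic and designed for nuclear-dye
images: Gaussian smoothing, Otsu threshold, 8-connected component
labeling, and an area filter.  An adapter hook exposes the same calling
contract for external learned segmenters (e.g. a Cellpose backend) so
they can be swapped in per position without touching the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage import filters, measure

from .errors import CapabilityError, LoopscopeError

__all__ = [
    "LabelMask",
    "CellObservation",
    "segment_nuclei_threshold",
    "measure_cells",
    "external_segmenter_adapter",
]


@dataclass
class LabelMask:
    """Integer-labeled segmentation image (0 = background, 1..n = cells)."""

    labels: np.ndarray
    frame_time: float = 0.0
    position_name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0:
            raise LoopscopeError("label masks must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))


@dataclass
class CellObservation:
    """Geometry and intensity summary for one segmented cell.

    centroid is (x, y) = (col, row), 0-based, pixel-center convention,
    intensity-unweighted.  ``mean_intensity`` maps channel name to the
    mean pixel value over the cell's mask.
    """

    label: int
    centroid: tuple[float, float]
    area: int
    mean_intensity: dict[str, float]


def segment_nuclei_threshold(
    image: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area: int = 9,
    max_area: int = 10_000,
) -> LabelMask:
    """Segment nuclei by smoothing, Otsu thresholding, and labeling.

    Components outside ``[min_area, max_area]`` pixels are removed and the
    survivors renumbered 1..n in raster order of their first pixel.  A
    constant (e.g. all-zero) image yields an empty mask rather than an
    error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise LoopscopeError("segmentation expects a single-channel 2-D image")
    smoothed = filters.gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32))
    thresh = filters.threshold_otsu(smoothed)
    binary = smoothed > thresh
    labeled = measure.label(binary, connectivity=2)
    if labeled.max() == 0:
        return LabelMask(labeled.astype(np.int32))
    areas = np.bincount(labeled.ravel())
    keep = np.zeros(areas.size, dtype=np.int32)
    next_label = 0
    # measure.label numbers components in raster order of first pixel, so
    # renumbering in ascending old-label order preserves raster order
    for lab in range(1, areas.size):
        if min_area <= areas[lab] <= max_area:
            next_label += 1
            keep[lab] = next_label
    return LabelMask(keep[labeled])


def measure_cells(
    frames: dict[str, np.ndarray] | np.ndarray,
    mask: LabelMask,
) -> list[CellObservation]:
    """Per-cell area, centroid, and mean intensity per channel.

    ``frames`` maps channel name to an image sharing the mask's shape (a
    bare array is treated as channel ``"intensity"``).  Results are
    sorted by label.
    """
    if not isinstance(frames, dict):
        frames = {"intensity": frames}
    for name, img in frames.items():
        if np.asarray(img).shape != mask.labels.shape:
            raise LoopscopeError(
                f"channel {name!r} shape {np.asarray(img).shape} != mask shape {mask.labels.shape}"
            )
    labels = mask.labels
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        return []
    props = measure.regionprops(labels)
    by_label = {p.label: p for p in props}
    means = {
        name: ndsum_mean(labels, np.asarray(img, dtype=float), present)
        for name, img in frames.items()
    }
    out = []
    for i, lab in enumerate(present):
        p = by_label[int(lab)]
        r, c = p.centroid
        out.append(
            CellObservation(
                label=int(lab),
                centroid=(float(c), float(r)),
                area=int(p.area),
                mean_intensity={name: float(m[i]) for name, m in means.items()},
            )
        )
    return out


def ndsum_mean(labels: np.ndarray, img: np.ndarray, present: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.mean(img, labels=labels, index=present)


def external_segmenter_adapter(spec: dict) -> Callable[..., LabelMask]:
    """Resolve a segmentation module spec to a callable.

    ``spec`` is a parameter table with at least ``module``; the built-in
    ``"threshold"`` segmenter is returned directly, while named external
    backends are imported lazily and raise :class:`CapabilityError` at
    resolution time (plan build) rather than mid-run if absent.
    Parameters beyond ``module`` are passed through to the backend.
    """
    name = spec.get("module", "threshold")
    params = {k: v for k, v in spec.items() if k != "module"}
    if name == "threshold":
        accepted = {"smooth_sigma", "min_area", "max_area"}
        base = {k: v for k, v in params.items() if k in accepted}

        def seg(image: np.ndarray, **overrides) -> LabelMask:
            return segment_nuclei_threshold(image, **{**base, **overrides})

        return seg
    if name == "cellpose_adapter":
        try:
            from cellpose import models  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "segmentation module 'cellpose_adapter' requires the optional "
                "'cellpose' package, which is not installed"
            ) from exc

        def seg(image: np.ndarray, **overrides) -> LabelMask:  # pragma: no cover
            model = models.CellposeModel(**params.get("model_kwargs", {}))
            masks = model.eval(np.asarray(image))[0]
            return LabelMask(np.asarray(masks, dtype=np.int32))

        return seg
    raise CapabilityError(f"unknown segmentation module {name!r}")
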