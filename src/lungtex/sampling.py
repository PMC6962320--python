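"""ROI extraction around annotated points, and attenuation normalization.

Three region-of-interest representations feed the network zoo:

``axial2d``
    a 48 x 48 axial (x, y) patch through the point — the in-plane size
    covers a whole secondary pulmonary lobule at typical CT spacing;
``ortho2p5d``
    three orthogonal 48 x 48 planes (axial, sagittal, coronal) sharing the
    point, stacked as three channels;
``slab3d``
    a 48 x 48 x 7 block (7 axial slices) centred on the point.

Patches are taken in voxel units (48 px), not resampled to a fixed
physical size. Points closer than half a patch to the border are handled
by reflect padding (subpleural points sit near the lung edge); a strict
mode raises instead.

Normalization subtracts the pooled mean and divides by the pooled
*population* standard deviation of the training + validation patches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .tissue import TissueClass
from .volume import AnnotatedPoint, CTVolume

PATCH = 48          # in-plane patch side, voxels
SLAB_DEPTH = 7      # axial slices in the 3D slab
CONTEXT_SCALE = 2   # larger-scale view side = CONTEXT_SCALE * PATCH

ROI_MODES = ("axial2d", "ortho2p5d", "slab3d")


class ExtractionError(ValueError):
    """Point too close to the volume border with padding disabled."""


class NormalizationError(ValueError):
    """Degenerate statistics (zero variance) or too little data."""


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled attenuation mean/std (HU) used to standardize ROIs."""

    mean: float
    std: float

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.std):
            raise NormalizationError("normalization stats must be finite")
        if self.std <= 0:
            raise NormalizationError(f"std must be > 0, got {self.std}")


@dataclass
class ROISample:
    """An extracted patch in one of the three dimensionalities.

    ``data`` shape by mode: axial2d (48, 48); ortho2p5d (3, 48, 48) with
    channel order axial, sagittal, coronal; slab3d (48, 48, 7). ``context``
    is the larger-scale axial view (extracted at twice the side length and
    downsampled back to 48 x 48) consumed by the multi-context network;
    populated for axial2d extractions.
    """

    mode: str
    data: np.ndarray
    label: TissueClass
    source: Optional[AnnotatedPoint] = None
    context: Optional[np.ndarray] = None
    normalized: bool = False

    def __post_init__(self):
        if self.mode not in ROI_MODES:
            raise ValueError(f"mode must be one of {ROI_MODES}, got {self.mode!r}")
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = {
            "axial2d": (PATCH, PATCH),
            "ortho2p5d": (3, PATCH, PATCH),
            "slab3d": (PATCH, PATCH, SLAB_DEPTH),
        }[self.mode]
        if self.data.shape != expected:
            raise ValueError(
                f"{self.mode} data must have shape {expected}, got {self.data.shape}"
            )


def _window(vol_arr: np.ndarray, center: Sequence[int],
            half: Sequence[int], sizes: Sequence[int], pad: bool) -> np.ndarray:
    """Extract a window ``center - half .. center - half + size`` per axis,
    reflect-padding at the borders when allowed."""
    starts = [c - h for c, h in zip(center, half)]
    stops = [s + n for s, n in zip(starts, sizes)]
    need_pad = any(s < 0 or e > dim for s, e, dim in
                   zip(starts, stops, vol_arr.shape))
    if need_pad:
        if not pad:
            raise ExtractionError(
                f"point {tuple(center)} within half-patch of the border of "
                f"volume {vol_arr.shape} and padding is disabled"
            )
        pads = [(max(0, -s), max(0, e - dim)) for s, e, dim in
                zip(starts, stops, vol_arr.shape)]
        vol_arr = np.pad(vol_arr, pads, mode="reflect")
        starts = [s + p[0] for s, p in zip(starts, pads)]
        stops = [s + n for s, n in zip(starts, sizes)]
    sl = tuple(slice(s, e) for s, e in zip(starts, stops))
    return vol_arr[sl]


def extract_roi(vol: CTVolume, pt: AnnotatedPoint, mode: str,
                pad: bool = True, with_context: bool = True) -> ROISample:
    """Extract a normalized-geometry ROI of the given mode around a point.

    All planes/slabs are centred on ``pt.coord``: the window along an axis
    of length 48 spans indices ``c-24 .. c+23``; the 7-slice slab spans
    ``k-3 .. k+3``. For ``ortho2p5d`` the centre voxel value is therefore
    identical across the three planes.
    """
    if mode not in ROI_MODES:
        raise ValueError(f"mode must be one of {ROI_MODES}, got {mode!r}")
    i, j, k = pt.coord
    arr = vol.voxels
    half = PATCH // 2
    if mode == "axial2d":
        data = _window(arr, (i, j, k), (half, half, 0), (PATCH, PATCH, 1), pad)[..., 0]
        ctx = None
        if with_context:
            big = _window(arr, (i, j, k), (PATCH, PATCH, 0),
                          (2 * PATCH, 2 * PATCH, 1), pad)[..., 0]
            # 2x block-mean downsample back to 48 x 48
            ctx = big.reshape(PATCH, 2, PATCH, 2).mean(axis=(1, 3))
        return ROISample(mode=mode, data=data, label=pt.label, source=pt,
                         context=ctx)
    if mode == "ortho2p5d":
        axial = _window(arr, (i, j, k), (half, half, 0), (PATCH, PATCH, 1), pad)[..., 0]
        sagittal = _window(arr, (i, j, k), (0, half, half), (1, PATCH, PATCH), pad)[0]
        coronal = _window(arr, (i, j, k), (half, 0, half), (PATCH, 1, PATCH), pad)[:, 0]
        data = np.stack([axial, sagittal, coronal])
        return ROISample(mode=mode, data=data, label=pt.label, source=pt)
    # slab3d
    data = _window(arr, (i, j, k), (half, half, SLAB_DEPTH // 2),
                   (PATCH, PATCH, SLAB_DEPTH), pad)
    return ROISample(mode=mode, data=data, label=pt.label, source=pt)


def fit_normalization(samples: Iterable[ROISample]) -> NormalizationStats:
    """Pool all voxels of the supplied (training + validation) samples and
    return their mean and population standard deviation."""
    samples = list(samples)
    if len(samples) < 2:
        raise NormalizationError("need at least 2 samples to fit normalization")
    arrs = [s.data.ravel() for s in samples]
    allv = np.concatenate(arrs)
    if allv.size < 2:
        raise NormalizationError("combined voxel count must exceed 1")
    mean = float(allv.mean())
    std = float(allv.std(ddof=0))
    if std == 0.0:
        raise NormalizationError("zero variance across supplied samples")
    return NormalizationStats(mean=mean, std=std)


def apply_normalization(s: ROISample, stats: NormalizationStats) -> ROISample:
    """Standardize every voxel: (v - mean) / std. Label, geometry and mode
    are unchanged; the context plane, when present, is transformed too."""
    data = (s.data - stats.mean) / stats.std
    ctx = None if s.context is None else (s.context - stats.mean) / stats.std
    out = replace(s, data=data, context=ctx, normalized=True)
    if not np.all(np.isfinite(out.data)):
        raise NormalizationError("normalized patch contains non-finite values")
    return out


def denormalize(s: ROISample, stats: NormalizationStats) -> ROISample:
    data = s.data * stats.std + stats.mean
    ctx = None if s.context is None else s.context * stats.std + stats.mean
    return replace(s, data=data, context=ctx, normalized=False)


def extract_batch(vol: CTVolume, points: Sequence[AnnotatedPoint], mode: str,
                  pad: bool = True) -> List[ROISample]:
    return [extract_roi(vol, p, mode, pad=pad) for p in points]
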