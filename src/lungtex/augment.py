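"""Training-set augmentation.

Two families of transforms enlarge and diversify the training data:

* geometric transforms (rotation, shifts, flips, shearing) applied to the
  under-represented classes while balancing every class to a common roster
  size;
* a physiology-based density augmentation built on the *sponge model* of
  the lung: tissue mass is conserved over the respiratory cycle, so a
  proportional change in lung volume produces an inversely proportional
  change in density. With density taken as attenuation above air,
  rho = HU - air_hu, a random inspiratory volume change dV rescales

      rho' = rho * V / (V + dV),   HU' = rho' + air_hu

  which conserves mean-density x volume exactly.

Augmentation operates on HU patches *before* attenuation normalization:
the density rescaling would otherwise invalidate the pooled statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .sampling import ROISample
from .tissue import GEOMETRIC_AUG_CLASSES, TissueClass
from .volume import AnnotatedPoint

DEFAULT_AIR_HU = -1000.0
DEFAULT_LUNG_VOLUME_ML = 5000.0
DEFAULT_DELTA_V_RANGE_ML = (-100.0, 100.0)


class BalancingError(ValueError):
    """A class roster cannot be balanced (e.g. the class is empty)."""


class SpongeParameterError(ValueError):
    """Non-physical sponge parameters (V + dV <= 0)."""


@dataclass(frozen=True)
class GeometricTransform:
    """An affine patch transform; the all-zero/False instance is identity."""

    rotation: float = 0.0      # degrees, about the patch centre
    shift: Tuple[float, float] = (0.0, 0.0)   # (dx, dy) px
    flip_h: bool = False
    flip_v: bool = False
    shear: float = 0.0         # degrees

    @property
    def is_identity(self) -> bool:
        return (self.rotation == 0.0 and self.shift == (0.0, 0.0)
                and not self.flip_h and not self.flip_v and self.shear == 0.0)

    @staticmethod
    def random(rng: np.random.Generator,
               rotation_range: float = 180.0,
               shift_range: float = 4.0,
               shear_range: float = 8.0,
               flip: bool = True) -> "GeometricTransform":
        return GeometricTransform(
            rotation=float(rng.uniform(-rotation_range, rotation_range)),
            shift=(float(rng.uniform(-shift_range, shift_range)),
                   float(rng.uniform(-shift_range, shift_range))),
            flip_h=bool(flip and rng.random() < 0.5),
            flip_v=bool(flip and rng.random() < 0.5),
            shear=float(rng.uniform(-shear_range, shear_range)),
        )


@dataclass(frozen=True)
class SpongeParams:
    """Scan-level lung volume V, its random perturbation dV (both mL) and
    the attenuation of air used as the zero-density reference."""

    lung_volume: float = DEFAULT_LUNG_VOLUME_ML
    delta_v: float = 0.0
    air_hu: float = DEFAULT_AIR_HU

    def __post_init__(self):
        if self.lung_volume <= 0:
            raise SpongeParameterError(
                f"lung_volume must be > 0 mL, got {self.lung_volume}")
        if self.lung_volume + self.delta_v <= 0:
            raise SpongeParameterError(
                f"V + dV must be > 0 mL, got "
                f"{self.lung_volume} + {self.delta_v}")


def _plane_transform(plane: np.ndarray, t: GeometricTransform,
                     order: int = 1) -> np.ndarray:
    """Apply flip / rotation / shear / shift to one 2D plane.

    Rotation and shear are taken about the patch centre; interpolation is
    linear (order=1) with reflect boundary by default.
    """
    out = plane
    if t.flip_h:
        out = out[::-1, :]
    if t.flip_v:
        out = out[:, ::-1]
    if t.rotation != 0.0 or t.shear != 0.0 or t.shift != (0.0, 0.0):
        theta = np.deg2rad(t.rotation)
        sh = np.tan(np.deg2rad(t.shear))
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shear = np.array([[1.0, sh], [0.0, 1.0]])
        mat = rot @ shear
        centre = (np.asarray(out.shape) - 1) / 2.0
        # ndimage maps output coords to input coords: x_in = M x_out + off
        offset = centre - mat @ centre - mat @ np.asarray(t.shift)
        out = ndimage.affine_transform(out, mat, offset=offset, order=order,
                                       mode="reflect")
    return np.ascontiguousarray(out)


def apply_geometric(s: ROISample, t: GeometricTransform,
                    rng_seed: Optional[int] = None, order: int = 1) -> ROISample:
    """Apply a geometric transform to a 2D or 2.5D sample (plane-wise).

    The label and output shape are preserved; the identity transform
    returns the input values unchanged. ``rng_seed`` is accepted for
    interface symmetry (the transform itself is deterministic).
    """
    if s.mode == "slab3d":
        # in-plane transform applied to each axial slice of the slab
        data = np.stack([_plane_transform(s.data[..., z], t, order)
                         for z in range(s.data.shape[-1])], axis=-1)
    elif s.mode == "ortho2p5d":
        data = np.stack([_plane_transform(p, t, order) for p in s.data])
    else:
        data = _plane_transform(s.data, t, order)
    ctx = None if s.context is None else _plane_transform(s.context, t, order)
    return replace(s, data=data, context=ctx)


def sponge_augment(s: ROISample, p: SpongeParams,
                   rng_seed: Optional[int] = None) -> ROISample:
    """Rescale patch density by V / (V + dV) per the sponge model.

    Expects an HU patch (pre-normalization). Air-valued voxels are a fixed
    point; mean-density x volume is conserved to machine precision.
    """
    if s.normalized:
        raise ValueError("sponge augmentation must run on HU patches, "
                         "before attenuation normalization")
    factor = p.lung_volume / (p.lung_volume + p.delta_v)
    data = (s.data - p.air_hu) * factor + p.air_hu
    ctx = None if s.context is None else (s.context - p.air_hu) * factor + p.air_hu
    return replace(s, data=data, context=ctx)


def draw_sponge_params(rng: np.random.Generator,
                       lung_volume: float = DEFAULT_LUNG_VOLUME_ML,
                       delta_v_range: Tuple[float, float] = DEFAULT_DELTA_V_RANGE_ML,
                       air_hu: float = DEFAULT_AIR_HU) -> SpongeParams:
    """Draw dV ~ Uniform(delta_v_range) mL for one training sample."""
    dv = float(rng.uniform(*delta_v_range))
    return SpongeParams(lung_volume=lung_volume, delta_v=dv, air_hu=air_hu)


@dataclass(frozen=True)
class RosterEntry:
    """One entry of a balanced training roster: a source point plus the
    geometric transform to apply (identity for originals)."""

    point: AnnotatedPoint
    transform: GeometricTransform = GeometricTransform()

    @property
    def is_augmented(self) -> bool:
        return not self.transform.is_identity


def balance_classes(points_by_class: Dict[TissueClass, Sequence[AnnotatedPoint]],
                    target: int = 600, rng_seed: int = 0,
                    augment_classes=GEOMETRIC_AUG_CLASSES,
                    rotation_range: float = 180.0, shift_range: float = 4.0,
                    shear_range: float = 8.0, flip: bool = True,
                    ) -> Dict[TissueClass, List[RosterEntry]]:
    """Balance every class roster to exactly ``target`` entries.

    Classes at or above target are subsampled without augmentation; classes
    below target keep all originals and add (point, random transform) pairs,
    drawing source points with replacement when the deficit exceeds the
    class size. Deterministic under ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    rosters: Dict[TissueClass, List[RosterEntry]] = {}
    for cls in sorted(points_by_class, key=int):
        pts = list(points_by_class[cls])
        if not pts:
            raise BalancingError(f"class {cls.name} has no points to balance")
        if len(pts) >= target:
            idx = rng.choice(len(pts), size=target, replace=False)
            rosters[cls] = [RosterEntry(pts[i]) for i in idx]
            continue
        entries = [RosterEntry(p) for p in pts]
        deficit = target - len(pts)
        src_idx = rng.choice(len(pts), size=deficit, replace=True)
        for i in src_idx:
            t = GeometricTransform.random(
                rng, rotation_range=rotation_range, shift_range=shift_range,
                shear_range=shear_range, flip=flip)
            entries.append(RosterEntry(pts[i], t))
        if cls not in augment_classes and deficit > 0:
            # classes outside the named augmentation set still need filling
            # to reach a balanced roster; they reuse originals verbatim
            entries = [RosterEntry(p) for p in pts] + [
                RosterEntry(pts[i]) for i in src_idx]
        rosters[cls] = entries
    return rosters
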