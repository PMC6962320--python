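"""Synthetic CT texture phantoms.

Generates 3D HU volumes with an ellipsoidal "lung" mask and eight
parametric texture classes at annotated points, so the whole pipeline is
exercisable without clinical data. Realism is explicitly not the goal;
class separability and geometric plausibility are (subpleural lesions hug
the mask border, centrilobular holes sit centrally), so that the
confusion structure of the classifier can be probed qualitatively.

Default textures (HU):

==========  ========================================================
NP          lung base (-850) + Gaussian noise
GG          smooth +150 haze blob (Gaussian radial profile)
RETIC       oriented +300 line lattice inside a blob
NOD         small bright sphere (+450)
LINSC       single elongated bright streak (+350)
SUBPL       bright curve within 5 voxels of the mask border (+450)
PS          subpleural low-density pocket (-980)
CL          scattered central low-density holes (-980)
==========  ========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .sampling import ROISample, extract_roi
from .tissue import TissueClass
from .volume import AnnotatedPoint, CTVolume

DEFAULT_SHAPE = (96, 96, 96)
DEFAULT_SPACING = (0.7, 0.7, 0.7)


class CapacityError(ValueError):
    """Requested more lesions than placeable sites."""


@dataclass
class TextureParams:
    base_delta: float = 0.0     # additive HU change (bright lesions)
    set_value: Optional[float] = None  # absolute HU (low-density lesions)
    radius: float = 6.0


@dataclass
class PhantomSpec:
    """Geometry, class counts and texture parameters of one phantom."""

    shape: Tuple[int, int, int] = DEFAULT_SHAPE
    spacing: Tuple[float, float, float] = DEFAULT_SPACING
    class_counts: Dict[TissueClass, int] = field(default_factory=lambda:
                                                 dict(DEFAULT_CLASS_COUNTS))
    base_hu: float = -850.0
    noise_hu: float = 30.0
    rng_seed: int = 0
    kernel: str = "B50"         # "B35" adds a soft-kernel Gaussian blur

    def __post_init__(self):
        if any(v < 1 for v in self.class_counts.values()):
            raise ValueError("class_counts must all be >= 1")


#: Default per-phantom counts; the cohort's class skew scaled down
#: (normal parenchyma dominates, ground glass / nodular / linear scar are
#: scarce).
DEFAULT_CLASS_COUNTS = {
    TissueClass.NP: 60,
    TissueClass.GG: 2,
    TissueClass.RETIC: 14,
    TissueClass.NOD: 2,
    TissueClass.LINSC: 2,
    TissueClass.SUBPL: 3,
    TissueClass.PS: 10,
    TissueClass.CL: 9,
}

#: Per-phantom counts used when building *balanced* patch sets: closer to
#: each phantom's placement capacity per class so fewer phantoms are
#: needed for a given set size.
PATCHSET_CLASS_COUNTS = {
    TissueClass.NP: 12,
    TissueClass.GG: 6,
    TissueClass.RETIC: 8,
    TissueClass.NOD: 7,
    TissueClass.LINSC: 5,
    TissueClass.SUBPL: 5,
    TissueClass.PS: 7,
    TissueClass.CL: 7,
}


def _ellipsoid_mask(shape) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    centre = [(s - 1) / 2.0 for s in shape]
    radii = [0.46 * s for s in shape]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return r2 <= 1.0


def _sphere_at(shape, centre, radius) -> np.ndarray:
    """Boolean ball, computed only inside its bounding box."""
    out = np.zeros(shape, dtype=bool)
    lo = [max(0, int(np.floor(c - radius))) for c in centre]
    hi = [min(s, int(np.ceil(c + radius)) + 1) for s, c in zip(shape, centre)]
    sub = np.indices([h - l for l, h in zip(lo, hi)]).astype(float)
    r2 = sum((g + l - c) ** 2 for g, l, c in zip(sub, lo, centre))
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = r2 <= radius ** 2
    return out


def _paint(vol, region, delta=None, value=None, soft=None):
    if soft is not None:
        vol += soft
    elif value is not None:
        vol[region] = value
    else:
        vol[region] += delta


def _place_lesion(cls: TissueClass, centre, vol, mask, rng):
    """Stamp one lesion of the class at ``centre``; returns its footprint."""
    shape = vol.shape
    ci, cj, ck = centre
    if cls == TissueClass.GG:
        radius = 8.0
        grids = np.indices(shape).astype(float)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        haze = 150.0 * np.exp(-r2 / (2 * (radius / 2.0) ** 2))
        vol += np.where(mask, haze, 0.0)
        return _sphere_at(shape, centre, radius)
    if cls == TissueClass.RETIC:
        region = _sphere_at(shape, centre, 6.0) & mask
        ii, jj, kk = np.indices(shape)
        lattice = (((jj - cj) % 4 == 0) | ((kk - ck) % 4 == 0))
        vol[region & lattice] += 300.0
        return region
    if cls == TissueClass.NOD:
        region = _sphere_at(shape, centre, 2.5)
        vol[region] += 450.0
        return _sphere_at(shape, centre, 4.0)
    if cls == TissueClass.LINSC:
        theta = rng.uniform(0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta), 0.0])
        pts = np.asarray(centre, float) + d * np.arange(-7, 8)[:, None]
        region = np.zeros(shape, dtype=bool)
        for p in pts:
            region |= _sphere_at(shape, p, 1.5)
        vol[region & mask] += 350.0
        return ndimage.binary_dilation(region, iterations=1)
    if cls == TissueClass.SUBPL:
        # curved bright line following the border band
        band = _sphere_at(shape, centre, 5.0) & mask
        eroded = ndimage.binary_erosion(mask, iterations=2)
        shell = band & ~eroded
        if not shell[tuple(centre)]:
            shell = shell | _sphere_at(shape, centre, 1.5)
        vol[shell & mask] += 450.0
        return band
    if cls == TissueClass.PS:
        region = _sphere_at(shape, centre, 4.5) & mask
        vol[region] = -980.0
        return _sphere_at(shape, centre, 5.5)
    if cls == TissueClass.CL:
        footprint = _sphere_at(shape, centre, 6.5)
        holes = _sphere_at(shape, centre, 1.8)
        for _ in range(5):
            off = rng.uniform(-4, 4, size=3)
            holes |= _sphere_at(shape, np.asarray(centre, float) + off, 1.8)
        vol[holes & mask] = -980.0
        return footprint
    raise ValueError(f"no lesion texture for {cls}")


def generate_phantom(spec: Optional[PhantomSpec] = None
                     ) -> Tuple[CTVolume, List[AnnotatedPoint]]:
    """Generate one phantom volume and its annotated points.

    Deterministic under ``spec.rng_seed``. Every annotated point lies
    inside its lesion and inside the mask; subpleural points lie within 5
    voxels of the mask border. Raises :class:`CapacityError` when the
    requested counts cannot be placed without lesion overlap.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape)
    mask = _ellipsoid_mask(shape)
    vol = spec.base_hu + spec.noise_hu * rng.standard_normal(shape)
    vol[~mask] = -1000.0 + 5.0 * rng.standard_normal((~mask).sum())

    interior = ndimage.binary_erosion(mask, iterations=12)
    border_band = mask & ~ndimage.binary_erosion(mask, iterations=5)
    # subpleural lesion centres must keep a margin from the volume edge
    edge_ok = np.zeros(shape, dtype=bool)
    edge_ok[8:-8, 8:-8, 8:-8] = True
    occupied = np.zeros(shape, dtype=bool)

    points: List[AnnotatedPoint] = []
    scan_id = f"phantom{spec.rng_seed:04d}"
    subject_id = f"subj{spec.rng_seed:04d}"

    # clearance radius per class: how much empty space a new lesion centre
    # must see around itself (footprint extent + a small guard band)
    clearance = {TissueClass.GG: 9.0, TissueClass.RETIC: 7.0,
                 TissueClass.NOD: 5.0, TissueClass.LINSC: 9.0,
                 TissueClass.SUBPL: 6.0, TissueClass.PS: 6.5,
                 TissueClass.CL: 7.5}
    lesion_order = [c for c in TissueClass if c != TissueClass.NP]
    for cls in lesion_order:
        n = spec.class_counts.get(cls, 0)
        allowed = border_band & edge_ok if cls in (TissueClass.SUBPL,
                                                   TissueClass.PS) else interior
        for _ in range(n):
            centre = None
            cand_pool = np.argwhere(allowed & ~occupied)
            if len(cand_pool):
                for _try in range(200):
                    cand = tuple(cand_pool[rng.integers(len(cand_pool))])
                    probe = _sphere_at(shape, cand, clearance[cls])
                    if not (probe & occupied).any():
                        centre = cand
                        break
            if centre is None:
                raise CapacityError(
                    f"cannot place {n} x {cls.name} lesions in shape {shape}")
            footprint = _place_lesion(cls, centre, vol, mask, rng)
            occupied |= ndimage.binary_dilation(footprint, iterations=1)
            points.append(AnnotatedPoint(scan_id=scan_id, coord=centre,
                                         label=cls, kernel=spec.kernel,
                                         subject_id=subject_id))

    # normal-parenchyma points: in-mask, interior, clear of every lesion
    np_sites = np.argwhere(interior & ~occupied)
    n_np = spec.class_counts.get(TissueClass.NP, 0)
    if len(np_sites) < n_np:
        raise CapacityError(
            f"cannot place {n_np} NP points ({len(np_sites)} clear sites)")
    chosen = np_sites[rng.choice(len(np_sites), size=n_np, replace=False)]
    for c in chosen:
        points.append(AnnotatedPoint(scan_id=scan_id, coord=tuple(c),
                                     label=TissueClass.NP, kernel=spec.kernel,
                                     subject_id=subject_id))

    if spec.kernel == "B35":
        # soft-kernel emulation: mild smoothing of the reconstruction
        vol = ndimage.gaussian_filter(vol, sigma=1.0)

    volume = CTVolume(voxels=vol, spacing=spec.spacing, lung_mask=mask,
                      scan_id=scan_id)
    return volume, points


def generate_patchset(n_per_class: int, mode: str = "axial2d",
                      rng_seed: int = 0,
                      spec: Optional[PhantomSpec] = None,
                      modes: Optional[Sequence[str]] = None
                      ) -> Dict[str, List[ROISample]]:
    """Balanced labelled patch sets, one list per requested ROI mode.

    Phantoms are generated (with per-phantom seeds derived from
    ``rng_seed``) until every class has ``n_per_class`` annotated points;
    the same points feed every mode so the 2D/2.5D/3D sets are aligned.
    """
    modes = list(modes) if modes is not None else [mode]
    base = spec or PhantomSpec(class_counts=dict(PATCHSET_CLASS_COUNTS))
    needed = {c: n_per_class for c in TissueClass}
    per_phantom = dict(base.class_counts)
    collected: Dict[TissueClass, List[Tuple[CTVolume, AnnotatedPoint]]] = {
        c: [] for c in TissueClass}
    phantom_idx = 0
    while any(len(collected[c]) < needed[c] for c in TissueClass):
        counts = {c: min(per_phantom[c], needed[c]) for c in TissueClass}
        pspec = PhantomSpec(shape=base.shape, spacing=base.spacing,
                            class_counts=counts, base_hu=base.base_hu,
                            noise_hu=base.noise_hu,
                            rng_seed=(rng_seed * 1000 + phantom_idx) % 2 ** 31,
                            kernel=base.kernel)
        volume, pts = generate_phantom(pspec)
        for p in pts:
            if len(collected[p.label]) < needed[p.label]:
                collected[p.label].append((volume, p))
        phantom_idx += 1
        if phantom_idx > 200:
            raise CapacityError("phantom budget exhausted")
    out: Dict[str, List[ROISample]] = {m: [] for m in modes}
    for c in TissueClass:
        for volume, p in collected[c][:n_per_class]:
            for m in modes:
                out[m].append(extract_roi(volume, p, m))
    return out
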