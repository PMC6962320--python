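"""Lung parenchyma tissue classes.

Eight radiographic patterns are modelled: normal parenchyma, five
interstitial features (ground glass, reticular, nodular, linear scar,
subpleural line) and two emphysematous features (paraseptal and
centrilobular emphysema). Class order is fixed; integer indices are used
as network targets and as codes in exported label maps.
"""

from __future__ import annotations

import enum


class TissueGroup(enum.Enum):
    HEALTHY = "healthy"
    INTERSTITIAL = "interstitial"
    EMPHYSEMA = "emphysema"


class TissueClass(enum.IntEnum):
    """The eight parenchymal tissue patterns, in canonical index order."""

    NP = 0       # normal parenchyma
    GG = 1       # ground glass
    RETIC = 2    # reticular
    NOD = 3      # nodular
    LINSC = 4    # linear scar
    SUBPL = 5    # subpleural line
    PS = 6       # paraseptal emphysema
    CL = 7       # centrilobular emphysema

    @property
    def group(self) -> TissueGroup:
        return _GROUPS[self]

    @classmethod
    def from_name(cls, name: str) -> "TissueClass":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown tissue class {name!r}; expected one of "
                f"{[c.name for c in cls]}"
            ) from None


_GROUPS = {
    TissueClass.NP: TissueGroup.HEALTHY,
    TissueClass.GG: TissueGroup.INTERSTITIAL,
    TissueClass.RETIC: TissueGroup.INTERSTITIAL,
    TissueClass.NOD: TissueGroup.INTERSTITIAL,
    TissueClass.LINSC: TissueGroup.INTERSTITIAL,
    TissueClass.SUBPL: TissueGroup.INTERSTITIAL,
    TissueClass.PS: TissueGroup.EMPHYSEMA,
    TissueClass.CL: TissueGroup.EMPHYSEMA,
}

N_CLASSES = 8

#: Interstitial patterns counted by the ILA (interstitial lung abnormality)
#: score; emphysema is excluded by default but the set is configurable.
ILA_CLASSES = frozenset(
    {TissueClass.GG, TissueClass.RETIC, TissueClass.NOD,
     TissueClass.LINSC, TissueClass.SUBPL}
)

#: Classes eligible for geometric class-balancing augmentation (the
#: under-represented interstitial patterns).
GEOMETRIC_AUG_CLASSES = frozenset(
    {TissueClass.GG, TissueClass.NOD, TissueClass.LINSC, TissueClass.SUBPL}
)

#: CT reconstruction kernels represented in the annotation plumbing.
KERNELS = ("B35", "B50")
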