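"""Geometric primitives for measured stem profiles.

Diameters are outside-bark and in centimetres, heights in metres, volumes in
cubic metres throughout.  Cross-sectional areas use the constant
``K = pi / 40000`` so that ``K * d**2`` (d in cm) is an area in square metres.

A stem is described by an ordered sequence of (height, diameter) measurements
starting at the stump (0.1 m by convention).  Volumes between consecutive
measurements use Smalian's formula (section length times the mean of the end
cross-sectional areas); the unmeasured tip above the last measurement is
treated as a cone.  Multi-stemmed trees carry one profile per stem and a
tree-level equivalent diameter that preserves total basal area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "K",
    "FOREST_TYPES",
    "StemMeasurement",
    "StemProfile",
    "Tree",
    "VolumePoint",
    "equivalent_diameter",
    "cross_section_area",
    "smalian_section_volume",
    "cone_tip_volume",
    "accumulated_volume_profile",
    "tree_total_volume",
]

#: Converts squared diameter (cm^2) to cross-sectional area (m^2).
K = math.pi / 40000.0

#: Canonical forest-type labels, in the fixed dummy-variable order d1, d2, d3.
FOREST_TYPES = ("cerrado", "semideciduous", "rainforest")

#: Stump height convention: volumes are referenced to 0.1 m above ground.
STUMP_HEIGHT = 0.1


@dataclass(frozen=True)
class StemMeasurement:
    """A single outside-bark diameter measurement along a stem.

    Parameters
    ----------
    h : float
        Height above ground, metres.  Must be non-negative.
    d : float
        Outside-bark diameter at ``h``, centimetres.  Must be non-negative.
    """

    h: float
    d: float

    def __post_init__(self) -> None:
        if not (self.h >= 0):
            raise ValueError(f"measurement height must be >= 0, got {self.h}")
        if not (self.d >= 0):
            raise ValueError(f"measured diameter must be >= 0, got {self.d}")


@dataclass
class StemProfile:
    """Ordered (h, d) measurements for one stem.

    Heights must be strictly increasing and there must be at least two
    measurements; the first height is the stump (0.1 m by default protocol).

    ``nominal_dbh`` is optional bookkeeping used by generators of synthetic
    stems: the stem-level breast-height diameter the profile was built from.
    It is not required for measured data.
    """

    stem_id: str
    measurements: tuple[StemMeasurement, ...]
    nominal_dbh: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.measurements = tuple(self.measurements)
        if len(self.measurements) < 2:
            raise ValueError(
                f"stem {self.stem_id!r}: at least 2 measurements required, "
                f"got {len(self.measurements)}"
            )
        hs = [m.h for m in self.measurements]
        if any(b <= a for a, b in zip(hs, hs[1:])):
            raise ValueError(
                f"stem {self.stem_id!r}: heights must be strictly increasing"
            )

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.h for m in self.measurements])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([m.d for m in self.measurements])

    @property
    def top_height(self) -> float:
        return self.measurements[-1].h

    @property
    def top_diameter(self) -> float:
        return self.measurements[-1].d


@dataclass
class Tree:
    """A measured tree: identity, site, size and one or more stem profiles.

    ``dbh`` is the tree-level predictor diameter (cm); for multi-stemmed
    trees it is the equivalent diameter of the stem breast-height diameters.
    ``ht`` (m) must exceed the last measured height of every stem.
    """

    tree_id: str
    forest_type: str
    species: str
    dbh: float
    ht: float
    stems: tuple[StemProfile, ...]

    def __post_init__(self) -> None:
        self.stems = tuple(self.stems)
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(
                f"tree {self.tree_id!r}: unknown forest_type "
                f"{self.forest_type!r}; expected one of {FOREST_TYPES}"
            )
        if not (self.dbh > 0):
            raise ValueError(f"tree {self.tree_id!r}: dbh must be > 0")
        if not self.stems:
            raise ValueError(f"tree {self.tree_id!r}: at least one stem required")
        for stem in self.stems:
            if not (self.ht > stem.top_height):
                raise ValueError(
                    f"tree {self.tree_id!r}: total height {self.ht} must exceed "
                    f"last measured height {stem.top_height} of stem "
                    f"{stem.stem_id!r}"
                )


@dataclass(frozen=True)
class VolumePoint:
    """Accumulated outside-bark volume (m^3) from the stump up to height h."""

    h: float
    vac: float


def equivalent_diameter(diameters: Sequence[float] | np.ndarray) -> float:
    """Basal-area-preserving equivalent diameter of a set of stems.

    Returns ``sqrt(d1^2 + d2^2 + ... + dn^2)`` so that the cross-sectional
    area of the equivalent stem equals the summed areas of the individual
    stems.

    Parameters
    ----------
    diameters : sequence of float
        Stem diameters in cm, all strictly positive.
    """
    ds = np.asarray(diameters, dtype=float)
    if ds.size == 0:
        raise ValueError("equivalent_diameter requires at least one diameter")
    if np.any(ds <= 0):
        raise ValueError("all diameters must be > 0")
    return float(np.sqrt(np.sum(ds**2)))


def cross_section_area(d: float) -> float:
    """Cross-sectional area (m^2) of a circular section of diameter d (cm)."""
    if d < 0:
        raise ValueError(f"diameter must be >= 0, got {d}")
    return K * d * d


def smalian_section_volume(d_lower: float, d_upper: float, length: float) -> float:
    """Volume (m^3) of a stem section by Smalian's formula.

    The section volume is the length times the mean of the two end
    cross-sectional areas.  For a true conic frustum this overestimates
    slightly; the bias vanishes as sections shorten.
    """
    if not (length > 0):
        raise ValueError(f"section length must be > 0, got {length}")
    a_lo = cross_section_area(d_lower)
    a_up = cross_section_area(d_upper)
    return length * (a_lo + a_up) / 2.0


def cone_tip_volume(d_base: float, length: float) -> float:
    """Volume (m^3) of the unmeasured conic tip above the last measurement."""
    if length < 0:
        raise ValueError(f"tip length must be >= 0, got {length}")
    return cross_section_area(d_base) * length / 3.0


def accumulated_volume_profile(stem: StemProfile, ht: float) -> list[VolumePoint]:
    """Accumulated volume at every measurement height plus the tree tip.

    ``vac`` is zero at the first (stump) measurement; each subsequent point
    adds the Smalian volume of the section below it.  A final point at the
    total height ``ht`` adds a cone from the last measured diameter over the
    remaining length.

    Parameters
    ----------
    stem : StemProfile
    ht : float
        Total height (m); must exceed the stem's last measurement height.
    """
    if not (ht > stem.top_height):
        raise ValueError(
            f"total height {ht} must exceed last measurement height "
            f"{stem.top_height}"
        )
    points = [VolumePoint(stem.measurements[0].h, 0.0)]
    vac = 0.0
    for lo, hi in zip(stem.measurements, stem.measurements[1:]):
        vac += smalian_section_volume(lo.d, hi.d, hi.h - lo.h)
        points.append(VolumePoint(hi.h, vac))
    vac += cone_tip_volume(stem.top_diameter, ht - stem.top_height)
    points.append(VolumePoint(ht, vac))
    return points


def tree_total_volume(tree: Tree) -> float:
    """Total outside-bark volume (m^3): sum of the stems' final vac values."""
    return float(
        sum(accumulated_volume_profile(s, tree.ht)[-1].vac for s in tree.stems)
    )
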