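"""Simulation geometry and receptor placement.

The environment is a 2D box of membrane length ``L`` (x axis, periodic) and
height ``H`` (y axis, reflecting).  The membrane is the bottom segment
``y = 0``.  Each receptor sits at a fixed membrane position and carries a
square *affinity zone* of side ``b`` above it, ``[x - b/2, x + b/2] x [0, b]``:
a diffusing ligand may only bind while inside a zone.

Receptors are organized in ``r0/n`` clusters of ``n`` receptors whose centers
are evenly spaced along the membrane.  Within a cluster the zones are placed
according to the layout kind:

``homogeneous``
    single receptors (``n = 1``), evenly spaced — the mean-field reference.
``overstacked``
    all ``n`` zones of a cluster coincide exactly (an n-site macromolecule).
``contiguous``
    zones touch side by side but do not overlap.
``overlapping``
    neighbors within a cluster share a fraction ``overlap_fraction`` of their
    width; 0 reproduces ``contiguous`` and 1 reproduces ``overstacked``.
``spread``
    zone width stays ``b`` but center-to-center spacing inside a cluster is
    ``spacing_ratio * b`` (>= 1); 1 reproduces ``contiguous``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Geometry",
    "LayoutSpec",
    "ReceptorLayout",
    "LayoutError",
    "make_geometry",
    "aspect_for_coverage",
    "build_layout",
    "covered_length",
]

LAYOUT_KINDS = ("homogeneous", "overstacked", "contiguous", "overlapping", "spread")


class LayoutError(ValueError):
    """A receptor layout does not fit the requested geometry."""


@dataclass(frozen=True)
class Geometry:
    """2D simulation box with a membrane along y = 0.

    Attributes
    ----------
    membrane_length : float
        Box width ``L`` (the membrane length); x is periodic over ``[0, L)``.
    height : float
        Box height ``H``; y = 0 and y = H are reflecting walls.
    zone_side : float
        Affinity-zone side ``b``.
    """

    membrane_length: float
    height: float
    zone_side: float = 1.0

    def __post_init__(self) -> None:
        if self.membrane_length <= 0 or self.height <= 0 or self.zone_side <= 0:
            raise ValueError("box dimensions and zone side must be positive")
        if self.height < self.zone_side:
            raise ValueError(
                f"height {self.height} smaller than zone side {self.zone_side}: "
                "affinity zones must fit inside the box"
            )

    @property
    def area_total(self) -> float:
        """Total box area S_t = L * H."""
        return self.membrane_length * self.height

    @property
    def area_zone(self) -> float:
        """Affinity-zone area S_r = b**2."""
        return self.zone_side**2

    @property
    def area_ratio(self) -> float:
        """S_t / S_r, the space ratio entering the dissociation constant."""
        return self.area_total / self.area_zone


def make_geometry(area_ratio: float, zone_side: float = 1.0, aspect: float = 1.0) -> Geometry:
    """Build a box from the dimensionless space ratio ``S_t/S_r``.

    Parameters
    ----------
    area_ratio : float
        Target ``S_t / S_r``.
    zone_side : float
        Affinity-zone side ``b``.
    aspect : float
        ``H / L`` of the box.  The paper-style specification only pins
        ``S_t/S_r``; the aspect is the free parameter that decides how the
        area splits between membrane length and bulk height.
    """
    if area_ratio <= 0:
        raise ValueError("area_ratio must be positive")
    if aspect <= 0:
        raise ValueError("aspect must be positive")
    area = area_ratio * zone_side**2
    length = math.sqrt(area / aspect)
    height = area / length
    return Geometry(membrane_length=length, height=height, zone_side=zone_side)


def aspect_for_coverage(
    area_ratio: float, r0: int, coverage: float = 0.1, zone_side: float = 1.0
) -> float:
    """Aspect ratio H/L such that homogeneous zones cover ``coverage`` of the membrane.

    With ``L = r0 * b / coverage`` and ``H = area / L`` this keeps the
    receptor-free membrane stretches (the depletion mechanism) at a fixed
    relative size across box scales.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    length = r0 * zone_side / coverage
    height = area_ratio * zone_side**2 / length
    return height / length


@dataclass(frozen=True)
class LayoutSpec:
    """Receptor-organization recipe: ``r0`` receptors in clusters of ``n``."""

    r0: int
    n: int = 1
    kind: str = "homogeneous"
    overlap_fraction: float = 0.0
    spacing_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in LAYOUT_KINDS:
            raise ValueError(f"unknown layout kind {self.kind!r}; expected one of {LAYOUT_KINDS}")
        if self.n < 1 or self.r0 < 1:
            raise ValueError("r0 and n must be >= 1")
        if self.r0 % self.n:
            raise ValueError(f"cluster size n={self.n} must divide r0={self.r0}")
        if self.kind == "homogeneous" and self.n != 1:
            raise ValueError("homogeneous layout means n = 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.spacing_ratio < 1.0:
            raise ValueError("spacing_ratio must be >= 1")

    @property
    def n_clusters(self) -> int:
        return self.r0 // self.n

    def intra_cluster_step(self, zone_side: float) -> float:
        """Center-to-center distance between neighboring zones in a cluster."""
        if self.kind in ("homogeneous", "contiguous"):
            return zone_side
        if self.kind == "overstacked":
            return 0.0
        if self.kind == "overlapping":
            return (1.0 - self.overlap_fraction) * zone_side
        return self.spacing_ratio * zone_side  # spread


@dataclass(frozen=True)
class ReceptorLayout:
    """Concrete receptor positions and affinity-zone intervals on the membrane."""

    geometry: Geometry
    spec: LayoutSpec
    positions: np.ndarray = field(repr=False)  # (r0,) zone centers
    zone_lo: np.ndarray = field(repr=False)  # (r0,)
    zone_hi: np.ndarray = field(repr=False)  # (r0,)
    cluster_ids: np.ndarray = field(repr=False)  # (r0,) int

    @property
    def r0(self) -> int:
        return self.spec.r0

    def zone_intervals(self) -> np.ndarray:
        """(r0, 2) array of [x_lo, x_hi] membrane intervals."""
        return np.column_stack([self.zone_lo, self.zone_hi])

    def to_table(self) -> pd.DataFrame:
        """One row per receptor: index, cluster, center and zone interval."""
        return pd.DataFrame(
            {
                "receptor": np.arange(self.r0),
                "cluster_id": self.cluster_ids,
                "x_center": self.positions,
                "x_lo": self.zone_lo,
                "x_hi": self.zone_hi,
            }
        )

    @property
    def is_disjoint(self) -> bool:
        """True when no two zones share interior points (measure-zero touching allowed)."""
        order = np.argsort(self.zone_lo, kind="stable")
        lo, hi = self.zone_lo[order], self.zone_hi[order]
        return bool(np.all(lo[1:] >= hi[:-1] - 1e-12))


def build_layout(spec: LayoutSpec, geom: Geometry) -> ReceptorLayout:
    """Place receptors for ``spec`` in ``geom``.

    Cluster centers are evenly spaced with a half-spacing edge offset (the
    first center sits at ``L / (2 * n_clusters)``), which is symmetric under
    the periodic wrap.  Raises :class:`LayoutError` when the zones cannot fit
    (per-cluster block wider than the cluster spacing, or total zone width
    exceeding the membrane).
    """
    b = geom.zone_side
    L = geom.membrane_length
    m = spec.n_clusters
    step = spec.intra_cluster_step(b)
    block = b + (spec.n - 1) * step  # width of one cluster's zone block
    pitch = L / m  # center-to-center distance between clusters
    if spec.r0 * b > L + 1e-9:
        raise LayoutError(
            f"total zone width r0*b = {spec.r0 * b:g} exceeds membrane length {L:g}"
        )
    if block > pitch + 1e-9:
        raise LayoutError(
            f"cluster block width {block:g} exceeds inter-cluster spacing {pitch:g} "
            f"(n={spec.n}, kind={spec.kind!r}): neighboring clusters would overlap"
        )

    centers = (np.arange(m) + 0.5) * pitch
    offsets = (np.arange(spec.n) - (spec.n - 1) / 2.0) * step
    positions = (centers[:, None] + offsets[None, :]).ravel()
    positions = np.mod(positions, L)
    cluster_ids = np.repeat(np.arange(m), spec.n)
    return ReceptorLayout(
        geometry=geom,
        spec=spec,
        positions=positions,
        zone_lo=positions - b / 2.0,
        zone_hi=positions + b / 2.0,
        cluster_ids=cluster_ids,
    )


def covered_length(layout: ReceptorLayout) -> float:
    """Length of the membrane covered by at least one affinity zone.

    Computed as the measure of the union of the zone intervals (after
    periodic wrapping); decreases as intra-cluster overlap increases.
    """
    L = layout.geometry.membrane_length
    los = np.mod(layout.zone_lo, L)
    his = los + (layout.zone_hi - layout.zone_lo)
    segments = []
    for lo, hi in zip(los, his):
        if hi <= L:
            segments.append((lo, hi))
        else:  # interval wraps past the periodic seam
            segments.append((lo, L))
            segments.append((0.0, hi - L))
    segments.sort()
    total = 0.0
    cur_lo, cur_hi = segments[0]
    for lo, hi in segments[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return float(total)
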