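"""Geometric primitives for halogen-bond analysis.

A halogen bond C-X··Y is described by the halogen-acceptor distance *d*,
the Van der Waals overlap (sum of VdW radii minus *d*; positive means the
pair sits closer than their VdW radii allow), the angle θ1 at the halogen
(parent carbon - halogen - acceptor point; near 180° places the acceptor in
the σ-hole) and the angle θ2 at the acceptor (halogen - acceptor - covalent
neighbor of the acceptor; typically 90-120°).  For C-X···π interactions the
acceptor point is the centroid of an aromatic ring; θ2 and the VdW overlap
are undefined there.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BondGeometry",
    "angle",
    "compute_bond_geometry",
    "default_vdw_radii",
    "distance",
    "ring_centroid",
    "vdw_overlap",
]


@dataclass(frozen=True)
class BondGeometry:
    """Descriptors of one halogen-acceptor contact.

    ``theta2`` is the angle for the acceptor's primary covalent neighbor;
    when the acceptor has several heavy-atom neighbors (e.g. Met SD bonded
    to CG and CE) ``theta2_options`` carries one angle per neighbor, in the
    neighbor order supplied, and downstream scoring may pick the most
    favorable one.  For π acceptors ``theta2`` and ``vdw_overlap`` are None
    and ``theta2_options`` is empty.
    """

    d: float
    theta1: float
    vdw_overlap: float | None = None
    theta2: float | None = None
    theta2_options: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"distance must be positive, got {self.d}")
        if not 0.0 <= self.theta1 <= 180.0:
            raise ValueError(f"theta1 out of [0, 180]: {self.theta1}")
        for t2 in self.theta2_options:
            if not 0.0 <= t2 <= 180.0:
                raise ValueError(f"theta2 out of [0, 180]: {t2}")

    @property
    def is_pi(self) -> bool:
        return self.theta2 is None


def distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a: Sequence[float], vertex: Sequence[float], c: Sequence[float]) -> float:
    """Angle a-vertex-c in degrees, in [0, 180].

    Raises ValueError on a zero-length arm.  The cosine is clamped to
    [-1, 1] so collinear arms never produce a domain error.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u1 = a - v
    u2 = c - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle undefined: zero-length arm at the vertex")
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    cosang = max(-1.0, min(1.0, cosang))
    return math.degrees(math.acos(cosang))


def default_vdw_radii() -> dict[str, float]:
    """Van der Waals radii table (Å), read from the packaged TSV.

    The packaged values are the Bondi compilation radii for the elements
    this package touches.  The table is configuration: edit the TSV or
    pass your own mapping to match a different compilation.
    """
    radii: dict[str, float] = {}
    ref = resources.files("halobond.data").joinpath("vdw_radii.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            radii[row["element"].capitalize()] = float(row["radius"])
    return radii


def vdw_overlap(
    d: float,
    element_x: str,
    element_y: str,
    table: Mapping[str, float] | None = None,
) -> float:
    """(r_x + r_y) - d in Å; positive means interpenetrating VdW spheres."""
    if table is None:
        table = default_vdw_radii()
    try:
        rx = table[element_x.capitalize()]
    except KeyError:
        raise KeyError(f"no Van der Waals radius for element {element_x!r}") from None
    try:
        ry = table[element_y.capitalize()]
    except KeyError:
        raise KeyError(f"no Van der Waals radius for element {element_y!r}") from None
    return (rx + ry) - d


def ring_centroid(ring_positions: Sequence[Sequence[float]]) -> np.ndarray:
    """Unweighted arithmetic mean of ring atom positions.

    Requires at least 3 atoms (anything less does not define a ring plane).
    """
    pts = np.asarray(ring_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("ring centroid needs at least 3 points of dimension 3")
    return pts.mean(axis=0)


def compute_bond_geometry(
    x_pos: Sequence[float],
    x_element: str,
    parent_pos: Sequence[float],
    acceptor_point: Sequence[float],
    acceptor_element: str | None = None,
    neighbor_positions: Sequence[Sequence[float]] | None = None,
    vdw_table: Mapping[str, float] | None = None,
) -> BondGeometry:
    """Geometry of one halogen-acceptor contact.

    For an atomic acceptor pass ``acceptor_element`` and at least one
    covalent-neighbor position; θ2 and the VdW overlap are then computed.
    For a π acceptor pass the ring centroid as ``acceptor_point`` and leave
    ``acceptor_element``/``neighbor_positions`` unset.

    Raises ValueError if an atomic acceptor comes without any neighbor:
    θ2 cannot be measured then (this is why water never qualifies as an
    acceptor).
    """
    d = distance(x_pos, acceptor_point)
    theta1 = angle(parent_pos, x_pos, acceptor_point)

    if acceptor_element is None:
        return BondGeometry(d=d, theta1=theta1)

    if not neighbor_positions:
        raise ValueError(
            "atomic acceptor without a covalent neighbor: theta2 undefined"
        )
    theta2_all = tuple(
        angle(x_pos, acceptor_point, nb) for nb in neighbor_positions
    )
    overlap = vdw_overlap(d, x_element, acceptor_element, vdw_table)
    return BondGeometry(
        d=d,
        theta1=theta1,
        vdw_overlap=overlap,
        theta2=theta2_all[0],
        theta2_options=theta2_all,
    )
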