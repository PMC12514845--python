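"""Synthetic mmCIF structures with exactly prescribed halogen-bond geometry.

Every fixture contains one minimal halogenated ligand (a parent carbon
plus its halogen, with CCD-style connectivity embedded in the file) and a
minimal protein fragment holding the requested acceptor: a backbone
carbonyl oxygen (O-C), a methionine sulfur (S-C), or a complete aromatic
ring (His/Phe/Tyr/Trp) built as an ideal planar polygon with 1.39 Å
edges whose centroid sits at the prescribed distance.  Atoms are placed
analytically so that the recomputed distance/θ1/θ2 reproduce the request,
then the whole model is pushed through a seeded random rigid motion so
nothing is axis-aligned.  Coordinates are written at 7 decimals, keeping
the round-trip error below 1e-6 Å / 1e-4 degrees.

Randomness uses numpy's seeded PCG64 generator throughout, so identical
seeds give byte-identical files on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import gemmi
import numpy as np
from scipy.stats import truncnorm

from .geometry import BondGeometry, compute_bond_geometry
from .io import AtomSite, ModelMetadata, read_structure_string

__all__ = [
    "Corpus",
    "FixtureSpec",
    "FixtureTruth",
    "make_candidate_structure",
    "make_corpus",
]

_CX_BOND = {"F": 1.35, "Cl": 1.74, "Br": 1.90, "I": 2.10}  # C-X bond length, Å
_RING_EDGE = 1.39  # aromatic C-C bond length, Å

_PI_KINDS = {"His", "Phe", "Tyr", "Trp"}
_ATOMIC_KINDS = {"O-C", "S-C"}

_RING_NAMES = {
    "His": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "Phe": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Tyr": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Trp": ("CG", "CD1", "NE1", "CE2", "CD2"),  # pyrrole ring carries the centroid
}
_PI_RESNAME = {"His": "HIS", "Phe": "PHE", "Tyr": "TYR", "Trp": "TRP"}


@dataclass(frozen=True)
class FixtureSpec:
    """Prescription for one synthetic halogen-bond candidate."""

    halogen_element: Literal["F", "Cl", "Br", "I"] = "Cl"
    acceptor_kind: str = "O-C"
    d: float = 3.4
    theta1: float = 165.0
    theta2: float | None = 105.0
    halogen_altloc: bool = False
    add_water: bool = False
    extra_acceptors: tuple[tuple, ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.halogen_element not in _CX_BOND:
            raise ValueError(f"not a halogen: {self.halogen_element}")
        if self.acceptor_kind not in _ATOMIC_KINDS | _PI_KINDS:
            raise ValueError(f"unknown acceptor kind: {self.acceptor_kind}")
        if not self.d > 0:
            raise ValueError("d must be positive")
        if not 0.0 < self.theta1 < 180.0:
            raise ValueError("theta1 must lie in (0, 180)")
        if self.acceptor_kind in _ATOMIC_KINDS:
            if self.theta2 is None or not 0.0 < self.theta2 < 180.0:
                raise ValueError("atomic fixtures need theta2 in (0, 180)")

    @property
    def is_pi(self) -> bool:
        return self.acceptor_kind in _PI_KINDS


@dataclass
class FixtureTruth:
    """Ground truth returned alongside a generated fixture."""

    spec: FixtureSpec
    geometry: BondGeometry
    halogen_atom_name: str
    acceptor_label: str
    category_key: tuple[str, str]
    ligand_residue: tuple[str, int] = ("A", 371)


def _rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation (QR of a Gaussian matrix) + translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return lambda p: q @ np.asarray(p, float) + t


def _acceptor_frame(d: float, theta1: float, azimuth: float = 0.0):
    """Acceptor point at distance d with angle θ1 to the C-X axis.

    The halogen sits at the origin with its parent carbon on -x; the
    acceptor direction makes angle θ1 with the bond direction, rotated
    by ``azimuth`` about the C-X axis so several acceptors can coexist.
    """
    t1 = np.radians(theta1)
    direction = np.array(
        [-np.cos(t1), np.sin(t1) * np.cos(azimuth), np.sin(t1) * np.sin(azimuth)]
    )
    return d * direction, direction


def _neighbor_position(acc: np.ndarray, theta2: float, bond: float, azimuth: float):
    """A covalent neighbor of the acceptor at angle θ2 = X-acc-neighbor."""
    u = -acc / np.linalg.norm(acc)  # unit vector acceptor -> halogen (origin)
    # a unit vector perpendicular to u, stable for any acceptor placement
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p1 = np.cross(u, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(u, p1)
    t2 = np.radians(theta2)
    direction = np.cos(t2) * u + np.sin(t2) * (
        np.cos(azimuth) * p1 + np.sin(azimuth) * p2
    )
    return acc + bond * direction


def _ring_positions(
    kind: str, centroid: np.ndarray, normal_hint: np.ndarray
) -> dict[str, np.ndarray]:
    """Ideal planar ring(s) with the prescribed centroid.

    The ring plane is perpendicular to ``normal_hint`` (the halogen
    direction), i.e. the halogen faces the ring.  Tryptophan gets a full
    idealized indole: a pentagon whose centroid is the prescribed point,
    fused to a hexagon across the CD2-CE2 edge.
    """
    names = _RING_NAMES[kind]
    k = len(names)
    n = normal_hint / np.linalg.norm(normal_hint)
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    radius = _RING_EDGE / (2.0 * np.sin(np.pi / k))
    positions: dict[str, np.ndarray] = {}
    angles = {}
    for i, name in enumerate(names):
        phi = 2.0 * np.pi * i / k
        positions[name] = centroid + radius * (np.cos(phi) * e1 + np.sin(phi) * e2)
        angles[name] = phi

    if kind == "Trp":
        # fuse the benzene ring on the CD2-CE2 edge, pointing away from
        # the pyrrole centroid
        p_cd2, p_ce2 = positions["CD2"], positions["CE2"]
        mid = 0.5 * (p_cd2 + p_ce2)
        out = mid - centroid
        out /= np.linalg.norm(out)
        hex_center = mid + out * (_RING_EDGE * np.sqrt(3.0) / 2.0)

        def ring_angle(p):
            v = p - hex_center
            return np.arctan2(np.dot(v, e2), np.dot(v, e1))

        phi_cd2 = ring_angle(p_cd2)
        phi_ce2 = ring_angle(p_ce2)
        delta = phi_cd2 - phi_ce2
        delta = (delta + np.pi) % (2.0 * np.pi) - np.pi  # signed step of ±60°
        hex_radius = _RING_EDGE
        for j, name in enumerate(("CE3", "CZ3", "CH2", "CZ2"), start=1):
            phi = phi_cd2 + j * delta
            positions[name] = hex_center + hex_radius * (
                np.cos(phi) * e1 + np.sin(phi) * e2
            )
    return positions


def _new_atom(name: str, element: str, pos, altloc: str = "", b: float = 20.0):
    atom = gemmi.Atom()
    atom.name = name
    atom.element = gemmi.Element(element)
    atom.pos = gemmi.Position(*pos)
    atom.occ = 1.0
    atom.b_iso = b
    if altloc:
        atom.altloc = altloc
    return atom


def _build_acceptor_residue(
    kind: str, seqid: int, d: float, theta1: float, theta2: float | None,
    azimuth: float,
) -> tuple[gemmi.Residue, np.ndarray, str]:
    """Residue realizing one acceptor; returns (residue, acceptor point, label)."""
    acc_point, _ = _acceptor_frame(d, theta1, azimuth)
    res = gemmi.Residue()
    res.seqid = gemmi.SeqId(seqid, " ")
    res.het_flag = "A"
    if kind == "O-C":
        res.name = "ALA"
        carbonyl = _neighbor_position(acc_point, theta2, 1.23, azimuth=0.3)
        ca = carbonyl + 1.52 * _unit(carbonyl - acc_point, tilt=0.9)
        nitrogen = ca + 1.46 * _unit(ca - carbonyl, tilt=0.7)
        res.add_atom(_new_atom("N", "N", nitrogen))
        res.add_atom(_new_atom("CA", "C", ca))
        res.add_atom(_new_atom("C", "C", carbonyl))
        res.add_atom(_new_atom("O", "O", acc_point))
        return res, acc_point, "O"
    if kind == "S-C":
        res.name = "MET"
        cg = _neighbor_position(acc_point, theta2, 1.81, azimuth=0.3)
        # second covalent neighbor (CE) on the opposite azimuth
        ce = _neighbor_position(
            acc_point, min(theta2 + 40.0, 175.0), 1.79, azimuth=0.3 + np.pi
        )
        cb = cg + 1.52 * _unit(cg - acc_point, tilt=0.8)
        res.add_atom(_new_atom("CB", "C", cb))
        res.add_atom(_new_atom("CG", "C", cg))
        res.add_atom(_new_atom("SD", "S", acc_point))
        res.add_atom(_new_atom("CE", "C", ce))
        return res, acc_point, "SD"
    # π acceptor: complete ring with prescribed centroid
    res.name = _PI_RESNAME[kind]
    positions = _ring_positions(kind, acc_point, normal_hint=acc_point)
    for name, pos in positions.items():
        element = "N" if name.startswith("N") else "C"
        res.add_atom(_new_atom(name, element, pos))
    return res, acc_point, f"{res.name} ring"


def _unit(v: np.ndarray, tilt: float = 0.0) -> np.ndarray:
    """Unit vector along v, optionally tilted to break collinearity."""
    u = np.asarray(v, float)
    u = u / np.linalg.norm(u)
    if tilt:
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        p = np.cross(u, ref)
        p /= np.linalg.norm(p)
        u = np.cos(tilt) * u + np.sin(tilt) * p
    return u


def make_candidate_structure(spec: FixtureSpec) -> tuple[str, FixtureTruth]:
    """Emit an mmCIF fixture realizing ``spec``, plus its ground truth.

    Raises ValueError before writing anything if the spec is not
    satisfiable (enforced in :class:`FixtureSpec`).
    """
    rng = np.random.default_rng(spec.seed)
    move = _rigid_motion(rng)

    x_name = spec.halogen_element.upper() + "1"
    x_pos = np.zeros(3)
    parent_pos = np.array([-_CX_BOND[spec.halogen_element], 0.0, 0.0])

    st = gemmi.Structure()
    st.name = "HBFX"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")

    # protein fragment(s): the prescribed acceptor plus any decorations
    acceptor_specs = [(spec.acceptor_kind, spec.d, spec.theta1, spec.theta2)]
    acceptor_specs += [tuple(e) for e in spec.extra_acceptors]
    acc_point = None
    acc_label = ""
    for i, (kind, d, t1, t2) in enumerate(acceptor_specs):
        azimuth = 2.0 * np.pi * i / max(len(acceptor_specs), 1)
        res, point, label = _build_acceptor_residue(
            kind, seqid=97 + i, d=d, theta1=t1, theta2=t2, azimuth=azimuth
        )
        if i == 0:
            acc_point, acc_label = point, label
        chain.add_residue(res)

    lig = gemmi.Residue()
    lig.name = "LIG"
    lig.seqid = gemmi.SeqId(371, " ")
    lig.het_flag = "H"
    lig.add_atom(_new_atom("C1", "C", parent_pos))
    lig.add_atom(
        _new_atom(
            x_name,
            spec.halogen_element,
            x_pos,
            altloc="A" if spec.halogen_altloc else "",
        )
    )
    chain.add_residue(lig)

    if spec.add_water:
        wat = gemmi.Residue()
        wat.name = "HOH"
        wat.seqid = gemmi.SeqId(501, " ")
        wat.het_flag = "H"
        w_point, _ = _acceptor_frame(3.0, spec.theta1, azimuth=np.pi / 2)
        wat.add_atom(_new_atom("O", "O", w_point))
        chain.add_residue(wat)

    # seeded rigid motion: nothing in the file is axis-aligned
    for res in chain:
        for atom in res:
            atom.pos = gemmi.Position(*move([atom.pos.x, atom.pos.y, atom.pos.z]))

    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    block = doc.sole_block()

    # gemmi writes 3 decimals; rewrite coordinates at 7 for exact round trips
    table = block.find("_atom_site.", ["Cartn_x", "Cartn_y", "Cartn_z"])
    flat = [atom for res in chain for atom in res]
    for row, atom in zip(table, flat):
        for j, v in enumerate((atom.pos.x, atom.pos.y, atom.pos.z)):
            row[j] = f"{v:.7f}"

    # embedded CCD-style connectivity for the synthetic ligand
    atom_loop = block.init_loop(
        "_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"]
    )
    atom_loop.add_row(["LIG", "C1", "C"])
    atom_loop.add_row(["LIG", gemmi.cif.quote(x_name), spec.halogen_element.upper()])
    bond_loop = block.init_loop("_chem_comp_bond.", ["comp_id", "atom_id_1", "atom_id_2"])
    bond_loop.add_row(["LIG", "C1", gemmi.cif.quote(x_name)])

    truth_geometry = compute_bond_geometry(
        move(x_pos),
        spec.halogen_element,
        move(parent_pos),
        move(acc_point),
        acceptor_element=None if spec.is_pi else ("O" if spec.acceptor_kind == "O-C" else "S"),
        neighbor_positions=None if spec.is_pi else [
            move(_neighbor_position(acc_point, spec.theta2, 1.23 if spec.acceptor_kind == "O-C" else 1.81, azimuth=0.3))
        ],
    )
    truth = FixtureTruth(
        spec=spec,
        geometry=truth_geometry,
        halogen_atom_name=x_name,
        acceptor_label=acc_label,
        category_key=(spec.halogen_element, spec.acceptor_kind),
    )
    return doc.as_string(), truth


_DEFAULT_LAWS = {
    "O-C": {"d": ("normal", 3.5, 0.2), "theta1": ("normal", 160.0, 10.0),
            "theta2": ("normal", 105.0, 8.0)},
    "S-C": {"d": ("normal", 3.7, 0.2), "theta1": ("normal", 160.0, 10.0),
            "theta2": ("normal", 105.0, 8.0)},
    "pi": {"d": ("normal", 4.8, 0.35), "theta1": ("normal", 140.0, 12.0)},
}


def _law_bounds(param: str, is_pi: bool) -> tuple[float, float]:
    if param == "d":
        return (1.0, 6.0) if is_pi else (1.0, 4.0)
    if param == "theta1":
        return (90.0, 180.0)
    return (1.0, 179.0)


@dataclass
class Corpus:
    """A synthetic calibration corpus with its generating-law quartiles."""

    samples: list[tuple[list[AtomSite], ModelMetadata]]
    specs: list[FixtureSpec]
    drawn: dict[str, np.ndarray]
    true_quartiles: dict[str, tuple[float, float, float]]
    category_key: tuple[str, str]
    dictionary: dict = field(default_factory=dict)


def make_corpus(
    n: int,
    halogen: str = "Br",
    acceptor_kind: str = "O-C",
    laws: Mapping[str, tuple] | None = None,
    seed: int = 0,
) -> Corpus:
    """n i.i.d. synthetic single-bond structures drawn from stated laws.

    Each geometric parameter follows a truncated normal law (truncation
    keeps distances inside the detection shell and θ1 above 90° so every
    draw is detectable).  The analytic quartiles of each truncated law
    are returned for parameter-recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    is_pi = acceptor_kind in _PI_KINDS
    if laws is None:
        laws = _DEFAULT_LAWS["pi" if is_pi else acceptor_kind]

    rng = np.random.default_rng(seed)
    drawn: dict[str, np.ndarray] = {}
    true_quartiles: dict[str, tuple[float, float, float]] = {}
    for param, (law, mu, sd) in laws.items():
        if law != "normal":
            raise ValueError(f"unsupported law {law!r}")
        lo, hi = _law_bounds(param, is_pi)
        a, b = (lo - mu) / sd, (hi - mu) / sd
        dist = truncnorm(a, b, loc=mu, scale=sd)
        drawn[param] = dist.rvs(size=n, random_state=rng)
        true_quartiles[param] = tuple(dist.ppf([0.25, 0.5, 0.75]))

    meta_template = dict(resolution=2.0, r_factor=0.18, r_free=0.21)
    samples: list[tuple[list[AtomSite], ModelMetadata]] = []
    specs: list[FixtureSpec] = []
    dictionary: dict = {}
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    for i in range(n):
        spec = FixtureSpec(
            halogen_element=halogen,
            acceptor_kind=acceptor_kind,
            d=float(drawn["d"][i]),
            theta1=float(drawn["theta1"][i]),
            theta2=None if is_pi else float(drawn["theta2"][i]),
            seed=int(child_seeds[i]),
        )
        cif_text, _ = make_candidate_structure(spec)
        atoms, meta = read_structure_string(cif_text)
        if not dictionary:
            from .io import load_compound_dictionary

            dictionary = load_compound_dictionary(gemmi.cif.read_string(cif_text))
        meta = ModelMetadata(
            entry_id=f"SYN{i:04d}",
            per_compound_rscc={("A", 371): 0.95, ("A", 97): 0.95},
            **meta_template,
        )
        samples.append((atoms, meta))
        specs.append(spec)
    return Corpus(
        samples=samples,
        specs=specs,
        drawn=drawn,
        true_quartiles=true_quartiles,
        category_key=(halogen, acceptor_kind),
        dictionary=dictionary,
    )
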