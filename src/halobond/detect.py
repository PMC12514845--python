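"""Enumeration of halogen-bond candidates in a structure model.

Candidates are pairs of a ligand (or other halogen-containing compound)
halogen site and either an atomic acceptor (protein O or S bonded only to
carbon: the "O-C" and "S-C" classes) within 4 Å, or the π-system of a
His/Phe/Tyr/Trp side chain whose ring centroid lies within 6 Å.  Pairs
whose θ1 angle is not strictly above 90° are discarded — the σ-hole sits
opposite the C-X bond, so the acceptor cannot reach it at such angles.
Waters never act as acceptors (their θ2 is undefined) and halogens in
alternate conformations are skipped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .geometry import BondGeometry, compute_bond_geometry, distance, ring_centroid
from .io import HALOGENS, AtomSite, CompoundRecord, EXCLUDED_COMPOUND_IDS

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicAcceptor",
    "HalogenBondCandidate",
    "HalogenSite",
    "PiAcceptor",
    "apply_theta1_filter",
    "detect_candidates",
    "find_atomic_acceptors",
    "find_halogen_sites",
    "find_pi_acceptors",
    "select_mining_acceptor",
]

CANONICAL_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER
    THR TRP TYR VAL""".split()
)

#: Covalent heavy-atom neighbors of O/S acceptor atoms in canonical amino
#: acids.  Every listed neighbor is a carbon, so these atoms all fall in
#: the "O-C" / "S-C" acceptor classes.
_ACCEPTOR_NEIGHBORS: dict[tuple[str, str], tuple[str, ...]] = {}
for _res in CANONICAL_AMINO_ACIDS:
    _ACCEPTOR_NEIGHBORS[(_res, "O")] = ("C",)    # backbone carbonyl
    _ACCEPTOR_NEIGHBORS[(_res, "OXT")] = ("C",)  # C-terminal carboxylate
_ACCEPTOR_NEIGHBORS.update(
    {
        ("SER", "OG"): ("CB",),
        ("THR", "OG1"): ("CB",),
        ("TYR", "OH"): ("CZ",),
        ("ASP", "OD1"): ("CG",),
        ("ASP", "OD2"): ("CG",),
        ("GLU", "OE1"): ("CD",),
        ("GLU", "OE2"): ("CD",),
        ("ASN", "OD1"): ("CG",),
        ("GLN", "OE1"): ("CD",),
        ("CYS", "SG"): ("CB",),
        ("MET", "SD"): ("CG", "CE"),
    }
)

#: Aromatic ring atom sets per π-acceptor residue.  Tryptophan's indole
#: contributes its pyrrole and benzene rings as separate π-systems by
#: default ("separate"); "whole" uses the single 9-atom indole centroid.
_RING_ATOMS: dict[str, tuple[tuple[str, ...], ...]] = {
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    ),
}
_TRP_WHOLE_RING = (
    "CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2",
)

_PI_CLASS = {"HIS": "His", "PHE": "Phe", "TYR": "Tyr", "TRP": "Trp"}

# fallback covalent search radii (Å) when no dictionary connectivity exists;
# keyed by the element whose bonds are being resolved
_BOND_FALLBACK_RADIUS = {"S": 2.2, "Se": 2.3, "Cl": 1.95, "Br": 2.05, "I": 2.25}
_BOND_FALLBACK_DEFAULT = 1.9


@dataclass(frozen=True, eq=False)
class HalogenSite:
    """A carbon-bonded halogen atom eligible for halogen bonding."""

    atom: AtomSite
    parent_carbon: AtomSite
    source_compound: str
    compound_class: Literal["ligand", "non-canonical-residue", "nucleotide", "other"]

    def __post_init__(self) -> None:
        if self.atom.element not in HALOGENS:
            raise ValueError(f"not a halogen: {self.atom.element}")
        if self.parent_carbon.element != "C":
            raise ValueError("halogen parent must be carbon")
        if self.atom.altloc:
            raise ValueError("halogens in alternate conformations are excluded")


@dataclass(frozen=True, eq=False)
class AtomicAcceptor:
    """An O or S acceptor atom with its covalent neighbor(s)."""

    atom: AtomSite
    neighbors: tuple[AtomSite, ...]
    category: str  # "O-C", "S-C" or "other"
    canonical: bool

    @property
    def acceptor_point(self) -> np.ndarray:
        return self.atom.position


@dataclass(frozen=True, eq=False)
class PiAcceptor:
    """An aromatic side-chain π-system represented by its ring centroid."""

    residue_name: str
    chain_id: str
    residue_seq: int
    icode: str
    ring_atoms: tuple[AtomSite, ...]
    centroid: np.ndarray
    category: str  # "His", "Phe", "Tyr" or "Trp"

    @property
    def acceptor_point(self) -> np.ndarray:
        return self.centroid


@dataclass(frozen=True, eq=False)
class HalogenBondCandidate:
    """One halogen paired with one acceptor, plus measured geometry."""

    halogen: HalogenSite
    acceptor: AtomicAcceptor | PiAcceptor
    geometry: BondGeometry

    @property
    def is_pi(self) -> bool:
        return isinstance(self.acceptor, PiAcceptor)

    @property
    def category_key(self) -> tuple[str, str]:
        return (self.halogen.atom.element, self.acceptor.category)

    @property
    def acceptor_residue_key(self) -> tuple[str, int, str]:
        a = self.acceptor
        if isinstance(a, PiAcceptor):
            return (a.chain_id, a.residue_seq, a.icode)
        return a.atom.residue_key

    def _sort_key(self):
        a = self.acceptor
        name = a.category if isinstance(a, PiAcceptor) else a.atom.atom_name
        return (self.acceptor_residue_key, name)


def _group_by_residue(
    atoms: Iterable[AtomSite],
) -> dict[tuple[str, int, str], list[AtomSite]]:
    groups: dict[tuple[str, int, str], list[AtomSite]] = defaultdict(list)
    for atom in atoms:
        groups[atom.residue_key].append(atom)
    return groups


def _classify_compound(record: CompoundRecord | None, site_atom: AtomSite) -> str:
    if record is not None:
        ctype = record.component_type.lower()
        if "non-polymer" in ctype or ctype in ("", "other"):
            return "ligand"
        if "peptide" in ctype:
            return "non-canonical-residue"
        if "dna" in ctype or "rna" in ctype or "nucleotide" in ctype:
            return "nucleotide"
        return "other"
    # no dictionary record: fall back on the coordinate record type
    if site_atom.residue_name in CANONICAL_AMINO_ACIDS:
        return "other"
    return "ligand" if site_atom.het else "non-canonical-residue"


def _find_parent_carbon(
    halogen: AtomSite,
    residue_atoms: Sequence[AtomSite],
    record: CompoundRecord | None,
) -> AtomSite | None:
    if record is not None and record.bonds:
        parent_name = record.halogen_parent_carbon(halogen.atom_name)
        if parent_name is None:
            logger.info(
                "halogen %s of %s is not carbon-bonded; skipped",
                halogen.atom_name, record.ccd_id,
            )
            return None
        for atom in residue_atoms:
            if atom.atom_name == parent_name and atom.altloc in ("", halogen.altloc):
                return atom
        logger.info(
            "parent carbon %s of %s not present in coordinates; halogen skipped",
            parent_name, record.ccd_id,
        )
        return None
    # distance heuristic: nearest carbon within covalent range
    best: AtomSite | None = None
    best_d = _BOND_FALLBACK_RADIUS.get(halogen.element, _BOND_FALLBACK_DEFAULT)
    for atom in residue_atoms:
        if atom.element != "C" or atom is halogen:
            continue
        d = distance(halogen.position, atom.position)
        if d < best_d:
            best, best_d = atom, d
    if best is not None:
        logger.debug(
            "no connectivity for %s; parent carbon of %s resolved by distance",
            halogen.residue_name, halogen.atom_name,
        )
    return best


def find_halogen_sites(
    atoms: Sequence[AtomSite],
    dictionary: Mapping[str, CompoundRecord] | None = None,
) -> list[HalogenSite]:
    """All scorable halogen sites: carbon-bonded F/Cl/Br/I in non-excluded
    compounds, skipping alternate conformations."""
    sites: list[HalogenSite] = []
    by_residue = _group_by_residue(atoms)
    for key, residue_atoms in by_residue.items():
        res_name = residue_atoms[0].residue_name
        if res_name in EXCLUDED_COMPOUND_IDS:
            continue
        record = dictionary.get(res_name) if dictionary else None
        if record is not None and record.excluded:
            continue
        for atom in residue_atoms:
            if atom.element not in HALOGENS:
                continue
            if atom.altloc:
                continue
            parent = _find_parent_carbon(atom, residue_atoms, record)
            if parent is None:
                logger.info(
                    "halogen %s %s/%s%s has no resolvable parent carbon; skipped",
                    atom.atom_name, res_name, key[0], key[1],
                )
                continue
            sites.append(
                HalogenSite(
                    atom=atom,
                    parent_carbon=parent,
                    source_compound=res_name,
                    compound_class=_classify_compound(record, atom),
                )
            )
    sites.sort(key=lambda s: (s.atom.residue_key, s.atom.atom_name))
    return sites


def _resolve_neighbors(
    acceptor: AtomSite, residue_atoms: Sequence[AtomSite], names: tuple[str, ...]
) -> tuple[AtomSite, ...]:
    found = []
    for name in names:
        for atom in residue_atoms:
            if atom.atom_name == name and atom.altloc in ("", acceptor.altloc):
                found.append(atom)
                break
    return tuple(found)


def find_atomic_acceptors(
    site: HalogenSite,
    atoms: Sequence[AtomSite],
    max_d: float = 4.0,
    survey: bool = False,
    vdw_table: Mapping[str, float] | None = None,
) -> list[HalogenBondCandidate]:
    """Atomic acceptor candidates within ``max_d`` of the halogen.

    In the default (scoring) mode acceptors are O/S atoms of canonical
    amino acids whose covalent neighbors are all carbon — the O-C and S-C
    classes.  ``survey=True`` widens discovery to any O/N/S/P/Se atom in a
    non-water organic compound (category "other" unless O-C/S-C applies);
    survey candidates without resolvable neighbors are dropped with a
    logged reason, since θ2 cannot be measured for them.
    Contacts inside the halogen's own residue are never candidates.
    """
    candidates: list[HalogenBondCandidate] = []
    by_residue = _group_by_residue(atoms)
    x = site.atom
    survey_elements = frozenset({"O", "N", "S", "P", "Se"})
    for key, residue_atoms in by_residue.items():
        if key == x.residue_key:
            continue  # intra-compound contact
        res_name = residue_atoms[0].residue_name
        for atom in residue_atoms:
            if atom.is_water:
                continue  # θ2 undefined for water; excluded by design
            is_tabulated = (res_name, atom.atom_name) in _ACCEPTOR_NEIGHBORS
            if not survey and not is_tabulated:
                continue
            if survey and atom.element not in survey_elements:
                continue
            if not survey and atom.element not in ("O", "S"):
                continue
            d = distance(x.position, atom.position)
            if d > max_d:
                continue
            if is_tabulated:
                neighbor_names = _ACCEPTOR_NEIGHBORS[(res_name, atom.atom_name)]
                neighbors = _resolve_neighbors(atom, residue_atoms, neighbor_names)
                category = "O-C" if atom.element == "O" else "S-C"
            else:
                neighbors = _fallback_neighbors(atom, residue_atoms)
                category = "other"
            if not neighbors:
                logger.info(
                    "acceptor %s %s/%s%s has no resolvable covalent neighbor; "
                    "candidate rejected (theta2 undefined)",
                    atom.atom_name, res_name, key[0], key[1],
                )
                continue
            geometry = compute_bond_geometry(
                x.position,
                x.element,
                site.parent_carbon.position,
                atom.position,
                acceptor_element=atom.element,
                neighbor_positions=[nb.position for nb in neighbors],
                vdw_table=vdw_table,
            )
            acceptor = AtomicAcceptor(
                atom=atom,
                neighbors=neighbors,
                category=category,
                canonical=res_name in CANONICAL_AMINO_ACIDS,
            )
            candidates.append(
                HalogenBondCandidate(halogen=site, acceptor=acceptor, geometry=geometry)
            )
    candidates.sort(key=HalogenBondCandidate._sort_key)
    return candidates


def _fallback_neighbors(
    acceptor: AtomSite, residue_atoms: Sequence[AtomSite]
) -> tuple[AtomSite, ...]:
    """Covalent neighbors by bond-distance heuristic (no dictionary)."""
    radius = _BOND_FALLBACK_RADIUS.get(acceptor.element, _BOND_FALLBACK_DEFAULT)
    out = []
    for atom in residue_atoms:
        if atom is acceptor or atom.element == "H":
            continue
        if distance(acceptor.position, atom.position) <= radius:
            out.append(atom)
    return tuple(out)


def find_pi_acceptors(
    site: HalogenSite,
    atoms: Sequence[AtomSite],
    max_d: float = 6.0,
    trp_rings: Literal["separate", "whole"] = "separate",
) -> list[HalogenBondCandidate]:
    """π-system candidates: His/Phe/Tyr/Trp rings whose centroid lies
    within ``max_d`` of the halogen; θ1 is measured to the centroid.

    Residues with incomplete rings are skipped with a logged reason.
    """
    candidates: list[HalogenBondCandidate] = []
    by_residue = _group_by_residue(atoms)
    x = site.atom
    for key, residue_atoms in by_residue.items():
        if key == x.residue_key:
            continue
        res_name = residue_atoms[0].residue_name
        if res_name not in _RING_ATOMS:
            continue
        if res_name == "TRP" and trp_rings == "whole":
            ring_sets: tuple[tuple[str, ...], ...] = (_TRP_WHOLE_RING,)
        else:
            ring_sets = _RING_ATOMS[res_name]
        for ring_names in ring_sets:
            ring = _resolve_neighbors(residue_atoms[0], residue_atoms, ring_names)
            if len(ring) < len(ring_names):
                missing = set(ring_names) - {a.atom_name for a in ring}
                logger.info(
                    "incomplete %s ring at %s/%s (missing %s); skipped",
                    res_name, key[0], key[1], ",".join(sorted(missing)),
                )
                continue
            centroid = ring_centroid([a.position for a in ring])
            d = distance(x.position, centroid)
            if d > max_d:
                continue
            geometry = compute_bond_geometry(
                x.position, x.element, site.parent_carbon.position, centroid
            )
            acceptor = PiAcceptor(
                residue_name=res_name,
                chain_id=key[0],
                residue_seq=key[1],
                icode=key[2],
                ring_atoms=ring,
                centroid=centroid,
                category=_PI_CLASS[res_name],
            )
            candidates.append(
                HalogenBondCandidate(halogen=site, acceptor=acceptor, geometry=geometry)
            )
    candidates.sort(key=HalogenBondCandidate._sort_key)
    return candidates


def apply_theta1_filter(
    candidates: Iterable[HalogenBondCandidate],
) -> list[HalogenBondCandidate]:
    """Keep only candidates with θ1 strictly greater than 90°.

    At θ1 ≤ 90° the acceptor sits on the covalent-bond side of the
    halogen, where the σ-hole is unreachable.
    """
    return [c for c in candidates if c.geometry.theta1 > 90.0]


def select_mining_acceptor(
    candidates: Sequence[HalogenBondCandidate],
) -> HalogenBondCandidate | None:
    """The single acceptor kept per halogen when building reference
    distributions: the one with θ1 closest to 180°.  Exact θ1 ties break
    by smaller d, then by acceptor residue order, for determinism."""
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (-c.geometry.theta1, c.geometry.d, c._sort_key()),
    )


def detect_candidates(
    atoms: Sequence[AtomSite],
    dictionary: Mapping[str, CompoundRecord] | None = None,
    max_d_atomic: float = 4.0,
    max_d_pi: float = 6.0,
    trp_rings: Literal["separate", "whole"] = "separate",
    vdw_table: Mapping[str, float] | None = None,
) -> dict[HalogenSite, list[HalogenBondCandidate]]:
    """Full detection pass: θ1-filtered candidates grouped per halogen site."""
    out: dict[HalogenSite, list[HalogenBondCandidate]] = {}
    for site in find_halogen_sites(atoms, dictionary):
        cands = find_atomic_acceptors(site, atoms, max_d=max_d_atomic, vdw_table=vdw_table)
        cands += find_pi_acceptors(site, atoms, max_d=max_d_pi, trp_rings=trp_rings)
        out[site] = apply_theta1_filter(cands)
    return out
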