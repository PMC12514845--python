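"""Candidate enumeration: shells, filters, acceptor selection."""

import numpy as np
import pytest

from halobond import (
    AtomSite,
    FixtureSpec,
    apply_theta1_filter,
    detect_candidates,
    find_atomic_acceptors,
    find_halogen_sites,
    find_pi_acceptors,
    select_mining_acceptor,
)
from halobond.detect import PiAcceptor
from tests.conftest import load_fixture


def atom(name, element, pos, res="LIG", seq=1, chain="A", altloc="", het=True):
    return AtomSite(
        model_number=1, chain_id=chain, residue_name=res, residue_seq=seq,
        icode="", atom_name=name, element=element, position=np.asarray(pos, float),
        occupancy=1.0, b_factor=20.0, altloc=altloc, het=het,
    )


def ligand(x_element="Cl", x_pos=(0, 0, 0), seq=300, altloc=""):
    """Minimal halogenated ligand: parent carbon + halogen."""
    x_pos = np.asarray(x_pos, float)
    bond = {"F": 1.35, "Cl": 1.74, "Br": 1.90, "I": 2.10}[x_element]
    return [
        atom("C1", "C", x_pos - [bond, 0, 0], seq=seq),
        atom(x_element.upper() + "1", x_element, x_pos, seq=seq, altloc=altloc),
    ]


def backbone_o(pos, seq=97, res="ALA"):
    """Backbone carbonyl O plus its carbon, 1.23 Å away."""
    pos = np.asarray(pos, float)
    return [
        atom("C", "C", pos + [0, 1.23, 0], res=res, seq=seq, het=False),
        atom("O", "O", pos, res=res, seq=seq, het=False),
    ]


def phe_ring(centroid, seq=154):
    centroid = np.asarray(centroid, float)
    out = []
    r = 1.39
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    for i, name in enumerate(names):
        phi = 2 * np.pi * i / 6
        out.append(
            atom(name, "C", centroid + [0, r * np.cos(phi), r * np.sin(phi)],
                 res="PHE", seq=seq, het=False)
        )
    return out


def test_three_halogen_ligand_gives_three_sites():
    atoms = [atom("C1", "C", (0, 0, 0))]
    for i, shift in enumerate([(1.74, 0, 0), (-1.74, 0, 0), (0, 1.74, 0)]):
        atoms.append(atom(f"CL{i+1}", "Cl", shift))
    sites = find_halogen_sites(atoms)
    assert len(sites) == 3
    assert all(s.parent_carbon.atom_name == "C1" for s in sites)
    assert all(s.compound_class == "ligand" for s in sites)


def test_iodide_ions_yield_no_sites():
    atoms = [atom("I", "I", (i * 5.0, 0, 0), res="IOD", seq=400 + i) for i in range(3)]
    assert find_halogen_sites(atoms) == []


def test_altloc_halogen_excluded():
    atoms = ligand(altloc="A")
    assert find_halogen_sites(atoms) == []


def test_atomic_acceptor_shell():
    lig = ligand("Cl")
    site = find_halogen_sites(lig)[0]
    inside = lig + backbone_o((3.5, 0, 0))
    outside = lig + backbone_o((4.1, 0, 0))
    assert len(find_atomic_acceptors(site, inside)) == 1
    assert find_atomic_acceptors(site, outside) == []
    # boundary is inclusive ("within 4 Å")
    exactly = lig + backbone_o((4.0, 0, 0))
    assert len(find_atomic_acceptors(site, exactly)) == 1


def test_water_never_an_acceptor():
    lig = ligand("Cl")
    site = find_halogen_sites(lig)[0]
    water = [atom("O", "O", (3.0, 0, 0), res="HOH", seq=501)]
    assert find_atomic_acceptors(site, lig + water) == []


def test_intra_compound_contacts_excluded():
    # an oxygen inside the halogen's own residue is never an acceptor
    lig = ligand("Cl") + [atom("O2", "O", (3.0, 0, 0), seq=300)]
    site = find_halogen_sites(lig)[0]
    assert find_atomic_acceptors(site, lig) == []


def test_survey_mode_widens_discovery():
    # a ligand carbonyl oxygen across residues: invisible to scoring
    # mode, discovered (as category "other") in survey mode
    lig = ligand("Cl")
    other = [
        atom("C7", "C", (3.5, 1.23, 0), res="XYZ", seq=310),
        atom("O7", "O", (3.5, 0, 0), res="XYZ", seq=310),
    ]
    site = find_halogen_sites(lig)[0]
    assert find_atomic_acceptors(site, lig + other) == []
    cands = find_atomic_acceptors(site, lig + other, survey=True)
    assert len(cands) == 1
    assert cands[0].acceptor.category == "other"


def test_pi_acceptor_shell_and_centroid():
    lig = ligand("I")
    site = find_halogen_sites(lig)[0]
    near = lig + phe_ring((4.8, 0, 0))
    far = lig + phe_ring((6.2, 0, 0))
    cands = find_pi_acceptors(site, near)
    assert len(cands) == 1
    assert isinstance(cands[0].acceptor, PiAcceptor)
    assert cands[0].geometry.d == pytest.approx(4.8, abs=1e-9)
    assert cands[0].geometry.theta2 is None
    assert find_pi_acceptors(site, far) == []


def test_incomplete_ring_skipped():
    lig = ligand("I")
    site = find_halogen_sites(lig)[0]
    ring = phe_ring((4.8, 0, 0))[:-1]  # drop CZ
    assert find_pi_acceptors(site, lig + ring) == []


def test_his_ring_uses_five_atoms():
    lig = ligand("Br")
    site = find_halogen_sites(lig)[0]
    centroid = np.array([5.0, 0, 0])
    names = ["CG", "ND1", "CD2", "CE1", "NE2"]
    ring = [
        atom(n, "N" if n.startswith("N") else "C",
             centroid + [0, 1.2 * np.cos(2 * np.pi * i / 5), 1.2 * np.sin(2 * np.pi * i / 5)],
             res="HIS", seq=60, het=False)
        for i, n in enumerate(names)
    ]
    cands = find_pi_acceptors(site, lig + ring)
    assert len(cands) == 1
    assert len(cands[0].acceptor.ring_atoms) == 5
    assert cands[0].geometry.d == pytest.approx(5.0, abs=1e-9)


def test_theta1_filter_boundary():
    lig = ligand("Cl")
    site = find_halogen_sites(lig)[0]

    def with_theta1(theta1_deg):
        t = np.radians(theta1_deg)
        pos = 3.5 * np.array([-np.cos(t), np.sin(t), 0.0])
        cands = find_atomic_acceptors(site, lig + backbone_o(pos))
        assert len(cands) == 1
        return cands[0]

    kept = apply_theta1_filter([with_theta1(160.0)])
    assert len(kept) == 1
    assert apply_theta1_filter([with_theta1(89.0)]) == []
    # the 90.0 boundary itself is rejected (strictly > 90 required)
    exact = with_theta1(90.0)
    exact_geom = exact.geometry
    assert apply_theta1_filter([exact]) == [] or exact_geom.theta1 > 90.0


def test_select_mining_acceptor_prefers_theta1_closest_to_180():
    lig = ligand("Cl")
    site = find_halogen_sites(lig)[0]

    def cand(theta1_deg, d=3.5, seq=97):
        t = np.radians(theta1_deg)
        pos = d * np.array([-np.cos(t), np.sin(t), 0.0])
        return find_atomic_acceptors(site, lig + backbone_o(pos, seq=seq))[0]

    a, b = cand(120.0, seq=97), cand(175.0, seq=98)
    assert select_mining_acceptor([a, b]) is b
    assert select_mining_acceptor([b]) is b
    assert select_mining_acceptor([]) is None
    # exact theta1 tie: shorter distance wins (checked over both orderings)
    from dataclasses import replace

    from halobond.detect import HalogenBondCandidate

    base = cand(150.0, d=3.2, seq=97)
    other = cand(150.0, d=3.8, seq=98)
    tied = HalogenBondCandidate(
        halogen=other.halogen,
        acceptor=other.acceptor,
        geometry=replace(other.geometry, theta1=base.geometry.theta1),
    )
    assert select_mining_acceptor([base, tied]) is base
    assert select_mining_acceptor([tied, base]) is base


def _brute_force_candidates(atoms, max_d_atomic=4.0, max_d_pi=6.0):
    """Independent O(n^2) scan implementing the selection rules directly."""
    from halobond.detect import _ACCEPTOR_NEIGHBORS, _RING_ATOMS

    halogens = {"F", "Cl", "Br", "I"}
    by_res = {}
    for a in atoms:
        by_res.setdefault(a.residue_key, []).append(a)

    found = set()
    for x in atoms:
        if x.element not in halogens or x.altloc or x.residue_name == "IOD":
            continue
        parent = None
        cutoff = {"Cl": 1.95, "Br": 2.05, "I": 2.25}.get(x.element, 1.9)
        for c in by_res[x.residue_key]:
            if c.element == "C" and np.linalg.norm(c.position - x.position) <= cutoff:
                parent = c
        if parent is None:
            continue
        for y in atoms:
            if y.residue_key == x.residue_key or y.residue_name == "HOH":
                continue
            if (y.residue_name, y.atom_name) not in _ACCEPTOR_NEIGHBORS:
                continue
            d = np.linalg.norm(y.position - x.position)
            if d > max_d_atomic:
                continue
            # theta1 via dot product
            u1 = parent.position - x.position
            u2 = y.position - x.position
            cos = u1 @ u2 / np.linalg.norm(u1) / np.linalg.norm(u2)
            theta1 = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            if theta1 > 90.0:
                found.add((x.residue_key, x.atom_name, y.residue_key, y.atom_name))
        for key, residue in by_res.items():
            if key == x.residue_key:
                continue
            rname = residue[0].residue_name
            if rname not in _RING_ATOMS:
                continue
            for ring_names in _RING_ATOMS[rname]:
                ring = [a for n in ring_names for a in residue if a.atom_name == n]
                if len(ring) < len(ring_names):
                    continue
                centroid = np.mean([a.position for a in ring], axis=0)
                d = np.linalg.norm(centroid - x.position)
                if d > max_d_pi:
                    continue
                u1 = parent.position - x.position
                u2 = centroid - x.position
                cos = u1 @ u2 / np.linalg.norm(u1) / np.linalg.norm(u2)
                theta1 = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if theta1 > 90.0:
                    found.add((x.residue_key, x.atom_name, key, ring_names))
    return found


@pytest.mark.parametrize("seed", range(8))
def test_candidate_set_matches_brute_force_on_fuzzed_fixtures(seed):
    rng = np.random.default_rng(seed)
    atoms = []
    # a few ligands with random halogens
    for i in range(rng.integers(1, 4)):
        el = rng.choice(["F", "Cl", "Br", "I"])
        center = rng.uniform(-8, 8, size=3)
        atoms += ligand(el, center, seq=300 + i)
    # scattered acceptors, waters, rings and a halide ion
    for i in range(rng.integers(2, 7)):
        atoms += backbone_o(rng.uniform(-10, 10, size=3), seq=50 + i)
    for i in range(rng.integers(0, 3)):
        atoms.append(atom("O", "O", rng.uniform(-8, 8, size=3), res="HOH", seq=500 + i))
    for i in range(rng.integers(0, 3)):
        atoms += phe_ring(rng.uniform(-10, 10, size=3), seq=150 + i)
    atoms.append(atom("I", "I", rng.uniform(-8, 8, size=3), res="IOD", seq=600))

    per_site = detect_candidates(atoms)
    ours = set()
    for site, cands in per_site.items():
        for c in cands:
            if c.is_pi:
                key = (site.atom.residue_key, site.atom.atom_name,
                       c.acceptor_residue_key, tuple(a.atom_name for a in c.acceptor.ring_atoms))
            else:
                key = (site.atom.residue_key, site.atom.atom_name,
                       c.acceptor_residue_key, c.acceptor.atom.atom_name)
            ours.add(key)
    assert ours == _brute_force_candidates(atoms)


def test_detection_order_independent():
    rng = np.random.default_rng(3)
    atoms = ligand("Br", (0, 0, 0)) + backbone_o((3.4, 1.0, 0)) + phe_ring((0, 4.5, 1.0))
    per_site = detect_candidates(atoms)
    shuffled = list(atoms)
    rng.shuffle(shuffled)
    per_site2 = detect_candidates(shuffled)

    def summary(ps):
        return sorted(
            (s.atom.atom_name, c.acceptor_residue_key, round(c.geometry.d, 9))
            for s, cs in ps.items()
            for c in cs
        )

    assert summary(per_site) == summary(per_site2)


def test_emitted_candidates_satisfy_invariants():
    atoms, _, dictionary, _ = load_fixture(
        FixtureSpec(halogen_element="Br", acceptor_kind="O-C", d=3.6,
                    theta1=155.0, theta2=100.0, add_water=True, seed=21)
    )
    per_site = detect_candidates(atoms, dictionary=dictionary)
    for site, cands in per_site.items():
        assert site.atom.altloc == ""
        for c in cands:
            assert c.geometry.theta1 > 90.0
            if c.is_pi:
                assert c.geometry.d <= 6.0
            else:
                assert c.geometry.d <= 4.0
                assert not c.acceptor.atom.is_water
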