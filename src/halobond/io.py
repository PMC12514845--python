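"""Structure-model and chemical-component input.

All mmCIF/PDB parsing is delegated to :mod:`gemmi`; this module flattens
gemmi's hierarchy into plain :class:`AtomSite` records carrying the
author-facing identifiers (chain, residue number) that reports use, and
reads CCD-style chemical-component definitions (atoms plus covalent
bonds) needed to find the carbon each halogen hangs off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSite",
    "CompoundRecord",
    "ModelMetadata",
    "EXCLUDED_COMPOUND_IDS",
    "excluded_compound_ids",
    "load_compound_dictionary",
    "read_structure",
    "read_structure_string",
]

#: Halogen-containing CCD components excluded from halogen-bond analysis:
#: the bare halide ions and compounds whose halogen is not carbon-bonded
#: (halogen-metal complexes, halogen acids, and similar).
EXCLUDED_COMPOUND_IDS: frozenset[str] = frozenset(
    """
    F CL BR IOD 08T 0JC 0OD 0TE 202 2T8 4IR 4KV 5LN 61C 61D 6BP 6O0 73M
    7GE 8TH 8TR 8WV 9QB 9RU 9TH A9J AF3 ALF BE7 BEF BF2 BF4 BFD BPT C2C
    C7P CFO CPT CUL D0X D7Z DAA DAE DAQ E3D E5O ELJ F6Q F7T FPO HG2 HGI
    I2I I3M I83 J0K J0N JR3 KQB KYS KYT LCO LCP LN8 MF4 MGF MNQ N2N N2R
    N2S N2W NG8 NMQ NXC O1N ONP ORS OS1 OT1 P3C PC4 PCL PEJ PNQ PT7 QLT
    R1N RAX RBN RHE RSW RU0 RU7 RUD RUH SFL SRX SVP SXC TBR TPT U0J VKZ
    VL2 YPT YXX YXZ ZN0 ZN5 ZN6 ZN7 ZN8 ZN9 ZPT
    """.split()
)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def excluded_compound_ids() -> frozenset[str]:
    """CCD identifiers of halogen-containing compounds excluded from analysis."""
    return EXCLUDED_COMPOUND_IDS


@dataclass(frozen=True, eq=False)
class AtomSite:
    """One atom record, flattened from the structure hierarchy.

    ``chain_id``/``residue_seq``/``icode`` are the author identifiers (the
    numbering papers and reports cite, e.g. "Ala A97"); ``label_asym``
    keeps the label chain for internal joins.
    """

    model_number: int
    chain_id: str
    residue_name: str
    residue_seq: int
    icode: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    het: bool = False
    label_asym: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy out of [0, 1]: {self.occupancy}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor: {self.b_factor}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, seq, icode): identifies the residue this atom belongs to."""
        return (self.chain_id, self.residue_seq, self.icode)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES


@dataclass
class ModelMetadata:
    """Experiment/refinement metadata consumed by calibration filtering.

    Any field absent from the source file stays None ("missing"), never 0.
    RSCC values are per-compound real-space correlation coefficients keyed
    by (chain, residue_seq); they are consumed from sidecar files, never
    computed here.
    """

    entry_id: str | None = None
    resolution: float | None = None
    r_factor: float | None = None
    r_free: float | None = None
    mean_b: float | None = None
    per_compound_rscc: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"resolution must be positive: {self.resolution}")
        for key, rscc in self.per_compound_rscc.items():
            if not -1.0 <= rscc <= 1.0:
                raise ValueError(f"RSCC out of [-1, 1] for {key}: {rscc}")


@dataclass
class CompoundRecord:
    """One chemical component: identity, type, halogens and connectivity."""

    ccd_id: str
    component_type: str = "non-polymer"
    atoms: dict[str, str] = field(default_factory=dict)  # atom name -> element
    bonds: list[tuple[str, str]] = field(default_factory=list)
    excluded: bool = False

    @property
    def halogen_atom_names(self) -> list[str]:
        return [n for n, el in self.atoms.items() if el in HALOGENS]

    def bonded_atoms(self, atom_name: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == atom_name:
                out.append(b)
            elif b == atom_name:
                out.append(a)
        return out

    def halogen_parent_carbon(self, halogen_name: str) -> str | None:
        """Name of the carbon bonded to the halogen, or None if the halogen
        is not bonded to exactly one carbon (such halogens are unscorable)."""
        neighbors = self.bonded_atoms(halogen_name)
        carbons = [n for n in neighbors if self.atoms.get(n) == "C"]
        if len(carbons) == 1:
            return carbons[0]
        return None

    @property
    def unscorable_halogens(self) -> list[str]:
        """Halogens with no single carbon parent (flagged, not dropped)."""
        return [
            h for h in self.halogen_atom_names
            if self.halogen_parent_carbon(h) is None
        ]


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name
    if el in ("X", ""):
        # unknown element: infer from the atom name's leading letters
        guess = "".join(c for c in atom.name if c.isalpha())[:2].capitalize()
        if gemmi.Element(guess).atomic_number > 0:
            logger.warning(
                "unknown element for atom %s; inferred %s from its name",
                atom.name, guess,
            )
            return guess
        logger.warning("unknown element for atom %s; kept as-is", atom.name)
        return el
    return el


def _flatten(structure: gemmi.Structure, all_models: bool) -> list[AtomSite]:
    sites: list[AtomSite] = []
    if all_models:
        models = list(structure)
    else:
        models = [structure[0]] if len(structure) else []
    for model in models:
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    sites.append(
                        AtomSite(
                            model_number=model.num,
                            chain_id=chain.name,
                            residue_name=residue.name,
                            residue_seq=residue.seqid.num,
                            icode=residue.seqid.icode.strip(),
                            atom_name=atom.name,
                            element=_element_of(atom),
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            occupancy=min(max(atom.occ, 0.0), 1.0),
                            b_factor=max(atom.b_iso, 0.0),
                            altloc=atom.altloc if atom.altloc != "\0" else "",
                            het=het,
                            label_asym=residue.subchain,
                        )
                    )
    return sites


def _cif_float(block: gemmi.cif.Block, item: str) -> float | None:
    val = block.find_value(item)
    if val is None or val in ("?", "."):
        return None
    try:
        return float(gemmi.cif.as_string(val) or val)
    except ValueError:
        return None


def _metadata_from_block(block: gemmi.cif.Block) -> ModelMetadata:
    entry = block.find_value("_entry.id")
    return ModelMetadata(
        entry_id=gemmi.cif.as_string(entry) if entry else block.name or None,
        resolution=_cif_float(block, "_refine.ls_d_res_high"),
        r_factor=(
            _cif_float(block, "_refine.ls_R_factor_R_work")
            or _cif_float(block, "_refine.ls_R_factor_obs")
        ),
        r_free=_cif_float(block, "_refine.ls_R_factor_R_free"),
        mean_b=_cif_float(block, "_refine.B_iso_mean"),
    )


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="ignore")[:4096]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def read_structure(
    path: str | Path,
    format: str = "auto",
    all_models: bool = False,
) -> tuple[list[AtomSite], ModelMetadata]:
    """Read a structure model file into flat atom records plus metadata.

    By default only the first model of a multi-model file is returned
    (crystallographic files have one; set ``all_models`` for ensembles).
    Metadata items missing from the file are None.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "mmcif":
        try:
            doc = gemmi.cif.read(str(path))
        except (RuntimeError, ValueError) as exc:
            raise ValueError(f"cannot parse mmCIF {path}: {exc}") from None
        return _structure_from_document(doc, all_models)
    if fmt == "pdb":
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError) as exc:
            raise ValueError(f"cannot parse PDB {path}: {exc}") from None
        st.setup_entities()
        meta = ModelMetadata(
            entry_id=st.name or None,
            resolution=st.resolution if st.resolution > 0 else None,
        )
        return _flatten(st, all_models), meta
    raise ValueError(f"unknown structure format: {format!r}")


def read_structure_string(
    text: str, format: str = "mmcif", all_models: bool = False
) -> tuple[list[AtomSite], ModelMetadata]:
    """Parse structure text already in memory (fixtures, tests, pipes)."""
    if format == "mmcif":
        doc = gemmi.cif.read_string(text)
        return _structure_from_document(doc, all_models)
    if format == "pdb":
        st = gemmi.read_pdb_string(text)
        st.setup_entities()
        meta = ModelMetadata(
            entry_id=st.name or None,
            resolution=st.resolution if st.resolution > 0 else None,
        )
        return _flatten(st, all_models), meta
    raise ValueError(f"unknown structure format: {format!r}")


def _structure_from_document(
    doc: gemmi.cif.Document, all_models: bool
) -> tuple[list[AtomSite], ModelMetadata]:
    block = doc.sole_block() if len(doc) == 1 else doc[0]
    st = gemmi.make_structure_from_block(block)
    st.setup_entities()
    meta = _metadata_from_block(block)
    return _flatten(st, all_models), meta


def _compounds_from_block(block: gemmi.cif.Block) -> dict[str, CompoundRecord]:
    """Extract chem_comp_atom / chem_comp_bond categories from one block."""
    records: dict[str, CompoundRecord] = {}
    comp_types: dict[str, str] = {}
    type_table = block.find("_chem_comp.", ["id", "?type"])
    for row in type_table:
        cid = gemmi.cif.as_string(row[0])
        if type_table.has_column(1):
            comp_types[cid] = gemmi.cif.as_string(row[1]).lower()
    atom_table = block.find("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"])
    for row in atom_table:
        cid = gemmi.cif.as_string(row[0])
        rec = records.setdefault(
            cid,
            CompoundRecord(
                ccd_id=cid,
                component_type=comp_types.get(cid, "non-polymer"),
                excluded=cid in EXCLUDED_COMPOUND_IDS,
            ),
        )
        name = gemmi.cif.as_string(row[1])
        element = gemmi.cif.as_string(row[2]).capitalize()
        rec.atoms[name] = element
    bond_table = block.find("_chem_comp_bond.", ["comp_id", "atom_id_1", "atom_id_2"])
    for row in bond_table:
        cid = gemmi.cif.as_string(row[0])
        if cid in records:
            records[cid].bonds.append(
                (gemmi.cif.as_string(row[1]), gemmi.cif.as_string(row[2]))
            )
    return records


def load_compound_dictionary(
    source: str | Path | gemmi.cif.Document,
) -> dict[str, CompoundRecord]:
    """Load CCD-style component definitions.

    Accepts a full CCD dump (one block per component), a single-component
    file, or an mmCIF entry with embedded ``chem_comp_atom``/
    ``chem_comp_bond`` loops.  Only halogen-containing components are
    indexed.  Components on the exclusion list are marked ``excluded``;
    halogens without a unique carbon parent are flagged unscorable via
    :attr:`CompoundRecord.unscorable_halogens` (never dropped silently).
    """
    if isinstance(source, gemmi.cif.Document):
        doc = source
    else:
        doc = gemmi.cif.read(str(source))
    out: dict[str, CompoundRecord] = {}
    for block in doc:
        for cid, rec in _compounds_from_block(block).items():
            if not rec.halogen_atom_names:
                continue
            if not rec.bonds and rec.atoms.keys() - set(rec.halogen_atom_names):
                logger.warning(
                    "component %s has no bond records; its halogens are "
                    "unscorable without connectivity", cid,
                )
            out[cid] = rec
    return out


def merge_compound_dictionaries(
    base: dict[str, CompoundRecord],
    override: dict[str, CompoundRecord],
) -> dict[str, CompoundRecord]:
    """Merge dictionaries; entries in ``override`` (e.g. blocks embedded in
    the structure file itself) win on conflict."""
    merged = dict(base)
    merged.update(override)
    return merged
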