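"""Report writers: per-bond TSV, nested JSON, and an mmCIF-style summary block.

The TSV prints geometry at 2 decimals (Å) / 1 decimal (degrees) and
scores at 2 decimals; the JSON carries full precision.  The mmCIF block
uses the namespaced category ``_halobond_summary`` with items
``halogen_bond_count`` and ``mean_halbs`` (this package's own naming,
documented here, not claimed compatible with any other producer).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .detect import PiAcceptor
from .scoring import ModelSummary, ScoredBond

__all__ = [
    "bonds_to_frame",
    "write_json",
    "write_mmcif_block",
    "write_tsv",
]

_TSV_COLUMNS = [
    "chain", "residue", "seq", "atom", "halogen",
    "acceptor_chain", "acceptor_residue", "acceptor_seq", "acceptor_atom",
    "acceptor_class", "d", "vdw_overlap", "theta1", "theta2",
    "score_distance", "score_theta1", "score_theta2",
    "halbs", "classification",
]


def _bond_record(bond: ScoredBond) -> dict:
    cand = bond.candidate
    x = cand.halogen.atom
    acc = cand.acceptor
    geom = cand.geometry
    if isinstance(acc, PiAcceptor):
        acc_fields = dict(
            acceptor_chain=acc.chain_id,
            acceptor_residue=acc.residue_name,
            acceptor_seq=acc.residue_seq,
            acceptor_atom="ring",
        )
    else:
        acc_fields = dict(
            acceptor_chain=acc.atom.chain_id,
            acceptor_residue=acc.atom.residue_name,
            acceptor_seq=acc.atom.residue_seq,
            acceptor_atom=acc.atom.atom_name,
        )
    return dict(
        chain=x.chain_id,
        residue=x.residue_name,
        seq=x.residue_seq,
        atom=x.atom_name,
        halogen=x.element,
        **acc_fields,
        acceptor_class=acc.category,
        d=geom.d,
        vdw_overlap=geom.vdw_overlap,
        theta1=geom.theta1,
        theta2=bond.theta2,
        score_distance=bond.score_distance,
        score_theta1=bond.score_theta1,
        score_theta2=bond.score_theta2,
        halbs=bond.halbs,
        classification=bond.classification or bond.unscored_reason,
    )


def bonds_to_frame(bonds: Iterable[ScoredBond]) -> pd.DataFrame:
    """One row per reported bond, full precision."""
    records = [_bond_record(b) for b in bonds]
    return pd.DataFrame(records, columns=_TSV_COLUMNS)


def _round_for_tsv(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in ("d", "vdw_overlap"):
        out[col] = out[col].map(lambda v: None if _missing(v) else f"{v:.2f}")
    for col in ("theta1", "theta2"):
        out[col] = out[col].map(lambda v: None if _missing(v) else f"{v:.1f}")
    for col in ("score_distance", "score_theta1", "score_theta2", "halbs"):
        out[col] = out[col].map(lambda v: None if _missing(v) else f"{v:.2f}")
    return out


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def write_tsv(bonds: Sequence[ScoredBond], path_or_buffer) -> None:
    frame = _round_for_tsv(bonds_to_frame(bonds))
    frame.to_csv(path_or_buffer, sep="\t", index=False, na_rep=".")


def write_json(
    bonds: Sequence[ScoredBond],
    summary: ModelSummary,
    path_or_buffer,
    entry_id: str | None = None,
) -> None:
    payload = {
        "entry_id": entry_id,
        "summary": summary.as_dict(),
        "bonds": [_bond_record(b) for b in bonds],
    }
    if hasattr(path_or_buffer, "write"):
        json.dump(payload, path_or_buffer, indent=1)
        path_or_buffer.write("\n")
    else:
        Path(path_or_buffer).write_text(json.dumps(payload, indent=1) + "\n")


def write_mmcif_block(
    summary: ModelSummary, path_or_buffer, entry_id: str | None = None
) -> None:
    """Per-model summary as a small namespaced mmCIF key-value block."""
    mean = "." if summary.mean_halbs is None else f"{summary.mean_halbs:.2f}"
    text = (
        f"data_{entry_id or 'model'}\n"
        f"_halobond_summary.halogen_bond_count {summary.n_bonds}\n"
        f"_halobond_summary.mean_halbs {mean}\n"
    )
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        Path(path_or_buffer).write_text(text)
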