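"""Derivation of reference boxplot statistics from a structure corpus.

The reference distributions behind the score are built from observed
ligand-protein halogen bonds in well-determined models only: the halogen
atom must be reliably placed (B-factor ≤ 100 Å², compound RSCC ≥ 0.9 for
both partners, resolution at least 2.5 Å), the halogen must sit in a
ligand (a "non-polymer" component) and the acceptor in a canonical amino
acid.  One acceptor per halogen is kept — the one with θ1 closest to
180°, i.e. closest to the σ-hole axis — and per (halogen, acceptor class,
parameter) cell the boxplot statistics (n, mean, median, Q1, Q3, MAD)
are computed.  Cells with fewer than five observations are omitted, as
are cells with zero IQR (the score is undefined there).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import (
    HalogenBondCandidate,
    PiAcceptor,
    apply_theta1_filter,
    detect_candidates,
    select_mining_acceptor,
)
from .io import AtomSite, CompoundRecord, ModelMetadata
from .scoring import ACCEPTOR_CLASSES, CategoryStats, ReferenceStats

logger = logging.getLogger(__name__)

__all__ = [
    "BoxplotStats",
    "QualityThresholds",
    "boxplot_stats",
    "calibrate",
    "quality_filter",
    "restrict_to_ligand_protein",
]


@dataclass(frozen=True)
class QualityThresholds:
    """Quality-filter settings; the defaults are the calibration criteria
    described in the module docstring."""

    max_b_factor: float = 100.0   # Å², halogen atom
    min_rscc: float = 0.9         # per-compound real-space CC
    max_resolution: float = 2.5   # Å
    min_category_n: int = 5

    def __post_init__(self) -> None:
        for name in ("max_b_factor", "min_rscc", "max_resolution", "min_category_n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def quality_filter(
    candidate: HalogenBondCandidate,
    meta: ModelMetadata,
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[bool, str | None]:
    """Keep/reject one candidate for calibration, with a reason code.

    Boundary values survive: B exactly 100 Å², RSCC exactly 0.9 and
    resolution exactly 2.5 Å all pass ("worse than" is strict).  Missing
    metadata rejects with an "unverifiable" reason — calibration only
    accepts observations whose quality can be verified.
    """
    if meta.resolution is None:
        return False, "unverifiable:resolution"
    if meta.resolution > thresholds.max_resolution:
        return False, "resolution"
    if candidate.halogen.atom.b_factor > thresholds.max_b_factor:
        return False, "b_factor"
    hal_key = (
        candidate.halogen.atom.chain_id,
        candidate.halogen.atom.residue_seq,
    )
    acc_key = candidate.acceptor_residue_key[:2]
    for key, tag in ((hal_key, "halogen"), (acc_key, "acceptor")):
        rscc = meta.per_compound_rscc.get(key)
        if rscc is None:
            return False, f"unverifiable:rscc:{tag}"
        if rscc < thresholds.min_rscc:
            return False, f"rscc:{tag}"
    return True, None


def restrict_to_ligand_protein(
    candidates: Iterable[HalogenBondCandidate],
) -> list[HalogenBondCandidate]:
    """Keep only halogens in ligands whose acceptor is a canonical amino
    acid — the population the reference distributions describe."""
    kept = []
    for c in candidates:
        if c.halogen.compound_class != "ligand":
            continue
        if isinstance(c.acceptor, PiAcceptor):
            kept.append(c)  # π residues are canonical by construction
        elif c.acceptor.canonical:
            kept.append(c)
    return kept


@dataclass(frozen=True)
class BoxplotStats:
    """n, mean, median, Q1, Q3 and MAD of one sample."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    mad: float


def boxplot_stats(
    values: Sequence[float],
    min_n: int = 5,
    quartile_method: str = "linear",
) -> BoxplotStats | None:
    """Boxplot statistics of a sample, or None when n < ``min_n``.

    Quartiles use linear interpolation between closest ranks by default
    (numpy's ``linear``, R's type 7); the method is configurable because
    Q1/Q3 feed the score directly.  MAD is median(|v - median|),
    unscaled.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < min_n:
        return None
    med = float(np.median(vals))
    q1, q3 = (
        float(q) for q in np.percentile(vals, [25, 75], method=quartile_method)
    )
    return BoxplotStats(
        n=int(vals.size),
        mean=float(vals.mean()),
        median=med,
        q1=q1,
        q3=q3,
        mad=float(np.median(np.abs(vals - med))),
    )


def calibrate(
    corpus: Iterable[tuple[Sequence[AtomSite], ModelMetadata]],
    thresholds: QualityThresholds = QualityThresholds(),
    dictionary: Mapping[str, CompoundRecord] | None = None,
    quartile_method: str = "linear",
    trp_rings: str = "separate",
) -> tuple[ReferenceStats, pd.DataFrame, Counter]:
    """Build a full reference-statistics table from a corpus.

    ``corpus`` yields (atoms, metadata) pairs, one per structure model.
    Returns the reference table, a per-category observation-count table
    (halogen × acceptor class) and an attrition counter recording why
    observations were rejected.
    """
    observations: dict[tuple[str, str], dict[str, list[float]]] = defaultdict(
        lambda: {"distance": [], "theta1": [], "theta2": []}
    )
    attrition: Counter = Counter()

    n_structures = 0
    for atoms, meta in corpus:
        n_structures += 1
        per_site = detect_candidates(atoms, dictionary=dictionary, trp_rings=trp_rings)
        for site, candidates in per_site.items():
            attrition["candidates"] += len(candidates)
            survivors = []
            for cand in candidates:
                keep, reason = quality_filter(cand, meta, thresholds)
                if not keep:
                    attrition[reason] += 1
                    continue
                survivors.append(cand)
            survivors = restrict_to_ligand_protein(survivors)
            chosen = select_mining_acceptor(survivors)
            if chosen is None:
                continue
            attrition["selected"] += 1
            hal, acc_class = chosen.category_key
            geom = chosen.geometry
            cell = observations[(hal, acc_class)]
            cell["distance"].append(geom.d)
            cell["theta1"].append(geom.theta1)
            if geom.theta2 is not None:
                # primary-neighbor θ2: single-valued calibration population
                cell["theta2"].append(geom.theta2)

    if n_structures == 0 or not observations:
        logger.warning("calibration corpus produced no observations")

    cells: list[CategoryStats] = []
    counts: dict[tuple[str, str], int] = {}
    for (hal, acc_class), params in sorted(observations.items()):
        counts[(hal, acc_class)] = len(params["distance"])
        for parameter, values in params.items():
            if not values:
                continue
            stats = boxplot_stats(
                values, min_n=thresholds.min_category_n, quartile_method=quartile_method
            )
            if stats is None:
                logger.info(
                    "category %s···%s %s has %d < %d observations; omitted",
                    hal, acc_class, parameter, len(values), thresholds.min_category_n,
                )
                attrition[f"omitted:{hal}:{acc_class}:{parameter}"] += 1
                continue
            if stats.q3 - stats.q1 <= 0:
                logger.info(
                    "category %s···%s %s has zero IQR; omitted",
                    hal, acc_class, parameter,
                )
                attrition[f"zero_iqr:{hal}:{acc_class}:{parameter}"] += 1
                continue
            cells.append(
                CategoryStats(
                    halogen=hal,
                    acceptor_class=acc_class,
                    parameter=parameter,
                    n=stats.n,
                    mean=stats.mean,
                    median=stats.median,
                    q1=stats.q1,
                    q3=stats.q3,
                    mad=stats.mad,
                )
            )

    count_frame = pd.DataFrame(
        [
            {"acceptor_class": cls}
            | {
                hal: counts.get((hal, cls), 0)
                for hal in ("F", "Cl", "Br", "I")
            }
            for cls in ACCEPTOR_CLASSES
        ]
    ).set_index("acceptor_class")

    return ReferenceStats(cells), count_frame, attrition
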