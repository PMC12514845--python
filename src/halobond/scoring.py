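"""The halogen-bond geometric score (HalBS).

Each geometric parameter of a candidate bond (distance, θ1, and θ2 when
the acceptor is atomic) is scored against the reference boxplot of its
(halogen, acceptor-class) category:

    Score_geom = max( (value - Q3)/IQR, (Q1 - value)/IQR, 0 )

i.e. the distance of the value from the box boundaries in units of IQRs,
zero anywhere inside [Q1, Q3].  The overall score is the worst feature:

    HalBS = max(Score_distance, Score_θ1[, Score_θ2])

A value inside the box is *preferred* (score 0), within the 1.5×IQR
whiskers *allowed* (0 < HalBS ≤ 1.5), and beyond them an *outlier*
(HalBS > 1.5) that deserves a critical look.  The comparison with 1.5 is
exact: 1.5 itself is still allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import HalogenBondCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryStats",
    "ModelSummary",
    "ReferenceStats",
    "ScoredBond",
    "classify",
    "default_reference_stats",
    "halbs",
    "score_geom",
    "score_structure",
    "select_best_bond",
    "summarize_model",
]

PARAMETERS = ("distance", "theta1", "theta2")
ACCEPTOR_CLASSES = ("O-C", "S-C", "His", "Phe", "Tyr", "Trp")


@dataclass(frozen=True)
class CategoryStats:
    """Reference boxplot statistics for one (halogen, class, parameter) cell."""

    halogen: str
    acceptor_class: str
    parameter: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    mad: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError(
                f"inconsistent quartiles for {self.key}: "
                f"q1={self.q1} median={self.median} q3={self.q3}"
            )
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.halogen, self.acceptor_class, self.parameter)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


class ReferenceStats:
    """Lookup table of :class:`CategoryStats` cells.

    Cells with a non-positive IQR are rejected at load time — Eq-style
    IQR scoring would divide by zero on them.
    """

    def __init__(self, cells: Iterable[CategoryStats]):
        self._cells: dict[tuple[str, str, str], CategoryStats] = {}
        for cell in cells:
            if cell.iqr <= 0:
                raise ValueError(
                    f"reference cell {cell.key} has non-positive IQR; "
                    "scores would be undefined"
                )
            self._cells[cell.key] = cell

    def get(self, halogen: str, acceptor_class: str, parameter: str) -> CategoryStats | None:
        return self._cells.get((halogen, acceptor_class, parameter))

    def has_category(self, halogen: str, acceptor_class: str) -> bool:
        return self.get(halogen, acceptor_class, "distance") is not None

    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self):
        return iter(self._cells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "halogen": c.halogen,
                "acceptor_class": c.acceptor_class,
                "parameter": c.parameter,
                "n": c.n,
                "mean": c.mean,
                "median": c.median,
                "q1": c.q1,
                "q3": c.q3,
                "mad": c.mad,
            }
            for c in sorted(self._cells.values(), key=lambda c: c.key)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceStats":
        cells = [
            CategoryStats(
                halogen=str(row["halogen"]),
                acceptor_class=str(row["acceptor_class"]),
                parameter=str(row["parameter"]),
                n=int(row["n"]),
                mean=float(row["mean"]),
                median=float(row["median"]),
                q1=float(row["q1"]),
                q3=float(row["q3"]),
                mad=float(row["mad"]),
            )
            for _, row in frame.iterrows()
        ]
        return cls(cells)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceStats":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_reference_stats() -> ReferenceStats:
    """The packaged reference table.

    This table is a synthetic stand-in: observation counts follow the
    published per-category census of ligand-protein halogen bonds and the
    medians follow the published per-halogen medians, but the quartiles
    and MADs are plausible synthetic spreads, not measured ones.  For
    production scoring, recalibrate on a structure corpus
    (:func:`halobond.calibrate.calibrate`) or supply a measured table via
    :meth:`ReferenceStats.from_tsv`.
    """
    ref = resources.files("halobond.data").joinpath("reference_stats_synthetic.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return ReferenceStats.from_frame(pd.read_csv(fh, sep="\t"))


def score_geom(value: float, q1: float, q3: float) -> float:
    """IQR-based outlier score of one measured parameter value.

    Zero anywhere inside [q1, q3]; outside, the number of IQRs the value
    lies beyond the nearer box boundary.
    """
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError(f"IQR must be positive (q1={q1}, q3={q3})")
    return max((value - q3) / iqr, (q1 - value) / iqr, 0.0)


def classify(halbs_value: float) -> str:
    """preferred (0), allowed (≤ 1.5, inside the whiskers) or outlier (> 1.5)."""
    if halbs_value < 0:
        raise ValueError(f"scores are non-negative; got {halbs_value}")
    if halbs_value == 0.0:
        return "preferred"
    if halbs_value <= 1.5:
        return "allowed"
    return "outlier"


@dataclass(frozen=True, eq=False)
class ScoredBond:
    """A candidate with its per-parameter scores and overall HalBS.

    ``halbs`` is None when the candidate's category has no reference
    statistics (e.g. iodine···Trp): the bond is reported with its
    geometry and ``unscored_reason``, never silently dropped, and never
    enters model summaries.  ``theta2`` is the neighbor angle actually
    scored (the most favorable one when the acceptor has several
    covalent neighbors).
    """

    candidate: HalogenBondCandidate
    score_distance: float | None = None
    score_theta1: float | None = None
    score_theta2: float | None = None
    theta2: float | None = None
    halbs: float | None = None
    classification: str | None = None
    unscored_reason: str | None = None

    @property
    def scored(self) -> bool:
        return self.halbs is not None


def halbs(
    candidate: HalogenBondCandidate, stats: ReferenceStats
) -> ScoredBond:
    """Score one candidate against its category's reference statistics.

    HalBS is the maximum of the per-parameter scores — the least
    favorable geometric feature of the bond.  θ2 is scored for every
    covalent neighbor of the acceptor and the lowest θ2 score is kept.
    """
    hal, acc_class = candidate.category_key
    geom = candidate.geometry

    needed = ["distance", "theta1"] + ([] if geom.is_pi else ["theta2"])
    cells = {p: stats.get(hal, acc_class, p) for p in needed}
    missing = [p for p, c in cells.items() if c is None]
    if missing:
        return ScoredBond(
            candidate=candidate,
            theta2=geom.theta2,
            unscored_reason=(
                f"no reference statistics for {hal}···{acc_class} "
                f"({', '.join(missing)})"
            ),
        )

    s_d = score_geom(geom.d, cells["distance"].q1, cells["distance"].q3)
    s_t1 = score_geom(geom.theta1, cells["theta1"].q1, cells["theta1"].q3)
    scores = [s_d, s_t1]
    s_t2 = None
    chosen_t2 = None
    if not geom.is_pi:
        t2_cell = cells["theta2"]
        options = [
            (score_geom(t2, t2_cell.q1, t2_cell.q3), t2)
            for t2 in geom.theta2_options
        ]
        s_t2, chosen_t2 = min(options)
        scores.append(s_t2)

    value = max(scores)
    return ScoredBond(
        candidate=candidate,
        score_distance=s_d,
        score_theta1=s_t1,
        score_theta2=s_t2,
        theta2=chosen_t2,
        halbs=value,
        classification=classify(value),
    )


def select_best_bond(
    scored: Sequence[ScoredBond],
) -> ScoredBond | None:
    """The bond reported for one halogen: the lowest HalBS among its
    scored candidates (atomic and π together).

    Ties break by atomic-over-π, then smaller distance, then acceptor
    residue order.  Returns an unscored bond only when nothing at all
    could be scored (so unscorable categories stay visible).
    """
    if not scored:
        return None
    scorable = [s for s in scored if s.scored]
    if not scorable:
        return min(scored, key=lambda s: s.candidate._sort_key())
    return min(
        scorable,
        key=lambda s: (
            s.halbs,
            s.candidate.is_pi,      # False (atomic) sorts before True (π)
            s.candidate.geometry.d,
            s.candidate._sort_key(),
        ),
    )


@dataclass(frozen=True)
class ModelSummary:
    """Per-model report block: bond count and mean HalBS."""

    n_bonds: int
    mean_halbs: float | None

    def as_dict(self) -> dict:
        return {"halogen_bond_count": self.n_bonds, "mean_halbs": self.mean_halbs}


def summarize_model(selected: Iterable[ScoredBond]) -> ModelSummary:
    """Count and mean HalBS over the selected (scored) bonds of a model.

    Unscored bonds never enter the count or the mean; with zero scored
    bonds the mean is reported missing (None), not zero.
    """
    values = [s.halbs for s in selected if s.scored]
    if not values:
        return ModelSummary(n_bonds=0, mean_halbs=None)
    return ModelSummary(n_bonds=len(values), mean_halbs=sum(values) / len(values))


def score_structure(
    atoms,
    stats: ReferenceStats | None = None,
    dictionary: Mapping | None = None,
    trp_rings: str = "separate",
    vdw_table: Mapping[str, float] | None = None,
) -> tuple[list[ScoredBond], ModelSummary]:
    """Detection → scoring → best-bond selection → model summary.

    Returns one selected bond per halogen site that has any candidate,
    plus the model summary over the scored ones.
    """
    from .detect import detect_candidates

    if stats is None:
        stats = default_reference_stats()
    per_site = detect_candidates(
        atoms, dictionary=dictionary, trp_rings=trp_rings, vdw_table=vdw_table
    )
    selected: list[ScoredBond] = []
    for site, candidates in sorted(
        per_site.items(), key=lambda kv: (kv[0].atom.residue_key, kv[0].atom.atom_name)
    ):
        scored = [halbs(c, stats) for c in candidates]
        best = select_best_bond(scored)
        if best is not None:
            selected.append(best)
    return selected, summarize_model(selected)
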