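import gemmi
import pytest

from halobond import (
    FixtureSpec,
    ReferenceStats,
    CategoryStats,
    make_candidate_structure,
    read_structure_string,
)
from halobond.io import load_compound_dictionary


def make_stats(cells):
    """Hand-written reference table from (halogen, class, param, q1, q3) rows."""
    return ReferenceStats(
        CategoryStats(
            halogen=hal,
            acceptor_class=cls,
            parameter=param,
            n=50,
            mean=(q1 + q3) / 2,
            median=(q1 + q3) / 2,
            q1=q1,
            q3=q3,
            mad=(q3 - q1) / 2,
        )
        for hal, cls, param, q1, q3 in cells
    )


@pytest.fixture
def br_oc_stats():
    """Reference cells for a Br···O-C category with easy round numbers."""
    return make_stats(
        [
            ("Br", "O-C", "distance", 3.2, 3.6),
            ("Br", "O-C", "theta1", 140.0, 170.0),
            ("Br", "O-C", "theta2", 95.0, 125.0),
        ]
    )


def load_fixture(spec: FixtureSpec):
    """Generate a fixture and parse it back: (atoms, metadata, dictionary, truth)."""
    cif_text, truth = make_candidate_structure(spec)
    atoms, meta = read_structure_string(cif_text)
    dictionary = load_compound_dictionary(gemmi.cif.read_string(cif_text))
    return atoms, meta, dictionary, truth
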