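import json
from fractions import Fraction

import pytest

import coopeq as cq


@pytest.fixture
def pd_worked():
    """Two-player PD in dollars: (T,R,P,S) = (0.20, 0.15, 0.05, 0.00)."""
    return cq.make_prisoners_dilemma("0.20", "0.15", "0.05", "0.00")


@pytest.fixture
def td5():
    """Traveler's dilemma, claims 180..300, bonus/penalty 5."""
    return cq.make_travelers_dilemma(180, 300, 5)


@pytest.fixture
def pg_ghl():
    """Two-player public goods, marginal return 0.8, unit endowment, grid 0.01."""
    return cq.make_public_goods(2, 1, "0.8", "0.01")


@pytest.fixture
def chicken_kummerli():
    """Chicken from the quadruple {8,5,2,1}: (T,R,S,P) = (8,5,2,1)."""
    return cq.make_chicken(8, 5, 2, 1)


@pytest.fixture
def write_spec(tmp_path):
    """Write a game-spec JSON document and return its path."""

    def _write(doc, name="game.json"):
        path = tmp_path / name
        path.write_text(json.dumps(doc))
        return path

    return _write


def frac(s) -> Fraction:
    return Fraction(s)
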