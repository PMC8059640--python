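import numpy as np
import pytest

from gpcrsel import (
    FixtureSpec,
    GPCRSequence,
    TMDefinition,
    load_scale,
    make_registry,
    unit_matrix,
    write_fixture,
)
from gpcrsel.registry import STANDARD_RESIDUES

#: TM definition with well-spread helices for index-arithmetic tests;
#: center_3 = 110 and center_7 = 280 match the worked examples in the tests.
TM_WIDE = TMDefinition((
    (10, 40, 25), (50, 80, 65), (95, 125, 110), (140, 170, 155),
    (185, 215, 200), (230, 260, 245), (270, 285, 280),
))


@pytest.fixture(scope="session")
def scale():
    return load_scale()


@pytest.fixture(scope="session")
def unit():
    return unit_matrix()


@pytest.fixture(scope="session")
def fixture_registry():
    """A deterministic 5-template synthetic registry with planted truth."""
    return make_registry(FixtureSpec(seed=3))


@pytest.fixture
def fixture_paths(tmp_path):
    """The same registry written to disk (registry/truth/query files)."""
    return write_fixture(FixtureSpec(seed=3), tmp_path)


def build_seq(helices, loops=None, nterm="", cterm="", seq_id="SEQ",
              name="handmade", gpcr_class="A"):
    """Assemble a GPCRSequence from 7 helix strings and 6 loop strings,
    with each helix center placed at start + len//2."""
    loops = loops if loops is not None else [""] * 6
    assert len(helices) == 7 and len(loops) == 6
    seq = nterm
    spans = []
    for k, h in enumerate(helices):
        start = len(seq) + 1
        seq += h
        end = len(seq)
        spans.append((start, end, start + len(h) // 2))
        if k < 6:
            seq += loops[k]
    seq += cterm
    return GPCRSequence(id=seq_id, name=name, gpcr_class=gpcr_class,
                        sequence=seq, tm=TMDefinition(tuple(spans)))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=n))
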