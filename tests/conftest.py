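import pytest

from mitofrag import vocab
from mitofrag.rearrange import RearrangementEvent
from mitofrag.simulate import GeneratorConfig, evolve_pair, generate_ancestor
from mitofrag.thrips import TABLE_DIVERGENCE

#: the canonical contrast between the two cryptic species: two tRNA
#: inversions plus fission of a nad6+trnC mini-circle with duplicated
#: control region and trnS1
STUDY_EVENTS = (
    RearrangementEvent(kind="inversion", genes=frozenset(("trnF",))),
    RearrangementEvent(kind="inversion", genes=frozenset(("trnY",))),
    RearrangementEvent(kind="fragmentation",
                       genes=frozenset(("nad6", "trnC")),
                       duplicated=frozenset((vocab.CONTROL, "trnS1"))),
)


@pytest.fixture(scope="session")
def ancestor():
    return generate_ancestor(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def study_pair(ancestor):
    """Ancestor plus a derived genome carrying the published event set and
    per-homolog divergences."""
    return evolve_pair(ancestor, list(STUDY_EVENTS), dict(TABLE_DIVERGENCE),
                       seed=23)


@pytest.fixture(scope="session")
def bipartite_genome(study_pair):
    return study_pair[1]


@pytest.fixture(scope="session")
def minicircle(ancestor):
    """Mini-circle chromosome carved directly from the ancestor, keeping the
    generator's homopolymer-rich run structure (planted substitutions in an
    evolved genome thin the runs out)."""
    from mitofrag.simulate import fission_minicircle
    g = fission_minicircle(ancestor, {"nad6", "trnC"},
                           {vocab.CONTROL, "trnS1"},
                           {vocab.CONTROL: 1.65, "trnS1": 0.0}, seed=31)
    return min(g.chromosomes, key=lambda c: len(c.record))
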