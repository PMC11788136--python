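import pytest

from iglocus.locus import annotate_locus
from iglocus.pipeline import run_repertoire
from iglocus.reference import build_reference
from iglocus.simulate import (
    LocusSpec,
    RepertoireSpec,
    generate_locus,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def igh_locus():
    """A seeded heavy-chain locus with the default defect mix and a few
    reversed V genes."""
    return generate_locus(LocusSpec(seed=1, reversed_v_fraction=0.2))


@pytest.fixture(scope="session")
def annotated(igh_locus):
    return annotate_locus(
        igh_locus.genome, igh_locus.v_seeds, igh_locus.c_seeds, chain="IGH"
    )


@pytest.fixture(scope="session")
def reference(igh_locus):
    return build_reference(igh_locus.genes)


@pytest.fixture(scope="session")
def small_sim(reference):
    return simulate_repertoire(RepertoireSpec(reference=reference, n_reads=800, seed=11))


@pytest.fixture(scope="session")
def small_run(small_sim, reference):
    return run_repertoire(small_sim.reads, reference, sample_id="S1")
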