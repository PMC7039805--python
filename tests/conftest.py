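import math

import pytest

from histocompat import (
    Cohort,
    SimulationConfig,
    Subject,
    genotype,
    simulate_cohort,
    simulate_sequences,
)
from histocompat.simulate import DEFAULT_HLA_FREQUENCIES


def make_mother(subject_id="M1", family_id="F1", disease="control",
                n_live_births=2, **genos):
    return Subject(
        family_id=family_id,
        subject_id=subject_id,
        role="mother",
        disease=disease,
        n_live_births=n_live_births,
        genotypes={k: genotype(k, *v) for k, v in genos.items()},
    )


def make_child(subject_id="C1", family_id="F1", born_before=True, **genos):
    return Subject(
        family_id=family_id,
        subject_id=subject_id,
        role="child",
        born_before_diagnosis=born_before,
        genotypes={k: genotype(k, *v) for k, v in genos.items()},
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-size cohort with a true exposure effect at HLA-B."""
    cfg = SimulationConfig(
        n_mothers=400,
        exposure_log_or={"B": math.log(1.8)},
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_sequences():
    """Scoring resources covering the default simulated allele pools."""
    return simulate_sequences(
        {locus: list(pool) for locus, pool in DEFAULT_HLA_FREQUENCIES.items()},
        seed=3,
    )
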