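import warnings

import pytest

warnings.filterwarnings("ignore", category=DeprecationWarning)

from dromtrad.params import Params, load_params
from dromtrad.synthetic_locus import (
    LocusBlueprint,
    RepertoireBlueprint,
    generate_locus,
    generate_repertoire,
)


@pytest.fixture(scope="session")
def params() -> Params:
    return load_params()


@pytest.fixture(scope="session")
def locus(params):
    """Default synthetic locus with ground truth (seeded)."""
    return generate_locus(LocusBlueprint(seed=1), params)


@pytest.fixture(scope="session")
def clean_cohort(params, locus):
    """A mutation-free cohort: ground truth is exactly recoverable."""
    _, truth = locus
    clones, truth = generate_repertoire(
        truth, RepertoireBlueprint(n_clones=80, shm_rate=0.0, seed=11), params
    )
    return clones, truth


@pytest.fixture(scope="session")
def clean_decompositions(params, clean_cohort):
    from dromtrad.cdr3_decompose import decompose_cohort

    clones, truth = clean_cohort
    decs = decompose_cohort(
        clones, list(truth.v_gene_refs.values()), truth.j_refs, truth.d_refs, params
    )
    return decs, truth
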