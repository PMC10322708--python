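import numpy as np
import pytest

import hapdose as h


@pytest.fixture(scope="session")
def catalog():
    return h.generate_gene_catalog(
        n_chromosomes=5, chrom_length=100_000_000, genes_per_chromosome=100, seed=1
    )


@pytest.fixture(scope="session")
def controls(catalog):
    return h.simulate_controls(catalog, n_control=30, depth=100.0, seed=3)


@pytest.fixture(scope="session")
def control_summaries(catalog, controls):
    return h.quantify_cells(controls, controls, catalog)


@pytest.fixture(scope="session")
def refset(control_summaries):
    return h.build_reference(control_summaries)


@pytest.fixture(scope="session")
def aneuploid_ref(refset):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.build_aneuploid_reference(None, refset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
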