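import numpy as np
import pytest

from pentalayout.expression_io import ExpressionMatrix, SampleRecord
from pentalayout.ontology import OntologyEntry, OntologyMap
from pentalayout.panel import default_panel
from pentalayout.synthetic import (
    RegionalTruth,
    default_nuclei_truth,
    default_regional_truth,
    simulate_nuclei,
    simulate_probes,
    simulate_regional,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def ontology():
    from pentalayout.ontology import default_ontology

    return default_ontology()


def make_ontology(n_substructures, n_per_structure=10, prefix="R"):
    """A flat synthetic ontology with one major region."""
    entries = []
    for i in range(n_substructures):
        entries.append(
            OntologyEntry(
                substructure=f"{prefix}{i:03d}",
                structure=f"St{i // n_per_structure:02d}",
                major_region="M0",
                ontogenic_origin="telencephalon",
                rostro_caudal_rank=i,
            )
        )
    return OntologyMap(entries)


@pytest.fixture(scope="session")
def regional_fixture(panel, ontology):
    """Default 6-subject regional simulation at seed 1."""
    truth = default_regional_truth()
    matrices, ont = simulate_regional(truth, seed=1)
    return truth, matrices, ont


@pytest.fixture(scope="session")
def probe_fixture(regional_fixture):
    """4-probe-per-gene expansion of the regional fixture at noise 0.2."""
    _, matrices, _ = regional_fixture
    probe_mats, truth_map = simulate_probes(
        matrices, probes_per_gene=4, noise_sd=0.2, seed=1
    )
    return probe_mats, truth_map


@pytest.fixture(scope="session")
def nuclei_fixture(panel):
    truth = default_nuclei_truth(n_nuclei=100, n_excitatory=3, n_inhibitory=3,
                                 n_non_neuronal=1)
    matrix, records = simulate_nuclei(truth, seed=1)
    return truth, matrix, records


def toy_matrix(values, scale="linear", row_ids=None, samples=None, **sample_kwargs):
    """Small ExpressionMatrix builder for unit tests."""
    values = np.asarray(values, dtype=float)
    if row_ids is None:
        row_ids = [f"g{i}" for i in range(values.shape[0])]
    if samples is None:
        samples = [
            SampleRecord(sample_id=f"s{j}", **sample_kwargs)
            for j in range(values.shape[1])
        ]
    return ExpressionMatrix(row_ids, samples, values, scale=scale)
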