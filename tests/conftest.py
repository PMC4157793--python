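import numpy as np
import pytest

from pharmsig.datamodel import AxisSemantics, LabeledMatrix
from pharmsig.drug_response import threshold_ic50
from pharmsig.preprocess import collapse_probes, standard_normalize
from pharmsig.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, shared across tests (seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def expr_z(cohort):
    """Probe-collapsed, per-gene z-scored expression of the cohort."""
    gene = collapse_probes(cohort.probe_matrix, cohort.probe_gene_map)
    return standard_normalize(gene)


@pytest.fixture(scope="session")
def panel(cohort):
    """Ceiling-thresholded IC50 panel of the cohort."""
    return threshold_ic50(cohort.drug_response, cohort.config.ceiling)


def labeled(values, row_prefix="g", col_prefix="s",
            semantics=AxisSemantics.gene_by_sample, units=""):
    """Small helper to build a LabeledMatrix from a nested list."""
    values = np.asarray(values, dtype=float)
    rows = [f"{row_prefix}{i}" for i in range(values.shape[0])]
    cols = [f"{col_prefix}{j}" for j in range(values.shape[1])]
    return LabeledMatrix(rows, cols, values, semantics, units)
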