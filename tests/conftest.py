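import numpy as np
import pytest

from shrinkf import ExperimentDesign


@pytest.fixture(scope="session")
def design_222() -> ExperimentDesign:
    return ExperimentDesign.balanced(n_probes=2, n_groups=2, n_reps=2)


@pytest.fixture(scope="session")
def design_223() -> ExperimentDesign:
    return ExperimentDesign.balanced(n_probes=2, n_groups=2, n_reps=3)


@pytest.fixture(scope="session")
def worked_gene(design_222):
    """Hand-checkable 2x2x2 gene: group-1 variance 4, group-2 variance 1.

    Cell layout: group 1 probe 1 reps (1, 3), probe 2 reps (4, 2);
    group 2 probe 1 reps (5, 5), probe 2 reps (6, 8).  Exact decomposition:
    msi = 0.5, mse = 2.5, group variances (4, 1), so F1 = 0.2.
    """
    # observation order of ExperimentDesign.balanced: group, then rep, then probe
    y = np.array([1.0, 4.0, 3.0, 2.0, 5.0, 6.0, 5.0, 8.0])
    return y


def random_balanced_matrix(rng, n_genes, design, scale=1.0):
    return rng.standard_normal((n_genes, design.n_obs)) * scale
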