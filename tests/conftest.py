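import numpy as np
import pandas as pd
import pytest

from tdratio import ExpressionMatrix, build_references
from tdratio.simulate import CohortSimulator, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_matrix():
    """5 genes x 4 samples of strictly positive expression."""
    rng = np.random.default_rng(3)
    data = pd.DataFrame(rng.gamma(2.0, 50.0, size=(5, 4)) + 1.0,
                        index=[f"G{i}" for i in range(5)],
                        columns=[f"s{j}" for j in range(4)])
    return ExpressionMatrix(data, "cpm")


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort: normals + paired tumors + references."""
    sim = CohortSimulator(SimulationConfig(n_genes=400, n_patients=8,
                                           n_normal_per_tissue=8, seed=101))
    normals, normal_ann = sim.generate_reference_cohort()
    tumors, tumor_ann = sim.generate_tumor_cohort("colon", "liver")
    refs = build_references(normals, normal_ann)
    return {"sim": sim, "normals": normals, "normal_ann": normal_ann,
            "tumors": tumors, "tumor_ann": tumor_ann, "refs": refs}
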