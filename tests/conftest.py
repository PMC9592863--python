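import numpy as np
import pandas as pd
import pytest

from triadscreen import ExpressionMatrix, SampleDesign, SimulationConfig, simulate_experiment


def make_design(n_reps: int = 3, genotypes=("DT", "DS")) -> SampleDesign:
    rows = []
    for g in genotypes:
        for cond, tag in (("CK", "CK"), ("drought", "T")):
            for rep in range(1, n_reps + 1):
                rows.append({"sample": f"{g}{tag}{rep}", "genotype": g,
                             "condition": cond, "replicate": rep})
    return SampleDesign(pd.DataFrame(rows))


def make_matrix(values: np.ndarray, design: SampleDesign | None = None,
                unit: str = "counts", prefix: str = "f") -> ExpressionMatrix:
    design = design or make_design()
    features = [f"{prefix}{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=design.samples),
        unit=unit,
        design=design,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated experiment at the standard study conditions."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def design12() -> SampleDesign:
    return make_design()
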