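import numpy as np
import pandas as pd
import pytest

from brixomics import SimulationConfig, simulate_expression_experiment
from brixomics.preprocess import ExpressionExperiment


FIVE_ARCHETYPES = {
    "monotone_decrease": (0.2, 2.0),
    "monotone_increase": (0.2, 2.0),
    "tissue_offset": (0.2, 2.0),
    "skin_peak": (0.2, 2.0),
    "valley": (0.2, 2.0),
}


@pytest.fixture(scope="session")
def small_experiment():
    """500-gene mixed-archetype experiment with default noise."""
    cfg = SimulationConfig(n_genes=500, seed=11)
    return simulate_expression_experiment(cfg)


@pytest.fixture(scope="session")
def archetype_experiment():
    """1000 genes over the five non-flat archetypes (cluster recovery)."""
    cfg = SimulationConfig(n_genes=1000, effect_model=FIVE_ARCHETYPES,
                           noise_sd=0.25, seed=5)
    return simulate_expression_experiment(cfg)


def make_experiment(values: np.ndarray,
                    brix_levels=(22.6, 23.2),
                    tissues=("skin", "pulp"),
                    n_reps: int = 3) -> ExpressionExperiment:
    """Wrap a raw array into an experiment with a minimal factorial design."""
    n_genes = values.shape[0]
    sample_ids, rows = [], []
    for b in brix_levels:
        for t in tissues:
            for r in range(1, n_reps + 1):
                sid = f"bx{b:g}{t}_{r}"
                sample_ids.append(sid)
                rows.append((sid, b, t, r))
    design = pd.DataFrame(rows, columns=["sample_id", "brix", "tissue",
                                         "replicate"]).set_index("sample_id")
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                         columns=sample_ids)
    return ExpressionExperiment(frame, design)
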