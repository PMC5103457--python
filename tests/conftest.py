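import numpy as np
import pandas as pd
import pytest

from lncforge.io_formats import ExpressionMatrix
from lncforge.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_annotation(sim_config):
    """(GeneAnnotation, lncRNA models, truth) with 5 lncRNAs per class."""
    return simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def sim_expression(sim_config, sim_annotation):
    annotation, lncs, truth = sim_annotation
    features = [
        m.transcript_id for ms in annotation.transcripts_by_gene.values() for m in ms
    ] + [t.transcript_id for t in lncs]
    expr, _ = simulate_expression(
        sim_config, features, lnc_features={t.transcript_id for t in lncs}
    )
    return expr


def make_expr(values: dict[str, list[float]], tissues=None, conditions=None) -> ExpressionMatrix:
    """Small 12-sample matrix builder for hand-constructed fixtures."""
    tissues = tissues or ["brain", "kidney", "liver"]
    conditions = conditions or ["newborn", "4y", "4y_lowO2", "20y"]
    samples = [f"{t}_{c}" for t in tissues for c in conditions]
    meta = pd.DataFrame(
        {
            "tissue": [s.split("_", 1)[0] for s in samples],
            "condition": [s.split("_", 1)[1] for s in samples],
        },
        index=samples,
    )
    df = pd.DataFrame(values, index=samples).T
    return ExpressionMatrix(values=df, sample_meta=meta)


@pytest.fixture
def expr_builder():
    return make_expr


@pytest.fixture
def rng():
    return np.random.default_rng(202)
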