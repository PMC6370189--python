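import numpy as np
import pandas as pd
import pytest

import trmsig as t


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 11,000 genes, 4 conditions x 3 replicates."""
    cfg = t.SimulationConfig(seed=0)
    matrix, design, signature, sets, truth = t.simulate_study(cfg)
    return {
        "config": cfg,
        "matrix": matrix,
        "design": design,
        "signature": signature,
        "sets": sets,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_processed(default_study):
    expressed = t.filter_low_expression(default_study["matrix"])
    logged = t.log2_transform(expressed)
    standardised = t.standardise(logged)
    return {"expressed": expressed, "logged": logged, "standardised": standardised}


@pytest.fixture(scope="session")
def default_de(default_study, default_processed):
    """DE results for the three signature-stage comparisons."""
    logged = default_processed["logged"]
    design = default_study["design"]
    return {
        spec.name: t.differential_expression(logged, design, spec)
        for spec in t.study_comparisons()[:3]
    }


def make_log2_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return t.ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), scale="log2"
    )


def make_design(conditions, sample_ids=None):
    """Design table from a list of per-sample conditions."""
    rows, index = [], []
    counter: dict[str, int] = {}
    for i, cond in enumerate(conditions):
        counter[cond] = counter.get(cond, 0) + 1
        rows.append({"condition": cond, "replicate": counter[cond]})
        index.append(sample_ids[i] if sample_ids else f"{cond}_rep{counter[cond]}")
    return t.SampleDesign(table=pd.DataFrame(rows, index=index))
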