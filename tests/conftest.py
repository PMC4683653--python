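import numpy as np
import pandas as pd
import pytest

from gxd import (
    FeatureMatrix,
    PhenotypeTable,
    SampleMeta,
    generate_dataset,
    preset_scenario,
)


@pytest.fixture
def worked_example():
    """2 lines x 2 diets x 2 replicates with identical within-diet values.

    Line 1 carries {1, 2} in every cell, line 2 {3, 4}: pure genetic signal
    with hand-computable sums of squares (SS_G=8, SS_D=0, SS_GxD=0, SS_E=2).
    """
    rows = []
    for line, (a, b) in (("L1", (1.0, 2.0)), ("L2", (3.0, 4.0))):
        for diet in ("d1", "d2"):
            for rep, val in (("R1", a), ("R2", b)):
                rows.append((f"{line}.{diet}.{rep}", line, diet, rep, "microarray", val))
    tab = pd.DataFrame(rows, columns=["sample_id", "line_id", "diet_id",
                                      "replicate_id", "platform", "value"])
    meta = SampleMeta(tab.drop(columns="value"))
    fm = FeatureMatrix(pd.DataFrame([tab["value"].to_numpy()], index=["f1"],
                                    columns=tab["sample_id"]))
    return fm, meta


@pytest.fixture(scope="session")
def main_dataset():
    """One realisation of the main 20 x 4 x 3 scenario, shared across tests."""
    spec = preset_scenario("reed2015_main", seed=11)
    fm, meta, ph, truth = generate_dataset(spec)
    return spec, fm, meta, ph, truth


@pytest.fixture
def tiny_dataset(tmp_path):
    """3 features x 4 samples written as the TSV trio."""
    rng = np.random.default_rng(5)
    meta = SampleMeta(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "line_id": ["L1", "L1", "L2", "L2"],
        "diet_id": ["d1", "d2", "d1", "d2"],
        "replicate_id": ["R1"] * 4,
        "platform": ["microarray"] * 4,
    }))
    fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(3, 4)),
                                    index=["f1", "f2", "f3"],
                                    columns=meta.sample_ids))
    ph = PhenotypeTable(pd.DataFrame(
        {"weight": [1.0, 2.0, 3.0, np.nan],
         "triglyceride": [0.5, 0.1, 0.9, 0.2],
         "sugar": [2.0, 2.5, 1.5, 2.2]},
        index=pd.Index(meta.sample_ids, name="unit_id")))
    return fm, meta, ph
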