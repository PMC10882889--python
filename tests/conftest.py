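import numpy as np
import pandas as pd
import pytest

from mapklnc import simulate
from mapklnc.simulate import SimConfig


@pytest.fixture(scope="session")
def annotation_bundle():
    """Zero-noise synthetic annotation bundle: 5 planted novel lncRNAs,
    30 structural-noise transcripts, 50 reference-overlapping transcripts."""
    return simulate.gen_annotation(SimConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_cohorts():
    """Five-condition expression bundle at zero expression noise."""
    cfg = SimConfig(seed=1, noise_sd=0.0)
    matrices, truth = simulate.gen_expression_cohorts(cfg)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def noiseless_plate():
    """Zero-noise kinase plate: control + treated samples, K1 halved."""
    cfg = SimConfig(seed=1, plate_noise_cv=0.0, plate_effect={"K1": 0.5})
    kinase_map = simulate.default_kinase_map()
    layout = simulate.build_plate_layout(kinase_map, ["ctrl", "trt"])
    assay, truth = simulate.gen_kinase_plate(
        cfg, layout, kinase_map, treated_samples=["trt"]
    )
    return assay, {k: set(v) for k, v in kinase_map.items()}, truth
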