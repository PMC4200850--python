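import numpy as np
import pandas as pd
import pytest

import almaentropy as ae

#: Published reference coefficients in feature order.
REFERENCE_COEF = np.array([-0.403994, 0.199322, 0.434889, -0.020189, -0.001660])
REFERENCE_INTERCEPT = 1.139556


@pytest.fixture(scope="session")
def reference():
    return ae.reference_model()


@pytest.fixture(scope="session")
def toy_endpoints():
    """Tiny fully labeled endpoint table with descriptors attached."""
    frame = pd.DataFrame(
        {
            "compound_id": ["c1", "c2", "c3", "c4", "c5", "c6"],
            "smiles": ["CCO", "c1ccccc1", "CCN", "CCCC", "c1ccncc1", "CC(=O)O"],
            "curation_level": ["expert", "expert", "intermediate",
                               "autocuration", "expert", "intermediate"],
            "measure": ["Ki (nM)", "Ki (nM)", "IC50 (nM)", "IC50 (nM)",
                        "Ki (nM)", "IC50 (nM)"],
            "assay_id": ["a1", "a1", "a2", "a2", "a1", "a2"],
            "organism": ["hsa", "hsa", "rno", "rno", "hsa", "rno"],
            "target_id": ["t1", "t2", "t1", "t2", "t1", "t2"],
            "label": [1, 0, 1, 0, 1, 1],
        }
    )
    theta = ae.MarkovShannonEncoder().fit_transform(list(frame["smiles"]))[:, 5]
    return frame.assign(theta5=theta)


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic dataset with descriptors, shared across tests."""
    config = ae.SynthConfig(
        n_compounds=120, n_records=900, n_measures=6, n_assays=12,
        n_organisms=3, n_targets=8, seed=42,
    )
    frame, truth = ae.simulate(config)
    pairs = frame[["compound_id", "smiles"]].drop_duplicates("compound_id")
    enc = ae.MarkovShannonEncoder()
    theta = dict(zip(pairs["compound_id"],
                     enc.fit_transform(list(pairs["smiles"]))[:, 5]))
    return frame.assign(theta5=frame["compound_id"].map(theta)), truth, config
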