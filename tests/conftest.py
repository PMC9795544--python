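import numpy as np
import pytest
from rdkit import RDLogger

from oatpscreen import chem_data, synthgen

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def small_config():
    return synthgen.SynthConfig(n_compounds=400, seed=42)


@pytest.fixture(scope="session")
def small_compounds(small_config):
    return synthgen.gen_compounds(small_config.n_compounds, seed=small_config.seed)


@pytest.fixture(scope="session")
def small_fingerprints(small_compounds, small_config):
    return synthgen._fingerprints(small_compounds, small_config.nbits)


@pytest.fixture(scope="session")
def small_dataset(small_compounds, small_config, small_fingerprints):
    """Planted activities + consolidated labels on the small library."""
    planted = synthgen.make_planted_model(small_config)
    records, latent = synthgen.plant_activities(
        small_compounds, planted, small_config, fingerprints=small_fingerprints
    )
    dataset = chem_data.build_dataset(records)
    return {
        "records": records,
        "latent": latent,
        "dataset": dataset,
        "planted": planted,
    }


@pytest.fixture(scope="session")
def qsar_labels_t1b1(small_compounds, small_dataset):
    """Binary OATP1B1 labels aligned with the compound order."""
    labels = small_dataset["dataset"].labels
    sub = labels[labels["target"] == "OATP1B1"].set_index("compound_id")["label"]
    return np.array(
        [1 if sub[c.compound_id] == chem_data.ACTIVE else 0 for c in small_compounds]
    )
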