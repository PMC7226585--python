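import numpy as np
import pandas as pd
import pytest

from ribomech import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A 200-gene transcriptome with mixed planted site types."""
    config = sd.SimConfig(
        n_genes=200,
        target_fraction=0.4,
        multi_site_fraction=0.2,
        site_type_weights={"8mer": 0.3, "7mer-m8": 0.3, "7mer-1a": 0.3, "6mer": 0.1},
        seed=7,
    )
    transcripts, truth = sd.generate_transcriptome(config)
    return config, transcripts, truth


@pytest.fixture(scope="session")
def null_counts():
    """Paired null count matrices (no effects), 2000 genes, phi=0.1."""
    config = sd.SimConfig(n_genes=2000, target_fraction=0.0, dispersion=0.1, seed=99)
    truth = sd.null_truth(config)
    counts, design = sd.simulate_counts(truth, config)
    return counts, design


@pytest.fixture
def toy_design():
    samples = [f"{a}_{c}_{r}" for a in ("mrna", "rpf") for c in ("control", "treatment") for r in (1, 2, 3)]
    return pd.DataFrame(
        {
            "condition": [s.split("_")[1] for s in samples],
            "assay": [s.split("_")[0] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
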