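import numpy as np
import pytest

from provmeta.data_io import traits_to_frame
from provmeta.effect_conversion import derive_effect_sizes
from provmeta.phylo_tools import phylo_corr
from provmeta.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12-species synthetic dataset with derived effect sizes."""
    cfg = SimConfig(
        n_species=12,
        seed=7,
        studies_per_species=(1, 2),
        records_per_study=(1, 2),
    )
    tree, traits, records, sidecar = generate_dataset(cfg)
    records = derive_effect_sizes(records)
    tframe = traits_to_frame(traits)
    tframe["pace_pc1"] = np.linspace(-1, 1, len(tframe))
    return {
        "config": cfg,
        "tree": tree,
        "traits": traits,
        "tframe": tframe,
        "records": records,
        "sidecar": sidecar,
        "C": phylo_corr(tree),
    }


@pytest.fixture(scope="session")
def medium_dataset():
    """40-species default-sized dataset (the study-scale fixture)."""
    cfg = SimConfig(seed=11)
    tree, traits, records, sidecar = generate_dataset(cfg)
    records = derive_effect_sizes(records)
    return {
        "config": cfg,
        "tree": tree,
        "traits": traits,
        "records": records,
        "sidecar": sidecar,
        "C": phylo_corr(tree),
    }
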