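import numpy as np
import pandas as pd
import pytest

from seasonet.simulate import SimConfig, simulate_community


def small_config(seed: int = 11) -> SimConfig:
    """A fast community: 3 stations, 6 taxa, small catalogs."""
    return SimConfig(
        n_stations=3,
        n_taxa=6,
        transcripts_per_taxon=150,
        n_kos=180,
        n_pathways=12,
        n_pfams=300,
        depth_mean=30_000,
        n_modules=2,
        module_size=40,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_community():
    return simulate_community(small_config())


@pytest.fixture()
def toy_annotations():
    """Hand-built annotation table exercising identity and null handling."""
    return pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3", "t4", "t5"],
            "taxon_id": ["SpA", "SpA", "SpB", None, "SpC"],
            "lineage": [
                "diatom;GenA;SpA",
                "diatom;GenA;SpA",
                "dino;GenB;SpB",
                None,
                "hapto;GenC;SpC",
            ],
            "percent_identity": [95.0, 91.0, 85.0, np.nan, 90.0],
            "ko_id": ["K00001", "K00001", "K00002", None, None],
            "pfam_ids": ["PF1,PF2", "PF1", "PF3", None, "PF2"],
        }
    )
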