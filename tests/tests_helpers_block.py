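"""Shared helper: module labels for one planted block of a given size."""

import numpy as np
import pandas as pd

from seasonet.network import NetConfig, adjacency, detect_modules, tom_dissimilarity


def block_labels(block_size: int, n_noise: int = 60, seed: int = 0) -> pd.Series:
    """Detect modules on one tight block of ``block_size`` KOs plus noise."""
    rng = np.random.default_rng(seed)
    n_samples = 100
    latent = rng.standard_normal(n_samples)
    block = latent[None, :] + 0.3 * rng.standard_normal((block_size, n_samples))
    noise = rng.standard_normal((n_noise, n_samples))
    expr = pd.DataFrame(
        np.vstack([block, noise]),
        index=[f"K{i:04d}" for i in range(block_size + n_noise)],
    )
    diss = tom_dissimilarity(adjacency(expr, 6))
    labels = detect_modules(diss, NetConfig(min_module_size=70))
    return labels.iloc[:block_size]
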