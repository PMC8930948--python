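"""Fixed-density random reference networks.

The comparison baseline for the culture networks: directed graphs of the
cohort's average size (153 cells) with a fixed number of uniformly placed
connections (5814, giving connectivity degree 0.25 exactly) and edge
weights drawn from the cohort's connection-strength population,
Normal(0.41, 0.03).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import EffectiveNetwork

__all__ = ["RandomReferenceConfig", "generate_random_networks"]


@dataclass(frozen=True)
class RandomReferenceConfig:
    n_networks: int = 100
    n_cells: int = 153
    n_edges: int = 5814
    weight_mean: float = 0.41
    weight_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.n_cells < 2:
            raise ValueError("need at least one network of at least two cells")
        if not (0 <= self.n_edges <= self.n_cells * (self.n_cells - 1)):
            raise ValueError("n_edges exceeds the number of possible directed connections")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be nonnegative")


def generate_random_networks(config: RandomReferenceConfig) -> list[EffectiveNetwork]:
    """Generate seeded fixed-density random directed weighted networks.

    Each network places exactly ``n_edges`` distinct directed connections
    sampled uniformly without replacement from the off-diagonal positions
    (self-connections prohibited) and assigns each a weight drawn from
    Normal(weight_mean, weight_sd), clipped into (0, 1] since connection
    strengths are probabilities (the default law puts negligible mass
    outside).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    # flat indices of the off-diagonal positions
    offdiag = np.flatnonzero(~np.eye(n, dtype=bool))
    networks = []
    for _ in range(config.n_networks):
        chosen = rng.choice(offdiag, size=config.n_edges, replace=False)
        adjacency = np.zeros(n * n, dtype=np.uint8)
        adjacency[chosen] = 1
        adjacency = adjacency.reshape(n, n)
        weights = np.zeros(n * n)
        weights[chosen] = np.clip(
            rng.normal(config.weight_mean, config.weight_sd, size=config.n_edges),
            1e-9,
            1.0,
        )
        networks.append(
            EffectiveNetwork(adjacency, weights.reshape(n, n), provenance={"reference": True})
        )
    return networks
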