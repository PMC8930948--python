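"""Directed weighted effective networks.

An effective network records, for one recording, which directed cell-to-cell
influences were predicted (binary adjacency ``a_ij``) and how strong each
predicted connection is (``S_ij``, the probability that a spike in the source
is followed by a spike in the target within one frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EffectiveNetwork", "DegenerateNetworkWarning", "complete_network"]


class DegenerateNetworkWarning(UserWarning):
    """Raised (as a warning) when a convention fills in a degenerate value."""


@dataclass
class EffectiveNetwork:
    """Binary directed adjacency plus per-edge connection strengths.

    ``weights[i, j]`` is nonzero only where ``adjacency[i, j] == 1`` and lies
    in [0, 1].  ``provenance`` records how the network was obtained (measures,
    lag, threshold, calibration statistics, reference flag, ...).
    """

    adjacency: np.ndarray
    weights: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.ndim != 2 or self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.weights.shape != (n, n):
            raise ValueError("weights must be congruent with adjacency")
        if not np.isin(np.unique(self.adjacency), [0, 1]).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = self.adjacency.astype(np.uint8)
        if np.diag(self.adjacency).any():
            raise ValueError("self-connections are not allowed")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
        if ((self.weights != 0) & (self.adjacency == 0)).any():
            raise ValueError("weights must be zero off the predicted edge set")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


def complete_network(n: int, weight: float = 1.0) -> EffectiveNetwork:
    """Fully connected directed network with uniform edge weights."""
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return EffectiveNetwork(a, weight * a)
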