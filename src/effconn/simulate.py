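"""Synthetic spiking networks and calcium forward model.

The generator plants a modular directed graph whose edges carry ground-truth
spike-propagation probabilities, then simulates activity with a one-frame
Bernoulli cascade: a spike in cell *i* at frame *t* triggers a spike in each
of its targets *j* at frame *t+1* independently with the edge's propagation
probability; simultaneous causes combine as a noisy-OR together with a
spontaneous background rate.  A short absolute refractory period terminates
the culture-wide avalanches this cascade produces, yielding the sparse
population bursts riding on low-rate background activity that spontaneous
recordings of dissociated cultures show.

:func:`synthesize_calcium` is the matching forward model for the spike
inference stage: each spike adds a stereotyped fluorescence transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .calcium import TransientTemplate, template_kernel
from .raster import DEFAULT_FRAME_RATE, CalciumTraces, SpikeRaster

__all__ = [
    "WeightDistribution",
    "SimulationConfig",
    "GroundTruthNetwork",
    "generate_ground_truth_network",
    "simulate_spikes",
    "synthesize_calcium",
    "generate_cohort",
]


@dataclass(frozen=True)
class WeightDistribution:
    """Truncated-normal law for per-edge propagation probabilities.

    Defaults put the bulk of edge weights near the population of connection
    strengths seen in culture recordings (mean 0.41), truncated to the
    validated propagation range [0.05, 0.8].
    """

    mean: float = 0.41
    sd: float = 0.1
    low: float = 0.05
    high: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError("require 0 <= low < high <= 1")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, float(np.clip(self.mean, self.low, self.high)))
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated culture.

    The defaults are calibrated so that a control cohort reproduces the
    summary statistics of spontaneous culture recordings: connectivity
    degree ~0.25, mean firing rate ~0.2 spikes/s, and sparse culture-wide
    bursting.  ``background_rate`` is the per-cell rate of spontaneous
    (network-independent) spikes in spikes/s; with a supercritical cascade
    almost every spontaneous spike ignites one population burst, so the
    cohort firing rate is approximately
    ``n_cells * background_rate * spikes_per_burst_per_cell``.
    """

    n_cells: int = 100
    n_modules: int = 4
    p_within: float = 0.6
    p_between: float = 0.138
    weight_distribution: WeightDistribution = field(default_factory=WeightDistribution)
    background_rate: float = 0.002
    duration_s: float = 120.0
    frame_rate: float = DEFAULT_FRAME_RATE
    refractory_frames: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (1 <= self.n_modules):
            raise ValueError("n_modules must be >= 1")
        if self.n_modules > self.n_cells:
            raise ValueError("n_modules may not exceed n_cells")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if self.background_rate / self.frame_rate > 1:
            raise ValueError("background_rate exceeds one spike per frame")
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration_s and frame_rate must be positive")
        if self.refractory_frames < 0:
            raise ValueError("refractory_frames must be >= 0")

    @property
    def n_frames(self) -> int:
        return round(self.duration_s * self.frame_rate)


@dataclass
class GroundTruthNetwork:
    """Planted directed topology with per-edge propagation probabilities."""

    adjacency: np.ndarray
    propagation_prob: np.ndarray
    module_labels: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.propagation_prob = np.asarray(self.propagation_prob, dtype=float)
        self.module_labels = np.asarray(self.module_labels, dtype=int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n) or self.propagation_prob.shape != (n, n):
            raise ValueError("adjacency and propagation_prob must be square and congruent")
        if np.diag(self.adjacency).any():
            raise ValueError("self-connections are not allowed")
        if ((self.propagation_prob != 0) & (self.adjacency == 0)).any():
            raise ValueError("propagation_prob must be zero off the edge set")
        if self.module_labels.shape != (n,):
            raise ValueError("module_labels must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def density(self) -> float:
        n = self.n_cells
        return self.n_edges / (n * (n - 1)) if n > 1 else 0.0


def _module_labels(n_cells: int, n_modules: int) -> np.ndarray:
    """Contiguous, nearly equal-sized modules labelled 1..M (no empty module)."""
    sizes = np.full(n_modules, n_cells // n_modules)
    sizes[: n_cells % n_modules] += 1
    return np.repeat(np.arange(1, n_modules + 1), sizes)


def generate_ground_truth_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruthNetwork:
    """Sample a planted-partition directed graph with propagation weights.

    Ordered pairs within a module connect with probability ``p_within``,
    pairs across modules with ``p_between``; self-connections are excluded.
    Each realized edge gets a propagation probability drawn from the
    configured truncated-normal weight distribution.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    labels = _module_labels(n, config.n_modules)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, config.p_within, config.p_between)
    adjacency = (rng.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(adjacency, 0)
    weights = np.zeros((n, n))
    idx = np.nonzero(adjacency)
    weights[idx] = config.weight_distribution.sample(len(idx[0]), rng)
    return GroundTruthNetwork(adjacency, weights, labels)


def simulate_spikes(
    net: GroundTruthNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    initial_spikes: np.ndarray | None = None,
) -> SpikeRaster:
    """Run the one-frame Bernoulli cascade on a planted network.

    Per frame ``t`` every non-refractory cell fires spontaneously with
    probability ``background_rate / frame_rate``; in addition every edge
    ``i -> j`` whose source fired at ``t-1`` triggers ``j`` independently
    with its propagation probability.  Causes combine as a noisy-OR.  A cell
    that fired is silenced for ``refractory_frames`` subsequent frames.

    ``initial_spikes`` optionally forces the frame-0 pattern exactly (no
    background draw at frame 0), which makes single-propagation experiments
    deterministic.
    """
    if net.n_cells != config.n_cells:
        raise ValueError("network and config disagree on n_cells")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, n_frames = net.n_cells, config.n_frames
    p_bg = config.background_rate / config.frame_rate
    no_transmit = 1.0 - net.propagation_prob  # (i, j): P(edge i->j does not fire)
    spikes = np.zeros((n, n_frames), dtype=np.uint8)
    last_spike = np.full(n, -np.inf)
    prev = np.zeros(n, dtype=bool)
    for t in range(n_frames):
        if t == 0 and initial_spikes is not None:
            fire = np.asarray(initial_spikes, dtype=bool).copy()
        else:
            if prev.any():
                p_quiet = (1.0 - p_bg) * np.prod(no_transmit[prev], axis=0)
            else:
                p_quiet = np.full(n, 1.0 - p_bg)
            fire = rng.random(n) < 1.0 - p_quiet
        if config.refractory_frames:
            fire &= t - last_spike > config.refractory_frames
        spikes[:, t] = fire
        last_spike[fire] = t
        prev = fire
    return SpikeRaster(spikes, frame_rate=config.frame_rate, duration_s=config.duration_s)


def synthesize_calcium(
    raster: SpikeRaster,
    template: TransientTemplate | None = None,
    noise_sd: float = 0.03,
    baseline: float = 100.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> CalciumTraces:
    """Forward model: raster -> raw fluorescence traces.

    Each spike adds one peak-normalized rise/decay transient (in dF/F units,
    scaled by ``baseline``); overlapping transients superpose linearly and
    i.i.d. Gaussian noise with standard deviation ``noise_sd * baseline`` is
    added on top of the constant baseline.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if template is None:
        template = TransientTemplate()
    if rng is None:
        rng = np.random.default_rng(seed)
    kernel = template_kernel(template, raster.frame_rate)
    x = raster.spikes.astype(float)
    n, n_frames = x.shape
    dff = np.empty_like(x)
    for c in range(n):
        dff[c] = np.convolve(x[c], kernel)[:n_frames]
    fluor = baseline * (1.0 + dff)
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd * baseline, size=fluor.shape)
    return CalciumTraces(fluor, frame_rate=raster.frame_rate)


def generate_cohort(
    group_configs: Mapping[str, SimulationConfig],
    n_networks: int | Mapping[str, int],
    seed: int = 0,
) -> dict[str, list[tuple[GroundTruthNetwork, SpikeRaster]]]:
    """Simulate a labelled cohort: per group, independent network/raster pairs.

    The master ``seed`` deterministically spawns one independent random
    stream per simulated culture, so the same master seed reproduces the
    cohort bit for bit.
    """
    if not group_configs:
        raise ValueError("at least one group is required")
    counts = {
        g: (n_networks if isinstance(n_networks, int) else n_networks[g]) for g in group_configs
    }
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(counts.values()) * 2))
    cohort: dict[str, list[tuple[GroundTruthNetwork, SpikeRaster]]] = {}
    for group, config in group_configs.items():
        pairs = []
        for _ in range(counts[group]):
            net = generate_ground_truth_network(config, np.random.default_rng(next(children)))
            raster = simulate_spikes(net, config, np.random.default_rng(next(children)))
            pairs.append((net, raster))
        cohort[group] = pairs
    return cohort


def mean_firing_rate(cohort: Mapping[str, list[tuple[GroundTruthNetwork, SpikeRaster]]]) -> float:
    """Grand mean per-cell firing rate (spikes/s) across a cohort."""
    rates = [
        raster.spike_counts() / raster.duration_s
        for pairs in cohort.values()
        for _, raster in pairs
    ]
    return float(np.mean(np.concatenate(rates)))
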