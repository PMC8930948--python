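"""Effective-network reconstruction from binary spike rasters.

A binary directed network is predicted by an ensemble of pairwise directed
association measures evaluated at a fixed lag (default one frame, the spike
propagation window): lagged cross-correlation, lagged Cohen's kappa, lagged
mutual information, the follow frequency ``c_ij/s_i``, first-order transfer
entropy, and generalized (burst-conditioned) transfer entropy.  During a
culture-wide burst every cell drives every other cell statistically, so the
lagged contingency measures (cross-correlation, kappa, mutual information,
follow frequency) and the generalized transfer entropy are evaluated only
on non-burst source frames — frames in which no more than a configurable
fraction of the population is co-active; plain transfer entropy on all
frames completes the ensemble.  The member scores are rank-transformed to
[0, 1] across the ordered cell pairs and averaged into a single joint
score; a threshold on the joint score — calibrated on simulated ground
truth — yields the binary adjacency, and each predicted edge is weighted by
its spike-propagation probability ``S_ij`` measured on all frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .metrics import strength_matrix
from .network import EffectiveNetwork
from .raster import SpikeRaster
from .simulate import GroundTruthNetwork

__all__ = [
    "PairwiseScoreStack",
    "CalibrationResult",
    "DEFAULT_MEASURES",
    "pairwise_scores",
    "combine_scores",
    "calibrate_threshold",
    "reconstruct",
]

DEFAULT_MEASURES = (
    "cross_correlation",
    "kappa",
    "mutual_information",
    "transfer_entropy",
    "generalized_transfer_entropy",
    "follow_frequency",
)


@dataclass
class PairwiseScoreStack:
    """One cells x cells score matrix per ensemble measure (diagonals nan)."""

    scores: dict[str, np.ndarray]
    lag: int

    @property
    def measure_names(self) -> tuple[str, ...]:
        return tuple(self.scores)

    @property
    def n_cells(self) -> int:
        return next(iter(self.scores.values())).shape[0]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, ...]:
    """2x2 contingency counts for every ordered (source, target) pair."""
    m = a.shape[1]
    n11 = a @ b.T
    sa = a.sum(axis=1)
    sb = b.sum(axis=1)
    n10 = sa[:, None] - n11
    n01 = sb[None, :] - n11
    n00 = m - n11 - n10 - n01
    return n11, n10, n01, n00, sa, sb


def _xlogy(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """p * log2(q) with the 0 * log 0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = p * (np.log2(np.where(q > 0, q, 1.0)))
    return np.where(p > 0, out, 0.0)


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = a.shape[1]
    n11, _, _, _, sa, sb = _pair_counts(a, b)
    pa, pb = sa / m, sb / m
    cov = n11 / m - np.outer(pa, pb)
    var = np.outer(pa * (1 - pa), pb * (1 - pb))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(var > 0, cov / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return r


def _lagged_kappa(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = a.shape[1]
    n11, _, _, n00, sa, sb = _pair_counts(a, b)
    p_o = (n11 + n00) / m
    pa, pb = sa / m, sb / m
    p_e = np.outer(pa, pb) + np.outer(1 - pa, 1 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(p_e < 1.0, (p_o - p_e) / (1.0 - p_e), 0.0)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = a.shape[1]
    n11, n10, n01, n00, sa, sb = _pair_counts(a, b)
    mi = np.zeros_like(n11, dtype=float)
    for nab, pa_m, pb_m in (
        (n11, sa[:, None], sb[None, :]),
        (n10, sa[:, None], m - sb[None, :]),
        (n01, (m - sa)[:, None], sb[None, :]),
        (n00, (m - sa)[:, None], (m - sb)[None, :]),
    ):
        p = nab / m
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = nab * m / np.where(pa_m * pb_m > 0, pa_m * pb_m, 1.0)
        mi += _xlogy(p, ratio)
    return mi


def _transfer_entropy(x: np.ndarray, lag: int, cols: np.ndarray | None = None) -> np.ndarray:
    """First-order transfer entropy TE(i -> j) in bits.

    Uses the triple (target next state, target previous state, source
    previous state); when ``cols`` is given, only those source frames enter
    the counts (the generalized, burst-conditioned variant).
    """
    src_frames = x[:, :-lag]
    tgt_prev = x[:, :-lag]
    tgt_next = x[:, lag:]
    if cols is not None:
        src_frames = src_frames[:, cols]
        tgt_prev = tgt_prev[:, cols]
        tgt_next = tgt_next[:, cols]
    m = src_frames.shape[1]
    if m == 0:
        return np.zeros((x.shape[0], x.shape[0]))
    src = {1: src_frames, 0: 1.0 - src_frames}
    tgt = {
        (b, c): ((tgt_next == b) & (tgt_prev == c)).astype(float)
        for b in (0, 1)
        for c in (0, 1)
    }
    # counts[a][(b, c)][i, j] = #frames with source i in state a, target j in (next=b, prev=c)
    counts = {a: {bc: src[a] @ tgt[bc].T for bc in tgt} for a in src}
    n = x.shape[0]
    te = np.zeros((n, n))
    for c_state in (0, 1):
        n_c = sum(counts[a][(b, c_state)] for a in (0, 1) for b in (0, 1))
        for a_state in (0, 1):
            n_ac = counts[a_state][(0, c_state)] + counts[a_state][(1, c_state)]
            for b_state in (0, 1):
                n_abc = counts[a_state][(b_state, c_state)]
                n_bc = counts[0][(b_state, c_state)] + counts[1][(b_state, c_state)]
                # p(b|a,c) / p(b|c) = (n_abc / n_ac) / (n_bc / n_c)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = (n_abc * n_c) / np.where(n_ac * n_bc > 0, n_ac * n_bc, 1.0)
                te += _xlogy(n_abc / m, ratio)
    return te


def pairwise_scores(
    raster: SpikeRaster,
    lag_frames: int = 1,
    measures: Sequence[str] = DEFAULT_MEASURES,
    burst_fraction: float = 0.05,
) -> PairwiseScoreStack:
    """Directed association scores from cell i at t to cell j at t + lag.

    All contingency-based measures and the generalized transfer entropy are
    conditioned on the network state: their counts are restricted to
    non-burst source frames, those in which at most
    ``max(burst_fraction * n_cells, 2)`` cells are co-active (default: 5% of the population).  This
    suppresses the common drive that culture-wide avalanches exert on every
    ordered pair, which would otherwise dominate the lag-1 statistics.
    Plain (unconditioned) first-order transfer entropy is the remaining
    member.
    """
    if raster.n_cells < 2:
        raise ValueError("pairwise scores require at least two cells")
    if raster.n_frames < lag_frames + 2:
        raise ValueError("raster too short for the requested lag")
    if raster.spikes.sum() == 0:
        raise ValueError("all-silent raster carries no pairwise information")
    x = raster.spikes.astype(np.float64)
    n = raster.n_cells
    # non-burst source frames: a "burst" needs at least 3 co-active cells
    n_active = x.sum(axis=0)[: x.shape[1] - lag_frames]
    cols = n_active <= max(burst_fraction * n, 2.0)
    if not cols.any():
        cols = np.ones_like(cols, dtype=bool)
    a, b = x[:, :-lag_frames][:, cols], x[:, lag_frames:][:, cols]
    out: dict[str, np.ndarray] = {}
    for name in measures:
        if name == "cross_correlation":
            s = _cross_correlation(a, b)
        elif name == "kappa":
            s = _lagged_kappa(a, b)
        elif name == "mutual_information":
            s = _mutual_information(a, b)
        elif name == "transfer_entropy":
            s = _transfer_entropy(x, lag_frames)
        elif name == "generalized_transfer_entropy":
            s = _transfer_entropy(x, lag_frames, cols=cols)
        elif name == "follow_frequency":
            sa = a.sum(axis=1)
            with np.errstate(invalid="ignore"):
                s = np.where(sa[:, None] > 0, (a @ b.T) / np.where(sa[:, None] > 0, sa[:, None], 1.0), 0.0)
        else:
            raise ValueError(f"unknown measure {name!r}")
        s = s.astype(float).copy()
        np.fill_diagonal(s, np.nan)
        out[name] = s
    return PairwiseScoreStack(scores=out, lag=lag_frames)


def combine_scores(stack: PairwiseScoreStack) -> np.ndarray:
    """Rank-average the ensemble into one joint score matrix in [0, 1].

    Each measure's off-diagonal scores are rank-transformed (ties averaged)
    and scaled to [0, 1]; the joint score is the mean across measures.  A
    constant (uninformative) measure contributes 0.5 everywhere, with a
    warning.
    """
    if len(stack.scores) < 2:
        raise ValueError("combining requires at least two measures")
    n = stack.n_cells
    off = ~np.eye(n, dtype=bool)
    k = off.sum()
    joint = np.zeros((n, n))
    for name, mat in stack.scores.items():
        vals = mat[off]
        if not np.isfinite(vals).all():
            raise ValueError(f"measure {name!r} has non-finite off-diagonal scores")
        if np.ptp(vals) == 0:
            warnings.warn(
                f"measure {name!r} is constant; contributing rank 0.5 everywhere",
                UserWarning,
                stacklevel=2,
            )
            ranked = np.full(k, 0.5)
        else:
            ranked = (rankdata(vals, method="average") - 1.0) / (k - 1.0)
        joint[off] += ranked
    joint /= len(stack.scores)
    np.fill_diagonal(joint, np.nan)
    return joint


@dataclass
class CalibrationResult:
    """Joint-score threshold with the detection quality achieved on it."""

    threshold: float
    mcc: float
    precision: float
    recall: float
    grid: np.ndarray = field(repr=False)
    objective: str = "mcc"


def _mcc(tp: float, fp: float, fn: float, tn: float) -> float:
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom > 0 else 0.0


def calibrate_threshold(
    simulated_pairs: Sequence[tuple[SpikeRaster, GroundTruthNetwork]],
    lag_frames: int = 1,
    grid_size: int = 200,
    objective: Callable[[float, float, float, float], float] | None = None,
) -> CalibrationResult:
    """Choose a joint-score cutoff on simulated ground truth.

    Joint scores and true edge labels are pooled over the supplied
    raster/network pairs (ordered pairs whose source never spikes are
    excluded — no edge can be predicted from them), a grid of ``grid_size``
    evenly spaced score quantiles is scanned, and the threshold maximizing
    the objective (default: Matthews correlation coefficient against the
    planted adjacency) is returned together with the achieved MCC,
    precision, and recall.
    """
    if not simulated_pairs:
        raise ValueError("at least one simulated pair is required")
    scores, labels = [], []
    for raster, net in simulated_pairs:
        joint = combine_scores(pairwise_scores(raster, lag_frames))
        n = net.n_cells
        active = raster.spike_counts() > 0
        mask = ~np.eye(n, dtype=bool) & active[:, None]
        scores.append(joint[mask])
        labels.append(net.adjacency[mask].astype(bool))
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    if y.all() or not y.any():
        raise ValueError("degenerate ground truth: all or no edges present")
    grid = np.unique(np.quantile(s, np.linspace(0.0, 1.0, grid_size)))
    obj = objective if objective is not None else _mcc
    best = None
    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    pos_total, neg_total = y.sum(), (~y).sum()
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(~y_sorted)])
    for thr in grid:
        # predictions are score > thr
        idx = np.searchsorted(s_sorted, thr, side="right")
        tp = pos_total - cum_pos[idx]
        fp = neg_total - cum_neg[idx]
        fn = cum_pos[idx]
        tn = cum_neg[idx]
        val = obj(tp, fp, fn, tn)
        if best is None or val > best[0] + 1e-12:
            best = (val, thr, tp, fp, fn, tn)
    assert best is not None
    _, thr, tp, fp, fn, tn = best
    return CalibrationResult(
        threshold=float(thr),
        mcc=float(_mcc(tp, fp, fn, tn)),
        precision=float(tp / (tp + fp)) if tp + fp > 0 else 0.0,
        recall=float(tp / (tp + fn)) if tp + fn > 0 else 0.0,
        grid=grid,
    )


def reconstruct(
    raster: SpikeRaster,
    threshold: float,
    lag_frames: int = 1,
    measures: Sequence[str] = DEFAULT_MEASURES,
    burst_fraction: float = 0.05,
) -> EffectiveNetwork:
    """Predict the effective network of one raster at a joint-score threshold.

    The adjacency contains every ordered pair whose joint score exceeds the
    threshold; pairs whose source cell never spikes are excluded.  Each
    predicted edge is weighted by the spike-propagation probability
    ``S_ij = c_ij / s_i`` measured in the same raster.
    """
    stack = pairwise_scores(raster, lag_frames, measures, burst_fraction)
    joint = combine_scores(stack)
    active = raster.spike_counts() > 0
    with np.errstate(invalid="ignore"):
        adjacency = (joint > threshold) & active[:, None]
    np.fill_diagonal(adjacency, False)
    weights = strength_matrix(raster, lag_frames) * adjacency
    return EffectiveNetwork(
        adjacency.astype(np.uint8),
        weights,
        provenance={
            "measures": list(measures),
            "lag": lag_frames,
            "threshold": float(threshold),
            "burst_fraction": burst_fraction,
        },
    )
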