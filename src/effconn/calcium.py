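"""Calcium trace processing: dF/F and template-peeling spike inference.

Fluorescence is first converted to relative fluorescence (dF/F) against a
sliding-percentile baseline.  Spikes are then estimated per cell by a greedy
template fitting and peeling loop: the residual trace is matched against a
stereotyped transient; while the best-fitting transient amplitude exceeds a
noise-scaled threshold, a spike is recorded at the match onset and the
fitted template is subtracted from the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransientTemplate",
    "template_kernel",
    "compute_dff",
    "peel_spikes",
    "filter_excitable",
]

from .raster import CalciumTraces, SpikeRaster


@dataclass(frozen=True)
class TransientTemplate:
    """Stereotyped single-spike fluorescence transient.

    The waveform is a peak-normalized difference of exponentials
    ``(1 - exp(-t/rise_tau)) * exp(-t/decay_tau)`` scaled to ``amplitude``
    (in dF/F units).  The default time constants are typical of a fast
    synthetic calcium indicator in dissociated cultures.
    """

    amplitude: float = 0.4
    rise_tau: float = 0.04
    decay_tau: float = 0.5
    length_s: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not (0 < self.rise_tau < self.decay_tau):
            raise ValueError("require 0 < rise_tau < decay_tau")
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")


def template_kernel(template: TransientTemplate, frame_rate: float) -> np.ndarray:
    """Sampled transient waveform, peak-normalized to ``template.amplitude``.

    The first sample (the spike frame itself) is zero; the transient rises
    over the following frames.
    """
    n = max(2, round(template.length_s * frame_rate))
    t = np.arange(n) / frame_rate
    h = (1.0 - np.exp(-t / template.rise_tau)) * np.exp(-t / template.decay_tau)
    return template.amplitude * h / h.max()


def compute_dff(
    traces: CalciumTraces,
    baseline_window_s: float = 30.0,
    baseline_percentile: float = 8.0,
) -> CalciumTraces:
    """Relative fluorescence (F - F0)/F0 with a sliding-percentile baseline.

    F0 is, per cell and frame, the given percentile of the raw trace inside
    a centered window of ``baseline_window_s`` seconds (edge frames use a
    window clamped to the recording).  A percentile low enough to sit below
    the transients (default 8th over 30 s) tracks slow drift while ignoring
    spiking activity.
    """
    w = round(baseline_window_s * traces.frame_rate)
    if w >= traces.n_frames:
        raise ValueError("baseline window must be shorter than the recording")
    if w < 1:
        raise ValueError("baseline window shorter than one frame")
    f = traces.fluorescence
    half = w // 2
    padded = np.pad(f, ((0, 0), (half, w - 1 - half)), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, w, axis=1)
    f0 = np.percentile(windows, baseline_percentile, axis=2)
    bad = np.nonzero((f0 <= 0).any(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"non-positive baseline fluorescence in cell(s) {bad.tolist()}: raw traces invalid"
        )
    return CalciumTraces((f - f0) / f0, frame_rate=traces.frame_rate, is_relative=True)


def robust_noise_sd(trace: np.ndarray) -> float:
    """Noise SD estimated as MAD of the first difference divided by sqrt(2).

    First-differencing removes the slow transient component, and the median
    absolute deviation (scaled to the normal) is insensitive to the sparse
    large excursions the spikes cause.
    """
    d = np.diff(trace)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def peel_spikes(
    dff: CalciumTraces,
    template: TransientTemplate | None = None,
    detection_threshold_sd: float = 3.0,
) -> SpikeRaster:
    """Greedy template fitting and peeling, one cell at a time.

    Per iteration the residual trace is cross-correlated with the template
    (a matched filter yielding the least-squares transient amplitude at each
    candidate onset); a spike is accepted while the best fitted amplitude
    exceeds ``detection_threshold_sd`` times the robust noise SD.  Because
    the matched filter of two overlapping unit transients peaks between
    them, the onset is then localized by a second, rising-edge correlation:
    among the frames within one rise time before the matched-filter peak,
    the earliest whose correlation with the template's rising front supports
    a full-amplitude transient is taken as the spike frame.  The fitted
    template is subtracted and the search repeats.  At most one spike per
    cell per frame is recorded.  The procedure is deterministic.
    """
    if detection_threshold_sd <= 0:
        raise ValueError("detection_threshold_sd must be positive")
    if template is None:
        template = TransientTemplate()
    kernel = template_kernel(template, dff.frame_rate)
    n_frames = dff.n_frames
    if kernel.size >= n_frames:
        raise ValueError("template longer than the trace")
    kk = float(kernel @ kernel)
    # rising front of the transient, used to pin the onset frame
    rise_extent = max(int(np.argmax(kernel)), 1)
    front = kernel[: rise_extent + 1]
    ff = float(front @ front)
    # overlapping transients can pull the matched-filter peak several frames
    # past the first onset; search back over the kernel's significant extent
    backtrack = int(np.nonzero(kernel >= 0.25 * kernel.max())[0][-1]) + 1
    spikes = np.zeros((dff.n_cells, n_frames), dtype=np.uint8)
    for c in range(dff.n_cells):
        residual = dff.fluorescence[c].astype(float).copy()
        sigma = robust_noise_sd(residual)
        # floor keeps the stopping rule meaningful on noiseless traces
        sigma = max(sigma, 1e-3 * template.amplitude)
        floor = detection_threshold_sd * sigma
        for _ in range(n_frames):
            # least-squares amplitude of a transient starting at each frame
            amp = np.correlate(residual, kernel, mode="full")[kernel.size - 1 :] / kk
            amp[spikes[c] == 1] = -np.inf  # one spike per frame
            peak = int(np.argmax(amp))
            if amp[peak] <= floor:
                break
            onset = peak
            for u in range(max(0, peak - backtrack), peak):
                if spikes[c, u]:
                    continue
                seg = residual[u : u + front.size]
                # offset-corrected rise: a transient starting at u leaves
                # residual[u] at the pre-transient level (the front starts at 0)
                if seg.size == front.size and float((seg - seg[0]) @ front) / ff >= 0.75:
                    onset = u
                    break
            spikes[c, onset] = 1
            m = min(kernel.size, n_frames - onset)
            residual[onset : onset + m] -= kernel[:m]
    return SpikeRaster(spikes, frame_rate=dff.frame_rate)


def filter_excitable(
    traces: CalciumTraces,
    stim_frame: int,
    window_s: float = 2.0,
    k_sd: float = 3.0,
) -> np.ndarray:
    """Indices of cells responding to the end-of-recording field stimulation.

    A cell is retained when its mean fluorescence in the ``window_s`` seconds
    after ``stim_frame`` exceeds its pre-stimulus mean by more than ``k_sd``
    pre-stimulus standard deviations.
    """
    if not (0 < stim_frame < traces.n_frames):
        raise ValueError("stim_frame must lie inside the recording")
    w = max(1, round(window_s * traces.frame_rate))
    pre = traces.fluorescence[:, :stim_frame]
    post = traces.fluorescence[:, stim_frame : stim_frame + w]
    if pre.shape[1] < 2:
        raise ValueError("empty pre-stimulus segment")
    thresh = pre.mean(axis=1) + k_sd * pre.std(axis=1)
    return np.nonzero(post.mean(axis=1) > thresh)[0]
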