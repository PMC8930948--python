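# Methods

## The generative model

Ground-truth networks are planted-partition directed graphs: cells are split
into `n_modules` contiguous, nearly equal modules; each ordered pair is
connected with probability `p_within` inside a module and `p_between`
between modules (no self-connections). The control defaults (100 cells, 4
modules, `p_within = 0.6`, `p_between = 0.138`) give an expected
connectivity degree of 0.25, the average density of the culture recordings
this generator emulates. Each edge carries a propagation probability drawn
from a truncated normal — mean 0.41, SD 0.1, truncated to [0.05, 0.8], the
validated propagation range — representing the probability that a spike in
the source cell triggers a spike in the target within one recording frame
(36.6 ms at 27.33 frames/s).

Spiking follows a one-frame Bernoulli cascade. Per frame, every
non-refractory cell fires spontaneously with probability
`background_rate / frame_rate`; in addition, each edge whose source fired in
the previous frame triggers its target independently with the edge's
propagation probability, and simultaneous causes combine as a noisy-OR.
This is the minimal dynamic under which the connection-strength definition
`S_ij = c_ij / s_i` (next-frame follows over source spikes) is exactly the
planted edge parameter for isolated propagation events.

**Refractoriness.** At the stated density and propagation strength the
cascade's branching factor is roughly `(N−1)·c·p ≈ 10`, i.e. deeply
supercritical: without a recovery mechanism a single spontaneous spike
ignites permanent saturation at the frame rate, which no culture shows. A
5-frame (~0.18 s) absolute refractory period is therefore part of the
default dynamics (configurable, including 0). It terminates each avalanche
after a few frames, producing the empirically observed pattern: long
quiescent stretches of isolated spikes punctuated by sparse culture-wide
population bursts in which most cells fire about once. Shorter refractory
periods (≤3 frames) let avalanches re-ignite in anti-phase and saturate the
network; this motivated the default.

**Calibration.** With supercritical propagation nearly every spontaneous
spike ignites one burst, so the cohort firing rate is approximately
`n_cells · background_rate · (spikes per burst per cell)`. The default
`background_rate = 0.002` spikes/s/cell was fixed once by a sweep
(0.0018 → 0.195, 0.0024 → 0.231 spikes/s at the default topology) to land
the control cohort at ~0.2 spikes/s, the firing rate of spontaneous culture
activity.

**What the generator does and does not emulate.** It reproduces population
sizes (100–300 cells), frame rate, firing rate, density, the
propagation-probability range, modular topology, and right-skewed
burst-participation histograms. It does not model membrane or synaptic
kinetics, inhibition, synaptic depression or facilitation, slow
development, or imaging artifacts (drift, bleaching, motion). Passing tests
therefore demonstrate correctness of the analysis chain under the stated
statistical structure, not robustness to every property of real recordings.

## Calcium forward model and spike inference

Each spike adds a peak-normalized difference-of-exponentials transient
`(1 − e^(−t/τ_rise)) · e^(−t/τ_decay)` (defaults τ_rise = 40 ms,
τ_decay = 0.5 s, amplitude 0.4 ΔF/F, 3 s support — typical fast-indicator
values, all configurable); transients superpose linearly on a constant
baseline with optional Gaussian noise.

ΔF/F uses F₀ = the 8th percentile of the raw trace in a centered 30 s
sliding window (clamped at the edges); a non-positive F₀ is treated as an
invalid recording and reported with the offending cell index.

Spike inference is greedy template fitting and peeling. A matched filter
gives the least-squares transient amplitude at every candidate onset; the
best candidate is accepted while its amplitude exceeds
`detection_threshold_sd` (default 3) times the robust noise SD (median
absolute deviation of the first difference, scaled by 1/√2 — insensitive to
transients; floored at 0.1% of the template amplitude so the stopping rule
survives noiseless input). Because the matched filter of two overlapping
unit transients peaks between their onsets, the onset is then pinned by a
rising-edge correlation: within the kernel's significant extent before the
peak, the earliest frame whose offset-corrected correlation with the
template's rising front reaches 75% of a unit transient is taken as the
spike frame. The fitted template is subtracted and the search repeats, at
most one spike per cell per frame. On noiseless traces this recovers
planted rasters exactly down to two-frame inter-spike intervals.

## Network reconstruction

Six directed pairwise measures are computed from source frame `t` to target
frame `t+lag` (lag defaults to one frame, the propagation window): lagged
Pearson cross-correlation, lagged Cohen's kappa, lagged mutual information,
the follow frequency `c_ij/s_i`, first-order transfer entropy, and
generalized transfer entropy. During a culture-wide burst every cell
statistically drives every other cell, and this common drive dominates all
lag-1 pair statistics; the contingency measures and the generalized
transfer entropy are therefore evaluated only on non-burst source frames —
frames with at most `max(0.05·N, 2)` co-active cells. The 5% ceiling was
chosen by a design sweep on a simulated benchmark (joint-score AUC 0.97 /
0.89 / 0.80 at ceilings 0.05 / 0.1 / 0.2) and is configurable. Plain,
unconditioned transfer entropy remains in the ensemble as the
all-frames member.

Member scores are rank-transformed to [0, 1] across the ordered cell pairs
of the recording (ties averaged; a constant measure contributes 0.5
everywhere with a warning) and averaged into the joint score. The decision
threshold is calibrated on simulated raster/ground-truth pairs by scanning
200 joint-score quantiles and maximizing the Matthews correlation
coefficient; pairs whose source cell never spikes are excluded (no edge can
be predicted from a silent source). Predicted edges are weighted by
`S_ij = c_ij/s_i` measured on all frames, per the connection-strength
definition.

**Known limitations.** (i) Because ranks are taken within each recording,
the joint score is scale-free: a single global threshold predicts a similar
*number* of edges in every recording, so between-group differences in true
density are attenuated in the predicted degree; group effects expressed in
raster statistics (synchrony, firing rate) or edge weights (network
strength) transfer unimpeded. (ii) In the supercritical avalanche regime
the follow-count weight estimator is biased low on true edges (a source
spike in a terminal avalanche stage is followed by network silence); it is
unbiased when propagation events are isolated, i.e. in subcritical or
weakly coupled activity. (iii) Only excitatory (positive) influences are
inferred.

## Graph metrics

All conventions follow the directed-weighted practice of the brain-network
literature:

- Synchrony K is the mean over ordered cell pairs of Cohen's kappa between
  the two binary spike trains; inside each pair's agreement terms the
  normalizer is the number of frames T (the only dimensionally consistent
  reading), while the outer average runs over the N(N−1) cell pairs. Pairs
  with chance agreement 1 contribute 0.
- Weighted distances accumulate edge lengths `1/S_ij`; an edge of zero
  weight is traversable only in the binary matrix.
- Characteristic path lengths exclude unreachable pairs and renormalize
  each node's average over its reachable targets (nodes reaching nothing
  are excluded from the outer mean); unreachable pairs contribute 0 to
  global efficiency and betweenness. This keeps values finite and
  comparable across sparse networks.
- Directed clustering counts triangles over all eight edge orientations,
  `½[(A+Aᵀ)³]_ii` over `(k_tot)(k_tot−1) − 2·reciprocal`, with cube-root
  weights in the numerator for the weighted variant (Fagiolo convention);
  zero-denominator nodes contribute 0.
- Modularity is the directed (Leicht–Newman) form
  `Q = (1/l) Σ (a_ij − k_i^out k_j^in / l) δ(m_i, m_j)` on the binary
  adjacency; a single all-in-one module gives exactly 0. Louvain community
  detection runs `n_restarts` seeded passes (default 100) and returns the
  partition with the highest Q as recomputed by this package's own
  modularity; ties keep the earlier run.
- Betweenness uses binary shortest paths with the `(N−1)(N−2)`
  normalization; vulnerability recomputes weighted global efficiency on the
  induced (N−1)-node network for every removal.
- Degenerate inputs resolve to 0-with-warning (silent sources, empty
  networks' strength) or raise (edgeless Louvain/modularity, vulnerability
  at zero efficiency).

Correctness is verified against independent brute-force oracles (explicit
Floyd–Warshall, exhaustive shortest-path enumeration, direct triple-loop
clustering, exhaustive set-partition search for maximal modularity): all 64
three-node digraphs exhaustively, randomized 4–6-node binary and 7-node
weighted graphs, and Louvain-vs-exhaustive partitions on 5–8-node graphs —
sizes chosen so the whole suite runs in minutes.

## Random reference networks and statistics

Reference networks place exactly 5814 directed connections uniformly
without replacement among the off-diagonal positions of a 153-cell
adjacency (the study-average size and density, degree 0.25 exactly) and
draw each weight from Normal(0.41, 0.03), clipped to (0, 1] since strengths
are probabilities (the clip is a no-op in practice).

Group comparisons use one-way ANOVA (df = (k−1, n−k)) followed by two-sided
Dunnett many-to-one tests against the control group via the multivariate-t
distribution of the contrast vector (equal variances), with stars at
0.05/0.01/0.001. Correlations between network-level quantities are plain
squared Pearson coefficients. The type-I error of the full
simulate→reconstruct→degree→ANOVA chain is checked by 400 seeded null
replicates (3 groups × 6 networks of 15 cells, 30 s, ignition rate scaled
to 0.02 so small rasters are never silent) against the Monte-Carlo 95%
interval around 0.05.

## Reproducibility

Every stochastic component takes a NumPy `Generator` or integer seed;
cohort generation spawns one independent stream per culture from a master
seed, and the pipeline derives per-stage seeds from its master seed, so
identical configurations reproduce outputs bit for bit. Output files carry
the SHA-256 hash of the generating configuration.
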