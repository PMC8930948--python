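"""End-to-end pipeline: simulate -> (calcium -> spikes) -> reconstruct ->
metrics -> random references -> group comparison.

The pipeline is fully reproducible: the master seed deterministically spawns
one sub-seed per stage (and per simulated culture), and every output file
carries the hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as effio
from .calcium import TransientTemplate, compute_dff, peel_spikes
from .metrics import compute_all
from .random_reference import RandomReferenceConfig, generate_random_networks
from .reconstruct import calibrate_threshold, reconstruct
from .simulate import SimulationConfig, WeightDistribution, generate_cohort
from .stats import comparison_table, summarize_cohort

logger = logging.getLogger("effconn")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    ``groups`` maps group names to simulation parameter overrides (fields of
    :class:`SimulationConfig`); the control group must be present.  When
    ``use_calcium`` is set, rasters are routed through the calcium forward
    model and the template-peeling inference instead of being passed to the
    reconstruction directly.
    """

    groups: dict[str, dict] = field(
        default_factory=lambda: {"control": {}, "treated": {"p_within": 0.45, "p_between": 0.1}}
    )
    n_networks: int = 5
    control: str = "control"
    use_calcium: bool = False
    noise_sd: float = 0.03
    detection_threshold_sd: float = 3.0
    template: dict = field(default_factory=dict)
    lag_frames: int = 1
    calibration_networks: int = 3
    threshold: float | None = None
    louvain_restarts: int = 20
    random_reference: dict | None = None
    seed: int = 0
    out_dir: str = "effconn_out"

    def __post_init__(self) -> None:
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} missing from groups")

    # --- lossless text round trip -------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def simulation_config(self, group: str, seed: int) -> SimulationConfig:
        params = dict(self.groups[group])
        wd = params.pop("weight_distribution", None)
        if wd is not None:
            params["weight_distribution"] = WeightDistribution(**wd)
        return SimulationConfig(seed=seed, **params)


def _stage(name: str, t0: float) -> None:
    logger.info("stage %-14s %6.2f s", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Returns a report dict with the per-network metric records, the group
    comparison table, and the calibrated threshold.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "config.yaml").write_text(config.to_yaml())
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_cal, seed_louvain, seed_ref = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    group_configs = {g: config.simulation_config(g, seed_sim) for g in config.groups}
    cohort = generate_cohort(group_configs, config.n_networks, seed=seed_sim)
    _stage("simulate", t0)

    # --- spike inference (optional calcium round trip) ------------------
    if config.use_calcium:
        t0 = time.perf_counter()
        from .simulate import synthesize_calcium

        template = TransientTemplate(**config.template)
        rng = np.random.default_rng(seed_sim + 1)
        for pairs in cohort.values():
            for k, (net, raster) in enumerate(pairs):
                traces = synthesize_calcium(raster, template, config.noise_sd, rng=rng)
                dff = compute_dff(traces)
                pairs[k] = (net, peel_spikes(dff, template, config.detection_threshold_sd))
        _stage("infer-spikes", t0)

    # --- calibrate ------------------------------------------------------
    t0 = time.perf_counter()
    if config.threshold is None:
        cal_config = config.simulation_config(config.control, seed_cal)
        cal_pairs = [
            (raster, net)
            for net, raster in (
                pair
                for pairs in generate_cohort(
                    {config.control: cal_config}, config.calibration_networks, seed=seed_cal
                ).values()
                for pair in pairs
            )
        ]
        calibration = calibrate_threshold(cal_pairs, lag_frames=config.lag_frames)
        threshold = calibration.threshold
        (out / "calibration.json").write_text(
            json.dumps(
                {
                    "threshold": calibration.threshold,
                    "mcc": calibration.mcc,
                    "precision": calibration.precision,
                    "recall": calibration.recall,
                    "config_hash": chash,
                },
                indent=1,
            )
            + "\n"
        )
    else:
        threshold = config.threshold
    _stage("calibrate", t0)

    # --- reconstruct + metrics -----------------------------------------
    t0 = time.perf_counter()
    metrics_by_group: dict[str, list] = {}
    for group, pairs in cohort.items():
        records = []
        for k, (net, raster) in enumerate(pairs):
            eff = reconstruct(raster, threshold, lag_frames=config.lag_frames)
            m = compute_all(
                eff, raster, louvain_restarts=config.louvain_restarts, seed=seed_louvain
            )
            records.append(m)
            prefix = out / f"{group}_{k:03d}"
            effio.write_raster(raster, prefix.with_name(prefix.name + "_raster.tsv"),
                               config_hash=chash, group=group)
            effio.write_network(eff, prefix, config_hash=chash, group=group)
            effio.write_metrics(m, prefix.with_name(prefix.name + "_metrics.json"),
                                config_hash=chash, group=group)
        metrics_by_group[group] = records
    _stage("reconstruct", t0)

    # --- random references ----------------------------------------------
    reference_metrics = None
    if config.random_reference is not None:
        t0 = time.perf_counter()
        ref_config = RandomReferenceConfig(seed=seed_ref, **config.random_reference)
        refs = generate_random_networks(ref_config)
        reference_metrics = [
            compute_all(r, louvain_restarts=config.louvain_restarts, seed=seed_louvain)
            for r in refs
        ]
        _stage("random-ref", t0)

    # --- group statistics -----------------------------------------------
    t0 = time.perf_counter()
    comparisons = summarize_cohort(metrics_by_group, control=config.control)
    table = comparison_table(comparisons)
    table.to_csv(out / "comparison.tsv", sep="\t", index=False)
    (out / "comparison.json").write_text(
        json.dumps([c.to_dict() for c in comparisons], indent=1, default=str) + "\n"
    )
    _stage("compare", t0)

    return {
        "config_hash": chash,
        "threshold": threshold,
        "metrics_by_group": metrics_by_group,
        "reference_metrics": reference_metrics,
        "comparisons": comparisons,
        "table": table,
    }
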