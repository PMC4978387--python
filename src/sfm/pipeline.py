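"""End-to-end pipeline: configuration, execution, artifact writing.

A :class:`PipelineConfig` captures every stage parameter (synthetic-scene
sizes, preprocessing flags, ground-truth model, analysis band, FC metric,
comparison space, inverse method, parameter grid, seeds, output directory)
and round-trips losslessly through YAML; unknown keys are rejected so stale
config files fail loudly. :func:`run_pipeline` executes

    synth scene -> "empirical" recording -> (inverse | sensor space)
    -> FC metric -> grid search -> local/node error analysis

and writes the edge table, node table, FC matrices and grid surface, all
stamped with a hash of the configuration, plus a timestamped provenance log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scipy.signal import sosfiltfilt

from . import __version__
from .estimators import StructureFunctionModel
from .evaluation import FitResult, node_metrics
from .io import save_dataset_h5
from .signals import bandpass_sos, compute_fc_metric, to_analytic
from .synthetic import generate_empirical_like_recording, generate_scene


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run. Seeds are always explicit."""

    # synthetic scene
    n_per_hemisphere: int = 33
    n_sensors: int = 64
    seed: int = 1
    # ground truth ("empirical" side)
    truth_model: str = "sar"
    true_k: float = 0.65
    true_h: float = 0.1
    sensor_snr: float = 10.0
    duration: float = 60.0
    sample_rate: float = 1000.0
    # preprocessing of the structural connectome
    size_norm: str = "product"
    length_weighting: bool = False
    input_norm: bool = True
    # analysis band and FC metric
    band_center: float = 8.0
    bandwidth: float = 4.0
    metric: str = "coh"
    # comparison space and inverse method
    space: str = "source"  # 'source' | 'sensor' | 'reconstructed'
    inverse_method: str = "lcmv"  # 'lcmv' | 'mne'
    reg_fraction: float = 0.05
    snr: float = 3.0
    band_limit_before_inverse: bool = True
    # model and search grid
    model: str = "sar"
    k_values: list = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 20)])
    h_values: list = field(default_factory=lambda: [0.0, 0.05, 0.1, 0.15, 0.2])
    kuramoto: dict = field(default_factory=dict)
    # output
    outdir: str = "sfm_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Short content hash; changes whenever any parameter changes."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def empirical_fc_from_recording(config: PipelineConfig, scene, recording):
    """Empirical-side FC and (for source-level comparisons) inverse weights.

    Sensor data are optionally band-limited to the analysis band before the
    inverse (standard practice for narrowband source connectivity: the
    in-band SNR is what matters for the spatial filter). Returns
    ``(fc_emp, weights)``; ``weights`` is None in sensor space.
    """
    from .electromagnetics import LCMVBeamformer, MinimumNormEstimate, SensorTimeSeries

    data = recording.data
    if config.band_limit_before_inverse and config.space != "sensor":
        sos = bandpass_sos(recording.sample_rate, config.band_center, config.bandwidth)
        data = sosfiltfilt(sos, data, axis=-1)

    weights = None
    if config.space in ("source", "reconstructed"):
        if config.inverse_method == "lcmv":
            inv = LCMVBeamformer(scene.leadfield, config.reg_fraction).fit(data.T)
        elif config.inverse_method == "mne":
            inv = MinimumNormEstimate(scene.leadfield, config.snr).fit()
        else:
            raise ValueError("inverse_method must be 'lcmv' or 'mne'")
        weights = inv.weights_
        data = inv.transform(data.T).T
    elif config.space != "sensor":
        raise ValueError("space must be 'source', 'sensor' or 'reconstructed'")
    aset = to_analytic(data, recording.sample_rate, config.band_center, config.bandwidth)
    return compute_fc_metric(aset, config.metric), weights


def run_pipeline(config: PipelineConfig) -> FitResult:
    """Execute every stage and write all artifacts under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.hash()
    log_path = outdir / f"pipeline_{tag}.log"
    t0 = time.time()

    def log(msg: str):
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        with open(log_path, "a") as fh:
            fh.write(f"{stamp} [{time.time() - t0:8.2f}s] {msg}\n")

    log(f"config hash {tag}; sfm version {__version__}")
    config.to_yaml(outdir / f"config_{tag}.yaml")

    stage = "synthetic scene"
    try:
        scene = generate_scene(config.n_per_hemisphere, config.n_sensors, seed=config.seed)
        log(f"stage done: {stage} (seeds {scene.seeds})")

        stage = "empirical recording"
        recording, _, _ = generate_empirical_like_recording(
            scene,
            model=config.truth_model,
            params={"k": config.true_k, "h": config.true_h},
            sensor_noise_snr=config.sensor_snr,
            duration=config.duration,
            sample_rate=config.sample_rate,
            band_center=config.band_center,
            bandwidth=config.bandwidth,
            seed=scene.seeds.get("recording", config.seed),
            size_norm=config.size_norm,
            input_norm=config.input_norm,
        )
        log(f"stage done: {stage}")

        stage = "empirical FC"
        fc_emp, weights = empirical_fc_from_recording(config, scene, recording)
        log(f"stage done: {stage} ({config.space} space, metric {config.metric})")

        stage = "grid search"
        est = StructureFunctionModel(
            raw=scene.raw,
            geometry=scene.geometry,
            model=config.model,
            grid={"k": np.asarray(config.k_values), "h": np.asarray(config.h_values)},
            size_norm=config.size_norm,
            length_weighting=config.length_weighting,
            input_norm=config.input_norm,
            metric=config.metric,
            kuramoto=config.kuramoto or None,
            band_center=config.band_center,
            bandwidth=config.bandwidth,
            space=config.space,
            leadfield=scene.leadfield if config.space != "source" else None,
            weights=weights,
        )
        est.fit(fc_emp)
        result = est.result_
        log(
            f"stage done: {stage} (best {result.best_params}, r = {result.best_r:.4f}, "
            f"{result.n_unstable} unstable grid points)"
        )

        stage = "artifact writing"
        _write_artifacts(config, scene, fc_emp, result, outdir, tag)
        log(f"stage done: {stage}")
    except Exception as err:
        log(f"stage FAILED: {stage}: {err!r} (partial outputs in {outdir})")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    log("pipeline complete")
    return result


def _write_artifacts(config, scene, fc_emp, result: FitResult, outdir: Path, tag: str):
    n = scene.geometry.n_rois
    iu = np.triu_indices(n, k=1)
    labels = scene.geometry.labels

    if config.space != "sensor":
        edges = pd.DataFrame(
            {
                "roi_i": [labels[i] for i in iu[0]],
                "roi_j": [labels[j] for j in iu[1]],
                "fc_model": result.fc_model[iu],
                "fc_emp": fc_emp[iu],
                "residual": result.residuals,
                "fiber_dist": scene.geometry.fiber_dist[iu],
                "euclid_dist": scene.geometry.euclid_dist[iu],
            }
        )
        edges.to_csv(outdir / f"edges_{tag}.csv", index=False)

        metrics = node_metrics(_best_s(result, scene, config))
        nodes = pd.DataFrame(
            {
                "label": labels,
                "size": scene.geometry.sizes,
                "betweenness": metrics["betweenness"],
                "strength": metrics["strength"],
                "eigenvector_centrality": metrics["eigenvector_centrality"],
                "clustering": metrics["clustering"],
                "mean_error": result.node_error,
            }
        )
        nodes.to_csv(outdir / f"nodes_{tag}.csv", index=False)

    surface_path = outdir / f"grid_{tag}.h5"
    save_dataset_h5(surface_path, "grid/performance", result.performance)
    for name, vals in result.grid_axes.items():
        save_dataset_h5(surface_path, f"grid/axis_{name}", vals)
    save_dataset_h5(surface_path, "fc/model", result.fc_model)
    save_dataset_h5(surface_path, "fc/empirical", fc_emp)


def _best_s(result: FitResult, scene, config) -> np.ndarray:
    from .connectome import build_structural_connectome

    sc = build_structural_connectome(
        scene.raw,
        geometry=scene.geometry,
        size_norm=config.size_norm,
        length_weighting=config.length_weighting,
        h=result.best_params.get("h", 0.0),
        input_norm=config.input_norm,
    )
    S = sc.S
    return 0.5 * (S + S.T)  # symmetrize for graph metrics when input-normalized
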