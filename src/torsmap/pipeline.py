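"""End-to-end pipeline: trajectory -> weights -> distances -> clusters ->
fingerprints -> classification -> thermodynamics, with every artifact
written to disk and a machine-readable run log."""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import DensityPeaks
from .errors import StageError, TorsmapError
from .fingerprints import FingerprintClassifier
from .io import (read_colvar, read_csv_trajectory, save_distance_matrix,
                 write_cluster_result, write_colvar, write_fingerprints,
                 write_labels_csv)
from .metric import distance_matrix
from .profiles import compute_weights, profile_weights
from .synthetic import sample_unbiased, sildenafil_like_world
from .thermo import decompose, reweight


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    Defaults follow the method's stated parameters: 2% neighbor fraction,
    300 K, Euclidean metric composition with rounded weights.
    """

    # input: either a trajectory file or a synthetic preset
    input_path: str | None = None
    input_format: str = "colvar"            # colvar | csv
    preset: str | None = None               # e.g. "sildenafil-like"
    n_frames: int = 6000
    seed: int = 1
    stride: int = 1
    bias_column: str | None = None
    energy_columns: dict = field(default_factory=dict)
    # weights
    barriers: list | None = None            # explicit per-torsion barriers (kT)
    # metric / clustering
    temperature: float = 300.0
    n_bins: int = 72                        # profile resolution
    fingerprint_bins: int = 36
    metric_form: str = "euclidean"
    use_rounded_weights: bool = True
    neighbor_fraction: float = 0.02
    k: int | None = None
    rho_min: float | None = None
    delta_min: float | None = None
    centers: list | None = None
    halo: str = "center-distance"
    support_min_count: int = 1
    tie_break: str = "probability"
    reference_cluster: int | None = None
    n_boot: int = 200
    outdir: str = "torsmap_run"


def _load_input(cfg: RunConfig):
    if cfg.preset:
        if cfg.preset != "sildenafil-like":
            raise StageError("input", f"unknown preset {cfg.preset!r}")
        world = sildenafil_like_world(temperature=cfg.temperature)
        traj, labels = sample_unbiased(world, cfg.n_frames, seed=cfg.seed)
        return traj, world
    if not cfg.input_path:
        raise StageError("input", "either input_path or preset is required")
    reader = read_colvar if cfg.input_format == "colvar" else read_csv_trajectory
    try:
        traj = reader(cfg.input_path, bias_column=cfg.bias_column,
                      energy_columns=cfg.energy_columns or None,
                      stride=cfg.stride)
    except TorsmapError as exc:
        raise StageError("input", str(exc)) from exc
    return traj, None


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write artifacts into ``cfg.outdir``.

    The run is a pure function of (inputs, config, seed): rerunning with
    the same configuration reproduces every artifact byte for byte.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    traj, world = _load_input(cfg)
    if cfg.preset:
        write_colvar(traj, out / "synthetic.colvar")

    try:
        if cfg.barriers is not None:
            weights = compute_weights(cfg.barriers,
                                      angle_names=traj.angle_names)
        else:
            weights = profile_weights(traj, n_bins=cfg.n_bins,
                                      temperature=cfg.temperature)
    except TorsmapError as exc:
        raise StageError("weights", str(exc)) from exc
    (out / "weights.json").write_text(json.dumps({
        "angle_names": list(traj.angle_names),
        "barriers_kT": np.asarray(weights.raw).tolist(),
        "normalized": weights.normalized.tolist(),
        "rounded": weights.rounded.tolist(),
    }, indent=1))

    try:
        dm = distance_matrix(traj, weights=weights, form=cfg.metric_form,
                             use_rounded=cfg.use_rounded_weights,
                             dtype=np.float32, weight_vector_id="weights.json")
        save_distance_matrix(dm, out / "dist.npz")
        model = DensityPeaks(
            metric="precomputed", neighbor_fraction=cfg.neighbor_fraction,
            k=cfg.k, rho_min=cfg.rho_min, delta_min=cfg.delta_min,
            centers=cfg.centers, halo=cfg.halo,
        ).fit(dm.values.astype(np.float64))
    except TorsmapError as exc:
        raise StageError("cluster", str(exc)) from exc
    model.decision_graph().to_csv(out / "decision_graph.tsv", sep="\t",
                                  index_label="point")
    write_cluster_result(model, out / "clusters.json")

    try:
        clf = FingerprintClassifier(
            n_bins=cfg.fingerprint_bins,
            support_min_count=cfg.support_min_count, tie_break=cfg.tie_break,
        ).fit(traj, model.labels_, is_core=model.is_core_)
        write_fingerprints(clf.fingerprints_, out / "fingerprints.json")
        classified = clf.classify(traj)
        write_labels_csv(classified, out / "labels.csv", time=traj.time)
    except TorsmapError as exc:
        raise StageError("fingerprint", str(exc)) from exc

    thermo_written = False
    if traj.energy_solute is not None and traj.energy_solute_solvent is not None:
        try:
            fw = reweight(traj.bias, cfg.temperature) if traj.bias is not None \
                else None
            ref = cfg.reference_cluster
            if ref is None:
                pops = [(classified.labels == c).sum()
                        for c in clf.classes_]
                ref = int(clf.classes_[int(np.argmax(pops))])
            report = decompose(traj, classified.labels, fw, ref,
                               temperature=cfg.temperature, n_boot=cfg.n_boot,
                               seed=cfg.seed)
            report.table.to_csv(out / "thermo.csv")
        except TorsmapError as exc:
            raise StageError("thermo", str(exc)) from exc
        thermo_written = True
    elif cfg.energy_columns:
        raise StageError(
            "thermo", "energy columns requested but absent from the input"
        )

    log = {
        "torsmap_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "config": asdict(cfg),
        "n_frames": traj.n_frames,
        "n_cv": traj.n_cv,
        "d_c": float(model.d_c_),
        "n_clusters": int(model.n_clusters_),
        "fraction_classified": classified.fraction_classified,
        "thermo_written": thermo_written,
    }
    (out / "run.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return out


def load_config(path) -> RunConfig:
    """Read a flat ``key = value`` config file (JSON values allowed)."""
    cfg = RunConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise StageError("config", f"{path}:{lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise StageError("config", f"{path}:{lineno}: unknown key {key!r}")
        try:
            parsed = json.loads(value)
        except json.JSONDecodeError:
            parsed = value
        setattr(cfg, key, parsed)
    return cfg
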