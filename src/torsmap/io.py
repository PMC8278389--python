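"""Readers and writers for trajectories, fingerprints, distance matrices and
cluster results.

Trajectory input follows the PLUMED COLVAR dialect — whitespace-delimited
columns introduced by a ``#! FIELDS <names...>`` header line — or plain CSV
with a header row. Fingerprints and cluster results are self-describing JSON;
distance matrices go into an ``.npz`` container with a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ColvarParseError, EmptyInputError, FormatError, MissingColumnError
from .trajectory import DihedralTrajectory, wrap_angles

FINGERPRINT_FORMAT = "torsmap-fingerprints"
FINGERPRINT_VERSION = 1

_ENERGY_KEYS = ("solute", "solvent", "solute_solvent")


def _parse_colvar_table(path):
    """Return (field_names, data ndarray) from a COLVAR file.

    Comment lines after the first header are ignored, except a ``#! FIELDS``
    line that changes the column set, which is an error mid-file.
    """
    fields = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line.split()
                if len(tokens) >= 2 and tokens[1] == "FIELDS":
                    names = tokens[2:]
                    if fields is None:
                        fields = names
                    elif names != fields:
                        raise ColvarParseError(
                            f"{path}:{lineno}: FIELDS header changed mid-file"
                        )
                continue
            if fields is None:
                raise ColvarParseError(
                    f"{path}:{lineno}: data before '#! FIELDS' header"
                )
            parts = line.split()
            if len(parts) != len(fields):
                raise ColvarParseError(
                    f"{path}:{lineno}: expected {len(fields)} columns, got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise ColvarParseError(
                    f"{path}:{lineno}: non-numeric entry in data row"
                )
    if fields is None:
        raise ColvarParseError(f"{path}: no '#! FIELDS' header found")
    if not rows:
        raise EmptyInputError(f"{path}: file contains no data rows")
    return fields, np.asarray(rows, dtype=float)


def _build_trajectory(fields, data, angle_columns, bias_column, energy_columns,
                      time_column, degrees, stride):
    colmap = {name: i for i, name in enumerate(fields)}

    def col(name):
        if name not in colmap:
            raise MissingColumnError(
                f"column {name!r} not in header; available: {fields}"
            )
        return data[:, colmap[name]]

    reserved = set()
    if time_column in colmap:
        reserved.add(time_column)
    if bias_column:
        reserved.add(bias_column)
    energy_columns = dict(energy_columns or {})
    for key in energy_columns:
        if key not in _ENERGY_KEYS:
            raise ValueError(
                f"unknown energy component {key!r}; expected one of {_ENERGY_KEYS}"
            )
    reserved.update(energy_columns.values())

    if angle_columns is None:
        angle_columns = [f for f in fields if f not in reserved]
    angles = np.column_stack([col(name) for name in angle_columns])
    if degrees:
        angles = np.deg2rad(angles)
    angles = wrap_angles(angles)

    kwargs = {}
    if time_column in colmap:
        kwargs["time"] = col(time_column)
    if bias_column:
        kwargs["bias"] = col(bias_column)
    for key, name in energy_columns.items():
        kwargs[f"energy_{key}"] = col(name)

    traj = DihedralTrajectory(angles, list(angle_columns), **kwargs)
    if stride > 1:
        traj = traj.take(np.arange(0, traj.n_frames, stride))
    return traj


def read_colvar(path, angle_columns=None, bias_column=None, energy_columns=None,
                time_column="time", degrees=False, stride=1) -> DihedralTrajectory:
    """Read a PLUMED-style COLVAR file into a :class:`DihedralTrajectory`.

    Parameters
    ----------
    angle_columns : sequence of str, optional
        Names of the torsion columns. Defaults to every field that is not the
        time column, the bias column, or an energy column.
    bias_column : str, optional
        Field holding the per-frame total bias potential (kJ/mol).
    energy_columns : mapping, optional
        Maps ``"solute"``, ``"solvent"``, ``"solute_solvent"`` to field names.
    degrees : bool
        Convert input angles from degrees to radians on read.
    stride : int
        Keep every ``stride``-th frame (the analysis stride is left to the
        user; 1 keeps everything).
    """
    fields, data = _parse_colvar_table(path)
    return _build_trajectory(fields, data, angle_columns, bias_column,
                             energy_columns, time_column, degrees, stride)


def read_csv_trajectory(path, angle_columns=None, bias_column=None,
                        energy_columns=None, time_column="time", degrees=False,
                        stride=1) -> DihedralTrajectory:
    """CSV alternative to :func:`read_colvar` (header row names the columns)."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: file contains no data rows")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ColvarParseError(f"{path}: non-numeric columns {non_numeric}")
    return _build_trajectory(list(df.columns), df.to_numpy(dtype=float),
                             angle_columns, bias_column, energy_columns,
                             time_column, degrees, stride)


def write_colvar(traj: DihedralTrajectory, path, bias_column="metad.bias",
                 energy_columns=None):
    """Write a trajectory in COLVAR format (lossless for float64 via repr)."""
    energy_columns = energy_columns or {
        "solute": "ene.solute",
        "solvent": "ene.solvent",
        "solute_solvent": "ene.xsolv",
    }
    names = ["time"] + list(traj.angle_names)
    cols = [traj.time if traj.time is not None
            else np.arange(traj.n_frames, dtype=float)]
    cols += [traj.angles[:, i] for i in range(traj.n_cv)]
    if traj.bias is not None:
        names.append(bias_column)
        cols.append(traj.bias)
    for key in _ENERGY_KEYS:
        val = getattr(traj, f"energy_{key}")
        if val is not None:
            names.append(energy_columns[key])
            cols.append(val)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# fingerprints

def write_fingerprints(fingerprints, path):
    """Serialize a :class:`~torsmap.fingerprints.FingerprintSet` as JSON.

    The format is self-describing (bin edges, per-bin probabilities, support
    masks, cluster ids, angle names) and round-trips float64 exactly.
    """
    payload = {
        "format": FINGERPRINT_FORMAT,
        "version": FINGERPRINT_VERSION,
        **fingerprints.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return Path(path)


def read_fingerprints(path):
    """Read fingerprints written by :func:`write_fingerprints`, validating
    format, version and per-angle normalization (tolerance 1e-6)."""
    from .fingerprints import FingerprintSet

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != FINGERPRINT_FORMAT:
        raise FormatError(f"{path}: not a fingerprint file")
    if payload.get("version") != FINGERPRINT_VERSION:
        raise FormatError(
            f"{path}: unsupported fingerprint version {payload.get('version')!r}"
        )
    required = {"angle_names", "bin_edges", "fingerprints"}
    missing = required - payload.keys()
    if missing:
        raise FormatError(f"{path}: missing fields {sorted(missing)}")
    fps = FingerprintSet.from_dict(payload)
    sums = fps.probs.sum(axis=2)
    nonempty = fps.probs.any(axis=2)
    if np.any(np.abs(sums[nonempty] - 1.0) > 1e-6):
        raise FormatError(
            f"{path}: per-angle probabilities do not sum to 1 within 1e-6"
        )
    return fps


# ---------------------------------------------------------------------------
# distance matrices

def save_distance_matrix(dm, path):
    """Persist a distance matrix in a binary ``.npz`` container with a
    SHA-256 checksum over the value bytes (matrices are O(N^2); text export
    is available separately via :func:`export_distance_matrix_text`)."""
    values = np.ascontiguousarray(dm.values)
    meta = {
        "checksum": hashlib.sha256(values.tobytes()).hexdigest(),
        "form": dm.form,
        "weight_vector_id": dm.weight_vector_id,
        "dtype": str(values.dtype),
    }
    np.savez(path, values=values, meta=np.array(json.dumps(meta)))
    return Path(path)


def load_distance_matrix(path):
    """Load and checksum-verify a distance matrix container."""
    from .metric import DistanceMatrix

    with np.load(path, allow_pickle=False) as npz:
        values = npz["values"]
        meta = json.loads(str(npz["meta"]))
    digest = hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()
    if digest != meta["checksum"]:
        raise FormatError(f"{path}: checksum mismatch; file corrupted")
    return DistanceMatrix(values, form=meta["form"],
                          weight_vector_id=meta["weight_vector_id"])


def export_distance_matrix_text(dm, path):
    np.savetxt(path, dm.values)
    return Path(path)


# ---------------------------------------------------------------------------
# cluster results

def write_cluster_result(model, path):
    """Serialize a fitted cluster model (densities, deltas, centers, labels,
    core flags, cutoff) as JSON."""
    payload = {
        "format": "torsmap-clusters",
        "version": 1,
        "d_c": float(model.d_c_),
        "rho": np.asarray(model.rho_).astype(int).tolist(),
        "delta": np.asarray(model.delta_).tolist(),
        "nearest_higher": np.asarray(model.nearest_higher_).astype(int).tolist(),
        "centers": np.asarray(model.centers_).astype(int).tolist(),
        "labels": np.asarray(model.labels_).astype(int).tolist(),
        "is_core": np.asarray(model.is_core_).astype(bool).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return Path(path)


def read_cluster_result(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "torsmap-clusters":
        raise FormatError(f"{path}: not a cluster-result file")
    out = {
        "d_c": float(payload["d_c"]),
        "rho": np.asarray(payload["rho"], dtype=int),
        "delta": np.asarray(payload["delta"], dtype=float),
        "nearest_higher": np.asarray(payload["nearest_higher"], dtype=int),
        "centers": np.asarray(payload["centers"], dtype=int),
        "labels": np.asarray(payload["labels"], dtype=int),
        "is_core": np.asarray(payload["is_core"], dtype=bool),
    }
    return out


def write_labels_csv(classified, path, time=None):
    """Write per-frame classification (frame, time, label, score) as CSV."""
    n = len(classified.labels)
    best = classified.scores.max(axis=1) if classified.scores.size else \
        np.zeros(n, dtype=int)
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time": time if time is not None else np.arange(n, dtype=float),
        "label": classified.labels,
        "score": best,
    })
    df.to_csv(path, index=False)
    return Path(path)
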