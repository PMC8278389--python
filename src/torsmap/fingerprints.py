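"""Per-cluster torsional fingerprints and the all-torsions matcher.

A fingerprint is, for each torsion, the normalized periodic histogram of
that torsion over all frames assigned to a cluster, together with the mask
of bins carrying nonzero probability (the support). A trajectory frame
matches a fingerprint when *every* torsion falls in a support bin; the match
score is the number of torsions that do, so a full score (6 for a
six-torsion molecule) assigns the frame to that conformer and anything less
leaves it unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import EmptyInputError
from .trajectory import DihedralTrajectory, wrap_angles

TWO_PI = 2.0 * np.pi


def _bin_index(angles, n_bins):
    """Bin index on the shared periodic grid over [-pi, pi)."""
    idx = ((wrap_angles(angles) + np.pi) // (TWO_PI / n_bins)).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


@dataclass
class FingerprintSet:
    """Fingerprints for a set of clusters on one shared bin grid.

    ``probs`` and ``support`` have shape (n_clusters, n_torsions, n_bins);
    per torsion the probabilities sum to 1 and ``support = probs > 0``.
    """

    angle_names: list[str]
    bin_edges: np.ndarray
    cluster_ids: np.ndarray
    probs: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        self.angle_names = list(self.angle_names)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.probs.shape != self.support.shape:
            raise ValueError("probs and support shapes differ")
        k, m, b = self.probs.shape
        if m != len(self.angle_names):
            raise ValueError("angle_names length does not match probs")
        if b != self.bin_edges.size - 1:
            raise ValueError("bin_edges do not match probs bin count")
        if k != self.cluster_ids.size:
            raise ValueError("cluster_ids length does not match probs")

    @property
    def n_clusters(self) -> int:
        return self.probs.shape[0]

    @property
    def n_cv(self) -> int:
        return self.probs.shape[1]

    @property
    def n_bins(self) -> int:
        return self.probs.shape[2]

    def to_dict(self) -> dict:
        return {
            "angle_names": self.angle_names,
            "bin_edges": self.bin_edges.tolist(),
            "fingerprints": [
                {
                    "cluster_id": int(cid),
                    "probs": self.probs[i].tolist(),
                    "support": self.support[i].astype(int).tolist(),
                }
                for i, cid in enumerate(self.cluster_ids)
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FingerprintSet":
        records = payload["fingerprints"]
        return cls(
            angle_names=list(payload["angle_names"]),
            bin_edges=np.asarray(payload["bin_edges"], dtype=float),
            cluster_ids=np.asarray([r["cluster_id"] for r in records]),
            probs=np.asarray([r["probs"] for r in records], dtype=float),
            support=np.asarray([r["support"] for r in records], dtype=bool),
        )


@dataclass
class ClassifiedTrajectory:
    """Per-frame labels (0 = unclassified) and per-cluster match scores."""

    labels: np.ndarray
    scores: np.ndarray
    cluster_ids: np.ndarray

    @property
    def fraction_classified(self) -> float:
        return float(np.mean(self.labels != 0))


def build_fingerprints(traj, labels, n_bins: int = 36, support_min_count: int = 1,
                       include_halo: bool = True, is_core=None) -> FingerprintSet:
    """Histogram every cluster's torsions into a fingerprint set.

    All frames assigned to a cluster contribute (core and halo alike) unless
    ``include_halo=False``, in which case ``is_core`` restricts the input to
    core frames. Bins whose raw count falls below ``support_min_count`` are
    zeroed (and the histogram renormalized) before the support mask is
    taken; the default of 1 keeps every visited bin, the literal
    nonzero-probability rule.
    """
    angles = traj.angles if isinstance(traj, DihedralTrajectory) else \
        wrap_angles(np.asarray(traj, dtype=float))
    names = traj.angle_names if isinstance(traj, DihedralTrajectory) else \
        [f"cv{i}" for i in range(angles.shape[1])]
    labels = np.asarray(labels)
    if labels.shape[0] != angles.shape[0]:
        raise ValueError("labels length must match frame count")
    if not include_halo:
        if is_core is None:
            raise ValueError("include_halo=False requires is_core flags")
        keep = np.asarray(is_core, dtype=bool)
        angles, labels = angles[keep], labels[keep]

    cluster_ids = np.unique(labels[labels > 0])
    if cluster_ids.size == 0:
        raise EmptyInputError("no labeled frames to build fingerprints from")
    m = angles.shape[1]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    bins = _bin_index(angles, n_bins)
    probs = np.zeros((cluster_ids.size, m, n_bins))
    for ci, cid in enumerate(cluster_ids):
        sel = labels == cid
        if not sel.any():
            raise EmptyInputError(f"cluster {cid} has no frames")
        for k in range(m):
            counts = np.bincount(bins[sel, k], minlength=n_bins).astype(float)
            counts[counts < support_min_count] = 0.0
            total = counts.sum()
            if total == 0:
                raise EmptyInputError(
                    f"cluster {cid}, torsion {names[k]}: support_min_count="
                    f"{support_min_count} empties the histogram"
                )
            probs[ci, k] = counts / total
    return FingerprintSet(
        angle_names=list(names),
        bin_edges=edges,
        cluster_ids=cluster_ids,
        probs=probs,
        support=probs > 0,
    )


def _score_matrix(angles, fps: FingerprintSet):
    bins = _bin_index(angles, fps.n_bins)          # (n, m)
    scores = np.zeros((angles.shape[0], fps.n_clusters), dtype=np.int64)
    for k in range(fps.n_cv):
        scores += fps.support[:, k, :][:, bins[:, k]].T
    return scores, bins


def _resolve_labels(scores, bins, fps: FingerprintSet, tie_break: str):
    n, m = bins.shape
    full = scores == fps.n_cv
    labels = np.zeros(n, dtype=np.int64)
    n_matches = full.sum(axis=1)
    single = n_matches == 1
    labels[single] = fps.cluster_ids[full[single].argmax(axis=1)]
    multi = np.flatnonzero(n_matches > 1)
    if multi.size:
        if tie_break == "first-match":
            labels[multi] = fps.cluster_ids[full[multi].argmax(axis=1)]
        elif tie_break == "probability":
            # rank candidate clusters by the product of per-torsion bin
            # probabilities at the frame's bins (all nonzero on a full match)
            with np.errstate(divide="ignore"):
                logp = np.log(fps.probs)
            for i in multi:
                cand = np.flatnonzero(full[i])
                ll = logp[cand, np.arange(m)[None, :], bins[i][None, :]].sum(axis=1)
                labels[i] = fps.cluster_ids[cand[int(np.argmax(ll))]]
        else:
            raise ValueError(f"unknown tie_break {tie_break!r}")
    return labels


def classify_frame(frame, fingerprints: FingerprintSet,
                   tie_break: str = "probability"):
    """Match one configuration against every fingerprint.

    Returns ``(label, scores)``: the score for cluster c counts the torsions
    falling in support bins of c; the label is c's id if exactly one cluster
    scores full (ties resolved per ``tie_break``), else 0.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (fingerprints.n_cv,):
        raise ValueError(
            f"frame must have {fingerprints.n_cv} torsions, got {frame.shape}"
        )
    scores, bins = _score_matrix(frame[None, :], fingerprints)
    labels = _resolve_labels(scores, bins, fingerprints, tie_break)
    return int(labels[0]), scores[0]


def classify_trajectory(traj, fingerprints: FingerprintSet,
                        tie_break: str = "probability") -> ClassifiedTrajectory:
    """Vectorized :func:`classify_frame` over a whole trajectory."""
    angles = traj.angles if isinstance(traj, DihedralTrajectory) else \
        wrap_angles(np.asarray(traj, dtype=float))
    if angles.ndim == 1:
        angles = angles[:, None]
    if angles.shape[1] != fingerprints.n_cv:
        raise ValueError(
            f"trajectory has {angles.shape[1]} torsions, fingerprints expect "
            f"{fingerprints.n_cv}"
        )
    scores, bins = _score_matrix(angles, fingerprints)
    labels = _resolve_labels(scores, bins, fingerprints, tie_break)
    return ClassifiedTrajectory(labels=labels, scores=scores,
                                cluster_ids=fingerprints.cluster_ids)


class FingerprintClassifier(ClassifierMixin, BaseEstimator):
    """Hard conformer classifier backed by torsional fingerprints.

    ``fit(X, y)`` builds one fingerprint per cluster id in ``y`` (ids > 0;
    0-labeled frames are ignored); ``predict(X)`` returns cluster ids, with
    0 for frames failing the all-torsions match.

    Parameters
    ----------
    n_bins : int
        Shared periodic histogram resolution; default 36 (10 deg bins).
    support_min_count : int
        Minimum raw count for a bin to enter the support; raising it trades
        classification rate for specificity.
    tie_break : {"probability", "first-match"}
        Resolution when a frame fully matches several fingerprints.
    """

    def __init__(self, *, n_bins=36, support_min_count=1,
                 tie_break="probability", include_halo=True):
        self.n_bins = n_bins
        self.support_min_count = support_min_count
        self.tie_break = tie_break
        self.include_halo = include_halo

    def fit(self, X, y, is_core=None):
        self.fingerprints_ = build_fingerprints(
            X, y, n_bins=self.n_bins,
            support_min_count=self.support_min_count,
            include_halo=self.include_halo, is_core=is_core,
        )
        self.classes_ = self.fingerprints_.cluster_ids
        self.n_features_in_ = self.fingerprints_.n_cv
        return self

    def predict(self, X):
        return self.classify(X).labels

    def classify(self, X) -> ClassifiedTrajectory:
        return classify_trajectory(X, self.fingerprints_,
                                   tie_break=self.tie_break)

    def score_matrix(self, X) -> np.ndarray:
        """(n_frames, n_clusters) integer match scores in 0..n_torsions."""
        return self.classify(X).scores
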