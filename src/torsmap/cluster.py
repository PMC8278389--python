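"""Fast Search and Find of Density Peaks (FSFDP) clustering.

Each point's local density rho is the number of neighbors strictly within a
distance cutoff d_c; its delta is the distance to the nearest point of
higher density (the global density maximum instead gets the largest distance
to any point). Cluster centers stand out on the (rho, delta) decision graph
as simultaneously dense and isolated; every other point inherits the label
of its nearest higher-density neighbor in a single descent pass. A cluster's
core is the set of members lying within d_c of its center; the remaining
members form the halo, the noise fringe around the core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import EmptyInputError, SelectionError, TuningError
from .metric import DistanceMatrix, distance_matrix


def _matrix_values(D):
    if isinstance(D, DistanceMatrix):
        return D.values
    D = np.asarray(D)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix")
    return D


def tune_cutoff(D, target_neighbor_fraction: float = 0.02) -> float:
    """Cutoff d_c realizing an average neighbor count of ``fraction * N``.

    Works on the sorted pooled pairwise distances: a cutoff admitting exactly
    m pairs yields a mean density of 2m/N, so the target pair count is
    ``fraction * N**2 / 2``. The closest achievable pair count within +-0.5
    neighbor of the target is located by binary search between consecutive
    sorted distances; ties in the pooled distances can make a count
    unachievable, in which case neighboring counts inside the band are
    tried before giving up.
    """
    values = _matrix_values(D)
    n = values.shape[0]
    if not 0.0 < target_neighbor_fraction < 1.0:
        raise ValueError("target_neighbor_fraction must be in (0, 1)")
    if n < 2:
        raise EmptyInputError("need at least 2 points to tune a cutoff")
    pooled = np.sort(values[np.triu_indices(n, k=1)])
    n_pairs = pooled.size
    target_mean = target_neighbor_fraction * n
    m_target = target_mean * n / 2.0
    # band of pair counts keeping the mean within +-0.5 neighbor
    m_lo = max(0, int(np.ceil((target_mean - 0.5) * n / 2.0 - 1e-9)))
    m_hi = min(n_pairs, int(np.floor((target_mean + 0.5) * n / 2.0 + 1e-9)))
    if m_lo > m_hi:
        raise TuningError(
            f"no integer pair count keeps the mean within +-0.5 of "
            f"{target_mean:.3f} neighbors (N={n})"
        )
    candidates = sorted(range(m_lo, m_hi + 1), key=lambda m: abs(m - m_target))
    for m in candidates:
        if m == 0:
            if pooled[0] > 0:
                return float(pooled[0] / 2.0)
            continue
        if m == n_pairs:
            return float(pooled[-1] * (1.0 + 1e-9) + 1e-12)
        if pooled[m - 1] < pooled[m]:
            return float(0.5 * (pooled[m - 1] + pooled[m]))
    raise TuningError(
        "neighbor-fraction target unattainable: pooled distances are too "
        f"degenerate near the target count (m in [{m_lo}, {m_hi}], "
        f"distance range [{pooled[0]:.6g}, {pooled[-1]:.6g}])"
    )


def compute_density(D, d_c: float) -> np.ndarray:
    """Integer densities: rho_i = #{j != i : d_ij < d_c} (strictly below)."""
    values = _matrix_values(D)
    if d_c <= 0:
        raise ValueError("d_c must be > 0")
    rho = (values < d_c).sum(axis=1)
    # the zero diagonal always satisfies 0 < d_c; remove the self count
    return (rho - 1).astype(np.int64)


def compute_delta(D, rho) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest point of higher density, plus that neighbor.

    Density ties are broken by frame index (the lower index counts as
    higher), so exactly one point — the global density maximum — has no
    higher neighbor; it receives delta = max_j d_ij and the sentinel -1.
    """
    values = _matrix_values(D)
    n = values.shape[0]
    rho = np.asarray(rho)
    if rho.shape != (n,):
        raise ValueError("rho must have one entry per point")
    order = np.lexsort((np.arange(n), -rho))  # rho desc, then index asc
    ordered = values[np.ix_(order, order)].astype(np.float64, copy=False)
    # mask out self and lower-priority points
    masked = np.where(np.tri(n, k=-1, dtype=bool), ordered, np.inf)
    delta_ord = masked.min(axis=1)
    nh_ord = masked.argmin(axis=1)
    delta = np.empty(n)
    nearest_higher = np.empty(n, dtype=np.int64)
    delta[order] = delta_ord
    nearest_higher[order] = order[nh_ord]
    top = order[0]
    delta[top] = values[top].max()
    nearest_higher[top] = -1
    return delta, nearest_higher


def select_centers(rho, delta, mode: str = "auto", rho_min=None, delta_min=None,
                   k=None, centers=None) -> np.ndarray:
    """Pick cluster centers off the decision graph.

    ``auto`` keeps points with rho >= rho_min and delta >= delta_min, or —
    when ``k`` is given — the top-k by gamma = rho * delta (mirroring how
    centers are circled by eye on the decision graph). ``manual`` takes an
    explicit index list. Centers are returned ordered by decreasing rho
    (index breaking ties), which fixes their label order 1..K.
    """
    rho = np.asarray(rho)
    delta = np.asarray(delta)
    if mode == "manual":
        if centers is None or len(centers) == 0:
            raise SelectionError("manual mode requires a non-empty center list")
        chosen = np.asarray(centers, dtype=int)
    elif mode == "auto":
        if k is not None:
            gamma = rho.astype(float) * delta
            # stable: larger gamma first, lower index on ties
            chosen = np.lexsort((np.arange(len(gamma)), -gamma))[:k]
        else:
            if rho_min is None or delta_min is None:
                raise ValueError(
                    "auto mode needs rho_min and delta_min, or k"
                )
            chosen = np.flatnonzero((rho >= rho_min) & (delta >= delta_min))
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    if chosen.size == 0:
        raise SelectionError(
            "no cluster centers selected; lower the thresholds or inspect "
            "the decision graph"
        )
    order = np.lexsort((chosen, -rho[chosen]))
    return chosen[order]


def assign_and_halo(D, rho, nearest_higher, centers, d_c: float,
                    halo: str = "center-distance"):
    """Assign labels by density descent and split each cluster core/halo.

    Labels are 1..K in the centers' order. In the default convention the
    core of a cluster is its members lying strictly within d_c of the
    cluster center; ``halo="border-density"`` instead uses the original
    FSFDP rule (core density above the highest density found in the
    cluster's border region, i.e. within d_c of another cluster).
    """
    values = _matrix_values(D)
    n = values.shape[0]
    rho = np.asarray(rho)
    nearest_higher = np.asarray(nearest_higher)
    centers = np.asarray(centers, dtype=int)
    if centers.size == 0:
        raise SelectionError("centers must be non-empty")

    labels = np.zeros(n, dtype=np.int64)
    labels[centers] = np.arange(1, centers.size + 1)
    order = np.lexsort((np.arange(n), -rho))
    for i in order:
        if labels[i] == 0:
            j = nearest_higher[i]
            if j < 0:
                # non-center global maximum: fall back to the nearest center
                labels[i] = labels[centers[np.argmin(values[i, centers])]]
            else:
                labels[i] = labels[j]

    center_of = centers[labels - 1]
    if halo == "center-distance":
        is_core = values[np.arange(n), center_of] < d_c
    elif halo == "border-density":
        is_core = np.ones(n, dtype=bool)
        near = values < d_c
        for c in range(1, centers.size + 1):
            mine = labels == c
            border = mine & (near & ~mine[None, :]).any(axis=1)
            if border.any():
                rho_b = rho[border].max()
                is_core[mine] = rho[mine] >= rho_b
    else:
        raise ValueError(f"unknown halo convention {halo!r}")
    return labels, is_core


class DensityPeaks(ClusterMixin, BaseEstimator):
    """Density-peaks clustering over the barrier-weighted torsional metric.

    Parameters
    ----------
    weights : array or WeightVector, optional
        Per-torsion metric weights (ignored when ``metric="precomputed"``).
    metric : {"torsion", "precomputed"}
        With ``"torsion"`` (default), ``fit`` receives an angle matrix and
        builds the weighted periodic distance matrix; with
        ``"precomputed"``, ``fit`` receives a square distance matrix.
    form : {"euclidean", "manhattan"}
        Composition of the per-torsion weighted differences.
    neighbor_fraction : float
        Target mean neighbor count as a fraction of the data set (the
        cutoff d_c is tuned so every point sees on average
        ``neighbor_fraction * N`` neighbors); ignored when ``d_c`` is given.
    k, rho_min, delta_min, centers
        Center selection: explicit index list (``centers``), top-k by
        rho*delta (``k``), or decision-graph thresholds. When none are
        given, thresholds default to ``rho_min = mean(rho) / 2`` and
        ``delta_min = 2 * d_c``, which isolates the dense-and-isolated
        upper-right corner of the decision graph.
    halo : {"center-distance", "border-density"}
        Core/halo convention (see :func:`assign_and_halo`).

    Attributes
    ----------
    d_c_, rho_, delta_, nearest_higher_, centers_, labels_, is_core_, gamma_
        ``labels_`` are 1..K (0 is reserved downstream for "unclassified").
    """

    def __init__(self, *, weights=None, metric="torsion", form="euclidean",
                 use_rounded=True, neighbor_fraction=0.02, d_c=None, k=None,
                 rho_min=None, delta_min=None, centers=None,
                 halo="center-distance", block_size=256, store_dtype="float64",
                 keep_distances=False):
        self.weights = weights
        self.metric = metric
        self.form = form
        self.use_rounded = use_rounded
        self.neighbor_fraction = neighbor_fraction
        self.d_c = d_c
        self.k = k
        self.rho_min = rho_min
        self.delta_min = delta_min
        self.centers = centers
        self.halo = halo
        self.block_size = block_size
        self.store_dtype = store_dtype
        self.keep_distances = keep_distances

    def fit(self, X, y=None):
        if self.metric == "precomputed":
            D = _matrix_values(X)
        else:
            dm = distance_matrix(X, weights=self.weights, form=self.form,
                                 use_rounded=self.use_rounded,
                                 block_size=self.block_size,
                                 dtype=np.dtype(self.store_dtype))
            D = dm.values
        n = D.shape[0]
        if n < 2:
            raise EmptyInputError("need at least 2 points to cluster")

        self.d_c_ = float(self.d_c) if self.d_c is not None else \
            tune_cutoff(D, self.neighbor_fraction)
        self.rho_ = compute_density(D, self.d_c_)
        self.delta_, self.nearest_higher_ = compute_delta(D, self.rho_)
        self.gamma_ = self.rho_.astype(float) * self.delta_

        if self.centers is not None:
            self.centers_ = select_centers(self.rho_, self.delta_,
                                           mode="manual", centers=self.centers)
        elif self.k is not None:
            self.centers_ = select_centers(self.rho_, self.delta_,
                                           mode="auto", k=self.k)
        else:
            rho_min = self.rho_min if self.rho_min is not None else \
                0.5 * self.rho_.mean()
            delta_min = self.delta_min if self.delta_min is not None else \
                2.0 * self.d_c_
            self.centers_ = select_centers(self.rho_, self.delta_,
                                           mode="auto", rho_min=rho_min,
                                           delta_min=delta_min)
        self.labels_, self.is_core_ = assign_and_halo(
            D, self.rho_, self.nearest_higher_, self.centers_, self.d_c_,
            halo=self.halo,
        )
        self.n_clusters_ = int(self.centers_.size)
        if self.keep_distances:
            self.distances_ = D
        self.n_features_in_ = None if self.metric == "precomputed" else \
            np.asarray(X).shape[1]
        return self

    def decision_graph(self) -> pd.DataFrame:
        """Per-point (rho, delta) table for plotting/inspection."""
        return pd.DataFrame({"rho": self.rho_, "delta": self.delta_})
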