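"""One-dimensional torsional free-energy profiles and clustering weights.

For each torsion a free-energy profile F(theta) = -ln p(theta) (units of
k_B*T) is estimated from a (optionally frame-weighted) periodic histogram.
The lowest rotational barrier of each torsion — the cheapest activated path
between adjacent free-energy minima on the periodic grid — sets that
torsion's weight in the configuration-space metric: barriers are normalized
by the smallest one, so the floppiest torsion carries weight 1 and stiff
torsions (whose rotation signals a genuine conformational transition rather
than a thermal adjustment) count proportionally more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoBarrierError
from .trajectory import DihedralTrajectory, wrap_angles

TWO_PI = 2.0 * np.pi


class DegenerateProfileWarning(UserWarning):
    """All samples fall into a single bin; the profile is uninformative."""


@dataclass
class TorsionProfile:
    """Periodic 1-D free-energy profile with located extrema.

    ``free_energy`` is in units of k_B*T, shifted so its minimum is exactly
    0; never-visited bins hold ``+inf`` and are excluded from barrier search.
    ``minima_idx`` / ``maxima_idx`` alternate along the periodic grid.
    ``lowest_barrier`` is None when the profile is unimodal.
    """

    angle_name: str
    bin_centers: np.ndarray
    free_energy: np.ndarray
    minima_idx: np.ndarray
    maxima_idx: np.ndarray
    lowest_barrier: float | None
    temperature: float = 300.0

    @property
    def unimodal(self) -> bool:
        return len(self.minima_idx) < 2


@dataclass
class WeightVector:
    """Per-torsion metric weights derived from rotational barriers.

    ``raw`` holds the input barriers (k_B*T), ``normalized`` the barriers
    divided by the smallest one (so min(normalized) == 1 exactly), and
    ``rounded`` the normalized weights rounded half-away-from-zero to one
    decimal — the form used by default in the distance metric.
    """

    raw: np.ndarray
    normalized: np.ndarray
    rounded: np.ndarray
    angle_names: list[str] | None = None

    def __len__(self):
        return len(self.raw)

    def values(self, use_rounded: bool = True) -> np.ndarray:
        return self.rounded if use_rounded else self.normalized


def _circular_smooth(counts, window):
    """Circular moving average; window must be odd (1 disables)."""
    if window <= 1:
        return counts.astype(float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window) / window
    padded = np.concatenate([counts[-(window // 2):], counts,
                             counts[: window // 2]])
    return np.convolve(padded, kernel, mode="valid")


def _periodic_extrema(values):
    """Strict alternating minima/maxima of a periodic sequence.

    Plateaus (runs of equal values) are collapsed to their middle index.
    Returns (minima_idx, maxima_idx), each sorted by grid position; empty if
    the sequence is constant.
    """
    n = len(values)
    # collapse consecutive equal values into runs (cyclically)
    run_starts = [0]
    for i in range(1, n):
        if values[i] != values[run_starts[-1]]:
            run_starts.append(i)
    if len(run_starts) == 1:
        return np.array([], dtype=int), np.array([], dtype=int)
    # merge wrap-around run: if last run value equals first run value
    if values[run_starts[-1]] == values[run_starts[0]]:
        first_len = run_starts[1] - run_starts[0]
        run_starts[0] = run_starts.pop()  # run now starts near the end
        if len(run_starts) == 1:
            return np.array([], dtype=int), np.array([], dtype=int)
        # representative index: middle of the wrapped run
        # (handled below via run lengths)
    k = len(run_starts)
    minima, maxima = [], []
    for r in range(k):
        prev_v = values[run_starts[(r - 1) % k]]
        cur_s = run_starts[r]
        cur_v = values[cur_s]
        next_s = run_starts[(r + 1) % k]
        next_v = values[next_s]
        run_len = (next_s - cur_s) % n
        rep = (cur_s + run_len // 2) % n
        if prev_v > cur_v < next_v:
            minima.append(rep)
        elif prev_v < cur_v > next_v:
            maxima.append(rep)
    return (np.array(sorted(minima), dtype=int),
            np.array(sorted(maxima), dtype=int))


def free_energy_profile(traj, angle=None, n_bins: int = 72,
                        temperature: float = 300.0, frame_weights=None,
                        smooth_window: int = 3) -> TorsionProfile:
    """Estimate F(theta) = -ln p(theta) in k_B*T for one torsion.

    Parameters
    ----------
    traj : DihedralTrajectory or 1-D array of angles (radians)
    angle : str, optional
        Torsion name when ``traj`` is a trajectory.
    n_bins : int
        Periodic histogram resolution over ``[-pi, pi)``; default 72 (5 deg).
    frame_weights : array, optional
        Nonnegative per-frame weights (e.g. metadynamics reweighting
        factors); uniform weights reproduce the unweighted profile.
    smooth_window : int
        Odd width of a circular moving average applied to the histogram
        before locating extrema, to suppress single-bin noise; 1 disables.
    """
    if isinstance(traj, DihedralTrajectory):
        if angle is None:
            raise ValueError("angle name required with a trajectory input")
        samples = traj.angle(angle)
        name = angle
    else:
        samples = wrap_angles(np.asarray(traj, dtype=float))
        name = angle or "angle"
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if samples.size == 0:
        raise ValueError("no frames")
    if frame_weights is not None:
        frame_weights = np.asarray(frame_weights, dtype=float)
        if frame_weights.shape != samples.shape:
            raise ValueError("frame_weights length must match frame count")
        if np.any(frame_weights < 0) or not np.any(frame_weights > 0):
            raise ValueError("frame_weights must be >= 0 and not all zero")

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges, weights=frame_weights)
    counts = _circular_smooth(counts, smooth_window)

    occupied = counts > 0
    if occupied.sum() <= max(1, smooth_window):
        warnings.warn(
            f"{name}: all samples fall within one bin; profile is degenerate",
            DegenerateProfileWarning,
        )
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        fe = -np.log(p)
    fe = fe - fe[occupied].min()   # min over visited bins is exactly 0

    minima, maxima = _periodic_extrema(fe)
    # never-visited bins cannot be minima
    minima = minima[np.isfinite(fe[minima])] if minima.size else minima
    profile = TorsionProfile(
        angle_name=name,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        free_energy=fe,
        minima_idx=minima,
        maxima_idx=maxima,
        lowest_barrier=None,
        temperature=temperature,
    )
    if not profile.unimodal:
        try:
            profile.lowest_barrier = lowest_rotational_barrier(profile)
        except NoBarrierError:
            profile.lowest_barrier = None
    return profile


def lowest_rotational_barrier(profile: TorsionProfile) -> float:
    """Lowest directed barrier between adjacent minima on the periodic grid.

    For every cyclically adjacent pair of minima with intervening maximum M,
    both crossing directions are considered: the cost is F(M) minus the free
    energy of the departing minimum. The smallest finite such cost is
    returned. Crossings through never-visited (infinite) bins are excluded.
    """
    fe = profile.free_energy
    minima = np.asarray(profile.minima_idx)
    maxima = np.asarray(profile.maxima_idx)
    if len(minima) < 2:
        raise NoBarrierError(
            f"{profile.angle_name}: profile is unimodal; no rotational barrier"
        )
    n = len(fe)
    best = np.inf
    k = len(minima)
    for a in range(k):
        m1, m2 = minima[a], minima[(a + 1) % k]
        # the unique maximum lying cyclically between m1 and m2
        span = (maxima - m1) % n
        limit = (m2 - m1) % n
        between = maxima[(span > 0) & (span < limit)]
        if between.size == 0:
            continue
        top = fe[between].max()
        if not np.isfinite(top):
            continue
        best = min(best, top - fe[m1], top - fe[m2])
    if not np.isfinite(best):
        raise NoBarrierError(
            f"{profile.angle_name}: all crossings pass through unvisited bins"
        )
    return float(best)


def _round_half_away(x, decimals=1):
    """Round half away from zero, snapping binary-float noise first.

    The scaled value is rounded to 6 decimals before the half-away step so
    that quotients like 1.5/1.2 (= 1.2499999999999998 in binary) round to
    1.3 as they would in exact decimal arithmetic.
    """
    scaled = np.round(np.asarray(x, dtype=float) * 10.0 ** decimals, 6)
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / 10.0 ** decimals


def compute_weights(barriers, angle_names=None) -> WeightVector:
    """Normalize per-torsion barriers into metric weights.

    Each barrier is divided by the smallest one, so the weights are
    dimensionless, scale-invariant, and the floppiest torsion gets exactly 1.
    The rounded form (one decimal, half away from zero) is what the distance
    metric uses by default.
    """
    raw = np.asarray(barriers, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("barriers must be a non-empty 1-D array")
    if np.any(~np.isfinite(raw)) or np.any(raw <= 0):
        raise ValueError("all barriers must be finite and > 0")
    normalized = raw / raw.min()
    return WeightVector(
        raw=raw,
        normalized=normalized,
        rounded=_round_half_away(normalized, 1),
        angle_names=list(angle_names) if angle_names is not None else None,
    )


def profile_weights(traj: DihedralTrajectory, n_bins: int = 72,
                    temperature: float = 300.0, frame_weights=None,
                    smooth_window: int = 3) -> WeightVector:
    """Convenience: profiles + barrier extraction + normalization for every
    torsion of a trajectory. Raises :class:`NoBarrierError` if any torsion
    is unimodal or its barriers are unresolvable."""
    barriers = []
    for name in traj.angle_names:
        prof = free_energy_profile(traj, name, n_bins=n_bins,
                                   temperature=temperature,
                                   frame_weights=frame_weights,
                                   smooth_window=smooth_window)
        if prof.lowest_barrier is None:
            raise NoBarrierError(
                f"{name}: no finite rotational barrier; supply barriers "
                "explicitly for this torsion"
            )
        barriers.append(prof.lowest_barrier)
    return compute_weights(barriers, angle_names=traj.angle_names)
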