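"""Synthetic torsional trajectories with planted conformational macrostates.

The generator emulates the statistical structure of torsional MD data
without any MD engine: each conformer is a product of von Mises modes in
torsion space (higher concentration mimicking deeper, better-separated
free-energy wells), frames are drawn from a categorical mixture over
conformers, an optional smooth bias potential over one designated torsion
emulates the final bias of a well-tempered metadynamics run (sampling from
the biased density via rejection, with the exact per-frame bias recorded so
reweighting can undo it), and per-frame energy components carry planted
cluster-dependent means under Gaussian noise — including a large,
conformer-independent solvent term that exercises the cancellation argument
behind the solute/solute-solvent energy split.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .thermo import KB
from .trajectory import DihedralTrajectory, wrap_angles

TWO_PI = 2.0 * np.pi


@dataclass
class PlantedWorld:
    """Ground-truth description of a synthetic conformational ensemble.

    ``means`` is (K conformers, M torsions) mode centers in radians;
    ``kappa`` the shared von Mises concentration (scalar or per-mode
    array); ``mixture_probs`` the conformer weights (sum to 1). ``bias``
    is an optional bounded function of the ``bias_angle``-th torsion,
    returning kJ/mol. Energy means are per conformer (kJ/mol); the solvent
    column is a common mean with (typically large) noise.
    """

    means: np.ndarray
    kappa: float | np.ndarray
    mixture_probs: np.ndarray
    angle_names: Sequence[str]
    bias_angle: int = 0
    bias: Callable | None = None
    energy_solute_means: np.ndarray | None = None
    energy_xsolv_means: np.ndarray | None = None
    sigma_solute: float = 1.5
    sigma_xsolv: float = 3.0
    solvent_mean: float = -8000.0
    sigma_solvent: float = 400.0
    temperature: float = 300.0

    def __post_init__(self):
        self.means = wrap_angles(np.atleast_2d(np.asarray(self.means, float)))
        self.mixture_probs = np.asarray(self.mixture_probs, dtype=float)
        if self.mixture_probs.shape != (self.means.shape[0],):
            raise ValueError("mixture_probs must have one entry per conformer")
        if not np.isclose(self.mixture_probs.sum(), 1.0):
            raise ValueError("mixture_probs must sum to 1")
        if np.any(np.asarray(self.kappa) <= 0):
            raise ValueError("kappa must be > 0")
        self.angle_names = list(self.angle_names)
        if len(self.angle_names) != self.means.shape[1]:
            raise ValueError("angle_names length must match means columns")
        for attr in ("energy_solute_means", "energy_xsolv_means"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (self.n_conformers,):
                    raise ValueError(f"{attr} must have one entry per conformer")
                setattr(self, attr, v)

    @property
    def n_conformers(self) -> int:
        return self.means.shape[0]

    @property
    def n_cv(self) -> int:
        return self.means.shape[1]


def make_gaussian_bias(centers, width: float = 0.3, height_kT: float = 2.5,
                       temperature: float = 300.0) -> Callable:
    """Sum of periodic Gaussians on the circle (kJ/mol).

    Emulates the accumulated hill potential of a metadynamics run: hills of
    the given width (rad) and height (k_B*T) at the given centers, summed
    over periodic images so the function is smooth across the boundary.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    height = height_kT * KB * temperature

    def bias(theta):
        theta = np.asarray(theta, dtype=float)
        diff = wrap_angles(theta[..., None] - centers[None, :])
        return height * np.exp(-0.5 * (diff / width) ** 2).sum(axis=-1)

    return bias


def sildenafil_like_world(kappa: float = 50.0, bias: Callable | None = None,
                          temperature: float = 300.0) -> PlantedWorld:
    """Default 12-conformer, 6-torsion world.

    The twelve basins are all combinations of 3 modes on the first torsion,
    2 on the second and 2 on the fifth (the remaining torsions are
    unimodal), placed on a well-separated grid. Four conformers — the
    analogues of the dominant crystal-like states — carry mixture mass 0.15
    each; the remaining eight share the rest (0.05 each), qualitatively
    mirroring a solution ensemble dominated by a few conformers. Energy
    means vary by a few kJ/mol across conformers beneath a large
    conformer-independent solvent term.
    """
    tau_a = [-2.1, 0.0, 2.1]
    tau_b = [-1.6, 1.6]
    tau_e = [-1.5, 1.5]
    means = np.array([[a, b, 0.5, -0.5, e, 2.0]
                      for a, b, e in product(tau_a, tau_b, tau_e)])
    probs = np.full(12, 0.05)
    probs[[0, 3, 8, 11]] = 0.15
    rng = np.random.default_rng(1234)  # fixed: part of the world definition
    return PlantedWorld(
        means=means,
        kappa=kappa,
        mixture_probs=probs,
        angle_names=["tauA", "tauB", "tauC", "tauD", "tauE", "tauF"],
        bias_angle=0,
        bias=bias,
        energy_solute_means=np.round(rng.uniform(-155.0, -145.0, 12), 3),
        energy_xsolv_means=np.round(rng.uniform(-85.0, -75.0, 12), 3),
        temperature=temperature,
    )


def sample_unbiased(world: PlantedWorld, n: int, seed=None):
    """Draw ``n`` frames from the planted mixture.

    Returns ``(trajectory, true_labels)`` with labels 1..K for recovery
    tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    comp = rng.choice(world.n_conformers, size=n, p=world.mixture_probs)
    angles = rng.vonmises(world.means[comp], np.broadcast_to(
        np.asarray(world.kappa, dtype=float), world.means.shape)[comp])
    traj = DihedralTrajectory(wrap_angles(angles), world.angle_names,
                              time=np.arange(n, dtype=float))
    return traj, comp + 1


def sample_biased(world: PlantedWorld, n: int, seed=None):
    """Draw ``n`` frames from the bias-tilted density via rejection.

    The bias potential V adds to the Hamiltonian, so the biased ensemble is
    proportional to p_unbiased(tau) * exp(-V(tau_bias)/kT): high-bias
    regions are depleted, exactly as repulsive metadynamics hills push the
    system out of the basins where they were deposited. The per-frame bias
    value V (kJ/mol) is recorded in the trajectory's ``bias`` column, so the
    max-shifted Boltzmann weight exp[(V - V_max)/kT] undoes the tilt
    exactly.
    """
    if world.bias is None:
        raise ValueError("world has no bias function")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    kT = KB * world.temperature
    grid = np.linspace(-np.pi, np.pi, 4096, endpoint=False)
    v_grid = np.asarray(world.bias(grid), dtype=float)
    if not np.all(np.isfinite(v_grid)):
        raise ValueError("bias function must be bounded on [-pi, pi)")
    v_min = v_grid.min()

    frames = np.empty((0, world.n_cv))
    labels = np.empty(0, dtype=np.int64)
    bias_vals = np.empty(0)
    while frames.shape[0] < n:
        batch = max(n, 1024)
        traj_b, lab_b = sample_unbiased(world, batch, rng)
        v = np.asarray(world.bias(traj_b.angles[:, world.bias_angle]), float)
        accept = rng.random(batch) < np.exp(-(v - v_min) / kT)
        frames = np.vstack([frames, traj_b.angles[accept]])
        labels = np.concatenate([labels, lab_b[accept]])
        bias_vals = np.concatenate([bias_vals, v[accept]])
    frames, labels, bias_vals = frames[:n], labels[:n], bias_vals[:n]
    traj = DihedralTrajectory(frames, world.angle_names,
                              time=np.arange(n, dtype=float), bias=bias_vals)
    return traj, labels


def sample_with_noise(world: PlantedWorld, n: int, noise_fraction: float = 0.05,
                      seed=None):
    """Solution-like trajectory: planted mixture with a fraction of frames
    replaced by uniform draws over the torus (out-of-support noise).

    Returns ``(trajectory, true_labels)`` where replaced frames carry the
    true label 0.
    """
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    traj, labels = sample_unbiased(world, n, rng)
    n_noise = int(round(noise_fraction * n))
    if n_noise:
        idx = rng.choice(n, n_noise, replace=False)
        angles = traj.angles.copy()
        angles[idx] = rng.uniform(-np.pi, np.pi, (n_noise, world.n_cv))
        labels = labels.copy()
        labels[idx] = 0
        traj = DihedralTrajectory(angles, world.angle_names,
                                  time=np.arange(n, dtype=float))
    return traj, labels


def attach_energies(traj: DihedralTrajectory, labels, world: PlantedWorld,
                    seed=None) -> DihedralTrajectory:
    """Add planted per-cluster energy components (kJ/mol) to a trajectory.

    Solute and solute-solvent columns are the conformer's planted mean plus
    Gaussian noise at the world's stated scales; the solvent column is a
    large common mean with large noise, conformer-independent by
    construction — differencing it between conformers adds pure noise,
    which is why the decomposition drops it.
    """
    if world.energy_solute_means is None or world.energy_xsolv_means is None:
        raise ValueError("world has no planted energy means")
    labels = np.asarray(labels)
    if labels.shape[0] != traj.n_frames:
        raise ValueError("labels length must match frame count")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    idx = labels - 1
    n = traj.n_frames
    e_solute = world.energy_solute_means[idx] + \
        rng.normal(0.0, world.sigma_solute, n)
    e_xsolv = world.energy_xsolv_means[idx] + \
        rng.normal(0.0, world.sigma_xsolv, n)
    e_solvent = world.solvent_mean + rng.normal(0.0, world.sigma_solvent, n)
    return traj.with_columns(energy_solute=e_solute,
                             energy_solute_solvent=e_xsolv,
                             energy_solvent=e_solvent)
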