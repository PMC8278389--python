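"""Reweighting, conformer populations, and free-energy decomposition.

A well-tempered metadynamics run deposits an external bias V(s) on a chosen
torsion; equilibrium statistics are recovered by giving frame i the
Boltzmann weight W_i = exp[(V_i - max_j V_j) / k_B T] of its max-shifted
total bias, so the most-biased region of collective-variable space (the
deepest free-energy basin) carries weight 1 and everything else less.

Conformer populations are the weighted label fractions; free-energy
differences follow from population ratios, Delta G = -k_B T ln(P_i / P_j).
The enthalpic part is approximated by the internal-energy difference
(conformational transitions leave the ensemble volume unchanged), computed
from the solute and solute-solvent potential-energy components only: the
solvent-solvent term is conformer-independent and cancels, which removes
the dominant source of fluctuation from the estimate. The entropic part is
obtained by difference, T*Delta S = Delta G - Delta H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .trajectory import DihedralTrajectory

#: Boltzmann constant in kJ/mol/K
KB = 0.0083144621


@dataclass
class FrameWeights:
    """Per-frame reweighting factors in (0, 1], with max(w) == 1 exactly."""

    w: np.ndarray
    kT: float

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)

    def __len__(self):
        return self.w.size


def reweight(bias, temperature: float = 300.0,
             bias_factor: float | None = None) -> FrameWeights:
    """Boltzmann weights from the per-frame total bias potential (kJ/mol).

    ``W_i = exp[(V_i - max_j V_j) / k_B T]``: the frame(s) at maximum
    deposited bias get weight exactly 1. With ``bias_factor`` (the
    well-tempered gamma), the bias is first scaled by gamma/(gamma - 1),
    the standard final-bias estimator; the default applies no prefactor.
    """
    v = np.asarray(bias, dtype=float)
    if v.size == 0:
        raise EmptyInputError("bias array is empty")
    if not np.all(np.isfinite(v)):
        raise ValueError("bias values must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if bias_factor is not None:
        if bias_factor <= 1:
            raise ValueError("bias_factor (gamma) must be > 1")
        v = v * (bias_factor / (bias_factor - 1.0))
    kT = KB * temperature
    return FrameWeights(np.exp((v - v.max()) / kT), kT)


def cluster_populations(labels, weights: FrameWeights | None = None):
    """Reweighted probability of each conformer cluster.

    Returns ``(populations, unclassified)`` where ``populations`` is a
    pandas Series indexed by cluster id (label > 0) and ``unclassified`` is
    the weight fraction of 0-labeled frames; together they sum to 1.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise EmptyInputError("labels must be a non-empty 1-D array")
    w = np.ones(labels.size) if weights is None else weights.w
    if w.shape != labels.shape:
        raise ValueError("labels and weights must have the same length")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    ids = np.unique(labels[labels > 0])
    pops = pd.Series(
        {int(c): float(w[labels == c].sum() / total) for c in ids},
        dtype=float, name="P",
    )
    unclassified = float(w[labels == 0].sum() / total)
    return pops, unclassified


def delta_g(p_i: float, p_j: float, temperature: float = 300.0) -> float:
    """Free-energy difference -k_B T ln(P_i / P_j) in kJ/mol.

    A zero probability flags the difference as infinite (with a warning)
    rather than raising.
    """
    kT = KB * temperature
    if p_i < 0 or p_j < 0:
        raise ValueError("probabilities must be nonnegative")
    if p_i == 0 or p_j == 0:
        warnings.warn("zero probability: free-energy difference is infinite")
        if p_i == p_j:
            return np.nan
        return np.inf if p_i == 0 else -np.inf
    return float(-kT * np.log(p_i / p_j))


def conditional_energy_average(energies, labels, weights: FrameWeights | None,
                               cluster: int, n_boot: int = 200,
                               seed: int = 0):
    """Reweighted mean of an energy component over one cluster's frames.

    This is the mean of the bias-corrected conditional density p(E | frame
    in cluster). The standard error comes from ``n_boot`` bootstrap
    resamples of the cluster's frames (seeded, hence reproducible).
    Returns ``(mean, se)``.
    """
    e = np.asarray(energies, dtype=float)
    labels = np.asarray(labels)
    if e.shape != labels.shape:
        raise ValueError("energies and labels must have the same length")
    sel = np.flatnonzero(labels == cluster)
    if sel.size == 0:
        raise EmptyInputError(f"cluster {cluster} has no frames")
    w = np.ones(sel.size) if weights is None else weights.w[sel]
    ec = e[sel]
    mean = float(np.average(ec, weights=w))
    if sel.size == 1:
        return mean, 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sel.size, size=(n_boot, sel.size))
    bw = w[idx]
    boot = (bw * ec[idx]).sum(axis=1) / bw.sum(axis=1)
    return mean, float(boot.std(ddof=1))


@dataclass
class ThermoReport:
    """Per-cluster populations and free-energy decomposition.

    ``table`` columns: P, delta_G, delta_U, T_delta_S, delta_U_se,
    E_solute, E_solute_se, E_xsolv, E_xsolv_se — energies in kJ/mol
    relative to ``reference`` (whose rows are exactly 0). T*Delta S is
    computed by difference, so Delta G = Delta U - T*Delta S holds
    identically. Delta H is approximated by Delta U (the pressure-volume
    term is negligible for a conformational change).
    """

    table: pd.DataFrame
    reference: int
    temperature: float
    unclassified: float


def decompose(traj: DihedralTrajectory, labels, weights: FrameWeights | None,
              reference: int, temperature: float = 300.0, n_boot: int = 200,
              seed: int = 0) -> ThermoReport:
    """Populations, Delta G, Delta U and T*Delta S for every cluster.

    Requires the trajectory's ``energy_solute`` and
    ``energy_solute_solvent`` columns; the internal-energy difference is
    the sum of the two component differences (the solvent-solvent term
    cancels between conformers and is deliberately not consulted).
    """
    if traj.energy_solute is None or traj.energy_solute_solvent is None:
        raise EmptyInputError(
            "decompose requires energy_solute and energy_solute_solvent "
            "columns"
        )
    labels = np.asarray(labels)
    pops, unclassified = cluster_populations(labels, weights)
    if reference not in pops.index:
        raise EmptyInputError(f"reference cluster {reference} is empty")

    rows = []
    comps = {"E_solute": traj.energy_solute,
             "E_xsolv": traj.energy_solute_solvent}
    means = {name: {} for name in comps}
    ses = {name: {} for name in comps}
    for cid in pops.index:
        for j, (name, col) in enumerate(comps.items()):
            m, s = conditional_energy_average(
                col, labels, weights, cid, n_boot=n_boot,
                seed=seed + 7919 * j,
            )
            means[name][cid] = m
            ses[name][cid] = s
    for cid in pops.index:
        dg = delta_g(pops[cid], pops[reference], temperature)
        du = sum(means[name][cid] - means[name][reference] for name in comps)
        du_se = float(np.sqrt(sum(
            ses[name][cid] ** 2 + ses[name][reference] ** 2 for name in comps
        ))) if cid != reference else 0.0
        if cid == reference:
            dg, du = 0.0, 0.0
        rows.append({
            "cluster": int(cid),
            "P": pops[cid],
            "delta_G": dg,
            "delta_U": du,
            "T_delta_S": dg - du,
            "delta_U_se": du_se,
            "E_solute": means["E_solute"][cid],
            "E_solute_se": ses["E_solute"][cid],
            "E_xsolv": means["E_xsolv"][cid],
            "E_xsolv_se": ses["E_xsolv"][cid],
        })
    table = pd.DataFrame(rows).set_index("cluster")
    return ThermoReport(table=table, reference=int(reference),
                        temperature=temperature, unclassified=unclassified)
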