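# Methods

## Model and assumptions

A molecular configuration is represented by its vector of `M` internal
torsional angles, wrapped to the half-open interval [−π, π). This is a
complete, non-degenerate description of internal rearrangement for a
single rigid-ring-plus-rotors molecule — in contrast to collapsed
descriptors such as RMSD — and it is transferable across environments: a
conformer defined in the gas phase keeps its meaning in any solvent.

**Metric.** The distance between two configurations is the weighted
Euclidean composition of per-torsion shortest-arc differences,
`d_ij = sqrt(sum_n (w_n d_n)^2)` with `d_n = |a_n − b_n|` folded to
`2π − d_n` above π. The quadrature composition preserves the metric axioms
(each per-torsion term is a metric on the circle; a weighted L2 product of
metrics is a metric), which the tests exercise via triangle-inequality
checks on random instances. A Manhattan composition (`form="manhattan"`)
is provided as an option; the default is Euclidean. Weights multiply the
per-torsion difference before squaring.

**Weights.** `w_n` is the lowest rotational free-energy barrier of torsion
n (in k_B·T, from its 1-D profile), normalized by the smallest barrier
across torsions. The intent is scale separation: crossings of high-barrier
torsions (true conformational transitions) dominate the metric, while
low-barrier wobble (conformational adjustment) contributes at the noise
level. By default distances use the weights rounded half-away-from-zero to
one decimal, reproducing the published weight table bit-for-bit from the
published barriers; `use_rounded=False` switches to exact quotients.
Numerical note: the quotient 1.5/1.2 is 1.2499999999999998 in binary
floating point, so the rounding first snaps the scaled value to six
decimals — otherwise the half-away rule would produce 1.2 where decimal
arithmetic gives 1.3.

**Free-energy profiles.** `F(θ) = −ln p(θ)` per torsion on a periodic
histogram (default 72 bins = 5°), optionally frame-weighted, shifted so the
minimum is exactly zero; unvisited bins carry +∞ and are excluded from
barrier search. Extrema are located after a circular moving average
(default window 3 bins, `smooth_window=1` disables) to suppress single-bin
noise; plateaus collapse to their middle bin so minima and maxima strictly
alternate. The lowest rotational barrier is the minimum over all directed
adjacent-minima crossings of `F(intervening maximum) − F(departing
minimum)` — the cheapest activated path in either direction, verified
against brute-force path enumeration on random periodic profiles.

**Clustering.** Standard FSFDP on the full distance matrix: integer
density `rho_i = #{j ≠ i : d_ij < d_c}` (strict inequality), and
`delta_i = min over denser j of d_ij`, with density ties broken by frame
index (lower index counts as denser) so exactly one global maximum exists
and receives `delta = max_j d_ij`. The cutoff d_c is tuned on the sorted
pooled pairwise distances so the mean neighbor count is 2% of the data-set
size, within ±0.5 neighbor; degenerate distance spectra for which no
cutoff realizes the band raise a tuning error with diagnostics. Labels
propagate in a single pass down the density ordering (each point inherits
its nearest denser neighbor's label). Core/halo: by default a member is
core when it lies strictly within d_c of its cluster center — the
convention used in the conformer-identification method this package
implements — with the original FSFDP border-density rule available as
`halo="border-density"`.

**Center selection.** In the source method centers are circled by eye on
the decision graph, so `DensityPeaks` always exposes the (rho, delta)
table and accepts an explicit center list (`centers=[...]`) or a count
(`k=...`, top-k by gamma = rho·delta). The automatic default — a design
choice of this package, since no published thresholds exist — keeps points
with `rho ≥ mean(rho)/2` and `delta ≥ 2·d_c`. Rationale: genuine centers
are at least as dense as a typical point and isolated on a scale larger
than the neighborhood radius, whereas non-centers have delta of order the
intra-basin point spacing (≪ d_c at the 2% tuning) and stray outliers
with large delta fail the density floor. On the synthetic reference
conditions this rule recovers exactly the planted number of basins in
every tested seed.

**Fingerprints and classification.** Per cluster and per torsion, the
normalized histogram of all assigned frames (core and halo; a core-only
switch exists) on a shared periodic grid, default 36 bins (10°, the usual
torsion-histogram resolution — fine enough to separate wells ~120° apart,
coarse enough that a few-hundred-frame cluster populates its support).
Bins with raw count below `support_min_count` (default 1) are zeroed and
the histogram renormalized. A frame scores one point per torsion landing
in a nonzero-probability bin; only a full score assigns the frame, all
other frames stay unclassified (label 0). When a frame fully matches
several fingerprints (the source method leaves this case unspecified), the
default tie-break assigns the cluster with the largest product of
per-torsion bin probabilities, deterministically; `tie_break="first-match"`
gives the literal first-match behavior.

**Reweighting.** `W_i = exp[(V_i − V_max)/k_B T]` from the final total
bias (k_B = 0.0083144621 kJ/mol/K; default 300 K). No well-tempered
γ/(γ−1) prefactor is applied by default, matching the max-shifted
Boltzmann-weight prescription implemented here; `bias_factor=γ` enables
the standard final-bias scaling for users who want it. Populations are
weighted label fractions; unclassified weight is reported separately, and
population mass is conserved to 1e−9.

**Decomposition.** ΔG_{i,ref} = −k_B T ln(P_i/P_ref);
ΔU = Δ⟨E⟩^solute + Δ⟨E⟩^solute−solvent with conditional means taken under
the frame weights; ΔH ≃ ΔU (conformational transitions do not change the
ensemble volume, so the pressure–volume term is negligible); TΔS = ΔG − ΔU
identically, so the closure ΔG = ΔU − TΔS holds to machine precision by
construction. The solvent–solvent energy never enters: it is
conformer-independent and differencing it would only add noise — the
synthetic tests demonstrate that a naive total-energy estimator's error
exceeds a planted 4 kJ/mol signal under realistic solvent fluctuations
while the component split recovers it. Standard errors come from 200
seeded bootstrap resamples of each cluster's frames (no error model is
prescribed by the source method; the bootstrap makes no distributional
assumption).

## Synthetic study conditions

`sildenafil_like_world()` defines the default planted ensemble: 6
torsions, 12 conformers laid out as all combinations of 3 modes on the
first torsion × 2 on the second × 2 on the fifth (the other three torsions
unimodal), von Mises concentration κ = 50 per mode (σ ≈ 0.14 rad,
inter-mode separations ≥ 3 rad ≫ σ — well-separated basins), and mixture
mass 0.15 for each of four dominant conformers (the crystal-like-state
analogues) with 0.05 for each of the remaining eight. Bias emulation uses
sums of periodic Gaussians (default width 0.3 rad, height 2.5 k_B·T,
mirroring a typical hill protocol); biased sampling is exact rejection
from p(τ)·exp(−V/kT) with the per-frame V recorded, so reweighting can
undo the bias with no approximation beyond Monte-Carlo noise. Energy
columns are planted per-conformer means (few-kJ/mol spread) under Gaussian
noise (solute 1.5, solute–solvent 3.0 kJ/mol), plus a large common solvent
term (σ = 400 kJ/mol) that exercises the cancellation argument.

What the generator does **not** emulate: time correlation (frames are
i.i.d., whereas MD frames decorrelate over picoseconds), anharmonic or
skewed basin shapes, inter-torsion coupling within a basin, transition
paths between basins (κ = 50 leaves inter-mode bins empty, so rotational
barriers are not estimable from these samples — barrier weights for the
synthetic conditions are supplied from the published barrier table), and
any force-field physics. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration of the pipeline, not the
convergence of real μs-scale explicit-solvent simulations.

Problem sizes in the test suite and acceptance script (6000-frame
reference trajectories, 50 recovery seeds, 1e5-frame reweighting runs,
200 bootstrap resamples) were chosen as the smallest sizes at which the
statistical claims are sharp; all run on a laptop-class single core in
minutes.

## Known limitations and behavior at the margins

* The O(N²) distance matrix limits desk-scale use to a few 10^4 frames;
  the computation streams in row blocks so peak temporary memory is
  O(block × N), but the matrix itself must fit (float32 storage keeps
  relative rounding ≤ 1e−7; all internal arithmetic is double).
* The all-torsions match rule is intentionally strict: a frame one
  histogram bin outside any single torsion's support is unclassified.
  Coverage of a fingerprint therefore has an irreducible finite-sample
  miss rate of order 1/n_cluster per torsion (the probability a fresh draw
  lands in a bin the training sample never visited). On a trajectory with
  a planted 5% out-of-support noise floor the expected classified fraction
  is consequently slightly *below* 95% (≈94.5% under the default
  conditions) for any reasonable bin width, because uniform torus noise
  essentially never matches a 6-torsion fingerprint and cannot compensate
  the misses. Raising `support_min_count` sharpens specificity at further
  cost to coverage; smoothing or widening supports would trade the other
  way but departs from the literal nonzero-probability rule.
* `tune_cutoff` fails loudly on pathological distance spectra (e.g. all
  pairwise distances equal) rather than returning an arbitrary cutoff.
* Unimodal torsions have no rotational barrier; `profile_weights` refuses
  to invent one and asks for explicit barriers instead.
* The decision-graph auto-threshold rule is a heuristic for clean,
  well-separated landscapes; for real data inspect `decision_graph()` and
  prefer `k=` or explicit `centers=` when the corner is ambiguous.
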