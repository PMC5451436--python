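# Methods

`lhcdyn` re-implements, as a tested pipeline, the trajectory statistics,
enhanced-sampling and spectral-convolution computations used to probe
conformational plasticity of photosystem II light-harvesting antenna
proteins (LHCII, CP29) under non-photochemical-quenching (NPQ) conditions:
lumen acidification (ΔpH) and ionic gradients (Δ(KCl)). The real systems are
40,000+-atom membrane MD setups; they are not desk-reproducible. Every
estimator here is therefore exercised on synthetic inputs with *known*
ground truth, so what the tests establish is parameter recovery and
estimator correctness — not the published free-energy profiles or absolute
diffusion coefficients themselves.

Units throughout: nm, kJ/mol, degrees, frame-indexed time with explicit
`dt`. Residue indices are 1-based, ranges inclusive (PDB convention). PDB
files are Å on disk, nm in memory.

## Synthetic study conditions

The `synthetic` module defines the conditions everything downstream is
measured under; its defaults are fixed once:

* **Two-state (L/M) protein** — a 60-residue Cα chain on a smooth
  superhelical curve. Helix D (residues 45–54) jumps between a lumen-facing
  (L) and a membrane-facing (M) position along the membrane normal,
  separated by `lm_amplitude` (default 0.8 nm — the magnitude is not an
  experimentally established number; it is a free parameter chosen large
  against the 0.05 nm thermal noise so the signal-to-noise regime resembles
  the clearly resolved two-conformation picture the statistics are meant to
  detect). Switching is a discrete-time two-state Markov chain with
  transition probabilities P(i→j) = rate·p_j, which leaves the configured
  occupancies (p_L, p_M) stationary for any rate in (0, 1/max p]. Every atom
  carries isotropic Gaussian noise per coordinate; frame 0 is the noiseless
  reference. What this emulates: a localized conformational switch on a
  thermally fluctuating backbone. What it does not: anharmonic side-chain
  coupling, solvent friction, or correlated loop motions — a peak found here
  says the estimator localizes a planted signal, not that real LHCII moves
  this way.
* **Brownian pair** — two rigid 4-atom groups whose centres diffuse freely
  with per-group coefficient D (default 5×10⁻⁴ nm²/frame). The relative
  displacement vector then diffuses with 2D; that factor is recorded in the
  trajectory metadata and is the ground truth for the Einstein fit.
* **Ornstein–Uhlenbeck series** — exact one-step OU transition
  x_{k+1} = ρ x_k + √(1−ρ²)·σ·ξ with ρ = exp(−dt/τ), so the autocorrelation
  is exp(−t/τ) at any sampling interval. The dihedral kind is emitted in
  degrees wrapped to (−180, 180]; default τ mirrors the low-pH backbone
  relaxation regime (2.2 time units).
* **Double well** — quartic U(s) = h((x²−w²)²/w⁴) with x = s−midpoint,
  h = barrier (10 kJ/mol default) and minima at 2.2/2.9 nm, echoing the
  low/high-pH inter-helix A–D distance basins. An optional linear tilt
  offsets the second minimum by `asymmetry` kJ/mol. Because the exact
  F(s) = U(s) − min U is returned alongside, the well is the metadynamics
  oracle.

All randomness flows from one `numpy.random.Generator` seeded per call;
identical specs give byte-identical outputs.

## Flexibility statistics

* **Superposition** is a rigid-body Kabsch fit (rotation + translation, no
  scaling) over a chosen atom subset via `scipy` `Rotation.align_vectors`;
  the fitted transform is applied to all atoms. Subsets of rank < 2
  (collinear) are rejected. The test oracle is an independent quaternion
  (Horn) implementation.
* **PCA-filtered RMSF**: per-residue Cα RMSF of the trajectory reconstructed
  in the top principal components of the superposed coordinates. Projecting
  out the low-variance tail strips uncorrelated thermal jitter while keeping
  collective motions; with the full component set the profile equals the
  plain RMSF exactly (asserted). The default component count is the smallest
  set explaining 75% of variance — the cut is exposed because no canonical
  value exists.
* **Qres**: per-residue environment similarity between two condition-mean
  structures, Q_i = ⟨exp(−(r_ij − r′_ij)²/(2σ_ij²))⟩ over partners with
  |i−j| ≥ 2, σ_ij = 0.1 nm·(1+|i−j|)^0.15 (the standard 1 Å prefactor in
  nm). A residue without eligible partners gets Q_i = 1 by convention (the
  case is reachable only for 3-residue chains). Mean-structure comparison is
  the default because conditions are compared as states; a frame-averaged
  variant sits behind a flag.
* **Differential profile**: |RMSF_low − RMSF_high| · (1 − Q_res). The
  composition order is a declared choice (the alternative
  product-then-difference order is available via `order=`): the profile is
  non-negative, zero for statistically identical ensembles, and peaks where
  a region is both differentially mobile and structurally rearranged.
* **Clustering** is gromos-style greedy centroid clustering on the pairwise
  frame RMSD matrix of an already-superposed trajectory (no per-pair
  refit, which is exact when a common static region anchors the fit).
  Populations sum to 1; the cluster count is non-increasing in the cutoff.
* **L/M classification** thresholds the helix-D COM along the membrane
  normal; by this package's axis convention the M (membrane-facing) state
  lies below the threshold. The generator writes a usable threshold (the
  midpoint of the two planted positions) into its metadata.

## Kinetics

* **MSD** of the relative COM vector r_AB(t) of a helix pair (the
  relative-vector reading is the only one that yields one curve per pair),
  time-origin averaged with the standard FFT decomposition; equality with
  the brute-force double loop is asserted. Uniform atom masses by default
  (Cα-only synthetic data has none); a mass vector is accepted.
* **Einstein fit**: OLS of MSD on lag; D = slope/6, c = intercept. A
  negative fitted D is returned flagged, never dropped. The default window
  is lags in [10%, 50%] of the curve's maximum lag. The relative standard
  error of a time-origin-averaged MSD at lag m grows like √(m/N), so for
  diffusion recovery on long trajectories the curve is computed only to
  `max_lag` = 100 frames of a 50,000-frame trajectory (fit window then
  10–50 frames); that choice keeps the per-seed D error near 2–3% where a
  half-length lag range would leave tens of percent of fit noise.
* **Percent change** vs the lowest-energization reference:
  100·(D − D_ref)/D_ref rounded half-away-from-zero to integer percent,
  matching the published table convention (verified against every
  parenthesized value of that table).
* **RCF**: C(t) = ⟨cos(φ(t₀+t) − φ(t₀))⟩ over time origins, pooled across
  the supplied backbone dihedral series (φ/ψ pooled; treating them
  separately is possible by passing them separately). A P2 variant sits
  behind `probe="p2"`. Fits are nonlinear least squares of a·exp(−t/t_f)
  with a log-linear initialisation and an explicit non-convergence status.
  For OU dihedrals the exact Gaussian-phase relation
  C(t) = exp(−σ²(1−ρ(t))) is inverted (ρ = 1 + ln C/σ²) before fitting, and
  the angular amplitude must not be tiny: the inversion divides the ACF
  noise by σ², so σ = 40° series are used in the analysis drivers.

## Nonbonded energetics

Group–group cross energies per frame: k_e q_i q_j/r_ij with
k_e = 138.935458 kJ mol⁻¹ nm e⁻², plus 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]
under Lorentz–Berthelot combination (arithmetic σ, geometric ε — the
original force field is out of scope, so the rule is a documented
convention). No periodic boundaries and no cutoff by default (synthetic
boxes are small and aperiodic); a plain distance cutoff exists for parity
experiments. Distances below 10⁻⁴ nm raise a singular-geometry error. The
energy ACF is the normalized fluctuation autocorrelation (time-origin
averaged, FFT); replicate averaging is the mean of per-replicate normalized
ACFs, never the ACF of a concatenation. Relaxations are ranked by
τ_int = Σ C(t) dt up to the first zero crossing (full range, flagged, if
none); the ACF is computed on the total energy by default with per-component
curves available, since the source analysis does not state the split.

## Well-tempered metadynamics

One CV, overdamped Euler–Maruyama Langevin: ds = (F_pot + F_bias)/γ_f · dt +
√(2 k_B T dt/γ_f)·ξ, with friction γ_f the inverse CV mobility. Gaussians of
width σ_G are deposited every `pace` steps with the well-tempered schedule
w_k = w₀ exp(−V(s_k)/(k_B ΔT)), ΔT = (γ−1)T, and the free energy is
reconstructed as F = −(γ/(γ−1))·V(s, t_end), min-anchored. Defaults
(γ = 10, w₀ = 1.2 kJ/mol, σ_G = 0.05 nm, pace = 500, T = 310 K, dt = 5×10⁻⁵,
2×10⁶ steps) follow common practice for a nm-scale CV over a few-k_BT
barrier; no canonical parameter set exists for the original systems, so all
are config-exposed. Numerical choices:

* the running bias and its force are cached on a grid of ~σ_G/10 spacing and
  linearly interpolated per step; reconstruction always re-sums the logged
  hills directly, and cache/direct-summation agreement is asserted in tests;
* reflective walls at the domain edges (the physical CV, an inter-helix
  distance, is bounded); profiles within ~σ_G of a wall should not be
  over-interpreted;
* a step moving the CV by more than a tenth of the domain aborts with a
  diagnostic (dt too large);
* w₀ = 0 degenerates to plain Langevin sampling, asserted against the
  Boltzmann distribution;
* hill heights at any fixed CV value are non-increasing in time (the bias
  only grows);
* multi-seed profiles are averaged after per-run min-anchoring.

The ΔE(t) convergence diagnostic is the difference of window-mean free
energies between two disjoint CV windows, recomputed from partial hills
logs at checkpoints; a checkpoint is NaN-flagged while either window is
still unvisited. Note that ΔE equals the well offset only for equal-width
windows mirrored about the barrier midpoint and centred on the minima —
for asymmetric windows (such as the 2.0–2.5 / 2.8–3.0 nm pair used in the
drivers) the correct reference is the exact window-mean difference of the
analytic potential, which the drivers print alongside.

At the default settings the three-seed recovery of the 10 kJ/mol double
well is ~0.12–0.14 k_BT RMS against the exact curve with the barrier within
~5–7% (the max of a noisy reconstruction is biased slightly upward).

## Spectra

Stick spectra (energy eV, oscillator strength) are broadened with
*unit-peak* Lorentzians A(E) = Σ f_i γ²/((E−E_i)² + γ²) — relative shapes
are all the downstream comparisons use, and a unit-area variant sits behind
a flag. Energy-domain (not wavelength-domain) convolution is the documented
choice. Default γ = 0.02 eV (none is published). λ = 1239.841984/E (hc in
eV·nm). The packaged Qy line table carries no oscillator strengths, so equal
weights are assigned: peak *positions* and difference-spectrum extrema
orderings are meaningful; relative intensities and the published ΔA peak
wavelengths (603 → 620 nm) are not reproducible from positions alone, and
only the redshift ordering is asserted. Two strongly overlapping lines
(separation < 2γ, e.g. the 1.515/1.500 eV high-pH doublet) physically merge
into a single maximum inside the multiplet span rather than peaking at
either input line — tests encode exactly that.

## Problem sizes

The shipped configurations are chosen for desk-scale determinism: 600–4,000
frame trajectories for flexibility/clustering, 50,000 frames for diffusion
recovery, 100,000 samples for OU/ACF recovery, 3 × 2×10⁶ Langevin steps for
metadynamics. These sizes keep every stochastic recovery inside its stated
tolerance at fixed seeds.

## Known limitations

* No binary trajectory formats (DCD/XTC) or force-field topologies; PDB/XYZ
  + YAML only.
* No cross-protein sequence alignment: profile superposition across homologs
  is accepted as a user-supplied residue mapping.
* No metadynamics reweighting of auxiliary observables; biased-trajectory
  ACFs are computed unweighted, mirroring the source usage. A standard
  reweighting hook is future work.
* Single-CV metadynamics only.
* The synthetic generators emulate statistical features, not physics:
  passing tests demonstrate estimator correctness, not membrane-protein
  behaviour.
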