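# lhcdyn

Trajectory statistics, single-CV well-tempered metadynamics and spectral
convolution for probing conformational plasticity of photosystem II antenna
proteins (major LHCII, CP29) under non-photochemical quenching (NPQ)
conditions — lumen acidification (ΔpH) and ionic gradients (Δ(KCl)).

Photoprotective quenching is thought to be gated by a conformational switch
of the short lumen-exposed helix D between a lumen-facing (L) and a
membrane-facing (M) orientation, which repacks the adjacent chlorophyll
613/614 pair and redshifts its Qy absorption. This package implements the
full chain of computations used to detect and quantify that response, each
validated against synthetic ground truth or exact closed forms:

* **flexibility** — Kabsch superposition, PCA-filtered Cα RMSF, the Qres
  environment-similarity score, the differential profile
  |ΔRMSF|·(1 − Q_res) that localizes pH-responsive regions, gromos-style
  cluster averaging, and L/M occupancy classification;
* **kinetics** — inter-helix centre-of-mass MSD, the Einstein relation
  MSD = 6·D·t + c with percent changes against a reference condition, and
  rotational correlation functions of backbone dihedrals fitted as
  a·exp(−t/t_f);
* **energetics** — group–group Coulomb + Lennard-Jones interaction energies
  and their normalized autocorrelation C(t), ranked by integrated
  correlation time (slower relaxation ⇔ closer pigment packing);
* **metadynamics** — an overdamped-Langevin, well-tempered metadynamics
  engine over one collective variable (the A–D inter-helix distance in the
  application), with hills logging, free-energy reconstruction
  F = −(γ/(γ−1))·V_bias and a two-window ΔE convergence diagnostic;
* **spectra** — Lorentzian broadening of Qy stick spectra,
  NPQ-minus-Fm difference spectra and eV↔nm conversion;
* **synthetic** — generators for every input above with known parameters
  (two-state helix-D switching, Brownian pairs, Ornstein–Uhlenbeck series,
  an analytic double well), so all estimators are testable without any
  download.

## Worked example

Generate a low-pH ensemble whose helix D (residues 45–54) switches between
two positions 0.8 nm apart with 30/70 occupancy, a high-pH ensemble with
thermal noise only, and locate the responsive region:

```python
import numpy as np
from lhcdyn.core import Topology
from lhcdyn.flexibility import cluster_average, flex_product, lm_fraction, superpose
from lhcdyn.synthetic import SyntheticSpec, gen_two_state_protein

low = gen_two_state_protein(SyntheticSpec(
    seed=1, n_frames=800, lm_amplitude=0.8, lm_populations=(0.3, 0.7),
    switch_rate=0.2, noise_sigma=0.05))
high = gen_two_state_protein(SyntheticSpec(
    seed=5001, n_frames=800, lm_amplitude=0.0, noise_sigma=0.05))

prof = flex_product(low, high)
print(prof.peak_residue())                # -> 51   (inside helix D, 45-54)

clusters = cluster_average(superpose(low, 0, np.arange(40)), rmsd_cutoff=0.15)
print(clusters.n_clusters,                # -> 2
      np.round(clusters.populations, 2))  # -> [0.76 0.24]

topo = Topology(helix_ranges={"D": (45, 54)},
                membrane_z_threshold=low.metadata["lm_threshold_z"])
print(round(lm_fraction(low, topo)["M"], 3))   # -> 0.76  (truth 0.7)
```

The |ΔRMSF|·(1 − Q_res) profile peaks at residue 51, inside the helix-D
range — the two ensembles differ only by the planted L/M switching, and the
statistic localizes it. Clustering at a cutoff between the noise and
displacement scales resolves exactly the two planted conformations, and the
threshold classifier recovers the 0.7 M-state occupancy within sampling
error (800 correlated frames).

The same workflows are packaged as narrative drivers:

```sh
python analysis/01_generate_inputs.py   --seed 1 --out results
python analysis/02_flexibility_profiles.py       --out results
python analysis/03_diffusion_and_rcf.py --seed 1 --out results
python analysis/04_metadynamics_fes.py  --seed 1 --out results
python analysis/05_pigment_energetics.py --seed 1 --out results
python analysis/06_qy_spectra.py                 --out results
```

Each prints what it found (e.g. `03` reports the Einstein fit recovering the
planted relative diffusion coefficient within a few percent and the
relaxation-time fits t_f = 2.2/4.1 with their 1.86 ratio; `04` reports the
double-well free energy recovered to ~0.13 k_BT RMS with the 10 kJ/mol
barrier within ~7%) and writes its tables under `results/`, logging
parameters and library versions to `results/run.log`.

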