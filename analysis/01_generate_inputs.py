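#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under <out>/inputs:
  * low/high "lumen pH" two-state Ca trajectories (multi-model PDB) — the
    low-pH ensemble carries the L/M helix-D switching, the high-pH one only
    thermal noise;
  * a Brownian helix pair with known relative diffusion coefficient (XYZ);
  * an Ornstein-Uhlenbeck backbone-dihedral series (TSV);
  * the topology annotation (YAML).
"""

import argparse
from pathlib import Path

import yaml

from lhcdyn import io as lio
from lhcdyn.synthetic import SyntheticSpec, gen_brownian_pair, gen_ou_series, gen_two_state_protein


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-frames", type=int, default=800)
    args = ap.parse_args()

    inputs = args.out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    low_spec = SyntheticSpec(
        seed=args.seed, n_frames=args.n_frames, lm_amplitude=0.8,
        lm_populations=(0.3, 0.7), switch_rate=0.2, noise_sigma=0.05,
    )
    high_spec = SyntheticSpec(
        seed=args.seed + 5000, n_frames=args.n_frames, lm_amplitude=0.0,
        noise_sigma=0.05,
    )
    low = gen_two_state_protein(low_spec)
    high = gen_two_state_protein(high_spec)
    lio.write_trajectory(low, inputs / "low_ph.pdb")
    lio.write_trajectory(high, inputs / "high_ph.pdb")

    brown = gen_brownian_pair(
        SyntheticSpec(seed=args.seed + 9000, n_frames=50_000, diffusion_coeff=5e-4)
    )
    lio.write_trajectory(brown, inputs / "brownian_pair.xyz")

    # four backbone dihedrals of the A-D loop, pooled downstream in the RCF
    for k in range(4):
        dihedral = gen_ou_series(
            SyntheticSpec(seed=args.seed + 13000 + k, n_frames=100_000,
                          relax_time=2.2, dt=0.05, ou_sigma=40.0),
            kind="dihedral",
        )
        lio.write_timeseries(dihedral, inputs / f"loop_dihedral_{k}.tsv")

    topo = {
        "helices": [
            {"label": "A", "start": 5, "end": 20},
            {"label": "B", "start": 25, "end": 38},
            {"label": "D", "start": 45, "end": 54},
        ],
        "membrane_normal": "z",
        "membrane_z_threshold": float(low.metadata["lm_threshold_z"]),
    }
    with open(inputs / "topology.yaml", "w") as fh:
        yaml.safe_dump(topo, fh)

    lio.write_run_log(args.out, {
        "script": "01_generate_inputs",
        "seed": args.seed,
        "n_frames": args.n_frames,
        "lm_amplitude_nm": 0.8,
        "lm_populations": (0.3, 0.7),
        "noise_sigma_nm": 0.05,
        "diffusion_coeff_nm2_per_frame": 5e-4,
        "dihedral_relax_time": 2.2,
    })
    print(f"wrote synthetic inputs to {inputs}/ "
          f"(low/high pH PDB, Brownian XYZ, dihedral TSV, topology YAML)")


if __name__ == "__main__":
    main()
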