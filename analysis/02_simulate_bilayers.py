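#!/usr/bin/env python
"""Generate the four synthetic study bilayers and record their ground truth.

The systems stand in for the MD engine: pure PC and 4:1 PC:PS bilayers in
a low- and a high-calcium regime, with binding occupancies, geometry and
hydration markers set to mirror the reported trends.  Writes the per-system
ground truth to results/ground_truth/<name>.json and a one-frame GRO
snapshot of each system to scratch/ for inspection; downstream scripts
regenerate the trajectories deterministically from (spec, seed) instead of
reading bulky files.
"""

import sys
from pathlib import Path

from calcimem.io import write_gro
from calcimem.study import SYSTEMS, seed_for
from calcimem.synth import generate

ROOT = Path(__file__).resolve().parents[1]
TRUTH_DIR = ROOT / "results" / "ground_truth"
SCRATCH = ROOT / "scratch"


def main() -> int:
    TRUTH_DIR.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    for name, spec in SYSTEMS.items():
        traj, truth = generate(spec, seed_for(name))
        truth.to_json(TRUTH_DIR / f"{name}.json")
        write_gro(traj.frame(0), traj.topology, SCRATCH / f"{name}_frame0.gro",
                  title=name)
        print(f"{name:10s}: {traj.n_frames} frames x {traj.n_atoms} atoms, "
              f"APL {truth.apl_per_frame[0]:.3f} nm^2, "
              f"P-P thickness {truth.thickness:.2f} nm, "
              f"expected adsorbed Ca {truth.expected_adsorbed:.1f} "
              f"({truth.lipids_per_adsorbed_ion:.1f} lipids/ion)")
    print(f"\nground truth in {TRUTH_DIR}, snapshots in {SCRATCH}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
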