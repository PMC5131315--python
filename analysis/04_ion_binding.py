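#!/usr/bin/env python
"""Calcium-binding analysis of the four synthetic bilayers.

First coordination numbers per head group, coordination of the adsorbed
ions, lipids per adsorbed ion (0.42 nm all-contacts criterion), hydration
numbers at the RDF-derived cutoffs (2.4 A carbonyl O, 3.35 A phosphate P),
and contact-residence statistics.  Each recovered quantity is printed next
to the generator's ground truth; the coordination/hydration summary is
laid out like the study's adsorption table in results/binding_table.csv.
"""

import sys
from pathlib import Path

from calcimem import binding
from calcimem.io import GroupTag
from calcimem.pipeline import make_table1
from calcimem.study import SHELL_CUTOFFS, SYSTEMS, seed_for
from calcimem.synth import generate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

LABELS = {
    "POPC_low": ("POPC", "low Ca"),
    "POPC_high": ("POPC", "high Ca"),
    "PCPS_low": ("POPC/POPS 4:1", "low Ca"),
    "PCPS_high": ("POPC/POPS 4:1", "high Ca"),
}


def main() -> int:
    OUT.mkdir(exist_ok=True)
    cutoffs = {GroupTag(k): v for k, v in SHELL_CUTOFFS.items()}
    reports = []
    for name, spec in SYSTEMS.items():
        traj, truth = generate(spec, seed_for(name))
        rep = binding.binding_report(traj, cutoffs)
        ions = traj.topology.indices_with_tag(GroupTag.CA)
        tl = binding.adsorption_timeline(traj, ions)
        res = binding.residence_times(tl, spec.frame_spacing, gap_tolerance=0)
        print(f"\n{name}")
        print(f"  lipids per adsorbed Ca: {rep.lipids_per_ion:6.2f} "
              f"(truth {truth.lipids_per_adsorbed_ion:.2f})")
        # expected_n1 is the single-site stationary expectation; measured n1
        # runs above it when an ion bound to one group also sits inside the
        # shell of a neighbouring group of the same lipid (carboxylate +
        # phosphate bridging), and scatters because a short window holds
        # few independent binding configurations
        for tag in ("PHOS_P", "CARBONYL_O_SN2", "COO_PS"):
            t = truth.expected_n1.get(tag, float('nan'))
            print(f"  n1[{tag:>15s}]: {rep.n1[tag]:.3f} +/- {rep.n1_se[tag]:.3f} "
                  f"(site-occupancy expectation {t:.3f})")
        for tag in ("PHOS_P", "CARBONYL_O_SN2"):
            m, sd = rep.hydration[tag]
            print(f"  hydration[{tag:>15s}]: {m:.2f} +/- {sd:.2f} waters/lipid "
                  f"(truth {truth.hydration[tag]:.2f})")
        finite = res.intervals_ns[~res.censored]
        frac_cens = res.censored.mean() if len(res.censored) else float("nan")
        if len(finite):
            print(f"  mean uncensored contact residence: {finite.mean():.1f} ns "
                  f"({frac_cens:.0%} of intervals window-censored; "
                  f"chain dwell {truth.expected_residence_ns:.1f} ns)")
        sys_label, conc = LABELS[name]
        reports.append((sys_label, conc, rep.as_dict()))
    table = make_table1(reports)
    table.to_csv(OUT / "binding_table.csv", index=False)
    print("\nCoordination / hydration summary (per adsorbed ion):")
    print(table.to_string(index=False))
    print(f"\nwrote {OUT / 'binding_table.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
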