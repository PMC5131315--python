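"""Synthetic study systems.

Four bilayer conditions mirroring the simulated systems of the study this
package reimplements: pure PC and 4:1 PC:PS, each in a low- and a
high-calcium regime.  The structural parameters encode the reported
*trends* (lateral compression and thickening with calcium, carboxylate
binding in the mixed bilayer, progressive dehydration); the synthetic
generator produces no physics, so these presets define known ground truth
for the analysis chain rather than a reproduction of the MD observables.

Composition constants follow the simulated setup: 128 lipids (64 per
leaflet), 12 PC->PS replacements per leaflet in the mixed system, lipid
charges unscaled, ionic charges ECC-scaled (+1.5e / -0.75e), 16
neutralising cations for the mixed bilayer.
"""

from __future__ import annotations

from .synth import SyntheticSpec

#: frames retained for time-independent analysis (the tail of each run)
ANALYSIS_FRAMES = 60
FRAME_SPACING_NS = 0.1


def _base(**kw) -> SyntheticSpec:
    defaults = dict(
        lipids_per_leaflet=64,
        n_frames=ANALYSIS_FRAMES,
        frame_spacing=FRAME_SPACING_NS,
        waters_per_lipid=8,
        sigma=0.03,
        mean_residence=10.0,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


SYSTEMS: dict[str, SyntheticSpec] = {
    # pure PC, low calcium: few ions, nearly all adsorbed, deep binding,
    # mild compression; ~1 adsorbed ion per 17 lipids
    "POPC_low": _base(
        apl_start=0.63, z_phosphate=1.95, n_ca=8, n_cl=16,
        p_phos=0.55, p_carb=0.43,
        shell_waters_carbonyl=2, shell_waters_phosphate=3,
    ),
    # pure PC, high calcium: many ions, partial adsorption, compressed and
    # thickened bilayer, fewer first-shell waters
    "POPC_high": _base(
        apl_start=0.57, z_phosphate=2.05, n_ca=60, n_cl=120,
        p_phos=0.40, p_carb=0.30,
        shell_waters_carbonyl=1, shell_waters_phosphate=2,
    ),
    # 4:1 PC:PS, low calcium: carboxylate binding dominates
    "PCPS_low": _base(
        apl_start=0.59, z_phosphate=2.0, ps_per_leaflet=12,
        n_ca=26, n_cl=20,
        p_phos=0.30, p_carb=0.25, p_coo=0.40,
        shell_waters_carbonyl=2, shell_waters_phosphate=3,
    ),
    # 4:1 PC:PS, high calcium: phosphate binding overtakes carboxylate
    "PCPS_high": _base(
        apl_start=0.54, z_phosphate=2.1, ps_per_leaflet=12,
        n_ca=70, n_cl=128,
        p_phos=0.40, p_carb=0.18, p_coo=0.25,
        shell_waters_carbonyl=1, shell_waters_phosphate=2,
    ),
}

#: first-shell cutoffs (nm) used by the coordination analyses; the
#: hydration cutoffs (0.24 / 0.335 nm) live in calcimem.binding
SHELL_CUTOFFS = {"PHOS_P": 0.30, "CARBONYL_O_SN2": 0.30, "COO_PS": 0.30}

#: base seed of the study realisations analysed by the numbered scripts
BASE_SEED = 20160


def seed_for(name: str) -> int:
    """Deterministic per-system seed for the study realisations."""
    return BASE_SEED + sorted(SYSTEMS).index(name)
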