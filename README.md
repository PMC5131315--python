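# calcimem

Analysis toolkit for calcium–phospholipid-bilayer binding studies that
combine scaled-charge molecular dynamics with time-resolved fluorescence.
It covers the full computational chain around such a study — everything
except the MD engine and the spectrometer, both of which are replaced by
synthetic-data generators with exact ground truth:

* **Ion preparation** — electronic continuum correction (ECC): ionic
  charges are scaled by f = 1/√ε_el with ε_el ≈ 1.78 the electronic
  (optical-frequency) part of the water dielectric constant, giving
  f ≈ 0.75 and simulation charges of +1.5 e for Ca²⁺ and −0.75 e for Cl⁻;
  neutralisation counts and nominal concentrations (c = n/n_w × 55.51 M)
  follow from composition arithmetic.
* **Bilayer structure** — area per lipid A(t) = LₓL_y/N_leaflet with
  block-analysis standard errors; number-density profiles along the
  membrane normal (leaflet-averaged); bilayer thickness as the distance
  between the phosphate density peaks; distributions of the angle Φ_P–N
  between each lipid's P→N vector and the outward leaflet normal.
* **Ion binding** — radial distribution functions with minimum-image
  distances, first coordination numbers n₁ inside the first g(r) minimum,
  adsorption via a 0.42 nm all-contacts criterion (lipids per adsorbed
  ion), per-adsorbed-ion coordination of phosphate / carbonyl /
  carboxylate groups, hydration numbers at RDF-derived cutoffs (2.4 Å
  carbonyl O, 3.35 Å phosphate P), and contact-residence times from a
  gap-tolerant interval analysis.
* **TDFS spectroscopy** — iterative-reconvolution fitting of TCSPC decays,
  reconstruction of time-resolved emission spectra from the fitted decays
  and the steady-state spectrum, Siano–Metzler log-normal fits of each
  time slice to obtain ν(t), the total shift Δν = ν(0) − ν(∞) (probe
  constants ν(0) = 23800 cm⁻¹ for Laurdan, 22750 cm⁻¹ for Dtmac) and the
  integrated relaxation time τ = ∫₀^∞ (ν(t) − ν(∞))/Δν dt; plus the
  Langmuir–Freundlich isotherm ζ(c) = ζ₀ + (ζ_max−ζ₀)(Kc)ⁿ/(1+(Kc)ⁿ) for
  zeta-potential titrations.

The synthetic bilayer generator builds two-leaflet head-group skeletons
(64 lipids per leaflet, optional 4:1 PC:PS mixture) with prescribed
geometry, two-state Markov ion-binding dynamics and hydration-shell
markers, so every analysis above is validated as a parameter-recovery
problem against known ground truth. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

Composition arithmetic for the mixed bilayer, from the command line:

```sh
$ cat comp.yaml
lipid_counts: {POPC: 104, POPS: 24}
lipid_charges: {POPS: -1.0}
n_water: 4300
$ calcimem prep --composition comp.yaml
```

prints (abridged):

```json
{
 "n_lipids": 128,
 "net_lipid_charge_e": -24.0,
 "scaling_factor": 0.75,
 "scaled_charges_e": {"CA": 1.5, "CL": -0.75},
 "neutralizing_cations": 16,
 "net_charge_e": 0.0
}
```

i.e. with unscaled lipid charges and ECC-scaled ions, 16 calcium ions of
+1.5 e exactly neutralise the 24 anionic PS lipids.

The same chain in Python, together with a structural analysis of a
synthetic bilayer:

```python
from calcimem import charges, structure
from calcimem.io import GroupTag
from calcimem.synth import SyntheticSpec, generate

f = round(charges.scaling_factor(1.78), 2)        # 0.75
q = charges.scale_charges({"CA": 2.0}, f).scaled  # {'CA': 1.5}

traj, truth = generate(SyntheticSpec(n_ca=16, p_phos=0.4), seed=1)
apl = structure.block_average(structure.area_per_lipid(traj, 64))
prof = structure.density_profile(
    traj, traj.topology.indices_with_tag(GroupTag.PHOS_P), bin_width=0.1)
print(apl.mean, structure.bilayer_thickness(prof).thickness)
# 0.640 nm^2 per lipid, 4.003 nm phosphate-phosphate thickness
```

## Analysis scripts

The `analysis/` directory holds the numbered study drivers; each prints a
short narrative and writes tidy tables under `results/`:

1. `01_prepare_systems.py` — charge scaling, neutralisation,
   concentration table (`composition.csv`);
2. `02_simulate_bilayers.py` — the four synthetic study systems (pure PC
   and 4:1 PC:PS at low/high calcium) and their ground truth;
3. `03_structure_analysis.py` — APL, thickness, density profiles and
   head-group angles vs ground truth (`structure_summary.csv`, …);
4. `04_ion_binding.py` — coordination, adsorption ratios, hydration and
   residence statistics, laid out as an adsorption summary table
   (`binding_table.csv`);
5. `05_tdfs_analysis.py` — TDFS recovery for Laurdan-like and Dtmac-like
   probes and the Langmuir–Freundlich zeta fit (`tdfs_recovery.csv`,
   `zeta_langmuir_freundlich.json`).

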