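# Methods

This note records the models, conventions and numerical choices behind
each stage of the package, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Units and file formats

Lengths are nanometres internally; Ångström input is accepted at the I/O
boundary via an explicit `units` flag (the field mixes both: cutoffs are
often quoted in Å, box sizes in nm). Times are nanoseconds, charges in
units of the elementary charge, spectra in cm⁻¹. Only orthorhombic boxes
are supported; triclinic input is rejected because every pair analysis
applies the component-wise minimum-image convention, which is valid only
for rectangular cells. Trajectories travel as multi-frame GRO
(fixed-column, 3-decimal) or as an XYZ dialect with the three box edge
lengths appended to the comment line — the simplest plain-text carrier
for synthetic output. Atom→group assignment is a plain YAML map
(residue name → atom name → tag) shipped with templates for Berger-style
POPC/POPS/SPC naming and for the generator's own names; unmapped atoms
fall back to `OTHER` with a warning.

## Charge scaling

The electronic continuum correction treats electronic polarisation of
the medium in mean field by scaling ionic charges with f = 1/√ε_el.
With ε_el = 1.78 for water (the optical-frequency n²), f = 0.7495,
conventionally displayed as 0.75; the package stores full precision and
rounds only for display. The printed simulation charges (+1.5 e, −0.75 e)
follow from the two-decimal factor, which is therefore the default for
reproduction; the exact factor remains available. Lipid charges are
*not* scaled — only then does the neutralisation arithmetic close
exactly: 24 anionic lipids at −1 e are balanced by 16 cations at +1.5 e.
Nominal salt concentrations use the pure-water molarity convention
c = (n_pairs/n_water) × 55.51 mol/L; the convention is configurable
because other codes count ions per volume instead.

## Synthetic bilayers

The generator replaces the MD engine. It emits head-group skeletons: per
lipid a phosphate P, a choline N at a fixed P→N distance (0.45 nm) along
a sampled tilt direction, an sn-2 carbonyl O at its own depth, and for
PS lipids a two-oxygen carboxylate. Defaults (64 lipids per leaflet,
optional 12 PS per leaflet, carbonyl 1.5 nm < phosphate 2.0 nm <
choline 2.1 nm from the midplane, 0.1 ns frame spacing) mirror the
simulated systems whose analyses this package reimplements; the z-levels
are configuration, not physical claims. Lipids sit on a per-leaflet
square lattice at the scheduled area per lipid (constant or linear
ramp), with a fixed per-lipid lattice jitter and i.i.d. Gaussian
positional noise σ (default 0.03 nm) on every atom each frame. Molecules
are never wrapped: wrapping would split P–N pairs across the boundary,
and all analyses apply minimum image themselves.

Ion dynamics are a per-ion two-state (bound/free) Markov chain — the
simplest process with a well-defined residence time. The per-frame
unbind probability is the exact exponential discretisation
b = 1 − exp(−Δt/τ_res); the bind probability a = b·p/(1−p) pins the
stationary bound probability p = p_phos + p_carb + p_coo. When the
requested occupancy cannot be reached at that dwell (a > 1), the
occupancy wins — it is the contract of every recovery test — and the
dwell lengthens to (the ground truth reports the implied mean interval
Δt/b in either case). A bound ion sits at a fixed distance (0.25 nm)
from its sampled site atom; free ions, chloride and bulk waters are
uniform in the water slabs, which are kept clear of the head groups by
a margin larger than the 0.42 nm contact cutoff so that "free" never
counts as adsorbed.

Hydration ground truth comes from marker waters placed at fixed radii
inside the analysis cutoffs (0.20 nm at carbonyls vs the 0.24 nm cutoff;
0.30 nm at phosphates vs 0.335 nm), within a 25° cone about the normal
— carbonyl markers face the midplane, phosphate markers the water — so a
marker can never stray into a neighbouring lipid's shell. Under noise a
marker still leaves its own shell occasionally; the expected retention
is the closed-form radial CDF of an offset isotropic Gaussian with
s = √2·σ, and the ground-truth hydration applies it.

What the generator does **not** emulate: forces, energies, acyl chains,
water structure, lipid diffusion or flip-flop, ion–ion correlations, and
the actual coordination numbers of the real bilayers (those require real
MD and are out of scope). Expected first-shell coordination numbers in
the ground truth are *single-site stationary expectations*; measured n₁
can exceed them when a bound ion also falls inside the shell of another
group of the same lipid (carboxylate–phosphate bridging), which the
binding analyses count faithfully.

## Structural observables

APL is LₓL_y divided by lipids per leaflet, per frame. Block analysis
splits the series into n contiguous equal blocks (default 5, remainder
dropped from the front) and quotes stdev(block means)/√n, which stays
valid for correlated frames. Density profiles recentre each frame on the
lipid centre of mass; the centre is found by iterative minimum-image
refinement (so a bilayer straddling the periodic boundary is handled)
with an orientation check — carbonyls must lie interior to phosphates —
to break the two-slab ambiguity between midplane and mid-water. Profiles
are counts/(LₓL_yΔz) averaged over frames (bin width default 0.1 nm),
optionally symmetrised by z → −z averaging; the unsymmetrised integral
times the box area reproduces the selection size exactly for a constant
box. Thickness is the distance between the per-leaflet phosphate density
peaks, each refined by three-point parabolic interpolation, with one bin
width quoted as the uncertainty. The head-group angle Φ_P–N is measured
against the *outward* leaflet normal (leaflet = sign of the recentred
phosphate z), so means below 90° point toward water; isotropic
orientations give a sin Φ distribution with mean 90°.

## Binding analyses

All pair distances are minimum-image. g(r) normalises the pair-distance
histogram by the ideal shell count 4πr²Δr·ρ_B with ρ_B the mean density
of B over the whole box; this reference is documented as a caveat —
bilayer systems are inhomogeneous, so RDF magnitudes are relative, and
first-shell cutoffs may instead be supplied directly (the study's
printed cutoffs are used for its tables). Cumulative coordination n(r)
comes from direct pair counting, never from integrating g. The
first-shell cutoff is the first local minimum after the first maximum of
a 3-bin-smoothed g(r), with user-supplied fallback recorded as such.

Conventions: a multi-atom group (both carboxylate oxygens) counts an ion
once; "adsorbed" means ≥ 1 lipid head-group atom within 0.42 nm — the
only ion–lipid cutoff the source analyses attach to contacts; "lipids
per adsorbed ion" divides total lipids by the time-averaged adsorbed
count; per-adsorbed-ion coordination averages over adsorbed ions only.
Hydration counts water oxygens within the group-specific cutoff once per
lipid-group and reports mean ± SD over lipid-frame samples (SD because
the study's table quotes spread, block SE is also available for n₁).
Residence analysis bridges unbound gaps up to a configurable tolerance,
flags intervals touching either trajectory end as censored, and reports
interval statistics plus per-ion first-desorption times; censored
intervals are excluded from mean-dwell estimates, which biases them low
when the window is shorter than the dwell (the analysis scripts print
the censored fraction for this reason).

## TDFS

Decay fitting is iterative reconvolution: model = IRF ⊛ Σαᵢexp(−t/τᵢ)
on the channel grid, minimised under Neyman weights 1/√max(counts, 1).
`fit_decay` (1–4 free lifetimes) uses variable projection — amplitudes
solved linearly at each trial lifetime set, lifetimes refined by
deterministic multi-start least squares over log τ. Amplitudes are
signed: red-edge decays of a relaxing emitter rise before they fall.
For TRES reconstruction the package prefers `fit_decay_series`, the same
reconvolution model on a fixed logarithmic basis of 12 lifetimes
(channel width to half the record) with only linear amplitudes: it is
deterministic and approximates the smoothly evolving decays better than
a free 2–3-exponential fit, whose approximation bias propagates into
ν(t). TRES follow S_λ(t) = f_λ(t)·SS_λ/∫f_λdt with the integral taken
analytically (Σαᵢτᵢ), so per-wavelength time integrals conserve the
steady-state spectrum exactly; intensities move to the wavenumber axis
(ν = 10⁷/λ) with the λ² Jacobian. Each time slice is fitted with the
Siano–Metzler log-normal (Gaussian limit as asymmetry → 0); peaks
outside the measured window are flagged extrapolated.

ν(∞) is the mean of ν(t) over the final 10 % of the TRES window (a
configurable plateau criterion; a residual slope above 30 cm⁻¹/ns
triggers a warning), and Δν = ν(0) − ν(∞) uses the probe constant ν(0).
The integrated time τ = ∫C(t)dt is evaluated by fitting C with 1–3
exponentials (amplitudes constrained to sum to 1, AIC model choice) and
integrating analytically; component lifetimes are capped at a quarter of
the window because slower components are not data-constrained and would
convert plateau noise into spurious area — the window should therefore
cover at least four relaxation times. Trapezoidal integration is the
fallback. The default TRES window is 40 % of the TCSPC record: beyond
that the fluorescence has decayed and the reconstruction is pure model
extrapolation.

The synthetic TCSPC generator emits an area-normalised log-normal whose
peak drifts as ν(t) = ν(∞) + Δν·C(t) while total intensity decays with
the fluorescence lifetimes, sliced at the detection wavelengths
(400–550 nm in 10 nm steps), divided by the λ² Jacobian the analysis
re-applies, convolved with a Gaussian IRF and Poisson-sampled with the
brightest channel at the requested peak counts. Defaults represent a
Laurdan-like probe: ν(0) = 23800 cm⁻¹, Δν = 1700 cm⁻¹, biphasic C(t)
with τ = 2.0 ns, 1024 × 0.05 ns channels, 10⁴ peak counts. At those
settings the recovery scatter matches the method's intrinsic
uncertainties (±50 cm⁻¹ in Δν, ±0.05 ns in τ); single realisations
scatter at that scale by construction, while the mean over seeds is
unbiased. Probes with relaxation components near the instrument response
(the Dtmac-like preset, 0.2 ns) recover τ with visibly more bias — the
same limitation the experiment itself reports for fast headgroup
relaxation.

## Study systems and problem sizes

The four presets in `calcimem.study` (pure PC and 4:1 PC:PS, low/high
calcium) encode the reported *trends* — lateral compression with
thickening, carboxylate-dominated binding at low calcium overtaken by
phosphate at high, progressive dehydration, roughly 16 / 3 / 5 / 2
lipids per adsorbed ion — as generator parameters with known ground
truth. Analysis windows are 60 frames × 0.1 ns and the recovery suites
use tens of seeds at 128 lipids; these sizes keep every statistical
check comfortably resolved (standard errors well below the tested
effects) while the whole suite runs in well under a minute of CPU.

## Known limitations

* The RDF reference density (whole-box mean) makes g(r) magnitudes
  system-size dependent in inhomogeneous geometries; cutoffs and n(r)
  counts are unaffected.
* Leaflet assignment follows the sign of the recentred phosphate z;
  flip-flop is not modelled.
* The reconvolution model fits no channel-shift or background parameter;
  synthetic IRFs are aligned by construction, real instruments may need
  a shift term.
* Censored-interval exclusion biases mean residence low for windows
  shorter than a few dwell times; first-desorption times are reported
  alongside for that regime.
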