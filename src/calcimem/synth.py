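"""Synthetic bilayer trajectories with known ground truth.

This module replaces the MD engine: it emits two-leaflet head-group
"skeleton" bilayers (no acyl chains — no analysis in scope touches them)
whose structural and binding statistics are known by construction, so every
downstream observable can be checked as a parameter-recovery problem.

The generated architecture:

* lipids on a jittered square lattice per leaflet at a scheduled area per
  lipid (constant or linear ramp), 64 per leaflet by default;
* each lipid carries a phosphate P, a choline N displaced along a sampled
  P→N tilt direction (angle measured against the outward leaflet normal),
  and an sn-2 carbonyl O at its own z-level; PS lipids add a two-oxygen
  carboxylate;
* each Ca²⁺ follows a two-state (bound/free) Markov chain with a given
  mean residence time; when bound it sits at a fixed distance from a
  sampled binding-site atom (phosphate / carbonyl / carboxylate with
  prescribed stationary occupancies), when free it is uniform in the water
  slab;
* bulk waters fill the slab, kept clear of the head-group region so that
  prescribed first-shell placements are the only waters inside the
  hydration cutoffs;
* independent Gaussian positional noise of width sigma on every atom.

Identical (spec, seed) inputs produce bit-identical trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .binding import DEFAULT_HYDRATION_CUTOFFS
from .io import GroupTag, Topology, Trajectory

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "expected_statistics"]

_MASSES = {"P": 30.974, "N": 14.007, "O": 15.999, "Ca": 40.078, "Cl": 35.453}


class GenerationError(ValueError):
    """The requested geometry cannot be built without atom overlap."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic bilayer.

    Defaults mirror the simulated study systems: 64 lipids per leaflet,
    optional 12 PS per leaflet (the 4:1 PC:PS mixture), head-group z-levels
    ordered carbonyl < phosphate < choline as in measured density profiles,
    and 0.1 ns frame spacing.
    """

    lipids_per_leaflet: int = 64
    ps_per_leaflet: int = 0  # 12 for the 4:1 PC:PS system
    apl_start: float = 0.64  # nm^2
    apl_end: float | None = None  # linear ramp end; None = constant
    # mean |z| of each group relative to the bilayer midplane, nm
    z_phosphate: float = 2.0
    z_choline: float = 2.1
    z_carbonyl: float = 1.5
    z_coo: float = 2.15
    pn_distance: float = 0.45  # |P->N|, nm
    tilt_mean_deg: float | None = 80.0  # None -> isotropic orientations
    tilt_conc: float = 25.0  # concentration kappa; sd = 1/sqrt(kappa) rad
    sigma: float = 0.03  # positional noise, nm
    n_ca: int = 0
    p_phos: float = 0.0  # stationary occupancy of phosphate sites per ion
    p_carb: float = 0.0
    p_coo: float = 0.0
    bound_distance: float = 0.25  # ion-site distance when bound, nm
    mean_residence: float = 10.0  # ns; mean bound-state dwell
    n_cl: int = 0
    waters_per_lipid: int = 8
    shell_waters_carbonyl: int = 0  # first-shell waters placed per lipid
    shell_waters_phosphate: int = 0
    shell_distance_carbonyl: float = 0.20  # nm, inside the 0.24 nm cutoff
    shell_distance_phosphate: float = 0.30  # nm, inside the 0.335 nm cutoff
    free_margin: float = 0.55  # water slab clearance above head groups, nm
    n_frames: int = 50
    frame_spacing: float = 0.1  # ns
    box_z: float = 7.0  # nm
    z_drift: float = 0.0  # optional per-frame whole-system z shift amplitude

    def __post_init__(self) -> None:
        if self.ps_per_leaflet > self.lipids_per_leaflet:
            raise ValueError("ps_per_leaflet exceeds lipids_per_leaflet")
        if min(self.p_phos, self.p_carb, self.p_coo) < 0:
            raise ValueError("occupancies must be non-negative")
        if self.p_bound > 1:
            raise ValueError("site occupancies must sum to at most 1 per ion")
        if self.p_coo > 0 and self.ps_per_leaflet == 0:
            raise ValueError("carboxylate occupancy requires PS lipids")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        for name in ("lipids_per_leaflet", "n_ca", "n_cl", "waters_per_lipid", "n_frames"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def p_bound(self) -> float:
        return self.p_phos + self.p_carb + self.p_coo

    @property
    def n_lipids(self) -> int:
        return 2 * self.lipids_per_leaflet

    @property
    def n_ps(self) -> int:
        return 2 * self.ps_per_leaflet

    def apl_schedule(self) -> np.ndarray:
        if self.apl_end is None or self.n_frames < 2:
            return np.full(max(self.n_frames, 1), self.apl_start)
        return np.linspace(self.apl_start, self.apl_end, self.n_frames)


@dataclass
class GroundTruth:
    """Exact expected statistics implied by a spec (and, where stochastic,
    the realised per-seed state sequences)."""

    apl_per_frame: np.ndarray
    thickness: float
    mean_pn_angle_deg: float
    expected_n1: dict[str, float]  # ions per group instance, first shell
    expected_adsorbed: float  # mean simultaneously bound ions
    lipids_per_adsorbed_ion: float
    hydration: dict[str, float]  # waters per lipid within the cutoffs
    expected_residence_ns: float  # mean bound-interval length, ns
    bound_states: np.ndarray | None = None  # (n_ca, n_frames) bool, realised
    site_types: np.ndarray | None = None  # per-run site type codes

    def to_json(self, path: str | Path) -> None:
        d = {
            "apl_per_frame": self.apl_per_frame.tolist(),
            "thickness": self.thickness,
            "mean_pn_angle_deg": self.mean_pn_angle_deg,
            "expected_n1": self.expected_n1,
            "expected_adsorbed": self.expected_adsorbed,
            "lipids_per_adsorbed_ion": self.lipids_per_adsorbed_ion,
            "hydration": self.hydration,
            "expected_residence_ns": self.expected_residence_ns,
        }
        if self.bound_states is not None:
            d["bound_states"] = self.bound_states.astype(int).tolist()
        Path(path).write_text(json.dumps(d, indent=1))


def _shell_retention(r0: float, cutoff: float, sigma: float) -> float:
    """P(|x| <= cutoff) for x ~ N(mu, s^2 I3) with |mu| = r0 and
    s = sqrt(2) sigma (both the marker water and its anchor atom jitter).

    Closed form for the radial CDF of an offset isotropic Gaussian.
    """
    if sigma <= 0:
        return 1.0 if r0 <= cutoff else 0.0
    s = np.sqrt(2.0) * sigma
    from scipy.stats import norm

    a, b = (cutoff - r0) / s, (-cutoff - r0) / s
    gauss_term = (s / (r0 * np.sqrt(2 * np.pi))) * (
        np.exp(-((cutoff + r0) ** 2) / (2 * s**2))
        - np.exp(-((cutoff - r0) ** 2) / (2 * s**2))
    )
    return float(norm.cdf(a) - norm.cdf(b) + gauss_term)


def expected_statistics(spec: SyntheticSpec) -> GroundTruth:
    """Closed-form expectations implied by the spec alone (no realisation)."""
    n_lip = spec.n_lipids
    if spec.tilt_mean_deg is None:
        mean_angle = 90.0  # isotropic: <angle to fixed axis> = 90 deg by symmetry
    else:
        mean_angle = float(spec.tilt_mean_deg)
    p_b = spec.p_bound
    exp_ads = spec.n_ca * p_b
    dt = spec.frame_spacing
    _, b = _chain_rates(spec)
    # geometric dwell: mean interval = dt / (per-frame unbind probability)
    exp_res = dt / b if b > 0 else float("inf")
    if p_b <= 0:
        exp_res = 0.0
    n1 = {
        "PHOS_P": spec.n_ca * spec.p_phos / n_lip if n_lip else 0.0,
        "CARBONYL_O_SN2": spec.n_ca * spec.p_carb / n_lip if n_lip else 0.0,
        "COO_PS": spec.n_ca * spec.p_coo / spec.n_ps if spec.n_ps else 0.0,
    }
    return GroundTruth(
        apl_per_frame=spec.apl_schedule(),
        thickness=2.0 * spec.z_phosphate,
        mean_pn_angle_deg=mean_angle,
        expected_n1=n1,
        expected_adsorbed=exp_ads,
        lipids_per_adsorbed_ion=(n_lip / exp_ads) if exp_ads > 0 else float("inf"),
        hydration={
            # placement count times the probability that positional noise
            # keeps a marker water inside the analysis cutoff
            "CARBONYL_O_SN2": spec.shell_waters_carbonyl
            * _shell_retention(
                spec.shell_distance_carbonyl,
                DEFAULT_HYDRATION_CUTOFFS[GroupTag.CARBONYL_O_SN2],
                spec.sigma,
            ),
            "PHOS_P": spec.shell_waters_phosphate
            * _shell_retention(
                spec.shell_distance_phosphate,
                DEFAULT_HYDRATION_CUTOFFS[GroupTag.PHOS_P],
                spec.sigma,
            ),
        },
        expected_residence_ns=exp_res,
    )


def _build_topology(spec: SyntheticSpec) -> tuple[Topology, dict]:
    """Atom bookkeeping: lipids (upper leaflet then lower; PS first within
    each leaflet), then Ca, Cl, waters.  Returns the topology and an index
    layout dict."""
    names, resnames, resids, elements, tags, masses = [], [], [], [], [], []
    resid = 0
    site_atoms: dict[str, list[int]] = {"PHOS_P": [], "CARBONYL_O_SN2": [], "COO_PS": []}
    lipid_of_atom: list[int] = []

    def add(name: str, rn: str, el: str, tag: GroupTag, lipid: int = -1) -> int:
        names.append(name)
        resnames.append(rn)
        resids.append(resid)
        elements.append(el)
        tags.append(tag)
        masses.append(_MASSES[el])
        lipid_of_atom.append(lipid)
        return len(names) - 1

    lipid_idx = 0
    for _leaflet in range(2):
        for j in range(spec.lipids_per_leaflet):
            resid += 1
            is_ps = j < spec.ps_per_leaflet
            rn = "POPS" if is_ps else "POPC"
            site_atoms["PHOS_P"].append(add("P", rn, "P", GroupTag.PHOS_P, lipid_idx))
            add("N", rn, "N", GroupTag.CHOL_N, lipid_idx)
            site_atoms["CARBONYL_O_SN2"].append(
                add("OS2", rn, "O", GroupTag.CARBONYL_O_SN2, lipid_idx)
            )
            if is_ps:
                # carboxylate: two oxygens, counted once per group downstream
                site_atoms["COO_PS"].append(add("OC1", rn, "O", GroupTag.COO_PS, lipid_idx))
                add("OC2", rn, "O", GroupTag.COO_PS, lipid_idx)
            lipid_idx += 1
    for _ in range(spec.n_ca):
        resid += 1
        add("CA", "CA", "Ca", GroupTag.CA)
    for _ in range(spec.n_cl):
        resid += 1
        add("CL", "CL", "Cl", GroupTag.CL)
    n_shell = spec.n_lipids * (spec.shell_waters_carbonyl + spec.shell_waters_phosphate)
    n_bulk = spec.waters_per_lipid * spec.n_lipids
    for _ in range(n_shell + n_bulk):
        resid += 1
        add("OW", "SOL", "O", GroupTag.WATER_O)
    topo = Topology(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        elements=np.array(elements, dtype=object),
        tags=np.array(tags, dtype=object),
        masses=np.array(masses, dtype=float),
    )
    layout = {
        "site_atoms": {k: np.array(v, dtype=int) for k, v in site_atoms.items()},
        "lipid_of_atom": np.array(lipid_of_atom, dtype=int),
        "n_shell": n_shell,
        "n_bulk": n_bulk,
    }
    return topo, layout


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _cone_vector(rng: np.random.Generator, z_sign: float, half_angle_deg: float = 25.0) -> np.ndarray:
    """Unit vector within a cone about +/-z."""
    theta = np.deg2rad(half_angle_deg) * np.sqrt(rng.random())
    phi = rng.uniform(0, 2 * np.pi)
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), z_sign * np.cos(theta)]
    )


def _sample_tilt(
    rng: np.random.Generator, spec: SyntheticSpec, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (theta, phi): tilt angle from the outward normal and azimuth."""
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if spec.tilt_mean_deg is None:
        # isotropic on the sphere: cos(theta) uniform
        theta = np.arccos(rng.uniform(-1.0, 1.0, size=n))
    else:
        sd = 1.0 / np.sqrt(spec.tilt_conc) if spec.tilt_conc > 0 else 0.0
        theta = np.deg2rad(spec.tilt_mean_deg) + sd * rng.normal(size=n)
        theta = np.abs(theta)  # reflect at 0
        theta = np.where(theta > np.pi, 2 * np.pi - theta, theta)
    return theta, phi


def _chain_rates(spec: SyntheticSpec) -> tuple[float, float]:
    """Per-frame (bind, unbind) probabilities of the two-state chain.

    The unbind probability follows the exact exponential discretisation
    b = 1 - exp(-dt/tau_res); the bind probability a = b p/(1-p) pins the
    stationary occupancy p.  When that would require a > 1 (occupancy too
    high for the requested dwell at this frame spacing) the occupancy is
    kept — it is the generator's contract for recovery tests — and the
    dwell is lengthened instead (a = 1, b = (1-p)/p).
    """
    p_b = spec.p_bound
    if p_b <= 0:
        return 0.0, 1.0
    if p_b >= 1.0:
        return 1.0, 0.0
    if spec.mean_residence > 0 and spec.frame_spacing > 0:
        b = 1.0 - np.exp(-spec.frame_spacing / spec.mean_residence)
    else:
        b = 1.0
    a = b * p_b / (1.0 - p_b)
    if a > 1.0:
        a = 1.0
        b = (1.0 - p_b) / p_b
    return a, b


def _simulate_binding(
    rng: np.random.Generator, spec: SyntheticSpec, layout: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-ion two-state Markov chains plus per-run site assignments.

    Returns (bound (n_ca, F) bool, site_atom (n_ca, F) int, site_type codes,
    bound_dir unit vectors (n_ca, F, 3) for the ion placement)."""
    F = spec.n_frames
    n = spec.n_ca
    bound = np.zeros((n, F), dtype=bool)
    site_atom = np.full((n, F), -1, dtype=int)
    site_type = np.full((n, F), -1, dtype=int)  # 0 phos, 1 carb, 2 coo
    p_b = spec.p_bound
    a, b = _chain_rates(spec)
    types = ["PHOS_P", "CARBONYL_O_SN2", "COO_PS"]
    probs = np.array([spec.p_phos, spec.p_carb, spec.p_coo])
    probs = probs / probs.sum() if probs.sum() > 0 else probs
    site_pools = [layout["site_atoms"][t] for t in types]

    def new_site(ion: int, t0: int) -> None:
        k = rng.choice(3, p=probs)
        pool = site_pools[k]
        site = pool[rng.integers(len(pool))]
        site_atom[ion, t0] = site
        site_type[ion, t0] = k

    for ion in range(n):
        state = rng.random() < p_b
        bound[ion, 0] = state
        if state:
            new_site(ion, 0)
        for t in range(1, F):
            if bound[ion, t - 1]:
                if rng.random() < b:
                    state = False
                else:
                    state = True
            else:
                state = rng.random() < a
            bound[ion, t] = state
            if state:
                if bound[ion, t - 1]:
                    site_atom[ion, t] = site_atom[ion, t - 1]
                    site_type[ion, t] = site_type[ion, t - 1]
                else:
                    new_site(ion, t)
    bound_dir = _unit_vectors(rng, n).reshape(n, 1, 3).repeat(F, axis=1)
    return bound, site_atom, site_type, bound_dir


def generate(spec: SyntheticSpec, seed: int) -> tuple[Trajectory, GroundTruth]:
    """Build the synthetic trajectory and its ground truth.

    Raises :class:`GenerationError` when the scheduled area per lipid would
    force head-group atoms of neighbouring lipids closer than 0.08 nm.
    """
    rng = np.random.default_rng(seed)
    topo, layout = _build_topology(spec)
    apl = spec.apl_schedule()
    F = spec.n_frames
    n_pl = spec.lipids_per_leaflet
    z0 = spec.box_z / 2.0

    # lattice geometry guard: nearest-neighbour spacing sqrt(apl) minus
    # jitter must clear the 0.08 nm overlap floor
    spacing = np.sqrt(apl.min())
    if spacing * (1 - 2 * 0.15) < 0.08:
        raise GenerationError(
            f"area per lipid {apl.min():.4f} nm² packs lipids closer than the "
            "0.08 nm overlap floor"
        )
    head_top = max(
        spec.z_phosphate + spec.pn_distance, spec.z_choline, spec.z_coo
    )
    slab_lo = z0 + head_top + spec.free_margin
    slab_hi = spec.box_z - 0.05
    if slab_hi - slab_lo < 0.1 and (layout["n_bulk"] > 0 or spec.n_ca or spec.n_cl):
        raise GenerationError(
            "water slab too thin: increase box_z or reduce head-group extent"
        )

    m = int(np.ceil(np.sqrt(n_pl)))
    cells = np.array([(i, j) for i in range(m) for j in range(m)][:n_pl], dtype=float)
    # per-lipid lattice jitter in fractional cell units, fixed for the run
    jitter = rng.uniform(-0.15, 0.15, size=(2, n_pl, 2))

    bound, site_atom, site_type, bound_dir = _simulate_binding(rng, spec, layout)

    n_atoms = topo.n_atoms
    positions = np.empty((F, n_atoms, 3))
    boxes = np.empty((F, 3))
    times = np.arange(F) * spec.frame_spacing
    drifts = (
        rng.uniform(-spec.z_drift, spec.z_drift, size=F) if spec.z_drift > 0 else np.zeros(F)
    )

    idx = 0  # rebuild the same atom order as _build_topology
    # precompute atom index table per lipid
    lipid_atoms: list[dict[str, int | list[int]]] = []
    i = 0
    for leaflet in range(2):
        for j in range(n_pl):
            is_ps = j < spec.ps_per_leaflet
            entry: dict = {"P": i, "N": i + 1, "OS2": i + 2}
            i += 3
            if is_ps:
                entry["COO"] = [i, i + 1]
                i += 2
            entry["leaflet"] = 1 if leaflet == 0 else -1
            lipid_atoms.append(entry)
    ca_start = i
    cl_start = ca_start + spec.n_ca
    wat_start = cl_start + spec.n_cl
    shell_start = wat_start
    bulk_start = wat_start + layout["n_shell"]

    for f in range(F):
        L = np.sqrt(n_pl * apl[f])
        box = np.array([L, L, spec.box_z])
        boxes[f] = box
        s = L / m
        pos = np.empty((n_atoms, 3))
        theta, phi = _sample_tilt(rng, spec, spec.n_lipids)
        lat = {}
        for leaflet_i, sgn in enumerate((1, -1)):
            xy = (cells + 0.5 + jitter[leaflet_i]) * s
            lat[sgn] = xy
        k = 0
        shell_cursor = shell_start
        for li, entry in enumerate(lipid_atoms):
            sgn = entry["leaflet"]
            leaflet_i = 0 if sgn == 1 else 1
            j = li % n_pl
            x, y = lat[sgn][j]
            zP = z0 + sgn * spec.z_phosphate
            pos[entry["P"]] = (x, y, zP)
            th, ph = theta[li], phi[li]
            d = spec.pn_distance * np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), sgn * np.cos(th)]
            )
            pos[entry["N"]] = pos[entry["P"]] + d
            pos[entry["OS2"]] = (x, y, z0 + sgn * spec.z_carbonyl)
            if "COO" in entry:
                zc = z0 + sgn * spec.z_coo
                pos[entry["COO"][0]] = (x - 0.11, y, zc)
                pos[entry["COO"][1]] = (x + 0.11, y, zc)
            k += 1
        # shell waters at a fixed distance from their group atom, inside a
        # 25-degree cone about the membrane normal: carbonyl shells face
        # the midplane, phosphate shells the water phase.  The cone bounds
        # the lateral reach so a marker water can never stray into the
        # shell of a neighbouring lipid (or of the other group), keeping
        # the ground-truth hydration counts exact by construction.
        for entry in lipid_atoms:
            sgn = entry["leaflet"]
            for _ in range(spec.shell_waters_carbonyl):
                u = _cone_vector(rng, -sgn)
                pos[shell_cursor] = pos[entry["OS2"]] + spec.shell_distance_carbonyl * u
                shell_cursor += 1
            for _ in range(spec.shell_waters_phosphate):
                u = _cone_vector(rng, sgn)
                pos[shell_cursor] = pos[entry["P"]] + spec.shell_distance_phosphate * u
                shell_cursor += 1
        # ions
        for ion in range(spec.n_ca):
            ai = ca_start + ion
            if bound[ion, f]:
                site = site_atom[ion, f]
                pos[ai] = pos[site] + spec.bound_distance * bound_dir[ion, f]
            else:
                pos[ai] = _uniform_slab(rng, box, slab_lo, slab_hi, z0)
        for ci in range(spec.n_cl):
            pos[cl_start + ci] = _uniform_slab(rng, box, slab_lo, slab_hi, z0)
        # bulk waters, uniform in both slabs
        nb = layout["n_bulk"]
        if nb:
            pos[bulk_start : bulk_start + nb] = np.stack(
                [_uniform_slab(rng, box, slab_lo, slab_hi, z0) for _ in range(nb)]
            )
        if spec.sigma > 0:
            pos = pos + rng.normal(scale=spec.sigma, size=pos.shape)
        # molecules are kept whole (no wrapping): every analysis applies the
        # minimum-image convention itself, and wrapping would split P-N pairs
        pos[:, 2] = pos[:, 2] + drifts[f]
        positions[f] = pos

    truth = expected_statistics(spec)
    truth.bound_states = bound
    truth.site_types = site_type
    traj = Trajectory(topo, positions, boxes, np.asarray(times, dtype=float))
    return traj, truth


def _uniform_slab(
    rng: np.random.Generator, box: np.ndarray, slab_lo: float, slab_hi: float, z0: float
) -> np.ndarray:
    """Uniform point in one of the two water slabs (mirror-symmetric)."""
    x = rng.uniform(0, box[0])
    y = rng.uniform(0, box[1])
    z = rng.uniform(slab_lo, slab_hi)
    if rng.random() < 0.5:
        z = 2 * z0 - z  # mirror into the lower slab
    return np.array([x, y, z])
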