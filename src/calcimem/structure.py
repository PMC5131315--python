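"""Structural observables of the bilayer.

Area per lipid with block-analysis errors, number-density profiles along
the membrane normal, bilayer thickness as the phosphate-phosphate distance
between density-profile peaks, and the P-N head-group angle distribution.

Each frame is recentred so the lipid centre of mass sits at z = 0 before
z-binning; leaflets are assigned by the sign of the phosphate z coordinate
after recentring.  The head-group angle is measured against the *outward*
leaflet normal, so a mean below 90 deg means head groups point toward the
water phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GroupTag, LIPID_TAGS, StructureError, Trajectory

__all__ = [
    "ScalarSeries",
    "BlockStats",
    "DensityProfile",
    "AngleDistribution",
    "ThicknessResult",
    "area_per_lipid",
    "block_average",
    "density_profile",
    "bilayer_thickness",
    "pn_angle_distribution",
]


class AnalysisError(ValueError):
    """The requested observable is undefined for this input."""


@dataclass
class ScalarSeries:
    values: np.ndarray
    times: np.ndarray  # ns

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise StructureError("values and times must have equal length")


@dataclass
class BlockStats:
    mean: float
    se: float
    n_blocks: int
    block_means: np.ndarray


@dataclass
class DensityProfile:
    bin_centers: np.ndarray  # nm, distance from bilayer centre
    density: np.ndarray  # nm^-3 (number) or amu nm^-3 (mass)
    bin_width: float
    symmetrized: bool
    n_frames: int


@dataclass
class AngleDistribution:
    angle_grid: np.ndarray  # degrees, bin centres on [0, 180]
    density: np.ndarray  # per degree, integrates to 1
    mean: float  # degrees
    n_samples: int


@dataclass
class ThicknessResult:
    thickness: float  # nm
    uncertainty: float  # nm, one bin width
    z_upper: float
    z_lower: float

    def __float__(self) -> float:
        return self.thickness


def area_per_lipid(traj: Trajectory, lipids_per_leaflet: int) -> ScalarSeries:
    """APL(t) = Lx * Ly / lipids_per_leaflet for every frame."""
    if lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be positive")
    if np.any(traj.boxes[:, :2] <= 0):
        raise ValueError("box has a zero lateral dimension")
    apl = traj.boxes[:, 0] * traj.boxes[:, 1] / lipids_per_leaflet
    return ScalarSeries(values=apl, times=traj.times)


def block_average(series: ScalarSeries | np.ndarray, n_blocks: int = 5) -> BlockStats:
    """Block analysis of a correlated time series.

    The series is split into ``n_blocks`` contiguous equal-length blocks
    (any remainder is dropped from the front) and the standard error of the
    mean is estimated as stdev(block means)/sqrt(n_blocks), which remains
    valid when successive frames are correlated, unlike the naive
    per-frame estimate.
    """
    values = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(values) < n_blocks:
        raise ValueError(f"series of length {len(values)} cannot fill {n_blocks} blocks")
    drop = len(values) % n_blocks
    blocks = values[drop:].reshape(n_blocks, -1)
    bm = blocks.mean(axis=1)
    se = float(np.std(bm, ddof=1) / np.sqrt(n_blocks))
    return BlockStats(mean=float(bm.mean()), se=se, n_blocks=n_blocks, block_means=bm)


def _lipid_indices(traj: Trajectory) -> np.ndarray:
    idx = np.flatnonzero(np.array([t in LIPID_TAGS for t in traj.topology.tags]))
    if len(idx) == 0:
        raise AnalysisError("no lipid-tagged atoms; apply a group map first")
    return idx


def _recentered_z(traj: Trajectory, f: int, lipid_idx: np.ndarray) -> np.ndarray:
    """z coordinates with the lipid centre of mass shifted to 0, wrapped
    into [-Lz/2, Lz/2)."""
    Lz = traj.boxes[f, 2]
    masses = traj.topology.masses
    w = masses[lipid_idx] if masses is not None else np.ones(len(lipid_idx))
    zl = traj.positions[f, lipid_idx, 2]
    # iterative minimum-image refinement: find the centre about which the
    # mass-weighted mean min-image displacement of lipid atoms vanishes,
    # so a bilayer straddling the periodic z boundary is handled
    com = np.average(zl % Lz, weights=w)
    for _ in range(8):
        disp = (zl - com + Lz / 2) % Lz - Lz / 2
        shift = np.average(disp, weights=w)
        com += shift
        if abs(shift) < 1e-10:
            break
    # a two-slab distribution has two fixed points (midplane and mid-water);
    # carbonyls sit interior to phosphates only about the true midplane
    tags = traj.topology.tags
    carb = np.flatnonzero(
        np.array([t in (GroupTag.CARBONYL_O_SN1, GroupTag.CARBONYL_O_SN2) for t in tags])
    )
    phos = np.flatnonzero(np.array([t is GroupTag.PHOS_P for t in tags]))
    if len(carb) and len(phos):
        def mean_abs(idx: np.ndarray, c: float) -> float:
            d = (traj.positions[f, idx, 2] - c + Lz / 2) % Lz - Lz / 2
            return float(np.abs(d).mean())

        if mean_abs(carb, com) > mean_abs(phos, com):
            com += Lz / 2
    z = traj.positions[f, :, 2] - com
    return (z + Lz / 2) % Lz - Lz / 2


def density_profile(
    traj: Trajectory,
    selection: np.ndarray,
    bin_width: float = 0.1,
    symmetrize: bool = False,
    mass_weighted: bool = False,
) -> DensityProfile:
    """Number (or mass) density of the selected atoms vs distance from the
    bilayer centre, averaged over frames.

    Each frame contributes counts/(Lx*Ly*dz); the integral of the
    unsymmetrised profile times the lateral box area therefore recovers the
    selection size exactly for a constant box.  With ``symmetrize`` the
    profile is averaged with its z -> -z mirror (leaflet averaging).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    selection = np.asarray(selection, dtype=int)
    lipid_idx = _lipid_indices(traj)
    half = float(traj.boxes[:, 2].max()) / 2.0
    n_bins = max(int(np.ceil(2 * half / bin_width)), 1)
    edges = -half + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = np.zeros(n_bins)
    weights = None
    if mass_weighted:
        if traj.topology.masses is None:
            raise AnalysisError("mass-weighted profile requires topology masses")
        weights = traj.topology.masses[selection]
    for f in range(traj.n_frames):
        z = _recentered_z(traj, f, lipid_idx)[selection]
        area = traj.boxes[f, 0] * traj.boxes[f, 1]
        hist, _ = np.histogram(z, bins=edges, weights=weights)
        acc += hist / (area * bin_width)
    dens = acc / traj.n_frames
    if symmetrize:
        dens = 0.5 * (dens + dens[::-1])
    return DensityProfile(
        bin_centers=centers,
        density=dens,
        bin_width=bin_width,
        symmetrized=symmetrize,
        n_frames=traj.n_frames,
    )


def _refine_peak(centers: np.ndarray, density: np.ndarray) -> float:
    """Peak position by 3-point parabolic interpolation around the maximal
    bin; raises when the maximum sits on the grid boundary (monotone
    profile, no interior peak)."""
    i = int(np.argmax(density))
    if i == 0 or i == len(density) - 1:
        raise AnalysisError("density profile has no interior peak")
    y0, y1, y2 = density[i - 1], density[i], density[i + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    dz = centers[1] - centers[0]
    return float(centers[i] + offset * dz)


def bilayer_thickness(profile: DensityProfile) -> ThicknessResult:
    """Phosphate-phosphate distance between the per-leaflet density peaks.

    Each leaflet's peak is refined by parabolic interpolation; the quoted
    uncertainty is one bin width, reflecting the peak-location resolution.
    """
    pos = profile.bin_centers > 0
    neg = profile.bin_centers < 0
    if profile.density[pos].max(initial=0) <= 0 or profile.density[neg].max(initial=0) <= 0:
        raise AnalysisError("profile lacks a peak in one leaflet")
    z_up = _refine_peak(profile.bin_centers[pos], profile.density[pos])
    z_dn = _refine_peak(profile.bin_centers[neg], profile.density[neg])
    return ThicknessResult(
        thickness=abs(z_up - z_dn),
        uncertainty=profile.bin_width,
        z_upper=z_up,
        z_lower=z_dn,
    )


def _pn_pairs(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-lipid (P atom, N atom) index pairs, matched by residue id."""
    topo = traj.topology
    p_idx = topo.indices_with_tag(GroupTag.PHOS_P)
    n_idx = topo.indices_with_tag(GroupTag.CHOL_N)
    n_by_res = {int(topo.resids[i]): i for i in n_idx}
    pairs_p, pairs_n = [], []
    for i in p_idx:
        res = int(topo.resids[i])
        if res not in n_by_res:
            raise StructureError(f"lipid residue {res} has a P but no N atom")
        pairs_p.append(i)
        pairs_n.append(n_by_res[res])
    if not pairs_p:
        raise StructureError("no P-N pairs in topology")
    return np.array(pairs_p), np.array(pairs_n)


def pn_angle_distribution(
    traj: Trajectory, bin_width_deg: float = 2.0
) -> AngleDistribution:
    """Distribution of the angle between each lipid's P->N vector and the
    outward leaflet normal, pooled over lipids and frames.

    The outward normal is +z for the upper leaflet and -z for the lower
    (leaflets assigned by the sign of the recentred phosphate z), so an
    angle below 90 deg means the head group points toward water.
    """
    p_idx, n_idx = _pn_pairs(traj)
    lipid_idx = _lipid_indices(traj)
    angles = []
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        d = traj.positions[f, n_idx] - traj.positions[f, p_idx]
        d -= box * np.round(d / box)  # same molecule, but guard PBC splits
        z = _recentered_z(traj, f, lipid_idx)
        sgn = np.sign(z[p_idx])
        sgn[sgn == 0] = 1.0
        cosphi = sgn * d[:, 2] / np.linalg.norm(d, axis=1)
        angles.append(np.degrees(np.arccos(np.clip(cosphi, -1.0, 1.0))))
    samples = np.concatenate(angles)
    n_bins = int(round(180.0 / bin_width_deg))
    hist, edges = np.histogram(samples, bins=n_bins, range=(0.0, 180.0))
    density = hist / (len(samples) * bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngleDistribution(
        angle_grid=centers,
        density=density,
        mean=float(samples.mean()),
        n_samples=len(samples),
    )
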