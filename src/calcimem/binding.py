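"""Ion-binding statistics: RDFs, coordination numbers, contacts,
adsorption ratios, hydration and residence times.

All pair distances use the minimum-image convention in an orthorhombic
box.  Chemical groups may span several atoms (the PS carboxylate counts
both oxygens); an ion within the cutoff of *any* atom of a group counts
once for that group.

Conventions, recorded with every result:

* first coordination number n1 of a group type = mean number of ions
  inside the first-shell cutoff of a group instance, averaged over frames
  and instances;
* an ion is *adsorbed* in a frame iff at least one lipid head-group atom
  lies within the contact cutoff (0.42 nm by default);
* "lipids per adsorbed ion" = total lipid count / time-averaged adsorbed
  count;
* hydration number of a lipid group = waters whose oxygen lies within the
  group-specific cutoff of any group atom of that lipid, counted once per
  lipid-group, averaged over lipids and frames (SD reported alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GroupTag, LIPID_TAGS, Topology, Trajectory

__all__ = [
    "RDFResult",
    "CutoffResult",
    "CoordinationReport",
    "ResidenceResult",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_HYDRATION_CUTOFFS",
    "min_image_distances",
    "rdf",
    "first_shell_cutoff",
    "group_atom_sets",
    "coordination_per_group",
    "adsorbed_ions",
    "adsorption_timeline",
    "coordination_of_adsorbed",
    "hydration_numbers",
    "contact_timeline",
    "residence_times",
]

#: Ion-lipid contact cutoff used for the adsorption criterion, nm.
DEFAULT_CONTACT_CUTOFF = 0.42

#: First-shell water cutoffs from the water-group RDFs, nm.
DEFAULT_HYDRATION_CUTOFFS = {
    GroupTag.CARBONYL_O_SN2: 0.24,
    GroupTag.PHOS_P: 0.335,
}


class AnalysisError(ValueError):
    pass


def min_image_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances in an
    orthorhombic box."""
    delta = pos_a[:, None, :] - pos_b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=2))


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray  # bin centres, nm
    g: np.ndarray  # pair correlation, dimensionless
    n_cum: np.ndarray  # cumulative coordination per A atom
    reference_density: float  # mean number density of B over the box, nm^-3
    bin_width: float


def rdf(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    r_max: float,
    bin_width: float = 0.002,
) -> RDFResult:
    """Radial distribution function g(r) between two selections.

    g(r) is the pair-distance histogram normalised by the ideal-gas shell
    count 4*pi*r^2*dr*rho_B per A atom per frame; the cumulative
    coordination n(r) comes from direct pair counting, not from
    integrating g.  Self-pairs (shared indices) are excluded.
    """
    sel_a = np.asarray(sel_a, int)
    sel_b = np.asarray(sel_b, int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("selections must be non-empty")
    if r_max <= 0 or bin_width <= 0:
        raise ValueError("r_max and bin_width must be positive")
    if r_max > traj.boxes.min() / 2 + 1e-12:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge "
            f"({traj.boxes.min() / 2:.4f} nm); minimum-image distances are "
            "ambiguous beyond that"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    shared = np.intersect1d(sel_a, sel_b)
    rho_sum = 0.0
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        d = min_image_distances(traj.positions[f, sel_a], traj.positions[f, sel_b], box)
        if len(shared):
            for i, ai in enumerate(sel_a):
                j = np.searchsorted(sel_b, ai)
                if j < len(sel_b) and sel_b[j] == ai:
                    d[i, j] = np.inf
        hist, _ = np.histogram(d[d < r_max], bins=edges)
        counts += hist
        rho_sum += len(sel_b) / box.prod()
    rho = rho_sum / traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4 * np.pi * centers**2 * bin_width
    norm = traj.n_frames * len(sel_a) * rho * shell
    g = counts / norm
    n_cum = np.cumsum(counts) / (traj.n_frames * len(sel_a))
    return RDFResult(r=centers, g=g, n_cum=n_cum, reference_density=rho, bin_width=bin_width)


@dataclass
class CutoffResult:
    cutoff: float  # nm
    source: str  # "rdf" or "user"

    def __float__(self) -> float:
        return self.cutoff


def first_shell_cutoff(
    rdf_result: RDFResult, fallback: float | None = None
) -> CutoffResult:
    """First-shell cutoff: r at the first local minimum after the first
    maximum of g(r), after 3-bin moving-average smoothing.

    Falls back to a user-supplied cutoff (source "user") when g has no
    such minimum within the computed range.
    """
    g = rdf_result.g
    if len(g) >= 3:
        smooth = np.convolve(g, np.ones(3) / 3, mode="same")
    else:
        smooth = g
    # first local maximum with non-trivial amplitude
    peak = None
    for i in range(1, len(smooth) - 1):
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1] and smooth[i] > 1e-12:
            peak = i
            break
    if peak is not None:
        for i in range(peak + 1, len(smooth) - 1):
            if smooth[i] <= smooth[i - 1] and smooth[i] < smooth[i + 1]:
                return CutoffResult(cutoff=float(rdf_result.r[i]), source="rdf")
    if fallback is not None:
        return CutoffResult(cutoff=float(fallback), source="user")
    raise AnalysisError(
        "g(r) has no first-shell minimum in range and no fallback cutoff was given"
    )


# ---------------------------------------------------------------------------
# Coordination and contacts
# ---------------------------------------------------------------------------

def group_atom_sets(topology: Topology, tag: GroupTag) -> list[np.ndarray]:
    """Atom-index sets of each group instance of the given type.

    Atoms sharing a residue id form one group (both carboxylate oxygens of
    a PS lipid are a single group; a phosphate group is represented by its
    single P atom).
    """
    idx = topology.indices_with_tag(tag)
    if len(idx) == 0:
        return []
    groups: dict[int, list[int]] = {}
    for i in idx:
        groups.setdefault(int(topology.resids[i]), []).append(int(i))
    return [np.array(v, dtype=int) for _, v in sorted(groups.items())]


def _group_min_dist(
    pos: np.ndarray, groups: list[np.ndarray], ion_idx: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """(n_groups, n_ions) matrix of min distance from any group atom."""
    flat = np.concatenate(groups)
    d = min_image_distances(pos[flat], pos[ion_idx], box)
    out = np.empty((len(groups), len(ion_idx)))
    start = 0
    for gi, g in enumerate(groups):
        out[gi] = d[start : start + len(g)].min(axis=0)
        start += len(g)
    return out


def coordination_per_group(
    traj: Trajectory,
    groups: list[np.ndarray],
    ion_idx: np.ndarray,
    cutoff: float,
) -> tuple[float, np.ndarray]:
    """First coordination number n1 = mean ions within the cutoff of a
    group instance; also returns the per-frame series for block analysis.

    An ion near several atoms of one multi-atom group counts once for that
    group.
    """
    if len(groups) == 0 or len(ion_idx) == 0:
        raise ValueError("empty group or ion selection")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    per_frame = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = _group_min_dist(traj.positions[f], groups, np.asarray(ion_idx), traj.boxes[f])
        per_frame[f] = (d <= cutoff).sum() / len(groups)
    return float(per_frame.mean()), per_frame


def _lipid_head_atoms(topology: Topology) -> np.ndarray:
    idx = np.flatnonzero(np.array([t in LIPID_TAGS for t in topology.tags]))
    if len(idx) == 0:
        raise AnalysisError("no lipid-tagged atoms; apply a group map first")
    return idx


def adsorbed_ions(
    positions: np.ndarray,
    box: np.ndarray,
    ion_idx: np.ndarray,
    lipid_atom_idx: np.ndarray,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> np.ndarray:
    """Indices (into ion_idx) of ions with >= 1 lipid head-group atom
    within the contact cutoff in this frame."""
    d = min_image_distances(positions[np.asarray(ion_idx)], positions[lipid_atom_idx], box)
    return np.flatnonzero((d <= contact_cutoff).any(axis=1))


def adsorption_timeline(
    traj: Trajectory,
    ion_idx: np.ndarray,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    lipid_atom_idx: np.ndarray | None = None,
) -> np.ndarray:
    """(n_ions, n_frames) boolean adsorbed-state matrix."""
    ion_idx = np.asarray(ion_idx, int)
    if lipid_atom_idx is None:
        lipid_atom_idx = _lipid_head_atoms(traj.topology)
    tl = np.zeros((len(ion_idx), traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        ads = adsorbed_ions(traj.positions[f], traj.boxes[f], ion_idx, lipid_atom_idx, contact_cutoff)
        tl[ads, f] = True
    return tl


def lipids_per_adsorbed_ion(timeline: np.ndarray, n_lipids: int) -> float:
    """Total lipid count over the time-averaged adsorbed-ion count;
    infinity (with a warning) when no ion is ever adsorbed."""
    mean_ads = timeline.sum(axis=0).mean()
    if mean_ads == 0:
        warnings.warn("no adsorbed ions; lipids-per-ion ratio is undefined", UserWarning)
        return float("inf")
    return n_lipids / float(mean_ads)


def coordination_of_adsorbed(
    traj: Trajectory,
    ion_idx: np.ndarray,
    group_sets: dict[GroupTag, list[np.ndarray]],
    cutoffs: dict[GroupTag, float],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    lipid_atom_idx: np.ndarray | None = None,
) -> dict[GroupTag, tuple[float, float]]:
    """Per adsorbed ion, the mean (and SD) number of distinct groups of
    each type inside that type's cutoff; free ions are excluded from the
    average."""
    ion_idx = np.asarray(ion_idx, int)
    if lipid_atom_idx is None:
        lipid_atom_idx = _lipid_head_atoms(traj.topology)
    samples: dict[GroupTag, list[np.ndarray]] = {t: [] for t in group_sets}
    any_ads = False
    for f in range(traj.n_frames):
        pos, box = traj.positions[f], traj.boxes[f]
        ads = adsorbed_ions(pos, box, ion_idx, lipid_atom_idx, contact_cutoff)
        if len(ads) == 0:
            continue
        any_ads = True
        ads_atoms = ion_idx[ads]
        for tag, groups in group_sets.items():
            if not groups:
                continue
            d = _group_min_dist(pos, groups, ads_atoms, box)
            samples[tag].append((d <= cutoffs[tag]).sum(axis=0))
    if not any_ads:
        raise AnalysisError("no adsorbed ions in any frame; coordination undefined")
    out = {}
    for tag, chunks in samples.items():
        if not chunks:
            out[tag] = (float("nan"), float("nan"))
            continue
        allv = np.concatenate(chunks).astype(float)
        out[tag] = (float(allv.mean()), float(allv.std(ddof=0)))
    return out


def hydration_numbers(
    traj: Trajectory,
    cutoffs: dict[GroupTag, float] | None = None,
) -> dict[GroupTag, tuple[float, float]]:
    """Waters per lipid in the first shell of each lipid group.

    For every lipid and frame, waters whose oxygen lies within the
    group-specific cutoff of any of that lipid's group atoms are counted
    once per lipid-group.  Returns (mean, SD) over lipid-frame samples.
    """
    if cutoffs is None:
        cutoffs = dict(DEFAULT_HYDRATION_CUTOFFS)
    topo = traj.topology
    water_idx = topo.indices_with_tag(GroupTag.WATER_O)
    if len(water_idx) == 0:
        raise AnalysisError("no water oxygens tagged in the system")
    out = {}
    for tag, cutoff in cutoffs.items():
        groups = group_atom_sets(topo, tag)
        if not groups:
            out[tag] = (float("nan"), float("nan"))
            continue
        per_sample = []
        for f in range(traj.n_frames):
            d = _group_min_dist(traj.positions[f], groups, water_idx, traj.boxes[f])
            per_sample.append((d <= cutoff).sum(axis=1))
        allv = np.concatenate(per_sample).astype(float)
        out[tag] = (float(allv.mean()), float(allv.std(ddof=0)))
    return out


def contact_timeline(
    traj: Trajectory,
    ion_idx: np.ndarray,
    partner_idx: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    """(n_ions, n_frames) boolean: ion within cutoff of any partner atom."""
    ion_idx = np.asarray(ion_idx, int)
    partner_idx = np.asarray(partner_idx, int)
    tl = np.zeros((len(ion_idx), traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        d = min_image_distances(
            traj.positions[f, ion_idx], traj.positions[f, partner_idx], traj.boxes[f]
        )
        tl[:, f] = (d <= cutoff).any(axis=1)
    return tl


# ---------------------------------------------------------------------------
# Residence times
# ---------------------------------------------------------------------------

@dataclass
class ResidenceResult:
    intervals_ns: np.ndarray  # all bound-interval lengths
    mean_ns: float
    max_ns: float
    first_desorption_ns: np.ndarray  # per ion; nan if never desorbed
    gap_tolerance: int
    censored: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def _runs_with_gaps(states: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal bound runs [start, end] (inclusive), bridging unbound gaps
    of at most gap_tolerance frames."""
    bound_frames = np.flatnonzero(states)
    if len(bound_frames) == 0:
        return []
    runs = []
    start = prev = bound_frames[0]
    for fidx in bound_frames[1:]:
        if fidx - prev - 1 <= gap_tolerance:
            prev = fidx
        else:
            runs.append((start, prev))
            start = prev = fidx
    runs.append((start, prev))
    return runs


def residence_times(
    timeline: np.ndarray,
    frame_spacing: float,
    gap_tolerance: int = 0,
) -> ResidenceResult:
    """Bound-interval statistics from boolean per-ion timelines.

    An interval of k bound frames has length k * frame_spacing ns; unbound
    gaps up to ``gap_tolerance`` frames are bridged.  Intervals touching
    either trajectory end are flagged censored (their true length is
    unknown).  The first-desorption time of an ion is the time of the
    first unbound frame terminating its initial bound run (nan when never
    bound or never desorbed).
    """
    timeline = np.atleast_2d(np.asarray(timeline, bool))
    n_ions, n_frames = timeline.shape
    intervals, censored = [], []
    first_des = np.full(n_ions, np.nan)
    for ion in range(n_ions):
        runs = _runs_with_gaps(timeline[ion], gap_tolerance)
        for start, end in runs:
            intervals.append((end - start + 1) * frame_spacing)
            censored.append(start == 0 or end == n_frames - 1)
        if runs:
            _, e0 = runs[0]
            if e0 < n_frames - 1:
                first_des[ion] = (e0 + 1) * frame_spacing
    iv = np.array(intervals, dtype=float)
    return ResidenceResult(
        intervals_ns=iv,
        mean_ns=float(iv.mean()) if len(iv) else float("nan"),
        max_ns=float(iv.max()) if len(iv) else float("nan"),
        first_desorption_ns=first_des,
        gap_tolerance=gap_tolerance,
        censored=np.array(censored, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class CoordinationReport:
    """Everything the binding stage computes for one system, with the
    cutoffs recorded alongside every number."""

    n1: dict[str, float]
    n1_se: dict[str, float]
    per_adsorbed: dict[str, tuple[float, float]]  # mean, SD
    lipids_per_ion: float
    hydration: dict[str, tuple[float, float]]  # mean, SD
    cutoffs: dict[str, float]
    contact_cutoff: float

    def as_dict(self) -> dict:
        return {
            "n1": self.n1,
            "n1_se": self.n1_se,
            "per_adsorbed_mean": {k: v[0] for k, v in self.per_adsorbed.items()},
            "per_adsorbed_sd": {k: v[1] for k, v in self.per_adsorbed.items()},
            "lipids_per_adsorbed_ion": self.lipids_per_ion,
            "hydration_mean": {k: v[0] for k, v in self.hydration.items()},
            "hydration_sd": {k: v[1] for k, v in self.hydration.items()},
            "cutoffs_nm": self.cutoffs,
            "contact_cutoff_nm": self.contact_cutoff,
        }


def binding_report(
    traj: Trajectory,
    cutoffs: dict[GroupTag, float],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hydration_cutoffs: dict[GroupTag, float] | None = None,
    n_blocks: int = 5,
) -> CoordinationReport:
    """Run the full binding analysis of a tagged trajectory."""
    from .structure import block_average

    topo = traj.topology
    ion_idx = topo.indices_with_tag(GroupTag.CA)
    if len(ion_idx) == 0:
        raise AnalysisError("no Ca ions in the system")
    group_sets = {tag: group_atom_sets(topo, tag) for tag in cutoffs}
    n1, n1_se = {}, {}
    for tag, groups in group_sets.items():
        if not groups:
            n1[tag.value] = float("nan")
            n1_se[tag.value] = float("nan")
            continue
        mean, series = coordination_per_group(traj, groups, ion_idx, cutoffs[tag])
        n1[tag.value] = mean
        n1_se[tag.value] = (
            block_average(series, n_blocks).se if len(series) >= n_blocks else float("nan")
        )
    per_ads = coordination_of_adsorbed(traj, ion_idx, group_sets, cutoffs, contact_cutoff)
    tl = adsorption_timeline(traj, ion_idx, contact_cutoff)
    n_lipids = len(group_atom_sets(topo, GroupTag.PHOS_P))
    hyd = hydration_numbers(traj, hydration_cutoffs)
    return CoordinationReport(
        n1=n1,
        n1_se=n1_se,
        per_adsorbed={t.value: v for t, v in per_ads.items()},
        lipids_per_ion=lipids_per_adsorbed_ion(tl, n_lipids),
        hydration={t.value: v for t, v in hyd.items()},
        cutoffs={t.value: c for t, c in cutoffs.items()},
        contact_cutoff=contact_cutoff,
    )
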