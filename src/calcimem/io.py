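"""Trajectory and topology I/O.

Coordinates are stored in nanometres throughout; Ångström input is accepted
at the boundary via an explicit ``units`` flag.  Only orthorhombic boxes are
supported — every downstream analysis applies the minimum-image convention
dimension by dimension, which is only valid for rectangular cells.

Two plain-text carriers are supported:

* GRO (GROMACS fixed-column coordinate format, nm, 3-decimal positions),
  including concatenated multi-frame files;
* an XYZ dialect where the three box edge lengths are appended to the
  comment line (``t= <ns> <Lx> <Ly> <Lz>``), used as the simplest carrier
  for synthetic trajectories.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GroupTag",
    "Topology",
    "Frame",
    "Trajectory",
    "GroupMap",
    "read_gro",
    "write_gro",
    "read_xyz",
    "write_xyz",
    "apply_group_map",
    "select",
    "ParseError",
    "StructureError",
]


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class StructureError(ValueError):
    """Inputs are internally inconsistent (counts, pairing, box shape)."""


class GroupTag(enum.Enum):
    """Chemical-group labels attached to atoms.

    These are the groups the binding and structural analyses resolve:
    lipid phosphate phosphorus, choline nitrogen, the two ester-carbonyl
    oxygens, the PS carboxylate oxygens, water oxygen and the two ion
    species.  Everything else is OTHER.
    """

    PHOS_P = "PHOS_P"
    CHOL_N = "CHOL_N"
    CARBONYL_O_SN1 = "CARBONYL_O_SN1"
    CARBONYL_O_SN2 = "CARBONYL_O_SN2"
    COO_PS = "COO_PS"
    WATER_O = "WATER_O"
    CA = "CA"
    CL = "CL"
    OTHER = "OTHER"


#: Tags that belong to a lipid molecule (used for recentering and for
#: "lipid heavy atoms" in contact analysis).
LIPID_TAGS = frozenset(
    {
        GroupTag.PHOS_P,
        GroupTag.CHOL_N,
        GroupTag.CARBONYL_O_SN1,
        GroupTag.CARBONYL_O_SN2,
        GroupTag.COO_PS,
    }
)


@dataclass
class Topology:
    """Per-atom static attributes shared by all frames of a trajectory."""

    names: np.ndarray  # atom names, str
    resnames: np.ndarray  # residue names, str
    resids: np.ndarray  # 1-based residue indices, int
    elements: np.ndarray  # element symbols, str
    tags: np.ndarray  # GroupTag per atom (object dtype)
    charges: np.ndarray | None = None  # e
    masses: np.ndarray | None = None  # amu

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr_name in ("resnames", "resids", "elements", "tags"):
            if len(getattr(self, arr_name)) != n:
                raise StructureError(
                    f"topology field {arr_name!r} has length "
                    f"{len(getattr(self, arr_name))}, expected {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def tag_counts(self) -> dict[GroupTag, int]:
        """Number of atoms carrying each tag (zero-count tags included)."""
        counts = {tag: 0 for tag in GroupTag}
        for t in self.tags:
            counts[t] += 1
        return counts

    def indices_with_tag(self, tag: GroupTag) -> np.ndarray:
        return np.flatnonzero(np.array([t is tag for t in self.tags]))


@dataclass
class Frame:
    """One snapshot: positions (nm), orthorhombic box edges (nm), time (ns)."""

    positions: np.ndarray  # (n_atoms, 3)
    box: np.ndarray  # (3,)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,):
            raise StructureError("box must be three orthorhombic edge lengths")
        if np.any(self.box <= 0):
            raise StructureError("box edge lengths must be positive")


class Trajectory:
    """An ordered stack of frames over one topology.

    Positions are held as a single ``(n_frames, n_atoms, 3)`` array; times
    must be strictly increasing.
    """

    def __init__(
        self,
        topology: Topology,
        positions: np.ndarray,
        boxes: np.ndarray,
        times: np.ndarray,
    ):
        positions = np.asarray(positions, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        times = np.asarray(times, dtype=float)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise StructureError("positions must have shape (n_frames, n_atoms, 3)")
        if positions.shape[1] != topology.n_atoms:
            raise StructureError(
                f"trajectory has {positions.shape[1]} atoms per frame but the "
                f"topology defines {topology.n_atoms}"
            )
        if boxes.shape != (positions.shape[0], 3):
            raise StructureError("boxes must have shape (n_frames, 3)")
        if np.any(boxes <= 0):
            raise StructureError("box edge lengths must be positive")
        if len(times) != positions.shape[0]:
            raise StructureError("times must have one entry per frame")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise StructureError("frame times must be strictly increasing")
        self.topology = topology
        self.positions = positions
        self.boxes = boxes
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_spacing(self) -> float:
        """Mean inter-frame spacing in ns (0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 0.0
        return float(np.mean(np.diff(self.times)))

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.boxes[i], float(self.times[i]))

    def __iter__(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def slice_time(self, start: float | None = None, end: float | None = None) -> "Trajectory":
        """Restrict to frames with start ≤ t ≤ end (the analysis window)."""
        mask = np.ones(self.n_frames, dtype=bool)
        if start is not None:
            mask &= self.times >= start
        if end is not None:
            mask &= self.times <= end
        if not mask.any():
            raise StructureError("analysis window contains no frames")
        return Trajectory(
            self.topology, self.positions[mask], self.boxes[mask], self.times[mask]
        )


# ---------------------------------------------------------------------------
# GRO format
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_box_line(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed box line {line!r}") from exc
    if len(vals) < 3:
        raise ParseError(f"line {lineno}: box line needs at least 3 floats")
    if len(vals) > 3 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise StructureError(
            f"line {lineno}: triclinic box detected (non-zero off-diagonal "
            "components); only orthorhombic boxes are supported"
        )
    return np.array(vals[:3], dtype=float)


def read_gro(path: str | Path, units: str = "nm") -> Trajectory:
    """Read a (possibly concatenated multi-frame) GRO file.

    Frame times are taken from a ``t=`` field on the title line when
    present, otherwise the frame index is used.  Velocities, if present,
    are ignored.
    """
    scale = _unit_scale(units)
    lines = Path(path).read_text().splitlines()
    pos_frames: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    times: list[float] = []
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    i = 0
    frame_idx = 0
    n_atoms_ref: int | None = None
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 2}: truncated frame (missing atom count)")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ParseError(
                f"line {i + 2}: malformed atom-count line {lines[i + 1]!r}"
            ) from exc
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise StructureError(
                f"line {i + 2}: frame {frame_idx} declares {n_atoms} atoms, "
                f"previous frames had {n_atoms_ref}"
            )
        atom_block = lines[i + 2 : i + 2 + n_atoms]
        if len(atom_block) < n_atoms:
            raise ParseError(f"line {len(lines)}: truncated frame (expected {n_atoms} atoms)")
        positions = np.empty((n_atoms, 3), dtype=float)
        for j, line in enumerate(atom_block):
            try:
                positions[j, 0] = float(line[20:28])
                positions[j, 1] = float(line[28:36])
                positions[j, 2] = float(line[36:44])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {i + 3 + j}: malformed atom line {line!r}") from exc
            if frame_idx == 0:
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
        box_lineno = i + 2 + n_atoms
        if box_lineno >= len(lines):
            raise ParseError(f"line {box_lineno + 1}: missing box line")
        box = _parse_box_line(lines[box_lineno], box_lineno + 1)
        m = _TIME_RE.search(title)
        times.append(float(m.group(1)) if m else float(frame_idx))
        pos_frames.append(positions * scale)
        boxes.append(box * scale)
        i = box_lineno + 1
        frame_idx += 1
    if not pos_frames:
        raise ParseError("file contains no frames")
    topology = Topology(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        elements=np.array([_guess_element(n) for n in names], dtype=object),
        tags=np.array([GroupTag.OTHER] * len(names), dtype=object),
    )
    return Trajectory(topology, np.array(pos_frames), np.array(boxes), np.array(times))


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _unit_scale(units: str) -> float:
    if units == "nm":
        return 1.0
    if units in ("angstrom", "A"):
        return 0.1
    raise ValueError(f"unknown unit {units!r}; use 'nm' or 'angstrom'")


def write_gro(
    frame: Frame,
    topology: Topology,
    path: str | Path,
    title: str = "calcimem frame",
    append: bool = False,
) -> None:
    """Write one frame in fixed-column GRO format (nm, 3 decimals).

    Residue and atom serial numbers wrap modulo 100000 per the format's
    five-column field width.
    """
    if frame.positions.shape[0] != topology.n_atoms:
        raise StructureError(
            f"frame has {frame.positions.shape[0]} atoms, topology has {topology.n_atoms}"
        )
    out = [f"{title} t= {frame.time:.4f}", f"{topology.n_atoms:5d}"]
    for i in range(topology.n_atoms):
        resid = int(topology.resids[i]) % 100000
        serial = (i + 1) % 100000
        x, y, z = frame.positions[i]
        out.append(
            f"{resid:5d}{str(topology.resnames[i])[:5]:<5s}"
            f"{str(topology.names[i])[:5]:>5s}{serial:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    out.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(out) + "\n")


def write_gro_trajectory(traj: Trajectory, path: str | Path, title: str = "calcimem") -> None:
    """Write every frame of a trajectory as concatenated GRO blocks."""
    Path(path).write_text("")
    for frame in traj:
        write_gro(frame, traj.topology, path, title=title, append=True)


# ---------------------------------------------------------------------------
# XYZ-with-box dialect
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file; box lengths appended to the comment line."""
    parts: list[str] = []
    els = [str(e) for e in traj.topology.elements]
    for frame in traj:
        parts.append(str(traj.n_atoms))
        parts.append(
            f"t= {frame.time:.6f} {frame.box[0]:.6f} {frame.box[1]:.6f} {frame.box[2]:.6f}"
        )
        for el, (x, y, z) in zip(els, frame.positions):
            parts.append(f"{el:<4s} {x:15.9f} {y:15.9f} {z:15.9f}")
    Path(path).write_text("\n".join(parts) + "\n")


def read_xyz(path: str | Path, topology: Topology | None = None) -> Trajectory:
    """Read the multi-frame XYZ-with-box dialect.

    The comment line must end with the three box edge lengths; a ``t=``
    token, when present, supplies the frame time.  If no topology is given
    a minimal one is constructed from the element column.
    """
    lines = Path(path).read_text().splitlines()
    i = 0
    pos_frames, boxes, times, elements = [], [], [], []
    frame_idx = 0
    n_ref: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: malformed atom-count line") from exc
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise StructureError(f"line {i + 1}: inconsistent atom count across frames")
        comment = lines[i + 1]
        floats = re.findall(r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?", comment)
        if len(floats) < 3:
            raise ParseError(f"line {i + 2}: comment line lacks box lengths")
        box = np.array([float(x) for x in floats[-3:]])
        m = _TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else float(frame_idx))
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError("truncated XYZ frame")
        pos = np.empty((n, 3))
        for j, line in enumerate(block):
            parts = line.split()
            if frame_idx == 0:
                elements.append(parts[0])
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        pos_frames.append(pos)
        boxes.append(box)
        i += 2 + n
        frame_idx += 1
    if not pos_frames:
        raise ParseError("file contains no frames")
    if topology is None:
        n = len(elements)
        topology = Topology(
            names=np.array(elements, dtype=object),
            resnames=np.array(["UNK"] * n, dtype=object),
            resids=np.ones(n, dtype=int),
            elements=np.array(elements, dtype=object),
            tags=np.array([GroupTag.OTHER] * n, dtype=object),
        )
    return Trajectory(topology, np.array(pos_frames), np.array(boxes), np.array(times))


# ---------------------------------------------------------------------------
# Group mapping
# ---------------------------------------------------------------------------

@dataclass
class GroupMap:
    """(residue name, atom name) → group tag mapping.

    Atoms not covered by the map default to OTHER; a residue name that
    appears in the topology but nowhere in the map triggers a warning.
    """

    mapping: Mapping[tuple[str, str], GroupTag] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, str]]) -> "GroupMap":
        mapping = {}
        for resname, atoms in d.items():
            for atom, tag in atoms.items():
                mapping[(resname, atom)] = GroupTag(tag)
        return cls(mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "GroupMap":
        """Bundled template covering Berger-style POPC/POPS/SPC naming plus
        the synthetic generator's atom names."""
        from importlib.resources import files

        text = files("calcimem.data").joinpath("default_groups.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def residue_names(self) -> set[str]:
        return {rn for rn, _ in self.mapping}

    def tag_for(self, resname: str, atomname: str) -> GroupTag:
        return self.mapping.get((resname, atomname), GroupTag.OTHER)


def apply_group_map(topology: Topology, group_map: GroupMap) -> Topology:
    """Return a topology with group tags assigned from the map.

    Every atom receives exactly one tag (OTHER when unmapped).  Residue
    names absent from the map raise a UserWarning, as the spec of what is
    being analysed is then incomplete.
    """
    known = group_map.residue_names()
    missing = sorted(set(map(str, topology.resnames)) - known)
    if missing:
        warnings.warn(
            f"residue names not in group map (atoms tagged OTHER): {missing}",
            UserWarning,
            stacklevel=2,
        )
    tags = np.array(
        [
            group_map.tag_for(str(rn), str(an))
            for rn, an in zip(topology.resnames, topology.names)
        ],
        dtype=object,
    )
    return Topology(
        names=topology.names,
        resnames=topology.resnames,
        resids=topology.resids,
        elements=topology.elements,
        tags=tags,
        charges=topology.charges,
        masses=topology.masses,
    )


def select(
    topology: Topology,
    tags: Iterable[GroupTag | str],
    resnames: Sequence[str] | None = None,
) -> np.ndarray:
    """Sorted unique atom indices carrying any of the given tags.

    An optional residue-name filter restricts the selection.  An empty tag
    set or an unknown tag name is a usage error.
    """
    tag_list = list(tags)
    if not tag_list:
        raise ValueError("tag selection must be non-empty")
    resolved = set()
    for t in tag_list:
        resolved.add(GroupTag(t) if not isinstance(t, GroupTag) else t)
    mask = np.array([t in resolved for t in topology.tags])
    if resnames is not None:
        allowed = set(resnames)
        mask &= np.array([str(rn) in allowed for rn in topology.resnames])
    return np.flatnonzero(mask)
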