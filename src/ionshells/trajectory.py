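"""Trajectory data model, MD file readers, and the internal tabular format.

The in-memory :class:`Trajectory` holds one protein and one or more tracked
ions on a uniform time grid, in nm/ps.  Standard MD files (PDB/GRO topology
plus XTC/TRR/DCD coordinates) are read through MDAnalysis; a plain-text
tabular format is provided for diffable, language-agnostic fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomMeta",
    "Trajectory",
    "classify_oxygen",
    "load_trajectory",
    "read_internal",
    "write_internal",
]

OXYGEN_CLASSES = ("none", "backbone_carbonyl", "sidechain_carboxylate", "sidechain_other_polar")

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain oxygen classification for the 20 standard residues.
# Carboxylate oxygens (the charged pairs of ASP/GLU) are distinguished from
# the remaining polar side-chain oxygens (hydroxyls and amide carbonyls).
_SIDECHAIN_OXYGEN = {
    ("ASP", "OD1"): "sidechain_carboxylate",
    ("ASP", "OD2"): "sidechain_carboxylate",
    ("GLU", "OE1"): "sidechain_carboxylate",
    ("GLU", "OE2"): "sidechain_carboxylate",
    ("ASN", "OD1"): "sidechain_other_polar",
    ("GLN", "OE1"): "sidechain_other_polar",
    ("SER", "OG"): "sidechain_other_polar",
    ("THR", "OG1"): "sidechain_other_polar",
    ("TYR", "OH"): "sidechain_other_polar",
}


def classify_oxygen(residue_name: str, atom_name: str) -> str:
    """Classify a protein oxygen atom by its chemical role.

    Pure function of ``(residue_name, atom_name)`` following PDB naming
    conventions.  Backbone carbonyl oxygens are named ``O`` (the terminal
    ``OXT`` is grouped with them); side-chain oxygens are looked up per
    residue.  Non-oxygen names return ``"none"``.
    """
    rn, an = residue_name.upper(), atom_name.upper()
    if not an.startswith("O"):
        return "none"
    if an in ("O", "OXT"):
        return "backbone_carbonyl"
    return _SIDECHAIN_OXYGEN.get((rn, an), "none")


@dataclass(frozen=True)
class AtomMeta:
    """Identity and chemical role of one protein atom."""

    atom_id: int
    residue_id: int
    residue_name: str
    atom_name: str
    element: str
    is_heavy: bool
    oxygen_class: str = "none"

    def __post_init__(self) -> None:
        if self.oxygen_class not in OXYGEN_CLASSES:
            raise ValueError(f"unknown oxygen_class {self.oxygen_class!r}")
        if self.oxygen_class != "none" and self.element.upper() != "O":
            raise ValueError("oxygen_class set on a non-oxygen atom")


@dataclass
class Trajectory:
    """One protein plus tracked ions on a uniform time grid.

    Attributes
    ----------
    times : (F,) array
        Frame timestamps in ps, strictly increasing and uniformly spaced.
    box : (F, 3) array
        Orthorhombic box edge lengths in nm, per frame.
    protein_coords : (F, A, 3) array
        Protein atom positions in nm.
    ion_coords : (F, I, 3) array
        Tracked ion positions in nm.
    atoms : list of AtomMeta
        Per-protein-atom metadata, aligned with axis 1 of protein_coords.
    ions : list of str
        Labels of the tracked ions, aligned with axis 1 of ion_coords.
    """

    times: np.ndarray
    box: np.ndarray
    protein_coords: np.ndarray
    ion_coords: np.ndarray
    atoms: list[AtomMeta]
    ions: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.protein_coords = np.asarray(self.protein_coords, dtype=float)
        self.ion_coords = np.asarray(self.ion_coords, dtype=float)
        F = self.times.shape[0]
        if F == 0:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box.shape != (F, 3) or np.any(self.box <= 0):
            raise ValueError("box must be (F, 3) with positive edge lengths")
        if self.protein_coords.shape[:1] + self.ion_coords.shape[:1] != (F, F):
            raise ValueError("frame count mismatch between coordinate arrays")
        if self.protein_coords.shape[1] != len(self.atoms):
            raise ValueError("protein_coords/atoms atom-count mismatch")
        if self.ion_coords.shape[1] != len(self.ions):
            raise ValueError("ion_coords/ions count mismatch")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (requires >= 2 frames)."""
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    def ion_index(self, label: str) -> int:
        try:
            return self.ions.index(label)
        except ValueError:
            raise KeyError(f"no tracked ion labelled {label!r}") from None

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)


_TIME_TOL = 1e-6  # relative tolerance on time-step uniformity


def _check_uniform(times: np.ndarray) -> None:
    if len(times) < 2:
        return
    dts = np.diff(times)
    if dts.min() <= 0:
        raise ValueError("times must be strictly increasing")
    if (dts.max() - dts.min()) > _TIME_TOL * dts.mean():
        warnings.warn("non-uniform frame spacing detected", stacklevel=3)
        raise ValueError(
            "trajectory frames are not uniformly spaced; resampling is not supported"
        )


def _element_of(name: str, topo_element: str = "") -> str:
    if topo_element:
        return topo_element.capitalize()
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def load_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path | None,
    ion_selection: str,
    protein_selection: str = "protein",
) -> Trajectory:
    """Read a topology (PDB/GRO) plus coordinate trajectory (XTC/TRR/DCD).

    ``ion_selection`` is an MDAnalysis selection string identifying the
    tracked ion(s); every selected atom becomes one tracked ion labelled
    ``<name><serial>``.  Coordinates are converted to nm and times to ps.
    Triclinic boxes are rejected: only orthorhombic cells are supported.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(trajectory_path))

    ions_ag = u.select_atoms(ion_selection)
    if len(ions_ag) == 0:
        raise ValueError(f"no atom matches ion selection {ion_selection!r}")
    prot_ag = u.select_atoms(protein_selection)
    prot_ag = prot_ag - ions_ag
    if len(prot_ag) == 0:
        raise ValueError(f"no protein atoms match selection {protein_selection!r}")

    atoms = []
    try:
        elements = list(prot_ag.elements)
    except Exception:
        elements = [""] * len(prot_ag)
    for a, el in zip(prot_ag, elements):
        element = _element_of(a.name, el)
        atoms.append(
            AtomMeta(
                atom_id=int(a.ix),
                residue_id=int(a.resid),
                residue_name=str(a.resname),
                atom_name=str(a.name),
                element=element,
                is_heavy=element != "H",
                oxygen_class=classify_oxygen(str(a.resname), str(a.name))
                if element == "O"
                else "none",
            )
        )
    ion_labels = [f"{a.name}{a.ix}" for a in ions_ag]

    times, boxes, prot_xyz, ion_xyz = [], [], [], []
    for ts in u.trajectory:
        if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
            raise ValueError("trajectory frame lacks box dimensions")
        alpha, beta, gamma = ts.dimensions[3:6]
        if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
            raise ValueError("only orthorhombic boxes are supported")
        times.append(float(ts.time))
        boxes.append(ts.dimensions[:3] / 10.0)  # A -> nm
        prot_xyz.append(prot_ag.positions / 10.0)
        ion_xyz.append(ions_ag.positions / 10.0)

    times = np.asarray(times)
    _check_uniform(times)
    return Trajectory(
        times=times,
        box=np.asarray(boxes),
        protein_coords=np.asarray(prot_xyz),
        ion_coords=np.asarray(ion_xyz),
        atoms=atoms,
        ions=ion_labels,
    )


# ---------------------------------------------------------------------------
# Internal plain-text tabular format
#
# Layout (fixed column order, '%.9f' coordinates):
#   ionshells-trajectory 1
#   nframes <F> natoms <A> nions <I>
#   ions <label>...
#   atom <atom_id> <residue_id> <residue_name> <atom_name> <element>
#        <is_heavy:0/1> <oxygen_class>          (A lines)
#   frame <time> <bx> <by> <bz>
#   <x> <y> <z>                                  (A atom lines, then I ion lines)
# ---------------------------------------------------------------------------

_MAGIC = "ionshells-trajectory 1"
_FMT = "%.9f"


def write_internal(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the internal tabular text format (lossless at
    1e-9 nm / 1e-9 ps)."""
    lines = [_MAGIC]
    lines.append(
        f"nframes {traj.n_frames} natoms {len(traj.atoms)} nions {len(traj.ions)}"
    )
    lines.append("ions " + " ".join(traj.ions))
    for a in traj.atoms:
        lines.append(
            f"atom {a.atom_id} {a.residue_id} {a.residue_name} {a.atom_name} "
            f"{a.element} {int(a.is_heavy)} {a.oxygen_class}"
        )
    for f in range(traj.n_frames):
        bx, by, bz = traj.box[f]
        lines.append(
            "frame " + " ".join(_FMT % v for v in (traj.times[f], bx, by, bz))
        )
        for xyz in traj.protein_coords[f]:
            lines.append(" ".join(_FMT % v for v in xyz))
        for xyz in traj.ion_coords[f]:
            lines.append(" ".join(_FMT % v for v in xyz))
    Path(path).write_text("\n".join(lines) + "\n")


def read_internal(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_internal`."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _MAGIC:
        raise ValueError(f"{path}: not an internal trajectory file (bad header)")
    try:
        hdr = text[1].split()
        F, A, I = int(hdr[1]), int(hdr[3]), int(hdr[5])
        ions = text[2].split()[1:]
    except (IndexError, ValueError) as e:
        raise ValueError(f"{path}: malformed header") from e
    if F == 0:
        raise ValueError(f"{path}: empty trajectory (0 frames)")
    if len(ions) != I:
        raise ValueError(f"{path}: ion label count mismatch")

    atoms = []
    pos = 3
    for _ in range(A):
        f = text[pos].split()
        if f[0] != "atom" or len(f) != 8:
            raise ValueError(f"{path}: malformed atom line {pos + 1}")
        atoms.append(
            AtomMeta(int(f[1]), int(f[2]), f[3], f[4], f[5], bool(int(f[6])), f[7])
        )
        pos += 1

    times = np.empty(F)
    box = np.empty((F, 3))
    prot = np.empty((F, A, 3))
    ion = np.empty((F, I, 3))
    try:
        for fr in range(F):
            f = text[pos].split()
            if f[0] != "frame":
                raise ValueError(f"{path}: expected frame header at line {pos + 1}")
            times[fr] = float(f[1])
            box[fr] = [float(x) for x in f[2:5]]
            pos += 1
            for a in range(A):
                prot[fr, a] = [float(x) for x in text[pos].split()]
                pos += 1
            for i in range(I):
                ion[fr, i] = [float(x) for x in text[pos].split()]
                pos += 1
    except IndexError as e:
        raise ValueError(f"{path}: truncated frame block") from e
    return Trajectory(times, box, prot, ion, atoms, ions)
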