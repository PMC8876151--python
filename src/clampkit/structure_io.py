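"""Structure and trajectory I/O with a continuous residue numbering convention.

The sliding clamp is a homodimer of two 366-residue monomers deposited as two
chains. All residue selections in this package use a single *continuous*
1-based index obtained by concatenating the chains in file order, so that
residue ``r`` of the second monomer is addressed as ``r + 366`` (e.g. the
plane-triplet residues 75/169/267 of monomer 1 correspond to 441/535/633 of
monomer 2). Author numbering (with gaps and insertion codes) is preserved in a
mapping table for inspection but is never used for selection.

Coordinates are always in Ångström.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "Structure",
    "AtomSelection",
    "Trajectory",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "write_trajectory",
    "select_ca",
    "select_residue_range",
    "STANDARD_AMINO_ACIDS",
    "DNA_RESIDUE_NAMES",
]

# The 20 canonical amino acids; used for "standard protein residue" counts.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET
       PHE PRO SER THR TRP TYR VAL""".split()
)

# Deoxyribonucleotides incl. 5'/3' terminal variants.
DNA_RESIDUE_NAMES = frozenset(
    "DA DT DG DC DA5 DT5 DG5 DC5 DA3 DT3 DG3 DC3".split()
)


class StructureError(ValueError):
    """Raised for unparseable or inconsistent structural input."""


@dataclass
class Structure:
    """A single-model structure with a derived continuous residue index.

    Attributes
    ----------
    atoms : biotite.structure.AtomArray
        Atom records (one altloc per atom already resolved).
    continuous_index : np.ndarray of int
        Per-atom continuous residue index, 1-based, strictly increasing
        along the file with no gaps.
    residue_table : pandas.DataFrame
        One row per residue: ``continuous``, ``chain_id``, ``author_res_id``,
        ``ins_code``, ``res_name``, ``is_protein``, ``is_dna``, ``has_ca``.
    missing_ca : list[int]
        Continuous indices of protein residues lacking a CA atom.
    """

    atoms: bst.AtomArray
    continuous_index: np.ndarray
    residue_table: pd.DataFrame
    missing_ca: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("structure contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def n_residues(self) -> int:
        return len(self.residue_table)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array in Å."""
        return self.atoms.coord

    def n_standard_protein_residues(self) -> int:
        """Count residues with a canonical amino-acid residue name."""
        return int(self.residue_table["is_protein"].sum())

    def ca_index(self, continuous_residue: int) -> int:
        """Atom index of the CA atom of a residue (continuous numbering)."""
        mask = (self.continuous_index == continuous_residue) & (
            self.atoms.atom_name == "CA"
        )
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            raise KeyError(
                f"residue {continuous_residue} has no CA atom (or is absent)"
            )
        return int(hits[0])


@dataclass
class AtomSelection:
    """Ordered atom indices plus the expression they came from."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """Frames of coordinates sharing one topology.

    ``frame_spacing`` is an optional user-declared spacing between frames in
    whatever time unit the user chooses; nothing in the package assumes one.
    """

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("trajectory coordinates must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = np.flatnonzero(~np.isfinite(self.coords).all(axis=(1, 2)))
            raise StructureError(f"non-finite coordinates in frame {bad[0]}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _build_residue_tables(atoms: bst.AtomArray):
    """Assign the continuous index and build the residue mapping table."""
    starts = bst.get_residue_starts(atoms, add_exclusive_stop=True)
    n_res = len(starts) - 1
    continuous = np.empty(atoms.array_length(), dtype=int)
    rows = []
    missing_ca = []
    ins = (
        atoms.ins_code
        if "ins_code" in atoms.get_annotation_categories()
        else np.full(atoms.array_length(), "", dtype="U1")
    )
    for i in range(n_res):
        lo, hi = starts[i], starts[i + 1]
        continuous[lo:hi] = i + 1
        res_name = str(atoms.res_name[lo])
        is_protein = res_name in STANDARD_AMINO_ACIDS
        has_ca = bool(np.any(atoms.atom_name[lo:hi] == "CA"))
        if is_protein and not has_ca:
            missing_ca.append(i + 1)
        rows.append(
            {
                "continuous": i + 1,
                "chain_id": str(atoms.chain_id[lo]),
                "author_res_id": int(atoms.res_id[lo]),
                "ins_code": str(ins[lo]),
                "res_name": res_name,
                "is_protein": is_protein,
                "is_dna": res_name in DNA_RESIDUE_NAMES,
                "has_ca": has_ca,
            }
        )
    table = pd.DataFrame(rows)
    return continuous, table, missing_ca


def load_structure(path: str | Path, model: int | None = None) -> Structure:
    """Load a single model from a PDB file and derive continuous numbering.

    Alternate locations are resolved by highest occupancy (ties fall to the
    first-listed, conventionally 'A'). Protein residues without a CA atom are
    kept but reported in ``Structure.missing_ca`` with a warning, since
    CA-based metrics cannot use them.

    Parameters
    ----------
    path
        PDB file path.
    model
        1-based model number; defaults to the first model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = bpdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(
            model=model if model is not None else 1,
            altloc="occupancy",
            extra_fields=["occupancy"],
        )
    except Exception as exc:  # biotite reports the offending line in its message
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    continuous, table, missing_ca = _build_residue_tables(atoms)
    if missing_ca:
        warnings.warn(
            f"{len(missing_ca)} protein residue(s) without CA excluded from "
            f"CA-based analysis: {missing_ca[:10]}",
            stacklevel=2,
        )
    return Structure(atoms, continuous, table, missing_ca)


def write_structure(struct: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file."""
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(struct.atoms)
    pdb_file.write(str(path))


def select_ca(struct: Structure, residues) -> AtomSelection:
    """CA atom indices for the given continuous residue indices, in order.

    Raises ``KeyError`` naming every requested residue that is absent or has
    no CA atom.
    """
    residues = list(residues)
    indices = []
    missing = []
    for r in residues:
        try:
            indices.append(struct.ca_index(int(r)))
        except KeyError:
            missing.append(int(r))
    if missing:
        raise KeyError(f"residues without CA or absent from structure: {missing}")
    return AtomSelection(np.array(indices, dtype=int), f"CA of residues {residues}")


def select_residue_range(struct: Structure, expression: str) -> AtomSelection:
    """Parse a residue-range mini-language on continuous indices.

    The grammar is comma-separated terms, each ``N`` or ``N-M`` (inclusive),
    e.g. ``"1-366"`` or ``"75,169,267"``. Returns the CA selection.
    """
    residues: list[int] = []
    for term in expression.replace(" ", "").split(","):
        if not term:
            continue
        if "-" in term[1:]:  # allow no negative indices
            lo_s, hi_s = term.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
            if hi < lo:
                raise ValueError(f"empty range {term!r}")
            residues.extend(range(lo, hi + 1))
        else:
            residues.append(int(term))
    sel = select_ca(struct, residues)
    sel.expression = expression
    return sel


def _load_text_frames(path: Path, topology: Structure) -> np.ndarray:
    """Read the plain-text frame dialect: header ``natoms nframes`` then one
    ``x y z`` line per atom per frame."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise StructureError(f"{path}:1: expected header 'natoms nframes'")
        natoms, nframes = int(header[0]), int(header[1])
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    if data.shape != (natoms * nframes, 3):
        raise StructureError(
            f"{path}: expected {natoms * nframes} coordinate lines, "
            f"got {data.shape[0]}"
        )
    if natoms != topology.n_atoms:
        raise StructureError(
            f"{path}: frame atom count {natoms} does not match topology "
            f"({topology.n_atoms})"
        )
    return data.reshape(nframes, natoms, 3)


def load_trajectory(path: str | Path, topology: Structure) -> Trajectory:
    """Load a trajectory from a multi-model PDB or the plain-text frame format.

    The dialect is chosen by extension: ``.pdb``/``.ent`` are multi-model PDB,
    anything else is the text format (header ``natoms nframes``, then per
    frame one ``x y z`` line per atom).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        pdb_file = bpdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="occupancy")
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1] != topology.n_atoms:
            raise StructureError(
                f"frame atom count {coords.shape[1]} does not match topology "
                f"({topology.n_atoms})"
            )
    else:
        coords = _load_text_frames(path, topology)
    return Trajectory(topology, coords)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB or the plain-text frame format."""
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        stack = bst.stack(
            [traj.topology.atoms] * traj.n_frames
        )
        stack.coord = traj.coords.astype(np.float32)
        pdb_file = bpdb.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    else:
        with open(path, "w") as fh:
            fh.write(f"{traj.coords.shape[1]} {traj.n_frames}\n")
            for frame in traj.coords:
                np.savetxt(fh, frame, fmt="%.6f")
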