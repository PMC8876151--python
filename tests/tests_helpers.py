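"""Small builders shared by the test modules."""

import numpy as np
import biotite.structure as bst

from clampkit.structure_io import Structure, _build_residue_tables


def structure_from_ca_coords(coords, residue_ids=None, chain_id="A"):
    """Single-chain CA-only Structure from an (n, 3) coordinate array.

    ``residue_ids`` defaults to 1..n; pass explicit ids to leave sequence
    gaps (e.g. for neighbour-exclusion tests).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if residue_ids is None:
        residue_ids = np.arange(1, n + 1)
    atoms = bst.AtomArray(n)
    atoms.coord = coords.astype(np.float32)
    atoms.atom_name = np.full(n, "CA")
    atoms.res_name = np.full(n, "GLY")
    atoms.element = np.full(n, "C")
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.asarray(residue_ids, dtype=int)
    atoms.hetero = np.zeros(n, dtype=bool)
    continuous, table, missing = _build_residue_tables(atoms)
    struct = Structure(atoms, continuous, table, missing)
    struct.atoms.coord = coords
    return struct
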