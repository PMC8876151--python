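"""Conformational indicators for ring-clamp trajectories.

Three indicators monitor clamp opening:

* **Aperture** — the harmonic mean of CA–CA distances across an interface,
  i.e. the inverse of the averaged inverse distances,
  ``H = n / sum(1/d_i)``. Averaging inverses damps the influence of a few
  very long distances once the interface separates. The pair set is frozen
  from a reference frame: all CA pairs with one atom in each interface group
  and reference distance within a cutoff (default 8 Å).
* **Interplanar angle** — each half-ring defines a plane through three of its
  CA atoms; the angle between the two *oriented* plane normals tracks the
  mutual orientation of the monomers. For a planar ring with the two triplets
  listed in mirrored order the normals are nearly antiparallel, so the closed
  clamp sits near 180° (about 172° in the crystal structure) and out-of-plane
  opening drives the angle away from its reference value.
* **Backbone RMSD** — least-squares superposed RMSD to a reference frame, the
  generic similarity indicator.

A center-of-mass distance (e.g. protein vs DNA) is provided for binding
tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import AtomSelection, Structure, Trajectory

__all__ = [
    "ContactPairSet",
    "PlaneTriplet",
    "extract_contact_pairs",
    "aperture",
    "fit_plane_normal",
    "interplanar_angle",
    "out_of_plane_deviation",
    "backbone_rmsd",
    "com_distance",
    "compute_metric_series",
    "write_metric_series",
    "write_contact_pairs",
]

_COLLINEARITY_AREA_TOL = 1e-6  # Å²; triangle area below this is degenerate


@dataclass
class ContactPairSet:
    """Frozen set of interface CA pairs defined on a reference frame."""

    label: str
    pairs: np.ndarray            # (n_pairs, 2) atom indices, group1 then group2
    cutoff: float                # Å
    reference_distances: np.ndarray  # Å, per pair, all <= cutoff
    reference_frame: str = "frame0"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)
        if len({tuple(p) for p in self.pairs}) != len(self.pairs):
            raise ValueError("contact pairs must be unique")
        if np.any(self.reference_distances > self.cutoff):
            raise ValueError("reference distance exceeds cutoff")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PlaneTriplet:
    """Three ordered CA atom indices defining an oriented plane."""

    indices: tuple

    def __post_init__(self) -> None:
        self.indices = tuple(int(i) for i in self.indices)
        if len(self.indices) != 3 or len(set(self.indices)) != 3:
            raise ValueError("plane triplet needs three distinct atom indices")


def extract_contact_pairs(
    struct: Structure,
    group1,
    group2,
    cutoff: float = 8.0,
    label: str = "interface",
) -> ContactPairSet:
    """All CA pairs (one residue per group) within ``cutoff`` Å in ``struct``.

    ``group1``/``group2`` are disjoint lists of continuous residue indices.
    The resulting pair set is frozen: at later frames the same pairs are
    measured even when their distances exceed the cutoff.
    """
    g1, g2 = list(group1), list(group2)
    if set(g1) & set(g2):
        raise ValueError("interface groups must be disjoint")
    from .structure_io import select_ca

    idx1 = select_ca(struct, g1).indices
    idx2 = select_ca(struct, g2).indices
    coords = struct.coords
    diff = coords[idx1][:, None, :] - coords[idx2][None, :, :]
    dmat = np.linalg.norm(diff, axis=2)
    ii, jj = np.nonzero(dmat <= cutoff)
    if len(ii) == 0:
        raise ValueError(
            f"no CA pairs within {cutoff} Å between the groups; "
            "increase the cutoff — an interface without contacts cannot be monitored"
        )
    pairs = np.stack([idx1[ii], idx2[jj]], axis=1)
    return ContactPairSet(label, pairs, cutoff, dmat[ii, jj])


def aperture(frame: np.ndarray, pairs: ContactPairSet, mean: str = "harmonic") -> float:
    """Interface aperture in Å.

    The primary form is the harmonic mean of the pair distances (the inverse
    of the averaged inverse distances), which damps the influence of a few
    long distances after the joint separates; ``mean="arithmetic"`` gives
    the plain average for comparison.
    """
    if len(pairs) == 0:
        raise ValueError("empty contact pair set")
    d = np.linalg.norm(
        frame[pairs.pairs[:, 0]] - frame[pairs.pairs[:, 1]], axis=1
    )
    if np.any(d == 0):
        raise ValueError("coincident atoms in contact pair (zero distance)")
    if mean == "harmonic":
        return float(len(d) / np.sum(1.0 / d))
    if mean == "arithmetic":
        return float(np.mean(d))
    raise ValueError(f"unknown mean {mean!r}")


def fit_plane_normal(p1, p2, p3) -> np.ndarray:
    """Unit normal of the plane through three points.

    Oriented by the right-hand rule on the ordered points:
    ``normalize((p2-p1) x (p3-p1))``. Swapping two points flips the normal.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    cross = np.cross(p2 - p1, p3 - p1)
    area2 = np.linalg.norm(cross)  # twice the triangle area
    if area2 / 2.0 <= _COLLINEARITY_AREA_TOL:
        raise ValueError("collinear points: plane undefined")
    return cross / area2


def interplanar_angle(
    frame: np.ndarray, triplet_a: PlaneTriplet, triplet_b: PlaneTriplet
) -> float:
    """Angle in degrees between the oriented normals of two plane triplets.

    Reported in [0, 180] without folding, so antiparallel normals (coplanar
    triangles traversed in opposite sense) read 180°.
    """
    na = fit_plane_normal(*frame[list(triplet_a.indices)])
    nb = fit_plane_normal(*frame[list(triplet_b.indices)])
    return float(np.degrees(np.arccos(np.clip(np.dot(na, nb), -1.0, 1.0))))


def out_of_plane_deviation(angle: float, reference_angle: float) -> float:
    """Absolute deviation of the interplanar angle from its reference, degrees."""
    for v in (angle, reference_angle):
        if not 0.0 <= v <= 180.0:
            raise ValueError("angles must lie in [0, 180] degrees")
    return abs(angle - reference_angle)


def backbone_rmsd(
    frame: np.ndarray, reference: np.ndarray, selection: AtomSelection
) -> float:
    """RMSD in Å after optimal rigid superposition of the selected atoms.

    Translation plus proper rotation (Kabsch with reflection guard); no
    scaling. Symmetric in its two arguments.
    """
    idx = selection.indices
    if len(idx) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    a = np.asarray(frame, dtype=float)[idx]
    b = np.asarray(reference, dtype=float)[idx]
    if a.shape != b.shape:
        raise ValueError("selection size mismatch between frame and reference")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b, a)
    # recompute residuals after applying the fit: avoids the cancellation
    # noise of the solver's reported rssd near exact overlap
    resid = rot.apply(a) - b
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def com_distance(
    frame: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    weights_a: np.ndarray | None = None,
    weights_b: np.ndarray | None = None,
) -> float:
    """Distance between the (optionally mass-weighted) centroids of two selections."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    ca = np.average(frame[sel_a.indices], axis=0, weights=weights_a)
    cb = np.average(frame[sel_b.indices], axis=0, weights=weights_b)
    return float(np.linalg.norm(ca - cb))


def compute_metric_series(
    traj: Trajectory,
    pairs1: ContactPairSet,
    pairs2: ContactPairSet,
    triplet_a: PlaneTriplet,
    triplet_b: PlaneTriplet,
    rmsd_selection: AtomSelection,
    reference_angle: float | None = None,
    com_selections: tuple[AtomSelection, AtomSelection] | None = None,
) -> pd.DataFrame:
    """Per-frame metric table for a trajectory.

    Columns: ``frame, aperture1, aperture2, angle, deviation, rmsd`` and
    optionally ``com_distance``. The reference for RMSD is the topology's
    coordinates; the reference interplanar angle defaults to the frame-0
    angle.
    """
    ref_coords = traj.topology.coords
    if reference_angle is None:
        reference_angle = interplanar_angle(traj.coords[0], triplet_a, triplet_b)
    records = []
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        ang = interplanar_angle(frame, triplet_a, triplet_b)
        rec = {
            "frame": k,
            "aperture1": aperture(frame, pairs1),
            "aperture2": aperture(frame, pairs2),
            "angle": ang,
            "deviation": out_of_plane_deviation(ang, reference_angle),
            "rmsd": backbone_rmsd(frame, ref_coords, rmsd_selection),
        }
        if com_selections is not None:
            rec["com_distance"] = com_distance(frame, *com_selections)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_metric_series(series: pd.DataFrame, path) -> None:
    """Write the metric table as CSV with 6 significant digits."""
    series.to_csv(path, index=False, float_format="%.6g")


def write_contact_pairs(pairs: ContactPairSet, path) -> None:
    """Write a pair set as a two-column list with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(
            f"# label={pairs.label} cutoff={pairs.cutoff} "
            f"reference={pairs.reference_frame}\n"
        )
        for (i, j), d in zip(pairs.pairs, pairs.reference_distances):
            fh.write(f"{i}\t{j}\t{d:.6g}\n")
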