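"""Restraint-network generation and replica-exchange bookkeeping.

To keep each clamp subunit folded at high replica temperatures, every CA pair
within 8 Å in the initial structure receives a flat-bottom harmonic distance
restraint. The functional form has four ordered knots r1 <= r2 <= r3 <= r4:
zero energy on the plateau [r2, r3], quadratic shoulders k(r-r2)^2 / k(r-r3)^2
out to r1 / r4, and linear tails beyond that match value and slope at the
junction — so the penalty is C1-continuous everywhere and grows only linearly
for gross violations.

Replica-exchange bookkeeping follows the usual temperature-ladder Metropolis
scheme: swaps between adjacent replicas are accepted with
``p = min(1, exp[(beta_i - beta_j)(E_i - E_j)])``. A *walker* is a physical
system instance followed through the ladder; demultiplexing replays the
accepted swaps from the exchange log to recover each walker's replica index
over time, and round-trip counts (bottom -> top -> bottom traversals) are the
standard exchange-health diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AtomSelection, Structure

__all__ = [
    "RestraintSpec",
    "TemperatureLadder",
    "ExchangeLog",
    "WalkerPath",
    "build_restraint_network",
    "restraint_energy",
    "make_temperature_ladder",
    "metropolis_accept_probability",
    "demux_walkers",
    "round_trip_count",
    "write_restraints",
    "read_exchange_log",
    "write_exchange_log",
    "KB_KCAL_MOL_K",
]

KB_KCAL_MOL_K = 0.0019872041  # Boltzmann constant, kcal/(mol K)

DEFAULT_FLAT_WIDTH = 0.5   # Å, knot spacing Delta
DEFAULT_FORCE_CONSTANT = 250.0  # kcal/(mol Å²)


@dataclass
class RestraintSpec:
    """Flat-bottom distance restraint between two atoms."""

    atom_i: int
    atom_j: int
    r1: float
    r2: float
    r3: float
    r4: float
    k: float

    def __post_init__(self) -> None:
        if not (self.r1 <= self.r2 <= self.r3 <= self.r4):
            raise ValueError("restraint knots must satisfy r1 <= r2 <= r3 <= r4")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")


@dataclass
class TemperatureLadder:
    temperatures: np.ndarray  # K, strictly increasing

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("ladder temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class ExchangeLog:
    """Attempted swaps between adjacent replicas.

    ``attempts`` is an (n, 4) int array of rows ``step, replica_a, replica_b,
    accepted`` ordered by step; ``initial_mapping[w]`` is the replica that
    walker ``w`` occupies at step 0 (defaults to the identity).
    """

    n_replicas: int
    attempts: np.ndarray
    initial_mapping: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.attempts = np.asarray(self.attempts, dtype=int).reshape(-1, 4)
        if self.initial_mapping is None:
            self.initial_mapping = np.arange(self.n_replicas)
        self.initial_mapping = np.asarray(self.initial_mapping, dtype=int)
        if sorted(self.initial_mapping) != list(range(self.n_replicas)):
            raise ValueError("initial walker->replica mapping must be a bijection")
        for step, a, b, acc in self.attempts:
            if not (0 <= a < self.n_replicas and 0 <= b < self.n_replicas):
                raise ValueError(f"swap ({a},{b}) at step {step} out of range")
            if abs(a - b) != 1:
                raise ValueError(f"swap ({a},{b}) at step {step} is not adjacent")
            if acc not in (0, 1):
                raise ValueError("accepted flag must be 0 or 1")

    @property
    def n_steps(self) -> int:
        return int(self.attempts[:, 0].max()) + 1 if len(self.attempts) else 1


@dataclass
class WalkerPath:
    """Each walker's replica index at every step; rows are permutations."""

    replica_of_walker: np.ndarray  # (n_steps, n_walkers)

    def __post_init__(self) -> None:
        self.replica_of_walker = np.asarray(self.replica_of_walker, dtype=int)
        n = self.replica_of_walker.shape[1]
        ref = np.arange(n)
        for t, row in enumerate(self.replica_of_walker):
            if not np.array_equal(np.sort(row), ref):
                raise ValueError(f"assignment at step {t} is not a permutation")

    @property
    def n_steps(self) -> int:
        return self.replica_of_walker.shape[0]

    @property
    def n_walkers(self) -> int:
        return self.replica_of_walker.shape[1]


def build_restraint_network(
    struct: Structure,
    selection: AtomSelection,
    cutoff: float = 8.0,
    flat_width: float = DEFAULT_FLAT_WIDTH,
    k: float = DEFAULT_FORCE_CONSTANT,
    min_sequence_separation: int = 2,
) -> list[RestraintSpec]:
    """One flat-bottom restraint per CA pair within ``cutoff`` Å.

    Pairs within the same residue or closer than ``min_sequence_separation``
    along the chain are excluded: sequence neighbours are held by covalent
    geometry already, so restraining them is pointless. Chain adjacency is
    judged on author numbering within a chain (numbering gaps mean missing
    residues, not bonds), and atoms on different chains are never neighbours.
    Knots are centred on the reference distance d:
    ``(d - 2Δ, d - Δ, d + Δ, d + 2Δ)`` with Δ = ``flat_width``, floored at 0.
    """
    idx = selection.indices
    if len(idx) < 2:
        raise ValueError("restraint network needs at least 2 atoms")
    coords = struct.coords[idx]
    chain = struct.atoms.chain_id[idx]
    author = struct.atoms.res_id[idx]
    restraints = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if chain[a] == chain[b] and abs(
                int(author[a]) - int(author[b])
            ) < min_sequence_separation:
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            if d > cutoff:
                continue
            knots = np.maximum(
                0.0, d + flat_width * np.array([-2.0, -1.0, 1.0, 2.0])
            )
            restraints.append(
                RestraintSpec(int(idx[a]), int(idx[b]), *knots, k)
            )
    return restraints


def restraint_energy(r: float, spec: RestraintSpec) -> float:
    """Flat-bottom restraint energy at distance ``r``, kcal/mol.

    Zero on [r2, r3]; quadratic shoulders on [r1, r2) and (r3, r4]; linear
    tails beyond r1/r4 matching value and slope (C1-continuous).
    """
    if r < 0:
        raise ValueError("distance must be non-negative")
    k, r1, r2, r3, r4 = spec.k, spec.r1, spec.r2, spec.r3, spec.r4
    if r2 <= r <= r3:
        return 0.0
    if r1 <= r < r2:
        return k * (r - r2) ** 2
    if r3 < r <= r4:
        return k * (r - r3) ** 2
    if r < r1:
        return k * (r1 - r2) ** 2 + 2 * k * (r1 - r2) * (r - r1)
    return k * (r4 - r3) ** 2 + 2 * k * (r4 - r3) * (r - r4)


def make_temperature_ladder(
    n: int, t_min: float, t_max: float, schedule: str = "geometric"
) -> TemperatureLadder:
    """Replica temperature ladder with exact endpoints.

    Geometric: ``T_i = t_min * (t_max/t_min)**(i/(n-1))`` — constant ratio
    between neighbours, the standard choice for roughly uniform acceptance.
    """
    if n < 2:
        raise ValueError("ladder needs at least 2 replicas")
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    i = np.arange(n)
    if schedule == "geometric":
        temps = t_min * (t_max / t_min) ** (i / (n - 1))
    elif schedule == "linear":
        temps = t_min + (t_max - t_min) * i / (n - 1)
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    temps[0], temps[-1] = t_min, t_max
    return TemperatureLadder(temps)


def metropolis_accept_probability(
    e_i: float, e_j: float, t_i: float, t_j: float
) -> float:
    """Metropolis acceptance probability for swapping replicas i and j.

    ``p = min(1, exp[(beta_i - beta_j)(E_i - E_j)])`` with beta = 1/(kB T).
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    beta_i = 1.0 / (KB_KCAL_MOL_K * t_i)
    beta_j = 1.0 / (KB_KCAL_MOL_K * t_j)
    return float(min(1.0, np.exp((beta_i - beta_j) * (e_i - e_j))))


def demux_walkers(log: ExchangeLog) -> WalkerPath:
    """Replay accepted swaps to recover each walker's replica over time.

    A swap accepted at step ``s`` exchanges the occupants of the two replicas
    from step ``s`` onward. The returned path has one row per step,
    0 .. max(step); row ``t`` gives each walker's replica at step ``t``.
    """
    n = log.n_replicas
    replica_of = log.initial_mapping.copy()  # walker -> replica
    n_steps = log.n_steps
    path = np.empty((n_steps, n), dtype=int)
    attempts = log.attempts[np.argsort(log.attempts[:, 0], kind="stable")]
    ptr = 0
    for t in range(n_steps):
        while ptr < len(attempts) and attempts[ptr, 0] == t:
            _, a, b, acc = attempts[ptr]
            if acc:
                wa = int(np.flatnonzero(replica_of == a)[0])
                wb = int(np.flatnonzero(replica_of == b)[0])
                replica_of[wa], replica_of[wb] = b, a
            ptr += 1
        path[t] = replica_of
    return WalkerPath(path)


def round_trip_count(path: WalkerPath, walker_id: int) -> int:
    """Completed bottom -> top -> bottom ladder traversals by one walker."""
    series = path.replica_of_walker[:, walker_id]
    top = path.n_walkers - 1
    count = 0
    seen_bottom = series[0] == 0
    seen_top_after_bottom = False
    for r in series:
        if r == 0:
            if seen_top_after_bottom:
                count += 1
                seen_top_after_bottom = False
            seen_bottom = True
        elif r == top and seen_bottom:
            seen_top_after_bottom = True
    return count


def write_restraints(restraints, path) -> None:
    """Tab-separated restraint table with a comment header."""
    with open(path, "w") as fh:
        fh.write("# atom_i\tatom_j\tr1\tr2\tr3\tr4\tk\n")
        for s in restraints:
            fh.write(
                f"{s.atom_i}\t{s.atom_j}\t{s.r1:.6g}\t{s.r2:.6g}\t"
                f"{s.r3:.6g}\t{s.r4:.6g}\t{s.k:.6g}\n"
            )


def write_exchange_log(log: ExchangeLog, path) -> None:
    """Tab-separated exchange log: ``step replica_a replica_b accepted``."""
    with open(path, "w") as fh:
        fh.write(f"# n_replicas={log.n_replicas}\n")
        fh.write("# step\treplica_a\treplica_b\taccepted\n")
        for step, a, b, acc in log.attempts:
            fh.write(f"{step}\t{a}\t{b}\t{acc}\n")


def read_exchange_log(path, n_replicas: int | None = None) -> ExchangeLog:
    """Parse a tab-separated exchange log, reporting bad lines by number."""
    attempts = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_replicas=" in line and n_replicas is None:
                    n_replicas = int(line.split("n_replicas=")[1].split()[0])
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                attempts.append([int(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if n_replicas is None:
        raise ValueError(f"{path}: n_replicas not given and not in header")
    arr = np.array(attempts, dtype=int) if attempts else np.empty((0, 4), dtype=int)
    return ExchangeLog(n_replicas, arr)
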