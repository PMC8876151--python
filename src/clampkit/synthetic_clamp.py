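"""Synthetic toy-clamp structures, trajectories and exchange logs.

The generator emulates the geometry of a two-subunit ring clamp at CA
resolution: two semicircular arcs of beads (one bead per pseudo-residue) in
the z = 0 plane, joined at two interfaces on the ±x axis, with continuous
residue numbering running through arm 1 then arm 2. Opening events are
planted by rotating one arm rigidly about a hinge at the *opposite*
interface — about the z axis for in-plane opening (coplanarity preserved) or
about an in-plane axis for out-of-plane opening (coplanarity broken) — with
a linear ramp up to the scheduled amplitude and back. Isotropic Gaussian
coordinate noise is added per frame. Every generator is deterministic in its
seed and returns its schedule as ground truth, so detectors can be scored
for exact recovery.

This is a geometric test harness, not physics: no forces, no thermostat,
no realistic DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import biotite.structure as bst
from scipy.spatial.transform import Rotation

from .remd_tools import ExchangeLog, WalkerPath
from .structure_io import Structure, Trajectory, _build_residue_tables

__all__ = [
    "ToyClampParams",
    "PlantedEvent",
    "OpeningSchedule",
    "build_toy_clamp",
    "generate_trajectory",
    "generate_exchange_log",
    "generate_walker_cohort",
    "interface_groups",
    "default_plane_triplets",
]


@dataclass
class ToyClampParams:
    """Geometry of the toy two-arm ring.

    beads_per_arm : one CA-like bead per pseudo-residue (>= 6)
    radius : ring radius in Å
    gap_half_angle : angular half-gap at each interface, degrees; sets the
        closed-interface chord 2R·sin(gap) (default gives ~4 Å at R = 30)
    noise_sigma : per-coordinate Gaussian noise, Å
    """

    beads_per_arm: int = 20
    radius: float = 30.0
    gap_half_angle: float = 4.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beads_per_arm < 6:
            raise ValueError("need at least 6 beads per arm")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass
class PlantedEvent:
    """One scheduled opening episode on the toy clamp."""

    interface: int               # 1 (+x junction) or 2 (−x junction)
    open_frame: int
    close_frame: Optional[int]   # None = stays open to the last frame
    amplitude: float             # degrees of arm rotation at the peak
    mode: str = "in_plane"       # "in_plane" | "out_of_plane"

    def __post_init__(self) -> None:
        if self.interface not in (1, 2):
            raise ValueError("interface must be 1 or 2")
        if self.mode not in ("in_plane", "out_of_plane"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.close_frame is not None and self.close_frame <= self.open_frame:
            raise ValueError("close_frame must be after open_frame")


@dataclass
class OpeningSchedule:
    events: list = field(default_factory=list)
    n_frames: int = 100

    def __post_init__(self) -> None:
        for iface in (1, 2):
            spans = sorted(
                (e.open_frame, e.close_frame if e.close_frame is not None else self.n_frames)
                for e in self.events
                if e.interface == iface
            )
            for (a0, a1), (b0, _) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise ValueError(
                        f"overlapping events on interface {iface} "
                        f"(frames {a0}-{a1} and {b0}-...)"
                    )
        for e in self.events:
            if not (0 <= e.open_frame < self.n_frames):
                raise ValueError("event frames outside trajectory range")
            if e.close_frame is not None and e.close_frame >= self.n_frames:
                raise ValueError("event frames outside trajectory range")


def _arc_angles(params: ToyClampParams, arm: int) -> np.ndarray:
    g = np.radians(params.gap_half_angle)
    n = params.beads_per_arm
    if arm == 1:
        return np.linspace(g, np.pi - g, n)
    return np.linspace(np.pi + g, 2 * np.pi - g, n)


def build_toy_clamp(params: ToyClampParams) -> Structure:
    """Two coplanar semicircular bead arcs forming a ring with two gaps.

    Arm 1 occupies the upper half-plane (chain A, continuous residues
    1..n), arm 2 the lower (chain B, n+1..2n). Interface 1 is the junction
    on the +x axis, interface 2 on the −x axis; the junction bead pairs are
    within 8 Å by default construction.
    """
    n = params.beads_per_arm
    theta = np.concatenate([_arc_angles(params, 1), _arc_angles(params, 2)])
    coords = np.stack(
        [params.radius * np.cos(theta), params.radius * np.sin(theta),
         np.zeros_like(theta)],
        axis=1,
    )
    atoms = bst.AtomArray(2 * n)
    atoms.coord = coords.astype(np.float32)
    atoms.atom_name = np.full(2 * n, "CA")
    atoms.res_name = np.full(2 * n, "GLY")
    atoms.element = np.full(2 * n, "C")
    atoms.chain_id = np.array(["A"] * n + ["B"] * n)
    atoms.res_id = np.concatenate([np.arange(1, n + 1)] * 2)
    atoms.hetero = np.zeros(2 * n, dtype=bool)
    continuous, table, missing = _build_residue_tables(atoms)
    return Structure(atoms, continuous, table, missing)


def interface_groups(params: ToyClampParams, interface: int, n_res: int = 3):
    """Continuous-residue groups flanking one junction of the toy ring.

    Interface 1 (+x) joins the start of arm 1 with the end of arm 2;
    interface 2 (−x) joins the end of arm 1 with the start of arm 2.
    Returns ``(group_arm1, group_arm2)``, each ``n_res`` residues.
    """
    n = params.beads_per_arm
    if interface == 1:
        return list(range(1, n_res + 1)), list(range(2 * n - n_res + 1, 2 * n + 1))
    if interface == 2:
        return list(range(n - n_res + 1, n + 1)), list(range(n + 1, n + n_res + 1))
    raise ValueError("interface must be 1 or 2")


def default_plane_triplets(params: ToyClampParams):
    """Mirror-ordered (first, middle, last) bead triplets of the two arms.

    With this ordering the two oriented normals are antiparallel for the
    coplanar reference ring, so the interplanar angle reads 180° at σ = 0.
    """
    n = params.beads_per_arm
    arm1 = (1, (n + 1) // 2, n)
    arm2 = (2 * n, n + (n + 1) // 2, n + 1)  # reversed traversal sense
    return arm1, arm2


def _hinge_pivot(params: ToyClampParams, opening_interface: int) -> np.ndarray:
    """Midpoint of the junction *opposite* the opening interface."""
    x = params.radius * np.cos(np.radians(params.gap_half_angle))
    return np.array([-x, 0.0, 0.0]) if opening_interface == 1 else np.array([x, 0.0, 0.0])


def _event_angle(event: PlantedEvent, frame: int, n_frames: int) -> float:
    """Linear ramp 0 -> amplitude -> 0 (or hold if unterminated), degrees."""
    close = event.close_frame
    if close is None:
        # ramp up over the same span it would have used, then hold
        span = n_frames - event.open_frame
        mid = event.open_frame + span / 2.0
        if frame < event.open_frame:
            return 0.0
        if frame >= mid:
            return event.amplitude
        return event.amplitude * (frame - event.open_frame) / (mid - event.open_frame)
    if frame <= event.open_frame or frame >= close:
        return 0.0
    mid = (event.open_frame + close) / 2.0
    if frame <= mid:
        return event.amplitude * (frame - event.open_frame) / (mid - event.open_frame)
    return event.amplitude * (close - frame) / (close - mid)


def generate_trajectory(
    params: ToyClampParams, schedule: OpeningSchedule
):
    """Toy-clamp trajectory with planted opening events.

    For an event at interface 1, arm 1 rotates rigidly about the hinge at
    interface 2 (and vice versa): about the z axis for ``in_plane`` mode,
    about the in-plane y axis through the hinge for ``out_of_plane`` mode.
    Gaussian noise σ is added i.i.d. per coordinate per frame. Returns
    ``(Trajectory, schedule)`` — the schedule is the ground truth.
    """
    ref = build_toy_clamp(params)
    n = params.beads_per_arm
    # full-precision base: AtomArray stores float32, the planted geometry is
    # computed in float64 so sigma=0 frames match the scheduled rotations
    base = np.asarray(ref.coords, dtype=np.float64)
    rng = np.random.default_rng(params.seed)
    frames = np.empty((schedule.n_frames, 2 * n, 3))
    arm_slices = {1: slice(0, n), 2: slice(n, 2 * n)}
    for k in range(schedule.n_frames):
        coords = base.copy()
        for event in schedule.events:
            ang = _event_angle(event, k, schedule.n_frames)
            if ang == 0.0:
                continue
            pivot = _hinge_pivot(params, event.interface)
            # the arm adjacent to the opening interface swings; the sign
            # opens the gap (away from the partner arm)
            if event.interface == 1:
                moving, sign = arm_slices[1], +1.0
            else:
                moving, sign = arm_slices[2], +1.0
            if event.mode == "in_plane":
                axis = np.array([0.0, 0.0, 1.0])
            else:
                axis = np.array([0.0, 1.0, 0.0])
            rot = Rotation.from_rotvec(np.radians(sign * ang) * axis)
            coords[moving] = rot.apply(coords[moving] - pivot) + pivot
        if params.noise_sigma > 0:
            coords = coords + rng.normal(0.0, params.noise_sigma, coords.shape)
        frames[k] = coords
    return Trajectory(ref, frames), schedule


def generate_exchange_log(
    n_replicas: int,
    n_steps: int,
    accept_rate: float | None = None,
    planted_paths: np.ndarray | None = None,
    seed: int = 0,
):
    """Synthetic exchange log, either random or realizing given walker paths.

    Random mode: at each step adjacent pairs are attempted with the usual
    alternating even/odd pairing and accepted with probability
    ``accept_rate``. Planted mode: ``planted_paths`` is an
    (n_steps, n_walkers) array of replica indices; consecutive rows may
    differ only by disjoint adjacent transpositions, which become the
    accepted swaps. Returns ``(ExchangeLog, WalkerPath)`` ground truth.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if (accept_rate is None) == (planted_paths is None):
        raise ValueError("give exactly one of accept_rate or planted_paths")
    attempts = []
    if planted_paths is not None:
        paths = np.asarray(planted_paths, dtype=int)
        if not np.array_equal(paths[0], np.arange(n_replicas)):
            raise ValueError("planted paths must start from the identity mapping")
        for t in range(1, paths.shape[0]):
            prev, cur = paths[t - 1], paths[t]
            moved = np.flatnonzero(prev != cur)
            used = set()
            for w in moved:
                if w in used:
                    continue
                a, b = int(prev[w]), int(cur[w])
                if abs(a - b) != 1:
                    raise ValueError(
                        f"walker {w} jumps {a}->{b} at step {t}: not adjacent"
                    )
                partner = np.flatnonzero((prev == b) & (cur == a))
                if len(partner) != 1:
                    raise ValueError(f"step {t}: move of walker {w} is not a swap")
                used.update((int(w), int(partner[0])))
                attempts.append([t, min(a, b), max(a, b), 1])
        log = ExchangeLog(n_replicas, np.array(attempts or np.empty((0, 4))))
        return log, WalkerPath(paths)
    rng = np.random.default_rng(seed)
    replica_of = np.arange(n_replicas)
    path = np.empty((n_steps, n_replicas), dtype=int)
    path[0] = replica_of
    for t in range(1, n_steps):
        start = t % 2  # alternate even/odd adjacent pairings
        for a in range(start, n_replicas - 1, 2):
            accepted = int(rng.random() < accept_rate)
            attempts.append([t, a, a + 1, accepted])
            if accepted:
                wa = int(np.flatnonzero(replica_of == a)[0])
                wb = int(np.flatnonzero(replica_of == a + 1)[0])
                replica_of[wa], replica_of[wb] = a + 1, a
        path[t] = replica_of
    arr = np.array(attempts, dtype=int) if attempts else np.empty((0, 4), dtype=int)
    return ExchangeLog(n_replicas, arr), WalkerPath(path)


def _largest_remainder_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Integer class counts summing to n, by largest-remainder rounding."""
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_walker_cohort(
    n_walkers: int,
    proportions: Sequence[float],
    n_frames: int = 200,
    closed_aperture: float = 5.0,
    open_amplitude: float = 40.0,
    diss_aperture: float = 200.0,
    noise_sigma: float = 1.0,
    out_of_plane_fraction: float = 0.5,
    seed: int = 0,
):
    """Cohort of synthetic per-walker aperture/deviation series.

    ``proportions`` orders the classes (no_opening, reversible, dissociated);
    class counts are fixed by largest-remainder rounding so that stated
    cohort compositions are hit exactly. Reversible walkers get 1–3 complete
    rectangular events per trajectory, one interface at a time: the aperture
    sits at ``closed_aperture + open_amplitude`` from the event's open frame
    up to (but excluding) its close frame, so the planted open/close frames
    coincide with the hysteresis detector's crossing convention. Out-of-plane
    events carry a deviation pulse of 50° over the open frames. Dissociated
    walkers ramp both apertures beyond ``diss_aperture`` and stay there.

    Returns ``(walkers, ground_truth)`` where ``walkers[i]`` is a dict with
    ``aperture1, aperture2, deviation`` arrays and ``ground_truth[i]`` holds
    the planted class and event list.
    """
    counts = _largest_remainder_counts(proportions, n_walkers)
    rng = np.random.default_rng(seed)
    classes = (
        ["no_opening"] * counts[0]
        + ["reversible_opener"] * counts[1]
        + ["dissociated"] * counts[2]
    )
    walkers, truth = [], []
    for wid, cls in enumerate(classes):
        a1 = np.full(n_frames, closed_aperture, dtype=float)
        a2 = np.full(n_frames, closed_aperture, dtype=float)
        dev = np.zeros(n_frames)
        events = []
        if cls == "reversible_opener":
            n_events = int(rng.integers(1, 4))
            # partition the trajectory into equal slots, one event per slot
            slots = np.linspace(0, n_frames, n_events + 1).astype(int)
            for e in range(n_events):
                lo, hi = slots[e] + 5, slots[e + 1] - 5
                width = int(rng.integers(20, max(21, (hi - lo) // 2)))
                width = min(width, hi - lo - 1)
                open_f = int(rng.integers(lo, hi - width))
                close_f = open_f + width
                iface = int(rng.integers(1, 3))
                mode = (
                    "out_of_plane"
                    if rng.random() < out_of_plane_fraction
                    else "in_plane"
                )
                pulse = np.zeros(n_frames)
                pulse[open_f:close_f] = 1.0  # closed again at close_f
                target = a1 if iface == 1 else a2
                target += open_amplitude * pulse
                if mode == "out_of_plane":
                    dev += 50.0 * pulse
                events.append(
                    PlantedEvent(iface, open_f, close_f, open_amplitude, mode)
                )
        elif cls == "dissociated":
            onset = int(rng.integers(10, n_frames // 2))
            ramp = np.clip((np.arange(n_frames) - onset) / 10.0, 0.0, 1.0)
            a1 += diss_aperture * ramp
            a2 += diss_aperture * ramp
        a1 += rng.normal(0.0, noise_sigma, n_frames)
        a2 += rng.normal(0.0, noise_sigma, n_frames)
        dev = np.abs(dev + rng.normal(0.0, 1.0, n_frames))
        walkers.append({"aperture1": a1, "aperture2": a2, "deviation": dev})
        truth.append({"walker_id": wid, "class": cls, "events": events})
    return walkers, truth
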