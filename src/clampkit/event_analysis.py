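"""Opening-event detection, classification and frame clustering.

Ring opening is detected on the per-interface aperture series with a
two-threshold (hysteresis) state machine: an event opens at the first frame
with aperture strictly above ``theta_open`` while the interface is closed,
and closes at the first later frame strictly below ``theta_close``, with
``theta_close < theta_open`` so that noise around a single threshold cannot
chatter. Defaults are ``theta_open = 15`` Å — the smallest opening amplitude
the clamp is reported to reach — and ``theta_close = 10`` Å.

Events are classified *out-of-plane* when the interplanar-angle deviation
exceeds ``phi_threshold`` (default 30°) at any frame during the event, else
*in-plane*; the maximum rather than the mean is used because the mode is
diagnosed by the extreme excursion. Walkers whose both interfaces stay wide
open for a sustained window are flagged *dissociated* — the monomers have
diffused apart and later events are meaningless.

Frame clustering is hierarchical (average linkage by default) on the full
pairwise backbone-RMSD matrix, reporting cluster population fractions and
medoid frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry_metrics import backbone_rmsd
from .structure_io import AtomSelection, Trajectory

__all__ = [
    "EventRecord",
    "WalkerSummary",
    "ClusterResult",
    "detect_events",
    "classify_mode",
    "classify_walker",
    "detect_dissociation",
    "event_statistics",
    "hierarchical_cluster",
    "DEFAULT_THETA_OPEN",
    "DEFAULT_THETA_CLOSE",
    "DEFAULT_PHI_THRESHOLD",
    "DEFAULT_THETA_DISS",
    "DEFAULT_DISS_WINDOW",
]

DEFAULT_THETA_OPEN = 15.0    # Å
DEFAULT_THETA_CLOSE = 10.0   # Å
DEFAULT_PHI_THRESHOLD = 30.0  # degrees
DEFAULT_THETA_DISS = 100.0   # Å
DEFAULT_DISS_WINDOW = 10     # frames


@dataclass
class EventRecord:
    """One opening episode at one interface."""

    interface: str
    open_frame: int
    close_frame: Optional[int]   # None = unterminated at trajectory end
    peak_aperture: float         # Å
    peak_frame: int
    peak_deviation: float = float("nan")  # degrees, filled by classify_mode
    mode: Optional[str] = None   # "in_plane" | "out_of_plane"

    @property
    def complete(self) -> bool:
        return self.close_frame is not None

    @property
    def duration(self) -> Optional[int]:
        return None if self.close_frame is None else self.close_frame - self.open_frame


@dataclass
class WalkerSummary:
    walker_id: int
    complete_events: tuple  # per-interface counts of complete (reversible) events
    unterminated_events: int
    classification: str     # no_opening | reversible_opener | dissociated


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-frame, contiguous from 0
    populations: np.ndarray     # fraction of frames per cluster
    medoids: np.ndarray         # representative frame index per cluster
    linkage_method: str

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def detect_events(
    aperture_series: Sequence[float],
    theta_open: float = DEFAULT_THETA_OPEN,
    theta_close: float = DEFAULT_THETA_CLOSE,
    interface: str = "interface1",
) -> list[EventRecord]:
    """Hysteresis event detection on one aperture series.

    Strict inequalities at both thresholds; values equal to a threshold keep
    the current state. An event still open at the last frame is reported with
    ``close_frame=None`` and is never counted as reversible.
    """
    if not theta_close < theta_open:
        raise ValueError(
            f"theta_close ({theta_close}) must be < theta_open ({theta_open})"
        )
    series = np.asarray(aperture_series, dtype=float)
    events: list[EventRecord] = []
    open_frame = None
    peak = -np.inf
    peak_frame = -1
    for k, a in enumerate(series):
        if open_frame is None:
            if a > theta_open:
                open_frame, peak, peak_frame = k, a, k
        else:
            if a > peak:
                peak, peak_frame = a, k
            if a < theta_close:
                events.append(
                    EventRecord(interface, open_frame, k, float(peak), peak_frame)
                )
                open_frame = None
    if open_frame is not None:
        events.append(
            EventRecord(interface, open_frame, None, float(peak), peak_frame)
        )
    return events


def classify_mode(
    event: EventRecord,
    deviation_series: Sequence[float],
    phi_threshold: float = DEFAULT_PHI_THRESHOLD,
) -> str:
    """Label an event in_plane/out_of_plane from the angular-deviation series.

    Out-of-plane iff the maximum deviation over the event frames is strictly
    greater than ``phi_threshold``; a maximum exactly at the threshold stays
    in-plane. Sets ``event.mode`` and ``event.peak_deviation`` in place and
    returns the mode.
    """
    dev = np.asarray(deviation_series, dtype=float)
    end = event.close_frame if event.close_frame is not None else len(dev) - 1
    if event.open_frame >= len(dev) or end >= len(dev):
        raise IndexError("event frames outside deviation series range")
    peak_dev = float(np.max(dev[event.open_frame : end + 1]))
    event.peak_deviation = peak_dev
    event.mode = "out_of_plane" if peak_dev > phi_threshold else "in_plane"
    return event.mode


def detect_dissociation(
    aperture1: Sequence[float],
    aperture2: Sequence[float],
    theta_diss: float = DEFAULT_THETA_DISS,
    window: int = DEFAULT_DISS_WINDOW,
):
    """Flag irreversible monomer separation.

    Returns ``(flag, onset_frame)`` where the flag is set at the first frame
    starting a run of at least ``window`` consecutive frames with *both*
    apertures above ``theta_diss``; onset is None if never dissociated.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a1 = np.asarray(aperture1, dtype=float)
    a2 = np.asarray(aperture2, dtype=float)
    both = (a1 > theta_diss) & (a2 > theta_diss)
    run = 0
    for k, b in enumerate(both):
        run = run + 1 if b else 0
        if run >= window:
            return True, k - window + 1
    return False, None


def classify_walker(
    walker_id: int,
    events_if1: Sequence[EventRecord],
    events_if2: Sequence[EventRecord],
    dissociated: bool = False,
) -> WalkerSummary:
    """Summarize a walker: dissociation takes precedence over reversibility."""
    complete = (
        sum(1 for e in events_if1 if e.complete),
        sum(1 for e in events_if2 if e.complete),
    )
    unterminated = sum(1 for e in (*events_if1, *events_if2) if not e.complete)
    if dissociated:
        cls = "dissociated"
    elif complete[0] + complete[1] >= 1:
        cls = "reversible_opener"
    else:
        cls = "no_opening"
    return WalkerSummary(walker_id, complete, unterminated, cls)


def event_statistics(summaries: Sequence[WalkerSummary]) -> dict:
    """Aggregate a cohort of walker summaries.

    Returns class fractions (summing to 1), per-interface complete-event
    totals, and counts per class.
    """
    if len(summaries) == 0:
        raise ValueError("no walker summaries")
    n = len(summaries)
    classes = ("no_opening", "reversible_opener", "dissociated")
    counts = {c: sum(1 for s in summaries if s.classification == c) for c in classes}
    return {
        "n_walkers": n,
        "counts": counts,
        "fractions": {c: counts[c] / n for c in classes},
        "complete_events_interface1": sum(s.complete_events[0] for s in summaries),
        "complete_events_interface2": sum(s.complete_events[1] for s in summaries),
        "unterminated_events": sum(s.unterminated_events for s in summaries),
    }


def rmsd_matrix(traj: Trajectory, selection: AtomSelection) -> np.ndarray:
    """Full symmetric pairwise backbone-RMSD matrix over frames, in Å."""
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = backbone_rmsd(
                traj.coords[i], traj.coords[j], selection
            )
    return mat


def hierarchical_cluster(
    traj: Trajectory,
    selection: AtomSelection,
    n_clusters: int | None = None,
    distance_cutoff: float | None = None,
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of frames on the pairwise RMSD matrix.

    Exactly one of ``n_clusters`` / ``distance_cutoff`` must be given.
    Labels are contiguous from 0 in order of decreasing population (ties by
    earliest frame); the medoid of a cluster is its frame with minimal mean
    RMSD to the other members.
    """
    if (n_clusters is None) == (distance_cutoff is None):
        raise ValueError("give exactly one of n_clusters or distance_cutoff")
    if traj.n_frames < 2:
        raise ValueError("clustering needs at least 2 frames")
    if n_clusters is not None and n_clusters > traj.n_frames:
        raise ValueError("more clusters requested than frames")
    mat = rmsd_matrix(traj, selection)
    z = linkage(squareform(mat, checks=False), method=linkage_method)
    if n_clusters is not None:
        raw = fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(z, t=distance_cutoff, criterion="distance")
    # relabel: descending population, ties broken by first occurrence
    ids, counts = np.unique(raw, return_counts=True)
    first = np.array([np.argmax(raw == i) for i in ids])
    order = np.lexsort((first, -counts))
    remap = {ids[o]: rank for rank, o in enumerate(order)}
    labels = np.array([remap[r] for r in raw])
    k = len(ids)
    populations = np.array([(labels == c).mean() for c in range(k)])
    medoids = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        sub = mat[np.ix_(members, members)]
        medoids[c] = members[np.argmin(sub.mean(axis=1))]
    return ClusterResult(labels, populations, medoids, linkage_method)
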