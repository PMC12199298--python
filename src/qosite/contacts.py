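"""Per-frame H-bond / water-bridge detection and contact statistics.

A direct H-bond is formed when the minimum heavy-atom donor-acceptor distance
is strictly below the cutoff (default 0.35 nm; no angular term).  A k-water
bridge is formed when an ordered chain of k distinct water oxygens links
donor to acceptor with every consecutive distance strictly below the cutoff.
Bridge state is defined per frame: a water exchange with an immediate
replacement in the same frame keeps the contact formed.

From per-frame booleans the module derives occupancies, moving averages,
H-bond lifetimes with a gap tolerance, and hydration-count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AtomId,
    AtomSelection,
    Frame,
    ValidationError,
    cross_distances,
    min_group_distance,
)
from .survey import WATER_RESNAMES

__all__ = [
    "ContactSeries",
    "ContactSpec",
    "HydrationProfile",
    "Trajectory",
    "contact_series",
    "detect_bridge",
    "detect_direct",
    "hbond_lifetime",
    "hydration_counts",
    "load_md_trajectory",
    "moving_average",
    "water_oxygens_of",
]


@dataclass(frozen=True)
class ContactSpec:
    """One contact definition: donor/acceptor groups, bridge order, cutoff (nm)."""

    donor: AtomSelection
    acceptor: AtomSelection
    bridge_order: int = 0
    cutoff: float = 0.35
    label: str = ""

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.bridge_order not in (0, 1, 2, 3):
            raise ValidationError("bridge_order must be 0 (direct) to 3")


def water_oxygens_of(frame: Frame) -> AtomSelection:
    """All water oxygen atoms of a frame as a selection."""
    ids = [a for a in frame.atom_ids if a[2] in WATER_RESNAMES and a[3].startswith("O")]
    if not ids:
        raise ValidationError("frame contains no water oxygens")
    return AtomSelection(tuple(ids), label="waters")


def detect_direct(frame: Frame, spec: ContactSpec, box=None) -> bool:
    """True iff the minimum donor-acceptor distance is strictly below cutoff."""
    if spec.bridge_order != 0:
        raise ValidationError("detect_direct requires bridge_order 0")
    return min_group_distance(frame, spec.donor, spec.acceptor, box=box) < spec.cutoff


def detect_bridge(
    frame: Frame, spec: ContactSpec, waters: AtomSelection, box=None
) -> tuple[bool, list[tuple[AtomId, ...]]]:
    """Detect a k-water bridge; returns (formed, list of bridging water chains).

    k = spec.bridge_order >= 1.  Each returned chain is an ordered tuple of k
    distinct water oxygen ids with every consecutive link (donor-w1, w1-w2,
    ..., wk-acceptor) strictly below the cutoff.
    """
    k = spec.bridge_order
    if k < 1:
        raise ValidationError("detect_bridge requires bridge_order >= 1")
    if len(waters) == 0:
        raise ValidationError("empty water selection")
    pw = frame.positions(waters)
    pd_ = cross_distances(frame.positions(spec.donor), pw, box=box).min(axis=0)
    pa = cross_distances(pw, frame.positions(spec.acceptor), box=box).min(axis=1)
    c = spec.cutoff
    if k == 1:
        hits = np.nonzero((pd_ < c) & (pa < c))[0]
        chains = [(waters.atom_ids[i],) for i in hits]
        return bool(chains), chains
    ww = cross_distances(pw, pw, box=box)
    near_donor = np.nonzero(pd_ < c)[0]
    chains = []

    def extend(chain: tuple[int, ...]) -> None:
        if len(chain) == k:
            if pa[chain[-1]] < c:
                chains.append(tuple(waters.atom_ids[i] for i in chain))
            return
        for j in range(len(pw)):
            if j not in chain and ww[chain[-1], j] < c:
                extend(chain + (j,))

    for i in near_donor:
        extend((i,))
    return bool(chains), chains


@dataclass
class Trajectory:
    """A sequence of frames at uniform spacing dt (ns)."""

    frames: Sequence[Frame]
    dt: float
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValidationError("trajectory needs at least one frame")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.times is not None:
            diffs = np.diff(np.asarray(self.times, dtype=float))
            if len(diffs) and not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-12):
                raise ValidationError("non-uniform frame spacing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ContactSeries:
    """Per-frame formation record for one contact, with summary statistics."""

    formed: np.ndarray
    dt: float
    spec: ContactSpec | None = None
    bridging: list[list[tuple[AtomId, ...]]] | None = None

    def __post_init__(self) -> None:
        self.formed = np.asarray(self.formed, dtype=bool)
        if self.dt <= 0:
            raise ValidationError("dt must be positive")

    @property
    def occupancy(self) -> float:
        """Fraction of frames in which the contact is formed."""
        return float(self.formed.mean())

    def lifetimes(self, gap_tolerance: float | None = None) -> np.ndarray:
        """Durations (ns) of maximal formed runs, merging gaps <= gap_tolerance.

        The default tolerance is one frame interval.  A merged event's
        duration spans first to last formed frame inclusive.
        """
        if gap_tolerance is None:
            gap_tolerance = self.dt
        max_gap_frames = int(np.floor(gap_tolerance / self.dt + 1e-9))
        idx = np.nonzero(self.formed)[0]
        if len(idx) == 0:
            return np.empty(0)
        breaks = np.nonzero(np.diff(idx) > max_gap_frames + 1)[0]
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        return (ends - starts + 1) * self.dt

    def moving_average(self, window: float = 1.0) -> np.ndarray:
        """Rectangular moving average (window in ns), centred, edges truncated."""
        return moving_average(self.formed.astype(float), self.dt, window)

    def summary(self, gap_tolerance: float | None = None) -> dict:
        lt = self.lifetimes(gap_tolerance)
        return {
            "label": self.spec.label if self.spec else "",
            "occupancy": self.occupancy,
            "n_frames": int(len(self.formed)),
            "n_events": int(len(lt)),
            "mean_lifetime_ns": float(lt.mean()) if len(lt) else 0.0,
        }


def load_md_trajectory(
    topology: str, trajectory: str | None = None, dt: float | None = None, selection: str = "all"
) -> Trajectory:
    """Load a trajectory from standard MD formats into in-memory frames.

    ``topology`` is a PDB/GRO (or similar) file naming atoms; ``trajectory``
    an optional XTC/TRR/DCD/multi-model file.  Coordinates convert from
    Angstrom to nm; ``dt`` (ns) overrides the file's frame spacing.  Atom ids
    become (chain or segid, resid, resname, atom name).
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    group = u.select_atoms(selection)
    ids: list[AtomId] = []
    for atom in group:
        chain = getattr(atom, "chainID", "") or atom.segid or "A"
        ids.append((str(chain), int(atom.resid), str(atom.resname), str(atom.name)))
    frames = []
    times = []
    for ts in u.trajectory:
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            import MDAnalysis.lib.mdamath as mdamath

            box = mdamath.triclinic_vectors(ts.dimensions) * 0.1
        frames.append(Frame(list(ids), group.positions * 0.1, box=box))
        times.append(ts.time * 1e-3)  # ps -> ns
    if dt is None:
        dt = float(times[1] - times[0]) if len(times) > 1 and times[1] > times[0] else 1e-3
    return Trajectory(frames=frames, dt=dt, times=np.asarray(times) if len(set(times)) == len(times) else None)


def moving_average(x: np.ndarray, dt: float, window: float) -> np.ndarray:
    """Centred rectangular moving average; truncated windows at the edges.

    The window length in frames is round(window/dt), at least 1.  Each output
    value is the mean over the frames actually inside the (possibly truncated)
    window, so the frame-count-weighted mean of the output equals the mean of
    the input exactly.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    w = max(1, int(round(window / dt)))
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window=w, center=True, min_periods=1).mean().to_numpy()


def contact_series(traj: Trajectory, spec: ContactSpec, waters: AtomSelection | None = None, box=None) -> ContactSeries:
    """Evaluate one contact over a trajectory.

    For bridged contacts (bridge_order >= 1) a water selection is required;
    the per-frame bridging water chains are retained on the result.
    """
    if len(traj) < 2:
        raise ValidationError("contact series needs at least two frames")
    formed = np.empty(len(traj), dtype=bool)
    bridging: list[list[tuple[AtomId, ...]]] | None = None
    if spec.bridge_order == 0:
        for i, frame in enumerate(traj.frames):
            formed[i] = detect_direct(frame, spec, box=box)
    else:
        if waters is None:
            raise ValidationError("bridged contacts need a water selection")
        bridging = []
        for i, frame in enumerate(traj.frames):
            ok, chains = detect_bridge(frame, spec, waters, box=box)
            formed[i] = ok
            bridging.append(chains)
    return ContactSeries(formed=formed, dt=traj.dt, spec=spec, bridging=bridging)


def hbond_lifetime(series: ContactSeries, gap_tolerance: float | None = None) -> float:
    """Mean H-bond lifetime (ns); 0 (with a warning) when never formed."""
    lt = series.lifetimes(gap_tolerance)
    if len(lt) == 0:
        import warnings

        warnings.warn("contact never formed; lifetime defined as 0", stacklevel=2)
        return 0.0
    return float(lt.mean())


@dataclass
class HydrationProfile:
    """Per-frame counts of waters within H-bond distance of a centre group."""

    label: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def min(self) -> int:
        return int(self.counts.min())

    @property
    def median(self) -> float:
        return float(np.median(self.counts))

    @property
    def max(self) -> int:
        return int(self.counts.max())


def hydration_counts(
    traj: Trajectory | Iterable[Frame],
    center: AtomSelection,
    waters: AtomSelection,
    cutoff: float = 0.35,
    box=None,
    label: str = "",
) -> HydrationProfile:
    """Count distinct water oxygens within cutoff of any centre atom, per frame."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if len(waters) == 0:
        raise ValidationError("empty water selection")
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    counts = np.empty(len(frames), dtype=int)
    for i, frame in enumerate(frames):
        d = cross_distances(frame.positions(waters), frame.positions(center), box=box)
        counts[i] = int(np.sum(d.min(axis=1) < cutoff))
    return HydrationProfile(label=label or (center.label or "center"), counts=counts)
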