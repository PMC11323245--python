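"""Core geometric model of protein tunnels and water transport events.

A tunnel in one trajectory frame is a chain of spheres along a centerline,
ordered from the buried active-site end (index 0) to the protein surface.
A transport event is the passage of one water molecule through a tunnel
over a contiguous range of frames.  In each frame the migrating water is
assigned to the closest tunnel sphere (its *event sphere*); the smallest
event sphere over the whole passage is the *minimal event sphere*, whose
radius is the effective constriction the water squeezed through.

Distances and radii are in angstroms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TunnelSphere",
    "TunnelSnapshot",
    "TransportEvent",
    "EventSphereTrace",
    "MinimalEventSphere",
    "VdwTable",
    "BONDI_RADII",
    "assign_frame_sphere",
    "trace_event",
    "minimal_event_sphere",
    "surface_surface_distance",
    "classify_narrow",
]

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (angstrom) for the elements that occur in
#: protein/water systems.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
}


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"coordinates must be finite, got {a}")
    return a


@dataclass(frozen=True)
class TunnelSphere:
    """One sphere of a tunnel centerline."""

    index: int
    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        if self.index < 0:
            raise ValueError(f"sphere index must be >= 0, got {self.index}")
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")


class TunnelSnapshot:
    """One tunnel in one frame: ordered spheres from active site to surface.

    Sphere data are stored as arrays (``centers`` of shape (n, 3) and
    ``radii`` of shape (n,)) for efficiency; :meth:`sphere` and
    :attr:`spheres` give the per-sphere view.
    """

    __slots__ = ("frame_id", "tunnel_id", "indices", "centers", "radii")

    def __init__(self, frame_id: int, tunnel_id: str, centers, radii,
                 indices=None):
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        radii = np.asarray(radii, dtype=float).reshape(-1)
        if centers.shape[0] == 0:
            raise ValueError("no spheres")
        if centers.shape[0] != radii.shape[0]:
            raise ValueError("centers and radii length mismatch")
        if not np.all(radii > 0):
            raise ValueError("all sphere radii must be > 0")
        if indices is None:
            indices = np.arange(len(radii))
        else:
            indices = np.asarray(indices, dtype=int).reshape(-1)
            if np.any(np.diff(indices) <= 0):
                raise ValueError("sphere indices must be strictly increasing")
        self.frame_id = int(frame_id)
        self.tunnel_id = str(tunnel_id)
        self.indices = indices
        self.centers = centers
        self.radii = radii

    @classmethod
    def from_spheres(cls, frame_id: int, tunnel_id: str,
                     spheres: Sequence[TunnelSphere]) -> "TunnelSnapshot":
        spheres = list(spheres)
        if not spheres:
            raise ValueError("no spheres")
        return cls(
            frame_id, tunnel_id,
            centers=[s.center for s in spheres],
            radii=[s.radius for s in spheres],
            indices=[s.index for s in spheres],
        )

    @property
    def n_spheres(self) -> int:
        return len(self.radii)

    def sphere(self, position: int) -> TunnelSphere:
        """Sphere at array position ``position`` (not centerline index)."""
        return TunnelSphere(int(self.indices[position]),
                            self.centers[position],
                            float(self.radii[position]))

    @property
    def spheres(self) -> list[TunnelSphere]:
        return [self.sphere(i) for i in range(self.n_spheres)]

    @property
    def bottleneck_radius(self) -> float:
        """Smallest sphere radius along the tunnel in this frame."""
        return float(self.radii.min())

    @property
    def endpoint(self) -> np.ndarray:
        """Center of the highest-index sphere (the surface end)."""
        return self.centers[-1]

    def __repr__(self):
        return (f"TunnelSnapshot(frame={self.frame_id}, "
                f"tunnel={self.tunnel_id!r}, n_spheres={self.n_spheres})")


@dataclass
class TransportEvent:
    """Passage of one water molecule through the protein.

    Parameters
    ----------
    frames
        Strictly increasing frame ids covering the event.
    oxygen
        Water-oxygen position per frame, shape (n_frames, 3).
    hydrogens
        Optional water-hydrogen positions per frame, shape (n_frames, 2, 3).
    direction
        ``"inflow"`` (surface to active site) or ``"outflow"``; ``None``
        when unknown.
    matched_tunnels
        Per-frame sets of tunnel labels the water was matched to by the
        upstream tracking tool; used by the 70%-of-duration assignment rule.
    """

    event_id: str
    water_id: str
    frames: np.ndarray
    oxygen: np.ndarray
    hydrogens: np.ndarray | None = None
    direction: str | None = None
    matched_tunnels: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int).reshape(-1)
        if self.frames.size == 0:
            raise ValueError("event must cover at least one frame")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("event frames must be strictly increasing")
        self.oxygen = np.asarray(self.oxygen, dtype=float).reshape(-1, 3)
        if self.oxygen.shape[0] != self.frames.size:
            raise ValueError("one oxygen position required per frame")
        if self.hydrogens is not None:
            self.hydrogens = np.asarray(self.hydrogens, dtype=float)
            if self.hydrogens.shape != (self.frames.size, 2, 3):
                raise ValueError("hydrogens must have shape (n_frames, 2, 3)")
        if self.direction not in (None, "inflow", "outflow"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.matched_tunnels and len(self.matched_tunnels) != self.frames.size:
            raise ValueError("matched_tunnels must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    def frame_position(self, frame_id: int) -> int:
        pos = int(np.searchsorted(self.frames, frame_id))
        if pos >= self.frames.size or self.frames[pos] != frame_id:
            raise KeyError(f"event {self.event_id} has no frame {frame_id}")
        return pos


@dataclass
class EventSphereTrace:
    """Per-frame event-sphere assignment of one transport event.

    One entry per usable frame (a frame with a tunnel snapshot); at most
    one event sphere per frame.
    """

    event_id: str
    frame_ids: np.ndarray
    sphere_indices: np.ndarray
    sphere_radii: np.ndarray
    center_distances: np.ndarray
    water_positions: np.ndarray
    skipped_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.frame_ids = np.asarray(self.frame_ids, dtype=int).reshape(-1)
        self.sphere_indices = np.asarray(self.sphere_indices, dtype=int).reshape(-1)
        self.sphere_radii = np.asarray(self.sphere_radii, dtype=float).reshape(-1)
        self.center_distances = np.asarray(self.center_distances, dtype=float).reshape(-1)
        self.water_positions = np.asarray(self.water_positions, dtype=float).reshape(-1, 3)
        n = self.frame_ids.size
        if not (self.sphere_indices.size == self.sphere_radii.size
                == self.center_distances.size == self.water_positions.shape[0] == n):
            raise ValueError("trace arrays must have equal length")
        if len(np.unique(self.frame_ids)) != n:
            raise ValueError("at most one event sphere per frame")

    def __len__(self):
        return int(self.frame_ids.size)


@dataclass
class MinimalEventSphere:
    """The smallest event sphere encountered over a transport event."""

    event_id: str
    radius: float
    sphere_index: int
    minimal_frames: np.ndarray
    water_positions: np.ndarray

    def __post_init__(self):
        self.minimal_frames = np.asarray(self.minimal_frames, dtype=int).reshape(-1)
        self.water_positions = np.asarray(self.water_positions, dtype=float).reshape(-1, 3)
        if self.minimal_frames.size == 0:
            raise ValueError("minimal_frames must be non-empty")


class VdwTable:
    """Van der Waals radii by element symbol (angstrom).

    Defaults to the Bondi set; pass a mapping to override or extend.
    Element lookup is case-insensitive.
    """

    def __init__(self, radii: Mapping[str, float] | None = None):
        table = dict(BONDI_RADII)
        if radii is not None:
            table.update({str(k).upper(): float(v) for k, v in radii.items()})
        if not all(v > 0 for v in table.values()):
            raise ValueError("all van der Waals radii must be > 0")
        self._radii = table

    def __call__(self, element: str) -> float:
        try:
            return self._radii[str(element).upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {element!r}") from None

    def __contains__(self, element: str) -> bool:
        return str(element).upper() in self._radii

    def as_dict(self) -> dict[str, float]:
        return dict(self._radii)


def assign_frame_sphere(water_pos, snapshot: TunnelSnapshot) -> int:
    """Assign a water position to the closest tunnel sphere.

    "Closest" is the smallest Euclidean distance from the water oxygen to
    the sphere *center* (radius-independent).  Ties break to the lowest
    centerline index.

    Returns the centerline index of the assigned sphere.
    """
    if snapshot.n_spheres == 0:  # pragma: no cover - unconstructible
        raise ValueError("no spheres")
    water_pos = _as_point(water_pos)
    d2 = np.einsum("ij,ij->i", snapshot.centers - water_pos,
                   snapshot.centers - water_pos)
    # argmin returns the first minimum; indices are strictly increasing,
    # so ties resolve to the lowest centerline index.
    return int(snapshot.indices[int(np.argmin(d2))])


def trace_event(event: TransportEvent,
                snapshots: Mapping[int, TunnelSnapshot]) -> EventSphereTrace:
    """Assign the water to one event sphere in every usable frame.

    ``snapshots`` maps frame id to the tunnel's snapshot in that frame.
    Frames without a snapshot are skipped (recorded in
    ``trace.skipped_frames`` and logged); tunnel-detection tools
    legitimately miss a tunnel in some frames.

    Raises
    ------
    ValueError
        If no frame of the event has a snapshot.
    """
    frame_ids, sphere_idx, sphere_r, dists, positions = [], [], [], [], []
    skipped: list[int] = []
    for pos, frame in enumerate(event.frames):
        snap = snapshots.get(int(frame))
        if snap is None:
            skipped.append(int(frame))
            continue
        water = event.oxygen[pos]
        idx = assign_frame_sphere(water, snap)
        at = int(np.searchsorted(snap.indices, idx))
        frame_ids.append(int(frame))
        sphere_idx.append(idx)
        sphere_r.append(float(snap.radii[at]))
        dists.append(float(np.linalg.norm(water - snap.centers[at])))
        positions.append(water)
    if skipped:
        logger.debug("event %s: skipped %d frame(s) without snapshot: %s",
                     event.event_id, len(skipped), skipped)
    if not frame_ids:
        raise ValueError(f"event {event.event_id} untraceable: "
                         "no frame has a tunnel snapshot")
    return EventSphereTrace(
        event_id=event.event_id,
        frame_ids=np.array(frame_ids),
        sphere_indices=np.array(sphere_idx),
        sphere_radii=np.array(sphere_r),
        center_distances=np.array(dists),
        water_positions=np.array(positions),
        skipped_frames=skipped,
    )


def minimal_event_sphere(trace: EventSphereTrace,
                         tol: float = 1e-9) -> MinimalEventSphere:
    """Extract the minimal event sphere from an event-sphere trace.

    The radius is the minimum assigned sphere radius over the event;
    ``minimal_frames`` collects every frame whose assigned radius equals
    that minimum within ``tol``.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    rmin = float(trace.sphere_radii.min())
    at = trace.sphere_radii <= rmin + tol
    first = int(np.argmax(at))
    return MinimalEventSphere(
        event_id=trace.event_id,
        radius=rmin,
        sphere_index=int(trace.sphere_indices[first]),
        minimal_frames=trace.frame_ids[at],
        water_positions=trace.water_positions[at],
    )


def surface_surface_distance(water_oxygen,
                             protein_atoms: Iterable[tuple] | tuple,
                             vdw: VdwTable | None = None) -> float:
    """Minimum surface-to-surface distance from a water oxygen to protein.

    For each protein atom the surface distance is the center distance minus
    both van der Waals radii; the minimum over atoms is returned.  A
    negative value signals steric overlap between the water and the
    protein — the signature of transport through a space formally too
    narrow for a water molecule.

    ``protein_atoms`` is an iterable of ``(position, element)`` pairs, or a
    pre-packed ``(positions_array, elements_sequence)`` tuple.
    """
    if vdw is None:
        vdw = VdwTable()
    water_oxygen = _as_point(water_oxygen)
    r_water = vdw("O")
    if isinstance(protein_atoms, tuple) and len(protein_atoms) == 2 and \
            isinstance(protein_atoms[0], np.ndarray):
        positions, elements = protein_atoms
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    else:
        pairs = list(protein_atoms)
        if not pairs:
            raise ValueError("at least one protein atom required")
        positions = np.array([_as_point(p) for p, _ in pairs])
        elements = [e for _, e in pairs]
    if positions.shape[0] == 0:
        raise ValueError("at least one protein atom required")
    radii = np.array([vdw(e) for e in elements])
    d = np.linalg.norm(positions - water_oxygen, axis=1)
    return float(np.min(d - r_water - radii))


def classify_narrow(mes: MinimalEventSphere | float,
                    threshold: float = 1.4) -> bool:
    """Is this a narrow-tunnel transport event?

    True iff the minimal event sphere radius is strictly below
    ``threshold`` (default 1.4 angstrom, the conventional radius of a
    water molecule); an exactly-threshold radius is *not* narrow.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    radius = mes.radius if isinstance(mes, MinimalEventSphere) else float(mes)
    return radius < threshold
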