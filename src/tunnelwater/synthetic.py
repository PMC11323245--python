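"""Synthetic tunnels, lining atoms, and water passages with ground truth.

Every downstream stage of the pipeline is testable without trajectory
data: tunnels are generated as sphere chains with a controlled bottleneck
radius, water passages walk the centerline with truncated lateral noise,
and hydrogen-bond partners are constructed analytically to satisfy the
geometric criteria with margin (donor-acceptor distance 2.9 A, vertex
angle 165 degrees), so detection counts can be checked against the
manifest exactly.

The generator emulates the *shape* of tunnel-profile and water-tracking
outputs, not any particular protein: numbers echoing published systems
(a ~20% narrow share, bimodal radius peaks near 1.15 and 1.65 A) are
generator targets chosen to exercise the statistics, not reproductions
of molecular-dynamics results.

Simulations are independent replicas: each gets a disjoint block of
global frame ids, its own tunnels, and its own events.  Within one
tunnel every event receives a unique bottleneck frame, so the planted
H-bond partners of different events never interfere.  Partner groups are
mobile: away from their event's bottleneck frame they are parked far
outside the system (beyond any interaction cutoff), which keeps the atom
count constant across frames for multi-model PDB export.  Simulation
replicas are offset in space so all their atoms can coexist in one
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import TransportEvent, TunnelSnapshot
from .hbonds import AtomRecord, hbond_angle
from .network import TunnelEndpoint

__all__ = [
    "TunnelSpec",
    "PassageSpec",
    "ManifestEntry",
    "SyntheticBundle",
    "generate_tunnel",
    "generate_lining_atoms",
    "plant_hbond_partners",
    "generate_passages",
    "scenario_clean",
    "scenario_bimodal",
    "generate_endpoint_blobs",
]

#: frames per simulation are offset by this block size to keep one global
#: frame space across simulations
FRAME_BLOCK = 1000

_D_OH = 0.9572      # water O-H bond length, A
_HOH = 104.52       # water H-O-H angle, degrees
_D_PLANT = 2.9      # planted donor-acceptor heavy distance, A
_ANGLE_PLANT = 165.0  # planted vertex angle, degrees
_L_NH = 1.01        # amide N-H length, A
_L_CO = 1.23        # carbonyl C=O length, A
PARK_SHIFT = np.array([0.0, 0.0, 5000.0])  # parking for inactive partners
SIM_SPACING = 200.0  # angstrom between simulation replicas in space
_MIN_RADIUS = 0.05  # radii are clamped here after wobble, A


@dataclass
class TunnelSpec:
    """Geometry of one synthetic tunnel over time.

    The radius profile is a V shape: ``end_radius`` at both ends tapering
    linearly to the bottleneck radius ``r_star`` at ``bottleneck_index``,
    so the bottleneck is a strict minimum with a definite gap to its
    neighbours.  Per-frame radius wobble is i.i.d. Gaussian per sphere.
    """

    tunnel_id: str = "T1"
    n_spheres: int = 21
    spacing: float = 0.8
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    curvature: float = 0.0   # radians of gentle bend over the full length
    end_radius: float = 2.5
    r_star: float = 1.65
    bottleneck_index: int | None = None  # default: middle sphere
    radius_wobble: float = 0.02
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_spheres < 2:
            raise ValueError("need at least 2 spheres")
        if not self.spacing > 0:
            raise ValueError(f"invalid geometry: spacing must be > 0, "
                             f"got {self.spacing}")
        if not (0 < self.r_star <= self.end_radius):
            raise ValueError("require 0 < r_star <= end_radius")
        if self.bottleneck_index is None:
            self.bottleneck_index = self.n_spheres // 2


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _frame_basis(axis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(t, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(t, helper))
    v = np.cross(t, u)
    return t, u, v


def _centerline(spec: TunnelSpec) -> np.ndarray:
    t, u, _ = _frame_basis(spec.axis)
    s = np.arange(spec.n_spheres) * spec.spacing
    pts = np.asarray(spec.origin, dtype=float) + np.outer(s, t)
    if spec.curvature:
        # smooth lateral bow, zero at both ends
        length = s[-1] if s[-1] else 1.0
        bow = math.tan(spec.curvature) * length / 4.0
        pts = pts + np.outer(bow * np.sin(np.pi * s / length), u)
    return pts


def _radius_profile(spec: TunnelSpec) -> np.ndarray:
    i = np.arange(spec.n_spheres)
    b = spec.bottleneck_index
    half = np.maximum(np.where(i < b, b, spec.n_spheres - 1 - b), 1)
    frac = np.abs(i - b) / half
    return spec.r_star + (spec.end_radius - spec.r_star) * frac


def generate_tunnel(spec: TunnelSpec,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[TunnelSnapshot], list[TunnelEndpoint]]:
    """Generate per-frame snapshots (and endpoints) for one tunnel.

    Sphere centers are static; radii get i.i.d. Gaussian wobble per
    sphere per frame (clamped at 0.05 A).  Deterministic given the spec
    seed (or a supplied generator).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    centers = _centerline(spec)
    profile = _radius_profile(spec)
    snapshots, endpoints = [], []
    for frame in range(spec.n_frames):
        radii = profile.copy()
        if spec.radius_wobble > 0:
            radii = radii + rng.normal(0.0, spec.radius_wobble,
                                       size=radii.shape)
        radii = np.maximum(radii, _MIN_RADIUS)
        snap = TunnelSnapshot(frame, spec.tunnel_id, centers, radii)
        snapshots.append(snap)
        endpoints.append(TunnelEndpoint.from_snapshot(snap))
    return snapshots, endpoints


def generate_lining_atoms(snapshot: TunnelSnapshot,
                          donor_density: float,
                          seed: int = 0,
                          residue_start: int = 1,
                          chain_id: str = "L") -> list[AtomRecord]:
    """Backbone-like N-H and C=O groups on the tunnel wall.

    ``donor_density`` is groups per angstrom of centerline (alternating
    amide and carbonyl).  Groups sit on the wall (sphere radius plus a
    carbon van der Waals radius from the centerline) with the hydrogen /
    carbonyl oxygen pointing *outward*, so they line the tunnel without
    satisfying the bond criteria toward an on-axis water by construction.
    """
    if donor_density < 0:
        raise ValueError(f"density must be >= 0, got {donor_density}")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    if donor_density == 0 or snapshot.n_spheres < 2:
        return atoms
    length = float(np.sum(np.linalg.norm(np.diff(snapshot.centers, axis=0),
                                         axis=1)))
    n_groups = max(1, int(round(donor_density * length)))
    res_id = residue_start
    for g in range(n_groups):
        s = (g + 0.5) / n_groups * (snapshot.n_spheres - 1)
        i = int(s)
        frac = s - i
        center = (1 - frac) * snapshot.centers[i] \
            + frac * snapshot.centers[min(i + 1, snapshot.n_spheres - 1)]
        radius = (1 - frac) * snapshot.radii[i] \
            + frac * snapshot.radii[min(i + 1, snapshot.n_spheres - 1)]
        local_axis = snapshot.centers[min(i + 1, snapshot.n_spheres - 1)] \
            - snapshot.centers[max(i - 1, 0)]
        _, u, v = _frame_basis(local_axis)
        phi = rng.uniform(0, 2 * np.pi)
        outward = math.cos(phi) * u + math.sin(phi) * v
        wall = center + (radius + 1.7) * outward
        if g % 2 == 0:
            atoms.append(AtomRecord("N", "N", "GLY", res_id, chain_id, wall))
            atoms.append(AtomRecord("H", "H", "GLY", res_id, chain_id,
                                    wall + _L_NH * outward))
        else:
            atoms.append(AtomRecord("C", "C", "GLY", res_id, chain_id, wall))
            atoms.append(AtomRecord("O", "O", "GLY", res_id, chain_id,
                                    wall + _L_CO * outward))
        res_id += 1
    return atoms


def _wall_scaffold(spec: TunnelSpec, centers: np.ndarray,
                   profile: np.ndarray, n_ring: int = 6,
                   chain_id: str = "A",
                   residue_start: int = 1) -> list[AtomRecord]:
    """Static ring of side-chain carbons around each sphere, at the
    distance where a CAVER-like sphere touches the atom surface."""
    _, u, v = _frame_basis(spec.axis)
    atoms = []
    res_id = residue_start
    for i in range(len(centers)):
        wall_r = profile[i] + 1.7
        for j in range(n_ring):
            phi = 2 * np.pi * (j + 0.5 * (i % 2)) / n_ring
            pos = centers[i] + wall_r * (math.cos(phi) * u
                                         + math.sin(phi) * v)
            atoms.append(AtomRecord("CB", "C", "ALA", res_id, chain_id, pos))
            res_id += 1
    return atoms


# partner-group recipes: (kind, residue, heavy atom, classification notes)
_ACCEPTOR_RECIPES = [("GLY", "O", "C"),    # backbone carbonyl
                     ("SER", "OG", "CB"),  # polar side chain
                     ("ASP", "OD1", "CG")]  # negative side chain
_DONOR_RECIPES = [("GLY", "N", "H"),       # backbone amide
                  ("LYS", "NZ", "HZ1")]    # positive side chain


def plant_hbond_partners(water_o, axis, n_bonds: int,
                         residue_start: int = 1,
                         chain_id: str = "P",
                         variety: int = 0,
                         ) -> tuple[list[AtomRecord], np.ndarray]:
    """Construct partner atoms forming exactly ``n_bonds`` hydrogen bonds.

    Water hydrogens are oriented in the plane perpendicular to the travel
    ``axis``; up to two bonds are water-as-donor toward planted acceptors
    (at 165 degrees through each hydrogen) and the rest water-as-acceptor
    from planted donor groups, all at heavy-atom distance 2.9 A.  At most
    5 bonds (2 acceptors + 3 donors) can be planted.

    ``variety`` cycles the partner residue types so classification tests
    see backbone and side-chain chemistry.

    Returns the partner atom records and the two water-hydrogen
    positions; the construction is self-checked against the geometric
    criteria with margin.
    """
    if not 0 <= n_bonds <= 5:
        raise ValueError("can plant between 0 and 5 bonds")
    water_o = np.asarray(water_o, dtype=float).reshape(3)
    t, u, v = _frame_basis(axis)
    half = math.radians(_HOH / 2)
    h_dirs = [math.cos(half) * u + math.sin(half) * v,
              math.cos(half) * u - math.sin(half) * v]
    water_h = np.array([water_o + _D_OH * d for d in h_dirs])

    atoms: list[AtomRecord] = []
    res_id = residue_start
    theta = math.radians(_ANGLE_PLANT)

    n_acc = min(n_bonds, 2)
    planted: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i in range(n_acc):
        h_dir, normal = h_dirs[i], (t if i == 0 else -t)
        w = math.cos(theta) * (-h_dir) + math.sin(theta) * normal
        b = 2 * _D_OH * float(np.dot(h_dir, w))
        c = _D_OH ** 2 - _D_PLANT ** 2
        step = (-b + math.sqrt(b * b - 4 * c)) / 2
        acc = water_o + _D_OH * h_dir + step * w
        res, acc_name, anchor_name = _ACCEPTOR_RECIPES[
            (variety + i) % len(_ACCEPTOR_RECIPES)]
        anchor = acc + _L_CO * _unit(acc - water_o)
        elem = acc_name[0]
        atoms.append(AtomRecord(acc_name, elem, res, res_id, chain_id, acc))
        atoms.append(AtomRecord(anchor_name, anchor_name[0], res, res_id,
                                chain_id, anchor))
        planted.append((water_o, water_h[i], acc))
        res_id += 1

    donor_dirs = [-u,
                  _unit(-u + t),
                  _unit(-u - t)]
    for j in range(n_bonds - n_acc):
        d_hat = donor_dirs[j]
        e_hat = v if j == 0 else _unit(np.cross(d_hat, v))
        n_pos = water_o + _D_PLANT * d_hat

        def angle_err(phi):
            m = math.cos(phi) * (-d_hat) + math.sin(phi) * e_hat
            h_pos = n_pos + _L_NH * m
            return hbond_angle(n_pos, h_pos, water_o) - _ANGLE_PLANT

        phi = brentq(angle_err, 0.0, 1.2)
        m = math.cos(phi) * (-d_hat) + math.sin(phi) * e_hat
        h_pos = n_pos + _L_NH * m
        res, don_name, h_name = _DONOR_RECIPES[
            (variety + j) % len(_DONOR_RECIPES)]
        atoms.append(AtomRecord(don_name, "N", res, res_id, chain_id, n_pos))
        atoms.append(AtomRecord(h_name, "H", res, res_id, chain_id, h_pos))
        planted.append((n_pos, h_pos, water_o))
        res_id += 1

    for d_pos, h_pos, a_pos in planted:
        dist = float(np.linalg.norm(a_pos - d_pos))
        ang = hbond_angle(d_pos, h_pos, a_pos)
        if not (dist <= 3.4 and ang >= 150.0):  # margin below 3.5 / 135
            raise RuntimeError("planted bond lost its safety margin")
    return atoms, water_h


@dataclass
class PassageSpec:
    """Population of synthetic water passages.

    ``narrow_fraction`` routes events through the narrow tunnel of each
    simulation (when one exists); ``bond_intercept``/``bond_slope`` set
    the planted per-event bond count ``round(intercept - slope * r*)``
    plus Gaussian noise, clipped to [0, 5] — a decreasing function of the
    bottleneck radius.  ``unassigned_fraction`` of events get tunnel
    match flags on only half their frames, so the 70% duration rule
    leaves them unassigned.
    """

    n_events: int = 1000
    lateral_noise: float = 0.08
    narrow_fraction: float = 0.2
    bond_intercept: float = 4.35
    bond_slope: float = 2.0
    bond_noise: float = 0.6
    unassigned_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("need at least 1 event")
        if not 0 <= self.narrow_fraction <= 1:
            raise ValueError("narrow_fraction must be in [0, 1]")


@dataclass
class ManifestEntry:
    """Ground truth for one generated event."""

    event_id: str
    sim_id: str
    tunnel_id: str
    planted_min_radius: float
    planted_bond_counts: list[int]
    bottleneck_frame: int
    direction: str
    assignable: bool


@dataclass
class SyntheticBundle:
    """Everything a pipeline run needs, plus the ground-truth manifest."""

    snapshots: list[TunnelSnapshot]
    events: list[TransportEvent]
    manifest: dict[str, ManifestEntry]
    scaffold_by_sim: dict[str, list[AtomRecord]]
    partners_by_frame: dict[int, list[AtomRecord]]
    sim_of_event: dict[str, str]
    seed: int
    scenario: str = "custom"

    @staticmethod
    def sim_of_frame(frame_id: int) -> str:
        """Simulation replica a global frame id belongs to."""
        return f"S{frame_id // FRAME_BLOCK:02d}"

    def snapshots_by_key(self) -> dict[tuple[str, int], TunnelSnapshot]:
        return {(s.tunnel_id, s.frame_id): s for s in self.snapshots}

    def snapshots_by_sim(self) -> dict[str, list[TunnelSnapshot]]:
        out: dict[str, list[TunnelSnapshot]] = {}
        for snap in self.snapshots:
            out.setdefault(self.sim_of_frame(snap.frame_id),
                           []).append(snap)
        return out

    def protein_atoms(self, frame_id: int,
                      sim_id: str | None = None) -> list[AtomRecord]:
        """Protein atoms visible in one frame: the static wall scaffold of
        that frame's simulation plus the partner groups active there."""
        sim_id = sim_id or self.sim_of_frame(frame_id)
        return (self.scaffold_by_sim.get(sim_id, [])
                + self.partners_by_frame.get(frame_id, []))


def generate_passages(tunnels: Mapping[str, tuple[TunnelSpec, list[TunnelSnapshot]]],
                      spec: PassageSpec,
                      rng: np.random.Generator,
                      sim_id: str,
                      frame_base: int,
                      event_start: int = 0,
                      ) -> tuple[list[TransportEvent], dict[str, ManifestEntry],
                                 dict[int, list[AtomRecord]]]:
    """Generate water passage events through already-generated tunnels.

    Each event walks one tunnel's centerline, one sphere per frame, with
    truncated lateral noise (the water stays well inside the local
    sphere, so the closest-sphere assignment recovers the planted path).
    Bottleneck frames are unique per tunnel; hydrogen-bond partners are
    planted at each event's bottleneck frame only.
    """
    tunnel_ids = sorted(tunnels)
    if not tunnel_ids:
        raise ValueError("need at least one tunnel")
    any_spec = tunnels[tunnel_ids[0]][0]
    if any_spec.n_spheres < 2:
        raise ValueError("events need at least 2 frames")

    narrow_ids = [tid for tid in tunnel_ids
                  if tunnels[tid][0].r_star < 1.4]
    wide_ids = [tid for tid in tunnel_ids if tid not in narrow_ids] \
        or tunnel_ids

    # unique start offsets per tunnel -> unique bottleneck frames
    offsets: dict[str, list[int]] = {tid: [] for tid in tunnel_ids}
    choices = []
    for _ in range(spec.n_events):
        if narrow_ids and rng.random() < spec.narrow_fraction:
            tid = narrow_ids[int(rng.integers(len(narrow_ids)))]
        else:
            tid = wide_ids[int(rng.integers(len(wide_ids)))]
        choices.append(tid)
        offsets[tid].append(len(offsets[tid]))

    events, manifest = [], {}
    partners_by_frame: dict[int, list[AtomRecord]] = {}
    residue_counter = 1000
    for k, tid in enumerate(choices):
        tspec, snaps = tunnels[tid]
        offset = offsets[tid].pop(0)
        n = tspec.n_spheres
        start = frame_base + offset
        frames = np.arange(start, start + n)
        if frames[-1] - frame_base >= len(snaps):
            raise ValueError("tunnel has too few frames for this event")
        direction = "inflow" if rng.random() < 0.5 else "outflow"
        order = np.arange(n) if direction == "outflow" \
            else np.arange(n - 1, -1, -1)

        centers = snaps[0].centers
        t_axis, u, v = _frame_basis(tspec.axis)
        oxy = np.empty((n, 3))
        for pos, sphere_i in enumerate(order):
            local_snap = snaps[frames[pos] - frame_base]
            rad = float(local_snap.radii[sphere_i])
            rho = min(abs(rng.normal(0.0, spec.lateral_noise)),
                      0.4 * rad) if spec.lateral_noise > 0 else 0.0
            phi = rng.uniform(0, 2 * np.pi)
            oxy[pos] = centers[sphere_i] + rho * (math.cos(phi) * u
                                                  + math.sin(phi) * v)

        # planted bonds at the bottleneck visit
        b_pos = int(np.where(order == tspec.bottleneck_index)[0][0])
        b_frame = int(frames[b_pos])
        raw = spec.bond_intercept - spec.bond_slope * tspec.r_star
        if spec.bond_noise > 0:
            raw += rng.normal(0.0, spec.bond_noise)
        n_bonds = int(np.clip(round(raw), 0, 5))
        partner_atoms, planted_h = plant_hbond_partners(
            oxy[b_pos], tspec.axis, n_bonds,
            residue_start=residue_counter, variety=k)
        residue_counter += 8
        partners_by_frame.setdefault(b_frame, []).extend(partner_atoms)

        # hydrogens: planted orientation at the bottleneck frame, a fixed
        # in-plane orientation elsewhere
        hyd = np.empty((n, 2, 3))
        half = math.radians(_HOH / 2)
        d1 = math.cos(half) * u + math.sin(half) * v
        d2 = math.cos(half) * u - math.sin(half) * v
        for pos in range(n):
            hyd[pos, 0] = oxy[pos] + _D_OH * d1
            hyd[pos, 1] = oxy[pos] + _D_OH * d2
        hyd[b_pos] = planted_h

        assignable = rng.random() >= spec.unassigned_fraction
        flags = []
        for pos in range(n):
            if assignable or pos % 2 == 0:
                flags.append(frozenset({tid}))
            else:
                flags.append(frozenset())

        event_id = f"E{event_start + k:05d}"
        events.append(TransportEvent(
            event_id=event_id,
            water_id=f"W{event_start + k:05d}",
            frames=frames,
            oxygen=oxy,
            hydrogens=hyd,
            direction=direction,
            matched_tunnels=flags,
        ))
        manifest[event_id] = ManifestEntry(
            event_id=event_id,
            sim_id=sim_id,
            tunnel_id=tid,
            planted_min_radius=float(tspec.r_star),
            planted_bond_counts=[n_bonds],
            bottleneck_frame=b_frame,
            direction=direction,
            assignable=assignable,
        )
    return events, manifest, partners_by_frame


def _build_scenario(seed: int,
                    n_events: int,
                    n_sims: int,
                    tunnel_plan,
                    passage_kwargs: dict,
                    scenario: str) -> SyntheticBundle:
    rng = np.random.default_rng(seed)
    events_per_sim = [n_events // n_sims] * n_sims
    for i in range(n_events - sum(events_per_sim)):
        events_per_sim[i] += 1

    all_snaps: list[TunnelSnapshot] = []
    all_events: list[TransportEvent] = []
    manifest: dict[str, ManifestEntry] = {}
    scaffold_by_sim: dict[str, list[AtomRecord]] = {}
    partners_by_frame: dict[int, list[AtomRecord]] = {}
    sim_of_event: dict[str, str] = {}
    event_counter = 0

    for s in range(n_sims):
        sim_id = f"S{s:02d}"
        frame_base = s * FRAME_BLOCK
        n_ev = events_per_sim[s]
        n_frames = 21 + n_ev + 1

        tunnels: dict[str, tuple[TunnelSpec, list[TunnelSnapshot]]] = {}
        scaffold: list[AtomRecord] = []
        for tspec in tunnel_plan(sim_id, rng):
            tspec.n_frames = n_frames
            # replicas are spatially separated so their atom sets can be
            # pooled into one structure without interfering
            tspec.origin = (tspec.origin[0], tspec.origin[1] + s * SIM_SPACING,
                            tspec.origin[2])
            snaps, _ = generate_tunnel(tspec, rng=rng)
            # shift into the simulation's global frame block
            snaps = [TunnelSnapshot(frame_base + sn.frame_id, sn.tunnel_id,
                                    sn.centers, sn.radii, sn.indices)
                     for sn in snaps]
            tunnels[tspec.tunnel_id] = (tspec, snaps)
            all_snaps.extend(snaps)
            scaffold.extend(_wall_scaffold(
                tspec, snaps[0].centers, _radius_profile(tspec),
                residue_start=1 + 100 * len(tunnels)))
        scaffold_by_sim[sim_id] = scaffold

        pspec = PassageSpec(n_events=n_ev, seed=seed, **passage_kwargs)
        events, mani, partners = generate_passages(
            tunnels, pspec, rng, sim_id, frame_base,
            event_start=event_counter)
        event_counter += n_ev
        all_events.extend(events)
        manifest.update(mani)
        partners_by_frame.update(partners)
        for eid in mani:
            sim_of_event[eid] = sim_id

    return SyntheticBundle(
        snapshots=all_snaps,
        events=all_events,
        manifest=manifest,
        scaffold_by_sim=scaffold_by_sim,
        partners_by_frame=partners_by_frame,
        sim_of_event=sim_of_event,
        seed=seed,
        scenario=scenario,
    )


def scenario_clean(seed: int = 0,
                   n_events: int = 1000,
                   n_sims: int = 50) -> SyntheticBundle:
    """Low-noise scenario for parameter-recovery checks.

    One tunnel per simulation with a bottleneck radius drawn uniformly in
    [1.0, 2.0] A, gentle radius wobble (sigma 0.015 A) and small lateral
    noise, so recovered minimal radii should sit within 0.05 A of the
    planted bottleneck and planted bond counts should be recovered
    exactly.
    """
    def plan(sim_id: str, rng: np.random.Generator):
        r_star = float(rng.uniform(1.0, 2.0))
        return [TunnelSpec(tunnel_id="T1",
                           r_star=r_star,
                           end_radius=r_star + 1.0,
                           radius_wobble=0.015)]

    return _build_scenario(
        seed, n_events, n_sims, plan,
        passage_kwargs=dict(lateral_noise=0.05, narrow_fraction=0.0,
                            bond_noise=0.5),
        scenario="clean")


def scenario_bimodal(seed: int = 0,
                       n_events: int = 5000,
                       n_sims: int = 50) -> SyntheticBundle:
    """Bimodal mixture scenario for the statistical surface.

    Each simulation carries a wide tunnel (bottleneck ~N(1.65, 0.05) A)
    and a narrow one (~N(1.15, 0.03) A, spatially well separated); ~20%
    of events route through the narrow tunnel.  Planted bond counts
    decrease with the bottleneck radius, producing a negative
    radius/H-bond rank correlation, and 5% of events carry ambiguous
    tunnel match flags so the 70% assignment rule leaves them out.
    """
    def plan(sim_id: str, rng: np.random.Generator):
        r_wide = float(np.clip(rng.normal(1.65, 0.05), 1.45, 1.85))
        r_narrow = float(np.clip(rng.normal(1.15, 0.03), 1.02, 1.28))
        return [
            TunnelSpec(tunnel_id="wide",
                       origin=(0.0, 0.0, 0.0),
                       r_star=r_wide, end_radius=r_wide + 1.0,
                       radius_wobble=0.02),
            TunnelSpec(tunnel_id="narrow",
                       origin=(60.0, 0.0, 0.0),
                       r_star=r_narrow, end_radius=r_narrow + 1.0,
                       radius_wobble=0.02),
        ]

    return _build_scenario(
        seed, n_events, n_sims, plan,
        passage_kwargs=dict(lateral_noise=0.08, narrow_fraction=0.2,
                            unassigned_fraction=0.05),
        scenario="bimodal")


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write a bundle as TunnelProfileCSV + EventTable + multi-model PDB.

    The PDB carries one model per planted bottleneck frame (the frames
    the hydrogen-bond analysis needs); partner groups of other events are
    parked far outside the system in each model so the atom set is
    constant.  ``meta.json`` records the model-to-frame mapping, the
    simulation grouping and the ground-truth manifest.
    """
    import dataclasses
    import json
    from pathlib import Path

    from .io import write_events, write_structure, write_tunnels

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"tunnels": outdir / "tunnels.csv",
             "events": outdir / "events.csv",
             "structure": outdir / "protein.pdb",
             "meta": outdir / "meta.json"}
    write_tunnels(bundle.snapshots, paths["tunnels"])
    write_events(bundle.events, paths["events"])

    model_frames = sorted(bundle.partners_by_frame)
    scaffold = [a for sim in sorted(bundle.scaffold_by_sim)
                for a in bundle.scaffold_by_sim[sim]]
    partner_list = [(f, a) for f in model_frames
                    for a in bundle.partners_by_frame[f]]
    models = []
    for fm in model_frames:
        atoms = list(scaffold)
        for f, a in partner_list:
            pos = a.position if f == fm else a.position + PARK_SHIFT
            atoms.append(dataclasses.replace(a, position=pos))
        models.append(atoms)
    write_structure(models, paths["structure"])

    meta = {
        "scenario": bundle.scenario,
        "seed": bundle.seed,
        "model_frames": model_frames,
        "sim_of_event": bundle.sim_of_event,
        "frame_block": FRAME_BLOCK,
        "manifest": {eid: dataclasses.asdict(m)
                     for eid, m in bundle.manifest.items()},
    }
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True)
                             + "\n")
    return paths


def generate_endpoint_blobs(centers: Sequence[Sequence[float]],
                            n_per_blob: int = 20,
                            sigma: float = 0.3,
                            seed: int = 0
                            ) -> tuple[list[TunnelEndpoint], np.ndarray]:
    """Gaussian blobs of tunnel endpoints with known labels, for
    exercising the entrance-clustering contract."""
    rng = np.random.default_rng(seed)
    endpoints, labels = [], []
    for b, c in enumerate(centers):
        pts = rng.normal(0.0, sigma, size=(n_per_blob, 3)) + np.asarray(c)
        for i, p in enumerate(pts):
            endpoints.append(TunnelEndpoint(
                frame_id=i, tunnel_instance_id=f"B{b}:{i}", position=p))
            labels.append(b)
    return endpoints, np.array(labels)
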