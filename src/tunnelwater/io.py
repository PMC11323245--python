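"""Readers and writers for tunnel profiles, event tables and structures.

Two documented CSV dialects carry the pipeline inputs:

``TunnelProfileCSV`` — one row per tunnel sphere, modeled on CAVER-style
tunnel profiles::

    frame,tunnel,sphere_index,x,y,z,radius

with 0-based integer frames, coordinates and radii in angstrom written
with four decimals, rows sorted by (frame, tunnel, sphere_index).

``EventTable`` — one row per event frame, emulating water-tracking path
exports::

    event_id,water_id,frame,ox,oy,oz,h1x,h1y,h1z,h2x,h2y,h2z,matched_tunnels

where ``matched_tunnels`` is a semicolon-separated list of tunnel labels
the water was matched to in that frame (may be empty).

Structures travel as (multi-model) PDB files read and written through
biotite.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import TransportEvent, TunnelSnapshot
from .hbonds import AtomRecord

__all__ = [
    "RunConfig",
    "read_tunnels",
    "write_tunnels",
    "read_events",
    "write_events",
    "read_structure",
    "write_structure",
]

_TUNNEL_COLUMNS = ["frame", "tunnel", "sphere_index", "x", "y", "z", "radius"]
_EVENT_COLUMNS = ["event_id", "water_id", "frame", "ox", "oy", "oz",
                  "h1x", "h1y", "h1z", "h2x", "h2y", "h2z",
                  "matched_tunnels"]
_FLOAT_FMT = "%.4f"


@dataclass
class RunConfig:
    """Analysis thresholds and run settings.

    Defaults are the standard criteria: H-bond donor-acceptor cutoff
    3.5 A with a 135-180 degree vertex-angle window, narrow-transport
    threshold 1.4 A, 70% duration rule for event-to-tunnel assignment,
    and 0.1 A histogram bins.
    """

    hbond_dmax: float = 3.5
    hbond_angle_min: float = 135.0
    hbond_angle_max: float = 180.0
    narrow_radius: float = 1.4
    assign_fraction: float = 0.70
    bin_width: float = 0.1
    vdw_radii: dict | None = None
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        for name in ("hbond_dmax", "narrow_radius", "assign_fraction",
                     "bin_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# tunnel profile CSV

def write_tunnels(snapshots: Sequence[TunnelSnapshot],
                  path: str | Path) -> None:
    """Write snapshots as TunnelProfileCSV, sorted by (frame, tunnel,
    sphere_index)."""
    rows = []
    for snap in snapshots:
        for i in range(snap.n_spheres):
            rows.append((snap.frame_id, snap.tunnel_id,
                         int(snap.indices[i]),
                         snap.centers[i, 0], snap.centers[i, 1],
                         snap.centers[i, 2], float(snap.radii[i])))
    df = pd.DataFrame(rows, columns=_TUNNEL_COLUMNS)
    df = df.sort_values(["frame", "tunnel", "sphere_index"],
                        kind="mergesort")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tunnels(path: str | Path) -> list[TunnelSnapshot]:
    """Parse a TunnelProfileCSV into snapshots grouped by (frame, tunnel)."""
    df = pd.read_csv(path, dtype={"tunnel": str})
    missing = [c for c in _TUNNEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["frame", "tunnel", "sphere_index"])
    if dup.any():
        row = int(df.index[dup][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: duplicated (frame, tunnel, sphere_index) "
                         f"at row {row}")
    snapshots = []
    for (frame, tunnel), grp in df.groupby(["frame", "tunnel"], sort=True):
        grp = grp.sort_values("sphere_index", kind="mergesort")
        idx = grp["sphere_index"].to_numpy(dtype=int)
        if np.any(np.diff(idx) <= 0):
            row = int(grp.index[0]) + 2
            raise ValueError(f"{path}: non-monotone sphere_index for frame "
                             f"{frame}, tunnel {tunnel} near row {row}")
        snapshots.append(TunnelSnapshot(
            int(frame), str(tunnel),
            grp[["x", "y", "z"]].to_numpy(dtype=float),
            grp["radius"].to_numpy(dtype=float),
            indices=idx))
    return snapshots


# ---------------------------------------------------------------------------
# event table CSV

def write_events(events: Sequence[TransportEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        for pos, frame in enumerate(ev.frames):
            if ev.hydrogens is not None:
                h = ev.hydrogens[pos]
            else:
                h = np.full((2, 3), np.nan)
            matched = ";".join(sorted(ev.matched_tunnels[pos])) \
                if ev.matched_tunnels else ""
            rows.append((ev.event_id, ev.water_id, int(frame),
                         *ev.oxygen[pos], *h[0], *h[1], matched))
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path) -> list[TransportEvent]:
    df = pd.read_csv(path, dtype={"event_id": str, "water_id": str,
                                  "matched_tunnels": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["event_id", "frame"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicated (event_id, frame) at row {row}")
    events = []
    for event_id, grp in df.groupby("event_id", sort=True):
        grp = grp.sort_values("frame", kind="mergesort")
        hcols = grp[["h1x", "h1y", "h1z", "h2x", "h2y", "h2z"]]
        hydrogens = None
        if not hcols.isna().any().any():
            hydrogens = hcols.to_numpy(dtype=float).reshape(-1, 2, 3)
        matched = []
        for raw in grp["matched_tunnels"]:
            if isinstance(raw, str) and raw:
                matched.append(frozenset(raw.split(";")))
            else:
                matched.append(frozenset())
        events.append(TransportEvent(
            event_id=str(event_id),
            water_id=str(grp["water_id"].iloc[0]),
            frames=grp["frame"].to_numpy(dtype=int),
            oxygen=grp[["ox", "oy", "oz"]].to_numpy(dtype=float),
            hydrogens=hydrogens,
            matched_tunnels=matched,
        ))
    return events


# ---------------------------------------------------------------------------
# PDB structures

_ELEMENT_FALLBACK_WARNED = False


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(path: str | Path) -> list[list[AtomRecord]]:
    """Read a (multi-model) PDB file into per-model atom records.

    Residue ids are 1-based as stored in the file.  Elements come from
    PDB columns 77-78; when blank they are inferred from the atom name
    with a warning.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    if stack.stack_depth() == 0:
        raise ValueError(f"{path}: no models found")

    elements = list(stack.element)
    names = list(stack.atom_name)
    inferred = False
    for i, el in enumerate(elements):
        if not el:
            elements[i] = _infer_element(names[i])
            inferred = True
    if inferred:
        warnings.warn(f"{path}: element column blank for some atoms; "
                      "inferred from atom names", stacklevel=2)

    models = []
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        models.append([
            AtomRecord(
                atom_name=str(names[i]),
                element=str(elements[i]),
                residue_name=str(stack.res_name[i]),
                residue_id=int(stack.res_id[i]),
                chain_id=str(stack.chain_id[i]),
                position=coords[i],
            )
            for i in range(stack.array_length())
        ])
    return models


def write_structure(models: Sequence[Sequence[AtomRecord]],
                    path: str | Path) -> None:
    """Write per-model atom records as a multi-model PDB file.

    All models must contain the same atoms (same count and identity);
    only coordinates may differ between models.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    models = [list(m) for m in models]
    if not models or not models[0]:
        raise ValueError("nothing to write")
    n_atoms = len(models[0])
    if any(len(m) != n_atoms for m in models):
        raise ValueError("all models must have the same number of atoms")

    template = models[0]
    stack = struc.AtomArrayStack(len(models), n_atoms)
    stack.coord = np.array([[a.position for a in m] for m in models])
    stack.chain_id = np.array([a.chain_id for a in template])
    stack.res_id = np.array([a.residue_id for a in template])
    stack.res_name = np.array([a.residue_name for a in template])
    stack.atom_name = np.array([a.atom_name for a in template])
    stack.element = np.array([a.element for a in template])
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
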