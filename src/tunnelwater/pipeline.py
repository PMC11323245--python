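"""End-to-end analysis: events in, per-event records and statistics out.

The flow mirrors the post-processing of tunnel-tracking output: assign
each event to a tunnel by the 70%-of-duration rule, trace the water
through the per-frame tunnel spheres, extract the minimal event sphere,
flag narrow transport (< 1.4 A), measure the steric surface-surface
distance to the closest protein atom, detect hydrogen bonds at the
minimal frames, and aggregate histograms, cumulative distributions and
per-tunnel usage tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import (TransportEvent, TunnelSnapshot, VdwTable,
                       classify_narrow, minimal_event_sphere,
                       surface_surface_distance, trace_event)
from .hbonds import (AtomRecord, HBondCriteria, classify_partner,
                     default_table, detect_hbonds)
from .io import RunConfig, read_events, read_structure, read_tunnels
from .network import assign_event_to_tunnel, usage_table
from .stats import cumulative_distribution, fraction_below, radius_histogram

__all__ = ["AnalysisResult", "analyze_events", "run_pipeline",
           "write_report"]

logger = logging.getLogger(__name__)

#: frame-protein accessor: (frame_id, sim_id or None) -> atom records or None
ProteinAccessor = Callable[[int, str | None], list | None]


@dataclass
class AnalysisResult:
    """All products of one analysis run."""

    events: pd.DataFrame          # one row per traceable assigned event
    hbonds: pd.DataFrame          # one row per detected bond
    histogram: pd.DataFrame       # radius histogram
    cdf: pd.DataFrame             # empirical cumulative distribution
    usage: pd.DataFrame           # per-tunnel usage table
    n_total: int
    n_assigned: int
    n_unassigned: int
    fraction_narrow: float
    counts_log: list[str] = field(default_factory=list)


def _water_atoms(event: TransportEvent, pos: int) -> list[AtomRecord]:
    atoms = [AtomRecord("O", "O", "WAT", 1, "W", event.oxygen[pos])]
    if event.hydrogens is not None:
        atoms.append(AtomRecord("H1", "H", "WAT", 1, "W",
                                event.hydrogens[pos, 0]))
        atoms.append(AtomRecord("H2", "H", "WAT", 1, "W",
                                event.hydrogens[pos, 1]))
    return atoms


def analyze_events(snapshots: Sequence[TunnelSnapshot],
                   events: Sequence[TransportEvent],
                   config: RunConfig | None = None,
                   protein: ProteinAccessor | Mapping[int, list] | None = None,
                   sim_of_event: Mapping[str, str] | None = None,
                   sim_of_frame: Callable[[int], str] | None = None,
                   ) -> AnalysisResult:
    """Run the full per-event analysis on in-memory objects.

    ``protein`` optionally supplies protein atoms per frame (a mapping
    from frame id, or a callable taking ``(frame_id, sim_id)``); without
    it the steric-overlap and hydrogen-bond columns stay empty.
    """
    config = config or RunConfig()
    criteria = HBondCriteria(config.hbond_dmax, config.hbond_angle_min,
                             config.hbond_angle_max)
    vdw = VdwTable(config.vdw_radii)
    table = default_table()
    if protein is not None and not callable(protein):
        mapping = protein

        def protein_accessor(frame, sim):
            return mapping.get(frame)
    else:
        protein_accessor = protein

    if not events:
        raise ValueError("no events")

    by_tunnel: dict[str, dict[int, TunnelSnapshot]] = {}
    for snap in snapshots:
        by_tunnel.setdefault(snap.tunnel_id, {})[snap.frame_id] = snap

    log: list[str] = []
    log.append(f"events: {len(events)} total")

    records = []
    bond_rows = []
    n_unassigned = 0
    n_untraceable = 0
    for event in events:
        tunnel = assign_event_to_tunnel(event, config.assign_fraction)
        if tunnel is None:
            n_unassigned += 1
            continue
        frames_map = by_tunnel.get(tunnel, {})
        try:
            trace = trace_event(event, frames_map)
        except ValueError:
            n_untraceable += 1
            continue
        mes = minimal_event_sphere(trace)
        narrow = classify_narrow(mes, config.narrow_radius)
        sim = sim_of_event.get(event.event_id) if sim_of_event else None

        overlap = np.nan
        counts: list[int] = []
        if protein_accessor is not None:
            for j, frame in enumerate(mes.minimal_frames):
                atoms = protein_accessor(int(frame), sim)
                if atoms is None:
                    logger.debug("event %s: no structure for minimal frame "
                                 "%d", event.event_id, frame)
                    continue
                positions = np.array([a.position for a in atoms])
                elements = [a.element for a in atoms]
                d = surface_surface_distance(
                    mes.water_positions[j], (positions, elements), vdw)
                overlap = d if np.isnan(overlap) else min(overlap, d)
                if event.hydrogens is not None:
                    pos = event.frame_position(int(frame))
                    bonds = detect_hbonds(_water_atoms(event, pos), atoms,
                                          table, criteria)
                    counts.append(len(bonds))
                    for b in bonds:
                        partner = b.donor if b.acceptor.residue_name == "WAT" \
                            else b.acceptor
                        try:
                            pclass = classify_partner(partner).value
                        except ValueError:
                            pclass = "unknown"
                        bond_rows.append((
                            event.event_id, int(frame),
                            f"{b.donor.residue_name}{b.donor.residue_id}"
                            f":{b.donor.atom_name}",
                            f"{b.acceptor.residue_name}{b.acceptor.residue_id}"
                            f":{b.acceptor.atom_name}",
                            round(b.distance, 4), round(b.angle, 2), pclass))

        records.append({
            "event_id": event.event_id,
            "tunnel": tunnel,
            "sim": sim,
            "minimal_radius": mes.radius,
            "sphere_index": mes.sphere_index,
            "n_minimal_frames": int(mes.minimal_frames.size),
            "narrow": narrow,
            "overlap_distance": overlap,
            "bond_counts": ";".join(str(c) for c in counts),
            "mean_bond_count": float(np.mean(counts)) if counts else np.nan,
        })

    log.append(f"assignment: {len(records) + n_untraceable} assigned, "
               f"{n_unassigned} unassigned (ambiguous or below "
               f"{config.assign_fraction:.0%} duration)")
    if n_untraceable:
        log.append(f"tracing: {n_untraceable} assigned event(s) had no "
                   "usable tunnel snapshots and were dropped")
    if not records:
        raise ValueError("no events could be assigned and traced")

    events_df = pd.DataFrame.from_records(records).set_index("event_id")
    radii = events_df["minimal_radius"].to_numpy()
    frac_narrow = fraction_below(radii, config.narrow_radius)
    log.append(f"narrow transport (< {config.narrow_radius} A): "
               f"{int(events_df['narrow'].sum())} events "
               f"({100 * frac_narrow:.1f}%)")

    hist = radius_histogram(radii, config.bin_width)
    hist_df = pd.DataFrame({
        "bin_left": hist.edges[:-1],
        "bin_right": hist.edges[1:],
        "count": hist.counts,
        "fraction": hist.fractions,
    })
    curve = cumulative_distribution(radii)
    cdf_df = pd.DataFrame({"radius": curve.radii,
                           "cumulative_fraction": curve.fractions})

    assignments = events_df["tunnel"].to_dict()
    snaps_by_sim = None
    if sim_of_frame is not None:
        snaps_by_sim = {}
        for snap in snapshots:
            snaps_by_sim.setdefault(sim_of_frame(snap.frame_id),
                                    []).append(snap)
    usage = usage_table(assignments, snaps_by_sim)
    log.append(f"usage: {len(usage)} tunnels, top "
               f"{usage.index[0]} at {usage['percent'].iloc[0]:.1f}%")

    bonds_df = pd.DataFrame(
        bond_rows, columns=["event_id", "frame", "donor", "acceptor",
                            "distance", "angle", "partner_class"])

    for line in log:
        logger.info("%s", line)
    return AnalysisResult(
        events=events_df,
        hbonds=bonds_df,
        histogram=hist_df,
        cdf=cdf_df,
        usage=usage,
        n_total=len(events),
        n_assigned=len(records) + n_untraceable,
        n_unassigned=n_unassigned,
        fraction_narrow=frac_narrow,
        counts_log=log,
    )


def write_report(result: AnalysisResult, outdir: str | Path,
                 config: RunConfig | None = None) -> dict[str, Path]:
    """Write the report bundle (TSV/CSV tables plus run metadata)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    paths = {
        "events": outdir / "events.tsv",
        "hbonds": outdir / "hbonds.tsv",
        "histogram": outdir / "histogram.csv",
        "cdf": outdir / "cdf.csv",
        "usage": outdir / "usage.tsv",
        "metadata": outdir / "metadata.json",
    }
    result.events.to_csv(paths["events"], sep="\t", float_format="%.6f")
    result.hbonds.to_csv(paths["hbonds"], sep="\t", index=False,
                         float_format="%.6f")
    result.histogram.to_csv(paths["histogram"], index=False,
                            float_format="%.6f")
    result.cdf.to_csv(paths["cdf"], index=False, float_format="%.6f")
    result.usage.to_csv(paths["usage"], sep="\t", float_format="%.6f")
    meta = {
        "package": "tunnelwater",
        "version": __version__,
        "config": config.to_dict(),
        "n_total_events": result.n_total,
        "n_assigned": result.n_assigned,
        "n_unassigned": result.n_unassigned,
        "fraction_narrow": result.fraction_narrow,
        "log": result.counts_log,
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True)
                                 + "\n")
    return paths


def run_pipeline(config: RunConfig,
                 tunnels_path: str | Path,
                 events_path: str | Path,
                 structure_path: str | Path | None = None,
                 meta_path: str | Path | None = None,
                 outdir: str | Path = "tunnelwater_out") -> AnalysisResult:
    """File-level pipeline: read inputs, analyze, write the report bundle.

    ``meta_path`` is the metadata JSON written by ``simulate``; it maps
    structure models to frame ids and events/tunnels to simulations (for
    jackknife grouping).  Without a structure the steric and H-bond
    columns stay empty.
    """
    snapshots = read_tunnels(tunnels_path)
    events = read_events(events_path)
    if not events:
        raise ValueError("no events")

    sim_of_event = sim_of_frame = None
    model_frames = None
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        sim_of_event = meta.get("sim_of_event")
        block = meta.get("frame_block")
        if block:
            sim_of_frame = lambda f: f"S{f // int(block):02d}"  # noqa: E731
        model_frames = meta.get("model_frames")

    protein = None
    if structure_path is not None:
        models = read_structure(structure_path)
        if model_frames is None:
            model_frames = list(range(len(models)))
        if len(model_frames) != len(models):
            raise ValueError(
                "frame-space mismatch: structure has "
                f"{len(models)} models but metadata lists "
                f"{len(model_frames)} frames")
        protein = {int(f): m for f, m in zip(model_frames, models)}

    # fail fast on inconsistent frame spaces
    snap_frames = {s.frame_id for s in snapshots}
    event_frames = set()
    for ev in events:
        event_frames.update(int(f) for f in ev.frames)
    if not event_frames & snap_frames:
        raise ValueError("frame-space mismatch: event frames and tunnel "
                         "frames are disjoint")

    result = analyze_events(snapshots, events, config, protein,
                            sim_of_event, sim_of_frame)
    write_report(result, outdir, config)
    return result
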