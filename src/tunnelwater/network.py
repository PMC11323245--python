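"""Tunnel identity over time and per-tunnel usage statistics.

Tunnel instances found frame-by-frame are given a consistent identity by
density-based clustering of their surface endpoints (HDBSCAN; endpoints
assigned to noise are discarded).  Transport events are attributed to a
tunnel only when the event was matched to that tunnel for at least 70% of
its duration — ambiguous events stay unassigned.  Usage tables report
per-tunnel transport percentages and average bottleneck radii with
jackknife variances over independent simulations, and two variants are
compared tunnel-by-tunnel on their percentage columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import TransportEvent, TunnelSnapshot
from .stats import jackknife

__all__ = [
    "TunnelEndpoint",
    "EntranceClusters",
    "cluster_endpoints",
    "assign_event_to_tunnel",
    "usage_table",
    "compare_variants",
]


@dataclass(frozen=True)
class TunnelEndpoint:
    """Surface end of one tunnel instance in one frame."""

    frame_id: int
    tunnel_instance_id: str
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "position",
            np.asarray(self.position, dtype=float).reshape(3))

    @classmethod
    def from_snapshot(cls, snapshot: TunnelSnapshot) -> "TunnelEndpoint":
        return cls(snapshot.frame_id, snapshot.tunnel_id, snapshot.endpoint)


@dataclass
class EntranceClusters:
    """Result of endpoint clustering; noise endpoints are kept separately
    but never contribute to downstream tables."""

    clusters: dict[int, list[TunnelEndpoint]] = field(default_factory=dict)
    noise: list[TunnelEndpoint] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels_for(self, endpoints: Sequence[TunnelEndpoint]) -> np.ndarray:
        """Cluster label per endpoint (-1 for noise), in input order."""
        lookup: dict[int, int] = {}
        for cid, members in self.clusters.items():
            for m in members:
                lookup[id(m)] = cid
        return np.array([lookup.get(id(e), -1) for e in endpoints])


def cluster_endpoints(endpoints: Sequence[TunnelEndpoint],
                      epsilon: float = 1.5,
                      min_samples: int = 5,
                      min_cluster_size: int = 5,
                      allow_single_cluster: bool = True) -> EntranceClusters:
    """Cluster tunnel surface endpoints into consistent entrances.

    Uses HDBSCAN with a cluster-selection epsilon (angstrom); groups
    smaller than ``min_cluster_size`` become noise and are discarded from
    downstream tables.  Fewer points than ``min_cluster_size`` means
    everything is noise.
    """
    endpoints = list(endpoints)
    if not endpoints:
        raise ValueError("no endpoints to cluster")
    X = np.array([e.position for e in endpoints])
    if len(endpoints) < max(min_samples, min_cluster_size):
        return EntranceClusters(clusters={}, noise=endpoints)

    from sklearn.cluster import HDBSCAN

    labels = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        cluster_selection_epsilon=float(epsilon),
        allow_single_cluster=allow_single_cluster,
        copy=True,
    ).fit(X).labels_

    result = EntranceClusters()
    for endpoint, label in zip(endpoints, labels):
        if label == -1:
            result.noise.append(endpoint)
        else:
            result.clusters.setdefault(int(label), []).append(endpoint)
    return result


def assign_event_to_tunnel(event: TransportEvent,
                           min_fraction: float = 0.70) -> str | None:
    """Attribute a transport event to a tunnel by the duration rule.

    The event is assigned to the tunnel it was matched to for the largest
    fraction of its frames, provided that fraction is at least
    ``min_fraction`` (inclusive — 70 of 100 frames passes at the default).
    A tie between tunnels at the top fraction is ambiguous and yields
    ``None`` (unassigned), as does every fraction below the threshold.
    """
    if not event.matched_tunnels:
        return None
    n = event.n_frames
    counts: dict[str, int] = {}
    for flags in event.matched_tunnels:
        for tunnel in flags:
            counts[tunnel] = counts.get(tunnel, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    if best / n < min_fraction:
        return None
    leaders = sorted(t for t, c in counts.items() if c == best)
    if len(leaders) != 1:
        return None
    return leaders[0]


def usage_table(assignments: Mapping[str, str],
                snapshots_by_sim: Mapping[str, Sequence[TunnelSnapshot]]
                | None = None) -> pd.DataFrame:
    """Per-tunnel usage table (counts, percentages, bottleneck radii).

    Parameters
    ----------
    assignments
        Map event id -> assigned tunnel label (unassigned events excluded;
        percentages are over *assigned* events, so they sum to 100).
    snapshots_by_sim
        Optional tunnel snapshots grouped by simulation, used for the
        average bottleneck radius per tunnel and its jackknife variance
        over simulations.

    Returns a DataFrame indexed by tunnel with columns ``count``,
    ``percent``, ``avg_bottleneck``, ``jackknife_var``, ``jackknife_sd``,
    ``n_sims``.
    """
    if not assignments:
        raise ValueError("no assigned events")
    counts = pd.Series(list(assignments.values())).value_counts()
    total = int(counts.sum())
    table = pd.DataFrame({
        "count": counts.astype(int),
        "percent": counts / total * 100.0,
    })
    table.index.name = "tunnel"

    avg = pd.Series(np.nan, index=table.index, dtype=float)
    jvar = pd.Series(np.nan, index=table.index, dtype=float)
    nsim = pd.Series(0, index=table.index, dtype=int)
    if snapshots_by_sim:
        # per tunnel: list of per-simulation bottleneck-radius arrays
        for tunnel in table.index:
            groups = []
            for snaps in snapshots_by_sim.values():
                radii = [s.bottleneck_radius for s in snaps
                         if s.tunnel_id == tunnel]
                if radii:
                    groups.append(np.asarray(radii))
            if not groups:
                continue
            nsim[tunnel] = len(groups)
            all_radii = np.concatenate(groups)
            avg[tunnel] = float(all_radii.mean())
            if len(groups) >= 2:
                _, var = jackknife(
                    lambda gs: float(np.concatenate(list(gs)).mean()), groups)
                jvar[tunnel] = var
    table["avg_bottleneck"] = avg
    table["jackknife_var"] = jvar
    table["jackknife_sd"] = np.sqrt(jvar)
    table["n_sims"] = nsim
    return table.sort_values("count", ascending=False)


def compare_variants(table_a: pd.DataFrame,
                     table_b: pd.DataFrame) -> pd.DataFrame:
    """Tunnel-by-tunnel usage difference between two variants.

    Matches tunnels by label (outer join; a tunnel absent from one
    variant contributes 0%) and reports ``difference = percent_a -
    percent_b`` at full precision — round only when rendering.  The
    conventional orientation is wild type as ``table_a`` and mutant as
    ``table_b``, so a positive difference means the wild type uses the
    tunnel more.
    """
    for name, tbl in (("table_a", table_a), ("table_b", table_b)):
        if tbl.index.has_duplicates:
            dups = sorted(tbl.index[tbl.index.duplicated()].unique())
            raise ValueError(f"duplicate tunnel labels in {name}: {dups}")
    a = table_a["percent"].astype(float)
    b = table_b["percent"].astype(float)
    out = pd.DataFrame({"percent_a": a, "percent_b": b}).fillna(0.0)
    out["difference"] = out["percent_a"] - out["percent_b"]
    out.index.name = "tunnel"
    return out.sort_values("percent_a", ascending=False)
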