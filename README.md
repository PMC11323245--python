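# tunnelwater

Analysis of water transport through narrow protein tunnels.

Buried active sites of enzymes such as α/β-hydrolases exchange water with
the bulk through tunnels — internal pathways approximated, frame by frame
of a molecular-dynamics trajectory, as chains of spheres along a
centerline. Tunnel-tracking tools (CAVER-style tunnel profiles,
AQUA-DUCT-style water paths, TransportTools-style event assignment)
produce per-frame tunnel geometries and water transport events; this
package implements the downstream analysis that characterizes *how
narrow* the passages actually are and *how* waters squeeze through them.

For each transport event the water oxygen is assigned in every frame to
the closest tunnel sphere (its *event sphere*, one per frame); the
smallest event sphere over the passage is the **minimal event sphere**,
whose radius r_min is the effective constriction of the event. Events
with r_min < 1.4 Å — the conventional water radius — are *narrow-tunnel
transport*. Around that core the package provides:

- **Geometric hydrogen bonds** at the minimal-sphere frames: a donor–
  acceptor heavy-atom distance d(D,A) ≤ 3.5 Å combined with an
  acceptor–hydrogen–donor angle ∠(A,H,D) ∈ [135°, 180°], both directions
  (water as donor and as acceptor), with partner atoms classified as
  backbone or by side-chain character (nonpolar / polar / positive /
  negative residues).
- **Steric verification**: the surface–surface distance
  min_i (|x_w − x_i| − r_vdw(O) − r_vdw(i)) from the water to the closest
  protein atom; negative values are genuine atomic overlaps, the
  signature of passage through a formally too-narrow space.
- **Tunnel identity and usage**: HDBSCAN clustering of tunnel surface
  endpoints (ε = 1.5 Å, min cluster size 5, noise discarded), the
  70%-of-duration rule for attributing events to tunnels (ties and
  sub-threshold events stay unassigned), per-tunnel usage tables with
  average bottleneck radii, and variant-vs-variant difference tables.
- **Distribution statistics**: 0.1 Å histograms of r_min (left-closed
  bins, so 1.4 Å is a bin edge), empirical cumulative distributions,
  below-threshold fractions, subsample variance (e.g. 100 draws of 45 of
  50 simulations) and leave-one-out jackknife variances,
  Var = (n−1)/n · Σ(θ̂₍₋ᵢ₎ − θ̂₍·₎)².
- **A synthetic-data generator** that plants tunnels with known
  bottleneck radii, water passages along them, and hydrogen-bond
  geometries constructed to satisfy the criteria with margin, so every
  stage can be validated against a ground-truth manifest without any
  trajectory data.

## Worked example

Generate a synthetic bundle (60 events, 3 simulation replicas, a wide
~1.65 Å tunnel and a narrow ~1.15 Å tunnel per replica) and analyze it:

```sh
tunnelwater simulate --scenario bimodal --seed 11 --n-events 60 --n-sims 3 --out demo_in
tunnelwater analyze --tunnels demo_in/tunnels.csv --events demo_in/events.csv \
    --structure demo_in/protein.pdb --meta demo_in/meta.json --out demo_out
tunnelwater report demo_out
```

prints

```
tunnelwater 0.1.0 report
  events: 60 total
  assignment: 58 assigned, 2 unassigned (ambiguous or below 70% duration)
  narrow transport (< 1.4 A): 13 events (22.4%)
  usage: 2 tunnels, top wide at 77.6%

per-tunnel usage (percent of assigned transport):
        count  percent  avg_bottleneck  jackknife_var  jackknife_sd  n_sims
tunnel
wide       45    77.59            1.63            0.0          0.01       3
narrow     13    22.41            1.15            0.0          0.02       3
```

Reading the numbers: 2 of 60 events carried ambiguous tunnel matches and
fall out at the 70% duration rule; of the 58 assigned events 13 (22.4%)
squeezed through constrictions narrower than a water molecule; the two
entrances carry 77.6% and 22.4% of the assigned transport, with average
bottleneck radii 1.63 Å and 1.15 Å and jackknife standard deviations
over the 3 replicas. The report directory also contains `events.tsv`
(per-event minimal sphere, narrow flag, steric overlap, H-bond counts),
`hbonds.tsv` (bond-level geometry and partner classes), `histogram.csv`,
`cdf.csv` and `metadata.json`.

The same flow is available as a library: `tunnelwater.synthetic`
generates bundles, `tunnelwater.analyze_events` runs the analysis on
in-memory objects, and the individual operations
(`assign_frame_sphere`, `minimal_event_sphere`, `detect_hbonds`,
`cluster_endpoints`, `jackknife`, …) are importable from the top level.

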