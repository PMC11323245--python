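# Methods

## The event-sphere model

A tunnel in one trajectory frame is an ordered chain of spheres along a
centerline, index 0 at the buried (active-site) end, the last index at
the protein surface; the frame's *bottleneck radius* is the smallest
sphere radius in the chain. A transport event — one water molecule
entering or leaving through a tunnel — spans a strictly increasing set
of frames with the water-oxygen position known in each.

In every frame of an event the water is assigned to the **closest
tunnel sphere**, measured as Euclidean distance from the water oxygen to
the sphere *center*. The center metric (rather than distance to the
sphere surface) is deliberate: it is deterministic, radius-independent,
and cannot be gamed by a wide sphere "capturing" a distant water. Ties
break to the lowest centerline index, making the assignment fully
reproducible. Frames in which the tunnel has no recorded geometry are
skipped, not interpolated — tunnel-detection tools legitimately miss a
tunnel in frames where it is collapsed, and inventing geometry there
would bias bottlenecks low. An event none of whose frames has geometry
is untraceable and reported as an error.

The **minimal event sphere** is the smallest assigned sphere over the
event; all frames whose assigned radius equals the minimum within
1e-9 Å count as *minimal frames* and are the frames at which hydrogen
bonding and steric contact are evaluated. An event is **narrow** when
its minimal radius is strictly below the threshold (default 1.4 Å, the
conventional effective radius of a water molecule); the strict
inequality puts an exactly-1.4 Å event in the conventional [1.4, 1.5)
histogram bin, consistent with the left-closed binning below.

## Hydrogen-bond criteria

A hydrogen bond requires both a donor–acceptor heavy-atom distance of at
most `d_max` (default 3.5 Å, boundary inclusive — "up to" a cutoff
includes it) and a vertex angle at the *hydrogen*, between the acceptor
heavy atom and the donor heavy atom, inside `[angle_min, angle_max]`
(default [135°, 180°], inclusive; a perfectly linear bond scores 180°).
Water participates in both directions — as donor through either of its
two hydrogens and as acceptor through its oxygen — and the same
heavy-atom pair reached through different hydrogens counts as distinct
bonds, matching how trajectory H-bond tools enumerate triples.

Donor/acceptor roles follow Amber ff14SB atom naming. Histidine depends
on the protonation state (HID: ND1 donor / NE2 acceptor; HIE the
reverse; HIP doubly protonated donor); a structure that says only `HIS`
is taken as the common ε-tautomer HIE. Sulfur acceptors (Met SD) are
not counted. Residues absent from the template table are skipped with a
warning rather than an error, so a stray ligand does not abort a run.

Partner atoms are classified as **backbone** (atom names N, CA, C, O,
OXT and their attached hydrogens, regardless of residue) or by the
side-chain character of their residue: nonpolar (Ala, Gly, Ile, Leu,
Met, Phe, Pro, Trp, Val), polar (Asn, Cys, Gln, Ser, Thr, Tyr),
positive (Arg, His, Lys), negative (Asp, Glu) — a partition of the 20
standard amino acids.

The radius/H-bond association is summarized as a Spearman rank
correlation over per-event (minimal radius, mean bond count) pairs, with
the two-sided p-value from the asymptotic t approximation; it is a
single test per system, so no multiplicity correction is applied.

## Steric verification

The surface–surface distance from a water oxygen to the protein is
`min_i (|x_w − x_i| − r_O − r_i)` over protein atoms *i*, with van der
Waals radii from the Bondi set (O 1.52, C 1.70, N 1.55, S 1.80,
H 1.20 Å), overridable in the run configuration. Negative values are
atomic overlaps; waters in sub-1.4 Å constrictions are expected to show
them, which is precisely the check that such events are squeezing
through genuinely restricted space rather than sitting in an unmodeled
side cavity.

## Tunnel identity, assignment, usage

Tunnel instances found per frame are given a consistent identity by
clustering their surface endpoints with HDBSCAN
(`cluster_selection_epsilon` 1.5 Å, `min_samples` and
`min_cluster_size` 5, `allow_single_cluster` true); endpoints labeled
noise are discarded from downstream tables. The implementation
delegates to scikit-learn's HDBSCAN behind this contract; inputs smaller
than the minimum cluster size are returned as all-noise directly.

An event is attributed to a tunnel only if it was matched to that tunnel
for at least 70% of its frames (inclusive: 70 of 100 passes). When two
tunnels tie at the top fraction the event is ambiguous and stays
unassigned — only unambiguous events enter usage tables. Usage
percentages are therefore computed over *assigned* events (they sum to
100 by construction); the unassigned count is reported separately in
the run metadata.

Per-tunnel average bottleneck radii are means over contributing
snapshots, with variance from a leave-one-simulation-out jackknife,
`Var = (n−1)/n · Σ(θ̂₍₋ᵢ₎ − θ̂₍·₎)²`. Variant comparison joins two usage
tables by tunnel label (a tunnel absent from one side contributes 0%)
and reports `difference = percent_A − percent_B` at full precision,
rounding only at render time to two decimals; the conventional
orientation is wild type minus mutant.

## Distributions and resampling

Histograms of minimal radii use fixed-width, left-closed/right-open bins
`[k·w, (k+1)·w)` with w = 0.1 Å by default — chosen so that the 1.4 Å
water radius falls exactly on a bin edge and peak positions can be
quoted as "1.6–1.7 Å". Bin indices are computed with a 1e-9 tolerance
so a radius stored as 1.2000000000000002 still lands in [1.2, 1.3).
The empirical CDF is inclusive (`F(x) = P(r ≤ x)`) and ends at 1.

Histogram uncertainty across independent simulations comes from
repeated subsampling without replacement (default 100 draws of 45 of 50
groups, seeded; an `exact` mode enumerates all C(n, k) subsamples for
small n) and is reported both as per-bin variance and standard
deviation.

## The synthetic generator

The generator's purpose is validation with planted ground truth, not
imitation of any particular protein.

*Tunnels*: straight (optionally gently bowed) centerlines with 0.8 Å
sphere spacing and 21 spheres; the radius profile is a V shape from
`end_radius` at both mouths to the bottleneck radius r\* at the middle
sphere, so the bottleneck is a strict minimum with a ~0.1 Å gap to its
neighbours. Radii wobble i.i.d. Gaussian per sphere per frame (clamped
at 0.05 Å); centers are static.

*Passages*: the water walks the centerline one sphere per frame, with
lateral (perpendicular) noise truncated to 0.4 of the local sphere
radius — because the noise is perpendicular to a straight centerline,
the closest-center assignment provably recovers the walked sphere, and
the planted minimal radius is recovered up to the radius wobble.

*Hydrogen bonds*: partner groups are constructed analytically at each
event's bottleneck frame — acceptors at 2.9 Å heavy-atom distance and
165° through a specific water hydrogen, donors as N–H groups aimed at
the water oxygen with the same margins — and the construction
self-checks that planted bonds pass the criteria with margin (≤ 3.4 Å,
≥ 150°) while cross-pairs fail by a wide margin (~59°). Up to five
bonds can be planted per frame (two through the water hydrogens, three
from protein donors). The tunnel wall itself is a ring of side-chain
carbons at `sphere radius + 1.70 Å` from the centerline — carbons
cannot hydrogen-bond, but they give the steric check a realistic wall:
a water at the center of a sphere of radius r has surface–surface
distance ≈ r − 1.52 Å, negative exactly when the constriction is
narrower than a water.

*Bookkeeping*: simulation replicas occupy disjoint 1000-frame blocks of
one global frame space and are offset 200 Å apart in space, so all
atoms can be pooled into one multi-model structure. Within a tunnel
every event gets a unique bottleneck frame, and partner groups are
"mobile": outside their event's bottleneck frame they are parked 5000 Å
away, which keeps them out of every cutoff while holding the atom count
constant per PDB model. Tunnels carry one label across replicas (the
identity that entrance clustering would supply), so usage tables can
jackknife over simulations.

Two stock scenarios define the study conditions:

- **clean** (n = 1000 events, 50 replicas): one tunnel per replica with
  r\* ~ U(1.0, 2.0) Å, radius wobble σ = 0.015 Å, lateral noise 0.05 Å.
  Under these conditions the recovered minimal radius is within 0.05 Å
  of r\* for ≥ 95% of events (the wobble at the bottleneck frame is the
  only error source, and 0.05 Å is 3.3 σ), and planted bond counts are
  recovered exactly.
- **bimodal** (n = 5000 events, 50 replicas): each replica has a wide
  tunnel (r\* ~ N(1.65, 0.05) Å) and a narrow one (r\* ~ N(1.15,
  0.03) Å); 20% of events route through the narrow tunnel, planted bond
  counts fall with radius (round(4.35 − 2.0·r\*) plus N(0, 0.6) noise,
  clipped to [0, 5]), and 5% of events carry ambiguous match flags that
  the 70% rule filters out. This produces a bimodal radius histogram
  with modes in [1.1, 1.2) and [1.6, 1.7), a below-1.4 Å fraction near
  20%, and a clearly negative radius/H-bond rank correlation.

What the scenarios do *not* emulate: real tunnels are asymmetric voids,
waters exchange between tunnels mid-passage, frames can be missing, and
H-bond geometry is thermally distributed rather than planted at fixed
margins. Passing tests therefore demonstrate the correctness of the
analysis chain on inputs with known answers, not agreement with any
molecular-dynamics observable.

## Numerical choices and limitations

- All coordinates and radii in Å; frames are 0-based integers.
- Assignment ties → lowest sphere index; assignment-fraction ties →
  unassigned; minimal-frame tolerance 1e-9 Å; histogram edge tolerance
  1e-9.
- CSV output uses four decimals (round-trip loss < 1e-4 Å, below the
  1e-3 Å precision of the PDB format used for structures).
- All stochastic routines take explicit seeds; identical seeds give
  byte-identical table output.
- Problem sizes in the stock scenarios (1000/5000 events, 50 replicas)
  are the package's validation conditions; they run in seconds on one
  CPU and their statistics are insensitive to the seed.
- The pipeline takes tunnel geometries and event paths as given; tunnel
  search, water path tracing and centerline construction belong to the
  upstream tools, and electrostatic interaction energies are out of
  scope.
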