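"""Distributions and resampling statistics for minimal-event-sphere radii.

Histograms use fixed-width bins that are left-closed / right-open
(``[k*w, (k+1)*w)``), so with the default 0.1 A width the conventional
1.4 A water radius falls exactly on a bin edge.  Uncertainty across
independent simulations is attached either by repeated subsampling of
simulations (e.g. 100 draws of 45 of 50) or by leave-one-out jackknife.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RadiusHistogram",
    "CumulativeCurve",
    "radius_histogram",
    "cumulative_distribution",
    "fraction_below",
    "subsample_variance",
    "SubsampleResult",
    "jackknife",
]

_EDGE_TOL = 1e-9


def _bin_index(radii: np.ndarray, bin_width: float) -> np.ndarray:
    """Bin index with a tolerance so values on (or within 1e-9 of) an
    upper edge land in the right-hand bin."""
    k = np.floor(radii / bin_width).astype(int)
    upper = (k + 1) * bin_width
    return np.where(radii >= upper - _EDGE_TOL, k + 1, k)


@dataclass
class RadiusHistogram:
    """Histogram of minimal event sphere radii.

    ``edges`` has ``len(counts) + 1`` entries; bin ``i`` covers
    ``[edges[i], edges[i+1])``.
    """

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    variance: np.ndarray | None = None

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        n = self.n_events
        return self.counts / n if n else self.counts.astype(float)

    def mode_bins(self, n_modes: int = 1) -> list[tuple[float, float]]:
        """Left/right edges of the ``n_modes`` local maxima, in order of
        decreasing count.  A local maximum is a bin strictly taller than
        both neighbours (ends compare against one side only)."""
        c = self.counts
        peaks = []
        for i in range(len(c)):
            left = c[i - 1] if i > 0 else -1
            right = c[i + 1] if i < len(c) - 1 else -1
            if c[i] > left and c[i] > right:
                peaks.append(i)
        peaks.sort(key=lambda i: -c[i])
        return [(float(self.edges[i]), float(self.edges[i + 1]))
                for i in peaks[:n_modes]]


def radius_histogram(radii: Sequence[float],
                     bin_width: float = 0.1,
                     edges: np.ndarray | None = None) -> RadiusHistogram:
    """Histogram of radii with left-closed / right-open fixed-width bins.

    ``edges`` may be supplied to force a common bin range (e.g. across
    resamples); otherwise bins span the data.  An empty input yields an
    empty histogram.
    """
    if not bin_width > 0:
        raise ValueError(f"bin width must be > 0, got {bin_width}")
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if radii.size and not np.all(radii > 0):
        raise ValueError("all radii must be > 0")
    if radii.size == 0 and edges is None:
        return RadiusHistogram(bin_width, np.empty(0), np.empty(0, dtype=int))
    if edges is None:
        k = _bin_index(radii, bin_width)
        k0, k1 = int(k.min()), int(k.max())
    else:
        edges = np.asarray(edges, dtype=float)
        k0 = int(round(edges[0] / bin_width))
        k1 = int(round(edges[-1] / bin_width)) - 1
    k = _bin_index(radii, bin_width) if radii.size else np.empty(0, dtype=int)
    counts = np.zeros(k1 - k0 + 1, dtype=int)
    for idx in k:
        if k0 <= idx <= k1:
            counts[idx - k0] += 1
    out_edges = (np.arange(k0, k1 + 2)) * bin_width
    return RadiusHistogram(bin_width, out_edges, counts)


@dataclass
class CumulativeCurve:
    """Empirical cumulative distribution of minimal radii."""

    radii: np.ndarray      # sorted
    fractions: np.ndarray  # i/n at each sorted radius

    def value_at(self, x: float) -> float:
        """Fraction of events with radius <= x."""
        n = self.radii.size
        return float(np.searchsorted(self.radii, x, side="right") / n)


def cumulative_distribution(radii: Sequence[float]) -> CumulativeCurve:
    """Empirical CDF of minimal radii, normalized to end at 1."""
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if radii.size == 0:
        raise ValueError("empty input")
    srt = np.sort(radii)
    frac = np.arange(1, srt.size + 1) / srt.size
    return CumulativeCurve(srt, frac)


def fraction_below(radii: Sequence[float], threshold: float = 1.4) -> float:
    """Fraction of events with minimal radius strictly below threshold."""
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if radii.size == 0:
        raise ValueError("empty input")
    return float(np.count_nonzero(radii < threshold) / radii.size)


@dataclass
class SubsampleResult:
    """Per-bin spread of histogram counts over subsampled simulations."""

    edges: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    sd: np.ndarray
    n_reps: int


def subsample_variance(groups: Sequence[Sequence[float]],
                       k: int = 45,
                       reps: int = 100,
                       seed: int | None = None,
                       bin_width: float = 0.1,
                       exact: bool = False) -> SubsampleResult:
    """Histogram variance from subsampling simulations without replacement.

    For each repetition, ``k`` of the ``n`` per-simulation radius groups
    are drawn without replacement and the radius histogram recomputed on
    the pooled draw; per-bin variance (and SD) across repetitions is
    reported on a bin range common to the full data.  With
    ``exact=True`` all C(n, k) subsamples are enumerated instead of
    sampling (only sensible for tiny n).
    """
    groups = [np.asarray(g, dtype=float).reshape(-1) for g in groups]
    n = len(groups)
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of "
                         f"groups ({n})")
    pooled = np.concatenate(groups) if groups else np.empty(0)
    full = radius_histogram(pooled, bin_width)
    edges = full.edges

    if exact:
        draws = list(itertools.combinations(range(n), k))
    else:
        rng = np.random.default_rng(seed)
        draws = [rng.choice(n, size=k, replace=False) for _ in range(reps)]

    rep_counts = np.empty((len(draws), len(full.counts)))
    for i, idx in enumerate(draws):
        sub = np.concatenate([groups[j] for j in idx])
        rep_counts[i] = radius_histogram(sub, bin_width, edges=edges).counts
    var = rep_counts.var(axis=0)
    return SubsampleResult(edges=edges,
                           mean=rep_counts.mean(axis=0),
                           variance=var,
                           sd=np.sqrt(var),
                           n_reps=len(draws))


def jackknife(statistic: Callable[[Sequence], float],
              groups: Sequence) -> tuple[float, float]:
    """Leave-one-group-out jackknife estimate and variance.

    ``statistic`` maps a sequence of groups to a scalar.  Returns the
    full-sample estimate and the jackknife variance
    ``(n-1)/n * sum((theta_(-i) - theta_bar)^2)``.
    """
    groups = list(groups)
    n = len(groups)
    if n < 2:
        raise ValueError("jackknife requires at least 2 groups")
    estimate = float(statistic(groups))
    loo = np.array([
        float(statistic(groups[:i] + groups[i + 1:])) for i in range(n)
    ])
    var = (n - 1) / n * float(np.sum((loo - loo.mean()) ** 2))
    return estimate, var
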