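"""Average heart-cycle morphology, DTW distances and prototype clustering.

Beats are cut R-to-R and resampled to a fixed cycle-percentage grid so that
morphology averages are independent of the individual heart rate.  An ideal
single-lead prototype set is built from excellent-quality normal-sinus
recordings: averaged morphologies are clustered on their pairwise dynamic
time warping (DTW) distances with a k-medoids partition (the DTW metric has
no vector-space mean, so medoids replace centroids; per-cluster display
morphologies are pointwise averages of the members), and clusters are
selected greedily by increasing morphological variance until they cover
~90% of the recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # jitted inner loop; plain Python fallback keeps the package importable
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


DEFAULT_N_POINTS = 200
DEFAULT_BAND = 0.10
DEFAULT_K = 4
DEFAULT_COVERAGE = 0.90

__all__ = [
    "BeatMorphology",
    "PrototypeCluster",
    "PrototypeSet",
    "TooFewBeatsError",
    "segment_beats",
    "resample_to_cycle",
    "average_morphology",
    "dtw_distance",
    "cluster_prototypes",
    "select_prototypes",
    "fit_prototypes",
]


class TooFewBeatsError(ValueError):
    """Not enough complete heart cycles for morphology analysis."""


@dataclass
class BeatMorphology:
    """Mean and spread of the heart cycle on a cycle-percentage grid."""

    cycle: np.ndarray
    std_curve: np.ndarray
    n_beats: int

    def __post_init__(self) -> None:
        self.cycle = np.asarray(self.cycle, dtype=float)
        self.std_curve = np.asarray(self.std_curve, dtype=float)
        if self.cycle.shape != self.std_curve.shape:
            raise ValueError("cycle and std_curve must align")


@dataclass
class PrototypeCluster:
    mean: np.ndarray
    std: np.ndarray
    fraction: float
    members: np.ndarray


@dataclass
class PrototypeSet:
    """k morphology clusters plus the subset selected as ideal prototypes."""

    clusters: list[PrototypeCluster]
    selected: list[int]
    k: int
    seed: int | None = None
    coverage_target: float = DEFAULT_COVERAGE

    @property
    def selected_prototypes(self) -> list[np.ndarray]:
        return [self.clusters[i].mean for i in self.selected]


def segment_beats(samples: np.ndarray, peaks: np.ndarray) -> list[np.ndarray]:
    """Cut the trace into R-to-R beats (half-open); partial edge cycles drop."""
    idx = np.asarray(peaks, dtype=int)
    if idx.size < 4:
        raise TooFewBeatsError(f"need at least 4 R-peaks, got {idx.size}")
    x = np.asarray(samples, dtype=float)
    return [x[idx[i] : idx[i + 1]] for i in range(idx.size - 1)]


def resample_to_cycle(beat: np.ndarray, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Linear interpolation of one beat onto [0, 100)% of the heart cycle."""
    b = np.asarray(beat, dtype=float)
    if b.size < 4:
        raise ValueError("beat too short to resample")
    pos = np.arange(n_points) / n_points * b.size
    return np.interp(pos, np.arange(b.size), b)


def average_morphology(
    beats: list[np.ndarray], n_points: int = DEFAULT_N_POINTS
) -> BeatMorphology:
    """Pointwise mean/std over the cycle-resampled beats."""
    if len(beats) < 3:
        raise TooFewBeatsError(f"need at least 3 beats, got {len(beats)}")
    stack = np.vstack([resample_to_cycle(b, n_points) for b in beats])
    return BeatMorphology(
        cycle=stack.mean(axis=0), std_curve=stack.std(axis=0), n_beats=len(beats)
    )


@njit(cache=False)
def _dtw_band(a, b, band_width):  # pragma: no cover - exercised via dtw_distance
    n, m = a.shape[0], b.shape[0]
    INF = 1e300
    cost = np.full((n + 1, m + 1), INF)
    cost[0, 0] = 0.0
    for i in range(1, n + 1):
        # classic Sakoe-Chiba band |i-j| <= w (symmetric in the arguments)
        lo = max(1, int(np.ceil(i - band_width)))
        hi = min(m, int(np.floor(i + band_width)))
        for j in range(lo, hi + 1):
            d = abs(a[i - 1] - b[j - 1])
            prev = cost[i - 1, j - 1]
            if cost[i - 1, j] < prev:
                prev = cost[i - 1, j]
            if cost[i, j - 1] < prev:
                prev = cost[i, j - 1]
            cost[i, j] = d + prev
    return cost[n, m]


def dtw_distance(a: np.ndarray, b: np.ndarray, band: float = DEFAULT_BAND) -> float:
    """Dynamic time warping alignment cost between two 1-D sequences.

    Classic dynamic program with absolute-difference local cost and a
    Sakoe-Chiba band of the given fractional width (``band=1`` disables the
    constraint).  Symmetric, non-negative, zero iff the sequences are equal.
    """
    x = np.ascontiguousarray(a, dtype=np.float64)
    y = np.ascontiguousarray(b, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("sequences must be non-empty")
    if not 0 < band <= 1:
        raise ValueError("band must be in (0, 1]")
    # the band must cover the length difference or no path is feasible
    width = max(1.0, band * max(x.size, y.size), float(abs(x.size - y.size)))
    if x.size * y.size <= 4 or not _HAVE_NUMBA:
        return float(_dtw_band.py_func(x, y, width) if _HAVE_NUMBA else _dtw_band(x, y, width))
    return float(_dtw_band(x, y, width))


def _pairwise_dtw(morphs: list[np.ndarray], band: float) -> np.ndarray:
    n = len(morphs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(morphs[i], morphs[j], band)
    return d


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 50):
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(n_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new[c] = members[np.argmin(within)]
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(dist[:, medoids], axis=1)
    total = dist[np.arange(n), medoids[labels]].sum()
    return medoids, labels, total


def cluster_prototypes(
    morphologies: list[np.ndarray],
    k: int = DEFAULT_K,
    seed: int | None = None,
    band: float = DEFAULT_BAND,
    n_restarts: int = 10,
) -> PrototypeSet:
    """Partition averaged morphologies by DTW distance (k-medoids, seeded).

    Runs ``n_restarts`` seeded restarts and keeps the partition with the
    lowest total within-cluster medoid distance.  Cluster display
    morphologies are pointwise averages of the members.  A degenerate input
    (all identical) collapses into one effective cluster; empty clusters are
    reported with fraction 0.
    """
    n = len(morphologies)
    if n < k:
        raise ValueError(f"need at least k={k} morphologies, got {n}")
    dist = _pairwise_dtw(morphologies, band)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        medoids, labels, total = _kmedoids(dist, k, rng)
        if best is None or total < best[2]:
            best = (medoids, labels, total)
    _, labels, _ = best
    stack = np.vstack(morphologies)
    clusters = []
    for c in range(k):
        members = np.where(labels == c)[0]
        if members.size == 0:
            clusters.append(
                PrototypeCluster(
                    mean=np.zeros(stack.shape[1]),
                    std=np.full(stack.shape[1], np.inf),
                    fraction=0.0,
                    members=members,
                )
            )
            continue
        sub = stack[members]
        clusters.append(
            PrototypeCluster(
                mean=sub.mean(axis=0),
                std=sub.std(axis=0),
                fraction=members.size / n,
                members=members,
            )
        )
    pset = PrototypeSet(clusters=clusters, selected=[], k=k, seed=seed)
    pset.selected = select_prototypes(pset)
    return pset


def select_prototypes(
    prototype_set: PrototypeSet, coverage_target: float = DEFAULT_COVERAGE
) -> list[int]:
    """Pick the ideal prototype clusters: low variance first, ~90% coverage.

    Clusters are added in increasing order of mean per-point standard
    deviation until their cumulative membership fraction reaches the
    coverage target.
    """
    order = np.argsort([c.std.mean() for c in prototype_set.clusters])
    selected: list[int] = []
    cum = 0.0
    for i in order:
        frac = prototype_set.clusters[i].fraction
        if frac == 0.0:
            continue
        selected.append(int(i))
        cum += frac
        if cum >= coverage_target:
            break
    prototype_set.coverage_target = coverage_target
    return selected


def fit_prototypes(
    recordings,
    k: int = DEFAULT_K,
    seed: int | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> PrototypeSet:
    """Build the ideal prototype set from excellent normal-sinus recordings.

    Each recording contributes its averaged morphology (after inversion
    correction and peak detection); recordings where preprocessing fails are
    skipped.
    """
    from .preprocessing import (
        PeakDetectionError,
        TooShortError,
        correct_inversion,
        detect_r_peaks,
    )

    morphs = []
    for rec in recordings:
        try:
            s, _ = correct_inversion(rec.samples)
            peaks = detect_r_peaks(s, rec.fs)
            beats = segment_beats(s, peaks.indices)
            morphs.append(average_morphology(beats, n_points).cycle)
        except (PeakDetectionError, TooShortError, TooFewBeatsError, ValueError):
            continue
    if len(morphs) < k:
        raise ValueError("too few usable recordings to fit prototypes")
    return cluster_prototypes(morphs, k=k, seed=seed)
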