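"""Pairwise footprint distances, orientation-distance maps, and the distance cutoff.

The central idea: two exposures of the same molecule at similar
orientations produce similar explosion footprints, so a small Euclidean
distance in pixel space,

    d(A, B) = ||A - B||_2 = sqrt(sum_i (A_i - B_i)^2)    (raw counts),

flags a small relative orientation angle theta.  Globally there is no
correlation — most random orientation pairs are far apart on SO(3) — but
below a *distance cutoff* the pairs are enriched in small angles.  The
cutoff is found without orientation knowledge: bin the (d, theta) scatter
along d, take the upper envelope

    f(x) = max{ theta | (x, theta) occupied by at least one pair },

and place the cutoff where the envelope rises fastest,

    x_cutoff = argmax df/dx,

estimated by forward differences over consecutive occupied bins.  Pairs
with d <= x_cutoff are the retrieved similarly-oriented set; their count
and mean angle quantify how much orientation information the footprints
carry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import pdist

from .detector import Footprint, gaussian_blur
from .rotations import pairwise_relative_angles

__all__ = [
    "OrientationDistanceMap",
    "EnvelopeCurve",
    "CutoffReport",
    "footprint_distance",
    "build_orientation_distance_map",
    "upper_envelope",
    "distance_cutoff",
    "under_cutoff_stats",
    "efficiency_sweep",
    "analyze_footprints",
    "PairSample",
    "pool_maps",
]


@dataclass
class OrientationDistanceMap:
    """All N(N-1)/2 (distance, relative angle) pairs for a set of footprints.

    ``i``/``j`` index the originating footprints; arrays are ordered like
    ``scipy.spatial.distance.pdist`` (row-major upper triangle, i < j).
    """

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    theta: np.ndarray
    n: int
    source_label: str = ""

    def __post_init__(self):
        m = self.n * (self.n - 1) // 2
        if not (len(self.d) == len(self.theta) == len(self.i) == len(self.j) == m):
            raise ValueError(f"expected {m} pairs for n={self.n}")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if np.any((self.theta < 0) | (self.theta > math.pi + 1e-12)):
            raise ValueError("relative angles must lie in [0, pi]")

    @property
    def n_pairs(self) -> int:
        return len(self.d)


@dataclass
class PairSample:
    """A bag of (distance, angle) pairs without per-footprint indexing.

    Produced by :func:`pool_maps` when pairs from several independent
    replicate maps are analyzed jointly (cross-replicate pairs are never
    formed); accepted everywhere a full map is.
    """

    d: np.ndarray
    theta: np.ndarray
    source_label: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.d)


def pool_maps(maps) -> PairSample:
    """Concatenate the pairs of several orientation-distance maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to pool")
    return PairSample(
        d=np.concatenate([m.d for m in maps]),
        theta=np.concatenate([m.theta for m in maps]),
        source_label=maps[0].source_label,
    )


@dataclass
class EnvelopeCurve:
    """Upper envelope of the binned orientation-distance scatter.

    ``f_values`` holds the per-bin maximum angle; only bins flagged in
    ``occupied`` carry a value (NaN elsewhere).
    """

    bin_edges: np.ndarray
    f_values: np.ndarray
    occupied: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied_centers(self) -> np.ndarray:
        return self.bin_centers[self.occupied]

    @property
    def occupied_values(self) -> np.ndarray:
        return self.f_values[self.occupied]


@dataclass
class CutoffReport:
    """Distance cutoff and the statistics of the pairs beneath it."""

    x_cutoff: float
    mean_angle_under: float  # NaN when no pair falls under the cutoff
    n_pairs_under: int
    n_pairs_total: int
    efficiency: float = 1.0
    source_label: str = ""
    valid: bool = True

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CutoffReport":
        return cls(**json.loads(text))


def _distance_input(x, partner) -> np.ndarray:
    if isinstance(x, Footprint):
        if not isinstance(partner, Footprint):
            raise ValueError(
                "cannot mix a raw Footprint with a blurred/float image; "
                "blur both or neither"
            )
        return x.counts.astype(np.float64)
    arr = np.asarray(x, dtype=np.float64)
    if isinstance(partner, Footprint):
        raise ValueError(
            "cannot mix a raw Footprint with a blurred/float image; blur both or neither"
        )
    return arr


def footprint_distance(A, B) -> float:
    """Euclidean norm in pixel space between two footprints (not normalized).

    Both inputs must be in the same preprocessing state: two raw
    :class:`Footprint` objects, or two float images blurred with the same
    sigma.
    """
    a = _distance_input(A, B)
    b = _distance_input(B, A)
    if a.shape != b.shape:
        raise ValueError(f"footprint shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def build_orientation_distance_map(
    footprints: list[Footprint],
    blur_sigma: float | None = 0.5,
    allow_mixed_sources: bool = False,
) -> OrientationDistanceMap:
    """Compute all pairwise (d, theta) tuples for a footprint set.

    Distances use the pixel-space Euclidean norm, after an optional
    per-panel Gaussian blur (default sigma 0.5 px — small spatial offsets
    between visually similar patterns would otherwise inflate d); angles
    come from the stored ground-truth orientations.
    """
    n = len(footprints)
    if n < 2:
        raise ValueError("need at least 2 footprints")
    labels = {fp.source_label for fp in footprints}
    if len(labels) > 1 and not allow_mixed_sources:
        raise ValueError(
            f"footprints come from mixed sources {sorted(labels)}; "
            "pass allow_mixed_sources=True to override"
        )

    if blur_sigma:
        images = np.stack([gaussian_blur(fp, blur_sigma) for fp in footprints])
    else:
        images = np.stack([fp.counts for fp in footprints]).astype(np.float64)
    d = pdist(images.reshape(n, -1))

    quats = np.stack([fp.orientation.q for fp in footprints])
    theta = pairwise_relative_angles(quats)

    iu, ju = np.triu_indices(n, k=1)
    return OrientationDistanceMap(
        i=iu, j=ju, d=d, theta=theta, n=n, source_label=sorted(labels)[0]
    )


def upper_envelope(odm: OrientationDistanceMap, n_bins: int = 100) -> EnvelopeCurve:
    """Bin the distance axis uniformly and take the max angle per occupied bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if odm.n_pairs < 1:
        raise ValueError("empty orientation-distance map")
    lo, hi = float(odm.d.min()), float(odm.d.max())
    if hi <= lo:  # all pairs at one distance: a single occupied bin
        hi = lo + max(abs(lo), 1.0) * 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.minimum(((odm.d - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)

    f = np.full(n_bins, -np.inf)
    np.maximum.at(f, idx, odm.theta)
    occupied = np.isfinite(f)
    f[~occupied] = np.nan
    return EnvelopeCurve(bin_edges=edges, f_values=f, occupied=occupied)


def distance_cutoff(env: EnvelopeCurve) -> float:
    """Distance at which the envelope's forward-difference slope is maximal.

    Slopes are taken between consecutive *occupied* bin centers (robust to
    gaps); the slope over [c_k, c_{k+1}] is attributed to c_k, and ties
    break toward the smaller distance.
    """
    c = env.occupied_centers
    f = env.occupied_values
    if len(c) < 3:
        raise ValueError("envelope too sparse: need at least 3 occupied bins")
    slopes = np.diff(f) / np.diff(c)
    return float(c[int(np.argmax(slopes))])


def under_cutoff_stats(
    odm: OrientationDistanceMap,
    x_cutoff: float,
    efficiency: float = 1.0,
) -> CutoffReport:
    """Count and average the relative angles of all pairs with d <= x_cutoff."""
    mask = odm.d <= x_cutoff
    n_under = int(mask.sum())
    mean_angle = float(odm.theta[mask].mean()) if n_under else float("nan")
    return CutoffReport(
        x_cutoff=float(x_cutoff),
        mean_angle_under=mean_angle,
        n_pairs_under=n_under,
        n_pairs_total=odm.n_pairs,
        efficiency=efficiency,
        source_label=odm.source_label,
        valid=n_under > 0,
    )


def analyze_footprints(
    footprints: list[Footprint],
    n_bins: int = 100,
    blur_sigma: float | None = 0.5,
    efficiency: float = 1.0,
) -> tuple[OrientationDistanceMap, EnvelopeCurve, CutoffReport]:
    """Full retrieval chain: map -> envelope -> cutoff -> under-cutoff stats."""
    odm = build_orientation_distance_map(footprints, blur_sigma=blur_sigma)
    env = upper_envelope(odm, n_bins=n_bins)
    cutoff = distance_cutoff(env)
    return odm, env, under_cutoff_stats(odm, cutoff, efficiency=efficiency)


def efficiency_sweep(
    footprint_sets: dict[float, list[Footprint]],
    n_bins: int = 100,
    blur_sigma: float | None = 0.5,
) -> list[CutoffReport]:
    """Run the retrieval chain for footprint sets at several detector efficiencies.

    Sets whose footprints are all empty (e.g. efficiency 0) yield an invalid
    report rather than an error.
    """
    reports = []
    for eff in sorted(footprint_sets):
        if not 0.0 <= eff <= 1.0:
            raise ValueError("efficiencies must lie in [0, 1]")
        fps = footprint_sets[eff]
        if all(fp.counts.sum() == 0 for fp in fps):
            reports.append(
                CutoffReport(
                    x_cutoff=float("nan"),
                    mean_angle_under=float("nan"),
                    n_pairs_under=0,
                    n_pairs_total=len(fps) * (len(fps) - 1) // 2,
                    efficiency=eff,
                    source_label=fps[0].source_label if fps else "",
                    valid=False,
                )
            )
            continue
        _, _, report = analyze_footprints(
            fps, n_bins=n_bins, blur_sigma=blur_sigma, efficiency=eff
        )
        reports.append(report)
    return reports
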