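"""Two-panel virtual ion detector: ray projection, pixel binning, efficiency, blur.

Two flat square detectors (side 120 mm, 18x18 pixels each) face the
explosion origin from +/-30 mm along the detector normal (lab z by
default).  Each asymptotic ion direction is ray-cast from the origin; the
panel intersection point is binned into the panel's pixel grid, rays
missing both panels are discarded.  The two panel images are stacked into
one (2n x n) integer count matrix — the *explosion footprint*.  Footprints
carry no time-of-flight, momentum, mass or coincidence information; they
are plain spatial ion histograms.

Pixel convention: the 18x18 "points" on each panel are the cell centers of
a uniform grid over the square; nearest-point assignment is then half-open
interval binning per axis, with the single top/right edge folded into the
last cell.  An on-axis ray hits the exact panel center, equidistant from 4
cell centers, and lands deterministically in cell (n/2, n/2).  The front
(+normal) panel occupies rows 0..n-1, the back panel rows n..2n-1; both are
indexed by the lab-frame transverse coordinates of the intersection point
(no mirroring).  Row index grows with the second transverse axis, column
index with the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .explosion import IonEjecta
from .rotations import Rotation

__all__ = [
    "DetectorGeometry",
    "Footprint",
    "project_to_detectors",
    "apply_efficiency",
    "gaussian_blur",
    "save_footprints",
    "load_footprints",
]

_AXES = {"x": 0, "y": 1, "z": 2}
_PLANE_TOL = 1e-12


@dataclass(frozen=True)
class DetectorGeometry:
    """Geometry of the two square panels, in millimetres."""

    side_length: float = 120.0
    distance: float = 30.0
    n_pixels_side: int = 18
    normal_axis: str = "z"

    def __post_init__(self):
        if self.side_length <= 0 or self.distance <= 0:
            raise ValueError("side_length and distance must be > 0")
        if self.n_pixels_side < 1:
            raise ValueError("n_pixels_side must be >= 1")
        if self.normal_axis not in _AXES:
            raise ValueError(f"normal_axis must be one of {sorted(_AXES)}")

    @property
    def pitch(self) -> float:
        """Pixel pitch in mm (default 120/18 ~= 6.67 mm)."""
        return self.side_length / self.n_pixels_side

    @property
    def shape(self) -> tuple[int, int]:
        return (2 * self.n_pixels_side, self.n_pixels_side)


@dataclass
class Footprint:
    """Stacked two-panel ion count histogram for one exposure.

    ``counts`` is a raw (2n, n) non-negative integer image; Gaussian-blurred
    variants are separate float arrays produced by :func:`gaussian_blur`,
    never stored back into a Footprint.
    """

    counts: np.ndarray
    orientation: Rotation
    efficiency: float = 1.0
    n_detected: int = 0
    n_ions: int = 0
    source_label: str = ""
    realization: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("footprint counts must be integers (blur returns a separate float view)")
        if self.counts.ndim != 2 or self.counts.shape[0] != 2 * self.counts.shape[1]:
            raise ValueError("footprint must have shape (2n, n)")
        if np.any(self.counts < 0):
            raise ValueError("footprint counts must be non-negative")
        self.counts = self.counts.astype(np.uint32)

    @property
    def n_pixels_side(self) -> int:
        return self.counts.shape[1]

    @property
    def panels(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_pixels_side
        return self.counts[:n], self.counts[n:]


def project_to_detectors(
    ejecta: IonEjecta, geom: DetectorGeometry, orientation: Rotation | None = None
) -> Footprint:
    """Bin ion directions (rotated by ``orientation``) into the stacked footprint.

    A ray with positive component along +normal intersects the front plane
    at +distance, negative the back plane at -distance; rays within 1e-12 of
    the detector plane, or intersecting outside the square, are discarded.
    ``n_detected + n_discarded = n_ions`` always holds.
    """
    orientation = orientation or Rotation.identity()
    dirs = ejecta.directions @ orientation.as_matrix().T

    ax = _AXES[geom.normal_axis]
    u_ax, v_ax = [a for a in range(3) if a != ax]
    n_comp = dirs[:, ax]
    half = geom.side_length / 2.0
    npix = geom.n_pixels_side

    counts = np.zeros(geom.shape, dtype=np.uint32)
    n_detected = 0
    for panel, mask in ((0, n_comp > _PLANE_TOL), (1, n_comp < -_PLANE_TOL)):
        if not np.any(mask):
            continue
        t = geom.distance / np.abs(n_comp[mask])
        u = dirs[mask, u_ax] * t
        v = dirs[mask, v_ax] * t
        hit = (np.abs(u) <= half) & (np.abs(v) <= half)
        col = np.minimum(((u[hit] + half) / geom.pitch).astype(np.int64), npix - 1)
        row = np.minimum(((v[hit] + half) / geom.pitch).astype(np.int64), npix - 1)
        np.add.at(counts, (row + panel * npix, col), 1)
        n_detected += int(hit.sum())

    return Footprint(
        counts=counts,
        orientation=orientation,
        efficiency=1.0,
        n_detected=n_detected,
        n_ions=ejecta.n_ions,
        source_label=ejecta.source_label,
    )


def apply_efficiency(fp: Footprint, efficiency: float, rng_seed=None) -> Footprint:
    """Binomially thin each pixel: every recorded ion is kept with ``efficiency``.

    Models an imperfect detector where only a fraction of impinging ions is
    registered.  Deterministic given ``rng_seed``; ``efficiency`` must lie
    in [0, 1].
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if efficiency == 1.0:
        return replace(fp, counts=fp.counts.copy())
    rng = np.random.default_rng(rng_seed)
    thinned = rng.binomial(fp.counts.astype(np.int64), efficiency).astype(np.uint32)
    return replace(
        fp,
        counts=thinned,
        efficiency=fp.efficiency * efficiency,
        n_detected=int(thinned.sum()),
    )


def gaussian_blur(fp, sigma: float = 0.5) -> np.ndarray:
    """Per-panel 2D Gaussian blur; returns a float image of the same shape.

    The two panels are physically separate detectors, so the convolution is
    applied to each n x n panel independently and never leaks across the
    stack boundary.  Boundary mode is constant-zero padding (hard detector
    edges); total intensity is preserved for counts away from panel edges.
    """
    image = fp.counts if isinstance(fp, Footprint) else np.asarray(fp)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = image.astype(np.float64)
    if image.ndim != 2 or image.shape[0] % 2:
        raise ValueError("expected a stacked (2n, n) image")
    if sigma == 0:
        return image.copy()
    n = image.shape[0] // 2
    out = np.empty_like(image)
    out[:n] = ndimage.gaussian_filter(image[:n], sigma, mode="constant")
    out[n:] = ndimage.gaussian_filter(image[n:], sigma, mode="constant")
    return out


# ---------------------------------------------------------------------------
# footprint set container (NPZ)
# ---------------------------------------------------------------------------

def save_footprints(path, footprints: list[Footprint], geom: DetectorGeometry) -> None:
    """Store a footprint set with orientations and geometry in one NPZ file."""
    np.savez_compressed(
        path,
        counts=np.stack([fp.counts for fp in footprints]),
        quaternions=np.stack([fp.orientation.q for fp in footprints]),
        efficiencies=np.array([fp.efficiency for fp in footprints]),
        n_ions=np.array([fp.n_ions for fp in footprints]),
        realizations=np.array([fp.realization for fp in footprints]),
        source_label=np.array(footprints[0].source_label if footprints else ""),
        geometry=np.array(
            [geom.side_length, geom.distance, float(geom.n_pixels_side)]
        ),
        normal_axis=np.array(geom.normal_axis),
    )


def load_footprints(path) -> tuple[list[Footprint], DetectorGeometry]:
    with np.load(path) as data:
        geom = DetectorGeometry(
            side_length=float(data["geometry"][0]),
            distance=float(data["geometry"][1]),
            n_pixels_side=int(data["geometry"][2]),
            normal_axis=str(data["normal_axis"]),
        )
        label = str(data["source_label"])
        fps = [
            Footprint(
                counts=c,
                orientation=Rotation(q),
                efficiency=float(e),
                n_detected=int(c.sum()),
                n_ions=int(ni),
                source_label=label,
                realization=int(r),
            )
            for c, q, e, ni, r in zip(
                data["counts"],
                data["quaternions"],
                data["efficiencies"],
                data["n_ions"],
                data["realizations"],
            )
        ]
    return fps, geom
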