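"""Explosion-reproducibility variance and fluence-robustness metrics.

How reproducible is an explosion?  Fix the orientation, explode K
independent realizations of the same structure, normalize each footprint
by its total intensity, and measure the per-pixel population variance
around the per-pixel mean; averaging over pixels gives a single scalar
per structure.  Lower variance means the ion pattern is more deterministic,
which is what makes pixel-space orientation matching work — the variance
drops as the number of atoms (and hence detected ions) grows.

The fluence-robustness metric compares mean raw-count images of two
footprint sets taken at different pulse fluences (same fixed orientation):
the summed and per-pixel mean absolute differences quantify how much of
the pattern shifts when the pulse intensity fluctuates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detector import Footprint

__all__ = [
    "VarianceReport",
    "FluenceRobustness",
    "normalize_image",
    "pattern_variance",
    "fluence_robustness",
]

logger = logging.getLogger(__name__)


@dataclass
class VarianceReport:
    """Per-pixel and pixel-averaged variance of K fixed-orientation footprints."""

    per_pixel_variance: np.ndarray
    protein_variance: float
    K: int
    mean_detected_ions: float
    source_label: str = ""


@dataclass
class FluenceRobustness:
    """Difference between mean raw-count images of two footprint sets."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    difference: np.ndarray
    summed_abs_error: float
    mean_abs_error_per_pixel: float


def normalize_image(fp) -> np.ndarray:
    """Divide a footprint by its total intensity so it sums to 1."""
    image = (fp.counts if isinstance(fp, Footprint) else np.asarray(fp)).astype(np.float64)
    total = image.sum()
    if total <= 0:
        raise ValueError("cannot normalize a zero-intensity footprint")
    return image / total


def _same_orientation(footprints: list[Footprint]) -> bool:
    q0 = footprints[0].orientation.q
    return all(
        min(np.abs(fp.orientation.q - q0).max(), np.abs(fp.orientation.q + q0).max()) < 1e-12
        for fp in footprints
    )


def pattern_variance(footprints: list[Footprint]) -> VarianceReport:
    """Pixel-wise population variance of normalized fixed-orientation footprints.

    All K footprints must share one orientation and one source (this is an
    intra-structure reproducibility measure, not an inter-structure one).
    Zero-intensity footprints are excluded with a logged warning.  The
    variance uses divisor K (population form), and the scalar summary is
    the mean of the per-pixel variances.
    """
    if len(footprints) < 2:
        raise ValueError("need at least 2 footprints")
    if len({fp.source_label for fp in footprints}) > 1:
        raise ValueError("footprints come from mixed sources")
    if not _same_orientation(footprints):
        raise ValueError("footprints have mixed orientations")

    usable = [fp for fp in footprints if fp.counts.sum() > 0]
    if len(usable) < len(footprints):
        logger.warning(
            "excluding %d zero-intensity footprint(s) from the variance",
            len(footprints) - len(usable),
        )
    if len(usable) < 2:
        raise ValueError("fewer than 2 non-empty footprints")

    stack = np.stack([normalize_image(fp) for fp in usable])
    per_pixel = stack.var(axis=0)  # divisor K
    return VarianceReport(
        per_pixel_variance=per_pixel,
        protein_variance=float(per_pixel.mean()),
        K=len(usable),
        mean_detected_ions=float(np.mean([fp.counts.sum() for fp in usable])),
        source_label=usable[0].source_label,
    )


def fluence_robustness(
    set_a: list[Footprint], set_b: list[Footprint]
) -> FluenceRobustness:
    """Compare mean raw-count images of two fixed-orientation footprint sets.

    Raw counts (not normalized images) are averaged, matching how ion-count
    errors are reported; the per-pixel figure divides the summed absolute
    difference by the full stacked pixel count.
    """
    if not set_a or not set_b:
        raise ValueError("both footprint sets must be non-empty")
    if not _same_orientation(list(set_a) + list(set_b)):
        raise ValueError("all footprints must share one fixed orientation")
    mean_a = np.mean([fp.counts for fp in set_a], axis=0)
    mean_b = np.mean([fp.counts for fp in set_b], axis=0)
    if mean_a.shape != mean_b.shape:
        raise ValueError("footprint shapes differ between the sets")
    diff = mean_a - mean_b
    summed = float(np.abs(diff).sum())
    return FluenceRobustness(
        mean_a=mean_a,
        mean_b=mean_b,
        difference=diff,
        summed_abs_error=summed,
        mean_abs_error_per_pixel=summed / diff.size,
    )
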