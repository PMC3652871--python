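"""Recursive zonal equal-area partition of the unit sphere.

Partitions S^2 into ``N`` regions of exactly equal spherical area: two polar
caps plus latitudinal collars, each collar subdivided into equal-area
cells by meridians.  Regions are closed at their northern/western bounds
and open at the southern/eastern ones (the south pole and the 2*pi meridian
are folded back in), so every point of the sphere belongs to exactly one
region.  The construction is fully analytic: each region's area is 4*pi/N
by construction, not by numerical optimisation.

Region ids are 0-based here; the parcellation layer shifts to the 1..N
node-id convention used in all user-facing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpherePartition", "eq_partition"]


def _cap_colatitude(frac: float) -> float:
    """Colatitude of a polar cap covering ``frac`` of the sphere's area."""
    return float(np.arccos(np.clip(1.0 - 2.0 * frac, -1.0, 1.0)))


@dataclass(frozen=True)
class SpherePartition:
    """Zonal equal-area partition: polar caps + collars of equal-area cells.

    Attributes
    ----------
    n_regions:
        Total number of regions ``N``.
    colat_bounds:
        Increasing colatitude bounds of the zones, from 0 to pi; zone ``z``
        spans ``[colat_bounds[z], colat_bounds[z+1])``.
    zone_counts:
        Number of equal-area cells in each zone (1 for the caps).
    """

    n_regions: int
    colat_bounds: np.ndarray
    zone_counts: np.ndarray
    zone_offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        offsets = np.concatenate([[0], np.cumsum(self.zone_counts)[:-1]])
        object.__setattr__(self, "zone_offsets", offsets.astype(np.intp))

    @property
    def n_zones(self) -> int:
        return len(self.zone_counts)

    def region_areas(self) -> np.ndarray:
        """Analytic spherical area of every region (all equal to 4*pi/N)."""
        cos_top = np.cos(self.colat_bounds[:-1])
        cos_bot = np.cos(self.colat_bounds[1:])
        zone_area = 2.0 * np.pi * (cos_top - cos_bot)
        return np.repeat(zone_area / self.zone_counts, self.zone_counts)

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Map direction vectors to 0-based region ids.

        ``points`` is (n, 3); vectors need not be normalised but must be
        non-zero.  The z-axis is the polar axis.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        norms = np.linalg.norm(pts, axis=1)
        if np.any(norms == 0):
            raise ValueError("cannot assign a zero direction vector to a region")
        z = pts[:, 2] / norms
        colat = np.arccos(np.clip(z, -1.0, 1.0))
        lon = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)

        zone = np.searchsorted(self.colat_bounds, colat, side="right") - 1
        zone = np.clip(zone, 0, self.n_zones - 1)
        counts = self.zone_counts[zone]
        cell = np.minimum((lon * counts / (2.0 * np.pi)).astype(np.intp), counts - 1)
        return self.zone_offsets[zone] + cell


def eq_partition(n_regions: int) -> SpherePartition:
    """Partition the unit sphere into ``n_regions`` regions of equal area.

    Two polar caps of area 4*pi/N each; the remaining band is cut into
    collars of roughly ideal angular height, and each collar into its
    share of equal-area cells.  Collar boundaries are placed so that every
    zone holds an integer number of cells, which keeps all areas exactly
    equal analytically.
    """
    n = int(n_regions)
    if n < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    if n == 1:
        return SpherePartition(1, np.array([0.0, np.pi]), np.array([1]))
    if n == 2:
        return SpherePartition(2, np.array([0.0, np.pi / 2, np.pi]), np.array([1, 1]))

    theta_cap = _cap_colatitude(1.0 / n)
    # ideal cell side: square root of the cell area
    delta_ideal = np.sqrt(4.0 * np.pi / n)
    band = np.pi - 2.0 * theta_cap
    n_collars = max(1, int(round(band / delta_ideal)))
    delta_fit = band / n_collars

    # ideal (real-valued) cell counts per collar, then error-diffused rounding
    tops = theta_cap + delta_fit * np.arange(n_collars + 1)
    ideal = (np.cos(tops[:-1]) - np.cos(tops[1:])) * 2.0 * np.pi / (4.0 * np.pi / n)
    counts = np.empty(n_collars, dtype=np.intp)
    carry = 0.0
    for i in range(n_collars):
        m = int(round(ideal[i] + carry))
        carry += ideal[i] - m
        counts[i] = m
    counts[-1] = n - 2 - int(counts[:-1].sum())  # absorb residual rounding
    if counts[-1] < 1 or np.any(counts < 1):
        raise RuntimeError(f"degenerate collar layout for N={n}")

    # zone boundaries from cumulative region counts; the final interior bound
    # (cumulative count n-1) is the south cap colatitude by construction
    cum = 1 + np.cumsum(counts)
    bounds = np.concatenate(
        [[0.0], [_cap_colatitude(c / n) for c in np.concatenate([[1], cum])], [np.pi]]
    )
    zone_counts = np.concatenate([[1], counts, [1]]).astype(np.intp)
    return SpherePartition(n, bounds, zone_counts)
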