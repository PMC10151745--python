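"""Equal-area global grid, spherical kernel smoothing, and overlap metrics.

The grid partitions the sphere into latitude rings subdivided into
longitudinal sectors, with ring boundaries placed so that every cell has
exactly the same area (4 pi R^2 / n cells) -- an equal-area stand-in for a
hexagonal discrete global grid, sufficient for point-in-cell lookup and
per-cell richness accounting.  Fields sampled at scattered sites are
interpolated with a Nadaraya-Watson great-circle Gaussian kernel; prediction
points with no site within five bandwidths are flagged unsupported, mirroring
the exclusion of severely undersampled regions from interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .spatialstats import EARTH_RADIUS_KM, great_circle_km

__all__ = [
    "GridCell",
    "EqualAreaGrid",
    "MatchCounts",
    "OverlapStats",
    "build_equal_area_grid",
    "kernel_smooth_sphere",
    "loo_bandwidth",
    "log_match_ratio",
    "overlap_stats",
    "unique_counts",
    "reference_coverage",
]


@dataclass(frozen=True)
class GridCell:
    cell_id: int
    lat: float
    lon: float
    area_km2: float


@dataclass
class EqualAreaGrid:
    """Latitude-ring equal-area partition of the sphere."""

    n_cells: int
    radius_km: float
    ring_cos_edges: np.ndarray     # descending cos(colatitude) = sin(latitude) edges
    ring_counts: np.ndarray        # sectors per ring
    ring_offsets: np.ndarray       # first cell id of each ring

    @property
    def cell_area_km2(self) -> float:
        return 4.0 * np.pi * self.radius_km ** 2 / self.n_cells

    @property
    def cells(self) -> list[GridCell]:
        out = []
        area = self.cell_area_km2
        for r, m in enumerate(self.ring_counts):
            mid = (self.ring_cos_edges[r] + self.ring_cos_edges[r + 1]) / 2.0
            lat = float(np.degrees(np.arcsin(np.clip(mid, -1.0, 1.0))))
            for s in range(m):
                lon = (s + 0.5) * 360.0 / m - 180.0
                out.append(GridCell(int(self.ring_offsets[r] + s), lat, float(lon), area))
        return out

    def assign(self, lat: float, lon: float) -> int:
        """Deterministic containment lookup: ring by latitude, sector by longitude.

        Ring bands and longitude sectors are half-open on their upper edge,
        so a point exactly on a boundary belongs to the lower cell.
        """
        if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
        z = np.sin(np.radians(lat))
        # edges descend from 1 to -1; ring r spans (edge[r+1], edge[r]]
        ring = int(np.searchsorted(-self.ring_cos_edges, -z, side="left")) - 1
        ring = min(max(ring, 0), len(self.ring_counts) - 1)
        m = int(self.ring_counts[ring])
        u = ((lon + 180.0) % 360.0) / 360.0
        sector = min(int(u * m), m - 1)
        return int(self.ring_offsets[ring] + sector)

    def assign_many(self, lats: Iterable[float], lons: Iterable[float]) -> np.ndarray:
        return np.array([self.assign(la, lo) for la, lo in zip(lats, lons)])


def build_equal_area_grid(n_cells: int, radius_km: float = EARTH_RADIUS_KM
                          ) -> EqualAreaGrid:
    """Construct an equal-area latitude-ring grid with exactly `n_cells` cells.

    Ring counts are chosen from an equal-colatitude template and adjusted to
    sum to `n_cells`; ring boundaries are then re-derived so each ring's band
    area is exactly its cell count times the target area, making all cell
    areas identical.
    """
    n_cells = int(n_cells)
    if n_cells < 12:
        raise ValueError("n_cells must be >= 12")
    target_sr = 4.0 * np.pi / n_cells
    n_rings = max(3, int(round(np.pi / np.sqrt(target_sr))))
    theta = np.linspace(0.0, np.pi, n_rings + 1)   # colatitude template
    band_sr = 2.0 * np.pi * (np.cos(theta[:-1]) - np.cos(theta[1:]))
    counts = np.maximum(1, np.round(band_sr / target_sr).astype(int))
    # adjust to the exact total, nudging the rings with the largest rounding slack
    while counts.sum() != n_cells:
        resid = band_sr / target_sr - counts
        if counts.sum() < n_cells:
            counts[int(np.argmax(resid))] += 1
        else:
            candidates = np.where(counts > 1, resid, np.inf)
            counts[int(np.argmin(candidates))] -= 1
    cos_edges = np.empty(n_rings + 1)
    cos_edges[0] = 1.0
    for r in range(n_rings):
        cos_edges[r + 1] = cos_edges[r] - counts[r] * target_sr / (2.0 * np.pi)
    cos_edges[-1] = -1.0
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return EqualAreaGrid(n_cells=n_cells, radius_km=radius_km,
                         ring_cos_edges=cos_edges, ring_counts=counts,
                         ring_offsets=offsets)


def kernel_smooth_sphere(values, site_lats, site_lons, pred_lats, pred_lons,
                         bandwidth_km: float, support_bandwidths: float = 5.0,
                         radius_km: float = EARTH_RADIUS_KM
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Nadaraya-Watson Gaussian kernel smoothing on great-circle distances.

    Returns (predictions, supported) where `supported` is False for
    prediction points with no observation within `support_bandwidths`
    bandwidths; such predictions are NaN.  Predictions are convex weights of
    the observations, hence bounded by their range, and tend to the global
    mean as the bandwidth grows.
    """
    v = np.asarray(values, dtype=float)
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be > 0")
    if v.size < 3:
        raise ValueError("need at least 3 sites")
    slat = np.asarray(site_lats, float)
    slon = np.asarray(site_lons, float)
    plat = np.atleast_1d(np.asarray(pred_lats, float))
    plon = np.atleast_1d(np.asarray(pred_lons, float))
    D = great_circle_km(plat[:, None], plon[:, None], slat[None, :], slon[None, :],
                        radius_km=radius_km)
    W = np.exp(-0.5 * (D / bandwidth_km) ** 2)
    supported = D.min(axis=1) <= support_bandwidths * bandwidth_km
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (W @ v) / W.sum(axis=1)
    pred[~supported] = np.nan
    return pred, supported


def loo_bandwidth(values, lats, lons, candidates_km: Sequence[float],
                  radius_km: float = EARTH_RADIUS_KM) -> float:
    """Leave-one-out cross-validated bandwidth over candidate values (km)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    D = great_circle_km(np.asarray(lats, float)[:, None], np.asarray(lons, float)[:, None],
                        np.asarray(lats, float)[None, :], np.asarray(lons, float)[None, :],
                        radius_km=radius_km)
    best_h, best_err = None, np.inf
    for h in candidates_km:
        W = np.exp(-0.5 * (D / h) ** 2)
        np.fill_diagonal(W, 0.0)
        denom = W.sum(axis=1)
        ok = denom > 0
        pred = np.full(n, np.nan)
        pred[ok] = (W @ v)[ok] / denom[ok]
        err = np.nanmean((pred - v) ** 2)
        if err < best_err:
            best_err, best_h = err, float(h)
    return best_h


@dataclass(frozen=True)
class MatchCounts:
    """Counts of reads/OTUs/taxa matching (or not) a reference set."""

    unit: str       # "reads" | "OTUs" | "taxa"
    rank: str       # "family" | "species"
    matched: int
    unmatched: int

    def __post_init__(self) -> None:
        if self.matched < 0 or self.unmatched < 0:
            raise ValueError("counts must be non-negative")


def log_match_ratio(mc: MatchCounts | tuple[int, int], correction: float = 0.5,
                    base: float = np.e) -> float:
    """Continuity-corrected log of matched/unmatched.

    ``log((matched + c) / (unmatched + c))`` with c = 0.5 by default; the
    correction keeps the ratio finite when either count is zero, and the
    statistic is antisymmetric under swapping matched and unmatched.
    """
    matched, unmatched = (mc.matched, mc.unmatched) if isinstance(mc, MatchCounts) else mc
    if matched + unmatched <= 0:
        raise ValueError("matched + unmatched must be > 0")
    return float(np.log((matched + correction) / (unmatched + correction)) / np.log(base))


@dataclass(frozen=True)
class OverlapStats:
    shared: int
    unique_a: int
    unique_b: int


def overlap_stats(taxa_a: set, taxa_b: set) -> OverlapStats:
    """Shared and set-unique taxon counts between two canonicalised name sets."""
    shared = len(taxa_a & taxa_b)
    return OverlapStats(shared=shared, unique_a=len(taxa_a) - shared,
                        unique_b=len(taxa_b) - shared)


def unique_counts(n_a: int, n_b: int, n_shared: int) -> tuple[int, int]:
    """Set-unique counts from totals and the intersection size."""
    if n_shared > min(n_a, n_b) or min(n_a, n_b, n_shared) < 0:
        raise ValueError("inconsistent totals and intersection")
    return n_a - n_shared, n_b - n_shared


def reference_coverage(observed_taxa: set, refdb_taxa: set) -> float:
    """Percentage of observed taxa represented in the reference database."""
    if not observed_taxa:
        raise ValueError("observed taxon set is empty")
    return 100.0 * len(observed_taxa & refdb_taxa) / len(observed_taxa)
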