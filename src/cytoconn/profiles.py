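"""Laminar intensity profile extraction from cell-body-stained section images.

A *laminar profile* is a 1-D curve of staining intensity sampled from the
pial (outer) surface to the white-matter (inner) surface of the cortical
ribbon.  Profiles are extracted at user-selected point pairs (one point on
each surface), assigned to atlas regions by nearest labeled pixel, passed
through two quality-control filters (distance outliers, boundary crossers)
and averaged per region.  Step-profiles built from classical per-layer
histology tables (neuron density x neuron size) are supported for
validation against the image-derived profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "PointPair",
    "Profile",
    "RegionalProfile",
    "EKLayerTable",
    "LabelIndex",
    "nearest_neighbor_pairs",
    "extract_profile",
    "assign_region",
    "qc_filter",
    "regional_profiles",
    "ek_profile",
    "compare_profiles",
]

logger = logging.getLogger(__name__)

N_BLOCKS_DEFAULT = 1000
MIN_PROFILES_PER_REGION = 20
IQR_FACTOR_DEFAULT = 1.5


@dataclass(eq=False)
class PointPair:
    """A pial-surface / white-matter-surface point pair on one section.

    Coordinates are (x, y) pixel positions; ``image[y, x]`` is the intensity
    at a pair point.
    """

    pair_id: int
    pial: np.ndarray
    wm: np.ndarray
    section_id: str = "0"

    def __post_init__(self) -> None:
        self.pial = np.asarray(self.pial, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        if self.pial.shape != (2,) or self.wm.shape != (2,):
            raise ValueError("pair points must be 2-D (x, y) coordinates")
        if np.array_equal(self.pial, self.wm):
            raise ValueError(f"pair {self.pair_id}: pial and wm points coincide")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.pial + self.wm)

    @property
    def segment_length(self) -> float:
        return float(np.linalg.norm(self.wm - self.pial))


@dataclass(eq=False)
class Profile:
    """One extracted laminar profile with its QC bookkeeping."""

    values: np.ndarray
    pair_id: int
    section_id: str = "0"
    region: int = 0
    nn_pair_id: int | None = None
    nn_distance: float = np.nan
    voxel_distance: float = np.nan
    segment_length: float = np.nan
    crosses_boundary: bool = False
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


@dataclass(eq=False)
class RegionalProfile:
    region: int
    mean_profile: np.ndarray
    n_profiles: int
    mean_thickness: float
    included: bool


@dataclass(eq=False)
class EKLayerTable:
    """Per-layer histology table: relative thickness, density, neuron size.

    ``total_thickness`` (mm), when given, is the absolute cortical thickness
    used for thickness-agreement checks.
    """

    thickness_fractions: np.ndarray
    neuron_density: np.ndarray
    neuron_size: np.ndarray
    total_thickness: float = np.nan

    def __post_init__(self) -> None:
        self.thickness_fractions = np.asarray(self.thickness_fractions, dtype=float)
        self.neuron_density = np.asarray(self.neuron_density, dtype=float)
        self.neuron_size = np.asarray(self.neuron_size, dtype=float)
        n = len(self.thickness_fractions)
        if len(self.neuron_density) != n or len(self.neuron_size) != n:
            raise ValueError("layer table columns have mismatched lengths")
        if np.any(self.thickness_fractions <= 0):
            raise ValueError("layer thickness fractions must be positive")
        if abs(self.thickness_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("layer thickness fractions must sum to 1")


def nearest_neighbor_pairs(
    pairs: list[PointPair],
) -> dict[int, tuple[int | None, float]]:
    """Map each point pair to its closest other pair within the same section.

    Distance is the Euclidean distance between segment midpoints.  Ties are
    broken by the lowest ``pair_id``; the relation need not be symmetric.  A
    pair that is alone on its section maps to ``(None, inf)``.
    """
    out: dict[int, tuple[int | None, float]] = {}
    by_section: dict[str, list[PointPair]] = {}
    for p in pairs:
        by_section.setdefault(p.section_id, []).append(p)
    for sec_pairs in by_section.values():
        sec_pairs = sorted(sec_pairs, key=lambda p: p.pair_id)
        if len(sec_pairs) == 1:
            out[sec_pairs[0].pair_id] = (None, np.inf)
            continue
        mids = np.array([p.midpoint for p in sec_pairs])
        d = cdist(mids, mids)
        np.fill_diagonal(d, np.inf)
        # argmin returns the first minimum; pairs are id-sorted, so ties
        # resolve to the lowest pair_id
        nn = np.argmin(d, axis=1)
        for i, p in enumerate(sec_pairs):
            out[p.pair_id] = (sec_pairs[nn[i]].pair_id, float(d[i, nn[i]]))
    return out


def _quad_area(corners: np.ndarray) -> float:
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def extract_profile(
    image: np.ndarray,
    pair: PointPair,
    neighbor: PointPair,
    n_blocks: int = N_BLOCKS_DEFAULT,
    n_across: int = 4,
) -> Profile:
    """Extract a laminar profile from the quadrilateral spanned by a point
    pair and its nearest-neighbor pair.

    The quadrilateral (pair.pial, neighbor.pial, neighbor.wm, pair.wm) is the
    image of the unit square under the bilinear map interpolating its corners
    (u across the two segments, v from pial to white matter).  It is
    partitioned into ``n_blocks`` depth strata at fractions k/n_blocks;
    ``values[k]`` is the mean of bilinearly interpolated image samples on a
    lattice inside stratum k (``n_across`` columns across u, and enough depth
    rows that strata thicker than one pixel are subsampled).  ``values[0]``
    lies at the pial surface, ``values[-1]`` at the white-matter surface.
    """
    if neighbor is None:
        raise ValueError(f"pair {pair.pair_id} has no nearest-neighbor pair")
    corners = np.array([pair.pial, neighbor.pial, neighbor.wm, pair.wm])
    if _quad_area(corners) <= 0:
        raise ValueError(
            f"degenerate quadrilateral for pair {pair.pair_id} / "
            f"neighbor {neighbor.pair_id}"
        )
    seg_len = max(pair.segment_length, neighbor.segment_length)
    n_sub = max(1, int(np.ceil(seg_len / n_blocks)))

    u = (np.arange(n_across) + 0.5) / n_across
    sub = (np.arange(n_sub) + 0.5) / n_sub
    k = np.arange(n_blocks)
    v = (k[:, None] + sub[None, :]).reshape(-1) / n_blocks  # (n_blocks*n_sub,)

    # bilinear map of the unit square onto the quadrilateral
    left = (1 - v)[:, None] * pair.pial + v[:, None] * pair.wm
    right = (1 - v)[:, None] * neighbor.pial + v[:, None] * neighbor.wm
    pts = (1 - u)[None, :, None] * left[:, None, :] + u[None, :, None] * right[:, None, :]
    # image sampling: rows are y, cols are x
    vals = map_coordinates(
        np.asarray(image, dtype=float),
        [pts[..., 1].ravel(), pts[..., 0].ravel()],
        order=1,
        mode="nearest",
    )
    values = vals.reshape(n_blocks, n_sub * n_across).mean(axis=1)
    return Profile(
        values=values,
        pair_id=pair.pair_id,
        section_id=pair.section_id,
        segment_length=pair.segment_length,
    )


class LabelIndex:
    """Nearest-labeled-pixel lookup over a region label map.

    Ties in distance are broken by the lowest region id, then the lowest
    pixel raster index, so assignment is deterministic.
    """

    def __init__(self, label_map: np.ndarray):
        label_map = np.asarray(label_map)
        ys, xs = np.nonzero(label_map)
        if len(ys) == 0:
            raise ValueError("label map contains no labeled pixels")
        self.coords = np.column_stack([xs, ys]).astype(float)
        self.labels = label_map[ys, xs].astype(int)
        self._tree = cKDTree(self.coords)

    def query(self, point: np.ndarray) -> tuple[int, float]:
        point = np.asarray(point, dtype=float)
        dmin, _ = self._tree.query(point)
        idx = self._tree.query_ball_point(point, dmin + 1e-9)
        best = min(idx, key=lambda i: (self.labels[i], i))
        return int(self.labels[best]), float(dmin)


def assign_region(
    pair: PointPair, label_map: np.ndarray | LabelIndex
) -> tuple[int, float]:
    """Assign a point pair to the region of the labeled pixel nearest to its
    segment midpoint; returns (region id, Euclidean distance in px)."""
    index = label_map if isinstance(label_map, LabelIndex) else LabelIndex(label_map)
    return index.query(pair.midpoint)


def qc_filter(
    profiles: list[Profile], iqr_factor: float = IQR_FACTOR_DEFAULT
) -> list[Profile]:
    """Apply the two exclusion rules, in this fixed order:

    1. distance outliers: profiles whose midpoint lies farther from the
       nearest labeled pixel than Q3 + ``iqr_factor`` * IQR of the
       ``voxel_distance`` distribution (one-sided upper rule; quartiles by
       linear interpolation);
    2. boundary crossers: profiles whose nearest-neighbor pair was assigned
       to a different region (plus pairs with no neighbor at all).

    Survivors are returned; excluded profiles get ``excluded_reason`` set.
    """
    if not profiles:
        logger.warning("qc_filter called with no profiles")
        return []
    region_of = {p.pair_id: p.region for p in profiles}
    dists = np.array([p.voxel_distance for p in profiles])
    if np.any(~np.isfinite(dists)):
        raise ValueError("voxel_distance must be set on every profile before QC")
    q1, q3 = np.quantile(dists, [0.25, 0.75])
    threshold = q3 + iqr_factor * (q3 - q1)

    kept: list[Profile] = []
    n_iqr = n_boundary = 0
    for p in profiles:
        if p.voxel_distance > threshold:
            p.excluded_reason = "iqr_outlier"
            n_iqr += 1
            continue
        if p.nn_pair_id is None:
            p.excluded_reason = "unpaired"
            n_boundary += 1
            continue
        if region_of.get(p.nn_pair_id) != p.region:
            p.crosses_boundary = True
            p.excluded_reason = "boundary_crossing"
            n_boundary += 1
            continue
        kept.append(p)
    logger.info(
        "qc_filter: %d profiles in, %d distance outliers, %d boundary "
        "crossers, %d kept",
        len(profiles), n_iqr, n_boundary, len(kept),
    )
    return kept


def regional_profiles(
    profiles: list[Profile], min_count: int = MIN_PROFILES_PER_REGION
) -> list[RegionalProfile]:
    """Average profiles per region.  Regions with fewer than ``min_count``
    members are retained in the output but flagged ``included=False``."""
    by_region: dict[int, list[Profile]] = {}
    for p in profiles:
        by_region.setdefault(int(p.region), []).append(p)
    out = []
    for region in sorted(by_region):
        members = by_region[region]
        mean_profile = np.mean([p.values for p in members], axis=0)
        out.append(
            RegionalProfile(
                region=region,
                mean_profile=mean_profile,
                n_profiles=len(members),
                mean_thickness=float(np.mean([p.segment_length for p in members])),
                included=len(members) >= min_count,
            )
        )
    return out


def ek_profile(layers: EKLayerTable, n_steps: int = N_BLOCKS_DEFAULT) -> np.ndarray:
    """Build a step profile from a per-layer table by sampling ``n_steps``
    depths from the pial to the white-matter surface; step k carries the
    (neuron density x neuron size) value of the layer containing depth
    (k + 0.5) / n_steps under the cumulative thickness fractions."""
    values = layers.neuron_density * layers.neuron_size
    cum = np.cumsum(layers.thickness_fractions)
    depths = (np.arange(n_steps) + 0.5) / n_steps
    idx = np.searchsorted(cum, depths, side="left")
    idx = np.clip(idx, 0, len(values) - 1)
    return values[idx]


def compare_profiles(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two equally sampled profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and equally sampled")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    return float(sps.pearsonr(a, b).statistic)
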