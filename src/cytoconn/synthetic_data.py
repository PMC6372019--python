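"""Synthetic inputs with known ground truth for the whole pipeline.

This module generates every input the analysis consumes, with planted
structure so downstream stages can be validated end to end:

* stained ribbon sections — a circular annulus (pial = outer circle, white
  matter = inner circle) split into angular sector "regions", each carrying
  a known 1,000-sample laminar intensity curve; pixel intensity equals the
  region's curve evaluated at the pixel's cortical depth plus optional
  Gaussian noise.  The annulus gives closed-form depths and perpendiculars,
  so extraction oracles are exact.
* surface point pairs sampled on the two circles (radial, hence
  perpendicular to both surfaces), in along-ribbon groups of four with
  short intervals.
* voxelwise orientation fields made of straight or bent "corridors" of
  coherent principal diffusion direction (high fractional anisotropy inside,
  low outside) with labeled end caps, for exercising deterministic tracking
  rules.
* multi-subject connectomes with a planted similarity -> connectivity
  coupling: a group-level edge indicator drawn once per region pair with
  probability logistic(logit(base_density) + coupling_beta * sim), and
  per-subject integer streamline counts for expressed edges.
* region geometry tables (mirrored hemispheric centroids, log-normal
  volumes and surface areas).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .connectome import ConnectivityMatrix
from .profiles import EKLayerTable, PointPair

__all__ = [
    "AnnulusGeometry",
    "StainedSection",
    "OrientationField",
    "Corridor",
    "CohortSpec",
    "RegionGeometry",
    "make_truth_profiles",
    "make_section",
    "sample_point_pairs",
    "make_orientation_field",
    "make_bent_corridor",
    "make_cohort",
    "make_region_geometry",
    "make_ek_tables",
]


# ---------------------------------------------------------------------------
# stained sections
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AnnulusGeometry:
    """Circular-annulus ribbon: pial surface at ``r_pial``, white-matter
    surface at ``r_wm`` (< r_pial), regions as equal angular sectors."""

    center: tuple[float, float]
    r_pial: float
    r_wm: float
    n_regions: int
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.r_wm < self.r_pial:
            raise ValueError("require 0 < r_wm < r_pial")
        if self.n_regions < 1:
            raise ValueError("need at least one region")

    def depth(self, r: np.ndarray) -> np.ndarray:
        """Relative cortical depth: 0 at the pial surface, 1 at the WM."""
        return (self.r_pial - r) / (self.r_pial - self.r_wm)

    def sector(self, theta: np.ndarray) -> np.ndarray:
        """1-based region id of an angle."""
        rel = np.mod(theta - self.theta0, 2 * np.pi)
        return np.minimum(
            (rel / (2 * np.pi / self.n_regions)).astype(int), self.n_regions - 1
        ) + 1


@dataclass(eq=False)
class StainedSection:
    image: np.ndarray
    label_map: np.ndarray
    pial_curve: np.ndarray  # (N, 2) ordered (x, y) polyline
    wm_curve: np.ndarray
    truth_profiles: dict[int, np.ndarray]
    geometry: AnnulusGeometry
    section_id: str = "0"


def make_truth_profiles(
    n_regions: int,
    n_blocks: int = 1000,
    n_harmonics: int = 6,
    region_noise: float = 0.3,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Ground-truth laminar curves that vary smoothly along the ribbon.

    Every curve is a shared base laminar curve plus a region-specific
    deviation (a sine series in cortical depth whose coefficients drift
    smoothly with region index, plus per-region jitter).  The deviation is
    scaled by a per-region differentiation factor that itself varies
    smoothly along the ribbon: weakly differentiated regions stay close to
    the base curve and are therefore similar to most of the cortex, so the
    mean similarity level has planted variance across regions, not just
    across pairs.  Curves are min-max scaled to [0.15, 0.85] intensity
    units (Pearson similarity is unaffected by the per-curve rescale).
    """
    rng = np.random.default_rng(seed)
    d = (np.arange(n_blocks) + 0.5) / n_blocks
    m = np.arange(1, n_harmonics + 1)
    basis = np.sin(np.pi * m[:, None] * d[None, :])  # (H, n_blocks)
    amp = 1.0 / m
    base_coeff = amp * rng.normal(size=n_harmonics)
    phase = rng.uniform(0, 2 * np.pi, n_harmonics)
    waves = rng.integers(1, 4, n_harmonics)
    r_idx = np.arange(n_regions)
    coeff = amp[:, None] * np.cos(
        2 * np.pi * waves[:, None] * r_idx[None, :] / n_regions + phase[:, None]
    )
    coeff = coeff + region_noise * amp[:, None] * rng.normal(
        size=(n_harmonics, n_regions)
    )
    # per-region differentiation scale: smooth along the ribbon + jitter
    s_phase = rng.uniform(0, 2 * np.pi)
    scale = 0.3 + 1.1 * 0.5 * (
        1 + np.cos(2 * np.pi * r_idx / n_regions + s_phase)
    ) + rng.uniform(0.0, 0.4, n_regions)
    coeff = base_coeff[:, None] + scale[None, :] * coeff
    curves = coeff.T @ basis  # (R, n_blocks)
    lo = curves.min(axis=1, keepdims=True)
    hi = curves.max(axis=1, keepdims=True)
    curves = 0.15 + 0.7 * (curves - lo) / (hi - lo)
    return {r + 1: curves[r] for r in range(n_regions)}


def make_section(
    region_profiles: dict[int, np.ndarray],
    ribbon: AnnulusGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    n_curve_points: int = 4096,
    dark_stain_high: bool = True,
    section_id: str = "0",
) -> StainedSection:
    """Render an annulus section whose intensity at depth d inside region r
    equals ``region_profiles[r]`` evaluated at d, plus i.i.d. Gaussian noise.

    ``dark_stain_high=False`` flips the digitization polarity (recorded
    intensity = 1 - curve value); the convention is configurable because
    only correlations of profiles matter downstream.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n_regions = len(region_profiles)
    n_blocks = None
    for r, curve in region_profiles.items():
        curve = np.asarray(curve)
        if n_blocks is None:
            n_blocks = len(curve)
        if len(curve) != 1000:
            raise ValueError(
                f"region {r}: truth curves must have 1,000 samples, "
                f"got {len(curve)}"
            )
    if ribbon is None:
        ribbon = AnnulusGeometry(
            center=(128.0, 128.0), r_pial=110.0, r_wm=75.0, n_regions=n_regions
        )
    if set(region_profiles) != set(range(1, ribbon.n_regions + 1)):
        raise ValueError("region_profiles must be keyed 1..n_regions")
    if shape is None:
        side = int(np.ceil(2 * ribbon.r_pial + 12))
        shape = (side, side)

    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xs - ribbon.center[0]
    dy = ys - ribbon.center[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    inside = (r >= ribbon.r_wm) & (r <= ribbon.r_pial)
    # stain does not vanish at the surfaces: render a thin continuation band
    # beyond each boundary (curve end values) so boundary samples are not
    # diluted by empty background; region labels stay confined to the ribbon
    pad = 3.0
    stained = (r >= ribbon.r_wm - pad) & (r <= ribbon.r_pial + pad)

    label_map = np.zeros(shape, dtype=int)
    label_map[inside] = ribbon.sector(theta[inside])

    depth_grid = (np.arange(1000) + 0.5) / 1000
    image = np.zeros(shape, dtype=float)
    # np.interp clamps depths outside [0, 1] to the curve end values
    depths = ribbon.depth(r[stained])
    labels_in = ribbon.sector(theta[stained])
    vals = np.empty(depths.shape)
    for region, curve in region_profiles.items():
        m = labels_in == region
        vals[m] = np.interp(depths[m], depth_grid, np.asarray(curve, dtype=float))
    if not dark_stain_high:
        vals = 1.0 - vals
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    image[stained] = vals

    ang = np.linspace(0, 2 * np.pi, n_curve_points, endpoint=False)
    cx, cy = ribbon.center
    pial_curve = np.column_stack(
        [cx + ribbon.r_pial * np.cos(ang), cy + ribbon.r_pial * np.sin(ang)]
    )
    wm_curve = np.column_stack(
        [cx + ribbon.r_wm * np.cos(ang), cy + ribbon.r_wm * np.sin(ang)]
    )
    return StainedSection(
        image=image,
        label_map=label_map,
        pial_curve=pial_curve,
        wm_curve=wm_curve,
        truth_profiles={r: np.asarray(c, dtype=float) for r, c in region_profiles.items()},
        geometry=ribbon,
        section_id=section_id,
    )


def sample_point_pairs(
    section: StainedSection,
    n_pairs: int,
    seed: int = 0,
    group_size: int = 4,
    spacing_px: float = 3.0,
    stratified: bool = False,
) -> list[PointPair]:
    """Sample pial/WM point pairs on the two surfaces of a section.

    Pairs come in along-ribbon groups of ``group_size`` with short intervals
    (``spacing_px`` along the pial surface), mirroring manual selection of a
    few pairs at a time at random positions.  On the annulus every segment
    is radial, hence perpendicular to both surfaces.  With ``stratified``
    the group centers are spread evenly (with jitter) around the ribbon so
    every region receives pairs.  Points are snapped to the stored surface
    polylines.
    """
    if n_pairs < 2:
        raise ValueError("need at least two point pairs")
    if n_pairs > len(section.pial_curve):
        raise ValueError("n_pairs exceeds available surface curve samples")
    rng = np.random.default_rng(seed)
    geo = section.geometry
    n_groups = int(np.ceil(n_pairs / group_size))
    if stratified:
        centers = (
            geo.theta0
            + 2 * np.pi * (np.arange(n_groups) + rng.uniform(0.25, 0.75, n_groups))
            / n_groups
        )
    else:
        centers = np.sort(rng.uniform(0, 2 * np.pi, n_groups))
    dtheta = spacing_px / geo.r_pial

    pairs: list[PointPair] = []
    pid = 0
    for c in centers:
        for mbr in range(group_size):
            if pid >= n_pairs:
                break
            ang = c + (mbr - (group_size - 1) / 2) * dtheta
            pial = _snap(section.pial_curve, _circle_point(geo, geo.r_pial, ang))
            wm = _snap(section.wm_curve, _circle_point(geo, geo.r_wm, ang))
            pairs.append(
                PointPair(pair_id=pid, pial=pial, wm=wm, section_id=section.section_id)
            )
            pid += 1
    return pairs


def _circle_point(geo: AnnulusGeometry, radius: float, ang: float) -> np.ndarray:
    return np.array(
        [geo.center[0] + radius * np.cos(ang), geo.center[1] + radius * np.sin(ang)]
    )


def _snap(curve: np.ndarray, point: np.ndarray) -> np.ndarray:
    i = np.argmin(np.sum((curve - point) ** 2, axis=1))
    return curve[i].copy()


# ---------------------------------------------------------------------------
# orientation fields
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class OrientationField:
    """Voxelwise principal diffusion direction field for tracking.

    ``dirs`` holds a unit 3-vector per voxel (axial: sign is arbitrary),
    ``fa`` the fractional anisotropy in [0, 1], ``labels`` gray-matter
    region ids at corridor end caps (0 elsewhere), ``mask`` the tracking
    domain.
    """

    dirs: np.ndarray  # (X, Y, Z, 3)
    fa: np.ndarray  # (X, Y, Z)
    labels: np.ndarray  # (X, Y, Z) int
    mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.dirs, axis=-1)
        active = self.fa > 0.0
        if np.any(np.abs(norms[active] - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors wherever fa > 0")
        if np.any(self.labels.astype(bool) & ~self.mask):
            raise ValueError("labeled voxels must lie inside the tracking mask")


@dataclass(eq=False)
class Corridor:
    """A polyline corridor of coherent fiber direction between two regions."""

    waypoints: np.ndarray  # (k, 3) voxel coordinates
    region_a: int
    region_b: int
    radius: float = 1.0
    cap_len: float = 1.5

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.waypoints.ndim != 2 or self.waypoints.shape[1] != 3:
            raise ValueError("waypoints must be (k, 3)")
        if len(self.waypoints) < 2:
            raise ValueError("a corridor needs at least two waypoints")


def make_orientation_field(
    corridors: list[Corridor],
    grid_shape: tuple[int, int, int],
    fa_inside: float = 0.8,
    fa_outside: float = 0.05,
) -> OrientationField:
    """Rasterize corridors into an orientation field.

    Voxels within ``radius`` of a corridor polyline carry the unit direction
    of the nearest polyline segment and ``fa_inside``; all other voxels get
    ``fa_outside`` and a fixed +x direction.  Voxels whose along-corridor
    position lies within ``cap_len`` of either end are labeled with that
    end's region id.  The tracking mask is the full grid.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    dirs = np.zeros(grid_shape + (3,), dtype=float)
    dirs[..., 0] = 1.0
    fa = np.full(grid_shape, fa_outside, dtype=float)
    labels = np.zeros(grid_shape, dtype=int)

    centers = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)

    for cor in corridors:
        if np.any(cor.waypoints < -0.5) or np.any(
            cor.waypoints > np.array(grid_shape) - 0.5
        ):
            raise ValueError("corridor leaves the grid")
        seg_starts = cor.waypoints[:-1]
        seg_vecs = np.diff(cor.waypoints, axis=0)
        seg_lens = np.linalg.norm(seg_vecs, axis=1)
        if np.any(seg_lens == 0):
            raise ValueError("zero-length corridor segment")
        seg_dirs = seg_vecs / seg_lens[:, None]
        cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
        total = cum[-1]

        # distance of every voxel center to every segment
        best_d = np.full(len(centers), np.inf)
        best_seg = np.zeros(len(centers), dtype=int)
        best_arc = np.zeros(len(centers))
        for s in range(len(seg_starts)):
            rel = centers - seg_starts[s]
            t = np.clip(rel @ seg_dirs[s], 0.0, seg_lens[s])
            d = np.linalg.norm(rel - t[:, None] * seg_dirs[s], axis=1)
            better = d < best_d - 1e-12  # ties keep the earlier segment
            best_d[better] = d[better]
            best_seg[better] = s
            best_arc[better] = cum[s] + t[better]
        inside = best_d <= cor.radius
        idx = np.nonzero(inside)[0]
        vox = centers[idx].astype(int)
        dirs[vox[:, 0], vox[:, 1], vox[:, 2]] = seg_dirs[best_seg[idx]]
        fa[vox[:, 0], vox[:, 1], vox[:, 2]] = fa_inside
        arc = best_arc[idx]
        a_cap = arc <= cor.cap_len
        b_cap = arc >= total - cor.cap_len
        labels[vox[a_cap, 0], vox[a_cap, 1], vox[a_cap, 2]] = cor.region_a
        labels[vox[b_cap, 0], vox[b_cap, 1], vox[b_cap, 2]] = cor.region_b

    return OrientationField(
        dirs=dirs, fa=fa, labels=labels, mask=np.ones(grid_shape, dtype=bool)
    )


def make_bent_corridor(
    angle_deg: float,
    arm_len: float = 14.0,
    radius: float = 1.0,
    margin: int = 4,
) -> tuple[Corridor, tuple[int, int, int]]:
    """A two-segment corridor with a programmable bend at its midpoint.

    The first arm runs along +x; the second deviates by ``angle_deg`` in the
    x-y plane.  Returns the corridor (regions 1 and 2 at the ends) and a
    grid shape that contains it with a margin.
    """
    theta = np.deg2rad(angle_deg)
    start = np.array([float(margin), 0.0, 0.0])
    mid = start + np.array([arm_len, 0.0, 0.0])
    end = mid + arm_len * np.array([np.cos(theta), np.sin(theta), 0.0])
    z = margin + 1.0
    pts = np.array([start, mid, end]) + np.array([0.0, float(margin), z])
    lo = pts.min(axis=0)
    if np.any(lo < 0):
        pts = pts - np.minimum(lo, 0) + margin
    hi = pts.max(axis=0)
    shape = tuple(int(np.ceil(h + margin + 1)) for h in hi)
    shape = (shape[0], shape[1], max(shape[2], int(2 * z + 1)))
    return Corridor(waypoints=pts, region_a=1, region_b=2, radius=radius), shape


# ---------------------------------------------------------------------------
# cohorts and geometry
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class CohortSpec:
    """Planted-effect cohort: similarity -> connectivity coupling.

    ``coupling_beta`` acts both on the group-level edge-presence logit and
    (additively) on the mean streamline count of present edges;
    ``base_density`` is the expected group-level edge prevalence at zero
    similarity; ``subject_expression`` is the per-subject probability that a
    group-level edge is expressed in an individual connectome.
    """

    n_subjects: int
    n_regions: int
    coupling_beta: float = 2.0
    base_density: float = 0.25
    noise_sd: float = 5.0
    base_weight: float = 20.0
    subject_expression: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must lie in (0, 1]")


@dataclass(eq=False)
class RegionGeometry:
    region: int
    centroid: np.ndarray  # (3,) mm
    volume: float  # mm^3
    surface_area: float  # mm^2
    hemisphere: str  # "left" | "right"
    n_profiles: int = 0


def make_cohort(
    spec: CohortSpec,
    similarity: np.ndarray,
    geometry: list[RegionGeometry] | None = None,
) -> list[ConnectivityMatrix]:
    """Simulate per-subject streamline-count matrices with planted coupling.

    For each region pair (i, j) a group-level edge indicator is drawn once
    with probability expit(logit(base_density) + coupling_beta * sim_ij).
    Each subject expresses a group edge with probability
    ``subject_expression``; expressed edges get an integer count
    round(max(0, base_weight + coupling_beta * sim_ij + N(0, noise_sd))).
    Masked (NaN) similarity entries contribute zero coupling.
    """
    sim = np.asarray(getattr(similarity, "values", similarity), dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if sim.shape[0] != spec.n_regions:
        raise ValueError("similarity size does not match n_regions")
    off = ~np.eye(sim.shape[0], dtype=bool)
    finite_off = off & np.isfinite(sim)
    if not np.allclose(
        np.where(np.isfinite(sim), sim, 0.0),
        np.where(np.isfinite(sim.T), sim.T, 0.0),
        atol=1e-10,
    ):
        raise ValueError("similarity matrix must be symmetric")
    if np.any(np.abs(sim[finite_off]) > 1.0 + 1e-9):
        raise ValueError("similarity entries must lie in [-1, 1]")

    rng = np.random.default_rng(spec.seed)
    R = spec.n_regions
    iu, ju = np.triu_indices(R, k=1)
    s = np.where(np.isfinite(sim[iu, ju]), sim[iu, ju], 0.0)
    p_edge = expit(logit(spec.base_density) + spec.coupling_beta * s)
    group_edge = rng.random(len(s)) < p_edge

    subjects = []
    for subj in range(spec.n_subjects):
        expressed = group_edge & (rng.random(len(s)) < spec.subject_expression)
        w = spec.base_weight + spec.coupling_beta * s + rng.normal(
            0.0, spec.noise_sd, len(s)
        )
        nos = np.rint(np.maximum(0.0, w)).astype(int)
        nos[~expressed] = 0
        mat = np.zeros((R, R), dtype=int)
        mat[iu, ju] = nos
        mat[ju, iu] = nos
        subjects.append(
            ConnectivityMatrix(
                values=mat,
                weight_kind="nos",
                subject_id=f"sub-{subj:03d}",
                region_ids=np.arange(1, R + 1),
            )
        )
    return subjects


def make_region_geometry(n_regions: int, seed: int = 0) -> list[RegionGeometry]:
    """Region centroids in two mirrored hemispheric boxes, with log-normal
    volumes and surface areas.  Region ids 1..n/2 are left-hemisphere,
    n/2+1..n right-hemisphere."""
    if n_regions < 4 or n_regions % 2:
        raise ValueError("n_regions must be even and at least 4")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    out: list[RegionGeometry] = []
    for hemi, sign, offset in (("left", -1.0, 0), ("right", 1.0, half)):
        x = sign * rng.uniform(15.0, 70.0, half)
        y = rng.uniform(-80.0, 60.0, half)
        z = rng.uniform(-50.0, 60.0, half)
        vol = rng.lognormal(mean=np.log(8000.0), sigma=0.4, size=half)
        area = rng.lognormal(mean=np.log(2500.0), sigma=0.4, size=half)
        for k in range(half):
            out.append(
                RegionGeometry(
                    region=offset + k + 1,
                    centroid=np.array([x[k], y[k], z[k]]),
                    volume=float(vol[k]),
                    surface_area=float(area[k]),
                    hemisphere=hemi,
                )
            )
    return out


def make_ek_tables(
    truth_profiles: dict[int, np.ndarray],
    n_layers: int = 6,
    thickness_mm: dict[int, float] | None = None,
) -> dict[int, EKLayerTable]:
    """Collapse truth curves into classical per-layer tables.

    Each region's curve is split into ``n_layers`` equal-thickness layers;
    the layer's (density x size) value is the curve mean within the layer
    (density carries the value, size is 1).  This mimics a step-profile
    atlas derived from the same underlying laminar structure.
    """
    tables = {}
    for region, curve in truth_profiles.items():
        curve = np.asarray(curve, dtype=float)
        parts = np.array_split(curve, n_layers)
        density = np.array([p.mean() for p in parts])
        fracs = np.array([len(p) for p in parts], dtype=float)
        fracs = fracs / fracs.sum()
        tables[region] = EKLayerTable(
            thickness_fractions=fracs,
            neuron_density=density,
            neuron_size=np.ones(n_layers),
            total_thickness=(thickness_mm or {}).get(region, np.nan),
        )
    return tables
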