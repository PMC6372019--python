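"""Deterministic streamline tractography and connectome construction.

Implements a voxel-hopping FACT-style tracker (fiber assignment by
continuous tracking): from eight subvoxel seeds per voxel, streamlines
advance in half-voxel steps along the current voxel's principal diffusion
direction (sign-aligned with the direction of travel, since diffusion
directions are axial) and terminate on low fractional anisotropy, on
leaving the tracking mask, or on a sharp turn (> 45 degrees between
consecutive voxel directions).  Streamline endpoints falling in two
distinct labeled regions increment the number-of-streamlines (NOS) edge
weight; streamline density divides NOS by the mean volume of the two
regions.  A group consensus network keeps edges present in strictly more
than a prevalence threshold of subjects and weights them by the mean of
the nonzero subject weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "Streamline",
    "ConnectivityMatrix",
    "GroupNetwork",
    "track_fact",
    "count_streamlines",
    "streamline_density",
    "group_network",
    "gaussianize_weights",
]

FA_STOP_DEFAULT = 0.1
ANGLE_STOP_DEFAULT = 45.0
SEEDS_PER_VOXEL_DEFAULT = 8
CONSENSUS_THRESHOLD_DEFAULT = 0.5


@dataclass(eq=False)
class Streamline:
    points: np.ndarray  # (k, 3) positions in voxel coordinates
    termination_forward: str
    termination_reverse: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least two points")

    @property
    def termination_reason(self) -> str:
        return self.termination_forward


@dataclass(eq=False)
class ConnectivityMatrix:
    """Symmetric region x region connectivity weights for one subject."""

    values: np.ndarray
    weight_kind: str = "nos"  # "nos" | "density" | "gaussianized"
    subject_id: str | None = None
    region_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("connectivity weights must be nonnegative")
        self.values = v
        if self.region_ids is None:
            self.region_ids = np.arange(1, v.shape[0] + 1)
        else:
            self.region_ids = np.asarray(self.region_ids)


@dataclass(eq=False)
class GroupNetwork:
    binary: np.ndarray
    weighted: np.ndarray
    prevalence: np.ndarray
    threshold: float
    region_ids: np.ndarray
    weight_kind: str = "nos"


def _voxel_of(p: np.ndarray) -> tuple[int, int, int]:
    v = np.floor(p + 0.5).astype(int)
    return int(v[0]), int(v[1]), int(v[2])


def _in_grid(v: tuple[int, int, int], shape: tuple[int, ...]) -> bool:
    return all(0 <= v[i] < shape[i] for i in range(3))


def _half_track(field, p0, v0, direction, fa_stop, cos_stop, step_size, max_steps):
    """Step from p0 along `direction` until a termination rule fires.

    Returns (list of positions after p0, termination reason).
    """
    pts: list[np.ndarray] = []
    p = p0
    cur_v = v0
    cur_d = direction
    reason = "max_steps"
    for _ in range(max_steps):
        p_next = p + step_size * cur_d
        v_next = _voxel_of(p_next)
        if v_next != cur_v:
            if not _in_grid(v_next, field.fa.shape) or not field.mask[v_next]:
                reason = "exited_mask"
                break
            if field.fa[v_next] < fa_stop:
                reason = "low_fa"
                break
            d_new = field.dirs[v_next].copy()
            if float(d_new @ cur_d) < 0:
                d_new = -d_new
            if float(d_new @ cur_d) < cos_stop - 1e-12:
                reason = "sharp_turn"
                break
            cur_v = v_next
            cur_d = d_new
        p = p_next
        pts.append(p)
    return pts, reason


def track_fact(
    field,
    seeds_per_voxel: int = SEEDS_PER_VOXEL_DEFAULT,
    fa_stop: float = FA_STOP_DEFAULT,
    angle_stop: float = ANGLE_STOP_DEFAULT,
    step_size: float = 0.5,
    max_steps: int = 2000,
) -> list[Streamline]:
    """Deterministic FACT-style tracking over an orientation field.

    Seeds are placed on a fixed 2x2x2 subvoxel grid (offsets +-0.25 voxel)
    in every mask voxel with fa >= ``fa_stop`` (``seeds_per_voxel=1`` places
    a single central seed instead).  From each seed the two half-tracks
    (along +-the seed voxel's direction) are stepped and concatenated.
    Termination: entering a voxel with fa < ``fa_stop``, leaving the mask or
    grid, or a turn of more than ``angle_stop`` degrees between consecutive
    (sign-aligned) voxel directions.
    """
    if not 0 < step_size <= 1:
        raise ValueError("step_size must lie in (0, 1] voxels")
    if seeds_per_voxel == 8:
        offsets = np.array(list(product((-0.25, 0.25), repeat=3)))
    elif seeds_per_voxel == 1:
        offsets = np.zeros((1, 3))
    else:
        raise ValueError("seeds_per_voxel must be 8 (2x2x2 grid) or 1 (center)")
    cos_stop = float(np.cos(np.deg2rad(angle_stop)))

    seed_voxels = np.argwhere(field.mask & (field.fa >= fa_stop))
    tracks: list[Streamline] = []
    for vx, vy, vz in seed_voxels:
        v0 = (int(vx), int(vy), int(vz))
        d0 = field.dirs[v0]
        for off in offsets:
            p0 = np.array([vx, vy, vz], dtype=float) + off
            fwd, r_fwd = _half_track(
                field, p0, v0, d0, fa_stop, cos_stop, step_size, max_steps
            )
            rev, r_rev = _half_track(
                field, p0, v0, -d0, fa_stop, cos_stop, step_size, max_steps
            )
            pts = rev[::-1] + [p0] + fwd
            if len(pts) < 2:
                continue
            tracks.append(
                Streamline(
                    points=np.array(pts),
                    termination_forward=r_fwd,
                    termination_reverse=r_rev,
                )
            )
    return tracks


def count_streamlines(
    tracks: list[Streamline],
    labels: np.ndarray,
    region_ids: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Count streamlines whose two endpoints fall in distinct labeled
    regions.  Streamlines with an unlabeled endpoint, or starting and
    ending in the same region, contribute nothing."""
    labels = np.asarray(labels)
    if region_ids is None:
        present = np.unique(labels)
        region_ids = present[present > 0]
        if len(region_ids) == 0:
            region_ids = np.array([1])
    region_ids = np.asarray(region_ids)
    index = {int(r): k for k, r in enumerate(region_ids)}
    R = len(region_ids)
    nos = np.zeros((R, R), dtype=int)
    for t in tracks:
        va = _voxel_of(t.points[0])
        vb = _voxel_of(t.points[-1])
        if not (_in_grid(va, labels.shape) and _in_grid(vb, labels.shape)):
            continue
        la, lb = int(labels[va]), int(labels[vb])
        if la == 0 or lb == 0 or la == lb:
            continue
        i, j = index[la], index[lb]
        nos[i, j] += 1
        nos[j, i] += 1
    return ConnectivityMatrix(values=nos, weight_kind="nos", region_ids=region_ids)


def streamline_density(
    nos: ConnectivityMatrix, geometry: list
) -> ConnectivityMatrix:
    """Streamline density: NOS divided by the mean volume of the two
    connected regions."""
    vol = {g.region: g.volume for g in geometry}
    missing = [int(r) for r in nos.region_ids if r not in vol]
    if missing:
        raise ValueError(f"missing volumes for regions {missing}")
    v = np.array([vol[int(r)] for r in nos.region_ids], dtype=float)
    if np.any(v <= 0):
        raise ValueError("region volumes must be positive")
    mean_vol = 0.5 * (v[:, None] + v[None, :])
    dens = nos.values / mean_vol
    np.fill_diagonal(dens, 0.0)
    return ConnectivityMatrix(
        values=dens,
        weight_kind="density",
        subject_id=nos.subject_id,
        region_ids=nos.region_ids,
    )


def group_network(
    subjects: list[ConnectivityMatrix],
    threshold: float = CONSENSUS_THRESHOLD_DEFAULT,
) -> GroupNetwork:
    """Group consensus network over a cohort.

    An edge enters the binary network iff it is present (weight > 0) in
    strictly more than ``threshold`` of the subjects; its weight is the
    mean of the *nonzero* subject weights.
    """
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    ref = subjects[0].region_ids
    for s in subjects[1:]:
        if s.values.shape != subjects[0].values.shape or not np.array_equal(
            s.region_ids, ref
        ):
            raise ValueError("subjects have mismatched region sets")
    stack = np.stack([np.asarray(s.values, dtype=float) for s in subjects])
    present = stack > 0
    prevalence = present.mean(axis=0)
    binary = (prevalence > threshold).astype(int)
    np.fill_diagonal(binary, 0)
    n_nonzero = present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nonzero = np.where(n_nonzero > 0, stack.sum(axis=0) / np.maximum(n_nonzero, 1), 0.0)
    weighted = np.where(binary > 0, mean_nonzero, 0.0)
    return GroupNetwork(
        binary=binary,
        weighted=weighted,
        prevalence=prevalence,
        threshold=threshold,
        region_ids=np.asarray(ref),
        weight_kind=subjects[0].weight_kind,
    )


def gaussianize_weights(
    net: GroupNetwork, target_mean: float = 1.0, target_sd: float = 0.2
) -> GroupNetwork:
    """Rank-matched normal transform of the consensus edge weights (the same
    transform applied to profile similarities), mirrored symmetrically."""
    from .similarity import rank_gaussianize

    iu, ju = np.triu_indices(net.binary.shape[0], k=1)
    on = net.binary[iu, ju] > 0
    w = net.weighted[iu, ju][on]
    wg = rank_gaussianize(w, target_mean=target_mean, target_sd=target_sd)
    out = np.zeros_like(net.weighted)
    out[iu[on], ju[on]] = wg
    out[ju[on], iu[on]] = wg
    return GroupNetwork(
        binary=net.binary.copy(),
        weighted=out,
        prevalence=net.prevalence.copy(),
        threshold=net.threshold,
        region_ids=net.region_ids.copy(),
        weight_kind="gaussianized",
    )
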