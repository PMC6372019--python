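"""Interregional profile-similarity matrix and its normalization.

The similarity matrix holds the Pearson correlation between the regional
mean laminar profiles of every pair of included regions.  Because raw
correlations are typically non-normal, the off-diagonal values can be
redistributed onto a normal distribution with a target mean and SD by
matching ranks (rank-based inverse-normal transform with an exact affine
rescale); the same transform is reused for streamline-count edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .profiles import RegionalProfile

__all__ = [
    "SimilarityMatrix",
    "RegionalSimilarity",
    "similarity_matrix",
    "rank_gaussianize",
    "gaussianize_matrix",
    "regional_mean_similarity",
]

TARGET_MEAN_DEFAULT = 1.0
TARGET_SD_DEFAULT = 0.2


@dataclass(eq=False)
class SimilarityMatrix:
    """Symmetric region x region profile similarity.

    ``values`` is R x R with NaN on the diagonal and on rows/columns of
    excluded regions; ``included`` flags which regions carry data;
    ``transform_state`` is "raw" (Pearson r in [-1, 1]) or "gaussianized".
    """

    values: np.ndarray
    region_ids: np.ndarray
    included: np.ndarray
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        a = np.where(np.isfinite(v), v, 0.0)
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v
        self.region_ids = np.asarray(self.region_ids)
        self.included = np.asarray(self.included, dtype=bool)

    def upper_values(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Off-diagonal upper-triangle entries over included region pairs.

        Returns (row indices, column indices, values)."""
        iu, ju = np.triu_indices(self.values.shape[0], k=1)
        ok = self.included[iu] & self.included[ju]
        return iu[ok], ju[ok], self.values[iu[ok], ju[ok]]


@dataclass(eq=False)
class RegionalSimilarity:
    """Per-region mean similarity to all other included regions."""

    region_ids: np.ndarray
    values: np.ndarray


def similarity_matrix(regional: list[RegionalProfile]) -> SimilarityMatrix:
    """Pearson similarity between the mean profiles of every pair of
    included regions; excluded regions are masked with NaN."""
    regional = sorted(regional, key=lambda r: r.region)
    region_ids = np.array([r.region for r in regional])
    included = np.array([r.included for r in regional], dtype=bool)
    if included.sum() < 2:
        raise ValueError("need at least two included regions")
    for r in regional:
        if r.included and np.std(r.mean_profile) == 0:
            raise ValueError(f"region {r.region}: constant mean profile")
    R = len(regional)
    values = np.full((R, R), np.nan)
    idx = np.nonzero(included)[0]
    profs = np.stack([regional[i].mean_profile for i in idx])
    corr = np.corrcoef(profs)
    np.fill_diagonal(corr, np.nan)
    values[np.ix_(idx, idx)] = corr
    return SimilarityMatrix(
        values=values, region_ids=region_ids, included=included, transform_state="raw"
    )


def rank_gaussianize(
    values: np.ndarray,
    target_mean: float = TARGET_MEAN_DEFAULT,
    target_sd: float = TARGET_SD_DEFAULT,
) -> np.ndarray:
    """Rank-matched normal redistribution.

    Values are replaced by standard-normal quantiles at plotting positions
    (rank - 0.5) / n (average ranks for ties), then affinely rescaled so the
    output has sample mean exactly ``target_mean`` and sample SD (ddof=1)
    exactly ``target_sd``.  The map is monotone, so rank order is preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector of at least two values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.all(values == values[0]):
        raise ValueError("transform undefined: all values identical")
    ranks = sps.rankdata(values, method="average")
    z = sps.norm.ppf((ranks - 0.5) / len(values))
    sd = z.std(ddof=1)
    if sd == 0:
        raise ValueError("transform undefined: degenerate rank distribution")
    return target_mean + (z - z.mean()) * (target_sd / sd)


def gaussianize_matrix(
    m: SimilarityMatrix,
    target_mean: float = TARGET_MEAN_DEFAULT,
    target_sd: float = TARGET_SD_DEFAULT,
) -> SimilarityMatrix:
    """Apply the rank-matched transform to the off-diagonal upper-triangle
    entries over included regions and mirror, preserving symmetry."""
    iu, ju, vals = m.upper_values()
    out = np.full_like(m.values, np.nan)
    g = rank_gaussianize(vals, target_mean=target_mean, target_sd=target_sd)
    out[iu, ju] = g
    out[ju, iu] = g
    return SimilarityMatrix(
        values=out,
        region_ids=m.region_ids.copy(),
        included=m.included.copy(),
        transform_state="gaussianized",
    )


def regional_mean_similarity(m: SimilarityMatrix) -> RegionalSimilarity:
    """Mean of each included region's column over the other included
    regions (diagonal excluded); masked regions contribute to nothing."""
    idx = np.nonzero(m.included)[0]
    if len(idx) < 2:
        raise ValueError("need at least two included regions")
    vals = []
    for i in idx:
        others = idx[idx != i]
        vals.append(float(np.mean(m.values[others, i])))
    return RegionalSimilarity(
        region_ids=m.region_ids[idx], values=np.array(vals)
    )
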