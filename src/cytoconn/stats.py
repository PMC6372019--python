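"""Statistical battery: edge- and node-level tests with family-wise FDR.

Implements the tests used to relate profile similarity to connectome
organization: pooled-variance two-sample t tests (connected vs nonconnected
region pairs), Pearson and partial correlations, ordinary least squares,
one-way ANOVA with post hoc t tests across distance categories,
residualization of nuisance geometry (distance, volume, surface area), and
Benjamini-Hochberg FDR across a declared family of tests.  Each test
returns a :class:`StatResult`; significance flags are set only after the
family-wise FDR step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "RegressionFit",
    "ttest2",
    "pearson_test",
    "partial_corr",
    "ols",
    "residualize",
    "anova1",
    "posthoc_ttests",
    "bh_fdr",
    "apply_fdr",
    "edge_distance",
    "bin_distances",
    "hemisphere_split",
]

FDR_ALPHA_DEFAULT = 0.05


@dataclass(eq=False)
class StatResult:
    name: str
    statistic: float
    df: float | tuple
    p: float
    q: float | None = None
    significant: bool | None = None
    family: str = "main"

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": float(self.p),
            "q": None if self.q is None else float(self.q),
            "significant": self.significant,
            "family": self.family,
        }


@dataclass(eq=False)
class RegressionFit:
    params: np.ndarray  # beta_0 (intercept) first
    pvalues: np.ndarray
    tvalues: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    r_squared: float
    df_resid: float


def ttest2(x, y, name: str = "ttest2", family: str = "main") -> StatResult:
    """Pooled-variance (Student) two-sample t test, two-tailed,
    df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=n1 + n2 - 2,
        p=float(res.pvalue),
        family=family,
    )


def pearson_test(x, y, name: str = "pearson", family: str = "main") -> StatResult:
    """Pearson correlation with two-tailed p from
    t = r sqrt((n-2) / (1-r^2)) on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned samples of at least three observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=len(x) - 2,
        p=float(res.pvalue),
        family=family,
    )


def partial_corr(
    x, y, covariates=None, name: str = "partial_corr", family: str = "main"
) -> StatResult:
    """Partial correlation: Pearson correlation of the residuals of x and y
    after regressing each on the covariates (with intercept); p via t on
    n - 2 - k df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((len(x), 0))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(x):
        C = C.T
    if C.shape[1] == 0:
        r = pearson_test(x, y, name=name, family=family)
        return r
    k = C.shape[1]
    n = len(x)
    if n <= k + 2:
        raise ValueError("too few observations for the number of covariates")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) <= 1e-10 * max(1.0, np.std(x)) or np.std(ry) <= 1e-10 * max(
        1.0, np.std(y)
    ):
        raise ValueError("partial correlation undefined: residuals constant")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    t = rho * np.sqrt(dof / (1.0 - rho**2))
    p = 2 * sps.t.sf(abs(t), dof)
    return StatResult(name=name, statistic=rho, df=dof, p=float(p), family=family)


def ols(y, X) -> RegressionFit:
    """Ordinary least squares of y on X with an intercept."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    design = sm.add_constant(X, has_constant="add")
    if len(y) <= design.shape[1]:
        raise ValueError("too few observations for the design")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    return RegressionFit(
        params=np.asarray(fit.params),
        pvalues=np.asarray(fit.pvalues),
        tvalues=np.asarray(fit.tvalues),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        r_squared=float(fit.rsquared),
        df_resid=float(fit.df_resid),
    )


def residualize(values, nuisance) -> np.ndarray:
    """Residuals of an OLS fit of ``values`` on the nuisance design (with
    intercept); the residual mean is zero."""
    return ols(values, nuisance).residuals


def anova1(
    groups: list, name: str = "anova", family: str = "main"
) -> StatResult:
    """One-way ANOVA, F on (k - 1, N - k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups of at least two values")
    if all(g.var(ddof=1) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere")
    res = sps.f_oneway(*groups)
    k = len(groups)
    N = sum(len(g) for g in groups)
    return StatResult(
        name=name,
        statistic=float(res.statistic),
        df=(k - 1, N - k),
        p=float(res.pvalue),
        family=family,
    )


def posthoc_ttests(
    groups: list, labels: list[str], family: str = "main", prefix: str = "posthoc"
) -> list[StatResult]:
    """All pairwise pooled-variance t tests between the groups."""
    out = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            out.append(
                ttest2(
                    groups[a],
                    groups[b],
                    name=f"{prefix}_{labels[a]}_vs_{labels[b]}",
                    family=family,
                )
            )
    return out


def bh_fdr(pvalues, alpha: float = FDR_ALPHA_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values (monotone-adjusted) and
    significance flags q < alpha."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def apply_fdr(
    results: list[StatResult], alpha: float = FDR_ALPHA_DEFAULT
) -> list[StatResult]:
    """Fill in q-values and significance flags across one declared family."""
    q, flags = bh_fdr([r.p for r in results], alpha=alpha)
    for r, qi, fi in zip(results, q, flags):
        r.q = float(qi)
        r.significant = bool(fi)
    return results


def edge_distance(geometry: list) -> np.ndarray:
    """Pairwise Euclidean distance between region centroids (R x R,
    zero diagonal), regions in id order."""
    geometry = sorted(geometry, key=lambda g: g.region)
    C = np.stack([np.asarray(g.centroid, dtype=float) for g in geometry])
    if len(np.unique(C, axis=0)) != len(C):
        raise ValueError("region centroids must be distinct")
    diff = C[:, None, :] - C[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def bin_distances(distances) -> np.ndarray:
    """Distance categories among connected pairs: the lowest ceil(E/4)
    ranks are "short", the highest ceil(E/4) "long", the remainder "mid".
    Ties are resolved by stable input order."""
    d = np.asarray(distances, dtype=float)
    E = len(d)
    if E < 4:
        raise ValueError("need at least four connected pairs")
    n_q = ceil(0.25 * E)
    order = np.argsort(d, kind="stable")
    cats = np.array(["mid"] * E, dtype=object)
    cats[order[:n_q]] = "short"
    cats[order[E - n_q:]] = "long"
    return cats


def hemisphere_split(
    pair_i, pair_j, hemisphere: dict[int, str]
) -> dict[str, np.ndarray]:
    """Partition region pairs into within-left, within-right and
    interhemispheric subsets (boolean masks keyed "LH", "RH", "LH-RH")."""
    pair_i = np.asarray(pair_i)
    pair_j = np.asarray(pair_j)
    try:
        hi = np.array([hemisphere[int(r)] for r in pair_i])
        hj = np.array([hemisphere[int(r)] for r in pair_j])
    except KeyError as e:
        raise ValueError(f"missing hemisphere label for region {e}") from e
    lh = (hi == "left") & (hj == "left")
    rh = (hi == "right") & (hj == "right")
    return {"LH": lh, "RH": rh, "LH-RH": ~(lh | rh)}
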