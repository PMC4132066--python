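"""Group-level statistics: Mantel permutation test, Mann-Whitney U,
median [range] summaries and the nest distance matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from coforage.trips import haversine_m

EXACT_MW_LIMIT = 400  # n1*n2 above which the normal approximation is used


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None = None


@dataclass(frozen=True)
class RankTestResult:
    U: float
    p: float
    n1: int
    n2: int
    method: str = "exact"


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _check_square_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if m.shape[0] < 4:
        raise ValueError(f"{name} must have at least 4 rows")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return m


def mantel_test(
    matrix_x, matrix_y, n_perm: int = 9999, seed: int | None = None
) -> MantelResult:
    """Permutation test for correlation between two distance matrices.

    The statistic is the Pearson correlation of the vectorised strict
    lower triangles; the null distribution is built by simultaneously
    permuting the rows and columns of the second matrix.  The two-sided
    p-value is ``(count(|r_perm| >= |r_obs|) + 1) / (n_perm + 1)``.

    NaN entries (e.g. masked dyads never at sea simultaneously) are
    excluded pairwise from every correlation.
    """
    x = _check_square_symmetric(matrix_x, "matrix_x")
    y = _check_square_symmetric(matrix_y, "matrix_y")
    if x.shape != y.shape:
        raise ValueError("matrices must have the same shape")
    n = x.shape[0]
    vx = _lower_triangle(x)

    def corr(vy: np.ndarray) -> float:
        ok = np.isfinite(vx) & np.isfinite(vy)
        a, b = vx[ok], vy[ok]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("zero-variance or empty triangle: r undefined")
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(_lower_triangle(y))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr(_lower_triangle(y[np.ix_(perm, perm)]))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed)


def mann_whitney(values_1, values_2) -> RankTestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Uses the exact distribution when ``n1*n2 <= 400`` and the data are
    tie-free, otherwise the tie-corrected normal approximation.  The
    reported U is the statistic of the first sample.
    """
    v1 = np.asarray(values_1, dtype=float)
    v2 = np.asarray(values_2, dtype=float)
    if len(v1) == 0 or len(v2) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([v1, v2])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(v1) * len(v2) <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(v1, v2, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return RankTestResult(U=float(res.statistic), p=float(res.pvalue),
                          n1=len(v1), n2=len(v2), method=method)


def median_range_summary(values) -> tuple[float, float, float]:
    """(median, min, max); even-length median is the mean of the central pair."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values to summarise")
    return float(np.median(v)), float(np.min(v)), float(np.max(v))


def nest_distance_matrix(deployments: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (m) between nest coordinates.

    Rows/columns are indexed by individual id in deployment-table order;
    the matrix is symmetric with a zero diagonal.
    """
    ids = deployments["individual_id"].astype(str).to_numpy()
    lat = deployments["nest_lat"].to_numpy(dtype=float)
    lon = deployments["nest_lon"].to_numpy(dtype=float)
    d = np.asarray(haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :]))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=ids, columns=ids)


def association_time_matrix(
    pair_table: pd.DataFrame,
    deployments: pd.DataFrame,
    mask_non_overlapping: bool = True,
) -> pd.DataFrame:
    """Square matrix of per-dyad total association time (minutes).

    Dyads that never associated score 0 when both individuals were
    deployed on the same date (they were at sea simultaneously) and NaN
    otherwise when `mask_non_overlapping` is set.
    """
    ids = deployments["individual_id"].astype(str).to_numpy()
    dates = dict(zip(ids, deployments["date"].astype(str)))
    n = len(ids)
    m = np.zeros((n, n))
    if mask_non_overlapping:
        for i in range(n):
            for j in range(n):
                if i != j and dates[ids[i]] != dates[ids[j]]:
                    m[i, j] = np.nan
    index = {ind: k for k, ind in enumerate(ids)}
    for _, row in pair_table.iterrows():
        a, b = str(row["id_a"]), str(row["id_b"])
        if a in index and b in index:
            m[index[a], index[b]] = m[index[b], index[a]] = row["assoc_duration_min"]
    np.fill_diagonal(m, 0.0)
    return pd.DataFrame(m, index=ids, columns=ids)
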