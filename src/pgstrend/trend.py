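"""Birth-cohort penetrance model and its robustness machinery.

The core fit is OLS of a phenotype on an intercept, the standardized
polygenic score, centered birth year, and their product; the interaction
coefficient is the quantity of interest.  On top of that sit a
cluster-robust (CR1 sandwich) covariance for household clustering, a SIMEX
simulation-extrapolation correction for score measurement error, and an
equal-frequency-bin variance homogeneity check across birth cohorts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "COEF_NAMES",
    "TrendFit",
    "SimexResult",
    "CohortVarianceReport",
    "fit_interaction",
    "cluster_robust_vcov",
    "simex_correct",
    "variance_by_cohort",
]

COEF_NAMES = ("intercept", "pgs", "birth_year", "pgs_x_birth_year")


@dataclasses.dataclass
class TrendFit:
    """OLS fit of phenotype ~ 1 + score + centered year + score x year."""

    params: np.ndarray
    cov_classical: np.ndarray
    pvalues_classical: np.ndarray
    n_obs: int
    df_resid: int
    year_center: float
    sigma2: float
    X: np.ndarray
    resid: np.ndarray
    xtx_inv: np.ndarray
    household_id: np.ndarray | None = None
    cov_cluster: np.ndarray | None = None
    pvalues_cluster: np.ndarray | None = None
    n_clusters: int | None = None

    @property
    def b_pgs(self) -> float:
        return float(self.params[1])

    @property
    def b_year(self) -> float:
        return float(self.params[2])

    @property
    def b_interaction(self) -> float:
        return float(self.params[3])

    def se(self, robust: bool = False) -> np.ndarray:
        cov = self.cov_cluster if robust else self.cov_classical
        if cov is None:
            raise ValueError("cluster-robust covariance not computed yet")
        return np.sqrt(np.diag(cov))

    def predict(self, score: np.ndarray, birth_year: np.ndarray) -> np.ndarray:
        c = np.asarray(birth_year, dtype=float) - self.year_center
        s = np.asarray(score, dtype=float)
        a, bp, by, bi = self.params
        return a + bp * s + by * c + bi * s * c


@dataclasses.dataclass
class SimexResult:
    """SIMEX trajectory and quadratic extrapolation to lambda = -1."""

    lambda_grid: np.ndarray
    coef_means: np.ndarray  # (1 + len(grid), 4); first row is lambda = 0
    extrapolation: np.ndarray  # quadratic coefficients, highest power first
    corrected: float
    naive: float
    B: int
    sigma2_err: float
    seed: int


@dataclasses.dataclass
class CohortVarianceReport:
    """Per-cohort-bin score variances with a Brown-Forsythe homogeneity test
    and a trend-sensitive slope of squared deviations on birth year."""

    bin_edges: list[tuple[int, int]]
    bin_sizes: np.ndarray
    variances: np.ndarray
    bf_stat: float
    bf_pvalue: float
    slope: float
    slope_pvalue: float


def _clean_inputs(*arrays: np.ndarray) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("inputs must have equal length")
    keep = np.ones(n, dtype=bool)
    for a in arrays:
        keep &= np.isfinite(a)
    return [a[keep] for a in arrays], keep


def fit_interaction(
    phenotype: np.ndarray,
    score: np.ndarray,
    birth_year: np.ndarray,
    household_id: np.ndarray | None = None,
) -> TrendFit:
    """OLS with classical covariance and two-sided t p-values.

    Birth year is centered at its sample mean internally, so the interaction
    coefficient is invariant to any constant shift of birth year.  Rows with
    a missing value in any input are dropped.
    """
    if household_id is not None:
        household_id = np.asarray(household_id)
        if len(household_id) != len(phenotype):
            raise ValueError("household_id length mismatch")
    (y, s, by), keep = _clean_inputs(phenotype, score, birth_year)
    if household_id is not None:
        household_id = household_id[keep]
    n = len(y)
    if n < 5:  # 4 parameters + at least 1 residual df
        raise ValueError(f"need at least 5 complete observations, got {n}")
    center = by.mean()
    c = by - center
    X = np.column_stack([np.ones(n), s, c, s * c])
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    params = xtx_inv @ (X.T @ y)
    resid = y - X @ params
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    tvals = params / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return TrendFit(
        params=params,
        cov_classical=cov,
        pvalues_classical=pvals,
        n_obs=n,
        df_resid=df,
        year_center=float(center),
        sigma2=sigma2,
        X=X,
        resid=resid,
        xtx_inv=xtx_inv,
        household_id=household_id,
    )


def cluster_robust_vcov(
    fit: TrendFit, household_id: np.ndarray | None = None
) -> np.ndarray:
    """CR1 sandwich covariance clustered by household.

    ``(X'X)^{-1} (sum_g X_g' u_g u_g' X_g) (X'X)^{-1}`` scaled by
    ``G/(G-1) * (n-1)/(n-k)``.  With singleton clusters this reduces to the
    HC1 heteroskedasticity-robust estimator.  Also stores the covariance and
    p-values (t with G-1 df) on the fit.
    """
    ids = household_id if household_id is not None else fit.household_id
    if ids is None:
        raise ValueError("household ids required for cluster-robust covariance")
    ids = np.asarray(ids)
    if len(ids) != fit.n_obs:
        raise ValueError("household_id length does not match fitted sample")
    uniques, codes = np.unique(ids, return_inverse=True)
    G = len(uniques)
    if G < 2:
        raise ValueError("need at least 2 clusters")
    n, k = fit.X.shape
    scores = fit.X * fit.resid[:, None]
    sums = np.zeros((G, k))
    np.add.at(sums, codes, scores)
    meat = sums.T @ sums
    factor = (G / (G - 1.0)) * ((n - 1.0) / (n - k))
    cov = factor * fit.xtx_inv @ meat @ fit.xtx_inv
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.diag(cov))
    tvals = fit.params / se
    fit.cov_cluster = cov
    fit.pvalues_cluster = 2.0 * stats.t.sf(np.abs(tvals), G - 1)
    fit.n_clusters = G
    return cov


def simex_correct(
    phenotype: np.ndarray,
    score: np.ndarray,
    birth_year: np.ndarray,
    sigma2_err: float,
    lambda_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
    B: int = 100,
    seed: int = 0,
) -> SimexResult:
    """Simulation-extrapolation correction of the interaction coefficient.

    For each lambda, B replicates add Normal(0, lambda * sigma2_err) noise
    to the score and refit; a quadratic in lambda through the naive point
    and the per-lambda means is evaluated at lambda = -1.
    """
    if sigma2_err <= 0:
        raise ValueError("sigma2_err must be positive")
    lam = np.asarray(lambda_grid, dtype=float)
    if len(lam) < 3:
        raise ValueError("lambda_grid must contain at least 3 values")
    if (lam <= 0).any() or (np.diff(lam) <= 0).any():
        raise ValueError("lambda_grid must be strictly increasing and positive")
    if B < 50:
        raise ValueError("B must be >= 50")

    (y, s, by), _ = _clean_inputs(phenotype, score, birth_year)
    n = len(y)
    naive_fit = fit_interaction(y, s, by)
    rng = np.random.default_rng(seed)

    c = by - by.mean()
    coef_means = [naive_fit.params]
    for lam_j in lam:
        sd = np.sqrt(lam_j * sigma2_err)
        acc = np.zeros(4)
        for _ in range(B):
            s_b = s + rng.normal(0.0, sd, size=n)
            X = np.column_stack([np.ones(n), s_b, c, s_b * c])
            params, *_ = np.linalg.lstsq(X, y, rcond=None)
            acc += params
        coef_means.append(acc / B)
    coef_means = np.vstack(coef_means)

    lambdas_all = np.concatenate([[0.0], lam])
    poly = np.polyfit(lambdas_all, coef_means[:, 3], 2)
    corrected = float(np.polyval(poly, -1.0))
    return SimexResult(
        lambda_grid=lam,
        coef_means=coef_means,
        extrapolation=poly,
        corrected=corrected,
        naive=float(naive_fit.b_interaction),
        B=B,
        sigma2_err=float(sigma2_err),
        seed=seed,
    )


def variance_by_cohort(
    score: np.ndarray, birth_year: np.ndarray, n_bins: int = 8
) -> CohortVarianceReport:
    """Score variance across equal-frequency birth-year bins.

    Uses Brown-Forsythe (median-centered Levene) for homogeneity, plus an
    OLS slope of squared deviations from the overall mean on centered birth
    year as a trend-sensitive supplement.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    (s, by), _ = _clean_inputs(score, birth_year)
    if s.var(ddof=1) == 0.0:
        raise ValueError("constant score: variance check is degenerate")
    # tie-break by input order, NOT by score: splitting tied birth years by
    # score would truncate within-bin distributions and inflate the test size
    order = np.argsort(by, kind="stable")
    blocks = np.array_split(order, n_bins)
    if min(len(b) for b in blocks) < 10:
        raise ValueError("bins too small: need >= 10 observations per bin")
    groups = [s[b] for b in blocks]
    edges = [(int(by[b].min()), int(by[b].max())) for b in blocks]
    variances = np.array([g.var(ddof=1) for g in groups])
    bf_stat, bf_p = stats.levene(*groups, center="median")

    sq = (s - s.mean()) ** 2
    c = by - by.mean()
    X = np.column_stack([np.ones(len(s)), c])
    coef, *_ = np.linalg.lstsq(X, sq, rcond=None)
    resid = sq - X @ coef
    df = len(s) - 2
    sigma2 = resid @ resid / df
    se_slope = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    slope_p = 2.0 * stats.t.sf(abs(coef[1] / se_slope), df)
    return CohortVarianceReport(
        bin_edges=edges,
        bin_sizes=np.array([len(b) for b in blocks]),
        variances=variances,
        bf_stat=float(bf_stat),
        bf_pvalue=float(bf_p),
        slope=float(coef[1]),
        slope_pvalue=float(slope_p),
    )
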