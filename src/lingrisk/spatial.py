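"""Spatial regression: weights, Moran's I, OLS and SAR error models.

The workhorse is the simultaneous autoregressive (SAR) error model

    y = X beta + u,    u = lambda W u + eps,    eps ~ N(0, sigma^2 I)

with W a row-standardised distance-band neighbour matrix over cell
centroids.  Maximum likelihood concentrates beta and sigma^2 out:

    logL(lambda) = const + ln|I - lambda W| - (n/2) ln(RSS(lambda)/n)

where RSS(lambda) is the residual sum of squares of the spatially
filtered system ((I - lambda W) y on (I - lambda W) X).  The
log-determinant uses the (precomputable) eigenvalues of W, so repeated
fits with the same weights — the all-subsets averaging, the Monte Carlo
suites — pay the eigendecomposition once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.sparse import linalg as sparse_linalg  # noqa: F401  (registers sparse.linalg)
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class SpatialWeights:
    """Distance-band spatial weights over point coordinates.

    ``adjacency`` is the symmetric binary neighbour matrix (CSR); ``w``
    its row-standardised copy (rows of isolates stay zero and are
    flagged rather than dropped, so n is stable across candidate
    distance thresholds).
    """

    threshold_km: float
    adjacency: sparse.csr_matrix
    w: sparse.csr_matrix
    isolates: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all (row-standardised) weights."""
        return float(self.w.sum())

    _eigs: np.ndarray | None = field(default=None, repr=False)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardised W (cached).

        W = D^-1 A with symmetric A is similar to the symmetric
        D^-1/2 A D^-1/2, so its spectrum is real; isolate rows contribute
        zeros.
        """
        if self._eigs is None:
            deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
            n = self.n
            active = deg > 0
            eigs = np.zeros(n)
            if active.any():
                d = deg[active]
                A = self.adjacency[np.ix_(active, active)].toarray()
                S = A / np.sqrt(np.outer(d, d))
                eigs_active = np.linalg.eigvalsh(S)
                eigs[: eigs_active.size] = eigs_active
            self._eigs = np.sort(eigs)
        return self._eigs


def distance_band_neighbors(centroids, threshold_km: float) -> SpatialWeights:
    """Binary adjacency for point pairs within ``threshold_km``.

    ``centroids`` is (n, 2) in kilometres (projected coordinates / 1000).
    Self-neighbours are excluded; isolates (empty rows) are flagged.
    """
    pts = np.asarray(centroids, float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two centroids")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=threshold_km, output_type="ndarray")
    n = pts.shape[0]
    if pairs.size:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        adj = sparse.csr_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    else:
        adj = sparse.csr_matrix((n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    isolates = deg == 0
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    w = sparse.diags(inv) @ adj
    return SpatialWeights(
        threshold_km=float(threshold_km),
        adjacency=adj.tocsr(),
        w=w.tocsr(),
        isolates=isolates,
    )


def logdet_sparse_lu(w: sparse.spmatrix, lam: float) -> float:
    """ln|I - lam W| via sparse LU (the large-n path).

    Agrees with the eigenvalue route; useful when a dense
    eigendecomposition of W is not affordable.
    """
    n = w.shape[0]
    A = (sparse.identity(n, format="csc") - lam * w.tocsc()).tocsc()
    lu = sparse.linalg.splu(A, permc_spec="NATURAL", diag_pivot_thresh=0.0)
    diag = lu.U.diagonal()
    if np.any(diag == 0):
        return -np.inf
    return float(np.sum(np.log(np.abs(diag))))


@dataclass
class MoranResult:
    i_value: float
    expected: float
    p_value: float
    n: int
    permutations: int


def morans_i(values, weights: SpatialWeights, permutations: int = 999, seed: int = 0):
    """Global Moran's I with a two-sided permutation test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values; expectation -1/(n-1) under spatial randomness.  The p-value
    compares |I - E| against 999 seeded permutations.
    """
    z = np.asarray(values, float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(z) == 0:
        raise ValueError("constant values; Moran's I undefined")
    z = z - z.mean()
    w = weights.w
    s0 = weights.s0

    def stat(zv):
        return (n / s0) * float(zv @ (w @ zv)) / float(zv @ zv)

    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        zp = rng.permutation(z)
        if abs(stat(zp) - expected) >= abs(i_obs - expected) - 1e-15:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return MoranResult(i_value=i_obs, expected=expected, p_value=p, n=n, permutations=permutations)


def moran_correlogram(values, centroids, distance_classes, permutations: int = 199, seed: int = 0):
    """Moran's I per distance class (annulus weights).

    ``distance_classes`` is an increasing sequence of bin edges in km.
    Returns a DataFrame (d_lo, d_hi, i_value, p_value, n_pairs).
    """
    pts = np.asarray(centroids, float)
    z = np.asarray(values, float)
    n = pts.shape[0]
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    rows = []
    edges = list(distance_classes)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (dist > lo) & (dist <= hi)
        np.fill_diagonal(mask, False)
        n_pairs = int(mask.sum()) // 2
        if n_pairs == 0:
            rows.append((lo, hi, np.nan, np.nan, 0))
            continue
        adj = sparse.csr_matrix(mask.astype(float))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        sw = SpatialWeights(hi, adj, sparse.diags(inv) @ adj, deg == 0)
        res = morans_i(z, sw, permutations=permutations, seed=seed)
        rows.append((lo, hi, res.i_value, res.p_value, n_pairs))
    return pd.DataFrame(rows, columns=["d_lo", "d_hi", "i_value", "p_value", "n_pairs"])


@dataclass
class OlsFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    log_likelihood: float
    aic: float
    residuals: np.ndarray
    names: list


def fit_ols(y, X, names=None) -> OlsFit:
    """Ordinary least squares with Gaussian ML log-likelihood.

    ``X`` must include the intercept column.  AIC counts k = p + 1
    parameters (coefficients plus the error variance) so it is
    commensurate with the SAR AIC (p + 2).  Rank deficiency raises with
    the offending columns named.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"design matrix rank deficient; implicated columns: {bad}")
    res = sm.OLS(y, X).fit()
    n, p = X.shape
    rss = float(res.ssr)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = p + 1
    return OlsFit(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        sigma2=sigma2,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        residuals=np.asarray(res.resid),
        names=names,
    )


@dataclass
class SarFit:
    beta: np.ndarray
    se: np.ndarray
    lam: float
    sigma2: float
    log_likelihood: float
    aic: float
    residuals: np.ndarray
    names: list
    lambda_at_boundary: bool = False
    pseudo_r2: float | None = None


def nagelkerke_r2(fit_logL: float, null_logL: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox–Snell rescaled by its maximum.

    R²_CS = 1 - exp(-(2/n)(logL - logL0)); its maximum (a perfect fit)
    is 1 - exp((2/n) logL0), and the Nagelkerke value is the ratio.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cox_snell = 1.0 - np.exp(-(2.0 / n) * (fit_logL - null_logL))
    max_cs = 1.0 - np.exp((2.0 / n) * null_logL)
    if max_cs <= 0:
        return 0.0
    return float(min(cox_snell / max_cs, 1.0))


class SarErrorRegression(BaseEstimator, RegressorMixin):
    """Maximum-likelihood SAR error model (spatial error dependence).

    Parameters
    ----------
    weights : SpatialWeights
        Row-standardised neighbour structure (fixed, not learned).
    lam : float or None
        Fix the autoregression parameter (None = estimate by ML).
    xtol : scalar-search tolerance on lambda.
    compute_pseudo_r2 : attach the Nagelkerke pseudo-R² against the
        intercept-only OLS null.

    Attributes
    ----------
    coef_ / se_ : GLS coefficients and standard errors at lambda-hat.
    lambda_, sigma2_, log_likelihood_, aic_ (k = p + 2), residuals_
    (spatially filtered), pseudo_r2_.
    """

    def __init__(self, weights=None, lam=None, xtol: float = 1e-8, compute_pseudo_r2: bool = True):
        self.weights = weights
        self.lam = lam
        self.xtol = xtol
        self.compute_pseudo_r2 = compute_pseudo_r2

    def fit(self, X, y):
        if self.weights is None:
            raise ValueError("SarErrorRegression requires spatial weights")
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        W = self.weights.w
        eigs = self.weights.eigenvalues()

        def filtered_rss(lam):
            Ay = y - lam * (W @ y)
            AX = X - lam * (W @ X)
            coef, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
            r = Ay - AX @ coef
            return float(r @ r), coef, AX, Ay

        def logdet(lam):
            v = 1.0 - lam * eigs
            if np.any(v <= 0):
                return -np.inf
            return float(np.sum(np.log(v)))

        def negloglik(lam):
            ld = logdet(lam)
            if not np.isfinite(ld):
                return np.inf
            rss = filtered_rss(lam)[0]
            return -(ld - 0.5 * n * np.log(rss / n))

        e_min, e_max = eigs.min(), eigs.max()
        lo = (1.0 / e_min + 1e-6) if e_min < 0 else -0.999999
        hi = (1.0 / e_max - 1e-6) if e_max > 0 else 0.999999

        boundary = False
        if self.lam is not None:
            lam_hat = float(self.lam)
        else:
            # coarse unimodality guard, then bounded refinement
            grid = np.linspace(lo, hi, 21)
            vals = np.array([negloglik(l) for l in grid])
            k = int(np.nanargmin(vals))
            a = grid[max(k - 1, 0)]
            b = grid[min(k + 1, grid.size - 1)]
            res = minimize_scalar(
                negloglik, bounds=(a, b), method="bounded", options={"xatol": self.xtol}
            )
            lam_hat = float(res.x)
            # never do worse than lambda = 0 (OLS)
            if negloglik(0.0) < negloglik(lam_hat):
                lam_hat = 0.0
            boundary = min(lam_hat - lo, hi - lam_hat) < 1e-4

        rss, coef, AX, Ay = filtered_rss(lam_hat)
        sigma2 = rss / n
        ld = logdet(lam_hat)
        if not np.isfinite(ld):
            raise ValueError("non-finite log-determinant at fitted lambda")
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + ld
        try:
            cov = sigma2 * np.linalg.inv(AX.T @ AX) * n / max(n - p, 1)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)

        self.coef_ = coef
        self.se_ = se
        self.lambda_ = lam_hat
        self.sigma2_ = sigma2
        self.log_likelihood_ = ll
        self.k_ = p + 2
        self.aic_ = -2.0 * ll + 2.0 * self.k_
        self.residuals_ = Ay - AX @ coef
        self.lambda_at_boundary_ = boundary
        self.n_ = n
        if self.compute_pseudo_r2:
            # evaluate both likelihoods on the unit-variance response: the
            # likelihood ratio is scale-invariant, but the Nagelkerke
            # normalisation needs a negative null log-likelihood, which a
            # response with tiny variance would otherwise violate
            null = fit_ols(y, np.ones((n, 1)))
            shift = n * np.log(max(np.std(y), np.finfo(float).tiny))
            self.pseudo_r2_ = nagelkerke_r2(ll + shift, null.log_likelihood + shift, n)
        else:
            self.pseudo_r2_ = None
        return self

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_


def fit_sar_error(y, X, weights: SpatialWeights, names=None, lam=None, **kwargs) -> SarFit:
    """Functional wrapper over :class:`SarErrorRegression`."""
    X = np.asarray(X, float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    est = SarErrorRegression(weights=weights, lam=lam, **kwargs).fit(X, np.asarray(y, float))
    return SarFit(
        beta=est.coef_,
        se=est.se_,
        lam=est.lambda_,
        sigma2=est.sigma2_,
        log_likelihood=est.log_likelihood_,
        aic=est.aic_,
        residuals=est.residuals_,
        names=names,
        lambda_at_boundary=est.lambda_at_boundary_,
        pseudo_r2=est.pseudo_r2_,
    )


def select_neighborhood(y, X, centroids_km, candidate_thresholds, names=None):
    """Fit the SAR error model at each distance band; keep the lowest AIC.

    Returns (threshold, SarFit, table) where ``table`` is the AIC per
    candidate.  Per-candidate failures are tolerated as long as at least
    one candidate fits.
    """
    candidates = list(candidate_thresholds)
    if not candidates:
        raise ValueError("no candidate thresholds")
    rows = []
    fits = {}
    for d in candidates:
        try:
            sw = distance_band_neighbors(centroids_km, d)
            if sw.isolates.all():
                raise ValueError("all cells isolated at this threshold")
            fit = fit_sar_error(y, X, sw, names=names)
            fits[d] = (fit, sw)
            rows.append({"threshold_km": d, "aic": fit.aic, "error": None})
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append({"threshold_km": d, "aic": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    if not fits:
        raise ValueError("every candidate neighbourhood failed to fit")
    best = table.dropna(subset=["aic"]).sort_values("aic").iloc[0]["threshold_km"]
    fit, sw = fits[best]
    return float(best), fit, sw, table
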