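"""Segmented (breakpoint) regression and AIC model-family comparison.

A segmented regression is a continuous piecewise-linear model with one
unknown change point psi:

    y = b0 + b1 * x + b2 * (x - psi)_+ + e,   e ~ N(0, sigma^2)

estimated by least squares jointly over (b0, b1, b2, psi).  The primary
estimator is the iterative-linearisation scheme of Muggeo: augment the
design with the hinge (x - psi)_+ and its negative indicator -1{x > psi},
refit, and update psi <- psi + gamma_hat / b2_hat until the step falls
below ``tol_factor * range(x)``.  Basins are located by a coarse profile
scan of the residual sum of squares, so the final optimum agrees with an
exhaustive profile search.  Candidate model families (null, linear,
quadratic, segmented) are compared by AIC computed from the Gaussian
maximum likelihood, counting the error variance as a parameter
(k = 2, 3, 4, 5 respectively).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood with sigma^2 = RSS / n."""
    if rss <= 0:
        rss = np.finfo(float).tiny * n
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


@dataclass
class CandidateFit:
    """One member of the null/linear/quadratic/segmented comparison."""

    family: str
    coefficients: np.ndarray
    log_likelihood: float
    k: int
    aic: float


def _profile_rss(x, y, psi):
    """RSS of the best continuous two-segment fit with the break at psi."""
    Z = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    coef, res, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ coef
    return float(np.sum((y - fitted) ** 2)), coef


def profile_breakpoint_search(x, y, n_grid: int = 1000):
    """Exhaustive profile search for the breakpoint on an even grid.

    Scans ``n_grid`` candidate psi values strictly inside the observed x
    range and returns (psi, rss, grid_step).  Ties break to the smallest
    psi.  This is the slow, transparent reference path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo, hi = x.min(), x.max()
    grid = np.linspace(lo, hi, n_grid + 2)[1:-1]
    best_psi, best_rss = None, np.inf
    for psi in grid:
        rss, _ = _profile_rss(x, y, psi)
        if best_psi is None or rss < best_rss - 1e-12 * (1 + best_rss):
            best_rss, best_psi = rss, psi
    return float(best_psi), float(best_rss), float(grid[1] - grid[0])


class SegmentedRegression(BaseEstimator, RegressorMixin):
    """One-breakpoint continuous piecewise-linear least squares.

    Parameters
    ----------
    n_scan : int
        Coarse profile-scan resolution used to locate basins before the
        iterative refinement.
    max_iter, tol_factor : iterative-linearisation stopping rule; the
        update stops once ``|delta psi| < tol_factor * range(x)``.
    ci_method : 'delta' or 'bootstrap'
        95% interval for psi: the delta method from the augmented design
        (the 'segmented'-package convention) or a case-resampling
        bootstrap.
    n_boot : bootstrap resamples.
    random_state : seed for the bootstrap.

    Attributes
    ----------
    psi_, psi_ci_ : breakpoint and its 95% interval.
    intercept_, slope_left_, slope_right_ : segment parameters.
    sigma2_, rss_, log_likelihood_, aic_ : fit quality (k = 5).
    degenerate_ : True when no interior optimum exists (profile RSS
        monotone); callers should fall back to the linear family.
    """

    def __init__(
        self,
        n_scan: int = 100,
        max_iter: int = 50,
        tol_factor: float = 1e-6,
        ci_method: str = "delta",
        n_boot: int = 500,
        random_state=None,
    ):
        self.n_scan = n_scan
        self.max_iter = max_iter
        self.tol_factor = tol_factor
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _muggeo(self, x, y, psi0, lo, hi, tol):
        """Iterative linearisation from one start; returns psi or None."""
        psi = psi0
        for _ in range(self.max_iter):
            hinge = np.clip(x - psi, 0.0, None)
            ind = -(x > psi).astype(float)
            Z = np.column_stack([np.ones_like(x), x, hinge, ind])
            try:
                coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            except np.linalg.LinAlgError:
                return None
            b2, gamma = coef[2], coef[3]
            if abs(b2) < 1e-12:
                return None
            step = gamma / b2
            new_psi = np.clip(psi + step, lo, hi)
            if abs(new_psi - psi) < tol:
                return float(new_psi)
            psi = new_psi
        return float(psi)

    def fit(self, X, y):
        x = np.asarray(X, float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("segmented regression takes a single predictor")
            x = x[:, 0]
        y = np.asarray(y, float)
        n = x.size
        if n < 7:
            raise ValueError("need at least 7 observations")
        if np.unique(x).size < 5:
            raise ValueError("need at least 5 distinct x values")

        rng_span = x.max() - x.min()
        tol = self.tol_factor * rng_span
        # interior window: keep at least 2 points on each side
        xs = np.sort(x)
        lo = xs[1] + 1e-9 * rng_span
        hi = xs[-2] - 1e-9 * rng_span
        if hi <= lo:
            raise ValueError("degenerate predictor span")

        # coarse profile scan to locate basins
        scan = np.linspace(lo, hi, self.n_scan)
        scan_rss = np.array([_profile_rss(x, y, p)[0] for p in scan])
        order = np.argsort(scan_rss, kind="stable")
        starts = list(scan[order[:5]]) + [float(np.median(x))]

        candidates = []
        for s in starts:
            psi = self._muggeo(x, y, float(np.clip(s, lo, hi)), lo, hi, tol)
            if psi is not None:
                candidates.append(psi)
        candidates.extend(scan[order[:3]])  # scan minima as fallbacks

        best_psi, best_rss, best_coef = None, np.inf, None
        for psi in candidates:
            rss, coef = _profile_rss(x, y, psi)
            if best_psi is None or rss < best_rss - 1e-12 * (1 + best_rss) or (
                abs(rss - best_rss) <= 1e-12 * (1 + best_rss)
                and (best_psi is None or psi < best_psi)
            ):
                best_psi, best_rss, best_coef = float(psi), rss, coef

        # local polish of the profile RSS around the leading basins (the
        # linearisation step can stall a fraction of a grid step away, and
        # near-tied basins need refining before they can be compared)
        half = (hi - lo) / max(self.n_scan - 1, 1)
        scored = sorted(
            {round(p, 12) for p in candidates}, key=lambda p: _profile_rss(x, y, p)[0]
        )
        basins = []
        for p in scored:
            if all(abs(p - b) > half for b in basins):
                basins.append(p)
            if len(basins) == 5:
                break
        for centre in basins:
            res = minimize_scalar(
                lambda p: _profile_rss(x, y, p)[0],
                bounds=(max(lo, centre - half), min(hi, centre + half)),
                method="bounded",
                options={"xatol": max(tol, 1e-12)},
            )
            rss_ref, coef_ref = _profile_rss(x, y, float(res.x))
            if rss_ref < best_rss - 1e-12 * (1 + best_rss) or (
                abs(rss_ref - best_rss) <= 1e-12 * (1 + best_rss) and res.x < best_psi
            ):
                best_psi, best_rss, best_coef = float(res.x), rss_ref, coef_ref

        # an exact fit leaves numerically-ragged tiny RSS values across
        # families; snap them to zero on a common scale so AIC comparisons
        # reduce to parameter counts
        y_scale = max(np.max(np.abs(y)), 1.0)
        if best_rss < n * (1e-12 * y_scale) ** 2:
            best_rss = 0.0

        # degenerate when the profile scan is monotone (optimum at a scan
        # edge with no better interior candidate) or the slope change is
        # negligible against the data scale (no-break limit)
        edge = min(scan_rss[0], scan_rss[-1])
        interior_gain = edge - best_rss
        monotone = bool(
            interior_gain <= 1e-10 * (1 + edge)
            and np.argmin(scan_rss) in (0, self.n_scan - 1)
        )
        b2 = best_coef[2]
        slope_scale = max(abs(best_coef[1]), np.std(y) / rng_span, np.finfo(float).tiny)
        self.degenerate_ = monotone or abs(b2) < 1e-8 * slope_scale

        self.psi_ = best_psi
        self.rss_ = best_rss
        self.intercept_ = float(best_coef[0])
        self.slope_left_ = float(best_coef[1])
        self.slope_right_ = float(best_coef[1] + best_coef[2])
        self.n_ = n
        self.sigma2_ = best_rss / n
        self.log_likelihood_ = gaussian_loglik(best_rss, n)
        self.k_ = 5
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * self.k_
        self.x_range_ = (float(x.min()), float(x.max()))
        self.psi_ci_ = self._psi_ci(x, y)
        return self

    def _psi_ci(self, x, y):
        if self.ci_method == "bootstrap":
            rng = np.random.default_rng(self.random_state)
            n = x.size
            boots = []
            for _ in range(self.n_boot):
                idx = rng.integers(0, n, n)
                xb, yb = x[idx], y[idx]
                if np.unique(xb).size < 5:
                    continue
                try:
                    est = SegmentedRegression(
                        n_scan=self.n_scan,
                        max_iter=self.max_iter,
                        tol_factor=self.tol_factor,
                        ci_method="none",
                    )
                    est.psi_ci_ = (np.nan, np.nan)
                    est.fit(xb, yb)
                    if not est.degenerate_:
                        boots.append(est.psi_)
                except (ValueError, np.linalg.LinAlgError):
                    continue
            if len(boots) < 10:
                return (np.nan, np.nan)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            return (float(lo), float(hi))
        if self.ci_method != "delta":
            return (np.nan, np.nan)
        # delta method on the augmented design at the optimum: with the
        # gap parameter gamma ~ 0 at convergence, se(psi) = se(gamma)/|b2|
        psi = self.psi_
        hinge = np.clip(x - psi, 0.0, None)
        ind = -(x > psi).astype(float)
        Z = np.column_stack([np.ones_like(x), x, hinge, ind])
        n, p = Z.shape
        try:
            XtX_inv = np.linalg.inv(Z.T @ Z)
        except np.linalg.LinAlgError:
            return (np.nan, np.nan)
        dof = max(n - p, 1)
        s2 = self.rss_ / dof
        b2 = self.slope_right_ - self.slope_left_
        if abs(b2) < 1e-12:
            return (np.nan, np.nan)
        se_psi = np.sqrt(max(s2 * XtX_inv[3, 3], 0.0)) / abs(b2)
        z = stats.norm.ppf(0.975)
        return (float(psi - z * se_psi), float(psi + z * se_psi))

    def predict(self, X):
        check_is_fitted(self, "psi_")
        x = np.asarray(X, float)
        if x.ndim == 2:
            x = x[:, 0]
        return (
            self.intercept_
            + self.slope_left_ * x
            + (self.slope_right_ - self.slope_left_) * np.clip(x - self.psi_, 0.0, None)
        )


@dataclass
class BreakpointFit:
    """Reporting view of a fitted segmented model."""

    psi: float
    psi_ci: tuple
    slope_left: float
    slope_right: float
    intercept: float
    sigma2: float
    degenerate: bool
    aic: float
    log_likelihood: float


def fit_segmented(x, y, **kwargs) -> BreakpointFit:
    """Functional wrapper over :class:`SegmentedRegression`."""
    est = SegmentedRegression(**kwargs).fit(np.asarray(x, float), np.asarray(y, float))
    return BreakpointFit(
        psi=est.psi_,
        psi_ci=est.psi_ci_,
        slope_left=est.slope_left_,
        slope_right=est.slope_right_,
        intercept=est.intercept_,
        sigma2=est.sigma2_,
        degenerate=est.degenerate_,
        aic=est.aic_,
        log_likelihood=est.log_likelihood_,
    )


def _poly_candidate(x, y, family: str) -> CandidateFit:
    n = x.size
    if family == "null":
        Z = np.ones((n, 1))
        k = 2
    elif family == "linear":
        Z = np.column_stack([np.ones(n), x])
        k = 3
    elif family == "quadratic":
        Z = np.column_stack([np.ones(n), x, x * x])
        k = 4
    else:
        raise ValueError(family)
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rss = float(np.sum((y - Z @ coef) ** 2))
    y_scale = max(np.max(np.abs(y)), 1.0)
    if rss < n * (1e-12 * y_scale) ** 2:  # exact fit: snap for fair AIC
        rss = 0.0
    ll = gaussian_loglik(rss, n)
    return CandidateFit(family, coef, ll, k, -2.0 * ll + 2.0 * k)


def fit_candidates(x, y, segmented_kwargs=None):
    """Fit the four model families and return their AIC table.

    Returns (candidates, breakpoint_fit) where ``breakpoint_fit`` is None
    when the segmented member is degenerate (no interior breakpoint); the
    degenerate member is then absent from the comparison, matching the
    fall-back-to-linear contract.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    candidates = [_poly_candidate(x, y, fam) for fam in ("null", "linear", "quadratic")]
    bp = None
    try:
        bp = fit_segmented(x, y, **(segmented_kwargs or {}))
    except (ValueError, np.linalg.LinAlgError):
        bp = None
    if bp is not None and not bp.degenerate:
        coefs = np.array(
            [bp.intercept, bp.slope_left, bp.slope_right - bp.slope_left, bp.psi]
        )
        candidates.append(CandidateFit("segmented", coefs, bp.log_likelihood, 5, bp.aic))
    else:
        bp = None
    return candidates, bp


def best_family(candidates) -> str:
    return min(candidates, key=lambda c: c.aic).family


PAIRWISE_ANALYSES = {
    # response <- predictor, with transforms applied to the component table
    "range_vs_population": ("log10_area", "log10_population"),
    "growth_vs_range": ("rate", "log10_area"),
    "growth_vs_initial_population": ("rate", "log10_initial_population"),
}


def pairwise_threshold_analyses(language_table, segmented_kwargs=None) -> dict:
    """The three pairwise risk-component threshold analyses.

    ``language_table`` is the per-language component table (area_km2,
    population, rate, initial_population).  Range and population enter on
    the log10 scale; the growth rate stays raw.  Initial population (the
    count at the oldest survey year) is used against the growth rate to
    avoid circularity.  Breakpoints on log10 predictors are
    back-transformed to natural units (speakers, km²).

    Returns a dict keyed by analysis name with the candidate table, the
    breakpoint fit, the winning family, n, and — for log10 predictors —
    ``psi_natural`` / ``psi_ci_natural``.
    """
    t = language_table
    cols = {}
    if "area_km2" in t:
        cols["log10_area"] = np.log10(t["area_km2"].where(t["area_km2"] > 0))
    if "population" in t:
        cols["log10_population"] = np.log10(t["population"].where(t["population"] > 0))
    if "initial_population" in t:
        cols["log10_initial_population"] = np.log10(
            t["initial_population"].where(t["initial_population"] > 0)
        )
    if "rate" in t:
        cols["rate"] = t["rate"]
    frame = pd.DataFrame(cols)

    out = {}
    for name, (resp, pred) in PAIRWISE_ANALYSES.items():
        if resp not in frame or pred not in frame:
            continue
        sub = frame[[resp, pred]].dropna()
        if sub.empty:
            raise ValueError(f"{name}: empty join of response and predictor")
        x = sub[pred].to_numpy()
        y = sub[resp].to_numpy()
        candidates, bp = fit_candidates(x, y, segmented_kwargs=segmented_kwargs)
        entry = {
            "candidates": candidates,
            "breakpoint": bp,
            "best_family": best_family(candidates),
            "n": int(len(sub)),
        }
        if bp is not None and pred.startswith("log10_"):
            entry["psi_natural"] = 10.0 ** bp.psi
            entry["psi_ci_natural"] = tuple(10.0 ** np.asarray(bp.psi_ci))
        out[name] = entry
    return out
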