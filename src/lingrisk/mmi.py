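"""Multimodel inference: screening, all-subsets AIC and model averaging.

Candidate variables first pass a collinearity screen (pairwise |r| > 0.8
drops the lower-priority partner; tolerances 1 - R² of each survivor on
the others are reported).  All 2^p subsets are then fitted, Akaike
weights w_i = exp(-dAIC_i/2) / sum are computed, the smallest prefix of
the weight-ranked models reaching 95% cumulative weight forms the
confidence set, and coefficients / SEs / z-values are averaged across it.
The per-variable sum of w_i doubles as a relative-importance measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .spatial import SpatialWeights, fit_sar_error


@dataclass
class ScreenReport:
    retained: list
    excluded: list  # (variable, partner, r)
    tolerance: dict  # variable -> 1 - R^2 on the other retained variables


def collinearity_screen(data: pd.DataFrame, priority=None, threshold: float = 0.8) -> ScreenReport:
    """Greedy pairwise screen at |Pearson r| > ``threshold``.

    ``priority`` orders variables from most to least preferred; for each
    offending pair the lower-priority member is dropped.  Tolerances for
    the survivors come from exact least-squares R² of each variable on
    the rest.
    """
    cols = list(data.columns)
    if priority is None:
        priority = cols
    rank = {v: i for i, v in enumerate(priority)}
    for c in cols:
        if data[c].nunique() <= 1:
            raise ValueError(f"constant column {c!r}")

    retained = sorted(cols, key=lambda v: rank.get(v, len(rank)))
    excluded = []
    changed = True
    while changed:
        changed = False
        corr = data[retained].corr()
        worst = None
        for a, b in combinations(retained, 2):
            r = corr.loc[a, b]
            if abs(r) > threshold and (worst is None or abs(r) > abs(worst[2])):
                worst = (a, b, r)
        if worst is not None:
            a, b, r = worst
            drop = b if rank.get(a, 1e9) <= rank.get(b, 1e9) else a
            keep = a if drop == b else b
            retained.remove(drop)
            excluded.append((drop, keep, float(r)))
            changed = True

    tol = {}
    Xall = data[retained].to_numpy(float)
    n = Xall.shape[0]
    for j, v in enumerate(retained):
        if len(retained) == 1:
            tol[v] = 1.0
            continue
        yv = Xall[:, j]
        Z = np.column_stack([np.ones(n), np.delete(Xall, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yv, rcond=None)
        resid = yv - Z @ coef
        tss = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        tol[v] = float(np.clip(1.0 - r2, 0.0, 1.0))
    return ScreenReport(retained=retained, excluded=excluded, tolerance=tol)


def all_subsets(variables) -> list:
    """Every subset of the candidate variables, including the empty
    (intercept-only) model, as tuples in enumeration order."""
    variables = list(variables)
    p = len(variables)
    if p > 20:
        raise ValueError(
            f"{p} variables gives 2^{p} models; restrict the candidate set (guard at 20)"
        )
    subsets = []
    for r in range(p + 1):
        subsets.extend(combinations(variables, r))
    return subsets


def akaike_weights(aics) -> np.ndarray:
    """w_i = exp(-dAIC_i / 2), normalised; non-finite AICs get weight 0."""
    aics = np.asarray(aics, float)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("no finite AIC values")
    w = np.zeros_like(aics)
    d = aics[finite] - aics[finite].min()
    ew = np.exp(-0.5 * d)
    w[finite] = ew / ew.sum()
    return w


@dataclass
class ModelScore:
    subset: tuple
    aic: float
    delta_aic: float
    weight: float


def score_models(subsets, aics):
    aics = np.asarray(aics, float)
    w = akaike_weights(aics)
    base = np.nanmin(aics[np.isfinite(aics)])
    return [
        ModelScore(subset=tuple(s), aic=float(a), delta_aic=float(a - base), weight=float(wi))
        for s, a, wi in zip(subsets, aics, w)
    ]


def confidence_set(models, level: float = 0.95):
    """Smallest weight-ranked prefix with cumulative weight >= level."""
    ranked = sorted(models, key=lambda m: (-m.weight, m.aic))
    out, cum = [], 0.0
    for m in ranked:
        out.append(m)
        cum += m.weight
        if cum >= level - 1e-12:
            break
    return out


@dataclass
class AveragedCoefficient:
    variable: str
    coef: float
    se: float
    z_value: float
    sum_wi: float


def model_average(models, coefs, ses, level: float = 0.95, renormalize: bool = True):
    """Average coefficients over the confidence set.

    Parameters
    ----------
    models : list of ModelScore over the full candidate set.
    coefs, ses : dicts ``subset -> {variable: value}`` of per-model
        estimates and standard errors.
    renormalize : rescale weights to sum to 1 within the confidence set.

    Conditional ("natural") averaging: each variable is averaged over the
    confidence-set models that contain it, with weights renormalised
    within that sub-set.  The unconditional SE follows Burnham–Anderson:
    se = sum_i w'_i sqrt(se_i² + (b_i - b̄)²).  ``sum_wi`` is the summed
    weight of confidence-set models containing the variable (an
    importance measure); z = |coef| / se.
    """
    cset = confidence_set(models, level=level)
    total = sum(m.weight for m in cset)
    scale = (1.0 / total) if (renormalize and total > 0) else 1.0

    variables = []
    for m in cset:
        for v in m.subset:
            if v not in variables:
                variables.append(v)

    out = []
    for v in variables:
        entries = [
            (m.weight * scale, coefs[m.subset][v], ses[m.subset][v])
            for m in cset
            if v in m.subset
        ]
        wsum = sum(w for w, _, _ in entries)
        if wsum <= 0:
            continue
        bbar = sum(w * b for w, b, _ in entries) / wsum
        se = sum(w * np.sqrt(s * s + (b - bbar) ** 2) for w, b, s in entries) / wsum
        z = abs(bbar) / se if se > 0 else np.inf
        out.append(AveragedCoefficient(v, float(bbar), float(se), float(z), float(wsum)))
    return out


def all_subsets_sar(
    y,
    X: pd.DataFrame,
    weights: SpatialWeights,
    level: float = 0.95,
    renormalize: bool = True,
):
    """All-subsets SAR-error fitting with model averaging.

    ``X`` holds the candidate variables (no intercept column; one is
    added to every subset).  lambda is re-estimated per model.  Returns
    (averaged, models, table) — the averaged coefficients, the scored
    model list and a tidy per-variable DataFrame.
    """
    y = np.asarray(y, float)
    variables = list(X.columns)
    subsets = all_subsets(variables)
    n = y.size

    weights.eigenvalues()  # warm the cache once; reused by every subset fit
    aics, coefs, ses = [], {}, {}
    for sub in subsets:
        cols = list(sub)
        Xs = np.column_stack([np.ones(n)] + [X[c].to_numpy(float) for c in cols])
        try:
            fit = fit_sar_error(y, Xs, weights, names=["intercept"] + cols, compute_pseudo_r2=False)
            aics.append(fit.aic)
            coefs[sub] = dict(zip(cols, fit.beta[1:]))
            ses[sub] = dict(zip(cols, fit.se[1:]))
        except (ValueError, np.linalg.LinAlgError):
            aics.append(np.nan)
            coefs[sub] = {}
            ses[sub] = {}
    models = score_models(subsets, aics)
    averaged = model_average(models, coefs, ses, level=level, renormalize=renormalize)
    table = pd.DataFrame(
        [
            {
                "variable": a.variable,
                "coef": a.coef,
                "se": a.se,
                "z_value": a.z_value,
                "sum_wi": a.sum_wi,
                "important": a.z_value > 2.0,
            }
            for a in averaged
        ]
    )
    return averaged, models, table
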