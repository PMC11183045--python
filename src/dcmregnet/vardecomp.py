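"""Per-regulon variance decomposition and disease-responsive selection.

Each regulon's activity over units (metacells by default) is modeled as

    y = mu + a_celltype + b_group + e,
    a ~ N(0, s2_ct) per cell type,  b ~ N(0, s2_grp) per group,
    e ~ N(0, s2_e),

with both factors random.  The restricted likelihood is maximized
numerically over the variance ratios (residual variance profiled out in
closed form), the three components are normalized to proportions, and
within each regulon module the regulons are ranked by their group
proportion; the leading regulons above the knee of the normalized curve
(segment slopes steeper than -1) are selected as disease-responsive.

Estimating a variance from a 2-level group factor is statistically
fragile; the recovery benchmarks in the test suite quantify how well the
group proportion is recovered under the synthetic model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger("dcmregnet")

_START_GRID = (0.01, 0.1, 1.0)      # variance-ratio starts per component
_LOG_BOUNDS = (-16.0, 10.0)


@dataclass
class VarianceDecomposition:
    """REML variance components for one regulon."""

    sigma2_celltype: float
    sigma2_group: float
    sigma2_resid: float
    p_celltype: float
    p_group: float
    p_resid: float
    converged: bool
    reml_loglik: float


def _indicator(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    z = np.zeros((len(labels), len(levels)))
    z[np.arange(len(labels)), inv] = 1.0
    return z


class _RemlProblem:
    """Sufficient statistics for the profiled restricted likelihood.

    With ``W = I + sum_j gamma_j Z_j Z_j'`` (V = s2_e W), Woodbury and the
    determinant lemma reduce every evaluation to algebra on the q x q
    matrix ``A = D^-1 + Z'Z`` (q = total factor levels), so the criterion
    costs O(q^3) per call regardless of n.  The intercept is the only
    fixed effect.
    """

    def __init__(self, y: np.ndarray, z_blocks: list[np.ndarray]) -> None:
        z = np.hstack(z_blocks)
        self.n = y.size
        self.sizes = [zb.shape[1] for zb in z_blocks]
        self.ztz = z.T @ z
        self.zty = z.T @ y
        self.zt1 = z.sum(axis=0)
        self.yty = float(y @ y)
        self.one_ty = float(y.sum())

    def _core(self, d: np.ndarray):
        active = d > 0
        if not active.any():
            xtwix = float(self.n)
            xtwiy = self.one_ty
            ytwiy = self.yty
            logdet_w = 0.0
        else:
            a = self.ztz[np.ix_(active, active)] + np.diag(1.0 / d[active])
            sign, logdet_a = np.linalg.slogdet(a)
            if sign <= 0 or not np.isfinite(logdet_a):
                return None
            try:
                ainv = np.linalg.inv(a)
            except np.linalg.LinAlgError:
                return None
            zy, z1 = self.zty[active], self.zt1[active]
            ytwiy = self.yty - zy @ ainv @ zy
            xtwiy = self.one_ty - z1 @ ainv @ zy
            xtwix = self.n - z1 @ ainv @ z1
            logdet_w = logdet_a + float(np.sum(np.log(d[active])))
        return ytwiy, xtwiy, xtwix, logdet_w

    def neg2_reml(self, log_gammas: np.ndarray) -> float:
        gammas = np.exp(np.clip(log_gammas, _LOG_BOUNDS[0], _LOG_BOUNDS[1]))
        d = np.concatenate([np.full(sz, g)
                            for sz, g in zip(self.sizes, gammas)])
        core = self._core(d)
        if core is None:
            return 1e30
        ytwiy, xtwiy, xtwix, logdet_w = core
        if xtwix <= 0:
            return 1e30
        ypy = ytwiy - xtwiy ** 2 / xtwix
        if ypy <= 0:
            return 1e30
        s2e = ypy / (self.n - 1)
        crit = (self.n - 1) * np.log(s2e) + logdet_w + np.log(xtwix)
        return float(crit) if np.isfinite(crit) else 1e30

    def profiled_s2e(self, gammas: np.ndarray) -> float:
        d = np.concatenate([np.full(sz, g)
                            for sz, g in zip(self.sizes, gammas)])
        core = self._core(d)
        if core is None:
            return np.nan
        ytwiy, xtwiy, xtwix, _ = core
        ypy = ytwiy - xtwiy ** 2 / xtwix
        return max(ypy / (self.n - 1), np.finfo(float).tiny)


def reml_variance_components(y: np.ndarray,
                             factors: dict[str, np.ndarray]
                             ) -> tuple[dict[str, float], float, bool, float]:
    """REML estimates for crossed random factors plus residual.

    Returns ``(sigma2 per factor, sigma2_resid, converged, loglik)`` where
    ``loglik`` is -0.5 times the minimized profiled criterion.  The
    optimization runs in log-variance-ratio space from a multi-start grid;
    ratios driven to the lower bound are reported as a zero component.
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()        # intercept absorbs the shift; conditions the
    names = list(factors)   # sufficient statistics numerically
    z_blocks = [_indicator(np.asarray(factors[k])) for k in names]
    k = len(z_blocks)
    problem = _RemlProblem(y, z_blocks)

    best = None
    results = []
    from itertools import product
    for start in product(_START_GRID, repeat=k):
        x0 = np.log(np.asarray(start))
        res = minimize(problem.neg2_reml, x0,
                       method="L-BFGS-B",
                       bounds=[_LOG_BOUNDS] * k,
                       options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8})
        results.append(res)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    # converged when the optimizer reports success at the optimum or two
    # independent starts agree on the minimum (multi-start consensus)
    n_at_best = sum(1 for r in results if r.fun <= best.fun + 1e-6)
    converged = bool(best.success or n_at_best >= 2) and best.fun < 1e29
    gammas = np.exp(best.x)
    # snap near-boundary ratios to an exact zero component
    gammas[best.x <= _LOG_BOUNDS[0] + 1e-6] = 0.0

    s2e = problem.profiled_s2e(gammas)
    sigma2 = {name: float(g * s2e) for name, g in zip(names, gammas)}
    return sigma2, float(s2e), converged, float(-0.5 * best.fun)


def fit_lmm_reml(y: np.ndarray, celltype: np.ndarray,
                 group: np.ndarray) -> VarianceDecomposition:
    """Decompose one activity vector into cell-type / group / residual."""
    y = np.asarray(y, dtype=float)
    celltype = np.asarray(celltype)
    group = np.asarray(group)
    if y.size < 20:
        raise ValueError("need at least 20 units")
    if len(np.unique(celltype)) < 2:
        raise ValueError("need at least 2 cell types")
    if len(np.unique(group)) != 2:
        raise ValueError("need exactly 2 groups")
    sigma2, s2e, converged, loglik = reml_variance_components(
        y, {"celltype": celltype, "group": group})
    p = variance_proportions((sigma2["celltype"], sigma2["group"], s2e))
    return VarianceDecomposition(
        sigma2_celltype=sigma2["celltype"], sigma2_group=sigma2["group"],
        sigma2_resid=s2e, p_celltype=p[0], p_group=p[1], p_resid=p[2],
        converged=converged, reml_loglik=loglik)


def variance_proportions(components) -> tuple[float, float, float]:
    """Normalize non-negative variance components to proportions."""
    c = np.asarray(components, dtype=float)
    if np.any(c < 0):
        raise ValueError("components must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    p = c / total
    return tuple(float(v) for v in p)


def knee_select(p_group: pd.Series, slope_threshold: float = -1.0,
                min_value: float = 0.0) -> list[str]:
    """Select the leading regulons on the sorted group-proportion curve.

    Values are sorted descending, the y-axis min-max normalized and the
    x-axis mapped to rank fractions in [0, 1].  With segment slopes
    ``s_i``, the selection keeps every point above the inflection where
    the curve flattens for good: the prefix ends one past the last
    segment steeper than ``slope_threshold``.  A curve with no steep
    segment (including the strictly linear one, all slopes exactly -1)
    selects nothing.  ``min_value`` additionally drops selected regulons
    whose raw group proportion falls below the floor (this keeps the
    selection a prefix because values are sorted).
    """
    if len(p_group) < 2:
        raise ValueError("need at least 2 regulons")
    ordered = p_group.sort_values(ascending=False, kind="mergesort")
    y = ordered.to_numpy(dtype=float)
    span = y[0] - y[-1]
    if span == 0:
        warnings.warn("flat group-proportion curve; nothing selected")
        return []
    n = len(y)
    ynorm = (y - y[-1]) / span
    dx = 1.0 / (n - 1)
    slopes = np.diff(ynorm) / dx
    # strict inequality with a float guard: an exactly linear curve has
    # every slope at the threshold and selects nothing
    steep = np.flatnonzero(slopes < slope_threshold - 1e-9)
    if steep.size == 0:
        selected = []
    else:
        selected = list(ordered.index[:int(steep[-1]) + 2])
    return [r for r in selected if ordered[r] >= min_value]


def decompose_all(ras: pd.DataFrame, modules: pd.Series,
                  celltype: np.ndarray, group: np.ndarray,
                  min_group_fraction: float = 0.05,
                  slope_threshold: float = -1.0,
                  dominant_group_fraction: float = 0.25):
    """Fit every regulon, knee-select within each module.

    The knee rule is relative to a module's curve, so it has no purchase
    on a module whose members are uniformly group-driven (no null tail to
    cut against); regulons whose group proportion reaches
    ``dominant_group_fraction`` — variance predominantly explained by the
    disease contrast on the scale where null fits sit near zero — are
    therefore selected outright.  Returns ``(table, selections,
    responsive)``: a per-regulon frame with components, proportions,
    module and selection flag; the per-module selected lists; and their
    union.  Non-converged fits are excluded from selection with a warning.
    """
    rows = {}
    for reg in ras.columns:
        fit = fit_lmm_reml(ras[reg].to_numpy(), celltype, group)
        rows[reg] = {
            "sigma2_celltype": fit.sigma2_celltype,
            "sigma2_group": fit.sigma2_group,
            "sigma2_resid": fit.sigma2_resid,
            "p_celltype": fit.p_celltype,
            "p_group": fit.p_group,
            "p_resid": fit.p_resid,
            "converged": fit.converged,
            "reml_loglik": fit.reml_loglik,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["module"] = modules.loc[table.index]
    if not table["converged"].all():
        bad = table.index[~table["converged"]].tolist()
        warnings.warn(f"{len(bad)} regulons did not converge; excluded "
                      f"from selection: {bad[:5]}")
    selections: dict[str, list[str]] = {}
    for m in sorted(table["module"].unique(), key=lambda s: (len(s), s)):
        sub = table[(table["module"] == m) & table["converged"]]
        if len(sub) <= 2:
            # the min-max-normalized knee is degenerate below 3 points
            # (its mean slope is forced to -1), so tiny modules fall back
            # to the group-fraction floor alone
            ordered = sub["p_group"].sort_values(ascending=False)
            selections[m] = list(ordered.index[ordered >= min_group_fraction])
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            knee = knee_select(sub["p_group"],
                               slope_threshold=slope_threshold,
                               min_value=min_group_fraction)
        dominant = sub["p_group"].sort_values(ascending=False)
        dominant = list(dominant.index[dominant >= dominant_group_fraction])
        # union of knee prefix and absolute-dominance set is still a
        # prefix of the sorted order
        selections[m] = (knee if len(knee) >= len(dominant) else dominant)
    responsive = [r for m in selections for r in selections[m]]
    table["selected"] = table.index.isin(responsive)
    return table, selections, responsive
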