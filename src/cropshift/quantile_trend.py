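"""Area-weighted quantile regression of growing-season temperature on year.

The fitted line (a, b) minimizes the weighted check (pinball) loss

    sum_i w_i * rho_tau(y_i - a - b * t_i),   rho_tau(u) = u * (tau - 1{u<0}),

pooled over all cell-year observations, with harvested areas (hectares) as
weights. The observed model uses dynamic (annually varying) rainfed areas;
the counterfactual model uses areas frozen at a reference window, so the
slope difference isolates the effect of area change from climate change.

Solver
------
The problem is the classic quantile-regression linear program. Because the
check loss is positively homogeneous, ``w * rho_tau(u) = rho_tau(w * u)``,
the weighted fit reduces to an unweighted fit on row-scaled data. We solve
the box-constrained dual

    max  y'd   s.t.  X'd = (1 - tau) X'1,   d in [0, 1]^n

with a Mehrotra predictor-corrector interior-point method (the
Frisch-Newton scheme used for quantile regression); with two parameters the
normal equations are 2x2, so each iteration costs O(n). The interior
solution is then *polished to a vertex*: an optimal basic solution
interpolates two observations, so we enumerate candidate lines through
pairs of near-zero-residual points, take the best, and verify a subgradient
optimality certificate. Ties among optimal vertices are broken by smallest
|slope|, then smallest intercept. For small n the enumeration is exhaustive
and the fit is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

try:  # optional JIT: the numpy path below implements the identical algorithm
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "TrendObservation",
    "QuantileFit",
    "fit_weighted_quantile",
    "period_change",
    "fit_pair",
    "pinball_objective",
]

#: Problems up to this size are solved by exhaustive pair enumeration.
_EXHAUSTIVE_N = 60
#: Candidate pool sizes for the vertex polish after the interior-point solve.
_POLISH_K = (12, 40, 160)
_MAX_IPM_ITER = 60


class TrendObservation(NamedTuple):
    """One pooled observation: a cell-year with its area weight (hectares)."""

    year: float
    temperature: float
    weight: float


@dataclass
class QuantileFit:
    """A fitted weighted quantile trend line.

    ``intercept`` is on the original (uncentered) year axis, i.e. the value
    of the line at year 0; ``slope`` is degC per year. ``objective`` is the
    weighted check loss at the solution in the original weight scale.
    """

    tau: float
    intercept: float
    slope: float
    objective: float
    n_obs: int
    weight_mode: str = "unspecified"

    def predict(self, year: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


def pinball_objective(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float, a: float, b: float
) -> float:
    """Weighted check loss of the line y = a + b t."""
    u = y - a - b * t
    return float(np.sum(w * u * (tau - (u < 0))))


def _as_arrays(
    obs: Iterable[TrendObservation] | Sequence | None,
    year: np.ndarray | None,
    temperature: np.ndarray | None,
    weight: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if obs is not None:
        arr = np.asarray([(o[0], o[1], o[2]) for o in obs], dtype=float)
        if arr.size == 0:
            raise ValueError("empty observation set")
        return arr[:, 0], arr[:, 1], arr[:, 2]
    return (
        np.asarray(year, dtype=float),
        np.asarray(temperature, dtype=float),
        np.asarray(weight, dtype=float),
    )


def _ipm_slope(t: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float) -> tuple[float, float]:
    """Frisch-Newton interior-point solve; returns an approximate (a, b).

    Operates on row-scaled data (X_i = w_i * [1, t_i], y_i' = w_i * y_i) so
    the dual box is [0, 1]^n regardless of weights.
    """
    n = t.size
    X = np.empty((n, 2))
    X[:, 0] = w
    X[:, 1] = w * t
    ys = w * y

    beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
    r = ys - X @ beta
    scale = max(np.abs(r).max(), 1e-8)
    if np.abs(r).max() < 1e-12 * max(1.0, np.abs(ys).max()):
        return float(beta[0]), float(beta[1])

    if _HAVE_NUMBA:
        b0, b1 = _ipm_core_compiled(
            np.ascontiguousarray(X[:, 0]),
            np.ascontiguousarray(X[:, 1]),
            ys,
            float(tau),
            float(scale),
            float(beta[0]),
            float(beta[1]),
            _MAX_IPM_ITER,
        )
        return float(b0), float(b1)

    # dual variables: a in (0,1)^n with slack s = 1 - a; z is the multiplier
    # complementary to s (active when the point lies above the line), om the
    # multiplier complementary to a (point below the line); z - om equals the
    # scaled residual at optimality.
    delta = 0.1 * scale
    a_ = np.full(n, 1.0 - tau)
    s_ = np.full(n, tau)
    z = np.maximum(r, 0.0) + delta
    om = z - r  # = max(-r,0) + delta > 0
    rhs = (1.0 - tau) * X.sum(axis=0)

    def _steplen(v: np.ndarray, dv: np.ndarray) -> float:
        neg = dv < 0
        if not neg.any():
            return 1.0
        return min(1.0, float(np.min(-v[neg] / dv[neg])))

    for _ in range(_MAX_IPM_ITER):
        gap = s_ @ z + a_ @ om
        if gap < 1e-13 * n * scale:
            break
        r_d = ys - X @ beta - z + om
        r_p = rhs - X.T @ a_
        zs = z / s_
        oa = om / a_
        qinv = 1.0 / (zs + oa)
        M = X.T @ (qinv[:, None] * X)

        # affine-scaling predictor (mu = 0)
        rho = r_d + z - om
        try:
            dbeta = np.linalg.solve(M, X.T @ (qinv * rho) - r_p)
        except np.linalg.LinAlgError:
            break
        da = qinv * (rho - X @ dbeta)
        dz = -z + zs * da
        dom = -om - oa * da

        ap = min(_steplen(a_, da), _steplen(s_, -da))
        ad = min(_steplen(z, dz), _steplen(om, dom))
        gap_aff = (s_ - ap * da) @ (z + ad * dz) + (a_ + ap * da) @ (om + ad * dom)
        sigma = (max(gap_aff, 0.0) / gap) ** 3
        mu = sigma * gap / (2 * n)

        # corrector with second-order complementarity terms
        c4 = mu + da * dz  # target adjustment for s.z complementarity
        c5 = mu - da * dom  # for a.om complementarity
        rho = r_d - c4 / s_ + z + c5 / a_ - om
        try:
            dbeta = np.linalg.solve(M, X.T @ (qinv * rho) - r_p)
        except np.linalg.LinAlgError:
            break
        da = qinv * (rho - X @ dbeta)
        dz = c4 / s_ - z + zs * da
        dom = c5 / a_ - om - oa * da

        eta = 0.9995
        ap = eta * min(_steplen(a_, da), _steplen(s_, -da))
        ad = eta * min(_steplen(z, dz), _steplen(om, dom))
        a_ += ap * da
        s_ -= ap * da
        beta += ad * dbeta
        z += ad * dz
        om += ad * dom
        np.clip(a_, 1e-14, None, out=a_)
        np.clip(s_, 1e-14, None, out=s_)
        np.clip(z, 1e-14 * scale, None, out=z)
        np.clip(om, 1e-14 * scale, None, out=om)
    return float(beta[0]), float(beta[1])


def _ipm_core_compiled(X0, X1, ys, tau, scale, beta0, beta1, max_iter):
    """Loop-fused twin of :func:`_ipm_slope`'s iteration, for JIT compilation."""
    n = ys.size
    delta = 0.1 * scale
    a_ = np.full(n, 1.0 - tau)
    s_ = np.full(n, tau)
    z = np.empty(n)
    om = np.empty(n)
    for i in range(n):
        r = ys[i] - X0[i] * beta0 - X1[i] * beta1
        z[i] = (r if r > 0.0 else 0.0) + delta
        om[i] = z[i] - r
    rhs0 = 0.0
    rhs1 = 0.0
    for i in range(n):
        rhs0 += X0[i]
        rhs1 += X1[i]
    rhs0 *= 1.0 - tau
    rhs1 *= 1.0 - tau

    qinv = np.empty(n)
    rd = np.empty(n)
    da = np.empty(n)
    dz = np.empty(n)
    dom = np.empty(n)

    for _ in range(max_iter):
        gap = 0.0
        for i in range(n):
            gap += s_[i] * z[i] + a_[i] * om[i]
        if gap < 1e-13 * n * scale:
            break
        # pass 1: residuals, scaling, normal equations for the predictor
        m00 = 0.0
        m01 = 0.0
        m11 = 0.0
        g0 = 0.0
        g1 = 0.0
        rp0 = rhs0
        rp1 = rhs1
        for i in range(n):
            rd[i] = ys[i] - X0[i] * beta0 - X1[i] * beta1 - z[i] + om[i]
            q = 1.0 / (z[i] / s_[i] + om[i] / a_[i])
            qinv[i] = q
            m00 += q * X0[i] * X0[i]
            m01 += q * X0[i] * X1[i]
            m11 += q * X1[i] * X1[i]
            rho = rd[i] + z[i] - om[i]
            g0 += q * X0[i] * rho
            g1 += q * X1[i] * rho
            rp0 -= X0[i] * a_[i]
            rp1 -= X1[i] * a_[i]
        det = m00 * m11 - m01 * m01
        if det == 0.0:
            break
        db0 = (m11 * (g0 - rp0) - m01 * (g1 - rp1)) / det
        db1 = (m00 * (g1 - rp1) - m01 * (g0 - rp0)) / det
        # pass 2: predictor directions and step lengths
        ap = 1.0
        ad = 1.0
        for i in range(n):
            rho = rd[i] + z[i] - om[i]
            dai = qinv[i] * (rho - X0[i] * db0 - X1[i] * db1)
            da[i] = dai
            dz[i] = -z[i] + z[i] / s_[i] * dai
            dom[i] = -om[i] - om[i] / a_[i] * dai
            if dai < 0.0 and -a_[i] / dai < ap:
                ap = -a_[i] / dai
            if dai > 0.0 and s_[i] / dai < ap:
                ap = s_[i] / dai
            if dz[i] < 0.0 and -z[i] / dz[i] < ad:
                ad = -z[i] / dz[i]
            if dom[i] < 0.0 and -om[i] / dom[i] < ad:
                ad = -om[i] / dom[i]
        gap_aff = 0.0
        for i in range(n):
            gap_aff += (s_[i] - ap * da[i]) * (z[i] + ad * dz[i])
            gap_aff += (a_[i] + ap * da[i]) * (om[i] + ad * dom[i])
        if gap_aff < 0.0:
            gap_aff = 0.0
        sigma = (gap_aff / gap) ** 3
        mu = sigma * gap / (2.0 * n)
        # pass 3: corrector normal equations
        g0 = 0.0
        g1 = 0.0
        for i in range(n):
            c4 = mu + da[i] * dz[i]
            c5 = mu - da[i] * dom[i]
            rho = rd[i] - c4 / s_[i] + z[i] + c5 / a_[i] - om[i]
            g0 += qinv[i] * X0[i] * rho
            g1 += qinv[i] * X1[i] * rho
        db0c = (m11 * (g0 - rp0) - m01 * (g1 - rp1)) / det
        db1c = (m00 * (g1 - rp1) - m01 * (g0 - rp0)) / det
        # pass 4: corrector directions and steps
        ap = 1.0
        ad = 1.0
        for i in range(n):
            c4 = mu + da[i] * dz[i]
            c5 = mu - da[i] * dom[i]
            rho = rd[i] - c4 / s_[i] + z[i] + c5 / a_[i] - om[i]
            dai = qinv[i] * (rho - X0[i] * db0c - X1[i] * db1c)
            dzi = c4 / s_[i] - z[i] + z[i] / s_[i] * dai
            domi = c5 / a_[i] - om[i] - om[i] / a_[i] * dai
            da[i] = dai
            dz[i] = dzi
            dom[i] = domi
            if dai < 0.0 and -a_[i] / dai < ap:
                ap = -a_[i] / dai
            if dai > 0.0 and s_[i] / dai < ap:
                ap = s_[i] / dai
            if dzi < 0.0 and -z[i] / dzi < ad:
                ad = -z[i] / dzi
            if domi < 0.0 and -om[i] / domi < ad:
                ad = -om[i] / domi
        ap *= 0.9995
        ad *= 0.9995
        beta0 += ad * db0c
        beta1 += ad * db1c
        zfloor = 1e-14 * scale
        for i in range(n):
            a_[i] += ap * da[i]
            if a_[i] < 1e-14:
                a_[i] = 1e-14
            s_[i] -= ap * da[i]
            if s_[i] < 1e-14:
                s_[i] = 1e-14
            z[i] += ad * dz[i]
            if z[i] < zfloor:
                z[i] = zfloor
            om[i] += ad * dom[i]
            if om[i] < zfloor:
                om[i] = zfloor
    return beta0, beta1


def _pinball_pairs_compiled(t, y, w, tau, slopes, intercepts):
    """Objective of every candidate line over all observations."""
    out = np.empty(slopes.size)
    for k in range(slopes.size):
        a = intercepts[k]
        b = slopes[k]
        acc = 0.0
        for i in range(t.size):
            u = y[i] - a - b * t[i]
            acc += w[i] * u * (tau if u >= 0.0 else tau - 1.0)
        out[k] = acc
    return out


if _HAVE_NUMBA:
    _ipm_core_compiled = _njit(cache=True, fastmath=False)(_ipm_core_compiled)
    _pinball_pairs_compiled = _njit(cache=True, fastmath=False)(_pinball_pairs_compiled)


def _linprog_slope(t: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact LP solve of the check-loss problem (slow; last-resort fallback)."""
    from scipy import sparse
    from scipy.optimize import linprog

    n = t.size
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], tau * w, (1.0 - tau) * w])
    A = sparse.hstack(
        [
            sparse.csc_matrix(np.column_stack([np.ones(n), -np.ones(n), t, -t])),
            sparse.identity(n, format="csc"),
            -sparse.identity(n, format="csc"),
        ]
    )
    res = linprog(c, A_eq=A, b_eq=y, method="highs")
    if res.status != 0:  # pragma: no cover
        raise RuntimeError(f"quantile LP failed: {res.message}")
    x = res.x
    return float(x[0] - x[1]), float(x[2] - x[3])


def _pair_lines(
    t: np.ndarray, y: np.ndarray, cand: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Slopes/intercepts of all lines through candidate point pairs with t_i != t_j."""
    ti, yi = t[cand], y[cand]
    ii, jj = np.triu_indices(cand.size, k=1)
    dt = ti[ii] - ti[jj]
    ok = dt != 0
    ii, jj, dt = ii[ok], jj[ok], dt[ok]
    slopes = (yi[ii] - yi[jj]) / dt
    intercepts = yi[ii] - slopes * ti[ii]
    return slopes, intercepts


def _best_pair_line(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tau: float,
    cand: np.ndarray,
    chunk: int = 256,
) -> tuple[float, float, float]:
    """Minimum-objective line through candidate pairs, with deterministic tie-breaks."""
    t = np.ascontiguousarray(t, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    w = np.ascontiguousarray(w, dtype=float)
    slopes, intercepts = _pair_lines(t, y, cand)
    if slopes.size == 0:
        raise ValueError("trend undefined: candidate points share a single year")
    best = (np.inf, np.inf, np.inf)  # (objective, |slope|, intercept) lexicographic
    best_line = (0.0, 0.0)
    tol = None
    for start in range(0, slopes.size, chunk):
        b = np.ascontiguousarray(slopes[start : start + chunk])
        a = np.ascontiguousarray(intercepts[start : start + chunk])
        if _HAVE_NUMBA:
            obj = _pinball_pairs_compiled(t, y, w, tau, b, a)
        else:
            u = y[None, :] - a[:, None] - b[:, None] * t[None, :]
            obj = np.sum(w[None, :] * u * (tau - (u < 0)), axis=1)
        if tol is None:
            # ties only at true degeneracy: vertex-to-vertex objective gaps in
            # large noisy samples reach ~1e-8 and must not be merged
            tol = 1e-12 * max(1.0, float(np.abs(obj).max()))
        for k in np.argsort(obj)[: min(8, obj.size)]:
            key = (float(obj[k]), abs(float(b[k])), float(a[k]))
            if key[0] < best[0] - tol or (
                abs(key[0] - best[0]) <= tol and (key[1], key[2]) < (best[1], best[2])
            ):
                best = (min(key[0], best[0]), key[1], key[2])
                best_line = (float(a[k]), float(b[k]))
    return best_line[0], best_line[1], pinball_objective(t, y, w, tau, *best_line)


def _subgradient_certificate(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float, a: float, b: float
) -> bool:
    """Exact optimality check: 0 must lie in the subgradient of the check loss.

    Observations off the line contribute fixed gradient mass; observations on
    the line contribute anywhere in [-(1-tau) w_i, tau w_i]. Optimality holds
    iff the fixed mass can be cancelled by a feasible assignment to the
    on-line points (a tiny box-constrained feasibility problem in <=2 dims).
    """
    u = y - a - b * t
    scale = max(1.0, float(np.abs(y).max()))
    on = np.abs(u) <= 1e-8 * scale
    g0 = float(np.sum(w[~on] * (tau - (u[~on] < 0))))
    g1 = float(np.sum(w[~on] * t[~on] * (tau - (u[~on] < 0))))
    lo = -(1.0 - tau) * w[on]
    hi = tau * w[on]
    tt = t[on]
    # need c in [lo, hi]^m with sum c = -g0 and sum c t = -g1
    m = tt.size
    tolg = 1e-7 * max(1.0, float(np.sum(w)))
    if m == 0:
        return abs(g0) <= tolg and abs(g1) <= tolg * max(1.0, np.abs(t).max())
    if m <= 2 or np.unique(tt).size <= 2:
        # direct solve on the (at most) two distinct year values
        vals = np.unique(tt)
        if vals.size == 1:
            c_tot_lo, c_tot_hi = lo.sum(), hi.sum()
            ok1 = c_tot_lo - tolg <= -g0 <= c_tot_hi + tolg
            ok2 = abs(-g1 - (-g0) * vals[0]) <= tolg * max(1.0, abs(vals[0]))
            return bool(ok1 and ok2)
        t1, t2 = vals
        A = np.array([[1.0, 1.0], [t1, t2]])
        sums = np.linalg.solve(A, np.array([-g0, -g1]))
        lo1, hi1 = lo[tt == t1].sum(), hi[tt == t1].sum()
        lo2, hi2 = lo[tt == t2].sum(), hi[tt == t2].sum()
        return bool(
            lo1 - tolg <= sums[0] <= hi1 + tolg and lo2 - tolg <= sums[1] <= hi2 + tolg
        )
    # degenerate pileup on the line: fall back to a tiny feasibility LP
    from scipy.optimize import linprog

    res = linprog(
        np.zeros(m),
        A_eq=np.vstack([np.ones(m), tt]),
        b_eq=np.array([-g0, -g1]),
        bounds=np.column_stack([lo - tolg, hi + tolg]),
        method="highs",
    )
    return bool(res.status == 0)


def fit_weighted_quantile(
    obs: Iterable[TrendObservation] | None = None,
    tau: float = 0.95,
    *,
    year: np.ndarray | None = None,
    temperature: np.ndarray | None = None,
    weight: np.ndarray | None = None,
    weight_mode: str = "unspecified",
) -> QuantileFit:
    """Fit the weighted tau-quantile trend line of temperature on year.

    Accepts either an iterable of :class:`TrendObservation` (or (year,
    temperature, weight) triples) or the three arrays as keywords.
    Zero-weight observations are dropped; at least two distinct years with
    positive weight are required. Years are centered at their weighted mean
    before solving; the returned intercept is on the original year axis.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    t, y, w = _as_arrays(obs, year, temperature, weight)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = (w > 0) & np.isfinite(y) & np.isfinite(t)
    t, y, w = t[keep], y[keep], w[keep]
    if t.size == 0:
        raise ValueError("all weights zero")
    if np.unique(t).size < 2:
        raise ValueError("trend undefined: single distinct year")

    wsum = float(w.sum())
    wn = w / wsum
    t0 = float(np.sum(wn * t))
    tc = t - t0

    if t.size <= _EXHAUSTIVE_N:
        a, b, obj = _best_pair_line(tc, y, wn, tau, np.arange(t.size))
        if not _subgradient_certificate(tc, y, wn, tau, a, b):  # pragma: no cover
            raise RuntimeError("exhaustive vertex search failed the optimality certificate")
    else:
        a_ip, b_ip = _ipm_slope(tc, y, wn, tau)
        resid = np.abs(y - a_ip - b_ip * tc)
        a = b = obj = None
        for k in _POLISH_K:
            cand = np.argpartition(resid, min(k, resid.size - 1))[: min(k, resid.size)]
            a, b, obj = _best_pair_line(tc, y, wn, tau, cand)
            if _subgradient_certificate(tc, y, wn, tau, a, b):
                break
        else:
            # rare: interior point landed far from the optimal support; resolve
            # with an exact LP and polish around that solution instead
            a_lp, b_lp = _linprog_slope(tc, y, wn, tau)
            resid = np.abs(y - a_lp - b_lp * tc)
            cand = np.argpartition(resid, min(40, resid.size - 1))[: min(40, resid.size)]
            a2, b2, obj2 = _best_pair_line(tc, y, wn, tau, cand)
            if obj2 <= obj:
                a, b, obj = a2, b2, obj2

    return QuantileFit(
        tau=tau,
        intercept=float(a - b * t0),
        slope=float(b),
        objective=float(obj * wsum),
        n_obs=int(t.size),
        weight_mode=weight_mode,
    )


def period_change(fit: QuantileFit, year_start: int = 1973, year_end: int = 2012) -> float:
    """Temperature change implied by the fitted slope over [year_start, year_end]."""
    if year_end <= year_start:
        raise ValueError("year_end must exceed year_start")
    return fit.slope * (year_end - year_start)


def _panel_observations(panel, weights, years: np.ndarray):
    temp = panel.data.sel(year=years)
    wda = weights.for_years(years)
    t = np.broadcast_to(
        years[:, None], (years.size, temp.sizes["lat"] * temp.sizes["lon"])
    ).ravel()
    yv = temp.values.reshape(years.size, -1).ravel()
    wv = wda.transpose("year", "lat", "lon").values.reshape(years.size, -1).ravel()
    return t.astype(float), yv, np.nan_to_num(wv, nan=0.0)


def fit_pair(panel, dynamic, static, tau: float) -> tuple[QuantileFit, QuantileFit]:
    """Observed (dynamic-weight) and counterfactual (static-weight) fits.

    Both models see the same pooled cell-year temperatures; only the weights
    differ. Masked temperatures and zero-weight observations are dropped per
    model independently.
    """
    years = panel.years
    t, y, wd = _panel_observations(panel, dynamic, years)
    _, _, ws = _panel_observations(panel, static, years)
    observed = fit_weighted_quantile(
        year=t, temperature=y, weight=wd, tau=tau, weight_mode="dynamic"
    )
    counterfactual = fit_weighted_quantile(
        year=t, temperature=y, weight=ws, tau=tau, weight_mode="static"
    )
    return observed, counterfactual
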