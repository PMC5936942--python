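"""Continuous piecewise-linear (segmented) regression with AIC breakpoint selection.

The model is y = b0 + b1 x + sum_h d_h (x - psi_h)_+ + e: a line whose slope
changes by d_h at each breakpoint psi_h, continuous everywhere.  Breakpoints
are estimated by iterative linearization: at a working value of psi the model
gains an indicator regressor whose coefficient, divided by the slope change,
is the first-order correction to psi; iterating to a fixed point gives the
least-squares breakpoint.  Initialization and fallback use a coarse grid of
interior candidates.  The number of breakpoints is chosen by AIC after
sequential forward addition.  Per-segment slopes are cumulative sums of the
difference coefficients, with delta-method 95% confidence intervals used to
classify each segment as increasing, decreasing or no-change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SegmentedModel",
    "SegmentedFit",
    "fit_segmented",
    "select_k_by_aic",
    "classify_segments",
    "compare_decline_recovery",
]

_GRID_SIZE = 20  # interior breakpoint candidates for initialization
_MAX_ITER = 50
_TOL = 1e-6  # convergence tolerance on breakpoints, relative to the x range
#: extra degrees of freedom charged per breakpoint beyond its slope-change
#: coefficient: an adaptively estimated knot is a non-regular parameter, and
#: charging ~3 df (the knot-cost convention of adaptive regression splines)
#: keeps AIC selection of the breakpoint count close to nominal.
KNOT_DF = 3.0


def _design(x: np.ndarray, psi: np.ndarray, with_indicator: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.maximum(x - p, 0.0))
    if with_indicator:
        for p in psi:
            cols.append(-(x > p).astype(float))
    return np.column_stack(cols)


def _rss_at(x, y, psi):
    X = _design(x, np.sort(psi), with_indicator=False)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class SegmentedFit:
    """Results of a segmented fit: breakpoints, per-segment slopes and their CIs.

    Slope confidence intervals are 95% t-intervals from the asymptotic
    covariance of the linearized fit; ``classification`` labels each segment
    ``increase`` (CI entirely above 0), ``decrease`` (entirely below) or
    ``no_change``.  ``converged`` is False when the iterative refinement
    failed and the best grid solution is reported instead.
    """

    breakpoints: np.ndarray
    breakpoint_se: np.ndarray
    intercept: float
    slopes: np.ndarray
    slope_se: np.ndarray
    slope_ci: np.ndarray  # (k+1, 2)
    rss: float
    aic: float
    n: int
    converged: bool
    x: np.ndarray
    y: np.ndarray
    response: str = "y"

    @property
    def k(self) -> int:
        return len(self.breakpoints)

    @property
    def n_segments(self) -> int:
        return self.k + 1

    @property
    def classification(self) -> list[str]:
        return classify_segments(self)

    def segment_bounds(self) -> list[tuple[float, float]]:
        edges = [float(self.x.min()), *self.breakpoints.tolist(), float(self.x.max())]
        return list(zip(edges[:-1], edges[1:]))

    @property
    def fittedvalues(self) -> np.ndarray:
        X = _design(self.x, self.breakpoints, with_indicator=False)
        beta = np.concatenate([[self.intercept, self.slopes[0]],
                               np.diff(self.slopes)])
        return X @ beta

    def predict(self, xnew) -> np.ndarray:
        xnew = np.asarray(xnew, dtype=float)
        X = _design(xnew, self.breakpoints, with_indicator=False)
        beta = np.concatenate([[self.intercept, self.slopes[0]], np.diff(self.slopes)])
        return X @ beta

    def summary(self) -> str:
        lines = [
            f"Segmented regression: {self.response}",
            "=" * (22 + len(self.response)),
            f"n = {self.n}, breakpoints = {self.k}, AIC = {self.aic:.2f}, "
            f"RSS = {self.rss:.4g}, converged = {self.converged}",
        ]
        if self.k:
            bp = ", ".join(f"{b:.3f} (se {s:.3f})"
                           for b, s in zip(self.breakpoints, self.breakpoint_se))
            lines.append(f"breakpoints at x = {bp}")
        lines.append(f"{'segment':>8s} {'from':>10s} {'to':>10s} {'slope':>10s} "
                     f"{'95% lo':>10s} {'95% hi':>10s}  class")
        for i, ((a, b), lab) in enumerate(zip(self.segment_bounds(), self.classification)):
            lines.append(
                f"{i + 1:>8d} {a:>10.3f} {b:>10.3f} {self.slopes[i]:>10.4f} "
                f"{self.slope_ci[i, 0]:>10.4f} {self.slope_ci[i, 1]:>10.4f}  {lab}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "response": self.response,
            "n": int(self.n),
            "k": int(self.k),
            "breakpoints": self.breakpoints.tolist(),
            "breakpoint_se": self.breakpoint_se.tolist(),
            "intercept": float(self.intercept),
            "slopes": self.slopes.tolist(),
            "slope_ci": self.slope_ci.tolist(),
            "classification": self.classification,
            "rss": float(self.rss),
            "aic": float(self.aic),
            "converged": bool(self.converged),
        }


class SegmentedModel:
    """Continuous piecewise-linear model of y on sorted x.

    ``fit(k)`` estimates *k* breakpoints (grid-initialized iterative
    linearization); ``fit_auto(k_max)`` picks the breakpoint count by AIC
    after sequential forward addition.
    """

    def __init__(self, x, y, response: str = "y"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if np.any(np.diff(x) < 0):
            order = np.argsort(x, kind="stable")
            x, y = x[order], y[order]
        self.x, self.y = x, y
        self.response = response

    # -- internals -----------------------------------------------------
    def _aic(self, rss: float, k: int) -> float:
        n = len(self.x)
        return n * np.log(max(rss, 1e-300) / n) + 2.0 * (2 + (1.0 + KNOT_DF) * k)

    def _fit_k0(self) -> SegmentedFit:
        x, y = self.x, self.y
        X = _design(x, np.empty(0), with_indicator=False)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        n = len(x)
        dof = max(n - 2, 1)
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[1, 1])
        tq = stats.t.ppf(0.975, dof)
        return SegmentedFit(
            breakpoints=np.empty(0), breakpoint_se=np.empty(0),
            intercept=float(beta[0]), slopes=np.array([beta[1]]),
            slope_se=np.array([se]),
            slope_ci=np.array([[beta[1] - tq * se, beta[1] + tq * se]]),
            rss=rss, aic=self._aic(rss, 0), n=n, converged=True,
            x=x, y=y, response=self.response,
        )

    def _min_separation(self) -> float:
        xs = np.unique(self.x)
        if len(xs) < 2:
            return 0.0
        return 3.0 * float(np.median(np.diff(xs)))

    def _refine(self, psi0: np.ndarray):
        """Muggeo iterations from psi0; returns (psi, rss, converged)."""
        x, y = self.x, self.y
        rng_x = np.ptp(x)
        # keep breakpoints away from the edges: >= 3 points on each side
        xs = np.unique(x)
        lo = xs[min(2, len(xs) - 1)]
        hi = xs[max(len(xs) - 3, 0)]
        if hi <= lo:
            lo, hi = xs[0] + 1e-9 * rng_x, xs[-1] - 1e-9 * rng_x
        min_sep = self._min_separation()
        psi = np.sort(np.clip(np.asarray(psi0, dtype=float), lo, hi))
        best_psi, best_rss = psi.copy(), _rss_at(x, y, psi)
        converged = False
        for _ in range(_MAX_ITER):
            X = _design(x, psi, with_indicator=True)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            k = len(psi)
            delta = beta[2:2 + k]
            gamma = beta[2 + k:2 + 2 * k]
            if np.any(np.abs(delta) < 1e-12 * (np.std(y) / max(rng_x, 1e-300) + 1e-300)):
                break
            step = gamma / delta
            new = np.sort(np.clip(psi + step, lo, hi))
            if len(new) > 1 and np.min(np.diff(new)) < min_sep:
                break  # breakpoints collided
            rss = _rss_at(x, y, new)
            if rss < best_rss:
                best_rss, best_psi = rss, new.copy()
            if np.max(np.abs(new - psi)) < _TOL * rng_x:
                psi = new
                converged = True
                break
            psi = new
        return best_psi if not converged else psi, _rss_at(x, y, best_psi if not converged else psi), converged

    def _package(self, psi: np.ndarray, converged: bool) -> SegmentedFit:
        x, y = self.x, self.y
        n = len(x)
        k = len(psi)
        psi = np.sort(psi)
        Xv = _design(x, psi, with_indicator=True)
        beta_v, *_ = np.linalg.lstsq(Xv, y, rcond=None)
        X = _design(x, psi, with_indicator=False)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        dof = max(n - (2 + 2 * k), 1)
        sigma2 = rss / dof
        # the indicator-augmented design propagates breakpoint uncertainty
        # into the slope covariance (first-order, as in the iterative scheme)
        cov_v = sigma2 * np.linalg.pinv(Xv.T @ Xv)
        delta = beta_v[2:2 + k]
        se_psi = np.sqrt(np.abs(np.diag(cov_v)[2 + k:2 + 2 * k])) / np.maximum(
            np.abs(delta), 1e-300)
        # slope_j = beta1 + sum_{h<=j} delta_h  -> linear combination c_j
        slopes = np.empty(k + 1)
        slope_se = np.empty(k + 1)
        for j in range(k + 1):
            c = np.zeros(2 + 2 * k)
            c[1] = 1.0
            c[2:2 + j] = 1.0
            slopes[j] = float(c[:2 + k] @ beta)
            slope_se[j] = float(np.sqrt(max(c @ cov_v @ c, 0.0)))
        tq = stats.t.ppf(0.975, dof)
        ci = np.column_stack([slopes - tq * slope_se, slopes + tq * slope_se])
        return SegmentedFit(
            breakpoints=psi, breakpoint_se=se_psi,
            intercept=float(beta[0]), slopes=slopes, slope_se=slope_se,
            slope_ci=ci, rss=rss, aic=self._aic(rss, k), n=n,
            converged=converged, x=x, y=y, response=self.response,
        )

    def _grid_candidates(self) -> np.ndarray:
        x = self.x
        return np.linspace(x.min(), x.max(), _GRID_SIZE + 2)[1:-1]

    def _add_one_breakpoint(self, psi_prev: np.ndarray):
        """Best grid candidate added to an existing breakpoint set (RSS search)."""
        cands = self._grid_candidates()
        min_sep = self._min_separation()
        best = None
        for c in cands:
            if len(psi_prev) and np.min(np.abs(psi_prev - c)) < min_sep:
                continue
            rss = _rss_at(self.x, self.y, np.append(psi_prev, c))
            if best is None or rss < best[0]:
                best = (rss, c)
        if best is None:
            raise RuntimeError("no feasible breakpoint candidate")
        return np.sort(np.append(psi_prev, best[1]))

    # -- public API ----------------------------------------------------
    def fit(self, k_breakpoints: int, init=None) -> SegmentedFit:
        """Fit with exactly *k_breakpoints* breakpoints.

        *init* gives starting breakpoints; by default they are built by
        sequential greedy grid search.  Requires n >= 2k + 4.
        """
        n = len(self.x)
        k = int(k_breakpoints)
        if k < 0:
            raise ValueError("k_breakpoints must be >= 0")
        if n < 2 * k + 4:
            raise ValueError(f"too few points (n={n}) for k={k} breakpoints")
        if len(np.unique(self.x)) < k + 2:
            raise ValueError("not enough distinct x values")
        if k == 0:
            return self._fit_k0()
        if init is not None:
            psi0 = np.sort(np.asarray(init, dtype=float))
            if len(psi0) != k:
                raise ValueError("init must supply one value per breakpoint")
        else:
            psi0 = np.empty(0)
            while len(psi0) < k:
                psi0 = self._add_one_breakpoint(psi0)
        psi, _, converged = self._refine(psi0)
        return self._package(psi, converged)

    def fit_auto(self, k_max: int = 6):
        """Choose the breakpoint count by AIC with sequential forward addition.

        Each size is initialized from the previous solution plus one
        grid-searched breakpoint.  Returns ``(best_fit, fits, aic_trace)``
        where *aic_trace* has k_max + 1 entries (NaN for failed sizes).
        """
        if k_max < 0:
            raise ValueError("k_max must be >= 0")
        fits: dict[int, SegmentedFit] = {}
        trace = np.full(k_max + 1, np.nan)
        psi_prev = np.empty(0)
        for k in range(k_max + 1):
            try:
                if k == 0:
                    f = self._fit_k0()
                else:
                    psi0 = self._add_one_breakpoint(psi_prev)
                    psi, _, conv = self._refine(psi0)
                    f = self._package(psi, conv)
                fits[k] = f
                trace[k] = f.aic
                psi_prev = f.breakpoints
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                break
        if not fits:
            raise RuntimeError("no segmented fit succeeded")
        best_k = min(fits, key=lambda k: fits[k].aic)
        return fits[best_k], fits, trace


def fit_segmented(x, y, k_breakpoints: int, init=None, response: str = "y") -> SegmentedFit:
    """Functional wrapper around :meth:`SegmentedModel.fit`."""
    return SegmentedModel(x, y, response=response).fit(k_breakpoints, init=init)


def select_k_by_aic(x, y, k_max: int = 6, response: str = "y"):
    """Functional wrapper around :meth:`SegmentedModel.fit_auto`."""
    return SegmentedModel(x, y, response=response).fit_auto(k_max)


def classify_segments(fit: SegmentedFit) -> list[str]:
    """Label each segment by its slope CI: increase, decrease or no_change."""
    labels = []
    for lo, hi in fit.slope_ci:
        if lo > 0:
            labels.append("increase")
        elif hi < 0:
            labels.append("decrease")
        else:
            labels.append("no_change")
    return labels


def compare_decline_recovery(fit: SegmentedFit, event_time: float) -> dict:
    """Hysteresis report around *event_time* (same units as x).

    Decline = decreasing segments whose midpoint precedes the event; recovery
    = increasing segments whose midpoint follows it.  Reports the steepest
    decline magnitude, the steepest recovery slope, their ratio
    (|decline|/recovery; > 1 means recovery is slower), the segment ranges and
    the total span of declining and recovering segments.
    """
    labels = fit.classification
    declines, recoveries = [], []
    decline_span = recovery_span = 0.0
    principal_decline = principal_recovery = None  # (|total change|, span)
    for (a, b), lab, s in zip(fit.segment_bounds(), labels, fit.slopes):
        mid = 0.5 * (a + b)
        drop = abs(s) * (b - a)
        if lab == "decrease":
            decline_span += b - a
            if principal_decline is None or drop > principal_decline[0]:
                principal_decline = (drop, b - a)
            if mid < event_time:
                declines.append((abs(s), (a, b)))
        elif lab == "increase":
            recovery_span += b - a
            if principal_recovery is None or drop > principal_recovery[0]:
                principal_recovery = (drop, b - a)
            if mid >= event_time:
                recoveries.append((s, (a, b)))
    out = {
        "max_decline_rate": max(declines)[0] if declines else np.nan,
        "decline_range": max(declines)[1] if declines else None,
        "max_recovery_rate": max(recoveries)[0] if recoveries else np.nan,
        "recovery_range": max(recoveries)[1] if recoveries else None,
        "decline_span": decline_span,
        "recovery_span": recovery_span,
        "principal_decline_span": principal_decline[1] if principal_decline else np.nan,
        "principal_recovery_span": principal_recovery[1] if principal_recovery else np.nan,
    }
    if declines and recoveries and out["max_recovery_rate"] > 0:
        out["hysteresis_ratio"] = out["max_decline_rate"] / out["max_recovery_rate"]
    else:
        out["hysteresis_ratio"] = np.nan
    return out
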