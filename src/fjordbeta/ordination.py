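"""Redundancy analysis (RDA), predictor selection and variance partitioning.

RDA is the constrained ordination used throughout: a multivariate least-squares
regression of the (centred, typically Hellinger-transformed) community matrix
on a predictor set, followed by a PCA of the fitted values.  Explanatory power
is the Ezekiel-adjusted R².  Around it sit the standard model-building steps
for ecological predictor tables: removal of significant linear time trends
from the responses, collinearity screening to VIF <= 10, greedy forward
selection under a multivariate AIC, and the three-set variance partitioning
(environment / positive temporal correlation / negative temporal correlation)
that decomposes adjusted R² into the seven Venn regions by inclusion-exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

__all__ = [
    "RDA",
    "RDAResults",
    "detrend_linear",
    "adjusted_r2",
    "vif_screen",
    "stepwise_select",
    "SelectionResult",
    "variance_partition",
    "VariancePartition",
    "time_polynomial_rda",
]


def _as_frame(a, prefix: str) -> pd.DataFrame:
    if isinstance(a, pd.DataFrame):
        return a.astype(float)
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return pd.DataFrame(a, columns=[f"{prefix}{i + 1}" for i in range(a.shape[1])])


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjusted R²: 1 - (1 - R²)(n - 1)/(n - m - 1); NaN when n <= m + 1."""
    if n - m - 1 <= 0:
        warnings.warn(f"adjusted R2 undefined for n={n}, m={m}", stacklevel=2)
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


class RDA:
    """Redundancy analysis model: multivariate regression of Y on X plus a PCA of fits.

    Both matrices are column-centred internally (the intercept).  ``fit()``
    returns an :class:`RDAResults`.  A rank-deficient predictor matrix is
    rejected with the names of the redundant columns.

    Parameters
    ----------
    endog : (n, p) response matrix (community data, already transformed).
    exog : (n, m) predictor matrix.
    """

    def __init__(self, endog, exog):
        self.endog = _as_frame(endog, "y")
        self.exog = _as_frame(exog, "x")
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog must have the same number of rows")
        if len(self.endog) <= self.exog.shape[1]:
            raise ValueError("need more rows than predictors for a full-rank RDA")

    def fit(self) -> "RDAResults":
        y = self.endog.to_numpy()
        x = self.exog.to_numpy()
        n = y.shape[0]
        yc = y - y.mean(axis=0, keepdims=True)
        xc = x - x.mean(axis=0, keepdims=True)
        m = xc.shape[1]
        if m:
            _, r, piv = qr(xc, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            rank = int((diag > max(n, m) * np.finfo(float).eps * (diag[0] if diag.size else 1)).sum())
            if rank < m:
                bad = [self.exog.columns[j] for j in piv[rank:]]
                raise ValueError(f"predictor matrix is rank deficient; collinear columns: {bad}")
            beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
            fitted = xc @ beta
        else:
            beta = np.zeros((0, yc.shape[1]))
            fitted = np.zeros_like(yc)
        ss_total = float((yc * yc).sum())
        ss_fit = float((fitted * fitted).sum())
        r2 = ss_fit / ss_total if ss_total > 0 else np.nan
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        nax = int((s > (s[0] if s.size else 0) * 1e-12).sum())
        axes = [f"RDA{i + 1}" for i in range(nax)]
        site = pd.DataFrame(u[:, :nax] * s[:nax], index=self.endog.index, columns=axes)
        species = pd.DataFrame(vt[:nax].T, index=self.endog.columns, columns=axes)
        # weighted-averaging scores: sites placed by their observed composition
        site_wa = pd.DataFrame(yc @ vt[:nax].T, index=self.endog.index, columns=axes)
        return RDAResults(
            model=self,
            params=pd.DataFrame(beta, index=self.exog.columns, columns=self.endog.columns),
            fittedvalues=pd.DataFrame(fitted, index=self.endog.index, columns=self.endog.columns),
            resid=pd.DataFrame(yc - fitted, index=self.endog.index, columns=self.endog.columns),
            r2=r2,
            adj_r2=adjusted_r2(r2, n, m) if ss_total > 0 else np.nan,
            eigenvalues=pd.Series((s[:nax] ** 2) / (n - 1), index=axes),
            site_scores=site,
            site_scores_wa=site_wa,
            species_scores=species,
            ss_total=ss_total,
            ss_fitted=ss_fit,
        )


@dataclass
class RDAResults:
    """Fitted RDA: coefficients, canonical axes, explained variance, permutation test."""

    model: RDA
    params: pd.DataFrame
    fittedvalues: pd.DataFrame
    resid: pd.DataFrame
    r2: float
    adj_r2: float
    eigenvalues: pd.Series
    site_scores: pd.DataFrame
    site_scores_wa: pd.DataFrame
    species_scores: pd.DataFrame
    ss_total: float
    ss_fitted: float
    p_value: float | None = None

    @property
    def nobs(self) -> int:
        return len(self.fittedvalues)

    def permutation_test(self, n_permutations: int = 999, seed: int = 0) -> float:
        """Overall-model significance by unrestricted row permutation of Y.

        The statistic is R² (monotone in the pseudo-F at fixed predictor
        count); p = (1 + #{R²* >= R²}) / (1 + n_permutations).
        """
        y = self.model.endog.to_numpy()
        x = self.model.exog.to_numpy()
        xc = x - x.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(xc)
        rng = np.random.default_rng(seed)
        yc = y - y.mean(axis=0, keepdims=True)
        ss_total = (yc * yc).sum()
        geq = 1
        for _ in range(n_permutations):
            yp = yc[rng.permutation(len(yc)), :]
            yp = yp - yp.mean(axis=0, keepdims=True)
            proj = q.T @ yp
            if (proj * proj).sum() / (yp * yp).sum() >= self.r2 - 1e-12:
                geq += 1
        self.p_value = geq / (1.0 + n_permutations)
        return self.p_value

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            "===================",
            f"n observations      {self.nobs}",
            f"n predictors        {self.params.shape[0]}",
            f"n responses         {self.params.shape[1]}",
            f"R2                  {self.r2:.4f}",
            f"adjusted R2         {self.adj_r2:.4f}",
        ]
        if self.p_value is not None:
            lines.append(f"permutation p       {self.p_value:.4f}")
        ev = self.eigenvalues
        if len(ev):
            share = ev / ev.sum()
            lines.append("canonical axes (share of constrained variance):")
            for name, s in share.items():
                lines.append(f"  {name:<8s} {s:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# response detrending
# ---------------------------------------------------------------------------

def detrend_linear(Y, timestamps=None, alpha: float = 0.05):
    """Remove significant linear time trends from each response column.

    Columns whose OLS slope on time is significant at *alpha* are replaced by
    their residuals plus the column mean; others are untouched.  Returns
    ``(detrended, detrended_columns)``.
    """
    Y = _as_frame(Y, "y")
    if len(Y) < 3:
        raise ValueError("need at least 3 time points to detrend")
    if timestamps is None:
        timestamps = Y.index
    t = pd.DatetimeIndex(timestamps)
    tt = (t - t[0]).total_seconds().to_numpy() / 86400.0
    X = sm.add_constant(tt)
    out = Y.copy()
    hit = []
    for c in Y.columns:
        y = Y[c].to_numpy()
        if np.allclose(y, y[0]):
            continue
        fit = sm.OLS(y, X).fit()
        if fit.pvalues[1] < alpha:
            out[c] = fit.resid + y.mean()
            hit.append(c)
    return out, hit


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def vif_screen(X, threshold: float = 10.0):
    """Iteratively drop the highest-VIF column until all VIF <= threshold.

    VIF_j = 1 / (1 - R²_j) with R²_j from regressing (centred) column j on the
    remaining columns.  Zero-variance columns are dropped first.  Returns
    ``(screened, report)`` where *report* lists the drop order and final VIFs.
    """
    X = _as_frame(X, "x")
    if X.shape[1] < 2:
        return X.copy(), {"dropped": [], "vif": dict.fromkeys(X.columns, 1.0)}
    cols = list(X.columns)
    dropped = []
    xc = X - X.mean(axis=0)
    const = [c for c in cols if np.allclose(xc[c], 0)]
    for c in const:
        cols.remove(c)
        dropped.append((c, np.inf))

    def vifs(cs):
        out = {}
        m = xc[cs].to_numpy()
        for j, c in enumerate(cs):
            others = np.delete(m, j, axis=1)
            yj = m[:, j]
            ss = float(yj @ yj)
            if others.shape[1] == 0 or ss == 0:
                out[c] = 1.0
                continue
            beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ beta
            r2 = 1.0 - float(resid @ resid) / ss
            out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while len(cols) >= 2:
        v = vifs(cols)
        worst = max(cols, key=lambda c: v[c])
        if v[worst] <= threshold:
            break
        cols.remove(worst)
        dropped.append((worst, v[worst]))
    final = vifs(cols) if len(cols) >= 2 else dict.fromkeys(cols, 1.0)
    return X[cols].copy(), {"dropped": dropped, "vif": final}


# ---------------------------------------------------------------------------
# forward AIC selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Greedy forward-selection outcome: chosen columns plus the step trace."""

    selected: list[str]
    trace: pd.DataFrame
    criterion: str = "aic"

    def __iter__(self):
        return iter(self.selected)


def _multivariate_aic(rss_total: float, n: int, m: int) -> float:
    """n ln(RSS/n) + 2m — the multivariate surrogate with sigma² profiled out."""
    return n * np.log(max(rss_total, 1e-300) / n) + 2.0 * m


def stepwise_select(
    Y,
    X,
    criterion: str = "aic",
    direction: str = "forward",
    adjr2_stop: float | None = None,
    max_terms: int | None = None,
) -> SelectionResult:
    """Greedy forward predictor addition under a multivariate AIC.

    At each step the candidate that most lowers ``n ln(RSS_total/n) + 2m``
    (RSS summed over centred response columns, m = number of selected
    predictors) is added; selection stops when no candidate lowers the
    criterion.  Ties break deterministically by column order.  With
    *adjr2_stop* set, selection additionally stops once the selected model's
    adjusted R² exceeds that value (the double stopping rule used with
    forward selection in canonical ordination).
    """
    if direction != "forward":
        raise NotImplementedError("only forward selection is implemented")
    if criterion != "aic":
        raise ValueError(f"unknown criterion {criterion!r}")
    Y = _as_frame(Y, "y")
    X = _as_frame(X, "x")
    n = len(Y)
    yc = Y.to_numpy() - Y.to_numpy().mean(axis=0, keepdims=True)
    ss_total = float((yc * yc).sum())
    xc = X.to_numpy() - X.to_numpy().mean(axis=0, keepdims=True)
    cols = list(X.columns)

    selected: list[int] = []
    current_aic = _multivariate_aic(ss_total, n, 0)
    rows = [{"step": 0, "added": None, "aic": current_aic, "adj_r2": 0.0}]
    q = np.zeros((n, 0))
    resid_y = yc.copy()

    while cols and (max_terms is None or len(selected) < max_terms):
        best = None
        for j, c in enumerate(X.columns):
            if j in selected:
                continue
            v = xc[:, j] - q @ (q.T @ xc[:, j])
            nv = np.linalg.norm(v)
            if nv < 1e-10 * max(1.0, np.linalg.norm(xc[:, j])):
                continue  # numerically collinear with the current model
            v = v / nv
            proj = v @ resid_y
            rss = float((resid_y * resid_y).sum()) - float(proj @ proj)
            aic = _multivariate_aic(rss, n, len(selected) + 1)
            if best is None or aic < best[0] - 1e-12:
                best = (aic, j, v, rss)
        if best is None or best[0] >= current_aic:
            break
        current_aic, j, v, rss = best
        selected.append(j)
        q = np.column_stack([q, v])
        resid_y = resid_y - np.outer(v, v @ resid_y)
        r2 = 1.0 - rss / ss_total if ss_total > 0 else np.nan
        ar2 = adjusted_r2(r2, n, len(selected))
        rows.append({"step": len(selected), "added": X.columns[j],
                     "aic": current_aic, "adj_r2": ar2})
        if adjr2_stop is not None and ar2 > adjr2_stop:
            break

    return SelectionResult(selected=[X.columns[j] for j in selected],
                           trace=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Adjusted-R² fractions of the three-set Venn diagram.

    ``fractions`` holds the 7 exclusive regions plus the residual:
    ``env``, ``pos``, ``neg`` (unique), ``env_pos``, ``env_neg``, ``pos_neg``
    (pairwise intersections excluding the third set) and ``all`` (the triple
    intersection); negative values are reported as-is (conventionally not
    displayed).  ``model_adj_r2`` are the seven fitted component models.
    """

    fractions: dict[str, float]
    model_adj_r2: dict[str, float]
    set_sizes: dict[str, int]

    REGIONS = ("env", "pos", "neg", "env_pos", "env_neg", "pos_neg", "all")

    def largest_region(self) -> str:
        vals = {k: v for k, v in self.fractions.items() if k in self.REGIONS and np.isfinite(v)}
        return max(vals, key=vals.get)

    def summary(self) -> str:
        lines = ["Variance partition (adjusted R2 fractions)",
                 "=========================================="]
        for k in (*self.REGIONS, "residual"):
            v = self.fractions.get(k, np.nan)
            shown = f"{v:.4f}" if np.isfinite(v) else "NA"
            note = "  (not shown)" if np.isfinite(v) and v < 0 and k != "residual" else ""
            lines.append(f"  [{k:<8s}] {shown}{note}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        def clean(d):
            return {k: (None if not np.isfinite(v) else float(v)) for k, v in d.items()}
        return {"fractions": clean(self.fractions),
                "model_adj_r2": clean(self.model_adj_r2),
                "set_sizes": self.set_sizes}


def _adj_r2_of(Y, X) -> float:
    """Projection-based adjusted R² tolerant of collinear column unions.

    Combined predictor sets may share information (or literal columns); the
    projection onto their column space is still well defined, and the Ezekiel
    correction uses the space's rank rather than the raw column count.
    """
    if X is None or X.shape[1] == 0:
        return 0.0
    yc = Y.to_numpy() - Y.to_numpy().mean(axis=0, keepdims=True)
    xc = X.to_numpy() - X.to_numpy().mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    keep = diag > (diag.max() if diag.size else 1.0) * 1e-10
    q = q[:, keep]
    rank = int(keep.sum())
    ss_total = float((yc * yc).sum())
    proj = q.T @ yc
    r2 = float((proj * proj).sum()) / ss_total
    return adjusted_r2(r2, len(Y), rank)


def variance_partition(Y, set_env, set_pos, set_neg) -> VariancePartition:
    """Three-set variance partitioning by inclusion-exclusion on adjusted R².

    Fits the seven RDAs (each set alone, each pair, all three), converts each
    to adjusted R², and solves the linear system for the seven exclusive Venn
    fractions; the residual is 1 minus the full-model adjusted R².  Empty sets
    contribute zero; a component model without enough degrees of freedom
    yields NaN fractions wherever it enters.
    """
    Y = _as_frame(Y, "y")
    sets = {"E": _as_frame(set_env, "e") if set_env is not None else None,
            "P": _as_frame(set_pos, "p") if set_pos is not None else None,
            "N": _as_frame(set_neg, "n") if set_neg is not None else None}
    for k, v in sets.items():
        if v is not None and v.shape[1] == 0:
            sets[k] = None

    def combo(keys):
        frames = [sets[k] for k in keys if sets[k] is not None]
        if not frames:
            return None
        out = pd.concat(frames, axis=1)
        out.index = Y.index
        return out

    names = ("E", "P", "N", "EP", "EN", "PN", "EPN")
    r = {}
    for nm in names:
        xs = combo(tuple(nm))
        if xs is not None and len(Y) <= xs.shape[1] + 1:
            r[nm] = np.nan
        else:
            r[nm] = _adj_r2_of(Y, xs)

    # regions: a=unique E, b=unique P, c=unique N, d=EP, e=EN, f=PN, g=EPN
    design = np.array([
        # a  b  c  d  e  f  g
        [1, 0, 0, 1, 1, 0, 1],  # E
        [0, 1, 0, 1, 0, 1, 1],  # P
        [0, 0, 1, 0, 1, 1, 1],  # N
        [1, 1, 0, 1, 1, 1, 1],  # EP
        [1, 0, 1, 1, 1, 1, 1],  # EN
        [0, 1, 1, 1, 1, 1, 1],  # PN
        [1, 1, 1, 1, 1, 1, 1],  # EPN
    ], dtype=float)
    vals = np.array([r[nm] for nm in names])
    if np.all(np.isfinite(vals)):
        frac = np.linalg.lstsq(design, vals, rcond=None)[0]
    else:
        frac = np.full(7, np.nan)
    keys = ("env", "pos", "neg", "env_pos", "env_neg", "pos_neg", "all")
    fractions = dict(zip(keys, (float(v) for v in frac)))
    fractions["residual"] = float(1.0 - r["EPN"]) if np.isfinite(r["EPN"]) else np.nan
    return VariancePartition(
        fractions=fractions,
        model_adj_r2={nm: float(v) for nm, v in r.items()},
        set_sizes={k: (0 if sets[k] is None else sets[k].shape[1]) for k in sets},
    )


# ---------------------------------------------------------------------------
# time-polynomial ordination
# ---------------------------------------------------------------------------

def time_polynomial_rda(Y, timestamps=None, transform: str | None = None) -> RDAResults:
    """RDA of the responses on (t, t²): the sequential community-turnover ordination.

    Site scores traced in time order show whether the trajectory returns to
    its start (species recovery) or heads elsewhere (species replacement).
    *transform='hellinger'* applies the Hellinger transform first.
    """
    Y = _as_frame(Y, "y")
    if len(Y) < 4:
        raise ValueError("need at least 4 time points")
    if transform == "hellinger":
        from .diversity import hellinger
        Y = hellinger(Y)
    if timestamps is None:
        timestamps = Y.index
    t = pd.DatetimeIndex(timestamps)
    tt = (t - t[0]).total_seconds().to_numpy() / 86400.0
    tt = (tt - tt.mean()) / max(tt.std(), 1e-12)
    X = pd.DataFrame({"t": tt, "t2": tt * tt}, index=Y.index)
    return RDA(Y, X).fit()
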