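"""Distance-based Moran's eigenvector maps (dbMEM) for irregular time series.

dbMEMs are an orthogonal basis of temporal structure at all scales the
sampling design can resolve.  Construction (the PCNM family): truncate the
pairwise time-distance matrix at a threshold (distances beyond it are replaced
by four times the threshold), Gower-centre -D^2/2, and eigendecompose; the
eigenvectors with non-negligible eigenvalues are the eigenfunctions.  Each is
classified by its Moran's I — above the expectation E(I) = -1/(n-1) it models
positive temporal correlation, below it negative — against the binary
connectivity implied by the truncation distance.

Records with a long instrument-service gap are handled with a *staggered*
basis: eigenfunctions are built per deployment block and assembled
block-diagonally, so no eigenfunction spans the unsampled gap.  Remaining
small gaps are first padded with *supplementary* time points that enter the
basis construction but never carry response data; they are removed (with a
slight, reported loss of orthogonality) before any response modelling.
Positive-class eigenfunctions can be banded into broad/medium/fine timescales
by their dominant periodogram period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

logger = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "DbMEMBasis",
    "insert_supplementary_points",
    "build_dbmem",
    "staggered_basis",
    "build_staggered_dbmem",
    "drop_supplementary_rows",
    "morans_i",
    "dominant_period",
    "assign_scale_bands",
    "DEFAULT_SCALE_BANDS",
]

#: scale bands in days: broad, medium, fine
DEFAULT_SCALE_BANDS = {"broad": (53.0, 172.0), "medium": (11.0, 26.0), "fine": (2.7, 7.5)}


@dataclass
class TimeGrid:
    """Analysis timestamps with supplementary-point flags and deployment blocks."""

    timestamps: pd.DatetimeIndex
    supplementary: np.ndarray = None
    block: np.ndarray = None

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        n = len(self.timestamps)
        if n and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.supplementary is None:
            self.supplementary = np.zeros(n, dtype=bool)
        self.supplementary = np.asarray(self.supplementary, dtype=bool)
        if self.block is None:
            self.block = np.zeros(n, dtype=int)
        self.block = np.asarray(self.block, dtype=int)

    @classmethod
    def from_timestamps(cls, timestamps, block_gap="10D") -> "TimeGrid":
        """Grid from response timestamps; gaps longer than *block_gap* split blocks."""
        ts = pd.DatetimeIndex(timestamps)
        block = np.zeros(len(ts), dtype=int)
        if len(ts) > 1:
            block[1:] = np.cumsum(np.diff(ts.asi8) > pd.Timedelta(block_gap).value)
        return cls(ts, block=block)

    @property
    def n_response(self) -> int:
        return int((~self.supplementary).sum())

    def block_ids(self) -> list[int]:
        return sorted(set(self.block.tolist()))

    def blocks(self) -> list["TimeGrid"]:
        out = []
        for b in self.block_ids():
            m = self.block == b
            out.append(TimeGrid(self.timestamps[m], self.supplementary[m], self.block[m]))
        return out

    def days(self) -> np.ndarray:
        """Times as days from the first point."""
        return (self.timestamps - self.timestamps[0]).total_seconds().to_numpy() / 86400.0


def insert_supplementary_points(grid: TimeGrid, max_interval="24h") -> TimeGrid:
    """Pad within-block gaps so no spacing exceeds *max_interval*.

    For each within-block gap of length g, the minimal number of equally
    spaced points, ceil(g / max_interval) - 1, is inserted and flagged
    supplementary.  Between-block gaps are never padded.
    """
    max_iv = pd.Timedelta(max_interval)
    if max_iv <= pd.Timedelta(0):
        raise ValueError("max_interval must be positive")
    ts, supp, blk = [], [], []
    for g in grid.blocks():
        t = g.timestamps
        for i in range(len(t)):
            ts.append(t[i]); supp.append(bool(g.supplementary[i])); blk.append(int(g.block[0]))
            if i + 1 < len(t):
                gap = t[i + 1] - t[i]
                m = int(np.ceil(gap / max_iv)) - 1
                for j in range(1, m + 1):
                    ts.append(t[i] + gap * j / (m + 1))
                    supp.append(True)
                    blk.append(int(g.block[0]))
    return TimeGrid(pd.DatetimeIndex(ts), np.array(supp, dtype=bool), np.array(blk, dtype=int))


@dataclass
class DbMEMBasis:
    """Temporal eigenfunctions with their eigenvalues, Moran's I and metadata.

    ``functions`` holds one unit-norm eigenfunction per column on the grid's
    rows (staggered bases are zero outside their own block).  Per-column
    metadata: ``eigenvalues``, ``morans_i``, ``sign_class`` ('positive' if
    Moran's I exceeds its expectation -1/(n-1) on the column's block),
    ``col_block`` and ``scale_band``.  Per-row: ``row_block`` and
    ``supplementary``.
    """

    functions: pd.DataFrame
    eigenvalues: pd.Series
    morans_i: pd.Series
    sign_class: pd.Series
    col_block: pd.Series
    row_block: pd.Series
    supplementary: pd.Series
    truncation_days: dict[int, float]
    scale_band: pd.Series = None
    gram_max_offdiag: float = 0.0

    def __post_init__(self):
        if self.scale_band is None:
            self.scale_band = pd.Series("unassigned", index=self.functions.columns)

    @property
    def k(self) -> int:
        return self.functions.shape[1]

    def columns_of_class(self, sign: str) -> list[str]:
        return list(self.sign_class.index[self.sign_class == sign])

    def positive(self) -> pd.DataFrame:
        return self.functions[self.columns_of_class("positive")]

    def negative(self) -> pd.DataFrame:
        return self.functions[self.columns_of_class("negative")]

    def to_csv(self, path) -> None:
        out = self.functions.copy()
        out.index.name = "timestamp"
        out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%SZ")

    def sidecar(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.to_dict(),
            "morans_i": self.morans_i.to_dict(),
            "sign_class": self.sign_class.to_dict(),
            "scale_band": self.scale_band.to_dict(),
            "block": {c: int(b) for c, b in self.col_block.items()},
            "truncation_days": {str(k): float(v) for k, v in self.truncation_days.items()},
            "gram_max_offdiag": float(self.gram_max_offdiag),
        }


def morans_i(x: np.ndarray, w: np.ndarray) -> float:
    """Moran's I of *x* under the (symmetric, zero-diagonal) weight matrix *w*."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = float(xc @ xc)
    s0 = float(w.sum())
    if denom == 0 or s0 == 0:
        return np.nan
    return (n / s0) * float(xc @ w @ xc) / denom


def build_dbmem(grid, truncation: float | None = None, eig_tol: float = 1e-10,
                prefix: str = "MEM") -> DbMEMBasis:
    """dbMEM eigenfunctions for one block of time points.

    The pairwise time-distance matrix (days) is truncated: distances greater
    than the threshold (by default the largest consecutive spacing) are
    replaced by four times the threshold.  Principal coordinates of the
    Gower-centred -D^2/2 with |eigenvalue| above ``eig_tol * max|eigenvalue|``
    are retained, unit-norm, ordered by decreasing eigenvalue.  Moran's I is
    computed against binary connectivity within the truncation distance.
    """
    if isinstance(grid, TimeGrid):
        g = grid
    else:
        g = TimeGrid(pd.DatetimeIndex(grid))
    if len(set(g.block.tolist())) > 1:
        raise ValueError("build_dbmem works on a single block; use build_staggered_dbmem")
    t = g.days()
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 time points per block")
    if np.allclose(np.ptp(t), 0):
        raise ValueError("all timestamps equal")

    d = np.abs(t[:, None] - t[None, :])
    if truncation is None:
        truncation = float(np.max(np.diff(t)))
    if truncation <= 0:
        raise ValueError("truncation must be positive")
    dmod = np.where(d > truncation, 4.0 * truncation, d)
    a = -0.5 * dmod * dmod
    a -= a.mean(axis=0, keepdims=True)
    a -= a.mean(axis=1, keepdims=True)
    # a is symmetric after double-centring up to roundoff
    lam, vec = np.linalg.eigh((a + a.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = np.abs(lam) > eig_tol * np.max(np.abs(lam))
    lam, vec = lam[keep], vec[:, keep]

    w = ((d <= truncation) & (d > 0)).astype(float)
    e_i = -1.0 / (n - 1)
    cols = [f"{prefix}{i + 1}" for i in range(vec.shape[1])]
    mi = pd.Series([morans_i(vec[:, j], w) for j in range(vec.shape[1])], index=cols)
    blk = int(g.block[0]) if len(g.block) else 0
    return DbMEMBasis(
        functions=pd.DataFrame(vec, index=g.timestamps, columns=cols),
        eigenvalues=pd.Series(lam, index=cols),
        morans_i=mi,
        sign_class=pd.Series(np.where(mi > e_i, "positive", "negative"), index=cols),
        col_block=pd.Series(blk, index=cols),
        row_block=pd.Series(g.block, index=g.timestamps),
        supplementary=pd.Series(g.supplementary, index=g.timestamps),
        truncation_days={blk: float(truncation)},
    )


def staggered_basis(bases: list[DbMEMBasis]) -> DbMEMBasis:
    """Block-diagonal assembly of per-block bases spanning a long gap.

    Each block's eigenfunctions occupy that block's rows and are exactly zero
    elsewhere, so cross-block columns are orthogonal by construction.  Columns
    are renamed ``B<block>_MEM<i>``.
    """
    if not bases:
        raise ValueError("need at least one block basis")
    if len(bases) == 1:
        return bases[0]
    ends = [(b.functions.index[0], b.functions.index[-1]) for b in bases]
    for (s1, e1), (s2, _) in zip(ends[:-1], ends[1:]):
        if s2 <= e1:
            raise ValueError("blocks overlap in time")
    all_idx = bases[0].functions.index
    for b in bases[1:]:
        all_idx = all_idx.append(b.functions.index)
    funcs, eig, mi, sc, cb, trunc = [], [], [], [], [], {}
    rb = pd.concat([b.row_block for b in bases])
    supp = pd.concat([b.supplementary for b in bases])
    for b in bases:
        blk = int(b.col_block.iloc[0])
        ren = {c: f"B{blk}_{c}" for c in b.functions.columns}
        f = b.functions.rename(columns=ren).reindex(all_idx).fillna(0.0)
        funcs.append(f)
        eig.append(b.eigenvalues.rename(index=ren))
        mi.append(b.morans_i.rename(index=ren))
        sc.append(b.sign_class.rename(index=ren))
        cb.append(b.col_block.rename(index=ren))
        trunc.update(b.truncation_days)
    return DbMEMBasis(
        functions=pd.concat(funcs, axis=1),
        eigenvalues=pd.concat(eig),
        morans_i=pd.concat(mi),
        sign_class=pd.concat(sc),
        col_block=pd.concat(cb),
        row_block=rb,
        supplementary=supp,
        truncation_days=trunc,
    )


def build_staggered_dbmem(grid: TimeGrid, max_interval="24h",
                          truncation: float | None = None) -> DbMEMBasis:
    """Supplement each block to *max_interval* and assemble the staggered basis."""
    padded = insert_supplementary_points(grid, max_interval)
    bases = [build_dbmem(b, truncation=truncation) for b in padded.blocks()]
    return staggered_basis(bases)


def drop_supplementary_rows(basis: DbMEMBasis, grid: TimeGrid | None = None) -> DbMEMBasis:
    """Restrict the basis to response rows (supplementary points removed).

    Column labels and metadata are preserved.  The maximum off-diagonal
    absolute Gram entry of the restricted basis — the orthogonality lost by
    removing rows — is computed, logged and stored on the result.
    """
    supp = basis.supplementary.to_numpy()
    keep = ~supp
    f = basis.functions.loc[keep]
    gram_dev = 0.0
    for blk in sorted(set(basis.col_block)):
        cols = basis.col_block.index[basis.col_block == blk]
        m = f[cols].to_numpy()
        g = m.T @ m
        if g.shape[0] > 1:
            off = g - np.diag(np.diag(g))
            gram_dev = max(gram_dev, float(np.max(np.abs(off))))
    if supp.any():
        logger.info("dropped %d supplementary rows; max off-diagonal Gram %.3g",
                    int(supp.sum()), gram_dev)
    return DbMEMBasis(
        functions=f,
        eigenvalues=basis.eigenvalues,
        morans_i=basis.morans_i,
        sign_class=basis.sign_class,
        col_block=basis.col_block,
        row_block=basis.row_block.loc[keep],
        supplementary=basis.supplementary.loc[keep],
        truncation_days=basis.truncation_days,
        scale_band=basis.scale_band.copy(),
        gram_max_offdiag=gram_dev,
    )


def dominant_period(t_days: np.ndarray, x: np.ndarray,
                    n_freq: int = 600) -> float:
    """Dominant period (days) by Lomb–Scargle periodogram on an irregular grid."""
    t = np.asarray(t_days, dtype=float)
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    span = np.ptp(t)
    dt = np.min(np.diff(np.sort(t)))
    periods = np.geomspace(max(2 * dt, 1e-6), 2 * span, n_freq)
    power = lombscargle(t, x, 2 * np.pi / periods)
    return float(periods[int(np.argmax(power))])


def assign_scale_bands(basis: DbMEMBasis,
                       bands: dict[str, tuple[float, float]] | None = None) -> DbMEMBasis:
    """Band positive-class eigenfunctions by dominant period (days).

    Each positive eigenfunction's dominant period is estimated on its own
    block's grid; it is assigned the band whose (lo, hi) interval contains the
    period, or 'unassigned' when no band does.  Negative-class columns stay
    unassigned.
    """
    bands = bands or DEFAULT_SCALE_BANDS
    t0 = basis.functions.index[0]
    t_days_all = (basis.functions.index - t0).total_seconds().to_numpy() / 86400.0
    band_col = basis.scale_band.copy()
    for c in basis.columns_of_class("positive"):
        blk = basis.col_block[c]
        rows = basis.row_block.to_numpy() == blk
        per = dominant_period(t_days_all[rows], basis.functions[c].to_numpy()[rows])
        label = "unassigned"
        for name, (lo, hi) in bands.items():
            if lo <= per <= hi:
                label = name
                break
        band_col[c] = label
    basis.scale_band = band_col
    return basis
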