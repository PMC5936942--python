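"""Alpha diversity and temporal beta-diversity partitioning.

Total beta diversity is taken as the total variance of the (transformed)
time x species matrix: BD_total = SS_total / (n - 1), where SS_total is the
sum of squared deviations of each cell from its species (column) mean.  Row
shares of SS_total are the local contributions to beta diversity (LCBD, one
value per time point: how compositionally unusual that sample is relative to
the whole series) and column shares are the species contributions (SCBD).
Both sets of shares sum to one by construction.  LCBD significance is judged
against a null that permutes abundances independently within each species
column, which preserves species abundance distributions while breaking their
joint temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "BetaPartition",
    "standardize_density",
    "hellinger",
    "alpha_diversity",
    "beta_partition",
    "lcbd_permutation_test",
]

#: combined imaged seafloor area for a paired-image sample, m^2
PAIRED_IMAGE_AREA_M2 = 2.7
#: imaged area when only a single photo is usable, m^2
SINGLE_IMAGE_AREA_M2 = 1.3


class CommunityMatrix:
    """Time x species density matrix (ind m-2) with guild metadata and a row mask.

    Rows are sampling timestamps (unique, increasing), columns species.  The
    optional row mask marks whole sampling occasions as missing (camera
    failures) without deleting the stored values.
    """

    def __init__(
        self,
        densities: pd.DataFrame,
        guilds: pd.Series | None = None,
        row_mask: np.ndarray | pd.Series | None = None,
    ):
        if not isinstance(densities.index, pd.DatetimeIndex):
            raise TypeError("CommunityMatrix requires a DatetimeIndex")
        if densities.index.has_duplicates or (
            len(densities) > 1 and not densities.index.is_monotonic_increasing
        ):
            raise ValueError("row timestamps must be unique and increasing")
        if (densities.to_numpy() < 0).any():
            raise ValueError("densities must be nonnegative")
        self.densities = densities.astype(float)
        if guilds is not None:
            guilds = guilds.reindex(densities.columns)
        self.guilds = guilds
        if row_mask is None:
            row_mask = np.zeros(len(densities), dtype=bool)
        self.row_mask = pd.Series(np.asarray(row_mask, dtype=bool), index=densities.index)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.densities.index

    @property
    def species(self) -> list[str]:
        return list(self.densities.columns)

    def __len__(self) -> int:
        return len(self.densities)

    def with_row_mask(self, mask) -> "CommunityMatrix":
        return CommunityMatrix(self.densities, self.guilds,
                               self.row_mask.to_numpy() | np.asarray(mask, dtype=bool))

    def observed(self) -> "CommunityMatrix":
        """Drop masked rows."""
        keep = ~self.row_mask.to_numpy()
        return CommunityMatrix(self.densities.loc[keep], self.guilds)

    def guild_totals(self) -> pd.DataFrame:
        """Summed density per guild per time point."""
        if self.guilds is None:
            raise ValueError("no guild metadata attached")
        return self.densities.T.groupby(self.guilds).sum().T

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path, guilds_path=None) -> None:
        out = self.densities.mask(self.row_mask, axis=0)
        out.index.name = "timestamp"
        out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%SZ")
        if guilds_path is not None and self.guilds is not None:
            self.guilds.rename_axis("species").to_csv(guilds_path)

    @classmethod
    def from_csv(cls, path, guilds_path=None) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col="timestamp", parse_dates=["timestamp"])
        df.index = pd.DatetimeIndex(df.index).tz_localize(None)
        mask = df.isna().any(axis=1).to_numpy()
        guilds = None
        if guilds_path is not None:
            g = pd.read_csv(guilds_path, index_col="species")
            guilds = g[g.columns[0]].rename("guild")
        return cls(df.fillna(0.0), guilds=guilds, row_mask=mask)


def standardize_density(counts, area_m2: float = PAIRED_IMAGE_AREA_M2,
                        single_photo=None) -> pd.DataFrame:
    """Convert raw counts per sampling occasion to densities (ind m-2).

    *area_m2* is the combined imaged area for paired-image occasions (2.7 m2);
    rows flagged in *single_photo* use the single-image area (~1.3 m2).
    """
    if area_m2 <= 0:
        raise ValueError("imaged area must be positive")
    counts = pd.DataFrame(counts).astype(float)
    area = np.full(len(counts), float(area_m2))
    if single_photo is not None:
        area = np.where(np.asarray(single_photo, dtype=bool), SINGLE_IMAGE_AREA_M2, area)
    return counts.div(area, axis=0)


def hellinger(matrix) -> pd.DataFrame:
    """Hellinger transform: square root of within-row relative abundances.

    Each output row has unit Euclidean norm, making Euclidean-based ordination
    appropriate for abundance data without overweighting rare species.
    All-zero rows are undefined and rejected with the offending timestamps.
    """
    df = pd.DataFrame(matrix).astype(float)
    rowsum = df.sum(axis=1)
    bad = rowsum <= 0
    if bad.any():
        raise ValueError(f"all-zero community rows at {list(df.index[bad])}")
    return np.sqrt(df.div(rowsum, axis=0))


def alpha_diversity(matrix) -> pd.DataFrame:
    """Shannon diversity H' (natural log), Pielou evenness J and richness per row.

    H' = -sum p_i ln p_i over nonzero proportions; J = H' / ln(richness),
    undefined (NaN) for rows with fewer than two species; empty rows give NaN
    throughout rather than zeros.
    """
    df = pd.DataFrame(matrix).astype(float)
    x = df.to_numpy()
    rowsum = x.sum(axis=1)
    rich = (x > 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = x / rowsum[:, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
        h = -terms.sum(axis=1)
        h[rowsum <= 0] = np.nan
        j = np.where(rich >= 2, h / np.log(np.maximum(rich, 2)), np.nan)
    rich[rowsum <= 0] = np.nan
    return pd.DataFrame({"shannon": h, "evenness": j, "richness": rich}, index=df.index)


@dataclass
class BetaPartition:
    """Total beta diversity and its local (time) and species partitions.

    ``lcbd`` and ``scbd`` each sum to one; ``bd_total`` is SS_total / (n - 1).
    ``p_values`` is filled by :func:`lcbd_permutation_test`.
    """

    bd_total: float
    ss_total: float
    lcbd: pd.Series
    scbd: pd.Series
    transform: str
    p_values: pd.Series | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"lcbd": self.lcbd})
        if self.p_values is not None:
            out["p_value"] = self.p_values
        return out

    def to_json_dict(self) -> dict:
        return {
            "bd_total": float(self.bd_total),
            "ss_total": float(self.ss_total),
            "transform": self.transform,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _partition_arrays(y: np.ndarray):
    dev = y - y.mean(axis=0, keepdims=True)
    s = dev * dev
    ss_total = float(s.sum())
    return ss_total, s.sum(axis=1), s.sum(axis=0)


def beta_partition(matrix, transform: str = "hellinger") -> BetaPartition:
    """Partition total community variance into per-time (LCBD) and per-species (SCBD) shares.

    The (optionally Hellinger-transformed) matrix is centred by species means;
    SS_total is the sum of all squared deviations, BD_total = SS_total/(n-1),
    and LCBD/SCBD are the row and column shares of SS_total.  Masked or
    all-zero rows must be handled by the caller (see pipeline); identical rows
    everywhere make beta diversity undefined.
    """
    df = pd.DataFrame(matrix).astype(float)
    if isinstance(matrix, CommunityMatrix):
        df = matrix.densities
    if len(df) < 2:
        raise ValueError("need at least two time points")
    if transform == "hellinger":
        df = hellinger(df)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")
    ss_total, ss_rows, ss_cols = _partition_arrays(df.to_numpy())
    if ss_total <= 0:
        raise ValueError("no beta diversity: all rows identical")
    return BetaPartition(
        bd_total=ss_total / (len(df) - 1),
        ss_total=ss_total,
        lcbd=pd.Series(ss_rows / ss_total, index=df.index, name="lcbd"),
        scbd=pd.Series(ss_cols / ss_total, index=df.columns, name="scbd"),
        transform=transform or "none",
    )


def lcbd_permutation_test(
    matrix,
    n_permutations: int = 999,
    seed: int = 0,
    transform: str = "hellinger",
) -> BetaPartition:
    """LCBD with permutation p-values under a within-species permutation null.

    Each permutation shuffles every species column independently (destroying
    temporal structure, preserving abundance distributions), the partition is
    recomputed, and p_i = (1 + #{LCBD*_i >= LCBD_i}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    part = beta_partition(matrix, transform=transform)
    df = matrix.densities if isinstance(matrix, CommunityMatrix) else pd.DataFrame(matrix)
    x = df.to_numpy(dtype=float).copy()
    n, p = x.shape
    rng = np.random.default_rng(seed)
    obs = part.lcbd.to_numpy()
    geq = np.ones(n)  # the observed ordering counts once
    for _ in range(n_permutations):
        perm = np.empty_like(x)
        for j in range(p):
            perm[:, j] = x[rng.permutation(n), j]
        rs = perm.sum(axis=1)
        rs[rs <= 0] = 1.0  # a permuted all-zero row carries no abundance
        if transform == "hellinger":
            y = np.sqrt(perm / rs[:, None])
        else:
            y = perm
        ss_total, ss_rows, _ = _partition_arrays(y)
        geq += (ss_rows / ss_total) >= obs
    part.p_values = pd.Series(geq / (1.0 + n_permutations), index=part.lcbd.index,
                              name="p_value")
    part.n_permutations = n_permutations
    part.seed = seed
    return part
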