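"""End-to-end analysis pipeline: environment -> diversity -> dbMEM -> RDA -> rates.

Runs the full temporal beta-diversity analysis on either a synthetic scenario
or user-supplied CSV inputs: sensor-offset correction and pO2, 12-h window
summaries aligned to the biological sampling times, alpha diversity and
LCBD/SCBD partitioning with permutation tests, staggered temporal
eigenfunctions with scale bands, forward-selected RDA models and three-set
variance partitioning, segmented decline/recovery rates per guild, the diel
midnight-vs-noon contrast, and long-term hypoxia-exposure trends.  Every
intermediate can be written to disk together with a checksum manifest, so a
fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import diversity as dv
from . import dbmem as dm
from . import envseries as es
from . import ordination as od
from . import segmented as sg
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline",
           "align_resolution", "diel_contrast", "build_env_predictors"]

STAGES = ("simulate", "preprocess", "diversity", "dbmem", "model", "segments", "trends")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Defaults follow the study conventions: 0.048 ml/l oxygen offset, 12-h
    predictor windows, 24-h analysis resolution, severe-hypoxia and
    ecophysiological thresholds at 0.5 and 0.88 ml/l, 24-h maximum
    supplementation interval, broad/medium/fine scale bands of 172-53, 26-11
    and 7.5-2.7 days, and up to six breakpoints per segmented fit.
    """

    scenario: sim.FjordScenario | None = None
    env_csv: str | None = None
    community_csv: str | None = None
    guilds_csv: str | None = None
    drivers_csv: str | None = None
    visibility_csv: str | None = None

    offset: float = 0.048  # ml/l
    window: str = "12h"
    resolution: str = "24h"
    thresholds: tuple[float, float] = (0.5, 0.88)
    max_interval: str = "24h"
    block_gap: str = "10D"
    scale_bands: dict = field(default_factory=lambda: dict(dm.DEFAULT_SCALE_BANDS))
    n_perm: int = 999
    k_max: int = 6
    detrend_alpha: float = 0.05
    vif_threshold: float = 10.0
    seed: int = 0
    event_time: pd.Timestamp | None = None  # reoxygenation onset for hysteresis

    # long-term trend stage (synthetic multi-year constructions)
    trend_years: float = 10.8
    trend_slope: float = -0.067  # ml/l per year
    duration_slope: float = 12.4  # days per year
    duration_base: float = 60.0

    def __post_init__(self):
        if self.scenario is None and self.env_csv is None:
            self.scenario = sim.default_scenario(seed=self.seed)
        for name in ("window", "resolution", "max_interval", "block_gap"):
            if pd.Timedelta(getattr(self, name)) <= pd.Timedelta(0):
                raise ValueError(f"{name} must be a positive duration")
        lohi = sorted(self.scale_bands.values())
        for (l1, h1), (l2, h2) in zip(lohi[:-1], lohi[1:]):
            if h1 > l2:
                raise ValueError("scale bands must not overlap")

    def to_dict(self) -> dict:
        d = {
            "offset": self.offset, "window": self.window, "resolution": self.resolution,
            "thresholds": list(self.thresholds), "max_interval": self.max_interval,
            "block_gap": self.block_gap,
            "scale_bands": {k: list(v) for k, v in self.scale_bands.items()},
            "n_perm": self.n_perm, "k_max": self.k_max,
            "detrend_alpha": self.detrend_alpha, "vif_threshold": self.vif_threshold,
            "seed": self.seed,
            "trend_years": self.trend_years, "trend_slope": self.trend_slope,
            "duration_slope": self.duration_slope, "duration_base": self.duration_base,
        }
        if self.scenario is not None:
            d["scenario"] = self.scenario.to_dict()
        for k in ("env_csv", "community_csv", "guilds_csv", "drivers_csv", "visibility_csv"):
            if getattr(self, k):
                d[k] = getattr(self, k)
        return d


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, stage by stage."""

    config: PipelineConfig
    env: es.EnvSeries | None = None
    community: dv.CommunityMatrix | None = None
    drivers: pd.DataFrame | None = None
    visibility: pd.Series | None = None
    truth: dict | None = None

    env_corrected: es.EnvSeries | None = None
    summaries: es.WindowSummary | None = None

    alpha: pd.DataFrame | None = None
    beta: dv.BetaPartition | None = None

    grid: dm.TimeGrid | None = None
    basis: dm.DbMEMBasis | None = None
    basis_response: dm.DbMEMBasis | None = None

    Y: pd.DataFrame | None = None
    X_env: pd.DataFrame | None = None
    detrended_columns: list | None = None
    vif_report: dict | None = None
    selections: dict | None = None
    varpart: od.VariancePartition | None = None
    time_rda: od.RDAResults | None = None
    model_table: pd.DataFrame | None = None

    segments: dict | None = None
    hysteresis: dict | None = None
    diel: pd.DataFrame | None = None

    decadal: dict | None = None
    exposure: es.ExposureReport | None = None

    manifest: dict | None = None


# ---------------------------------------------------------------------------
# alignment and diel contrast
# ---------------------------------------------------------------------------

def align_resolution(community: dv.CommunityMatrix, env_table: pd.DataFrame,
                     resolution: str = "24h"):
    """Restrict community rows to the analysis resolution and join predictors.

    The resolution must be a whole multiple of the community sampling
    interval; rows on the resolution grid (anchored at midnight) are kept and
    inner-joined with the predictor table by timestamp.  Unmatched rows are
    dropped with a log line.
    """
    res = pd.Timedelta(resolution)
    obs = community.observed()
    ts = obs.timestamps
    if len(ts) < 2:
        raise ValueError("too few community rows to align")
    interval = pd.Timedelta(np.median(np.diff(ts.asi8)), "ns")
    ratio = res / interval
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"resolution {resolution} is not a multiple of the "
                         f"community interval {interval}")
    on_grid = ((ts - ts[0].normalize()) % res) == pd.Timedelta(0)
    keep = ts[on_grid]
    joined = keep.intersection(env_table.dropna().index)
    dropped = len(keep) - len(joined)
    if dropped:
        logger.info("align_resolution: dropped %d rows without predictors", dropped)
    if len(joined) == 0:
        raise ValueError("no overlap between community rows and predictors")
    return obs.densities.loc[joined], env_table.loc[joined]


def diel_contrast(community: dv.CommunityMatrix, oxygenated: pd.Series | None = None,
                  species=None) -> pd.DataFrame:
    """Paired midnight-vs-noon density contrast per species, with a sign test.

    Days contribute when both the 00.00 and 12.00 samples are observed (and,
    if *oxygenated* — a boolean series indexed by date — is given, fall in the
    oxygenated phase).  The two-sided sign test drops tied pairs.
    """
    obs = community.observed()
    df = obs.densities
    hours = df.index.hour
    mid = df[hours == 0].copy()
    noon = df[hours == 12].copy()
    if mid.empty or noon.empty:
        raise ValueError("both midnight and noon samples are required")
    mid.index = mid.index.normalize()
    noon.index = noon.index.normalize()
    days = mid.index.intersection(noon.index)
    if oxygenated is not None:
        ox = oxygenated[oxygenated].index
        days = days.intersection(pd.DatetimeIndex(ox).normalize())
    if len(days) == 0:
        raise ValueError("no paired midnight/noon days in the requested phase")
    mid, noon = mid.loc[days], noon.loc[days]
    cols = species or list(df.columns)
    rows = {}
    for c in cols:
        d = mid[c].to_numpy() - noon[c].to_numpy()
        nz = d[d != 0]
        if len(nz):
            p = binomtest((nz > 0).sum(), len(nz), 0.5, alternative="two-sided").pvalue
        else:
            p = 1.0
        rows[c] = {
            "mean_midnight": float(mid[c].mean()),
            "mean_noon": float(noon[c].mean()),
            "n_pairs": int(len(days)),
            "n_nonzero": int(len(nz)),
            "p_sign_test": float(p),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def build_env_predictors(summaries: es.WindowSummary, drivers: pd.DataFrame | None,
                         visibility: pd.Series | None,
                         channels=("po2", "temperature", "backscatter")) -> pd.DataFrame:
    """Assemble the environmental predictor table.

    12-h mean/s.d./max/min for each physical channel, the binary biological
    drivers, and dummy-coded visibility ranks with the lowest level as the
    reference.
    """
    tab = summaries.table()
    cols = [f"{ch}_{st}" for ch in channels for st in ("mean", "sd", "max", "min")]
    X = tab[[c for c in cols if c in tab.columns]].copy()
    if drivers is not None:
        X = X.join(drivers.astype(float), how="left")
    if visibility is not None:
        levels = sorted(pd.unique(visibility.dropna()))
        for lv in levels[1:]:  # lowest rank is the reference
            X[f"visibility_{lv}"] = (visibility == lv).astype(float)
    return X


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(cfg: PipelineConfig, result: PipelineResult):
    if cfg.env_csv is not None:
        result.env = es.EnvSeries.from_csv(cfg.env_csv)
        if cfg.community_csv:
            result.community = dv.CommunityMatrix.from_csv(cfg.community_csv, cfg.guilds_csv)
        if cfg.drivers_csv:
            d = pd.read_csv(cfg.drivers_csv, index_col=0, parse_dates=[0])
            d.index = pd.DatetimeIndex(d.index).tz_localize(None)
            result.drivers = d
        if cfg.visibility_csv:
            v = pd.read_csv(cfg.visibility_csv, index_col=0, parse_dates=[0])
            v.index = pd.DatetimeIndex(v.index).tz_localize(None)
            result.visibility = v[v.columns[0]]
    else:
        data = sim.simulate_dataset(cfg.scenario)
        result.env = data["env"]
        result.community = data["community"]
        result.drivers = data["drivers"]
        result.visibility = data["visibility"]
        result.truth = data["truth"]


def _stage_preprocess(cfg: PipelineConfig, r: PipelineResult):
    env = es.correct_offset(r.env, cfg.offset)
    env = es.add_po2(env)
    r.env_corrected = env
    targets = r.community.timestamps if r.community is not None else None
    if targets is None:
        raise ValueError("no community sampling grid to summarize onto")
    r.summaries = es.summarize_window(env, targets, cfg.window)


def _stage_diversity(cfg: PipelineConfig, r: PipelineResult):
    comm = r.community.observed()
    if comm.densities.shape[1] == 0:
        raise ValueError("community matrix has no species")
    nonzero = comm.densities.sum(axis=1) > 0
    if (~nonzero).any():
        logger.warning("diversity: excluding %d all-zero rows", int((~nonzero).sum()))
        comm = dv.CommunityMatrix(comm.densities.loc[nonzero], comm.guilds)
    r.alpha = dv.alpha_diversity(comm.densities)
    r.beta = dv.lcbd_permutation_test(comm.densities, n_permutations=cfg.n_perm,
                                      seed=cfg.seed)


def _stage_dbmem(cfg: PipelineConfig, r: PipelineResult):
    comm = r.community.observed()
    keep = comm.densities.sum(axis=1) > 0
    ts = comm.timestamps[keep.to_numpy()]
    on_grid = ((ts - ts[0].normalize()) % pd.Timedelta(cfg.resolution)) == pd.Timedelta(0)
    grid = dm.TimeGrid.from_timestamps(ts[on_grid], block_gap=cfg.block_gap)
    sizes = pd.Series(grid.block).value_counts()
    small = sizes.index[sizes < 3]
    if len(small):
        logger.warning("dbmem: dropping %d points in blocks too small to decompose",
                       int(sizes[small].sum()))
        keep_blk = ~np.isin(grid.block, small)
        grid = dm.TimeGrid.from_timestamps(grid.timestamps[keep_blk],
                                           block_gap=cfg.block_gap)
    r.grid = grid
    padded = dm.insert_supplementary_points(r.grid, cfg.max_interval)
    bases = [dm.build_dbmem(b) for b in padded.blocks()]
    basis = dm.staggered_basis(bases) if len(bases) > 1 else bases[0]
    basis = dm.assign_scale_bands(basis, cfg.scale_bands)
    r.basis = basis
    r.basis_response = dm.drop_supplementary_rows(basis)


def _stage_model(cfg: PipelineConfig, r: PipelineResult):
    env_X = build_env_predictors(r.summaries, r.drivers, r.visibility)
    Y, X = align_resolution(r.community, env_X, cfg.resolution)
    rows = r.basis_response.functions.index.intersection(Y.index)
    Y = Y.loc[rows]
    X = X.loc[rows]
    mem = r.basis_response.functions.loc[rows]
    Yh = dv.hellinger(Y.loc[Y.sum(axis=1) > 0])
    X = X.loc[Yh.index]
    mem = mem.loc[Yh.index]
    Yd, detrended = od.detrend_linear(Yh, Yh.index, alpha=cfg.detrend_alpha)
    r.Y, r.detrended_columns = Yd, detrended

    X_screened, vif_rep = od.vif_screen(X, cfg.vif_threshold)
    r.X_env, r.vif_report = X_screened, vif_rep

    pos_cols = [c for c in r.basis_response.columns_of_class("positive") if c in mem.columns]
    neg_cols = [c for c in r.basis_response.columns_of_class("negative") if c in mem.columns]
    sel_env = od.stepwise_select(Yd, X_screened)
    sel_pos = od.stepwise_select(Yd, mem[pos_cols])
    sel_neg = od.stepwise_select(Yd, mem[neg_cols])
    r.selections = {"env": sel_env, "mem_pos": sel_pos, "mem_neg": sel_neg}

    r.varpart = od.variance_partition(
        Yd,
        X_screened[sel_env.selected] if sel_env.selected else None,
        mem[sel_pos.selected] if sel_pos.selected else None,
        mem[sel_neg.selected] if sel_neg.selected else None,
    )
    r.time_rda = od.time_polynomial_rda(Yd, Yd.index)

    # model summary table: global +/- models and block-2 scale-band sub-models
    rows_out = []

    def add_model(name, cols, frame, yy):
        if not cols:
            rows_out.append({"model": name, "n_mem": 0, "adj_r2": np.nan, "p_value": np.nan})
            return
        res = od.RDA(yy, frame[cols]).fit()
        res.permutation_test(n_permutations=199, seed=cfg.seed)
        rows_out.append({"model": name, "n_mem": len(cols), "adj_r2": res.adj_r2,
                         "p_value": res.p_value})

    add_model("global_positive", sel_pos.selected, mem, Yd)
    add_model("global_negative", sel_neg.selected, mem, Yd)
    blocks = sorted(set(r.basis_response.col_block))
    if len(blocks) > 1:
        b2 = blocks[-1]
        rows_b2 = r.basis_response.row_block.loc[rows] == b2
        y2 = Yd.loc[rows_b2.index[rows_b2]]
        for band in cfg.scale_bands:
            cols = [c for c in pos_cols
                    if r.basis_response.col_block[c] == b2
                    and r.basis_response.scale_band[c] == band]
            add_model(f"submodel_{band}", cols, mem.loc[y2.index], y2)
    r.model_table = pd.DataFrame(rows_out)


def _daily_series(values: pd.Series) -> pd.Series:
    return values.groupby(values.index.normalize()).mean()


def _stage_segments(cfg: PipelineConfig, r: PipelineResult):
    comm = r.community.observed()
    keep = comm.densities.sum(axis=1) > 0
    dens = comm.densities.loc[keep.to_numpy()]
    guild_tot = dv.CommunityMatrix(dens, comm.guilds).guild_totals()
    o2 = r.env_corrected.channel("o2_conc")
    o2_daily = _daily_series(o2.dropna())

    responses = {"oxygen": o2_daily}
    responses["total"] = _daily_series(dens.sum(axis=1))
    for g in ("mobile", "sessile"):
        if g in guild_tot.columns:
            responses[g] = _daily_series(guild_tot[g])

    t0 = min(s.index[0] for s in responses.values())
    event = cfg.event_time
    if event is None and cfg.scenario is not None:
        event = cfg.scenario.renewal_start
    event_days = ((pd.Timestamp(event) - t0).total_seconds() / 86400.0
                  if event is not None else None)

    fits, hyst = {}, {}
    for name, seriesv in responses.items():
        x = (seriesv.index - t0).total_seconds().to_numpy() / 86400.0
        best, _, trace = sg.select_k_by_aic(x, seriesv.to_numpy(),
                                            k_max=cfg.k_max, response=name)
        fits[name] = {"fit": best, "aic_trace": trace, "t0": t0}
        if event_days is not None and name in ("mobile", "sessile", "total"):
            hyst[name] = sg.compare_decline_recovery(best, event_days)
    r.segments = fits
    r.hysteresis = hyst

    if r.env_corrected is not None:
        daily = _daily_series(r.env_corrected.channel("o2_conc").dropna())
        ox_days = daily >= cfg.thresholds[0]
        try:
            r.diel = diel_contrast(r.community, oxygenated=ox_days)
        except ValueError as exc:
            logger.warning("diel contrast unavailable: %s", exc)
            r.diel = None


def _stage_trends(cfg: PipelineConfig, r: PipelineResult):
    cyc = sim.generate_trend_cycle(years=cfg.trend_years, slope=cfg.trend_slope,
                                   seed=cfg.seed + 10)
    slope, p, fit = es.decadal_trend(cyc)
    r.decadal = {"slope_ml_l_per_year": slope, "p_value": p,
                 "programmed_slope": cfg.trend_slope,
                 "adj_r2": float(fit.rsquared_adj)}
    expo = sim.generate_exposure_series(duration_slope=cfg.duration_slope,
                                        base_duration_days=cfg.duration_base,
                                        seed=cfg.seed + 11)
    r.exposure = es.threshold_durations(expo, thresholds=cfg.thresholds)


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "diversity": _stage_diversity,
    "dbmem": _stage_dbmem,
    "model": _stage_model,
    "segments": _stage_segments,
    "trends": _stage_trends,
}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 through: str = "trends") -> PipelineResult:
    """Run the pipeline up to (and including) the *through* stage.

    Stage order: simulate/load -> preprocess -> diversity -> dbmem -> model ->
    segments -> trends.  Failures raise :class:`StageError` naming the stage.
    With *outdir*, every intermediate is written plus a checksum manifest.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    r = PipelineResult(config=config)
    try:
        _load_inputs(config, r)
    except Exception as exc:  # noqa: BLE001 - rewrapped with the stage name
        raise StageError("simulate", str(exc)) from exc
    last = STAGES.index(through)
    for name in STAGES[1:last + 1]:
        try:
            _STAGE_FUNCS[name](config, r)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(name, str(exc)) from exc
    if outdir is not None:
        write_outputs(r, outdir)
    return r


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def write_outputs(r: PipelineResult, outdir: str | Path) -> dict:
    """Write every computed intermediate as CSV/JSON plus a checksum manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = r.config

    if r.env is not None:
        r.env.to_csv(out / "env_series.csv")
    if r.community is not None:
        r.community.to_csv(out / "community.csv", out / "guilds.csv")
    if r.drivers is not None:
        r.drivers.rename_axis("timestamp").to_csv(out / "drivers.csv")
    if r.summaries is not None:
        r.summaries.table().rename_axis("timestamp").to_csv(out / "env_summaries.csv")
    if r.beta is not None and r.alpha is not None:
        tab = r.alpha.join(r.beta.summary(), how="left")
        tab.rename_axis("timestamp").to_csv(out / "diversity_time.csv")
        r.beta.scbd.rename_axis("species").to_csv(out / "scbd.csv")
        _dump_json(r.beta.to_json_dict(), out / "beta.json")
    if r.basis_response is not None:
        r.basis_response.to_csv(out / "dbmem.csv")
        _dump_json(r.basis_response.sidecar(), out / "dbmem.json")
    if r.selections is not None:
        _dump_json({k: {"selected": s.selected,
                        "trace": s.trace.to_dict(orient="records")}
                    for k, s in r.selections.items()}, out / "selection.json")
    if r.varpart is not None:
        _dump_json(r.varpart.to_json_dict(), out / "varpart.json")
    if r.model_table is not None:
        r.model_table.to_csv(out / "model_summaries.csv", index=False)
    if r.time_rda is not None:
        r.time_rda.site_scores_wa.rename_axis("timestamp").to_csv(out / "turnover_sites.csv")
        r.time_rda.species_scores.rename_axis("species").to_csv(out / "turnover_species.csv")
    if r.segments is not None:
        rows = []
        for name, d in r.segments.items():
            f = d["fit"]
            _dump_json(f.to_json_dict(), out / f"segments_{name}.json")
            t0 = d["t0"]
            for (a, b), slope, (lo, hi), lab in zip(
                    f.segment_bounds(), f.slopes, f.slope_ci, f.classification):
                rows.append({
                    "response": name,
                    "period_start": (t0 + pd.Timedelta(days=a)).date().isoformat(),
                    "period_end": (t0 + pd.Timedelta(days=b)).date().isoformat(),
                    "mean_rate": slope, "ci_lower": lo, "ci_upper": hi,
                    "classification": lab,
                })
        pd.DataFrame(rows).to_csv(out / "segment_rates.csv", index=False)
        if r.hysteresis:
            _dump_json(r.hysteresis, out / "hysteresis.json")
    if r.diel is not None:
        r.diel.rename_axis("species").to_csv(out / "diel_contrast.csv")
    if r.decadal is not None:
        _dump_json(r.decadal, out / "decadal_trend.json")
    if r.exposure is not None:
        _dump_json(r.exposure.to_json_dict(), out / "exposure.json")

    cfg_dict = cfg.to_dict()
    cfg_blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "files": {name: _sha256(out / name) for name in files},
    }
    _dump_json(manifest, out / "manifest.json")
    r.manifest = manifest
    return manifest
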