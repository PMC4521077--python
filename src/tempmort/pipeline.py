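"""End-to-end orchestration: CSV inputs -> first stage -> pooling -> attribution.

The pipeline reads one CSV per location (date, deaths, tmean) plus a metadata
table, fits the location-specific quasi-Poisson DLNMs, reduces them, pools
them by multivariate REML meta-regression, derives BLUPs and per-location
minimum mortality temperatures, computes the attributable burden with Monte
Carlo empirical CIs, and writes report tables:

* a country-level table (median MMT percentile; total/cold/heat AF with eCIs);
* a component table (moderate/extreme x cold/heat AF per country);
* cached intermediates (reduced curves, meta-fit) that later stages reuse, and
  a manifest with config snapshot, seed, and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (
    COMPONENTS,
    MmtResult,
    RangeCutoffs,
    attributable_forward,
    find_mmt,
    monte_carlo_eci,
    split_components,
)
from .basis import (
    DEFAULT_EXPOSURE_PERCENTILES,
    LagBasisSpec,
    exposure_spec_from_temps,
    predict_curve,
)
from .data import LocationSeries
from .first_stage import ReducedCurve, curves_from_frame, curves_to_frame, fit_location
from .mvmeta import MetaFit, build_meta_design, compute_blups, fit_mvmeta

log = logging.getLogger("tempmort")

__all__ = [
    "AnalysisSettings",
    "PipelineConfig",
    "PipelineResult",
    "read_locations",
    "analyze_dataset",
    "run_pipeline",
    "export_figures",
]


@dataclass(frozen=True)
class AnalysisSettings:
    """Model settings; the defaults reproduce the main specification
    (exposure knots at the 10/75/90th percentiles, 21 lags with 3 log-spaced
    knots, 8 df/year, country + average temperature + range meta-predictors,
    MMT search over the 1st-99th percentiles, extreme cutoffs at 2.5/97.5)."""

    exposure_percentiles: tuple[float, ...] = DEFAULT_EXPOSURE_PERCENTILES
    max_lag: int = 21
    lag_knots: int = 3
    df_per_year: float = 8.0
    meta_country: bool = True
    meta_avg_temp: bool = True
    meta_temp_range: bool = True
    meta_method: str = "reml"
    mmt_bounds: tuple[int, int] = (1, 99)
    extra_cutoffs: tuple[float, ...] = ()
    n_sim: int = 1000
    seed: int = 12345
    direction: str = "forward"
    strict: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    data_dir: str
    metadata: str
    out_dir: str
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        settings = raw.pop("settings", {})
        for key in ("exposure_percentiles", "mmt_bounds", "extra_cutoffs"):
            if key in settings and settings[key] is not None:
                settings[key] = tuple(settings[key])
        return cls(settings=AnalysisSettings(**settings), **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    curves: list[ReducedCurve]
    metafit: MetaFit
    blups: list[ReducedCurve]
    mmts: list[MmtResult]
    cutoffs: list[RangeCutoffs]
    results: pd.DataFrame  # tidy AN/AF (+eCI) per level/name/component
    table_country: pd.DataFrame
    table_components: pd.DataFrame
    series: list[LocationSeries]
    metadata: pd.DataFrame
    failed_locations: list[str] = field(default_factory=list)


def read_locations(data_dir, metadata_path) -> tuple[list[LocationSeries], pd.DataFrame]:
    """Read and validate per-location CSVs; rows are date-sorted, gaps and
    validation problems are reported per file/row."""
    metadata = pd.read_csv(metadata_path)
    required = {"location", "country"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    errors: list[str] = []
    series: list[LocationSeries] = []
    for loc in metadata["location"]:
        path = Path(data_dir) / f"{loc}.csv"
        if not path.exists():
            errors.append(f"{loc}: missing file {path}")
            continue
        df = pd.read_csv(path)
        try:
            dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
        except (ValueError, KeyError) as exc:
            errors.append(f"{loc}: unparseable dates ({exc})")
            continue
        df = df.assign(date=dates).sort_values("date").reset_index(drop=True)
        neg = df.index[df["deaths"] < 0]
        if len(neg):
            errors.append(f"{loc}: negative death count at row {int(neg[0])}")
            continue
        gaps = df["date"].diff().dt.days.dropna()
        if (gaps > 1).any():
            log.warning("%s: %d gaps in the daily series", loc, int((gaps > 1).sum()))
        series.append(
            LocationSeries(
                location=str(loc),
                dates=pd.DatetimeIndex(df["date"]),
                deaths=df["deaths"].to_numpy(),
                tmean=df["tmean"].to_numpy(dtype=float),
            )
        )
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))
    # recompute the meta-predictors if absent
    if "avg_tmean" not in metadata.columns:
        metadata["avg_tmean"] = [s.tmean.mean() for s in series]
    if "range_tmean" not in metadata.columns:
        metadata["range_tmean"] = [s.tmean.max() - s.tmean.min() for s in series]
    return series, metadata


def _point_results(series_list, blups, mmts, cutoffs_list, countries, max_lag, direction):
    """Attribution point estimates only (no Monte Carlo), same tidy layout."""
    rows = []
    agg: dict[tuple[str, str], dict] = {}
    for s, blup, mmt, cut, country in zip(series_list, blups, mmts, cutoffs_list, countries):
        deaths = np.asarray(s.deaths, dtype=float)
        an_day, _, _ = attributable_forward(
            deaths, s.tmean, blup, mmt.mmt, max_lag=max_lag, direction=direction
        )
        comps = split_components(an_day, s.tmean, mmt.mmt, cut)
        total_deaths = float(deaths.sum())
        for comp in COMPONENTS:
            rows.append(
                {"level": "location", "name": s.location, "country": country,
                 "component": comp, "deaths": total_deaths, "an": comps[comp],
                 "af": comps[comp] / total_deaths, "af_low": np.nan, "af_high": np.nan,
                 "an_low": np.nan, "an_high": np.nan, "mmt_percentile": mmt.mmt_percentile}
            )
        for level, name in (("country", country), ("total", "Total")):
            d = agg.setdefault((level, name), {c: 0.0 for c in COMPONENTS} | {"deaths": 0.0})
            for comp in COMPONENTS:
                d[comp] += comps[comp]
            d["deaths"] += total_deaths
    for (level, name), d in agg.items():
        for comp in COMPONENTS:
            rows.append(
                {"level": level, "name": name, "country": name if level == "country" else "",
                 "component": comp, "deaths": d["deaths"], "an": d[comp],
                 "af": d[comp] / d["deaths"], "af_low": np.nan, "af_high": np.nan,
                 "an_low": np.nan, "an_high": np.nan, "mmt_percentile": None}
            )
    return pd.DataFrame(rows)


def analyze_dataset(
    series_list: list[LocationSeries],
    metadata: pd.DataFrame,
    settings: AnalysisSettings = AnalysisSettings(),
    curves: list[ReducedCurve] | None = None,
    metafit: MetaFit | None = None,
) -> PipelineResult:
    """Run the full two-stage analysis on in-memory data.

    ``curves``/``metafit`` may be supplied to resume from cached intermediates.
    """
    lspec = LagBasisSpec(max_lag=settings.max_lag, n_knots=settings.lag_knots)
    failed: list[str] = []
    if curves is None:
        curves = []
        kept = []
        for s in series_list:
            espec = exposure_spec_from_temps(s.tmean, settings.exposure_percentiles)
            try:
                _, curve, _ = fit_location(
                    s.dates, s.deaths, s.tmean, espec, lspec,
                    df_per_year=settings.df_per_year, location=s.location,
                )
            except Exception as exc:
                if settings.strict:
                    raise RuntimeError(f"first stage failed for {s.location}: {exc}") from exc
                log.warning("excluding %s: first stage failed (%s)", s.location, exc)
                failed.append(s.location)
                continue
            curves.append(curve)
            kept.append(s.location)
        series_list = [s for s in series_list if s.location not in failed]
        metadata = metadata[metadata["location"].isin(kept)].reset_index(drop=True)

    design = build_meta_design(
        metadata,
        use_country=settings.meta_country,
        use_avg_temp=settings.meta_avg_temp,
        use_temp_range=settings.meta_temp_range,
    )
    if metafit is None:
        metafit = fit_mvmeta(curves, design, method=settings.meta_method)
    blups = compute_blups(metafit, curves, design)

    mmts, cutoffs_list = [], []
    for s, blup in zip(series_list, blups):
        mmts.append(find_mmt(blup, s.tmean, *settings.mmt_bounds))
        cutoffs_list.append(RangeCutoffs.from_temps(s.tmean, extra=settings.extra_cutoffs))

    countries = list(metadata["country"])
    if settings.n_sim >= 100:
        results = monte_carlo_eci(
            series_list, blups, mmts, cutoffs_list, countries=countries,
            n_sim=settings.n_sim, seed=settings.seed, max_lag=settings.max_lag,
            direction=settings.direction,
        )
    else:
        results = _point_results(
            series_list, blups, mmts, cutoffs_list, countries,
            settings.max_lag, settings.direction,
        )

    table_country = _country_table(results, mmts, countries)
    table_components = _component_table(results)
    return PipelineResult(
        curves=curves, metafit=metafit, blups=blups, mmts=mmts, cutoffs=cutoffs_list,
        results=results, table_country=table_country, table_components=table_components,
        series=series_list, metadata=metadata, failed_locations=failed,
    )


def _country_table(results: pd.DataFrame, mmts, countries) -> pd.DataFrame:
    """Country rows + Total: median MMT percentile across the country's
    locations (unweighted), and total/cold/heat AF with eCIs, in percent."""
    pct = pd.DataFrame({"country": countries,
                        "mmt_percentile": [m.mmt_percentile for m in mmts]})
    med = pct.groupby("country")["mmt_percentile"].median()
    rows = []
    pooled = results[results["level"].isin(["country", "total"])]
    for (level, name), grp in pooled.groupby(["level", "name"], sort=False):
        wide = grp.set_index("component")
        row = {"country": name,
               "mmt_percentile": float(pct["mmt_percentile"].median())
               if level == "total" else float(med[name])}
        for comp in ("total", "cold", "heat"):
            row[f"af_{comp}_pct"] = 100 * wide.loc[comp, "af"]
            row[f"af_{comp}_low_pct"] = 100 * wide.loc[comp, "af_low"]
            row[f"af_{comp}_high_pct"] = 100 * wide.loc[comp, "af_high"]
        row["_order"] = 1 if level == "total" else 0
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["_order", "country"]).drop(columns="_order")
    return out.reset_index(drop=True)


def _component_table(results: pd.DataFrame) -> pd.DataFrame:
    """Moderate/extreme x cold/heat AF (percent) per country + Total."""
    comps = ["extreme_cold", "moderate_cold", "moderate_heat", "extreme_heat"]
    pooled = results[results["level"].isin(["country", "total"])]
    rows = []
    for (level, name), grp in pooled.groupby(["level", "name"], sort=False):
        wide = grp.set_index("component")
        row = {"country": name}
        for comp in comps:
            row[f"af_{comp}_pct"] = 100 * wide.loc[comp, "af"]
        row["_order"] = 1 if level == "total" else 0
        rows.append(row)
    return (pd.DataFrame(rows).sort_values(["_order", "country"])
            .drop(columns="_order").reset_index(drop=True))


def _metafit_to_json(fit: MetaFit) -> dict:
    return {
        "beta": fit.beta.tolist(),
        "b": fit.b.tolist(),
        "V_beta": fit.V_beta.tolist(),
        "Psi": fit.Psi.tolist(),
        "loglik": fit.loglik,
        "method": fit.method,
        "Q": fit.Q,
        "Q_df": fit.Q_df,
        "Q_pvalue": fit.Q_pvalue,
        "I2": fit.I2,
        "design_names": fit.design_names,
        "converged": fit.converged,
        "n_restarts_used": fit.n_restarts_used,
    }


def _metafit_from_json(raw: dict) -> MetaFit:
    return MetaFit(
        beta=np.asarray(raw["beta"]), b=np.asarray(raw["b"]),
        V_beta=np.asarray(raw["V_beta"]), Psi=np.asarray(raw["Psi"]),
        loglik=raw["loglik"], method=raw["method"], Q=raw["Q"], Q_df=raw["Q_df"],
        Q_pvalue=raw["Q_pvalue"], I2=raw["I2"], design_names=raw["design_names"],
        converged=raw["converged"], n_restarts_used=raw["n_restarts_used"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full run from CSV inputs to report tables, with resumable intermediates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, metadata = read_locations(config.data_dir, config.metadata)
    log.info("read %d locations", len(series))

    curves_path = out / "reduced_curves.csv"
    metafit_path = out / "metafit.json"
    curves = metafit = None
    if curves_path.exists():
        log.info("reusing cached reduced curves from %s", curves_path)
        # round_trip parsing: the cached %.17g floats must reload bit-exactly
        curves = curves_from_frame(pd.read_csv(curves_path, float_precision="round_trip"))
        if metafit_path.exists():
            log.info("reusing cached meta-fit from %s", metafit_path)
            metafit = _metafit_from_json(json.loads(metafit_path.read_text()))

    result = analyze_dataset(series, metadata, config.settings,
                             curves=curves, metafit=metafit)

    curves_to_frame(result.curves).to_csv(curves_path, index=False,
                                          float_format="%.17g")
    metafit_path.write_text(json.dumps(_metafit_to_json(result.metafit), indent=1))
    result.results.to_csv(out / "attribution_results.csv", index=False)
    result.table_country.to_csv(out / "table_country.csv", index=False)
    result.table_components.to_csv(out / "table_components.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.settings.seed,
        "failed_locations": result.failed_locations,
        "checksums": {
            p.name: _sha256(p)
            for p in [curves_path, metafit_path, out / "attribution_results.csv",
                      out / "table_country.csv", out / "table_components.csv"]
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def export_figures(result: PipelineResult, out_dir, plot: bool = True) -> list[Path]:
    """Per-location overall cumulative RR curve CSVs (temperature, logrr, rr,
    rr_low, rr_high) with MMT and extreme-percentile markers; optional plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for s, blup, mmt, cut in zip(result.series, result.blups, result.mmts, result.cutoffs):
        grid = np.linspace(s.tmean.min(), s.tmean.max(), 101)
        grid = np.unique(np.append(grid, mmt.mmt))
        curve = predict_curve(blup.eta, blup.vcov, blup.espec, at=grid, ref=mmt.mmt)
        curve = curve.drop(columns="se")
        path = out_dir / f"curve_{s.location}.csv"
        curve.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            ax.fill_between(curve["temperature"], curve["rr_low"], curve["rr_high"],
                            color="0.8")
            ax.plot(curve["temperature"], curve["rr"], color="firebrick")
            ax.axvline(mmt.mmt, color="0.4")
            for p in (2.5, 97.5):
                ax.axvline(cut.at(p), color="0.4", linestyle="--")
            ax.axhline(1.0, color="0.6", linewidth=0.5)
            ax.set_xlabel("temperature (degC)")
            ax.set_ylabel("RR")
            ax.set_title(s.location)
            fig.tight_layout()
            fig.savefig(out_dir / f"curve_{s.location}.png", dpi=100)
            plt.close(fig)
    return written
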