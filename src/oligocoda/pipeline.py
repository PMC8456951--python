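"""End-to-end pipeline: counts → subcomposition → imputation → geometry,
ordination and per-season regression, with every product written to disk.

Stage order follows the analysis workflow: build the subcomposition of
the dominant oligotypes, drop low-depth samples, impute zeros within
seasons, then compute the evenness (AI2) series, pairwise Aitchison
distances, the variation matrix, the covariance biplot, ilr coordinates
on the chosen SBP, and the per-season forward-selected multivariate
regression (plus a temperature-only restricted model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .balances import SBP, contrast_matrix, ilr, mvco_sbp, sbp_from_variation
from .geometry import (
    CompositionMatrix,
    ai2_series,
    pairwise_distance_matrix,
    variation_matrix,
)
from .io import (
    RunConfig,
    read_count_table,
    read_env_table,
    write_composition_matrix,
    write_table,
)
from .ordination import centred_clr_matrix, covariance_biplot
from .preprocess import filter_low_depth, impute_zeros, season_series, subcomposition
from .regression import (
    FittedSeries,
    RegressionFit,
    fit_season_models,
    predict_series,
    weekly_average_light,
)

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage for context."""


@dataclass
class PipelineResult:
    config: RunConfig
    compositions: CompositionMatrix
    ilr_coords: pd.DataFrame
    ai2: pd.DataFrame
    distance_matrix: pd.DataFrame
    variation: pd.DataFrame
    biplot_rays: pd.DataFrame
    biplot_scores: pd.DataFrame
    fits: dict[str, RegressionFit]
    fitted: FittedSeries
    temperature_only: dict[str, RegressionFit] | None
    fitted_temperature_only: FittedSeries | None
    log: list[str] = field(default_factory=list)


def _resolve_sbp(config: RunConfig, X: CompositionMatrix) -> SBP:
    src = config.sbp_source
    if src == "builtin:mvco":
        return mvco_sbp()
    if src == "from-variation":
        return sbp_from_variation(variation_matrix(X), linkage=config.sbp_linkage)
    return SBP.from_tsv(src)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the report bundle under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    log: list[str] = [f"oligocoda {__version__} config_hash={h}"]

    def stage(name):
        log.append(f"stage: {name}")
        logger.info("pipeline stage: %s", name)

    try:
        stage("read inputs")
        table = read_count_table(config.counts_path)
        env, env_dates = read_env_table(config.env_path)
        unmatched = [s for s in env.index if s not in table.counts.index]
        if unmatched:
            log.append(f"env rows without counts (ignored): {unmatched}")

        stage("subcomposition")
        keep = [p for p in config.keep_parts if p in table.counts.columns]
        if list(keep) != list(config.keep_parts):
            missing = set(config.keep_parts) - set(keep)
            raise StageError(f"subcomposition: parts absent from counts: {sorted(missing)}")
        table = subcomposition(table, keep)

        stage("low-depth filter")
        before = set(table.sample_ids)
        table = filter_low_depth(table, config.min_reads)
        removed = sorted(before - set(table.sample_ids))
        log.append(f"low-depth samples removed (min_reads={config.min_reads}): {removed}")

        stage("zero imputation")
        X, report = impute_zeros(
            table, strength=config.imputation_strength, return_report=True
        )
        log.append(f"zeros replaced per sample: {report.per_sample['n_zeros'].sum()} total")
        log.extend(report.warnings)

        stage("weekly light")
        if config.daily_light_path:
            daily, _ = read_env_table(config.daily_light_path)
            series = daily.iloc[:, 0]
            series.index = pd.to_datetime(series.index)
            env["weekly_light"] = [
                weekly_average_light(series, X.dates.loc[s])[0]
                if s in X.dates.index
                else float("nan")
                for s in env.index
            ]

        stage("geometry summaries")
        seasons = season_series(X.dates)
        ai2 = ai2_series(X)
        dm = pairwise_distance_matrix(X, seasons=seasons)
        T = variation_matrix(X)

        stage("ordination")
        Z = centred_clr_matrix(X)
        biplot = covariance_biplot(Z, X.n)

        stage("balances")
        sbp = _resolve_sbp(config, X)
        coords = ilr(X, sbp)

        stage("seasonal regression")
        env_use = env.loc[[s for s in X.sample_ids if s in env.index]]
        skipped_env = [s for s in X.sample_ids if s not in env.index]
        if skipped_env:
            log.append(f"samples without env data (excluded from regression): {skipped_env}")
        fits = fit_season_models(
            coords, env_use, X.dates.loc[env_use.index], alpha=config.alpha
        )
        fitted = predict_series(fits, env_use, X.dates.loc[env_use.index], sbp,
                                observed=coords)
        for s, f in fits.items():
            log.append(
                f"season {s}: selected {f.selected} "
                f"(overall Λ={f.overall.wilks_lambda:.3g})" if f.overall else
                f"season {s}: no variable selected"
            )
        t_only = fitted_t = None
        if config.temperature_only:
            t_only = fit_season_models(
                coords, env_use, X.dates.loc[env_use.index],
                alpha=config.alpha, variables=["temperature"],
            )
            fitted_t = predict_series(t_only, env_use, X.dates.loc[env_use.index],
                                      sbp, observed=coords)

        stage("write outputs")
        write_composition_matrix(X, out / "imputed_compositions.tsv", h)
        write_table(coords, out / "ilr_coordinates.tsv", h)
        write_table(ai2, out / "ai2_series.tsv", h)
        write_table(dm, out / "aitchison_distances.tsv", h)
        write_table(T.values, out / "variation_matrix.tsv", h, index_label="part")
        write_table(contrast_matrix(sbp).to_frame(), out / "contrast_matrix.tsv", h,
                    index_label="balance")
        write_table(biplot.ray_coords, out / "biplot_rays.tsv", h, index_label="part")
        write_table(biplot.sample_scores, out / "biplot_scores.tsv", h)
        write_table(fitted.compositions, out / "fitted_compositions.tsv", h)
        if fitted_t is not None:
            write_table(fitted_t.compositions,
                        out / "fitted_compositions_temperature_only.tsv", h)
        fit_report = {
            "package": f"oligocoda {__version__}",
            "config_hash": h,
            "seasons": {s: f.to_report(sbp) for s, f in fits.items()},
        }
        if t_only is not None:
            fit_report["temperature_only"] = {
                s: f.to_report(sbp) for s, f in t_only.items()
            }
        (out / "fit_report.json").write_text(json.dumps(fit_report, indent=2))
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
    except StageError:
        raise
    except Exception as exc:  # surface the failing stage
        raise StageError(f"{log[-1]}: {exc}") from exc

    return PipelineResult(
        config=config,
        compositions=X,
        ilr_coords=coords,
        ai2=ai2,
        distance_matrix=dm,
        variation=T.values,
        biplot_rays=biplot.ray_coords,
        biplot_scores=biplot.sample_scores,
        fits=fits,
        fitted=fitted,
        temperature_only=t_only,
        fitted_temperature_only=fitted_t,
        log=log,
    )
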