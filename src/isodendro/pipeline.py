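"""End-to-end pipeline: simulate → chronology → correct → calibrate → extremes.

Stages run in a fixed order, each writing its intermediate CSV (with the
config hash and seed in the header) so that any downstream stage can be
re-run from saved intermediates with identical results.  No stage mutates
its inputs; failures propagate with the stage name attached.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import io
from .chronology import build_chronology, summary_stats, trim_juvenile
from .config import PipelineConfig
from .containers import AtmosphericRecord, ClimateTable
from .errors import IsodendroError
from .extremes import detect_extremes, hamming_smooth, match_volcanic, period_contrast
from .suess import correct_suess
from .synthetic import default_eruption_catalog, generate_dataset
from .transfer import apply_transfer, calibrate_full, correlate_monthly

log = logging.getLogger("isodendro")


class StageError(IsodendroError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(func):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = func(*args, **kwargs)
            except IsodendroError as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc
            log.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return run
    return wrap


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and write all intermediates to ``outdir``.

    Returns a dict of in-memory results: the chronology, the corrected
    series, the correlation table, the calibration report, the
    reconstruction, the extremes table and the volcanic matches, plus the
    summary statistics block.  Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_sha256": config.hash(), "seed": config.seed}
    config.to_yaml(outdir / "config.yaml")

    # -- inputs: load or simulate ------------------------------------------
    @_stage("simulate")
    def load_inputs():
        truth = None
        if config.tree_csv is None:
            dataset = generate_dataset(
                year_range=config.year_range,
                n_trees=config.n_trees,
                target=(config.target_variable, config.target_months),
                transfer_slope=config.transfer_slope,
                tree_sd=config.tree_sd,
                noise_sd=config.noise_sd,
                juvenile_amplitude=config.juvenile_amplitude,
                juvenile_length=config.juvenile_exclude,
                ar1_coeff=config.ar1_coeff,
                innovation_sd=config.innovation_sd,
                volcanic_cooling=config.volcanic_cooling,
                seed=config.seed,
            )
            climate, atm, trees, truth = (
                dataset.climate, dataset.atm, dataset.trees, dataset.truth)
        else:
            trees = io.read_tree_csv(config.tree_csv)
            climate = io.read_climate_csv(config.climate_csv)
            atm = io.read_atm_csv(config.atm_csv)
        if config.climate_csv is not None and config.tree_csv is None:
            climate = io.read_climate_csv(config.climate_csv)
        if config.atm_csv is not None and config.tree_csv is None:
            atm = io.read_atm_csv(config.atm_csv)
        catalog = (io.read_eruption_csv(config.eruption_csv)
                   if config.eruption_csv else default_eruption_catalog())
        io.write_tree_csv(trees, outdir / "trees.csv", meta)
        io.write_climate_csv(climate, outdir / "climate.csv", meta)
        io.write_atm_csv(atm, outdir / "atm.csv", meta)
        io.write_csv(catalog, outdir / "eruptions.csv", meta)
        return climate, atm, trees, catalog, truth

    climate, atm, trees, catalog, truth = load_inputs()

    # -- chronology ---------------------------------------------------------
    @_stage("chronology")
    def stage_chronology():
        trimmed = [trim_juvenile(t, config.juvenile_exclude) for t in trees]
        chron = build_chronology(trimmed, config.min_replication)
        io.write_chronology_csv(chron, outdir / "chronology.csv", meta)
        return chron

    chron = stage_chronology()

    # -- Suess correction ---------------------------------------------------
    @_stage("correct")
    def stage_correct():
        corrected, delta = correct_suess(chron.mean, atm, config.suess_ref_year)
        io.write_annual_csv(corrected, outdir / "chronology_corrected.csv", meta,
                            value_column="corrected")
        io.write_annual_csv(delta, outdir / "suess_correction.csv", meta,
                            value_column="delta_applied")
        return corrected

    proxy = stage_correct()

    # -- correlation screening ---------------------------------------------
    @_stage("correlate")
    def stage_correlate():
        period = (min(config.verification_period[0], config.calibration_period[0]),
                  max(config.verification_period[1], config.calibration_period[1]))
        table = correlate_monthly(proxy, climate, period=period)
        io.write_csv(table, outdir / "correlations.csv", meta)
        return table

    correlations = stage_correlate()

    # -- calibration / verification ----------------------------------------
    @_stage("calibrate")
    def stage_calibrate():
        stat = "sum" if config.target_variable == "precipitation" else "mean"
        target = climate.aggregate(config.target_variable,
                                   list(config.target_months), stat=stat)
        report = calibrate_full(
            proxy, target,
            config.calibration_period, config.verification_period,
            n_bootstrap=config.n_bootstrap, seed=config.seed,
            proxy_name=chron.scale, target_name=target.name,
        )
        io.write_csv(report.to_frame(), outdir / "calibration.csv", meta)
        return report

    report = stage_calibrate()

    # -- reconstruction -----------------------------------------------------
    @_stage("reconstruct")
    def stage_reconstruct():
        rec = apply_transfer(report.final_model, proxy)
        out = rec.reset_index(names="year")
        io.write_csv(out, outdir / "reconstruction.csv", meta)
        return rec

    reconstruction = stage_reconstruct()

    # -- smoothing ----------------------------------------------------------
    @_stage("smooth")
    def stage_smooth():
        smoothed = hamming_smooth(reconstruction["reconstruction"], config.smooth_window)
        io.write_annual_csv(smoothed, outdir / "reconstruction_smoothed.csv", meta,
                            value_column="smoothed")
        return smoothed

    smoothed = stage_smooth()

    # -- extremes and volcanic matching -------------------------------------
    @_stage("extremes")
    def stage_extremes():
        table = detect_extremes(reconstruction["reconstruction"],
                                thresholds=config.sigma_thresholds)
        io.write_csv(table, outdir / "extremes.csv", meta)
        negative = table[table["sign"] == "negative"]
        matched = match_volcanic(negative, catalog,
                                 min_vei=config.min_vei, lag_window=config.lag_window)
        io.write_csv(matched["matches"], outdir / "volcanic_matches.csv", meta)
        return table, matched

    extreme_table, volcanic = stage_extremes()

    # -- summary ------------------------------------------------------------
    stats = summary_stats(chron)
    rec_stats = summary_stats(reconstruction["reconstruction"])
    mid = (config.year_range[0] + config.year_range[1]) // 2
    contrast = period_contrast(reconstruction["reconstruction"],
                               (config.year_range[0], mid),
                               (mid + 1, config.year_range[1]))
    summary = {
        "chronology": stats,
        "reconstruction": rec_stats,
        "verification": report.forward_stats.as_dict(),
        "reverse_verification": report.reverse_stats.as_dict(),
        "final_model": {
            "slope": report.final_model.slope,
            "intercept": report.final_model.intercept,
            "r": report.final_model.r,
            "r2": report.final_model.r2,
            "rmse": report.final_model.residual_rmse,
            "percentiles": report.coefficient_percentiles,
        },
        "period_contrast": contrast,
        "n_extremes": len(extreme_table),
        "volcanic": {k: v for k, v in volcanic.items() if k != "matches"},
    }
    if truth is not None:
        summary["truth"] = truth.as_dict()
    _write_summary(summary, outdir / "summary.txt", meta)

    return {
        "climate": climate, "atm": atm, "trees": trees, "catalog": catalog,
        "truth": truth, "chronology": chron, "proxy": proxy,
        "correlations": correlations, "report": report,
        "reconstruction": reconstruction, "smoothed": smoothed,
        "extremes": extreme_table, "volcanic": volcanic, "summary": summary,
    }


def _write_summary(summary: dict, path, meta: dict) -> None:
    lines = [f"# isodendro summary | config_sha256={meta['config_sha256']} "
             f"| seed={meta['seed']}"]

    def emit(prefix, obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                emit(f"{prefix}{k}.", v) if isinstance(v, dict) else lines.append(
                    f"{prefix}{k} = {v}")
        else:
            lines.append(f"{prefix} = {obj}")

    emit("", summary)
    Path(path).write_text("\n".join(lines) + "\n")
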