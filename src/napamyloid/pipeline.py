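"""End-to-end orchestration: simulate -> features -> register -> parameter
statistics -> waveform statistics, with one seed and one config."""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import param_stats as pstats
from . import registration as reg
from . import waveform_stats as wstats
from .config import RunConfig, config_as_dict, config_hash
from .errors import InsufficientDataError, NapamyloidError
from .simulate import WaveformDataset, simulate_experiment, write_dataset

__all__ = ["run_all", "StageError"]

log = logging.getLogger("napamyloid")


class StageError(NapamyloidError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_all(
    config: RunConfig,
    seed: int,
    out_dir: str | Path,
    *,
    waveform_expttimes: Sequence[int] | None = None,
    write_waveforms: bool = False,
    make_figures: bool = True,
) -> dict[str, Any]:
    """Run every stage and write a JSON + Markdown report bundle.

    Outputs land under ``out_dir``: features.csv, registration_params.csv,
    anova.csv, regression.csv, rm_anova.csv, count_table_*.csv,
    correlation_map.csv, report.json, report.md and (optionally) figures.
    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    report: dict[str, Any] = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config_as_dict(config),
    }

    # ----- simulate ------------------------------------------------------
    stage = "simulate"
    try:
        log.info("simulating %d nerves x %d segments", design.n_nerves, design.n_segments)
        dataset = simulate_experiment(
            design, config.protocol, config.population, config.drug, seed
        )
        if write_waveforms:
            write_dataset(dataset, out / "waveforms.csv",
                          config=config_as_dict(config), seed=seed)
        report["simulate"] = {
            "n_records": len(dataset),
            "n_nerves": design.n_nerves,
            "n_segments": design.n_segments,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ----- features ------------------------------------------------------
    stage = "features"
    try:
        table = feat.extract_feature_table(dataset, config.marking, design)
        table = feat.normalize_to_baseline(
            table, design.baseline_segment, design.analysis_segments
        )
        table.to_csv(out / "features.csv", index=False, float_format="%.10g")
        report["features"] = {
            "n_rows": len(table),
            "n_missing": int(table["normalized_value"].isna().sum()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ----- registration --------------------------------------------------
    stage = "registration"
    try:
        weights = reg.build_weights(
            dataset.window_samples,
            config.registration.zero_prefix,
            config.registration.plateau_end,
            config.registration.taper_tau,
        )
        registered, params = reg.register_experiment(
            dataset,
            config.registration.template_nerve,
            fit_segment=config.registration.fit_segment,
            weights=weights,
            ftol=config.registration.ftol,
            max_iter=config.registration.max_iter,
        )
        params.to_csv(out / "registration_params.csv", index=False,
                      float_format="%.10g")
        report["registration"] = {
            "n_fits": len(params),
            "median_objective": float(params["objective"].median()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ----- parameter statistics -----------------------------------------
    stage = "param_stats"
    try:
        report["param_stats"] = _param_stats_stage(table, config, out)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ----- waveform statistics ------------------------------------------
    stage = "waveform_stats"
    try:
        report["waveform_stats"] = _waveform_stage(
            registered, dataset, config, out, waveform_expttimes
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    report["summary"] = _summarize(report, config)

    if make_figures:
        try:
            _figures(table, registered, config, out)
        except Exception as exc:  # noqa: BLE001
            log.warning("figure generation failed: %s", exc)

    payload = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    (out / "report.md").write_text(_markdown(payload))
    return report


def _param_stats_stage(
    table: pd.DataFrame, config: RunConfig, out: Path
) -> dict[str, Any]:
    scfg = config.stats
    design = config.design
    endpoint = design.n_segments
    anova_rows, reg_rows = [], []
    for parameter in feat.PARAMETERS:
        try:
            a = pstats.endpoint_anova(table, parameter, expttime=endpoint)
            k = pstats.endpoint_kruskal(table, parameter, expttime=endpoint)
            anova_rows.append({
                "parameter": parameter, "F": a.F, "df_between": a.df_between,
                "df_within": a.df_within, "p_anova": a.p,
                "H": k.H, "df_kw": k.df, "p_kw": k.p,
                "significant": a.p < scfg.per_test_alpha_anova,
            })
        except InsufficientDataError:
            continue
        try:
            q = pstats.quadratic_regression(table, parameter, expttime=endpoint)
            for row in q.itertuples(index=False):
                reg_rows.append({"parameter": parameter, **row._asdict()})
        except InsufficientDataError:
            pass
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(out / "anova.csv", index=False, float_format="%.10g")
    pd.DataFrame(reg_rows).to_csv(out / "regression.csv", index=False,
                                  float_format="%.10g")

    rm_tables = []
    rm_out: dict[str, Any] = {}
    for within in ("isi", "current"):
        try:
            rm = pstats.repeated_measures(table, within, cfg=scfg)
        except (InsufficientDataError, NapamyloidError) as exc:
            rm_out[within] = {"error": str(exc)}
            continue
        rm = rm.assign(within_factor=within)
        rm_tables.append(rm)
        rm_out[within] = {
            row["effect"]: {"F": row["F"], "p": row["p"], "df": row["df"]}
            for _, row in rm.iterrows() if np.isfinite(row["F"])
        }
    if rm_tables:
        pd.concat(rm_tables).to_csv(out / "rm_anova.csv", index=False,
                                    float_format="%.10g")

    counts_out = {}
    for stim_set in (0, 1):
        screen = pstats.spearman_screen(table, stim_set, scfg)
        for mode in ("fdr", "raw_p"):
            res = pstats.build_count_table(table, stim_set, scfg, mode, screen=screen)
            res.counts.to_csv(out / f"count_table_set{stim_set}_{mode}.csv")
            counts_out[f"set{stim_set}_{mode}"] = {
                "total": int(res.counts.to_numpy().sum()),
                "chi2": res.chi2.chi2,
                "df": res.chi2.df,
                "p": res.chi2.p,
                "applicable": res.chi2.applicable,
                "row_totals": {
                    p: int(v) for p, v in res.counts.sum(axis=1).items()
                },
            }
    return {
        "endpoint": anova.to_dict("records"),
        "regression": reg_rows,
        "repeated_measures": rm_out,
        "count_tables": counts_out,
    }


def _waveform_stage(
    registered: WaveformDataset,
    raw: WaveformDataset,
    config: RunConfig,
    out: Path,
    expttimes: Sequence[int] | None,
) -> dict[str, Any]:
    scfg = config.stats
    design = config.design
    if expttimes is None:
        expttimes = list(design.analysis_segments)
    final = max(expttimes)
    template_nerve = (
        config.registration.template_nerve
        or sorted(raw.keys["nerve"].unique())[0]
    )
    combos = registered.keys[["stim_set", "seq"]].drop_duplicates()
    map_frames, out_stimuli = [], {}
    for stim_set, seq in combos.itertuples(index=False):
        maps = wstats.correlation_maps(registered, stim_set, seq, expttimes, scfg)
        final_map = next(m for m in maps if m.expttime == final)
        map_frames.append(final_map.to_frame())
        template = raw.get(template_nerve, config.registration.fit_segment,
                           stim_set, seq)
        entry: dict[str, Any] = {
            "n_sig_raw_final": int(final_map.sig_raw.sum()),
            "n_sig_fdr_final": int(final_map.sig_fdr.sum()),
        }
        wvec = reg.build_weights(
            registered.window_samples,
            config.registration.zero_prefix,
            config.registration.plateau_end,
            config.registration.taper_tau,
        ).values
        try:
            prof = wstats.r_vs_voltage_profile(final_map, template, weights=wvec)
            entry["profile_rho"] = prof.rho
            entry["profile_p"] = prof.p
        except InsufficientDataError as exc:
            entry["profile_error"] = str(exc)
        counts = wstats.significance_count_profile(maps)
        try:
            chi2, _ = wstats.timepoint_chi2(counts)
            entry["timepoint_chi2"] = {
                "chi2": chi2.chi2, "df": chi2.df, "p": chi2.p,
                "applicable": chi2.applicable,
            }
        except InsufficientDataError as exc:
            entry["timepoint_chi2"] = {"error": str(exc)}
        out_stimuli[f"set{stim_set}_seq{seq}"] = entry
    pd.concat(map_frames).to_csv(out / "correlation_map.csv", index=False,
                                 float_format="%.10g")
    return {"final_expttime": final, "stimuli": out_stimuli}


def _summarize(report: dict[str, Any], config: RunConfig) -> dict[str, Any]:
    scfg = config.stats
    endpoint = report["param_stats"]["endpoint"]
    endpoint_sig = [r["parameter"] for r in endpoint if r["significant"]]
    count_totals = {
        k: v["total"] for k, v in report["param_stats"]["count_tables"].items()
    }
    fdr_total = sum(v for k, v in count_totals.items() if k.endswith("_fdr"))
    wave_sig = sum(
        v.get("n_sig_raw_final", 0)
        for v in report["waveform_stats"]["stimuli"].values()
    )
    any_effect = bool(endpoint_sig) or fdr_total > 0
    return {
        "per_test_alpha_anova": scfg.per_test_alpha_anova,
        "endpoint_significant_parameters": endpoint_sig,
        "count_table_totals": count_totals,
        "waveform_raw_sig_points_final": int(wave_sig),
        "significant_concentration_effect": any_effect,
    }


def _figures(
    table: pd.DataFrame,
    registered: WaveformDataset,
    config: RunConfig,
    out: Path,
) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    endpoint = config.design.n_segments

    # dose-response of the endpoint amplitude
    sub = table[
        (table["parameter"] == "peak_to_peak_amplitude")
        & (table["expttime"] == endpoint)
        & (table["stim_set"] == 1) & (table["seq"] == 1)
    ]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    means = sub.groupby("conc")["normalized_value"].median()
    iqr_lo = sub.groupby("conc")["normalized_value"].quantile(0.25)
    iqr_hi = sub.groupby("conc")["normalized_value"].quantile(0.75)
    ax.errorbar(means.index, means, yerr=[means - iqr_lo, iqr_hi - means],
                fmt="o-", capsize=3)
    ax.set_xlabel("concentration ordinal")
    ax.set_ylabel("normalized peak-to-peak amplitude")
    fig.tight_layout()
    fig.savefig(fig_dir / "dose_response.png", dpi=120)
    plt.close(fig)

    # amplitude time-course per concentration (longest-interval stimulus)
    sub = table[
        (table["parameter"] == "peak_to_peak_amplitude")
        & (table["stim_set"] == 1) & (table["seq"] == 1)
    ]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for conc, g in sub.groupby("conc"):
        tc = g.groupby("expttime")["normalized_value"].mean()
        ax.plot(tc.index, tc.to_numpy(), label=f"conc {conc}")
    ax.set_xlabel("segment (EXPTTIME)")
    ax.set_ylabel("normalized amplitude")
    ax.legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(fig_dir / "time_course.png", dpi=120)
    plt.close(fig)

    # mean registered waveform per concentration at the final segment
    final = registered.select(expttime=endpoint, stim_set=1, seq=1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for conc in sorted(final.keys["conc"].unique()):
        sel = final.select(conc=conc)
        ax.plot(np.mean(sel.samples, axis=0), lw=0.8, label=f"conc {conc}")
    ax.set_xlabel("sample")
    ax.set_ylabel("registered voltage")
    ax.legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(fig_dir / "registered_waveforms.png", dpi=120)
    plt.close(fig)


def _markdown(report: dict[str, Any]) -> str:
    s = report["summary"]
    lines = [
        "# Pipeline report",
        "",
        f"- seed: {report['seed']}",
        f"- config hash: {report['config_hash']}",
        f"- records simulated: {report['simulate']['n_records']}",
        f"- per-test ANOVA level: {s['per_test_alpha_anova']}",
        "",
        "## Concentration effect",
        "",
    ]
    if s["significant_concentration_effect"]:
        lines.append(
            "Significant concentration effects detected for: "
            + ", ".join(s["endpoint_significant_parameters"] or ["(count tables only)"])
        )
    else:
        lines.append("No significant concentration effect at any stage.")
    lines += [
        "",
        "## Count-table totals",
        "",
    ]
    for k, v in s["count_table_totals"].items():
        lines.append(f"- {k}: {v}")
    lines += [
        "",
        f"Waveform raw-p significant points at final segment: "
        f"{s['waveform_raw_sig_points_final']}",
        "",
    ]
    return "\n".join(lines)
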