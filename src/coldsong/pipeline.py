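"""End-to-end orchestration: simulate, run stages, emit report tables.

Each stage reads/writes plain CSV (plus WAV audio for songs), records every
design-decision parameter it actually used, and stamps outputs with a config
hash so a rerun with identical configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coldsong import bootstrap as bt
from coldsong import cold_tolerance as ct
from coldsong import mating, song, synthetic

log = logging.getLogger("coldsong")


@dataclass
class PipelineConfig:
    input_dir: Path = Path("data")
    output_dir: Path = Path("results")
    seed: int = 0
    burst_gap_ms: float = song.DEFAULT_BURST_GAP_MS
    threshold_k: float = 8.0
    refractory_ms: float = song.DEFAULT_REFRACTORY_MS
    continuity: bool = True
    slope_override: float | None = None
    min_ipi: int = song.MIN_IPI_RETENTION
    bootstrap: bt.BootstrapSpec = field(default_factory=bt.BootstrapSpec)

    @property
    def slope(self) -> float:
        return self.slope_override if self.slope_override is not None \
            else song.DEFAULT_IPI_TEMP_SLOPE

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["output_dir"] = str(self.output_dir)
        return d

    @property
    def config_hash(self) -> str:
        # parameters and seed only: the same analysis in a different
        # directory is still the same analysis
        params = {k: v for k, v in self.to_dict().items()
                  if k not in ("input_dir", "output_dir")}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        df.to_csv(fh, index=False)


def read_stage_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate_stage(config: PipelineConfig,
                       n_songs: int = 148,
                       write_audio: bool = True) -> dict[str, Path]:
    """Write synthetic survival/courtship CSVs and song WAVs + metadata."""
    out = Path(config.input_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    lines = synthetic.DEFAULT_LINES
    surv_params = synthetic.SurvivalSimParams(
        lines=lines,
        basal_survival_by_line={l: float(p) for l, p in
                                zip(lines, rng.uniform(0.2, 0.8, len(lines)))},
        rch_effect_by_line={l: float(e) for l, e in
                            zip(lines, rng.uniform(0.0, 0.4, len(lines)))},
        seed=int(rng.integers(2 ** 31)))
    survival = synthetic.gen_survival_table(surv_params)
    court_params = synthetic.CourtshipSimParams(
        lines=lines, seed=int(rng.integers(2 ** 31)))
    courtship = synthetic.gen_courtship_table(court_params)
    paths = {"survival": out / "survival.csv",
             "courtship": out / "courtship.csv",
             "song_metadata": out / "song_metadata.csv"}
    _write_csv(survival, paths["survival"], config)
    _write_csv(courtship, paths["courtship"], config)

    song_params = synthetic.SongSimParams(seed=int(rng.integers(2 ** 31)))
    meta, trains = synthetic.gen_song_dataset(song_params, n_songs=n_songs)
    _write_csv(meta, paths["song_metadata"], config)
    if write_audio:
        wav_dir = out / "songs"
        wav_dir.mkdir(exist_ok=True)
        audio_rng = np.random.default_rng(song_params.seed + 1)
        for row, train in zip(meta.itertuples(), trains):
            audio = synthetic.synthesize_audio(
                train, song_params, rng=audio_rng,
                duration=row.courtship_end_s + 0.1)
            synthetic.write_wav(wav_dir / f"{row.song_id}.wav", audio)
        paths["songs"] = wav_dir
    log.info("simulate: %d survival rows, %d courtship rows, %d songs",
             len(survival), len(courtship), len(meta))
    return paths


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def run_survival_stage(config: PipelineConfig) -> dict[str, Path]:
    """Per-line RCH capacity table plus mixed-model report."""
    records = read_stage_csv(Path(config.input_dir) / "survival.csv")
    capacity = ct.rch_capacity_table(records, sex_mode="pooled")
    capacity_by_sex = ct.rch_capacity_table(records, sex_mode="by_sex")
    model = ct.survival_model_summary(records)
    out = Path(config.output_dir)
    paths = {"capacity": out / "rch_capacity.csv",
             "capacity_by_sex": out / "rch_capacity_by_sex.csv",
             "survival_model": out / "survival_model.tsv"}
    _write_csv(capacity, paths["capacity"], config)
    _write_csv(capacity_by_sex, paths["capacity_by_sex"], config)
    _write_model_report(model, "survival", paths["survival_model"], config)
    log.info("survival: %d input rows, %d lines", len(records), len(capacity))
    return paths


def _write_model_report(model: dict, response: str, path: Path,
                        config: PipelineConfig) -> None:
    fixed = model["fixed_effects"].copy()
    fixed.insert(0, "response", response)
    lrt = model["lrt_line_x_treatment"]
    lrt_row = pd.DataFrame([{
        "response": response, "term": "line_x_treatment (LRT)",
        "estimate": np.nan, "se": np.nan, "statistic": lrt["statistic"],
        "p": lrt["p"]}])
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        pd.concat([fixed, lrt_row], ignore_index=True).to_csv(
            fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

def run_mating_stage(config: PipelineConfig) -> dict[str, Path]:
    """Contingency tests, behavior models, line summaries, regressions."""
    obs = read_stage_csv(Path(config.input_dir) / "courtship.csv")
    obs = mating.apply_latency_censoring(obs)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = mating.mating_contingency(obs)
    stat_c, df_c, p_c = mating.chi_square_test(table, continuity=config.continuity)
    stat_u, _, p_u = mating.chi_square_test(table, continuity=False)
    contingency_report = {
        "counts": table.to_dict(),
        "continuity_default": config.continuity,
        "chi2": {"statistic": stat_c, "df": df_c, "p": p_c},
        "chi2_no_continuity": {"statistic": stat_u, "p": p_u},
    }
    paths = {"contingency": out / "mating_contingency.json",
             "latency_model": out / "latency_model.tsv",
             "duration_model": out / "duration_model.tsv",
             "line_summaries": out / "line_behavior_summaries.csv",
             "regressions": out / "plasticity_regressions.csv"}
    with open(paths["contingency"], "w", encoding="utf-8") as fh:
        json.dump(contingency_report, fh, indent=2, default=str)

    for response in ("latency", "duration"):
        model = mating.behavior_model_summary(obs, response=response)
        _write_model_report(model, response, paths[f"{response}_model"], config)

    summaries = mating.line_behavior_summaries(obs)
    _write_csv(summaries, paths["line_summaries"], config)

    survival_path = Path(config.output_dir) / "rch_capacity.csv"
    by_sex_path = Path(config.output_dir) / "rch_capacity_by_sex.csv"
    if by_sex_path.exists():
        cap = read_stage_csv(by_sex_path)
        cap = cap[cap["sex"] == "male"]  # male physiology predicts male behavior
    elif survival_path.exists():
        cap = read_stage_csv(survival_path)
    else:
        cap = None
    if cap is not None:
        merged = summaries.merge(cap[["line", "basal_mean", "capacity"]],
                                 on="line", how="inner")
        reg = mating.plasticity_regressions(merged)
        _write_csv(reg, paths["regressions"], config)
    log.info("mating: %d observations, continuity=%s", len(obs),
             config.continuity)
    return paths


# ---------------------------------------------------------------------------
# song
# ---------------------------------------------------------------------------

def _parse_intervals(cell: str) -> list[tuple[float, float]]:
    if not isinstance(cell, str) or not cell:
        return []
    return [tuple(map(float, part.split("-"))) for part in cell.split(";")]


def run_song_stage(config: PipelineConfig) -> dict[str, Path]:
    """Per-song metrics CSV with retention flag, plus bootstrap summary."""
    meta = read_stage_csv(Path(config.input_dir) / "song_metadata.csv")
    wav_dir = Path(config.input_dir) / "songs"
    metrics: list[song.SongMetrics] = []
    skipped = 0
    for row in meta.itertuples():
        wav_path = wav_dir / f"{row.song_id}.wav"
        try:
            audio = synthetic.read_wav(wav_path)
        except (OSError, ValueError) as err:
            log.warning("skipping %s: %s", wav_path, err)
            skipped += 1
            continue
        metrics.append(song.compute_song_metrics(
            audio, song_id=row.song_id,
            start_temp_c=row.start_temp, end_temp_c=row.end_temp,
            courtship_start_s=row.courtship_start_s,
            courtship_end_s=row.courtship_end_s,
            courting_intervals=_parse_intervals(row.courting_intervals),
            mated=row.mated, line=row.line, male_trt=row.male_trt,
            slope=config.slope, burst_gap_ms=config.burst_gap_ms,
            threshold_k=config.threshold_k,
            refractory_ms=config.refractory_ms))
    metrics_df = pd.DataFrame([{
        "song_id": m.song_id, "line": m.line, "male_trt": m.male_trt,
        "recording_temp": m.recording_temp_c, "n_ipi": m.n_ipi,
        "mean_ipi_raw": m.mean_ipi_raw,
        "mean_ipi_corrected": m.mean_ipi_corrected if m.retained else np.nan,
        "song_index": m.song_index, "courtship_index": m.courtship_index,
        "courtship_duration_s": m.courtship_duration_s,
        "mated": m.mated, "retained": m.retained,
    } for m in metrics])

    all_series = [m.extra["ipis"] for m in metrics if m.n_ipi > 0]
    slope_fit = song.estimate_ipi_temperature_slope(all_series) \
        if len(all_series) >= 3 else None
    log.info("song: temperature slope estimated %.4f ms/degC "
             "(configured default %.4f)",
             slope_fit.slope if slope_fit else float("nan"), config.slope)

    spec = dataclasses.replace(config.bootstrap, seed=config.seed)
    if all_series:
        top = bt.select_top_songs(all_series, config.bootstrap.top_fraction)
        results = bt.bootstrap_songs(top, spec)
        boot_df = bt.results_long_table(results)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stab = bt.stabilization_size(results)
    else:
        log.warning("song: no usable songs; writing empty outputs")
        boot_df = bt.results_long_table([])
        stab = None

    out = Path(config.output_dir)
    paths = {"metrics": out / "song_metrics.csv",
             "bootstrap": out / "ipi_bootstrap.csv",
             "song_summary": out / "song_summary.json"}
    _write_csv(metrics_df, paths["metrics"], config)
    _write_csv(boot_df, paths["bootstrap"], config)
    summary = {
        "n_songs": int(len(meta)),
        "n_processed": int(len(metrics)),
        "n_skipped_unreadable": int(skipped),
        "n_retained": int(metrics_df["retained"].sum()) if len(metrics_df) else 0,
        "temperature_slope_estimate": slope_fit.slope if slope_fit else None,
        "temperature_slope_configured": config.slope,
        "bootstrap_stabilization_size": int(stab) if stab is not None else None,
        "bootstrap_with_replacement": spec.with_replacement,
        "bootstrap_ci": "percentile",
        "burst_gap_ms": config.burst_gap_ms,
    }
    with open(paths["song_summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def song_anova_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect ANOVA of each song variable on male treatment, line and
    mated status with the treatment x mated interaction (Table-2-style
    layout). Mean IPI uses retained songs only."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    responses = {
        "mean_ipi_corrected": metrics[metrics["retained"]],
        "courtship_index": metrics,
        "song_index": metrics,
        "courtship_duration_s": metrics,
    }
    rows = []
    for response, df in responses.items():
        df = df.dropna(subset=[response])
        if df.empty or df["male_trt"].nunique() < 2:
            continue
        fit = smf.ols(f"{response} ~ C(male_trt) * C(mated) + C(line)",
                      df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(fit, typ=2)
        for term, row in table.iterrows():
            if term == "Residual":
                continue
            rows.append({"response": response, "term": term,
                         "F": float(row["F"]), "df": float(row["df"]),
                         "df_resid": float(table.loc["Residual", "df"]),
                         "p": float(row["PR(>F)"])})
    return pd.DataFrame(rows)


def run_full_report(config: PipelineConfig) -> Path:
    """Assemble the report bundle; sections with missing inputs are marked."""
    out = Path(config.output_dir)
    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    sections = {}
    for name, fname in [("capacity", "rch_capacity.csv"),
                        ("latency_model", "latency_model.tsv"),
                        ("duration_model", "duration_model.tsv"),
                        ("contingency", "mating_contingency.json"),
                        ("regressions", "plasticity_regressions.csv"),
                        ("song_metrics", "song_metrics.csv"),
                        ("bootstrap", "ipi_bootstrap.csv")]:
        src = out / fname
        if src.exists():
            (report_dir / fname).write_bytes(src.read_bytes())
            sections[name] = "present"
        else:
            sections[name] = "missing"
    if (out / "song_metrics.csv").exists():
        metrics = read_stage_csv(out / "song_metrics.csv")
        anova = song_anova_table(metrics)
        _write_csv(anova, report_dir / "song_anova.csv", config)
        sections["song_anova"] = "present"
    else:
        sections["song_anova"] = "missing"
    with open(report_dir / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict(),
                   "config_hash": config.config_hash,
                   "sections": sections}, fh, indent=2)
    log.info("report: sections %s", sections)
    return report_dir
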