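"""Readers, writers, pipeline configuration and the end-to-end pipeline.

The canonical on-disk series format is a long-format CSV with header
``tmfc_id,treatment,day,voltage_mV,missing`` (UTF-8, '.' decimal, day as a
decimal number of days since start, missing as 0/1).  Windowed datasets are
written as ``source_id,label,start_index,v1..vw`` CSVs.  ``run_pipeline``
chains simulate/ingest -> stability -> windowing -> standardization ->
classifier grid -> evaluation -> LME report, and writes a manifest so every
artifact is reproducible from the configuration and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import GridSetting, default_grid, results_table, run_grid
from .lme import compare_models, end_state_anova, fit_baseline, fit_single_treatment, fit_treatment
from .stability import DEFAULT_WINDOW, ObservationWindow, find_stable_onset, group_slopes
from .synthetic import ExperimentData, GeneratorConfig, TransientConfig, VoltageSeries, simulate_experiment
from .windows import Window, WindowedDataset

__all__ = [
    "SERIES_COLUMNS",
    "read_series_csv",
    "write_series_csv",
    "write_windows_csv",
    "read_windows_csv",
    "PipelineConfig",
    "load_pipeline_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ["tmfc_id", "treatment", "day", "voltage_mV", "missing"]


def write_series_csv(experiment: ExperimentData, path: str | Path) -> None:
    """Write an experiment as long-format CSV (full float precision)."""
    rows = []
    for s in experiment.series:
        for t, v, m in zip(s.times, s.voltages, s.missing_mask):
            rows.append((s.tmfc_id, s.treatment, repr(float(t)), repr(float(v)), int(m)))
    df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    df.to_csv(path, index=False)


def read_series_csv(path: str | Path) -> ExperimentData:
    """Read a long-format series CSV, reporting malformed rows by line number.

    Rows are grouped by ``tmfc_id`` and sorted by day; duplicate
    (tmfc_id, day) pairs, unparseable numerics and missing columns are
    rejected with the offending row named (line numbers count the header as
    line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing_cols = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    def parse_floats(col: pd.Series) -> pd.Series:
        # Python's float() is round-trip exact for repr output, unlike the
        # fast pandas parser (off by one ulp on some values).
        def conv(v):
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return np.nan
            try:
                return float(v)
            except ValueError:
                return np.nan

        return col.map(conv)

    day = parse_floats(df["day"])
    volt = parse_floats(df["voltage_mV"])
    miss = parse_floats(df["missing"])
    bad = day.isna() | miss.isna() | (volt.isna() & (miss != 1))
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        raise ValueError(f"{path}: unparseable numeric values at lines {lines}")
    dup = df.duplicated(subset=["tmfc_id", "day"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(f"{path}: duplicate (tmfc_id, day) rows at lines {lines}")

    df = df.assign(day=day, voltage_mV=volt.fillna(np.nan), missing=miss.astype(int))
    series = []
    for tmfc_id, grp in df.groupby("tmfc_id", sort=False):
        treatments = grp["treatment"].unique()
        if len(treatments) > 1:
            raise ValueError(
                f"{path}: tmfc_id {tmfc_id!r} has conflicting treatments {list(treatments)}"
            )
        grp = grp.sort_values("day")
        series.append(
            VoltageSeries(
                tmfc_id=str(tmfc_id),
                treatment=str(treatments[0]),
                times=grp["day"].to_numpy(),
                voltages=np.nan_to_num(grp["voltage_mV"].to_numpy()),
                missing_mask=grp["missing"].to_numpy().astype(bool),
            )
        )
    return ExperimentData(series)


def write_windows_csv(dataset: WindowedDataset, path: str | Path) -> None:
    """Windows as ``source_id,label,start_index,v1..vw`` with a JSON sidecar
    holding the dataset metadata."""
    cols = ["source_id", "label", "start_index"] + [f"v{i+1}" for i in range(dataset.w)]
    rows = [
        [win.source_id, win.label, win.start_index, *map(repr, map(float, win.values))]
        for win in dataset.windows
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    meta = {
        "w": dataset.w,
        "standardization": dataset.standardization,
        "observation_window": dataclasses.asdict(dataset.observation_window)
        if dataset.observation_window
        else None,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_windows_csv(path: str | Path) -> WindowedDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    vcols.sort(key=lambda c: int(c[1:]))
    windows = [
        Window(row[vcols].to_numpy(dtype=float), row["label"], row["source_id"], int(row["start_index"]))
        for _, row in df.iterrows()
    ]
    meta_path = Path(str(path) + ".meta.json")
    std, obs = "raw", None
    w = len(vcols)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        std = meta.get("standardization", "raw")
        if meta.get("observation_window"):
            obs = ObservationWindow(**meta["observation_window"])
        w = meta.get("w", w)
    return WindowedDataset(windows, w, standardization=std, observation_window=obs)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_csv: str | None = None  # ingest instead of simulate when set
    window: ObservationWindow = DEFAULT_WINDOW
    detect_window: bool = False  # use find_stable_onset instead of the fixed window
    stability_group_size: int = 4
    grid: list[GridSetting] | None = None  # None = full default grid
    test_fraction: float = 0.2
    split_mode: str = "window"
    seed: int = 0
    output_dir: str = "soilmfc_out"
    log_level: str = "INFO"


def _config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML (or JSON)."""
    raw = yaml.safe_load(Path(path).read_text())
    gen = raw.get("generator", {})
    transient = gen.pop("transient", "default")
    gcfg = GeneratorConfig(**gen)
    if transient is None:
        gcfg.transient = None
    elif transient != "default":
        gcfg.transient = TransientConfig(**transient)
    win = raw.get("window")
    window = ObservationWindow(**win) if win else DEFAULT_WINDOW
    grid = raw.get("grid")
    settings = [GridSetting(**g) for g in grid] if grid else None
    return PipelineConfig(
        generator=gcfg,
        input_csv=raw.get("input_csv"),
        window=window,
        detect_window=raw.get("detect_window", False),
        stability_group_size=raw.get("stability_group_size", 4),
        grid=settings,
        test_fraction=raw.get("test_fraction", 0.2),
        split_mode=raw.get("split_mode", "window"),
        seed=raw.get("seed", 0),
        output_dir=raw.get("output_dir", "soilmfc_out"),
        log_level=raw.get("log_level", "INFO"),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``output_dir``.

    Returns a report dict with the paths written and the key results.
    Stage failures raise with the stage name; artifacts written before the
    failure are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "ingest" if config.input_csv else "simulate"
    try:
        if config.input_csv:
            experiment = read_series_csv(config.input_csv)
        else:
            gcfg = dataclasses.replace(config.generator, seed=config.seed)
            experiment = simulate_experiment(gcfg)
        write_series_csv(experiment, out / "series.csv")

        stage = "stability"
        slopes = []
        for s in experiment.series:
            slopes.extend(group_slopes(s, config.stability_group_size))
        pd.DataFrame([dataclasses.asdict(g) for g in slopes]).to_csv(
            out / "slopes.csv", index=False
        )
        if config.detect_window:
            window = find_stable_onset(experiment, config.stability_group_size)
        else:
            window = config.window
        (out / "window.json").write_text(json.dumps(dataclasses.asdict(window), indent=2))

        stage = "grid"
        settings = config.grid if config.grid is not None else default_grid()
        results = run_grid(
            experiment,
            settings,
            seed=config.seed,
            window=window,
            test_fraction=config.test_fraction,
            split_mode=config.split_mode,
        )
        table = results_table(results)
        table.to_csv(out / "grid_results.csv", index=False)

        stage = "lme"
        base = fit_baseline(experiment, window)
        treat = fit_treatment(experiment, window)
        lrt = compare_models(treat, base)
        base.summary_frame().to_csv(out / "lme_baseline.csv", index=False)
        treat.summary_frame().to_csv(out / "lme_treatment.csv", index=False)
        per_treatment = {}
        for label in experiment.treatments:
            try:
                fit = fit_single_treatment(experiment, label, window)
                per_treatment[label] = {
                    "intercept": fit.fixed_effect("intercept").estimate,
                    "intercept_se": fit.fixed_effect("intercept").se,
                    "slope": fit.fixed_effect("slope").estimate,
                    "slope_se": fit.fixed_effect("slope").se,
                }
            except ValueError as exc:
                per_treatment[label] = {"error": str(exc)}
        comparison = {
            "lrt_statistic": lrt.statistic,
            "lrt_df": lrt.df,
            "lrt_p": lrt.p,
            "preferred": lrt.preferred,
            "aic": {"baseline": base.aic, "treatment": treat.aic},
            "bic": {"baseline": base.bic, "treatment": treat.bic},
            "r2_marginal": {"baseline": base.r2_marginal, "treatment": treat.r2_marginal},
            "r2_conditional": {"baseline": base.r2_conditional, "treatment": treat.r2_conditional},
            "per_treatment": per_treatment,
        }
        (out / "lme_comparison.json").write_text(json.dumps(comparison, indent=2))

        stage = "anova"
        anova = end_state_anova(experiment)
        anova.tukey.to_csv(out / "tukey.csv", index=False)

        stage = "report"
        manifest = {
            "soilmfc_version": __version__,
            "seed": config.seed,
            "config": _config_to_dict(config),
            "n_tmfc": experiment.n_tmfc,
            "treatments": list(experiment.treatments),
            "n_models": len(results),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

        best = next((r for r in results if not r.excluded), None)
        lines = [
            f"soilmfc pipeline run (seed {config.seed})",
            f"tMFCs: {experiment.n_tmfc}; treatments: {', '.join(experiment.treatments)}",
            f"observation window: days {window.start_day:g}-{window.end_day:g}",
            f"grid: {len(results)} model configurations, "
            f"{sum(r.excluded for r in results)} excluded by the Unknown/Identified filters",
        ]
        if best and best.general_accuracy is not None:
            lines.append(
                f"best model: {best.setting.label()} — General Accuracy "
                f"{best.general_accuracy:.1f}%, Identified Accuracy "
                f"{(best.identified_accuracy or float('nan')):.1f}%"
            )
        lines.append(
            f"LME: treatment model preferred={lrt.preferred!r} "
            f"(LRT p={lrt.p:.2g}); R2 marginal {base.r2_marginal:.2f} -> {treat.r2_marginal:.2f}"
        )
        lines.append(f"end-state ANOVA: F={anova.f_stat:.2f}, p={anova.p_value:.2g}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "output_dir": str(out),
        "window": window,
        "results": results,
        "baseline_fit": base,
        "treatment_fit": treat,
        "lrt": lrt,
        "anova": anova,
        "summary": "\n".join(lines),
    }
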