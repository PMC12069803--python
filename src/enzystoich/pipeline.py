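"""Pipeline orchestration: plate reduction → stoichiometry → comparisons → report.

One reproducible run reads plates (or pre-reduced activities) plus soil
chemistry, writes ``activities.csv``, ``stoichiometry.csv``,
``comparisons.csv``, ``summary.csv`` and a JSON manifest recording inputs,
config hash, seed and per-stage row counts.  Reruns with identical
inputs, config and seed produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assay import AssayConfig, read_plate_csv, reduce_plates
from .group_stats import METRIC_NAMES_DEFAULT, anova_comparisons, seasonal_comparisons
from .stoichiometry import (METRIC_COLUMNS, chemistry_from_frame,
                            profiles_from_frame, season_summary, stoich_table)
from .synthetic import default_regime, generate_samples

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Inputs and options of one pipeline run.

    Analysis mode requires exactly one of ``plates_path`` / ``activities_path``
    plus ``chemistry_path``; simulate mode generates both tables instead.
    """

    output_dir: Path
    plates_path: Path | None = None
    activities_path: Path | None = None
    chemistry_path: Path | None = None
    simulate: bool = False
    n_per_cell: int = 5
    assay_config: AssayConfig = field(default_factory=AssayConfig)
    alpha: float = 0.05
    molar: bool = False
    angle_tolerance: float = 1e-9
    seed: int = 0

    def validate(self) -> None:
        if self.simulate:
            return
        have = [p for p in (self.plates_path, self.activities_path) if p is not None]
        if len(have) != 1:
            raise ConfigError("exactly one of plates or activities input is required")
        if self.chemistry_path is None:
            raise ConfigError("chemistry input is required in analysis mode")
        for p in (*have, self.chemistry_path):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    def hash(self) -> str:
        payload = {k: str(v) for k, v in vars(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    A stage failure aborts the run, removes partial outputs and re-raises
    with the stage name attached.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"version": __version__, "config_hash": config.hash(),
                      "seed": config.seed, "stages": {}, "flags": {}}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _write_csv(df, path)
        written.append(path)
        manifest["stages"][name] = int(len(df))

    stage = "input"
    try:
        if config.simulate:
            stage = "simulate"
            regime = default_regime(n_per_cell=config.n_per_cell, seed=config.seed)
            activities, chemistry, _ = generate_samples(regime)
        else:
            stage = "reduce" if config.plates_path else "load-activities"
            if config.plates_path:
                batches = read_plate_csv(config.plates_path)
                reduced = reduce_plates(batches, config.assay_config)
                activities = reduced.drop(
                    columns=[c for c in reduced.columns if c.startswith("cv_")])
                manifest["flags"]["reduce"] = {
                    r.sample_id: r.flags for r in reduced.itertuples()
                    if isinstance(r.flags, str) and r.flags}
            else:
                activities = pd.read_csv(config.activities_path)
            chemistry = pd.read_csv(config.chemistry_path)
        emit(activities, "activities.csv")

        stage = "stoichiometry"
        results = stoich_table(profiles_from_frame(activities),
                               chemistry_from_frame(chemistry),
                               molar=config.molar,
                               angle_tolerance=config.angle_tolerance)
        emit(results, "stoichiometry.csv")
        manifest["flags"]["stoichiometry"] = {
            r.sample_id: r.flags for r in results.itertuples()
            if isinstance(r.flags, str) and r.flags}

        stage = "comparisons"
        frames = []
        t_rows = seasonal_comparisons(results, METRIC_NAMES_DEFAULT, alpha=config.alpha)
        if not t_rows.empty:
            t_rows.insert(0, "analysis", "season_t")
            frames.append(t_rows)
        a_rows = anova_comparisons(results, METRIC_NAMES_DEFAULT, alpha=config.alpha)
        if not a_rows.empty:
            a_rows.insert(0, "analysis", "two_way_anova")
            frames.append(a_rows)
        comparisons = (pd.concat(frames, ignore_index=True) if frames
                       else pd.DataFrame(columns=["analysis", "metric"]))
        emit(comparisons, "comparisons.csv")

        stage = "summary"
        summary = season_summary(results)
        emit(summary, "summary.csv")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        bad = getattr(exc, "sample_ids", None)
        raise type(exc)(f"stage {stage!r} failed: {exc}"
                        + (f" (samples: {bad})" if bad else "")) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest["stages"])
    return manifest


def report(output_dir) -> str:
    """Human-readable run summary from pipeline outputs.

    Per season × management: mean ± SD of each stoichiometric metric, the
    limitation-call tally, the ANOVA table with LSD letters, and a QC flag
    digest.
    """
    out = Path(output_dir)
    stoich_path = out / "stoichiometry.csv"
    if not stoich_path.exists():
        raise ConfigError(f"no pipeline outputs under {out}")
    results = pd.read_csv(stoich_path)
    lines = []
    if results.empty:
        return "no samples\n"
    summary = season_summary(results)
    lines.append("== Group means (mean ± SD) ==")
    for _, row in summary.iterrows():
        lines.append(f"[{row['season']} / {row['management']}] n={row['n_samples']}")
        for metric in METRIC_COLUMNS:
            mean, sd = row[f"{metric}_mean"], row[f"{metric}_sd"]
            sd_txt = f" ± {sd:.3f}" if pd.notna(sd) else ""
            lines.append(f"  {metric:>13}: {mean:.3f}{sd_txt}")
    lines.append("")
    lines.append("== Limitation calls ==")
    calls = results["limitation"].dropna()
    for call, count in calls.value_counts().items():
        lines.append(f"  {call}: {count}/{len(calls)} ({100 * count / len(calls):.0f}%)")
    comp_path = out / "comparisons.csv"
    if comp_path.exists():
        comparisons = pd.read_csv(comp_path)
        if not comparisons.empty:
            lines.append("")
            lines.append("== Comparisons ==")
            season_t = comparisons[comparisons["analysis"] == "season_t"]
            for _, row in season_t.iterrows():
                lines.append(
                    f"  t[{row['metric']}]: {row['group_a']} mean {row['mean_a']:.3f}"
                    f" vs {row['group_b']} mean {row['mean_b']:.3f},"
                    f" p={row['p_value']:.3g} ({row['transform']})")
            anova = comparisons[comparisons["analysis"] == "two_way_anova"]
            for _, row in anova.iterrows():
                letters = f" letters: {row['lsd_letters']}" if isinstance(
                    row.get("lsd_letters"), str) and row.get("lsd_letters") else ""
                lines.append(
                    f"  ANOVA[{row['metric']}] {row['source']}:"
                    f" F={row['F']:.3f}, p={row['p_value']:.3g}{letters}")
    flagged = results[results["flags"].notna() & (results["flags"] != "")]
    lines.append("")
    lines.append(f"== QC flags == ({len(flagged)} flagged sample(s))")
    for _, row in flagged.iterrows():
        lines.append(f"  {row['sample_id']}: {row['flags']}")
    return "\n".join(lines) + "\n"
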