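"""Table formats, run configuration and pipeline orchestration.

All tables are tab-delimited UTF-8 text with '.' decimals and times in
seconds to six decimals.  Every file written carries a header comment
with the package version, the seed and a hash of the run configuration,
so that a saved configuration reproduces deterministic stages exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version_guard  # noqa: F401  (circular-import guard)
from .analysis import (
    ScoreTable,
    aggregate_scores,
    fit_mixed_model,
    omnibus_tests,
    posthoc_contrasts,
    regress_clinical,
)
from .detect import FSRSignal, TapEventSeries
from .scoring import ScoringConfig, TapTrial, score_trial
from .simulate import ParticipantRecord, StudyDataset, StudyDesign, generate_study
from .stimuli import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_events_table",
    "read_events_table",
    "events_to_trials",
    "write_stimulus_table",
    "write_scores_table",
    "read_scores_table",
    "write_clinical_table",
    "read_clinical_table",
    "write_fsr_trace",
    "read_fsr_trace",
    "run_pipeline",
]

EVENT_COLUMNS = ["participant_id", "group", "condition", "trial", "tap_time_s"]
SCORE_COLUMNS = [
    "participant_id", "group", "condition", "trial", "multiplier", "parity",
    "n_taps", "R", "direction_rad", "logit_R", "rayleigh_p", "excluded", "reason",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    design: StudyDesign = field(default_factory=StudyDesign)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    df_method: str = "kenward_roger"
    alpha: float = 0.05
    run_analysis: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # planted_logit keys are tuples; make them YAML/JSON safe
        d["design"]["planted_logit"] = {
            f"{g}:{c}": v for (g, c), v in self.design.planted_logit.items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design_raw = raw.pop("design", {})
        planted = {
            tuple(k.split(":")): v for k, v in design_raw.pop("planted_logit", {}).items()
        }
        scoring_raw = raw.pop("scoring", {})
        return cls(
            design=StudyDesign(planted_logit=planted, **design_raw),
            scoring=ScoringConfig(**scoring_raw),
            **raw,
        )


def _header(seed: Optional[int] = None, config_hash: Optional[str] = None) -> str:
    parts = [f"# tapsync v{_version_guard}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, seed=None, config_hash=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_events_table(
    data: StudyDataset | pd.DataFrame, path: str | Path, seed=None, config_hash=None
) -> None:
    df = data.events_frame() if isinstance(data, StudyDataset) else data
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    _write_tsv(df[EVENT_COLUMNS], Path(path), seed, config_hash)


def read_events_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse events table {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (header line 2)")
    return df[EVENT_COLUMNS]


def events_to_trials(events: pd.DataFrame) -> list[TapTrial]:
    """Group a long-format event table into per-trial records.

    Imported tables carry no dropout metadata, so the post-dropout guard
    is a no-op for them (it is applied at detection/simulation time).
    """
    trials = []
    for (pid, group, cond_name, trial), sub in events.groupby(
        ["participant_id", "group", "condition", "trial"], sort=True
    ):
        cond = CONDITIONS[str(cond_name)]
        taps = np.unique(sub["tap_time_s"].to_numpy(dtype=float))
        trials.append(
            TapTrial(
                participant_id=str(pid),
                group=str(group),
                condition=cond,
                trial_index=int(trial),
                events=TapEventSeries(tap_times=taps, source="imported"),
                reference_stimuli=cond.reference_stimuli(),
                secondary_stimuli=cond.secondary_stimuli(),
            )
        )
    return trials


def write_stimulus_table(path: str | Path, seed=None, config_hash=None) -> None:
    """Write the onset times of every stream of every condition."""
    rows = []
    for name, cond in CONDITIONS.items():
        for stim in filter(None, [cond.reference_stimuli(), cond.secondary_stimuli()]):
            for t in stim.onsets:
                rows.append((name, stim.modality, round(float(t), 6)))
    df = pd.DataFrame(rows, columns=["condition", "modality", "onset_s"])
    _write_tsv(df, Path(path), seed, config_hash)


def scores_to_frame(scores) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "condition": s.condition,
                "trial": s.trial_index,
                "multiplier": s.multiplier_detected,
                "parity": s.parity,
                "n_taps": s.n_taps_scored,
                "R": s.vector_length,
                "direction_rad": s.vector_direction,
                "logit_R": s.logit_consistency,
                "rayleigh_p": s.rayleigh_p,
                "excluded": s.excluded,
                "reason": s.exclusion_reason,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_scores_table(scores, path: str | Path, seed=None, config_hash=None) -> None:
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    _write_tsv(df, Path(path), seed, config_hash)


def read_scores_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_clinical_table(
    participants: Sequence[ParticipantRecord], path: str | Path, seed=None, config_hash=None
) -> None:
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.id,
                "group": p.group,
                "age": round(p.age, 1),
                "onset_age": "pre_linguistic"
                if p.pre_linguistic
                else (round(p.onset_age, 1) if p.onset_age is not None else ""),
                "deafness_duration": "" if p.deafness_duration is None else round(p.deafness_duration, 1),
                "implantation_age": "" if p.implantation_age is None else round(p.implantation_age, 1),
                "ci_use_years": "" if p.ci_use_years is None else round(p.ci_use_years, 1),
            }
        )
    _write_tsv(pd.DataFrame(rows), Path(path), seed, config_hash)


def read_clinical_table(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"onset_age": str})
    out = []
    for _, r in df.iterrows():
        onset = r.get("onset_age")
        pre = isinstance(onset, str) and onset.strip() == "pre_linguistic"
        out.append(
            ParticipantRecord(
                id=str(r["participant_id"]),
                group=str(r["group"]),
                age=float(r["age"]),
                onset_age=None if pre or pd.isna(onset) or onset == "" else float(onset),
                pre_linguistic=pre,
                deafness_duration=None if pd.isna(r.get("deafness_duration")) else float(r["deafness_duration"]),
                implantation_age=None if pd.isna(r.get("implantation_age")) else float(r["implantation_age"]),
                ci_use_years=None if pd.isna(r.get("ci_use_years")) else float(r["ci_use_years"]),
            )
        )
    return out


def write_fsr_trace(signal: FSRSignal, path: str | Path) -> None:
    """Two-column (time_s, force) trace; dropout window kept in the header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header())
        fh.write(f"# sample_rate={signal.sample_rate:g}")
        if signal.dropout_interval is not None:
            lo, hi = signal.dropout_interval
            fh.write(f" dropout={lo:.6f},{hi:.6f}")
        fh.write("\n")
        pd.DataFrame(
            {"time_s": signal.times, "force": signal.samples}
        ).to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_fsr_trace(path: str | Path) -> FSRSignal:
    sample_rate = None
    dropout = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("sample_rate="):
                    sample_rate = float(tok.split("=", 1)[1])
                elif tok.startswith("dropout="):
                    lo, hi = tok.split("=", 1)[1].split(",")
                    dropout = (float(lo), float(hi))
    df = pd.read_csv(path, sep="\t", comment="#")
    if sample_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        sample_rate = 1.0 / float(np.median(dt))
    return FSRSignal(
        samples=df["force"].to_numpy(dtype=float),
        sample_rate=sample_rate,
        dropout_interval=dropout,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """simulate → score → analyze, writing every stage's outputs.

    Returns a dict of output paths.  On a stage failure the outputs of the
    completed stages remain on disk and the exception propagates with the
    stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    paths: dict[str, Path] = {}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tapsync")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths["log"] = log_path
    logger.info("run config hash=%s seed=%d", chash, config.seed)
    logger.info(
        "scoring defaults: kernel_sd=%gs grid=%gs refractory=%gs epsilon=%g "
        "n_trim=%d min_taps=%d pause_rule=Q3+%gxIQR(type-7) df_method=%s",
        config.scoring.kernel_sd_s, config.scoring.grid_dt_s, config.scoring.refractory_s,
        config.scoring.epsilon, config.scoring.n_trim, config.scoring.min_taps,
        config.scoring.pause_iqr_factor, config.df_method,
    )

    try:
        stage = "simulate"
        design = dataclasses.replace(config.design, seed=config.seed)
        dataset = generate_study(design)
        write_events_table(dataset, out / "events.tsv", config.seed, chash)
        write_stimulus_table(out / "stimuli.tsv", config.seed, chash)
        write_clinical_table(dataset.participants, out / "clinical.tsv", config.seed, chash)
        paths["events"] = out / "events.tsv"
        paths["stimuli"] = out / "stimuli.tsv"
        paths["clinical"] = out / "clinical.tsv"

        stage = "score"
        scores = [score_trial(t, config.scoring) for t in dataset.trials]
        write_scores_table(scores, out / "scores.tsv", config.seed, chash)
        paths["scores"] = out / "scores.tsv"
        table = aggregate_scores(scores)
        _write_tsv(table.exclusion_counts, out / "exclusions.tsv", config.seed, chash)
        paths["exclusions"] = out / "exclusions.tsv"

        if config.run_analysis:
            stage = "analyze"
            fit = fit_mixed_model(table)
            omni = omnibus_tests(fit, config.df_method)
            contrasts = posthoc_contrasts(fit, config.df_method)
            regressions = []
            for outcome in ("V_CI", "A_CI", "AVsync_minus_V"):
                for predictor in ("onset_age", "deafness_duration"):
                    r = regress_clinical(table, dataset.participants, outcome, predictor)
                    regressions.append(dataclasses.asdict(r))
            report = {
                "config_hash": chash,
                "seed": config.seed,
                "model": {
                    "structure": fit.structure,
                    "converged": fit.converged,
                    "loglike": fit.loglike,
                    "notes": fit.notes,
                },
                "omnibus": omni.to_dict(orient="records"),
                "contrasts": [dataclasses.asdict(c) for c in contrasts],
                "regressions": regressions,
                "exclusion_counts": table.exclusion_counts.to_dict(orient="records"),
            }
            report_path = out / "report.json"
            report_path.write_text(json.dumps(report, indent=2, default=float))
            paths["report"] = report_path
            summary = out / "summary.txt"
            with open(summary, "w") as fh:
                fh.write(_header(config.seed, chash))
                fh.write("Omnibus (type-3 Wald, %s df):\n" % config.df_method)
                for row in report["omnibus"]:
                    fh.write(
                        f"  {row['term']}: F({row['df1']:.0f}, {row['df2']:.1f}) = "
                        f"{row['F']:.3f}, p = {row['p']:.4g}\n"
                    )
                fh.write("Post-hoc contrasts (Bonferroni x 11):\n")
                for c in report["contrasts"]:
                    fh.write(
                        f"  {c['name']}: est = {c['estimate']:.3f}, "
                        f"t({c['df']:.1f}) = {c['t']:.2f}, p = {c['p_bonferroni']:.4g}\n"
                    )
            paths["summary"] = summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return paths
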