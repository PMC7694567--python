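"""End-to-end reproducible run: cohort simulation, pre-assessment, ten
training sessions per participant, post-assessment, and the statistical
battery — with every intermediate written to disk and a run log holding the
parameters needed to regenerate the bundle from scratch."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .datatypes import MEASURES
from .errors import ExoResistError
from .io import (
    RunConfig,
    write_outcome_table,
    write_session_log,
)
from .outcomes import TrialAnalyzer, results_frame
from .progression import simulate_training_course
from .synth import EffectConfig, generate_cohort, generate_profiles


class PipelineError(ExoResistError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full simulated trial and analysis.

    Stages: generate participant profiles and the pre/post outcome table at
    the configured effect sizes -> simulate each participant's ten-session
    training course -> run the statistical battery. Writes the outcome
    table, per-participant session logs, the results table, the formatted
    report and a JSON run log under ``out_dir``; returns a summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrap

    effects = EffectConfig()
    if config.effects:
        merged = dict(effects.effects)
        merged.update(config.effects)
        effects = EffectConfig(effects=merged)
    if config.sessions == 0:
        # no-training control: no systematic pre -> post change
        effects = EffectConfig.null()

    profiles = stage("cohort")(generate_profiles, config.n_participants, config.seed)
    table, _ = stage("assessment")(
        generate_cohort,
        config.n_participants,
        effects,
        config.seed,
        profiles=profiles,
    )
    write_outcome_table(table, out / "outcomes.csv")

    logs = {}
    for i, prof in enumerate(profiles):
        if config.sessions == 0:
            continue
        records = stage("training")(
            simulate_training_course,
            prof,
            config.start_resistance_nmkg,
            config.sessions,
            config.seed + 1000 + i,
            increment_nm=config.increment_nm,
            engagement_tolerance=config.engagement_tolerance,
        )
        write_session_log(records, out / f"sessions_{prof.id}.csv")
        logs[prof.id] = records

    analyzer = TrialAnalyzer(
        alpha=config.alpha,
        d_variant=config.d_variant,
        iqr_k=config.iqr_k,
        lilliefors_sims=config.lilliefors_sims,
        random_state=config.seed,
    )
    stage("statistics")(analyzer.fit, table)
    results_frame(analyzer.results_).to_csv(out / "stat_results.csv", index=False)
    (out / "report.txt").write_text(analyzer.report_ + "\n")

    run_log = {
        "package": "exoresist",
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "measures": list(MEASURES),
        "n_sessions_per_participant": config.sessions,
        "participants": [p.id for p in profiles],
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    return {
        "table": table,
        "results": analyzer.results_,
        "report": analyzer.report_,
        "session_logs": logs,
        "out_dir": str(out),
    }
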