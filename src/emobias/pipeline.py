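"""End-to-end orchestration: simulate/load -> QC -> fit -> analyze -> report.

One :class:`RunConfig` drives a full reproducible run.  Exactly one data
source is configured: either paths to real trial/participant tables or
a synthetic-cohort config.  Every participant of the input ends up
either with a psychometric fit or in the exclusion ledger with reasons;
the report embeds the config and seed it can be reproduced from.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from emobias import io
from emobias.errors import (ConfigError, DegenerateDataError, EmobiasError,
                            InsufficientDataError, StageError)
from emobias.inference import (SummaryStats, compare_groups,
                               skew_kurtosis_check, sqrt_transform)
from emobias.moderation import fit_hierarchical, simple_slopes
from emobias.psychometric import FitOptions, aggregate_levels, fit_psychometric
from emobias.qc import apply_exclusions
from emobias.simulate import CohortConfig, simulate_cohort

log = logging.getLogger("emobias")

REASON_DASS = "dass_above_cutoff"
REASON_NO_METADATA = "missing_metadata"
REASON_FIT = "fit_not_converged"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-compatible)."""

    trials_path: str | None = None
    participants_path: str | None = None
    simulation: CohortConfig | None = None
    min_trials: int = 30
    happy_floor: float = 0.75
    angry_ceiling: float = 0.25
    dass_max: int = io.DASS_INCLUSION_MAX
    fit_options: FitOptions = field(default_factory=FitOptions)
    cov_type: str = "HC3"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.trials_path is not None and self.participants_path is not None
        if real == (self.simulation is not None):
            raise ConfigError(
                "configure exactly one input: trials_path+participants_path "
                "or a simulation block")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        payload: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = payload.pop("simulation", None)
        fit = payload.pop("fit_options", None)
        config = cls(
            simulation=CohortConfig.from_dict(sim) if sim is not None else None,
            fit_options=FitOptions(**fit) if fit else FitOptions(),
            **payload)
        if seed is not None:
            config.seed = seed
            if config.simulation is not None:
                config.simulation = dataclasses.replace(config.simulation,
                                                        seed=seed)
        return config

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["simulation"] = (self.simulation.to_dict()
                                 if self.simulation else None)
        payload["fit_options"] = dataclasses.asdict(self.fit_options)
        return payload


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        trials, participants, truth = simulate_cohort(config.simulation)
        return trials, participants, truth
    trials = io.read_trials(config.trials_path)
    participants = io.read_participants(config.participants_path)
    return trials, participants, None


def run_pipeline(config: RunConfig) -> io.AnalysisReport:
    """Execute the full analysis and return the structured report.

    Stages: load/simulate, trial-level QC plus metadata gates,
    per-participant psychometric fits (non-converged fits are excluded
    and ledgered), group summaries and t-tests for PSE and slope, and
    the two moderation models with simple slopes.  Deterministic given
    config + seed.
    """
    try:
        trials, participants, _ = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise StageError("load", str(exc)) from exc

    meta = {p.participant_id: p for p in participants}
    try:
        decisions = apply_exclusions(trials, min_trials=config.min_trials,
                                     happy_floor=config.happy_floor,
                                     angry_ceiling=config.angry_ceiling)
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", str(exc)) from exc

    # Metadata gates on top of the trial-computed rules.
    ledger: list[dict] = []
    eligible: list[str] = []
    for decision in decisions:
        row = decision.to_dict()
        reasons = list(decision.reasons)
        record = meta.get(decision.participant_id)
        if record is None:
            reasons.append(REASON_NO_METADATA)
        elif record.dass_depression > config.dass_max:
            reasons.append(REASON_DASS)
        row["reasons"] = ";".join(reasons)
        row["included"] = not reasons
        ledger.append(row)
        if not reasons:
            eligible.append(decision.participant_id)
    log.info("qc: %d participants in, %d eligible", len(decisions),
             len(eligible))

    fits: list[dict] = []
    by_pid = dict(tuple(trials.groupby("participant_id", sort=True)))
    ledger_ix = {row["participant_id"]: row for row in ledger}
    for pid in eligible:
        try:
            counts = aggregate_levels(by_pid[pid])
            fit = fit_psychometric(counts, config.fit_options)
        except (DegenerateDataError, InsufficientDataError):
            fit = None
        if fit is None or not fit.converged:
            row = ledger_ix[pid]
            row["included"] = False
            row["reasons"] = REASON_FIT
            continue
        fits.append({"participant_id": pid, **fit.to_dict()})
    log.info("fit: %d converged fits", len(fits))

    report = io.AnalysisReport(
        provenance={
            "config": config.to_dict(),
            "config_hash": io.config_hash(config.to_dict()),
            "seed": config.seed,
            "package_version": _version(),
        },
        qc=ledger, fits=fits)
    _analyze(report, meta, config)
    return report


def _analyze(report: io.AnalysisReport, meta: dict, config: RunConfig) -> None:
    """Fill group-level sections in place; empty cohorts stay empty."""
    rows = []
    for fit in report.fits:
        record = meta[fit["participant_id"]]
        rows.append({
            "participant_id": fit["participant_id"],
            "sa": 1.0 if record.sa_status == "HSA" else 0.0,
            "pse": fit["pse"], "slope": fit["slope_at_pse"],
            "na": np.nan if record.panas_na is None else float(record.panas_na),
        })
    frame = pd.DataFrame(rows)
    if len(frame) == 0:
        return
    frame["na_sqrt"] = sqrt_transform(frame["na"])

    for measure in ("pse", "slope"):
        for sa, label in ((1.0, "HSA"), (0.0, "LSA")):
            values = frame.loc[frame["sa"] == sa, measure]
            if len(values) >= 2:
                summary = SummaryStats.from_values(values)
                entry = {"measure": measure, "group": label, "n": summary.n,
                         "mean": summary.mean, "sd": summary.sd}
                try:
                    check = skew_kurtosis_check(values)
                    entry.update({"skew": check.skew,
                                  "kurtosis": check.kurtosis,
                                  "normality_pass": check.passed})
                except DegenerateDataError:
                    pass
                report.group_summaries.append(entry)

    hsa = frame[frame["sa"] == 1.0]
    lsa = frame[frame["sa"] == 0.0]
    if len(hsa) >= 2 and len(lsa) >= 2:
        for measure in ("pse", "slope"):
            try:
                result = compare_groups(lsa[measure], hsa[measure],
                                        alpha=config.alpha)
            except DegenerateDataError:
                continue
            report.t_tests.append({"measure": measure,
                                   "order": "LSA-minus-HSA",
                                   **result.to_dict()})

    complete = frame.dropna(subset=["na_sqrt"])
    if len(complete) >= 8 and complete["sa"].nunique() == 2:
        for measure in ("pse", "slope"):
            try:
                result = fit_hierarchical(complete[measure], complete["sa"],
                                          complete["na_sqrt"],
                                          cov_type=config.cov_type)
            except EmobiasError as exc:
                log.warning("moderation for %s skipped: %s", measure, exc)
                continue
            report.moderation[measure] = result.to_dict()
            for slope in simple_slopes(result):
                report.simple_slopes.append({"outcome": measure,
                                             **slope.to_dict()})


def _version() -> str:
    from emobias import __version__
    return __version__
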