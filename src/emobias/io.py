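"""Reading, validation and writing of the pipeline's tables and reports.

Two delimited-text inputs drive everything: a *trial table* with one row
per presented face morph and judgment, and a *participant table* with
group status and questionnaire scores.  Both are CSV (UTF-8, ``.``
decimal, empty field = missing).  Structured results are written as one
JSON report plus flat CSV side tables.

Validation is total: any malformed row raises a located error rather
than being silently coerced or dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from emobias.errors import SchemaError, TableValidationError

#: Signed morph levels of the 9-level design (happy positive, angry negative).
DESIGN_LEVELS: tuple[int, ...] = (-80, -40, -20, -10, 0, 10, 20, 40, 80)

#: Closed response vocabulary.  ``omitted`` marks a trial with no judgment
#: inside the response window; such rows are preserved, never dropped.
RESPONSES: tuple[str, ...] = ("happy", "angry", "omitted")
VALID_RESPONSES: tuple[str, ...] = ("happy", "angry")

#: Social-anxiety classification cutoffs on the BFNE-S straightforward items.
HSA_BFNE_MIN = 25
LSA_BFNE_MAX = 12
#: Depression inclusion gate (participants above this score are excluded).
DASS_INCLUSION_MAX = 17

TRIAL_COLUMNS = ("participant_id", "trial_index", "morph_level", "response")
TRIAL_COLUMNS_ALL = ("participant_id", "trial_index", "morph_level", "face_id", "response")
PARTICIPANT_COLUMNS = ("participant_id", "sa_status", "bfne_s", "dass_depression",
                       "panas_pa", "panas_na")
PARTICIPANT_COLUMNS_ALL = PARTICIPANT_COLUMNS + ("age", "gender")


@dataclass(frozen=True)
class ParticipantRecord:
    """Group status and questionnaire scores for one participant.

    ``panas_pa``/``panas_na`` may be ``None`` (missing state-affect
    measurement); downstream moderation uses listwise deletion.
    """

    participant_id: str
    sa_status: str                      # "HSA" or "LSA"
    bfne_s: int                         # 8..40
    dass_depression: int                # 0..21
    panas_pa: int | None = None         # 10..50 or missing
    panas_na: int | None = None         # 10..50 or missing
    age: float | None = None
    gender: str | None = None

    def validate(self) -> None:
        if self.sa_status not in ("HSA", "LSA"):
            raise TableValidationError(
                f"sa_status must be HSA or LSA, got {self.sa_status!r}")
        if not (8 <= self.bfne_s <= 40):
            raise TableValidationError(
                f"bfne_s out of range 8..40: {self.bfne_s}")
        if self.sa_status == "HSA" and self.bfne_s < HSA_BFNE_MIN:
            raise TableValidationError(
                f"HSA requires bfne_s >= {HSA_BFNE_MIN}, got {self.bfne_s}")
        if self.sa_status == "LSA" and self.bfne_s > LSA_BFNE_MAX:
            raise TableValidationError(
                f"LSA requires bfne_s <= {LSA_BFNE_MAX}, got {self.bfne_s}")
        if not (0 <= self.dass_depression <= 21):
            raise TableValidationError(
                f"dass_depression out of range 0..21: {self.dass_depression}")
        for name in ("panas_pa", "panas_na"):
            value = getattr(self, name)
            if value is not None and not (10 <= value <= 50):
                raise TableValidationError(
                    f"{name} out of range 10..50: {value}")


def validate_trials(frame: pd.DataFrame,
                    levels: Sequence[int] = DESIGN_LEVELS) -> pd.DataFrame:
    """Validate a raw trial frame; returns a typed copy or raises.

    Checks required columns, the morph-level design set, the response
    vocabulary, and uniqueness of ``(participant_id, trial_index)``.
    """
    for col in TRIAL_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"trial table is missing required column {col!r}")
    out = frame.copy()
    out["participant_id"] = out["participant_id"].astype(str)
    if "face_id" not in out.columns:
        out["face_id"] = ""
    out["face_id"] = out["face_id"].fillna("").astype(str)

    for col in ("trial_index", "morph_level"):
        numeric = pd.to_numeric(out[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise TableValidationError(
                f"column {col!r} must be an integer, got {out[col].iloc[row - 1]!r}",
                row=row)
        out[col] = numeric.astype(int)

    bad = out["trial_index"] < 1
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise TableValidationError("trial_index must be >= 1", row=row)

    level_set = set(int(x) for x in levels)
    bad = ~out["morph_level"].isin(level_set)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise TableValidationError(
            f"morph_level {out['morph_level'].iloc[row - 1]} not in the design "
            f"set {sorted(level_set)}", row=row)

    out["response"] = out["response"].astype(str)
    bad = ~out["response"].isin(RESPONSES)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise TableValidationError(
            f"response {out['response'].iloc[row - 1]!r} not in {RESPONSES}",
            row=row)

    dup = out.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise TableValidationError(
            "duplicate (participant_id, trial_index) pair", row=row)
    return out[list(TRIAL_COLUMNS_ALL)]


def read_trials(path: str | Path, delimiter: str = ",",
                levels: Sequence[int] = DESIGN_LEVELS) -> pd.DataFrame:
    """Read and validate a trial table from delimited text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, dtype={"participant_id": str,
                                                    "face_id": str})
    return validate_trials(frame, levels=levels)


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated trial table as CSV (round-trips with read_trials)."""
    path = Path(path)
    validate_trials(trials).to_csv(path, index=False)
    return path


def _opt_int(value: Any) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read the participant metadata table.

    Missing PANAS fields (empty cells) are allowed and become ``None``;
    sa_status / bfne_s consistency is enforced against the group cutoffs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"participant table not found: {path}")
    frame = pd.read_csv(path, dtype={"participant_id": str, "gender": str})
    for col in PARTICIPANT_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(
                f"participant table is missing required column {col!r}")
    records: list[ParticipantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            age = getattr(row, "age", None)
            age = None if age is None or pd.isna(age) else float(age)
            gender = getattr(row, "gender", None)
            gender = None if gender is None or pd.isna(gender) else str(gender)
            rec = ParticipantRecord(
                participant_id=str(row.participant_id),
                sa_status=str(row.sa_status),
                bfne_s=int(row.bfne_s),
                dass_depression=int(row.dass_depression),
                panas_pa=_opt_int(row.panas_pa),
                panas_na=_opt_int(row.panas_na),
                age=age,
                gender=gender,
            )
            rec.validate()
        except TableValidationError as exc:
            raise TableValidationError(str(exc.args[0]).split(" (row ")[0],
                                       row=i) from exc
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"unparseable participant row: {exc}",
                                       row=i) from exc
        if rec.participant_id in seen:
            raise TableValidationError(
                f"duplicate participant_id {rec.participant_id!r}", row=i)
        seen.add(rec.participant_id)
        records.append(rec)
    return records


def participants_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS_ALL))
    return frame


def write_participants(records: Iterable[ParticipantRecord],
                       path: str | Path) -> Path:
    """Write participant records as CSV; missing values become empty fields."""
    path = Path(path)
    frame = participants_frame(records)
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Analysis report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Complete structured output of one pipeline run.

    Every participant of the input appears exactly once: either with a
    fit row in ``fits`` or in the ``qc`` ledger as excluded with reasons.
    ``provenance`` embeds the config and seed the run can be reproduced
    from; no wall-clock state is stored, so identical config + seed
    yields byte-identical serialized reports.
    """

    provenance: dict = field(default_factory=dict)
    qc: list[dict] = field(default_factory=list)
    fits: list[dict] = field(default_factory=list)
    group_summaries: list[dict] = field(default_factory=list)
    t_tests: list[dict] = field(default_factory=list)
    moderation: dict = field(default_factory=dict)
    simple_slopes: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "qc": self.qc,
            "fits": self.fits,
            "group_summaries": self.group_summaries,
            "t_tests": self.t_tests,
            "moderation": self.moderation,
            "simple_slopes": self.simple_slopes,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisReport":
        return cls(**{k: payload.get(k, cls.__dataclass_fields__[k].default_factory())
                      for k in cls.__dataclass_fields__})


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _table(rows: list[dict], columns: Sequence[str] | None = None) -> pd.DataFrame:
    if rows:
        return pd.DataFrame(rows)
    return pd.DataFrame(columns=list(columns or []))


def write_report(report: AnalysisReport, outdir: str | Path) -> dict:
    """Write the JSON report plus flat CSV side tables; returns a manifest.

    The manifest maps logical table names to written file paths.  Key
    order in the JSON document is deterministic (sorted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    manifest["report"] = str(report_path)

    tables = {
        "qc_ledger": _table(report.qc, ["participant_id", "n_valid_trials",
                                        "p_happy_at_plus80", "p_happy_at_minus80",
                                        "included", "reasons"]),
        "fits": _table(report.fits, ["participant_id", "mu", "sigma", "guess",
                                     "lapse", "pse", "slope_at_pse", "loglik",
                                     "deviance", "converged", "n_valid_trials"]),
        "group_tests": _table(report.t_tests, ["measure", "variant", "t", "df",
                                               "p", "cohens_d"]),
        "moderation": _moderation_table(report.moderation),
        "simple_slopes": _table(report.simple_slopes,
                                ["outcome", "level", "estimate", "se", "t", "p"]),
    }
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[name] = str(path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _moderation_table(moderation: dict) -> pd.DataFrame:
    """Flatten nested moderation results into a Tables 3/4-style layout."""
    rows: list[dict] = []
    for outcome, result in sorted(moderation.items()):
        if not result:
            continue
        for model_name, step in (("Model 1", result["step1"]),
                                 ("Model 2", result["step2"])):
            for predictor in step["coef"]:
                if predictor == "const":
                    continue
                rows.append({
                    "outcome": outcome,
                    "model": model_name,
                    "predictor": predictor,
                    "b": step["coef"][predictor],
                    "robust_se": step["robust_se"][predictor],
                    "beta": step["beta"][predictor],
                    "t": step["t"][predictor],
                    "p": step["p"][predictor],
                    "r2": step["r2"],
                    "delta_r2": result["delta_r2"] if model_name == "Model 2" else "",
                    "f_change": result["f_change"] if model_name == "Model 2" else "",
                    "p_change": result["p_change"] if model_name == "Model 2" else "",
                })
    return _table(rows, ["outcome", "model", "predictor", "b", "robust_se",
                         "beta", "t", "p", "r2", "delta_r2", "f_change",
                         "p_change"])


def read_report(path: str | Path) -> AnalysisReport:
    """Load a previously written JSON report."""
    payload = json.loads(Path(path).read_text())
    return AnalysisReport.from_dict(payload)
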