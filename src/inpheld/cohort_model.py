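"""Domain types, CSV I/O and validation for iNPH cohort and normative tables.

The cohort table is one row per patient: demographics, imaging indices
(Evans index, DESH score), the traditional assessment panel (MMSE, 5-m TUG,
10-m walk), the digital cognitive panel (grammatical reasoning, one-back,
trail-making time, Stroop correct count and reaction time), the quantitative
gait panel (step width, stride length, step height, gait velocity, turning
time) — each pre- and post-drainage — shunt status, and up to three
post-shunt follow-up visits (mRS and the three iNPH grading-scale domains).

The normative table carries, for each digital cognitive test, the healthy
population mean, SD, and scoring direction used for z standardisation.
Missing optional cells are represented as ``None`` (empty CSV cell), never
silently coerced to zero.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ValidationError",
    "CohortReadError",
    "CognitivePanel",
    "TraditionalPanel",
    "GaitPanel",
    "FollowUp",
    "PatientRecord",
    "NormEntry",
    "NormTable",
    "COGNITIVE_TESTS",
    "read_cohort",
    "write_cohort",
    "read_norms",
    "write_norms",
    "write_report",
    "read_report",
]

#: Digital cognitive tests that enter the composite z-score, with the
#: clinical orientation of their raw scale.
COGNITIVE_TESTS: dict[str, str] = {
    "grammatical_reasoning": "higher_better",
    "one_back": "higher_better",
    "tmt_time": "lower_better",
    "stroop_correct": "higher_better",
    "stroop_rt": "lower_better",
}

SEXES = ("male", "female")
COMORBIDITIES = ("hyperlipidemia", "hypertension", "diabetes")
SYMPTOMS = ("cognitive", "gait", "urinary")


class ValidationError(ValueError):
    """A record or table violates a documented invariant.

    The message always names the offending field (and record id when known).
    """


class CohortReadError(ValueError):
    """A CSV cell could not be parsed; names the row and column."""


def _check(cond: bool, message: str, record_id: str | None = None) -> None:
    if not cond:
        prefix = f"record {record_id}: " if record_id else ""
        raise ValidationError(prefix + message)


@dataclass(frozen=True)
class CognitivePanel:
    """One administration of the digital cognitive battery (summary scores)."""

    grammatical_reasoning: float  # correct minus errors
    one_back: float               # correct minus errors
    tmt_time: float               # seconds
    stroop_correct: float         # count
    stroop_rt: float              # seconds

    def validate(self, record_id: str | None = None) -> None:
        _check(self.tmt_time > 0, "tmt_time > 0", record_id)
        _check(self.stroop_rt > 0, "stroop_rt > 0", record_id)
        for f in fields(self):
            v = getattr(self, f.name)
            _check(v is not None and v >= 0, f"{f.name} nonnegative", record_id)


@dataclass(frozen=True)
class TraditionalPanel:
    """Guideline assessment battery: MMSE plus timed walking tests."""

    mmse: int          # 0-30
    tug_time: float    # seconds, 5-m timed up and go
    tmwt_time: float   # seconds, 10-m walk
    tmwt_steps: int    # step count, 10-m walk

    def validate(self, record_id: str | None = None) -> None:
        _check(0 <= self.mmse <= 30, "mmse in [0,30]", record_id)
        _check(self.tug_time > 0, "tug_time > 0", record_id)
        _check(self.tmwt_time > 0, "tmwt_time > 0", record_id)
        _check(self.tmwt_steps >= 1, "tmwt_steps >= 1", record_id)


@dataclass(frozen=True)
class GaitPanel:
    """Quantitative single-camera gait parameters."""

    step_width: float     # m (lower is better)
    stride_length: float  # m
    step_height: float    # m
    gait_velocity: float  # m/s
    turning_time: float   # s (lower is better)

    def validate(self, record_id: str | None = None) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _check(v is not None and v > 0, f"{f.name} > 0", record_id)


@dataclass(frozen=True)
class FollowUp:
    """One post-shunt follow-up visit."""

    interval_days: int
    mrs: int
    inphgs: tuple[int, int, int]  # (cognitive, gait, urinary), each 0-4
    subjective_improvement: bool

    def validate(self, record_id: str | None = None) -> None:
        _check(self.interval_days > 0, "interval_days > 0", record_id)
        _check(0 <= self.mrs <= 5, "mrs in [0,5]", record_id)
        _check(len(self.inphgs) == 3, "inphgs has 3 domains", record_id)
        for d in self.inphgs:
            _check(0 <= d <= 4, "inphgs domain in [0,4]", record_id)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: baseline state, pre/post-drainage panels, follow-up."""

    id: str
    age: float
    sex: str
    education: float
    comorbidities: frozenset[str]
    evans_index: float
    desh_score: int
    symptoms: frozenset[str]
    mrs_baseline: int
    inphgs_baseline: tuple[int, int, int]
    traditional_pre: Optional[TraditionalPanel] = None
    traditional_post: Optional[TraditionalPanel] = None
    cognitive_pre: Optional[CognitivePanel] = None
    cognitive_post: Optional[CognitivePanel] = None
    gait_pre: Optional[GaitPanel] = None
    gait_post: Optional[GaitPanel] = None
    shunted: bool = False
    followups: tuple[FollowUp, ...] = ()

    @property
    def inphgs_total(self) -> int:
        return sum(self.inphgs_baseline)

    def last_followup(self) -> Optional[FollowUp]:
        """The visit with maximal interval from surgery, if any."""
        return self.followups[-1] if self.followups else None

    def validate(self, desh_max: int = 10) -> None:
        rid = self.id
        _check(bool(self.id), "id nonempty", rid)
        _check(self.sex in SEXES, f"sex in {SEXES}", rid)
        _check(self.age > 0, "age > 0", rid)
        _check(self.education >= 0, "education >= 0", rid)
        _check(self.comorbidities <= set(COMORBIDITIES),
               f"comorbidities subset of {COMORBIDITIES}", rid)
        _check(self.symptoms <= set(SYMPTOMS),
               f"symptoms subset of {SYMPTOMS}", rid)
        _check(0 < self.evans_index < 1, "evans_index in (0,1)", rid)
        _check(0 <= self.desh_score <= desh_max,
               f"desh_score in [0,{desh_max}]", rid)
        _check(0 <= self.mrs_baseline <= 5, "mrs_baseline in [0,5]", rid)
        _check(len(self.inphgs_baseline) == 3, "inphgs_baseline has 3 domains", rid)
        for d in self.inphgs_baseline:
            _check(0 <= d <= 4, "inphgs domain in [0,4]", rid)
        _check(0 <= self.inphgs_total <= 12, "inphgs total in [0,12]", rid)
        for name in ("traditional", "cognitive", "gait"):
            pre = getattr(self, f"{name}_pre")
            post = getattr(self, f"{name}_post")
            _check(not (post is not None and pre is None),
                   f"{name}_post present only when {name}_pre present", rid)
            for panel in (pre, post):
                if panel is not None:
                    panel.validate(rid)
        if not self.shunted:
            _check(not self.followups, "followups only for shunted patients", rid)
        intervals = [f.interval_days for f in self.followups]
        _check(intervals == sorted(intervals) and len(set(intervals)) == len(intervals),
               "followup interval_days strictly increasing", rid)
        for f in self.followups:
            f.validate(rid)


@dataclass(frozen=True)
class NormEntry:
    """Healthy-population mean/SD and orientation for one cognitive test."""

    mean: float
    sd: float
    direction: str  # higher_better | lower_better

    def validate(self, test: str = "") -> None:
        _check(self.sd > 0, f"norm sd > 0 for {test}")
        _check(self.direction in ("higher_better", "lower_better"),
               f"norm direction for {test} in (higher_better, lower_better)")


class NormTable(dict):
    """Mapping test name -> :class:`NormEntry`; exactly one entry per test."""

    def validate(self) -> None:
        missing = set(COGNITIVE_TESTS) - set(self)
        _check(not missing, f"norms missing entries for {sorted(missing)}")
        for test, entry in self.items():
            entry.validate(test)


# --------------------------------------------------------------------------
# CSV schema
# --------------------------------------------------------------------------

_PANEL_SPECS = {
    "traditional": (TraditionalPanel, ["mmse", "tug_time", "tmwt_time", "tmwt_steps"]),
    "cognitive": (CognitivePanel, list(COGNITIVE_TESTS)),
    "gait": (GaitPanel, ["step_width", "stride_length", "step_height",
                         "gait_velocity", "turning_time"]),
}
_INT_CELLS = {"mmse", "tmwt_steps"}
MAX_FOLLOWUPS = 3

COHORT_COLUMNS: list[str] = (
    ["id", "age", "sex", "education"]
    + list(COMORBIDITIES)
    + ["evans_index", "desh_score"]
    + [f"sym_{s}" for s in SYMPTOMS]
    + ["mrs_baseline", "inphgs_cognitive", "inphgs_gait", "inphgs_urinary"]
    + [f"{c}_{phase}" for _, (_, cols) in _PANEL_SPECS.items()
       for phase in ("pre", "post") for c in cols]
    + ["shunted"]
    + [f"fu{k}_{c}" for k in range(1, MAX_FOLLOWUPS + 1)
       for c in ("interval_days", "mrs", "inphgs_cognitive", "inphgs_gait",
                 "inphgs_urinary", "subjective")]
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if hasattr(value, "item"):  # numpy scalar -> Python scalar
        value = value.item()
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse(cell: str, kind: str, row: int, col: str):
    cell = cell.strip()
    if cell == "":
        return None
    try:
        if kind == "int":
            return int(cell)
        if kind == "float":
            return float(cell)
        if kind == "bool":
            if cell in ("0", "1"):
                return cell == "1"
            raise ValueError("expected 0 or 1")
        return cell
    except ValueError as exc:
        raise CohortReadError(
            f"row {row}, column {col!r}: cannot parse {cell!r} as {kind} ({exc})"
        ) from exc


def _record_to_row(rec: PatientRecord) -> dict[str, str]:
    row: dict[str, object] = {
        "id": rec.id, "age": rec.age, "sex": rec.sex, "education": rec.education,
        "evans_index": rec.evans_index, "desh_score": rec.desh_score,
        "mrs_baseline": rec.mrs_baseline, "shunted": rec.shunted,
    }
    for c in COMORBIDITIES:
        row[c] = c in rec.comorbidities
    for s in SYMPTOMS:
        row[f"sym_{s}"] = s in rec.symptoms
    for name, d in zip(("cognitive", "gait", "urinary"), rec.inphgs_baseline):
        row[f"inphgs_{name}"] = d
    for pname, (_, cols) in _PANEL_SPECS.items():
        for phase in ("pre", "post"):
            panel = getattr(rec, f"{pname}_{phase}")
            for c in cols:
                row[f"{c}_{phase}"] = getattr(panel, c) if panel is not None else None
    for k in range(1, MAX_FOLLOWUPS + 1):
        fu = rec.followups[k - 1] if len(rec.followups) >= k else None
        row[f"fu{k}_interval_days"] = fu.interval_days if fu else None
        row[f"fu{k}_mrs"] = fu.mrs if fu else None
        for name, idx in (("cognitive", 0), ("gait", 1), ("urinary", 2)):
            row[f"fu{k}_inphgs_{name}"] = fu.inphgs[idx] if fu else None
        row[f"fu{k}_subjective"] = fu.subjective_improvement if fu else None
    return {k: _fmt(v) for k, v in row.items()}


def _row_to_record(row: dict[str, str], rownum: int) -> PatientRecord:
    def cell(col, kind):
        return _parse(row.get(col, ""), kind, rownum, col)

    def req(col, kind):
        v = cell(col, kind)
        if v is None:
            raise CohortReadError(f"row {rownum}, column {col!r}: required cell is empty")
        return v

    panels: dict[str, object] = {}
    for pname, (cls, cols) in _PANEL_SPECS.items():
        for phase in ("pre", "post"):
            vals = {c: cell(f"{c}_{phase}", "int" if c in _INT_CELLS else "float")
                    for c in cols}
            present = [v is not None for v in vals.values()]
            if all(present):
                panels[f"{pname}_{phase}"] = cls(**vals)
            elif any(present):
                missing = [c for c, v in vals.items() if v is None]
                raise CohortReadError(
                    f"row {rownum}: partial {pname}_{phase} panel, missing {missing}")
            else:
                panels[f"{pname}_{phase}"] = None

    followups = []
    for k in range(1, MAX_FOLLOWUPS + 1):
        days = cell(f"fu{k}_interval_days", "int")
        if days is None:
            continue
        followups.append(FollowUp(
            interval_days=days,
            mrs=req(f"fu{k}_mrs", "int"),
            inphgs=(req(f"fu{k}_inphgs_cognitive", "int"),
                    req(f"fu{k}_inphgs_gait", "int"),
                    req(f"fu{k}_inphgs_urinary", "int")),
            subjective_improvement=bool(req(f"fu{k}_subjective", "bool")),
        ))

    return PatientRecord(
        id=str(req("id", "str")),
        age=req("age", "float"),
        sex=req("sex", "str"),
        education=req("education", "float"),
        comorbidities=frozenset(c for c in COMORBIDITIES if req(c, "bool")),
        evans_index=req("evans_index", "float"),
        desh_score=req("desh_score", "int"),
        symptoms=frozenset(s for s in SYMPTOMS if req(f"sym_{s}", "bool")),
        mrs_baseline=req("mrs_baseline", "int"),
        inphgs_baseline=(req("inphgs_cognitive", "int"), req("inphgs_gait", "int"),
                         req("inphgs_urinary", "int")),
        shunted=bool(req("shunted", "bool")),
        followups=tuple(followups),
        **panels,
    )


def read_cohort(path, norm_path=None, desh_max: int = 10):
    """Read and validate a cohort CSV (and optionally a norms CSV).

    Returns ``list[PatientRecord]``, or ``(records, NormTable)`` when
    ``norm_path`` is given. Malformed cells raise :class:`CohortReadError`
    naming row and column; invariant violations raise
    :class:`ValidationError` naming the field.
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        unknown = set(reader.fieldnames or []) - set(COHORT_COLUMNS)
        if unknown:
            raise CohortReadError(f"unknown columns: {sorted(unknown)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            rec = _row_to_record(row, i)
            rec.validate(desh_max=desh_max)
            records.append(rec)
    if norm_path is None:
        return records
    return records, read_norms(norm_path)


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records to CSV; inverse of :func:`read_cohort` cell-for-cell."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COHORT_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))


def read_norms(path) -> NormTable:
    """Read a norms CSV with columns test, mean, sd, direction."""
    table = NormTable()
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            test = row["test"].strip()
            entry = NormEntry(
                mean=_parse(row["mean"], "float", i, "mean"),
                sd=_parse(row["sd"], "float", i, "sd"),
                direction=row["direction"].strip(),
            )
            if test in table:
                raise ValidationError(f"duplicate norm entry for {test}")
            table[test] = entry
    table.validate()
    return table


def write_norms(norms: NormTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["test", "mean", "sd", "direction"])
        for test, e in norms.items():
            writer.writerow([test, _fmt(e.mean), _fmt(e.sd), e.direction])


# --------------------------------------------------------------------------
# Report JSON
# --------------------------------------------------------------------------

def _sanitize(obj):
    """Recursively map NaN/inf to None so the report JSON never carries NaN."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if hasattr(obj, "item"):  # numpy scalar
        return _sanitize(obj.item())
    return obj


def write_report(report: dict, path) -> None:
    """Serialize an analysis report to JSON.

    Undefined metrics (NaN/inf) become ``null``; keys are sorted so that
    identical reports serialize byte-identically.
    """
    if "seed" not in report:
        raise ValidationError("report must carry a 'seed' key for reproducibility")
    Path(path).write_text(
        json.dumps(_sanitize(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
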