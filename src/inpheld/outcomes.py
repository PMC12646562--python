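"""Rule-based response classification.

Two label families are produced:

* drainage-test (ELD) positivity by the traditional criteria — at least one
  of: >=20% improvement in 10-m walk time or steps, >=10% improvement in
  both, >=10% improvement in TUG time, or >=3 raw points on the MMSE;
* shunt response — a >=1-point improvement in mRS, or in any single iNPH
  grading-scale domain, at the last follow-up versus baseline. Improvement
  that is only subjectively reported never qualifies.

All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .cohort_model import PatientRecord, TraditionalPanel, ValidationError
from .scoring import improvement_rate

__all__ = [
    "ResponderLabel",
    "classify_eld_response",
    "classify_shunt_response",
    "cohort_labels",
]

ELD_REASONS = ("tmwt_20", "tmwt_10_both", "tug_10", "mmse_3")
SHUNT_BASES = ("mrs", "inphgs_cognitive", "inphgs_gait", "inphgs_urinary")


@dataclass
class ResponderLabel:
    """Response labels for one patient."""

    id: str = ""
    eld_positive: Optional[bool] = None
    eld_reasons: set[str] = field(default_factory=set)
    shunt_responder: str = "not_shunted"  # responder | nonresponder | not_shunted
    basis: set[str] = field(default_factory=set)


def classify_eld_response(pre: TraditionalPanel, post: TraditionalPanel
                          ) -> ResponderLabel:
    """Traditional drainage-test positivity with every qualifying reason."""
    label = ResponderLabel()
    tmwt_time = improvement_rate(pre.tmwt_time, post.tmwt_time, "lower_better")
    tmwt_steps = improvement_rate(float(pre.tmwt_steps), float(post.tmwt_steps),
                                  "lower_better")
    tug = improvement_rate(pre.tug_time, post.tug_time, "lower_better")

    evaluable = False
    if tmwt_time is not None and tmwt_steps is not None:
        evaluable = True
        if tmwt_time >= 20.0 or tmwt_steps >= 20.0:
            label.eld_reasons.add("tmwt_20")
        if tmwt_time >= 10.0 and tmwt_steps >= 10.0:
            label.eld_reasons.add("tmwt_10_both")
    if tug is not None:
        evaluable = True
        if tug >= 10.0:
            label.eld_reasons.add("tug_10")
    # MMSE criterion is an absolute 3-point gain, not a percent
    evaluable = True
    if post.mmse - pre.mmse >= 3:
        label.eld_reasons.add("mmse_3")
    if not evaluable:
        raise ValidationError("no ELD criterion evaluable")
    label.eld_positive = bool(label.eld_reasons)
    return label


def classify_shunt_response(record: PatientRecord,
                            any_visit: bool = False) -> ResponderLabel:
    """Shunt-response label from follow-up mRS/iNPHGS versus baseline.

    By default only the last follow-up visit counts; ``any_visit=True``
    accepts improvement at any visit.
    """
    label = ResponderLabel(id=record.id)
    if not record.shunted:
        label.shunt_responder = "not_shunted"
        return label
    if not record.followups:
        raise ValidationError(f"record {record.id}: shunted but no follow-up")

    visits = record.followups if any_visit else (record.last_followup(),)
    for fu in visits:
        if record.mrs_baseline - fu.mrs >= 1:
            label.basis.add("mrs")
        for name, idx in (("inphgs_cognitive", 0), ("inphgs_gait", 1),
                          ("inphgs_urinary", 2)):
            if record.inphgs_baseline[idx] - fu.inphgs[idx] >= 1:
                label.basis.add(name)
    label.shunt_responder = "responder" if label.basis else "nonresponder"
    return label


def cohort_labels(records: Iterable[PatientRecord],
                  any_visit: bool = False) -> tuple[pd.DataFrame, dict]:
    """Per-patient labels plus cohort prevalence summary."""
    rows = []
    for rec in records:
        row = {"id": rec.id, "shunted": rec.shunted,
               "eld_positive": None, "eld_reasons": "",
               "shunt_responder": "not_shunted", "basis": ""}
        if rec.traditional_pre is not None and rec.traditional_post is not None:
            eld = classify_eld_response(rec.traditional_pre, rec.traditional_post)
            row["eld_positive"] = eld.eld_positive
            row["eld_reasons"] = "|".join(sorted(eld.eld_reasons))
        shunt = classify_shunt_response(rec, any_visit=any_visit)
        row["shunt_responder"] = shunt.shunt_responder
        row["basis"] = "|".join(sorted(shunt.basis))
        rows.append(row)
    table = pd.DataFrame(rows, columns=["id", "shunted", "eld_positive",
                                        "eld_reasons", "shunt_responder", "basis"])
    n_shunted = int(table["shunted"].sum()) if len(table) else 0
    n_resp = int((table["shunt_responder"] == "responder").sum()) if len(table) else 0
    n_nonresp = int((table["shunt_responder"] == "nonresponder").sum()) if len(table) else 0
    summary = {
        "n_total": len(table),
        "n_shunted": n_shunted,
        "n_responders": n_resp,
        "n_nonresponders": n_nonresp,
        "responder_proportion": (n_resp / n_shunted) if n_shunted else None,
    }
    return table, summary
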