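"""Direction-aware z standardisation and composite improvement rates.

All scores are mapped so that *larger is better*: for a higher-better test
z = (raw - mean)/sd, for a lower-better test (a time) z = (mean - raw)/sd.
Improvement rates are signed percents oriented the same way — positive
always means the patient got clinically better:

* higher-better parameter: (post - pre)/pre x 100
* lower-better parameter:  (pre - post)/pre x 100

The composite cognitive z is the mean of the five digital test z-scores;
its improvement rate divides by |z_pre| (configurable), because baseline
composite z is negative in an impaired cohort and a signed denominator
would flip the sign of every improvement. The gait rate is the mean of the
five oriented gait-parameter rates, the combined rate the (default equal-)
weighted mean of cognitive and gait rates, and the traditional rate the
mean of the four oriented traditional-test rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .cohort_model import (
    COGNITIVE_TESTS,
    CognitivePanel,
    GaitPanel,
    NormEntry,
    NormTable,
    PatientRecord,
    TraditionalPanel,
    ValidationError,
)

__all__ = [
    "ScoringOptions",
    "ImprovementProfile",
    "standardize",
    "inverse_standardize",
    "composite_cognitive_z",
    "improvement_rate",
    "gait_improvement",
    "cognitive_improvement",
    "combined_improvement",
    "traditional_composite",
    "improvement_profile",
    "GAIT_ORIENTATION",
    "TRADITIONAL_ORIENTATION",
]

#: Clinical orientation of each quantitative gait parameter.
GAIT_ORIENTATION = {
    "step_width": "lower_better",
    "stride_length": "higher_better",
    "step_height": "higher_better",
    "gait_velocity": "higher_better",
    "turning_time": "lower_better",
}

#: Clinical orientation of each traditional test. MMSE uses the
#: absolute-denominator percent form so the composite is commensurate.
TRADITIONAL_ORIENTATION = {
    "mmse": "higher_better",
    "tug_time": "lower_better",
    "tmwt_time": "lower_better",
    "tmwt_steps": "lower_better",
}


@dataclass(frozen=True)
class ScoringOptions:
    """Policy block for rate computation.

    cognitive_denominator
        ``"absolute"`` (default) divides the cognitive-z rate by |z_pre|;
        ``"raw"`` uses the signed baseline.
    eps
        denominators with |pre| <= eps are treated as undefined.
    combined_weights
        (cognitive, gait) weights for the combined rate.
    partial_mean
        when True, composites average over the components that are present
        instead of becoming undefined.
    """

    cognitive_denominator: str = "absolute"
    eps: float = 1e-9
    combined_weights: tuple[float, float] = (0.5, 0.5)
    partial_mean: bool = False

    def __post_init__(self):
        if self.cognitive_denominator not in ("absolute", "raw"):
            raise ValidationError("cognitive_denominator in (absolute, raw)")
        if not math.isclose(sum(self.combined_weights), 1.0):
            raise ValidationError("combined_weights must sum to 1")


@dataclass
class ImprovementProfile:
    """Per-parameter and composite improvement rates for one patient."""

    parameter_rates: dict[str, Optional[float]] = field(default_factory=dict)
    cognitive_z_pre: Optional[float] = None
    cognitive_z_post: Optional[float] = None
    cognitive_rate: Optional[float] = None
    gait_rate: Optional[float] = None
    combined_rate: Optional[float] = None
    traditional_rate: Optional[float] = None
    flags: set[str] = field(default_factory=set)


def standardize(raw: float, norm: NormEntry) -> float:
    """Direction-aware z-score; larger z always means better performance."""
    if norm.sd <= 0:
        raise ValidationError("norm sd > 0")
    if norm.direction == "higher_better":
        return (raw - norm.mean) / norm.sd
    if norm.direction == "lower_better":
        return (norm.mean - raw) / norm.sd
    raise ValidationError(f"unknown direction {norm.direction!r}")


def inverse_standardize(z: float, norm: NormEntry) -> float:
    """Raw score whose z-score is ``z`` under ``norm``."""
    if norm.direction == "higher_better":
        return norm.mean + z * norm.sd
    return norm.mean - z * norm.sd


def composite_cognitive_z(panel: CognitivePanel, norms: NormTable,
                          partial_mean: bool = False) -> Optional[float]:
    """Mean of the five digital-test z-scores; None if a norm is missing
    and partial averaging is off."""
    zs = []
    for test in COGNITIVE_TESTS:
        if test not in norms:
            if partial_mean:
                continue
            return None
        zs.append(standardize(getattr(panel, test), norms[test]))
    return sum(zs) / len(zs) if zs else None


def improvement_rate(pre: float, post: float, orientation: str,
                     denom: str = "raw", eps: float = 1e-9) -> Optional[float]:
    """Oriented percent change; positive means clinical improvement.

    ``denom="absolute"`` divides by |pre| (needed for scales that cross
    zero, such as the composite z). Returns None when |pre| <= eps.
    """
    if abs(pre) <= eps:
        return None
    d = abs(pre) if denom == "absolute" else pre
    if orientation == "higher_better":
        return (post - pre) / d * 100.0
    if orientation == "lower_better":
        return (pre - post) / d * 100.0
    raise ValidationError(f"unknown orientation {orientation!r}")


def gait_improvement(pre: GaitPanel, post: GaitPanel,
                     eps: float = 1e-9) -> tuple[Optional[float], dict, set]:
    """Mean oriented rate over the five gait parameters.

    Returns (rate, per-parameter rates, flags)."""
    rates, flags = {}, set()
    for p, orient in GAIT_ORIENTATION.items():
        r = improvement_rate(getattr(pre, p), getattr(post, p), orient, eps=eps)
        rates[p] = r
        if r is None:
            flags.add("zero_denominator")
    if any(v is None for v in rates.values()):
        flags.add("missing_component")
        return None, rates, flags
    return sum(rates.values()) / len(rates), rates, flags


def cognitive_improvement(z_pre: float, z_post: float,
                          denom: str = "absolute",
                          eps: float = 1e-9) -> Optional[float]:
    """Percent improvement of the composite cognitive z-score."""
    return improvement_rate(z_pre, z_post, "higher_better", denom=denom, eps=eps)


def combined_improvement(cognitive_rate: Optional[float],
                         gait_rate: Optional[float],
                         weights: tuple[float, float] = (0.5, 0.5)
                         ) -> Optional[float]:
    """Weighted mean of cognitive and gait rates (default equal weight)."""
    if cognitive_rate is None or gait_rate is None:
        return None
    wc, wg = weights
    return wc * cognitive_rate + wg * gait_rate


def traditional_composite(pre: TraditionalPanel, post: TraditionalPanel,
                          eps: float = 1e-9) -> tuple[Optional[float], dict, set]:
    """Mean oriented rate over the four traditional measures."""
    rates, flags = {}, set()
    for p, orient in TRADITIONAL_ORIENTATION.items():
        # MMSE crosses 0 only degenerately but use |pre| for commensurability
        denom = "absolute" if p == "mmse" else "raw"
        r = improvement_rate(float(getattr(pre, p)), float(getattr(post, p)),
                             orient, denom=denom, eps=eps)
        rates[p] = r
        if r is None:
            flags.add("zero_denominator")
    if any(v is None for v in rates.values()):
        flags.add("missing_component")
        return None, rates, flags
    return sum(rates.values()) / len(rates), rates, flags


def improvement_profile(record: PatientRecord, norms: NormTable,
                        options: ScoringOptions = ScoringOptions()
                        ) -> ImprovementProfile:
    """Full per-patient improvement profile from pre/post panels."""
    prof = ImprovementProfile()

    if record.cognitive_pre is not None and record.cognitive_post is not None:
        prof.cognitive_z_pre = composite_cognitive_z(
            record.cognitive_pre, norms, options.partial_mean)
        prof.cognitive_z_post = composite_cognitive_z(
            record.cognitive_post, norms, options.partial_mean)
        for test in COGNITIVE_TESTS:
            if test in norms:
                zp = standardize(getattr(record.cognitive_pre, test), norms[test])
                zq = standardize(getattr(record.cognitive_post, test), norms[test])
                prof.parameter_rates[test] = improvement_rate(
                    zp, zq, "higher_better", denom="absolute", eps=options.eps)
        if prof.cognitive_z_pre is not None and prof.cognitive_z_post is not None:
            prof.cognitive_rate = cognitive_improvement(
                prof.cognitive_z_pre, prof.cognitive_z_post,
                denom=options.cognitive_denominator, eps=options.eps)
            if prof.cognitive_rate is None:
                prof.flags.add("zero_denominator")
        else:
            prof.flags.add("missing_component")
    else:
        prof.flags.add("missing_component")

    if record.gait_pre is not None and record.gait_post is not None:
        prof.gait_rate, gait_rates, gflags = gait_improvement(
            record.gait_pre, record.gait_post, eps=options.eps)
        prof.parameter_rates.update(gait_rates)
        prof.flags |= gflags
    else:
        prof.flags.add("missing_component")

    prof.combined_rate = combined_improvement(
        prof.cognitive_rate, prof.gait_rate, options.combined_weights)

    if record.traditional_pre is not None and record.traditional_post is not None:
        prof.traditional_rate, trad_rates, tflags = traditional_composite(
            record.traditional_pre, record.traditional_post, eps=options.eps)
        prof.parameter_rates.update(trad_rates)
        prof.flags |= tflags
    else:
        prof.flags.add("missing_component")

    return prof
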