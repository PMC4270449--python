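"""Rule-based classification of CSA descriptor sets into six EEG patterns.

The six patterns describe the posterior dominant rhythm of a resting-state
recording, from a healthy stable alpha to a degraded unstable low-frequency
EEG:

* **1** stable alpha: alpha-dominant in >=60% of epochs, alpha DFV < 0.6 Hz,
  overall DFV < 1.6 Hz, little slow-band inscription;
* **1plus** unstable alpha: DF confined to the alpha band but with intrinsic
  variability >= 1.5 Hz;
* **2** unstable alpha with pre-alpha/theta: alpha-dominant in <50% of
  epochs, pre-alpha-dominant in >40%, DFV > 2 Hz;
* **3** stable pre-alpha: no alpha-dominant epoch, pre-alpha-dominant in
  >=70%, DF range within 5.6-7.9 Hz, DFV < 1.0 Hz;
* **4** unstable pre-alpha with theta/delta: no alpha, pre-alpha-dominant in
  <70%, theta/delta-dominant in >=40%, DFV > 2 Hz;
* **5** unstable low frequency: no alpha, no alpha/pre-alpha dominance in
  more than 2 consecutive epochs, DFV > 4 Hz.

The verbatim threshold rules overlap and leave gaps, so they are evaluated
in a fixed precedence order (stable/specific before unstable/general, and
the run-length-constrained pattern 5 before the broader pattern 4), with a
monotone fallback guaranteeing that every descriptor set receives exactly
one label.  Every decision is recorded in an auditable rule trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .descriptors import CSADescriptors


class PatternLabel(str, Enum):
    P1 = "1"
    P1PLUS = "1plus"
    P2 = "2"
    P3 = "3"
    P4 = "4"
    P5 = "5"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Order in which the verbatim rules are tried.
PRECEDENCE = (PatternLabel.P1, PatternLabel.P3, PatternLabel.P1PLUS,
              PatternLabel.P2, PatternLabel.P5, PatternLabel.P4)


@dataclass
class ClassificationResult:
    label: PatternLabel
    rule_trace: list = field(default_factory=list)
    fallback: bool = False


@dataclass
class OutcomePrediction:
    """EEG-only dementia-outcome prediction at the MCI stage."""

    predicted_group: str  # "DLB-like" or "AD-like"
    abnormal: bool


def _rule_p1(d: CSADescriptors) -> bool:
    return (
        d.df_mean >= 8.0
        and d.fp["alpha"] >= 60.0
        and d.dfv_alpha is not None
        and d.dfv_alpha < 0.6
        and d.dfv < 1.6
        and d.bi["prealpha"] < 30.0
        and d.bi["theta"] < 30.0
        and d.bi["delta"] < 30.0
    )


def _rule_p3(d: CSADescriptors) -> bool:
    return (
        d.fp["alpha"] == 0.0
        and d.fp["prealpha"] >= 70.0
        and d.df_min >= 5.6
        and d.df_max <= 7.9
        and d.dfv < 1.0
    )


def _rule_p1plus(d: CSADescriptors) -> bool:
    # DF confined to the alpha band with intrinsic variability >= 1.5 Hz.
    return d.fp["alpha"] == 100.0 and d.dfv >= 1.5


def _rule_p2(d: CSADescriptors) -> bool:
    return (
        0.0 < d.fp["alpha"] < 50.0
        and d.dfv > 2.0
        and d.fp["prealpha"] > 40.0
    )


def _rule_p5(d: CSADescriptors) -> bool:
    return d.fp["alpha"] == 0.0 and d.max_fast_run <= 2 and d.dfv > 4.0


def _rule_p4(d: CSADescriptors) -> bool:
    return (
        d.fp["alpha"] == 0.0
        and 0.0 < d.fp["prealpha"] < 70.0
        and d.fp["theta"] + d.fp["delta"] >= 40.0
        and d.dfv > 2.0
    )


_RULES = {
    PatternLabel.P1: _rule_p1,
    PatternLabel.P3: _rule_p3,
    PatternLabel.P1PLUS: _rule_p1plus,
    PatternLabel.P2: _rule_p2,
    PatternLabel.P5: _rule_p5,
    PatternLabel.P4: _rule_p4,
}


def _fallback(d: CSADescriptors, trace: list) -> PatternLabel:
    """Total assignment when no verbatim rule fires.

    Alpha-dominant recordings: FP-alpha >= 60 -> 1 if DFV < 1.5 else 1plus;
    any other alpha presence -> 2.  Alpha-absent recordings:
    FP-prealpha >= 70 -> 3, else 4 if DFV <= 4 else 5.  This interpolates
    the printed thresholds monotonically.
    """
    if d.fp["alpha"] > 0.0:
        if d.fp["alpha"] >= 60.0:
            label = PatternLabel.P1 if d.dfv < 1.5 else PatternLabel.P1PLUS
            trace.append((f"fallback:alpha>=60,dfv{'<' if d.dfv < 1.5 else '>='}1.5", True))
        else:
            label = PatternLabel.P2
            trace.append(("fallback:alpha<60", True))
    else:
        if d.fp["prealpha"] >= 70.0:
            label = PatternLabel.P3
            trace.append(("fallback:prealpha>=70", True))
        elif d.dfv <= 4.0:
            label = PatternLabel.P4
            trace.append(("fallback:slow,dfv<=4", True))
        else:
            label = PatternLabel.P5
            trace.append(("fallback:slow,dfv>4", True))
    return label


def classify(desc: CSADescriptors) -> ClassificationResult:
    """Assign exactly one pattern label; total over all descriptor sets."""
    trace = []
    for label in PRECEDENCE:
        fired = bool(_RULES[label](desc))
        trace.append((f"pattern_{label.value}", fired))
        if fired:
            return ClassificationResult(label=label, rule_trace=trace)
    label = _fallback(desc, trace)
    return ClassificationResult(label=label, rule_trace=trace, fallback=True)


def is_abnormal(desc: CSADescriptors, label: PatternLabel) -> bool:
    """Abnormal EEG: a pattern other than 1 with either mean epoch DF < 8 Hz
    or DFV > 1.5 Hz.  Pattern-1 recordings are never abnormal."""
    if label == PatternLabel.P1:
        return False
    return desc.df_mean < 8.0 or desc.dfv > 1.5


def predict_outcome(label: PatternLabel, abnormal: bool | None = None) -> OutcomePrediction:
    """Binary outcome prediction from the pattern at the MCI stage.

    Pattern 1 predicts conversion to AD; any other pattern predicts
    conversion to DLB.  Non-conversion is never predicted.
    """
    label = PatternLabel(label)
    dlb_like = label != PatternLabel.P1
    if abnormal is None:
        abnormal = dlb_like
    return OutcomePrediction(
        predicted_group="DLB-like" if dlb_like else "AD-like",
        abnormal=bool(abnormal),
    )
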