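"""Spirometry-derived responder classification after allergen inhalation.

Following inhaled allergen challenge, FEV1 is tracked for 7 hours.  All
allergic subjects show an early-phase fall (0-2 h); a subset develop the
late-phase asthmatic response (LAR), a second fall 3-7 h post-challenge.
Subjects with a maximum late-phase FEV1 drop of at least 15% are dual
responders (DR).  Because the LAR is accompanied by a roughly two-fold
drop in methacholine PC20, subjects still falling (>10% below baseline)
at 7 h whose allergen-induced shift (AIS = PC20_pre / PC20_post) is >= 2
are also called DR — they are presumed to have developed the LAR after
the last spirometry measurement.  Everyone else is an isolated early
responder (ER).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpirometryRecord:
    """FEV1 percent-change trajectory and PC20 pair for one subject.

    ``times`` in hours within [0, 7]; ``fev1_pct_change`` in percent
    relative to baseline (negative = fall); PC20 in mg/mL (> 0).
    """

    subject_id: str
    times: np.ndarray
    fev1_pct_change: np.ndarray
    pc20_pre: float
    pc20_post: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fev1_pct_change = np.asarray(self.fev1_pct_change, dtype=float)
        if self.times.shape != self.fev1_pct_change.shape:
            raise ValueError("times and fev1_pct_change must have the same length")
        if self.times.size and (self.times.min() < 0 or self.times.max() > 7):
            raise ValueError("measurement times must lie within [0, 7] hours")
        if self.pc20_pre <= 0 or self.pc20_post <= 0:
            raise ValueError("PC20 values must be positive")


@dataclass
class ResponderCall:
    label: str  # "ER" | "DR"
    rule_fired: str  # "late_drop" | "ais_rescue" | "none"

    def __post_init__(self) -> None:
        if (self.label == "DR") != (self.rule_fired in ("late_drop", "ais_rescue")):
            raise ValueError("label DR iff a DR rule fired")


def allergen_induced_shift(pc20_pre: float, pc20_post: float) -> float:
    """AIS = PC20(pre-challenge) / PC20(post-challenge); > 1 means increased
    airway hyperresponsiveness after allergen."""
    if pc20_pre <= 0 or pc20_post <= 0:
        raise ValueError("PC20 values must be positive")
    return pc20_pre / pc20_post


def max_late_drop(record: SpirometryRecord) -> float:
    """Most negative FEV1 percent change in the closed late window [3, 7] h."""
    mask = (record.times >= 3.0) & (record.times <= 7.0)
    if not mask.any():
        raise ValueError(f"subject {record.subject_id}: no measurements in [3, 7] h")
    return float(record.fev1_pct_change[mask].min())


def early_drop(record: SpirometryRecord) -> float:
    """Most negative FEV1 percent change in the early window [0, 2] h."""
    mask = (record.times >= 0.0) & (record.times <= 2.0)
    if not mask.any():
        raise ValueError(f"subject {record.subject_id}: no measurements in [0, 2] h")
    return float(record.fev1_pct_change[mask].min())


def drop_at_7h(record: SpirometryRecord, window: float = 0.25) -> float:
    """FEV1 percent change at the measurement nearest 7 h (within +/- ``window`` h)."""
    dist = np.abs(record.times - 7.0)
    i = int(np.argmin(dist))
    if dist[i] > window:
        raise ValueError(f"subject {record.subject_id}: no measurement within {window} h of 7 h")
    return float(record.fev1_pct_change[i])


def classify_responder(
    max_late_drop: float,
    drop_at_7h: float | None = None,
    ais: float | None = None,
) -> ResponderCall:
    """Classify ER vs DR from the late-phase drop, the 7 h drop, and the AIS.

    DR if the maximum late-phase fall reaches 15% (``max_late_drop <= -15``,
    inclusive); otherwise DR if FEV1 is still more than 10% below baseline
    at 7 h and AIS >= 2 (the subject is presumed to develop the LAR after
    the last measurement); otherwise ER.
    """
    if max_late_drop <= -15.0:
        return ResponderCall("DR", "late_drop")
    if drop_at_7h is not None and drop_at_7h < -10.0:
        if ais is None:
            raise ValueError("AIS required to evaluate the rescue rule (7 h drop > 10%)")
        if ais <= 0:
            raise ValueError("AIS must be positive")
        if ais >= 2.0:
            return ResponderCall("DR", "ais_rescue")
    return ResponderCall("ER", "none")


def classify_record(record: SpirometryRecord) -> ResponderCall:
    """Convenience wrapper applying the full DR/ER rule to one record."""
    return classify_responder(
        max_late_drop(record),
        drop_at_7h(record),
        allergen_induced_shift(record.pc20_pre, record.pc20_post),
    )
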