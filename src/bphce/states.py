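"""Health states and treatment arms of the BPH progression model.

The model follows men aged >=50 with symptomatic benign prostatic
hyperplasia through seven health states: symptomatic BPH, acute urinary
retention (AUR), first transurethral resection of the prostate (TURP),
repeat TURP, post-operative medical (pharmacological) management,
recovery, and death.  Death absorbs both procedure-related (30-day
post-TURP) and background all-cause mortality.
"""

from __future__ import annotations

from enum import IntEnum


class StateId(IntEnum):
    """Public seven-state space; BPH is the unique start state."""

    BPH = 0
    AUR = 1
    TURP = 2
    REPEAT_TURP = 3
    MEDICAL_INTERVENTION = 4
    RECOVERY = 5
    DEATH = 6


class Arm(IntEnum):
    """Treatment strategies compared by the model."""

    COMBINATION = 0   # single-dose dutasteride/tamsulosin daily
    MONOTHERAPY = 1   # tamsulosin 0.4 mg daily


N_STATES = len(StateId)

STATE_LABELS = {
    StateId.BPH: "BPH",
    StateId.AUR: "AUR",
    StateId.TURP: "TURP",
    StateId.REPEAT_TURP: "Repeat TURP",
    StateId.MEDICAL_INTERVENTION: "Medical intervention",
    StateId.RECOVERY: "Recovery",
    StateId.DEATH: "Death",
}

ARM_LABELS = {
    Arm.COMBINATION: "Combination therapy",
    Arm.MONOTHERAPY: "Monotherapy",
}


class ExpandedState(IntEnum):
    """Internal state space used by the simulation engines.

    The clinical rule that a patient undergoes at most two TURP
    procedures is history-dependent: a patient managed medically after a
    repeat TURP may not return to surgery, while one managed after the
    first TURP may.  The engines therefore split the medical and
    recovery states by the number of prior procedures; the public
    :class:`StateId` space is the aggregate of this chain.
    """

    BPH = 0
    AUR = 1
    TURP = 2
    REPEAT_TURP = 3
    MEDICAL_1 = 4   # medical management after one TURP (or after recovery)
    MEDICAL_2 = 5   # medical management after two TURPs; no further surgery
    RECOVERY_1 = 6
    RECOVERY_2 = 7
    DEATH = 8


N_EXPANDED = len(ExpandedState)

#: ExpandedState -> StateId aggregation map.
EXPANDED_TO_PUBLIC = {
    ExpandedState.BPH: StateId.BPH,
    ExpandedState.AUR: StateId.AUR,
    ExpandedState.TURP: StateId.TURP,
    ExpandedState.REPEAT_TURP: StateId.REPEAT_TURP,
    ExpandedState.MEDICAL_1: StateId.MEDICAL_INTERVENTION,
    ExpandedState.MEDICAL_2: StateId.MEDICAL_INTERVENTION,
    ExpandedState.RECOVERY_1: StateId.RECOVERY,
    ExpandedState.RECOVERY_2: StateId.RECOVERY,
    ExpandedState.DEATH: StateId.DEATH,
}
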