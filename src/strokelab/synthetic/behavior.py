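"""Cylinder-test event-stream generator.

Emulates the counting substrate of the cylinder test: per 15-min session a
fixed number of rears, each making first wall contact with the paw
contralateral to the lesion with a timepoint-specific probability. A
post-stroke deficit is simply a lowered contralateral probability that
recovers over the follow-up schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import numpy as np

from strokelab.behavior import TIMEPOINTS

__all__ = ["BehaviorSpec", "gen_paw_events"]

# Deficit emulating a significant early impairment recovering toward
# baseline by week four.
_DEFAULT_DEFICIT = {
    "4h": 0.25, "1d": 0.25, "3d": 0.30, "1w": 0.35,
    "2w": 0.45, "3w": 0.48, "4w": 0.50,
}


@dataclass
class BehaviorSpec:
    """Ground-truth paw-use probabilities for one subject.

    p_contra_by_timepoint maps each post-baseline timepoint to the
    probability that a rear's first contact uses the contralateral paw;
    missing timepoints fall back to ``p_contra_baseline``.
    """

    n_rears_per_session: int = 30
    p_contra_baseline: float = 0.5
    p_contra_by_timepoint: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEFICIT))
    subject_id: str = "m1"
    seed: int = 0

    def __post_init__(self):
        probs = [self.p_contra_baseline, *self.p_contra_by_timepoint.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all paw-use probabilities must be in [0, 1]")
        if self.n_rears_per_session < 0:
            raise ValueError("n_rears_per_session must be >= 0")
        unknown = set(self.p_contra_by_timepoint) - set(TIMEPOINTS)
        if unknown:
            raise ValueError(f"unknown timepoints {sorted(unknown)}")


def gen_paw_events(spec: BehaviorSpec) -> pd.DataFrame:
    """One row per rear: (subject_id, timepoint, rear_index, paw).

    Counts are binomial in the declared probabilities; an empty spec
    (zero rears) returns an empty, well-formed log.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for tp in TIMEPOINTS:
        p = (spec.p_contra_baseline if tp == "baseline"
             else spec.p_contra_by_timepoint.get(tp, spec.p_contra_baseline))
        for i in range(spec.n_rears_per_session):
            paw = "contra" if rng.random() < p else "ipsi"
            rows.append({"subject_id": spec.subject_id, "timepoint": tp,
                         "rear_index": i, "paw": paw})
    return pd.DataFrame(rows,
                        columns=["subject_id", "timepoint", "rear_index", "paw"])
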