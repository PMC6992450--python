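"""Cylinder-test scoring of forelimb-use asymmetry after stroke.

During rears in a glass cylinder, the paw (contralateral or ipsilateral to
the lesioned hemisphere) making first wall contact is counted per session.
Asymmetry is scored as the percent change from each animal's baseline in
its contralateral-use fraction — the fraction, not the raw count, so that
session length cancels and pre-existing paw preference is normalized out.
Reduced contralateral use after stroke therefore reads as a negative
percent change. Paired t-tests compare each post-stroke timepoint against
baseline across animals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TIMEPOINTS", "score_session", "longitudinal_tests"]

#: Testing schedule: baseline the week before stroke, then follow-up.
TIMEPOINTS = ("baseline", "4h", "1d", "3d", "1w", "2w", "3w", "4w")


def _validate_log(log: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "timepoint", "rear_index", "paw"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"event log missing columns {sorted(missing)}")
    bad_paw = set(log.paw.unique()) - {"contra", "ipsi"}
    if bad_paw:
        raise ValueError(f"unknown paw labels {sorted(bad_paw)}")
    bad_tp = set(log.timepoint.unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints {sorted(bad_tp)}")
    return log


def score_session(log: pd.DataFrame) -> pd.DataFrame:
    """Per subject x timepoint asymmetry table.

    Returns columns (subject_id, timepoint, n_contra, n_ipsi,
    contra_fraction, percent_change, flag). percent_change is
    100 * (f_t - f_baseline) / f_baseline on the contralateral-use fraction
    (0 at baseline by definition). A timepoint with zero rears yields a
    missing value flagged "no_rears"; a zero baseline contra count makes
    the percent change undefined, flagged "zero_baseline_use". Raw counts
    are kept alongside so a count-based reading is also available.
    """
    log = _validate_log(log)
    rows = []
    for subject, sub in log.groupby("subject_id", sort=True):
        counts = {}
        for tp in TIMEPOINTS:
            tp_events = sub[sub.timepoint == tp]
            counts[tp] = (int((tp_events.paw == "contra").sum()),
                          int((tp_events.paw == "ipsi").sum()))
        if sum(counts["baseline"]) == 0:
            raise ValueError(f"subject {subject!r} has no baseline session")
        nb_c, nb_i = counts["baseline"]
        f_base = nb_c / (nb_c + nb_i)
        for tp in TIMEPOINTS:
            n_c, n_i = counts[tp]
            total = n_c + n_i
            flag = ""
            if total == 0:
                frac = np.nan
                pct = np.nan
                flag = "no_rears"
            else:
                frac = n_c / total
                if tp == "baseline":
                    pct = 0.0
                elif f_base == 0:
                    pct = np.nan
                    flag = "zero_baseline_use"
                else:
                    pct = 100.0 * (frac - f_base) / f_base
            rows.append({"subject_id": subject, "timepoint": tp,
                         "n_contra": n_c, "n_ipsi": n_i,
                         "contra_fraction": frac, "percent_change": pct,
                         "flag": flag})
    return pd.DataFrame(rows)


def longitudinal_tests(table: pd.DataFrame, alpha: float = 0.05,
                       bonferroni: bool = False) -> pd.DataFrame:
    """Paired t-test of contralateral use at each timepoint vs baseline.

    Subjects lacking either member of a pair are dropped with a warning.
    ``bonferroni=True`` divides alpha by the number of post-baseline
    timepoints tested (no correction by default). Requires >= 2 complete
    pairs per tested timepoint.
    """
    wide = table.pivot(index="subject_id", columns="timepoint",
                       values="contra_fraction")
    if "baseline" not in wide.columns:
        raise ValueError("table has no baseline timepoint")
    post_tps = [tp for tp in TIMEPOINTS
                if tp != "baseline" and tp in wide.columns]
    alpha_eff = alpha / len(post_tps) if (bonferroni and post_tps) else alpha
    rows = []
    for tp in post_tps:
        pair = wide[["baseline", tp]].dropna()
        n_dropped = len(wide) - len(pair)
        if n_dropped:
            warnings.warn(f"{n_dropped} subject(s) without a complete "
                          f"baseline/{tp} pair dropped")
        if len(pair) < 2:
            raise ValueError(
                f"timepoint {tp!r}: need >= 2 paired subjects, "
                f"have {len(pair)}")
        base = pair["baseline"].to_numpy()
        post = pair[tp].to_numpy()
        if np.array_equal(base, post):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(post, base)
        rows.append({"timepoint": tp, "n_pairs": len(pair),
                     "mean_change": float(np.mean(post - base)),
                     "t": t, "p": p, "significant": p < alpha_eff})
    return pd.DataFrame(rows)
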