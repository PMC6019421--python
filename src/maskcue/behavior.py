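"""Behavioral statistics for the mask/face categorization task.

Covers the analyses the two simulated experiments need: per-condition
accuracy and reaction-time summaries, paired t-tests, Pearson correlations,
signal-detection measures (d', criterion C, unbiased p(correct)), quintile
subgrouping by mask accuracy, and the 2 x 2 mixed ANOVA contrasting the
extreme subgroups on mask vs face accuracy.

Signal-detection conventions: "mask" responses are hits (the task prompt
asks whether the person is wearing a mask), so H is the proportion of mask
trials answered "mask" and F the proportion of real-face trials answered
"mask".  d' = z(H) - z(F) and C = -(z(H) + z(F)) / 2 with z the inverse
standard-normal CDF.  Extreme rates are handled with the log-linear
correction (add 0.5 to each response cell, 1 to each trial count) by
default; p(correct) = (H + (1 - F)) / 2 always uses the raw rates.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as st

from .types import GroupStats, SDTSummary, TestResult, TrialRecord, group_stats

logger = logging.getLogger(__name__)

_P_FLOOR = float(np.nextafter(0.0, 1.0))


def trials_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a tidy DataFrame (one row per response)."""
    return pd.DataFrame({
        "participant_id": [t.participant_id for t in trials],
        "stimulus_id": [t.stimulus_id for t in trials],
        "condition": [t.condition.value for t in trials],
        "truth": [t.truth for t in trials],
        "response": [t.response for t in trials],
        "rt_ms": [t.rt_ms if t.rt_ms is not None else np.nan for t in trials],
        "correct": [t.correct for t in trials],
    })


def condition_accuracy(trials: Sequence[TrialRecord]
                       ) -> Tuple[pd.DataFrame, Dict[str, GroupStats]]:
    """Per-participant, per-condition proportion correct plus group stats.

    Returns a DataFrame with columns participant_id / condition / accuracy
    (one row per participant x condition actually present) and, per
    condition, the group mean, SE = sd/sqrt(n), and t-based 95% CI across
    participants.  A participant missing a condition that others have is a
    contract violation.
    """
    if not trials:
        raise ValueError("no trials")
    df = trials_frame(trials)
    conditions = sorted(df["condition"].unique())
    participants = sorted(df["participant_id"].unique())
    counts = df.groupby(["participant_id", "condition"]).size()
    for p in participants:
        for c in conditions:
            if (p, c) not in counts.index:
                raise ValueError(f"participant {p} has no trials in condition {c}")
    acc = (df.groupby(["participant_id", "condition"])["correct"]
           .mean().rename("accuracy").reset_index())
    stats = {
        c: group_stats(acc.loc[acc["condition"] == c, "accuracy"].to_numpy())
        for c in conditions
    }
    return acc, stats


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classical paired (within-subjects) t-test on x - y, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(name="t", value=0.0, df=(n - 1,), p=1.0)
        # Zero variance around a nonzero mean: infinite t, p below the
        # smallest representable positive float.
        return TestResult(name="t", value=math.copysign(math.inf, d.mean()),
                          df=(n - 1,), p=_P_FLOOR)
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2.0 * st.t.sf(abs(t), n - 1))
    return TestResult(name="t", value=float(t), df=(n - 1,), p=max(p, _P_FLOOR))


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided p via the t transform (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("pearson needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = _P_FLOOR
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = max(float(2.0 * st.t.sf(abs(t), n - 2)), _P_FLOOR)
    return TestResult(name="r", value=r, df=(n - 2,), p=p,
                      effect_size=r, effect_size_name="r")


def sdt(trials: Sequence[TrialRecord], correction: str = "loglinear") -> SDTSummary:
    """Signal-detection summary for one participant's trials.

    ``correction`` is "loglinear" (default: add 0.5 per response cell and 1
    per trial count before forming the rates used for d' and C) or "none",
    in which case a hit or false-alarm rate of exactly 0 or 1 raises rather
    than being silently clamped.
    """
    if correction not in ("none", "loglinear"):
        raise ValueError(f"unknown correction {correction!r}")
    n_sig = sum(1 for t in trials if t.truth == "mask")
    n_noise = sum(1 for t in trials if t.truth == "face")
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need both mask (signal) and face (noise) trials")
    hits = sum(1 for t in trials if t.truth == "mask" and t.response == "mask")
    fas = sum(1 for t in trials if t.truth == "face" and t.response == "mask")
    h_raw = hits / n_sig
    f_raw = fas / n_noise
    if correction == "loglinear":
        h = (hits + 0.5) / (n_sig + 1)
        f = (fas + 0.5) / (n_noise + 1)
    else:
        if h_raw in (0.0, 1.0) or f_raw in (0.0, 1.0):
            raise ValueError(
                "degenerate hit/false-alarm rate (0 or 1) with correction='none'")
        h, f = h_raw, f_raw
    zh = float(st.norm.ppf(h))
    zf = float(st.norm.ppf(f))
    return SDTSummary(
        hit_rate=h_raw,
        fa_rate=f_raw,
        hit_rate_corrected=h,
        fa_rate_corrected=f,
        dprime=zh - zf,
        criterion=-(zh + zf) / 2.0,
        pcorrect=pcorrect_from_rates(h_raw, f_raw),
        n_signal=n_sig,
        n_noise=n_noise,
        correction=correction,
    )


def pcorrect_from_rates(hit_rate: float, fa_rate: float) -> float:
    """Unbiased proportion correct: mean of hit and correct-rejection rates."""
    return (hit_rate + (1.0 - fa_rate)) / 2.0


def sdt_by_participant(trials: Sequence[TrialRecord],
                       correction: str = "loglinear") -> Dict[str, SDTSummary]:
    by: Dict[str, List[TrialRecord]] = defaultdict(list)
    for t in trials:
        by[t.participant_id].append(t)
    return {p: sdt(ts, correction=correction) for p, ts in sorted(by.items())}


def quintile_split(scores: Mapping[str, float]) -> pd.DataFrame:
    """Rank participants by score and assign performance quintiles.

    Returns a DataFrame (participant_id, score, rank, quintile, subgroup)
    where quintile 1 is the lowest-scoring fifth and subgroup flags the
    extreme quintiles as "low" / "high" (else "mid").  Ties are broken by
    ascending participant_id (stable).  When n is not divisible by 5 the
    split is near-equal: the extreme quintiles keep floor(n/5) members and
    the remainder is absorbed by the middle quintiles, so the contrasted
    subgroups stay balanced.
    """
    n = len(scores)
    if n < 5:
        raise ValueError("need at least 5 participants for a quintile split")
    items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    base = n // 5
    rem = n - 5 * base
    sizes = [base] * 5
    for k in range(rem):  # distribute the remainder to middle quintiles
        sizes[1 + (k % 3)] += 1
    bounds = np.cumsum([0] + sizes)
    rows = []
    for q in range(5):
        for rank in range(bounds[q], bounds[q + 1]):
            pid, sc = items[rank]
            sub = "low" if q == 0 else ("high" if q == 4 else "mid")
            rows.append((pid, sc, rank + 1, q + 1, sub))
    return pd.DataFrame(rows, columns=["participant_id", "score", "rank",
                                       "quintile", "subgroup"])


def mixed_anova_2x2(mask_acc: Mapping[str, float], face_acc: Mapping[str, float],
                    subgroup: Mapping[str, str]) -> Dict[str, TestResult]:
    """2 x 2 mixed ANOVA: image type (within) x subgroup (between).

    Classical sums-of-squares decomposition on the cell means; each
    participant contributes one mask and one face accuracy and belongs to
    one of two subgroups.  All three effects are tested on 1 numerator df;
    the between-subjects error term (df = N - 2) serves the subgroup effect
    and the within-subjects error term (df = N - 2) serves the image-type
    and interaction effects.  Effect sizes are partial eta-squared,
    SS_effect / (SS_effect + SS_error).
    """
    pids = sorted(mask_acc)
    if sorted(face_acc) != pids or any(p not in subgroup for p in pids):
        raise ValueError("mask_acc, face_acc and subgroup must cover the same participants")
    groups = sorted(set(subgroup[p] for p in pids))
    if len(groups) != 2:
        raise ValueError("exactly two subgroups required")
    for g in groups:
        if sum(1 for p in pids if subgroup[p] == g) < 2:
            raise ValueError(f"subgroup {g!r} has fewer than 2 participants")

    y = np.array([[mask_acc[p], face_acc[p]] for p in pids])  # (N, 2)
    glab = np.array([subgroup[p] for p in pids])
    n_total = len(pids)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_subjects = 2.0 * ((subj_means - grand) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    for g in groups:
        sel = glab == g
        n_g = sel.sum()
        ss_group += 2.0 * n_g * (y[sel].mean() - grand) ** 2
        for j in (0, 1):
            ss_cells += n_g * (y[sel, j].mean() - grand) ** 2
    ss_cond = n_total * ((cond_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_cond
    ss_total = ((y - grand) ** 2).sum()
    ss_err_between = ss_subjects - ss_group
    ss_err_within = ss_total - ss_subjects - ss_cond - ss_inter

    df_err = n_total - 2

    def _f(ss_eff: float, ss_err: float) -> TestResult:
        ms_err = ss_err / df_err
        f = ss_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else math.inf)
        if math.isinf(f):
            p = _P_FLOOR
        else:
            p = max(float(st.f.sf(f, 1, df_err)), _P_FLOOR)
        denom = ss_eff + ss_err
        eta = ss_eff / denom if denom > 0 else 0.0
        return TestResult(name="F", value=float(f), df=(1, df_err), p=p,
                          effect_size=float(eta), effect_size_name="partial_eta_sq")

    return {
        "image_type": _f(ss_cond, ss_err_within),
        "subgroup": _f(ss_group, ss_err_between),
        "interaction": _f(ss_inter, ss_err_within),
    }


def rt_summary(trials: Sequence[TrialRecord]
               ) -> Tuple[pd.DataFrame, Dict[str, GroupStats]]:
    """Mean correct-trial RT per participant per condition, plus group stats.

    Incorrect trials never contribute.  A participant with no correct
    trials in a condition is dropped from that condition's group statistics
    with a logged warning.
    """
    if not trials:
        raise ValueError("no trials")
    if any(t.rt_ms is None for t in trials):
        raise ValueError("rt_ms absent on some trials; RT summary unavailable")
    df = trials_frame(trials)
    correct = df[df["correct"]]
    per = (correct.groupby(["participant_id", "condition"])["rt_ms"]
           .mean().rename("mean_rt_ms").reset_index())
    out: Dict[str, GroupStats] = {}
    for c in sorted(df["condition"].unique()):
        vals = per.loc[per["condition"] == c, "mean_rt_ms"]
        n_missing = df["participant_id"].nunique() - len(vals)
        if n_missing:
            logger.warning("rt_summary: %d participant(s) had no correct trials "
                           "in condition %s and were dropped", n_missing, c)
        if len(vals):
            out[c] = group_stats(vals.to_numpy())
    return per, out
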