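"""Participant-level scoring of the three executive-function tasks.

Turns per-trial records of a task-switching paradigm, a 2-back spatial
working-memory task and a stop-signal task into the three performance
measures that feed the Unity-and-Diversity component analysis:

* switch cost — mean RT on switch trials minus mean RT on repeat trials,
  restricted to correct, informatively cued trials in mixed-task blocks;
* d' — signal-detection sensitivity Z(H) − Z(F) for the 2-back task,
  also returned negated so that higher always means worse;
* SSRT — stop-signal reaction time by the median method, median correct
  go RT minus median stop-signal delay.

All scorers accept a tidy :class:`pandas.DataFrame` of trials (one row per
trial, multiple participants allowed) plus the participant id to score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


class InsufficientTrialsError(ValueError):
    """Raised when a required trial cell is empty for a participant."""


class UndefinedRateError(ValueError):
    """Raised when a hit or false-alarm rate has no defining trials."""


@dataclass(frozen=True)
class BehavioralScores:
    """Per-participant performance summary across the three tasks.

    ``dprime_neg`` is exactly ``-dprime``; the sign flip orients the 2-back
    measure so that, like switch cost and SSRT, higher values mean worse
    performance.
    """

    participant_id: str
    switch_cost: float
    dprime: float
    dprime_neg: float
    ssrt: float
    go_rt_median: float
    stop_success_rate: float


def _participant_rows(trials: pd.DataFrame, participant: str) -> pd.DataFrame:
    rows = trials[trials["participant_id"].astype(str) == str(participant)]
    if rows.empty:
        raise InsufficientTrialsError(
            f"participant {participant!r}: no trials in table"
        )
    return rows


def score_switch_cost(trials: pd.DataFrame, participant: str) -> float:
    """Switch cost (ms) from mixed-block, informative-cue, correct trials.

    The cost is ``mean(RT | switch) - mean(RT | repeat)`` computed only over
    correct trials with an informative cue in mixed-task blocks; error trials
    are excluded because they trigger feedback and postpone the next trial,
    and noninformative-cue trials measure a different (cue-uninformed)
    process.
    """
    rows = _participant_rows(trials, participant)
    eligible = rows[
        (rows["block_kind"] == "mixed")
        & (rows["cue_kind"] == "informative")
        & rows["correct"].astype(bool)
        & rows["rt"].notna()
    ]
    switch_rt = eligible.loc[eligible["trial_kind"] == "switch", "rt"].to_numpy(float)
    repeat_rt = eligible.loc[eligible["trial_kind"] == "repeat", "rt"].to_numpy(float)
    for name, cell in (("switch", switch_rt), ("repeat", repeat_rt)):
        if cell.size == 0:
            raise InsufficientTrialsError(
                f"participant {participant!r}: insufficient trials in the "
                f"correct informative-cue mixed-block {name} cell"
            )
    return float(switch_rt.mean() - repeat_rt.mean())


def _rate_with_extreme_correction(hits: int, n: int) -> float:
    """Proportion hits/n with 0 and 1 replaced by 1/(2n) and 1 - 1/(2n)."""
    rate = hits / n
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def score_dprime(trials: pd.DataFrame, participant: str) -> tuple[float, float]:
    """2-back sensitivity d' = Z(H) − Z(F), plus its negation.

    H is the proportion of targets answered "same", F the proportion of
    nontargets answered "same". Omitted responses count as misses on targets
    and correct rejections on nontargets. Extreme rates (0 or 1) are replaced
    by 1/(2N) and 1 − 1/(2N) with N the number of trials in that cell, so the
    normal quantiles stay finite.
    """
    rows = _participant_rows(trials, participant)
    targets = rows[rows["is_target"].astype(bool)]
    nontargets = rows[~rows["is_target"].astype(bool)]
    if targets.empty or nontargets.empty:
        raise UndefinedRateError(
            f"participant {participant!r}: undefined rate "
            f"({len(targets)} targets, {len(nontargets)} nontargets)"
        )
    hit = _rate_with_extreme_correction(
        int((targets["response"] == "same").sum()), len(targets)
    )
    fa = _rate_with_extreme_correction(
        int((nontargets["response"] == "same").sum()), len(nontargets)
    )
    d = float(norm.ppf(hit) - norm.ppf(fa))
    return d, -d


def _go_and_stop_sets(
    trials: pd.DataFrame, participant: str
) -> tuple[np.ndarray, pd.DataFrame]:
    rows = _participant_rows(trials, participant)
    go = rows[
        (rows["trial_kind"] == "go")
        & rows["correct"].astype(bool)
        & rows["rt"].notna()
    ]
    stop = rows[rows["trial_kind"] == "stop"]
    if go.empty:
        raise InsufficientTrialsError(
            f"participant {participant!r}: insufficient trials (no correct "
            "responded go trials)"
        )
    if stop.empty:
        raise InsufficientTrialsError(
            f"participant {participant!r}: insufficient trials (no stop trials)"
        )
    return go["rt"].to_numpy(float), stop


def score_ssrt(trials: pd.DataFrame, participant: str) -> tuple[float, float, float]:
    """Median-method SSRT: median correct go RT minus median delivered SSD.

    Returns ``(ssrt, go_rt_median, stop_success_rate)``. Medians with an even
    number of values are the mean of the two central order statistics. The
    median method is used rather than the integration method because the
    latter leans harder on a constant-SSRT assumption of the horse-race
    model; see :func:`score_ssrt_integration` for the alternative.
    """
    go_rt, stop = _go_and_stop_sets(trials, participant)
    go_med = float(np.median(go_rt))
    ssd_med = float(np.median(stop["ssd"].to_numpy(float)))
    success_rate = float((stop["stop_outcome"] == "success").mean())
    return go_med - ssd_med, go_med, success_rate


def score_ssrt_integration(trials: pd.DataFrame, participant: str) -> float:
    """Integration-method SSRT (clearly-labeled alternative, not the default).

    The go-RT distribution is integrated up to the observed probability of
    responding on a stop trial; that quantile minus the mean SSD estimates
    SSRT under a constant-SSRT horse race.
    """
    go_rt, stop = _go_and_stop_sets(trials, participant)
    p_respond = float((stop["stop_outcome"] == "failure").mean())
    nth_rt = float(np.quantile(go_rt, p_respond)) if p_respond > 0 else float(
        np.min(go_rt)
    )
    return nth_rt - float(stop["ssd"].to_numpy(float).mean())


def score_participant(
    switch_trials: pd.DataFrame,
    nback_trials: pd.DataFrame,
    stop_trials: pd.DataFrame,
    participant: str,
) -> BehavioralScores:
    """Score one participant on all three tasks."""
    switch_cost = score_switch_cost(switch_trials, participant)
    d, d_neg = score_dprime(nback_trials, participant)
    ssrt, go_med, success = score_ssrt(stop_trials, participant)
    return BehavioralScores(
        participant_id=str(participant),
        switch_cost=switch_cost,
        dprime=d,
        dprime_neg=d_neg,
        ssrt=ssrt,
        go_rt_median=go_med,
        stop_success_rate=success,
    )


def score_participants(
    switch_trials: pd.DataFrame,
    nback_trials: pd.DataFrame,
    stop_trials: pd.DataFrame,
) -> pd.DataFrame:
    """Score every participant present in all three trial tables.

    Returns a tidy frame with one row per participant and columns
    ``participant_id, switch_cost, dprime, dprime_neg, ssrt, go_rt_median,
    stop_success_rate``, sorted by participant id.
    """
    ids = sorted(
        set(switch_trials["participant_id"].astype(str))
        & set(nback_trials["participant_id"].astype(str))
        & set(stop_trials["participant_id"].astype(str))
    )
    records = [
        score_participant(switch_trials, nback_trials, stop_trials, pid).__dict__
        for pid in ids
    ]
    return pd.DataFrame.from_records(
        records,
        columns=[
            "participant_id",
            "switch_cost",
            "dprime",
            "dprime_neg",
            "ssrt",
            "go_rt_median",
            "stop_success_rate",
        ],
    )
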