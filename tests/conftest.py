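"""Shared fixtures: tiny hand-checkable trial tables and graph builders."""

import numpy as np
import pandas as pd
import pytest


def make_switch_trials(rows, participant="p1"):
    """rows: iterable of (block_kind, cue_kind, trial_kind, rt, correct)."""
    return pd.DataFrame(
        [(participant, *r) for r in rows],
        columns=["participant_id", "block_kind", "cue_kind", "trial_kind",
                 "rt", "correct"],
    )


def make_nback_trials(n_target_same, n_target_other, n_nontarget_same,
                      n_nontarget_other, participant="p1"):
    """Counts of (target, 'same'), (target, other), (nontarget, 'same'),
    (nontarget, other) responses."""
    rows = (
        [(participant, True, "same", 800.0)] * n_target_same
        + [(participant, True, "different", 800.0)] * n_target_other
        + [(participant, False, "same", 800.0)] * n_nontarget_same
        + [(participant, False, "different", 800.0)] * n_nontarget_other
    )
    return pd.DataFrame(
        rows, columns=["participant_id", "is_target", "response", "rt"])


def make_stop_trials(go_rts, ssds, participant="p1", successes=None):
    """Go trials with the given RTs plus stop trials at the given SSDs."""
    if successes is None:
        successes = [True] * len(ssds)
    rows = [(participant, "go", rt, True, np.nan, np.nan, None)
            for rt in go_rts]
    for ssd, ok in zip(ssds, successes):
        rows.append((participant, "stop", np.nan if ok else 600.0, False,
                     float(ssd), 1, "success" if ok else "failure"))
    return pd.DataFrame(
        rows, columns=["participant_id", "trial_kind", "rt", "correct",
                       "ssd", "staircase_id", "stop_outcome"])


def random_modular_graph(rng, n_nodes, n_modules, allow_negative=True):
    """Random symmetric zero-diagonal weighted graph plus module labels."""
    W = rng.normal(0.4, 0.5, (n_nodes, n_nodes))
    if not allow_negative:
        W = np.abs(W)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    modules = rng.integers(0, n_modules, n_nodes)
    return W, modules


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
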