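"""Synthetic study data: task sessions, cohorts and connectivity matrices.

Everything the analysis pipeline consumes can be generated here with a known
ground truth, at the design sizes of the study it emulates:

* a stop-signal session simulator built on the independent horse-race model
  (ex-Gaussian go process, normally distributed stop process) run through
  the real adaptive procedure — two interleaved 1-up/1-down staircases
  starting at 150 and 350 ms, ±50 ms steps, stop-signal delay clamped to
  [0, 800] ms, five blocks of 100 go + 40 stop trials;
* mixed-block task-switching sequences with an exact 50% switch rate per
  block and no more than four same-kind trials in succession, plus RTs with
  an additive true switch cost;
* 2-back response streams from an equal-variance signal-detection model with
  a set true d' and criterion, on a positionally consistent target stream;
* participant cohorts with a linear age → mediators → EF path structure and
  a returned ground-truth ledger of every coefficient, for parameter-recovery
  and calibration experiments;
* modular weighted connectivity matrices with controllable within/between
  module strength for exercising the graph metrics.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

SSD_STEP = 50.0
SSD_BOUNDS = (0.0, 800.0)
SSD_STARTS = (150.0, 350.0)

STOP_COLUMNS = ["participant_id", "trial_kind", "rt", "correct", "ssd",
                "staircase_id", "stop_outcome"]
SWITCH_COLUMNS = ["participant_id", "block_kind", "cue_kind", "trial_kind",
                  "rt", "correct"]
NBACK_COLUMNS = ["participant_id", "is_target", "response", "rt"]


@dataclass(frozen=True)
class RaceModelParams:
    """Independent horse-race subject: ex-Gaussian go finishing times
    (mu, sigma, tau in ms) racing a normal stop process (mean, sd in ms;
    sd = 0 gives the constant-SSRT regime the median method assumes)."""

    go_mu: float = 500.0
    go_sigma: float = 50.0
    go_tau: float = 150.0
    ssrt_mean: float = 240.0
    ssrt_sd: float = 30.0
    go_omission_rate: float = 0.0
    go_error_rate: float = 0.0

    def __post_init__(self):
        for name in ("go_mu", "go_sigma", "go_tau", "ssrt_mean", "ssrt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("go_omission_rate", "go_error_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class StaircaseState:
    """The two interleaved stop-signal-delay staircases."""

    ssd_1: float = SSD_STARTS[0]
    ssd_2: float = SSD_STARTS[1]
    step: float = SSD_STEP
    lo: float = SSD_BOUNDS[0]
    hi: float = SSD_BOUNDS[1]


def staircase_update(
    state: StaircaseState, staircase_id: int, outcome: str
) -> StaircaseState:
    """Move one staircase ±step after a stop outcome, clamped to bounds.

    A successful stop makes the next delay harder (+step); a failed stop
    makes it easier (−step). The other staircase is untouched.
    """
    if staircase_id not in (1, 2):
        raise ValueError("staircase_id must be 1 or 2")
    if outcome not in ("success", "failure"):
        raise ValueError("outcome must be 'success' or 'failure'")
    delta = state.step if outcome == "success" else -state.step
    if staircase_id == 1:
        new = min(state.hi, max(state.lo, state.ssd_1 + delta))
        return StaircaseState(new, state.ssd_2, state.step, state.lo, state.hi)
    new = min(state.hi, max(state.lo, state.ssd_2 + delta))
    return StaircaseState(state.ssd_1, new, state.step, state.lo, state.hi)


def _ex_gaussian(rng: np.random.Generator, mu, sigma, tau, size) -> np.ndarray:
    g = rng.normal(mu, sigma, size) if sigma > 0 else np.full(size, float(mu))
    e = rng.exponential(tau, size) if tau > 0 else 0.0
    return g + e


def simulate_stop_signal_session(
    params: RaceModelParams,
    seed: int,
    participant_id: str = "sub-01",
    blocks: int = 5,
    go_per_block: int = 100,
    stop_per_block: int = 40,
) -> pd.DataFrame:
    """One subject's full stop-signal session under the adaptive procedure.

    Per stop trial: a go finishing time G and a stop finishing time S are
    drawn independently; the stop succeeds iff G > SSD + S (no response is
    emitted), otherwise the response escapes at RT = G. The staircase used
    on each stop trial is chosen uniformly at random and updated from the
    outcome. Go trials emit RT = G with the configured omission and error
    rates. Trial order is randomized within each block.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState()
    records = []
    for _ in range(blocks):
        kinds = np.array(["go"] * go_per_block + ["stop"] * stop_per_block)
        rng.shuffle(kinds)
        for kind in kinds:
            G = float(_ex_gaussian(rng, params.go_mu, params.go_sigma,
                                   params.go_tau, 1)[0])
            if kind == "go":
                omitted = rng.random() < params.go_omission_rate
                error = rng.random() < params.go_error_rate
                records.append(
                    (participant_id, "go",
                     np.nan if omitted else G,
                     (not omitted) and (not error),
                     np.nan, np.nan, None)
                )
                continue
            sc = int(rng.integers(1, 3))
            ssd = state.ssd_1 if sc == 1 else state.ssd_2
            S = (params.ssrt_mean if params.ssrt_sd == 0
                 else float(rng.normal(params.ssrt_mean, params.ssrt_sd)))
            success = G > ssd + S
            outcome = "success" if success else "failure"
            records.append(
                (participant_id, "stop",
                 np.nan if success else G,
                 False, ssd, sc, outcome)
            )
            state = staircase_update(state, sc, outcome)
    return pd.DataFrame.from_records(records, columns=STOP_COLUMNS)


def generate_switch_sequence(
    rng: np.random.Generator, n_trials: int = 70, max_run: int = 4
) -> np.ndarray:
    """Balanced switch/repeat labels with no same-kind run longer than
    ``max_run``, by shuffle-and-reject. Switch share is exactly half (the
    extra trial of an odd block is assigned at random)."""
    n_switch = n_trials // 2
    base = np.array(["switch"] * n_switch + ["repeat"] * (n_trials - n_switch))
    if n_trials % 2:
        base[-1] = rng.choice(["switch", "repeat"])
    for _ in range(100_000):
        rng.shuffle(base)
        runs = np.diff(np.flatnonzero(
            np.r_[True, base[1:] != base[:-1], True]))
        if runs.max() <= max_run:
            return base.copy()
    raise RuntimeError("could not satisfy the run-length constraint")


def simulate_switch_session(
    seed: int,
    participant_id: str = "sub-01",
    base_rt: float = 700.0,
    switch_cost_true: float = 80.0,
    noise_sd: float = 100.0,
    error_rate: float = 0.05,
    mixed_blocks_per_cue: int = 4,
    single_blocks: int = 4,
    trials_per_block: int = 70,
    max_run: int = 4,
) -> pd.DataFrame:
    """One subject's task-switching session.

    Mixed blocks (both informative- and noninformative-cue) carry the
    constrained switch/repeat sequence; single-task blocks are all repeat.
    RT = base + cost·1[switch] + N(0, noise_sd²); errors are injected
    independently at ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    records = []

    def emit(block_kind, cue_kind, kinds):
        for kind in kinds:
            rt = base_rt + (switch_cost_true if kind == "switch" else 0.0)
            if noise_sd > 0:
                rt += rng.normal(0.0, noise_sd)
            rt = max(rt, 1.0)
            correct = rng.random() >= error_rate
            records.append(
                (participant_id, block_kind, cue_kind, kind, rt, correct)
            )

    for _ in range(single_blocks):
        emit("single", "informative", ["repeat"] * trials_per_block)
    for cue in ("informative", "noninformative"):
        for _ in range(mixed_blocks_per_cue):
            emit("mixed", cue,
                 generate_switch_sequence(rng, trials_per_block, max_run))
    return pd.DataFrame.from_records(records, columns=SWITCH_COLUMNS)


def simulate_nback_session(
    seed: int,
    participant_id: str = "sub-01",
    true_dprime: float = 1.8,
    criterion: float = 0.0,
    blocks: int = 3,
    trials_per_block: int = 21,
    target_rate: float = 0.3,
    omission_rate: float = 0.02,
    n_positions: int = 9,
) -> pd.DataFrame:
    """One subject's 2-back session from an equal-variance SDT model.

    Stimulus positions are drawn on a grid so that ``is_target`` is exactly
    the 2-back positional match (the first two trials of a block are never
    targets). Targets are answered "same" with probability Φ(d'/2 − c),
    nontargets with probability Φ(−d'/2 − c); a small omission rate yields
    "none" responses.
    """
    if not np.isfinite(true_dprime):
        raise ValueError("true_dprime must be finite")
    rng = np.random.default_rng(seed)
    p_same_target = norm.cdf(true_dprime / 2.0 - criterion)
    p_same_nontarget = norm.cdf(-true_dprime / 2.0 - criterion)
    records = []
    for _ in range(blocks):
        positions: list[int] = []
        for t in range(trials_per_block):
            if t >= 2 and rng.random() < target_rate:
                positions.append(positions[t - 2])
            else:
                choices = list(range(n_positions))
                if t >= 2:
                    choices.remove(positions[t - 2])
                positions.append(int(rng.choice(choices)))
        for t, pos in enumerate(positions):
            is_target = t >= 2 and pos == positions[t - 2]
            if rng.random() < omission_rate:
                response, rt = "none", np.nan
            else:
                p_same = p_same_target if is_target else p_same_nontarget
                response = "same" if rng.random() < p_same else "different"
                rt = float(max(150.0, rng.normal(900.0, 250.0)))
            records.append((participant_id, is_target, response, rt))
    return pd.DataFrame.from_records(records, columns=NBACK_COLUMNS)


# ---------------------------------------------------------------------------
# cohort generator

#: default exposure→mediator standardized slopes; the six structural
#: measures sit in the negative range the study reports, the two network
#: measures are null
DEFAULT_AGE_SLOPES = {
    "gm_frontal_L": -0.50,
    "gm_frontal_R": -0.55,
    "gm_parietal_L": -0.45,
    "gm_parietal_R": -0.60,
    "fa_slf_L": -0.65,
    "fa_slf_R": -0.40,
    "pc_fp": 0.0,
    "wmd_fp": 0.0,
}

#: default mediator→outcome slopes: only the left frontal gray-matter
#: volume carries the outcome, giving one known nonzero indirect path
DEFAULT_B_PATHS = {
    "gm_frontal_L": -0.40,
    "gm_frontal_R": 0.0,
    "gm_parietal_L": 0.0,
    "gm_parietal_R": 0.0,
    "fa_slf_L": 0.0,
    "fa_slf_R": 0.0,
    "pc_fp": 0.0,
    "wmd_fp": 0.0,
}

#: mapping from z-scale task-score targets to natural units, anchored to the
#: study's printed task means/SDs (switch cost ~79±113 ms, SSRT ~241±113 ms,
#: d' sd ~0.6 around the level implied by ~81% accuracy)
TASK_SCALES = {
    "switch_cost": (78.69, 112.83),
    "dprime_neg": (-1.8, 0.6),
    "ssrt": (241.28, 113.29),
}


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth configuration of a simulated cohort.

    Slopes are on the standardized (z) scale. ``noise_scale`` in [0, 1]
    multiplies the residual standard deviation that would complete each
    equation to unit variance: 1 gives unit-variance variables whose
    construction slopes equal population-standardized coefficients. At 0 the
    mediators collapse onto the exposure and the path system is no longer
    identified; for exact ledger-recovery checks use ``exact_residuals``
    instead, which orthogonalizes every residual in-sample against its
    equation's design so that unstandardized OLS reproduces the ledger to
    machine precision while the system stays identified.
    """

    n: int = 126
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 78.0)
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    b_paths: dict = field(default_factory=lambda: dict(DEFAULT_B_PATHS))
    c_prime: float = 0.20
    covariate_effects: dict = field(default_factory=dict)
    noise_scale: float = 1.0
    task_loading: float = 0.85
    exact_residuals: bool = False

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not 0 <= self.noise_scale <= 1:
            raise ValueError("noise_scale must be in [0, 1]")
        if set(self.age_slopes) != set(self.b_paths):
            raise ValueError("age_slopes and b_paths must name the same mediators")


def cohort_truth(params: CohortParams) -> dict:
    """The ground-truth effect ledger implied by ``params``."""
    meds = list(params.age_slopes)
    a = {m: params.age_slopes[m] for m in meds}
    b = {m: params.b_paths[m] for m in meds}
    indirect = {m: a[m] * b[m] for m in meds}
    total_indirect = float(sum(indirect.values()))
    return {
        "mediators": meds,
        "a": a,
        "b": b,
        "indirect": indirect,
        "total_indirect": total_indirect,
        "direct": params.c_prime,
        "total": params.c_prime + total_indirect,
        "task_loading": params.task_loading,
    }


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Participant cohort with a known linear age→mediators→EF structure.

    Age is uniform on the configured range and standardized against its
    population moments; each mediator is ``a_j·z(age)`` plus noise scaled to
    unit variance; the outcome column ``ef_outcome`` follows the path model
    ``c'·z(age) + Σ b_j·m_j`` plus noise, with its residual chosen so the
    outcome has unit population variance. Three task-level true scores
    loading ``task_loading`` on the outcome are mapped to natural task units
    and stored alongside, so the trial-level generators and the scoring
    pipeline can be driven end-to-end. Covariates: gender ~ Bernoulli(0.5),
    education ~ clipped normal (14 ± 2.5 y), BDI-II ~ nonnegative normal
    clipped below the screening bound of 14.

    Returns the table and the ground-truth ledger.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    lo, hi = params.age_range
    age = rng.uniform(lo, hi, n)
    x = (age - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))

    gender = rng.integers(0, 2, n).astype(float)
    education = np.clip(rng.normal(14.0, 2.5, n), 6.0, 22.0)
    bdi = np.clip(rng.normal(5.0, 4.0, n), 0.0, 13.0)

    meds = list(params.age_slopes)
    table = pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": age,
            "age_z": x,  # population-standardized age used in construction
            "gender": gender,
            "education": education,
            "bdi": bdi,
        }
    )
    def _orthogonalize(e: np.ndarray, design: np.ndarray) -> np.ndarray:
        """Project e off the column space of design (incl. intercept)."""
        X = np.column_stack([np.ones(n), design])
        coefs, *_ = np.linalg.lstsq(X, e, rcond=None)
        return e - X @ coefs

    M = np.empty((n, len(meds)))
    a_vec = np.array([params.age_slopes[m] for m in meds])
    for j, m in enumerate(meds):
        resid_var = 1.0 - a_vec[j] ** 2
        if resid_var < 0:
            raise ValueError(f"|age slope| for {m} exceeds 1")
        sd = params.noise_scale * np.sqrt(resid_var)
        e = rng.normal(0.0, sd if sd > 0 else 1.0, n)
        if params.exact_residuals:
            e = _orthogonalize(e, x[:, None])
            e *= (sd if sd > 0 else np.sqrt(resid_var)) / e.std(ddof=1)
        elif sd == 0:
            e = np.zeros(n)
        M[:, j] = a_vec[j] * x + e
        table[m] = M[:, j]

    b_vec = np.array([params.b_paths[m] for m in meds])
    # population variance of the structural part of the outcome: mediators
    # have unit variance and pairwise covariance a_j a_k at noise_scale = 1
    cov_m = np.outer(a_vec, a_vec)
    np.fill_diagonal(cov_m, 1.0)
    signal_var = (
        params.c_prime ** 2
        + b_vec @ cov_m @ b_vec
        + 2.0 * params.c_prime * float(b_vec @ a_vec)
    )
    if signal_var > 1.0 + 1e-12:
        raise ValueError("path coefficients imply outcome variance > 1; "
                         "shrink c_prime or b_paths")
    y_sd = params.noise_scale * np.sqrt(max(0.0, 1.0 - signal_var))
    y = params.c_prime * x + M @ b_vec
    if params.exact_residuals:
        e = _orthogonalize(rng.normal(0.0, 1.0, n), np.column_stack([x, M]))
        if y_sd > 0:
            y = y + e * (y_sd / e.std(ddof=1))
    elif y_sd > 0:
        y = y + rng.normal(0.0, y_sd, n)
    table["ef_outcome"] = y

    lam = params.task_loading
    task_sd = params.noise_scale * np.sqrt(max(0.0, 1.0 - lam ** 2))
    for task, (mean, scale) in TASK_SCALES.items():
        z = lam * y + (rng.normal(0.0, task_sd, n) if task_sd > 0 else 0.0)
        table[f"{task}_true"] = mean + scale * z

    truth = cohort_truth(params)
    truth["n"] = n
    truth["seed"] = params.seed
    return table, truth


# ---------------------------------------------------------------------------
# connectivity generator

def simulate_fc_matrix(
    n_nodes: int,
    partition: np.ndarray,
    within_w: float = 1.0,
    between_w: float = 0.2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric zero-diagonal modular weight matrix.

    Edges take ``within_w`` inside a module and ``between_w`` across modules,
    plus symmetric Gaussian noise (which may create negative weights, on
    purpose, to exercise the negative-edge policy).
    """
    if not within_w >= between_w >= 0:
        raise ValueError("need within_w >= between_w >= 0")
    labels = np.asarray(partition)
    if len(labels) != n_nodes:
        raise ValueError("partition length must equal n_nodes")
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    W = np.where(same, within_w, between_w).astype(float)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, (n_nodes, n_nodes))
        W = W + (noise + noise.T) / np.sqrt(2.0)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# full input bundle

def write_input_bundle(
    outdir: str | Path,
    params: CohortParams | None = None,
    with_fc: bool = False,
    fc_nodes: int = 60,
    fc_modules: int = 4,
) -> dict:
    """Write every file the pipeline consumes, plus the truth ledger.

    Produces ``participants.csv`` (cohort with brain mediators and true task
    scores), one trial CSV per task spanning all participants (each driven
    by that participant's true task score), optionally per-participant dense
    FC matrices with a shared partition, ``truth.json`` and ``manifest.json``.
    Returns the manifest dict.
    """
    params = params or CohortParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(params)

    switch_tables, nback_tables, stop_tables = [], [], []
    rng = np.random.default_rng(params.seed + 1)
    for i, row in cohort.iterrows():
        pid = row["participant_id"]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        switch_tables.append(simulate_switch_session(
            seed=sub_seed, participant_id=pid,
            switch_cost_true=float(row["switch_cost_true"]),
        ))
        nback_tables.append(simulate_nback_session(
            seed=sub_seed + 1, participant_id=pid,
            true_dprime=float(max(0.05, -row["dprime_neg_true"])),
        ))
        stop_tables.append(simulate_stop_signal_session(
            RaceModelParams(ssrt_mean=float(max(80.0, row["ssrt_true"])),
                            go_omission_rate=0.02, go_error_rate=0.05),
            seed=sub_seed + 2, participant_id=pid,
        ))

    files = {
        "participants": outdir / "participants.csv",
        "switch_trials": outdir / "switch_trials.csv",
        "nback_trials": outdir / "nback_trials.csv",
        "stop_trials": outdir / "stop_trials.csv",
        "truth": outdir / "truth.json",
    }
    cohort.to_csv(files["participants"], index=False)
    pd.concat(switch_tables).to_csv(files["switch_trials"], index=False)
    pd.concat(nback_tables).to_csv(files["nback_trials"], index=False)
    pd.concat(stop_tables).to_csv(files["stop_trials"], index=False)
    files["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))

    if with_fc:
        fc_dir = outdir / "fc"
        fc_dir.mkdir(exist_ok=True)
        labels = np.repeat(np.arange(fc_modules), int(np.ceil(fc_nodes / fc_modules)))[:fc_nodes]
        node_ids = [f"node-{i:03d}" for i in range(fc_nodes)]
        pd.DataFrame({"node_id": node_ids, "module": labels}).to_csv(
            outdir / "partition.tsv", sep="\t", index=False)
        fp_nodes = node_ids[: max(1, fc_nodes // 3)]
        (outdir / "fp_nodes.txt").write_text("\n".join(fp_nodes) + "\n")
        fc_rng = np.random.default_rng(params.seed + 2)
        for pid in cohort["participant_id"]:
            W = simulate_fc_matrix(fc_nodes, labels, noise_sd=0.1,
                                   seed=int(fc_rng.integers(0, 2**31 - 1)))
            pd.DataFrame(W, columns=node_ids).to_csv(
                fc_dir / f"{pid}.tsv", sep="\t", index=False)
        files["fc_dir"] = fc_dir
        files["partition"] = outdir / "partition.tsv"
        files["fp_nodes"] = outdir / "fp_nodes.txt"

    manifest = {
        "seed": params.seed,
        "n": params.n,
        "params": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in asdict(params).items()},
        "files": {k: str(v) for k, v in files.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
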