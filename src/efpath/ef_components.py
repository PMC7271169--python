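"""Unity-and-Diversity executive-function components.

Implements the composite/residual arithmetic of the Miyake-style component
decomposition: each participant's three task measures (switch cost, negated
2-back d', SSRT — all oriented so that higher means worse) are z-scored
across the sample; their mean is the common EF component, and each task's
specific component is the OLS residual of its z-score after regressing out
the other two. Also provides plain and covariate-adjusted (partial) Pearson
correlation with t-based two-tailed p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: task measures entering the components, all oriented worse-is-higher
TASK_MEASURES = ("switch_cost", "dprime_neg", "ssrt")

COMPONENT_COLUMNS = (
    "common_ef",
    "shifting_specific",
    "updating_specific",
    "inhibition_specific",
)


def zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score (n−1 denominator). Raises on zero variance."""
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero-variance vector cannot be z-scored")
    return (x - x.mean()) / sd


def zscore_columns(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Return a copy of ``table`` with the named columns z-scored.

    Uses the sample standard deviation (n−1). A zero-variance column raises a
    ``ValueError`` naming the column.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(float)
        sd = np.nanstd(x, ddof=1)
        if not sd > 0:
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (x - np.nanmean(x)) / sd
    return out


def compute_common_ef(
    z_switch: np.ndarray, z_dneg: np.ndarray, z_ssrt: np.ndarray
) -> np.ndarray:
    """Common EF composite: the mean of the three z-scored task measures.

    Because every input is oriented worse-is-higher, a higher composite means
    generally worse executive function. Rows with any missing input come back
    as NaN (callers exclude them with a logged count).
    """
    stacked = np.column_stack(
        [np.asarray(z_switch, float), np.asarray(z_dneg, float), np.asarray(z_ssrt, float)]
    )
    missing = np.isnan(stacked).any(axis=1)
    if missing.any():
        logger.info("common EF: %d participant(s) excluded for missing inputs",
                    int(missing.sum()))
    out = stacked.mean(axis=1)
    out[missing] = np.nan
    return out


def compute_specific_ef(
    target: np.ndarray, other1: np.ndarray, other2: np.ndarray
) -> np.ndarray:
    """Specific EF component: OLS residuals of target on the other two tasks.

    Fits ``target ~ 1 + other1 + other2`` and returns the residuals in the
    original row order. Collinear regressors raise a rank-deficiency error.
    """
    y = np.asarray(target, float)
    X = np.column_stack(
        [np.ones_like(y), np.asarray(other1, float), np.asarray(other2, float)]
    )
    if y.size < 4:
        raise ValueError("need at least 4 rows to residualize on two regressors")
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: regressors are collinear")
    return y - X @ coefs


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), covariates])
    coefs, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coefs


def correlate_with_covariates(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y, optionally partialling out covariates.

    Both vectors are residualized on an intercept plus the covariate matrix
    and the residuals correlated; with no covariates this reduces to the
    ordinary Pearson r. The two-tailed p comes from the t-distribution with
    ``n − 2 − k`` degrees of freedom (k = number of covariates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(x):
            cov = cov.T
        k = cov.shape[1]
        rx = _residualize(x, cov)
        ry = _residualize(y, cov)
    n = len(x)
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"insufficient degrees of freedom (n={n}, covariates={k})")
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        raise ValueError("zero-variance residuals; correlation undefined")
    r = float((rx * ry).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p


def build_ef_components(
    scores: pd.DataFrame,
    rescale_specific: bool = True,
    dprime_column: str = "dprime_neg",
) -> pd.DataFrame:
    """Derive the four EF components from a participant score table.

    Parameters
    ----------
    scores
        One row per participant with columns ``participant_id`` and the three
        task measures (``switch_cost``, ``dprime_neg`` — or ``dprime`` if
        ``dprime_column`` says so — and ``ssrt``).
    rescale_specific
        Re-z-score the specific residuals before they leave, so every
        component is on the same unit-variance scale entering correlation and
        mediation models.
    dprime_column
        Which orientation of the 2-back measure to use in residualization;
        the negated d' keeps one worse-is-higher orientation everywhere and
        is the default.

    Returns
    -------
    DataFrame with ``participant_id``, ``common_ef``, ``shifting_specific``,
    ``updating_specific`` and ``inhibition_specific`` (all z-scale). Rows with
    a missing task measure are dropped with a logged count.
    """
    cols = ["switch_cost", dprime_column, "ssrt"]
    complete = scores.dropna(subset=cols)
    n_dropped = len(scores) - len(complete)
    if n_dropped:
        logger.info("EF components: %d participant(s) dropped (missing task scores)",
                    n_dropped)
    z_switch = zscore(complete["switch_cost"].to_numpy(float))
    z_dneg = zscore(complete[dprime_column].to_numpy(float))
    z_ssrt = zscore(complete["ssrt"].to_numpy(float))

    common = compute_common_ef(z_switch, z_dneg, z_ssrt)
    shifting = compute_specific_ef(z_switch, z_ssrt, z_dneg)
    updating = compute_specific_ef(z_dneg, z_switch, z_ssrt)
    inhibition = compute_specific_ef(z_ssrt, z_switch, z_dneg)
    if rescale_specific:
        shifting, updating, inhibition = map(zscore, (shifting, updating, inhibition))

    return pd.DataFrame(
        {
            "participant_id": complete["participant_id"].astype(str).to_numpy(),
            "common_ef": common,
            "shifting_specific": shifting,
            "updating_specific": updating,
            "inhibition_specific": inhibition,
        }
    )


def component_correlation_table(
    table: pd.DataFrame,
    columns: list[str],
    covariate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise (partial) correlation matrix as a tidy frame with r and p."""
    cov = (
        table[covariate_columns].to_numpy(float)
        if covariate_columns
        else None
    )
    records = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r, p = correlate_with_covariates(
                table[a].to_numpy(float), table[b].to_numpy(float), cov
            )
            records.append({"var_a": a, "var_b": b, "r": r, "p": p})
    return pd.DataFrame.from_records(records, columns=["var_a", "var_b", "r", "p"])
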