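"""Parallel multiple-mediator path model with bias-corrected bootstrap CIs.

The model is the saturated linear path system

    m_j = a0_j + a_j x + Σ g_jk c_k + e_j          (one per mediator j)
    y   = b0 + c' x + Σ_j b_j m_j + Σ d_k c_k + e  (outcome model)
    y   = t0 + c x + Σ d'_k c_k + e                (total-effect model)

with x the exposure (age), m_1..m_J the simultaneously entered mediators
(here 8 brain measures), y an executive-function component and c_k the
covariates (gender, education, BDI-II). Because the system is saturated,
ordinary least squares reproduces the maximum-likelihood point estimates,
and the OLS identity c = c' + Σ_j a_j b_j holds exactly on the fitted
sample. The specific indirect effect through mediator j is a_j·b_j, and the
total indirect effect is their sum.

Confidence intervals come from a cases bootstrap (participants resampled
with replacement) with bias-corrected (BC, no acceleration) percentile
endpoints: with z0 = Φ⁻¹(fraction of bootstrap draws below the full-sample
estimate, ties at midrank), the CI bounds are the empirical type-7 quantiles
of the bootstrap draws at levels Φ(2z0 + z_{α/2}) and Φ(2z0 + z_{1−α/2}).
Reported p-values invert that interval: the α at which an endpoint touches
zero. By default every variable is z-scored once on the listwise-complete
sample, so reported paths are standardized coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: the eight brain measures entered simultaneously in each model
DEFAULT_MEDIATORS = (
    "gm_frontal_L",
    "gm_frontal_R",
    "gm_parietal_L",
    "gm_parietal_R",
    "fa_slf_L",
    "fa_slf_R",
    "pc_fp",
    "wmd_fp",
)

DEFAULT_COVARIATES = ("gender", "education", "bdi")

#: the three executive-function outcomes, one mediation model each
STUDY_OUTCOMES = ("common_ef", "shifting_specific", "updating_specific")


@dataclass(frozen=True)
class MediationSpec:
    """Definition of one parallel mediation model."""

    x_name: str = "age"
    mediator_names: tuple[str, ...] = DEFAULT_MEDIATORS
    y_name: str = "common_ef"
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    n_boot: int = 5000
    ci_level: float = 95.0
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ci_level < 100:
            raise ValueError("ci_level must be in (0, 100)")
        meds = tuple(self.mediator_names)
        if not meds or len(set(meds)) != len(meds):
            raise ValueError("mediator_names must be nonempty and distinct")

    @property
    def columns(self) -> list[str]:
        return [self.x_name, *self.mediator_names, self.y_name,
                *self.covariate_names]


@dataclass
class MediationResult:
    """Estimates (and, after bootstrapping, BC CIs) for one model."""

    spec: MediationSpec
    a: dict[str, float]
    b: dict[str, float]
    indirect: dict[str, float]
    total_indirect: float
    c_prime: float
    c_total: float
    n_used: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    n_boot_redrawn: int = 0

    def effects(self) -> dict[str, float]:
        """Flat effect-name → estimate map (the bootstrap's target set)."""
        out: dict[str, float] = {}
        for m in self.spec.mediator_names:
            out[f"a:{m}"] = self.a[m]
            out[f"b:{m}"] = self.b[m]
            out[f"indirect:{m}"] = self.indirect[m]
        out["total_indirect"] = self.total_indirect
        out["direct"] = self.c_prime
        out["total"] = self.c_total
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy effect table (effect, estimate, ci_low, ci_high, p)."""
        rows = []
        for name, est in self.effects().items():
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append(
                {
                    "effect": name,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.pvalues.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "x": self.spec.x_name,
            "y": self.spec.y_name,
            "mediators": list(self.spec.mediator_names),
            "covariates": list(self.spec.covariate_names),
            "n_used": self.n_used,
            "n_boot": self.spec.n_boot,
            "ci_level": self.spec.ci_level,
            "a": self.a,
            "b": self.b,
            "indirect": self.indirect,
            "total_indirect": self.total_indirect,
            "direct": self.c_prime,
            "total": self.c_total,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "pvalues": self.pvalues,
        }


def _prepare_arrays(table: pd.DataFrame, spec: MediationSpec):
    """Listwise deletion, optional z-scoring; returns (x, M, y, C)."""
    missing = [c for c in spec.columns if c not in table.columns]
    if missing:
        raise ValueError(f"columns missing from table: {missing}")
    data = table[spec.columns].astype(float).dropna()
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("mediation %s ~ %s: %d row(s) dropped by listwise deletion",
                    spec.y_name, spec.x_name, n_dropped)
    J, K = len(spec.mediator_names), len(spec.covariate_names)
    n = len(data)
    if n <= J + K + 2:
        raise ValueError(
            f"insufficient sample: n={n} after listwise deletion, "
            f"need > {J + K + 2}"
        )
    Z = data.to_numpy(float)
    if spec.standardize:
        sd = Z.std(axis=0, ddof=1)
        zero = [spec.columns[i] for i in np.flatnonzero(sd == 0)]
        if zero:
            raise ValueError(f"zero-variance column(s): {zero}")
        Z = (Z - Z.mean(axis=0)) / sd
    x = Z[:, 0]
    M = Z[:, 1:1 + J]
    y = Z[:, 1 + J]
    C = Z[:, 2 + J:]
    return x, M, y, C


def _point_estimates(x, M, y, C):
    """OLS path estimates on one sample. Returns (a, b, c_prime, c_total)."""
    n, J = M.shape
    X1 = np.column_stack([np.ones(n), x, C])
    X2 = np.column_stack([np.ones(n), x, M, C])
    coef_m, _, rank1, _ = np.linalg.lstsq(X1, M, rcond=None)
    coef_y, _, rank2, _ = np.linalg.lstsq(X2, y, rcond=None)
    coef_t, *_ = np.linalg.lstsq(X1, y, rcond=None)
    if rank1 < X1.shape[1] or rank2 < X2.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design among exposure/mediators/covariates"
        )
    a = coef_m[1, :]
    c_prime = coef_y[1]
    b = coef_y[2:2 + J]
    c_total = coef_t[1]
    return a, b, float(c_prime), float(c_total)


def fit_path_model(table: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Point estimates of the parallel mediation model (no CIs)."""
    x, M, y, C = _prepare_arrays(table, spec)
    a, b, c_prime, c_total = _point_estimates(x, M, y, C)
    meds = spec.mediator_names
    indirect = {m: float(a[j] * b[j]) for j, m in enumerate(meds)}
    return MediationResult(
        spec=spec,
        a={m: float(a[j]) for j, m in enumerate(meds)},
        b={m: float(b[j]) for j, m in enumerate(meds)},
        indirect=indirect,
        total_indirect=float(sum(indirect.values())),
        c_prime=c_prime,
        c_total=c_total,
        n_used=len(x),
    )


def _batched_path_fits(x, M, y, C, idx):
    """Vectorized OLS path fits over resampled row-index matrix ``idx``.

    idx has shape (B, n). Returns arrays a (B,J), b (B,J), c_prime (B,),
    c_total (B,). Raises LinAlgError if any replicate is singular.
    """
    B, n = idx.shape
    J = M.shape[1]
    ones = np.ones((B, n, 1))
    xb = x[idx][..., None]
    Cb = C[idx] if C.shape[1] else np.empty((B, n, 0))
    Mb = M[idx]
    yb = y[idx][..., None]

    X1 = np.concatenate([ones, xb, Cb], axis=2)
    X2 = np.concatenate([ones, xb, Mb, Cb], axis=2)

    G1 = np.einsum("bni,bnj->bij", X1, X1)
    T1 = np.einsum("bni,bnj->bij", X1, np.concatenate([Mb, yb], axis=2))
    sol1 = np.linalg.solve(G1, T1)          # (B, p1, J+1)
    a = sol1[:, 1, :J]
    c_total = sol1[:, 1, J]

    G2 = np.einsum("bni,bnj->bij", X2, X2)
    T2 = np.einsum("bni,bn->bi", X2, yb[..., 0])
    sol2 = np.linalg.solve(G2, T2[..., None])[..., 0]   # (B, p2)
    c_prime = sol2[:, 1]
    b = sol2[:, 2:2 + J]
    return a, b, c_prime, c_total


def _bootstrap_draws(x, M, y, C, spec: MediationSpec):
    """Bootstrap the path fits; returns (draws dict, n_redrawn)."""
    n = len(x)
    B = spec.n_boot
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(B, n))
    try:
        a, b, c_prime, c_total = _batched_path_fits(x, M, y, C, idx)
        bad = ~(
            np.isfinite(a).all(axis=1)
            & np.isfinite(b).all(axis=1)
            & np.isfinite(c_prime)
            & np.isfinite(c_total)
        )
    except np.linalg.LinAlgError:
        # one singular replicate poisons the batched solve; refit each
        # replicate on its own rows and flag only the truly singular ones
        a = np.full((B, M.shape[1]), np.nan)
        b = np.full((B, M.shape[1]), np.nan)
        c_prime = np.full(B, np.nan)
        c_total = np.full(B, np.nan)
        bad = np.zeros(B, bool)
        for i in range(B):
            rows = idx[i]
            try:
                a[i], b[i], c_prime[i], c_total[i] = _point_estimates(
                    x[rows], M[rows], y[rows], C[rows]
                )
            except np.linalg.LinAlgError:
                bad[i] = True

    n_redrawn = 0
    max_attempts = 20
    attempts = 0
    while bad.any() and attempts < max_attempts:
        attempts += 1
        for i in np.flatnonzero(bad):
            rows = rng.integers(0, n, size=n)
            try:
                ai, bi, cpi, cti = _point_estimates(x[rows], M[rows], y[rows], C[rows])
            except np.linalg.LinAlgError:
                continue
            a[i], b[i], c_prime[i], c_total[i] = ai, bi, cpi, cti
            bad[i] = False
            n_redrawn += 1
    if bad.any():
        raise RuntimeError(
            f"{int(bad.sum())} of {B} bootstrap replicates degenerate even "
            "after redraws; the sample is too small or too discrete — "
            "consider a larger n"
        )
    if n_redrawn > 0.01 * B:
        raise RuntimeError(
            f"{n_redrawn} of {B} bootstrap replicates were singular and "
            "redrawn (> 1%); consider a larger n"
        )
    if n_redrawn:
        logger.info("bootstrap: %d singular replicate(s) redrawn", n_redrawn)

    meds = spec.mediator_names
    draws = {}
    for j, m in enumerate(meds):
        draws[f"a:{m}"] = a[:, j]
        draws[f"b:{m}"] = b[:, j]
        draws[f"indirect:{m}"] = a[:, j] * b[:, j]
    draws["total_indirect"] = (a * b).sum(axis=1)
    draws["direct"] = c_prime
    draws["total"] = c_total
    return draws, n_redrawn


def _midrank_proportion(draws: np.ndarray, value: float) -> float:
    B = len(draws)
    prop = (np.count_nonzero(draws < value)
            + 0.5 * np.count_nonzero(draws == value)) / B
    return float(np.clip(prop, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)))


def bc_interval(
    draws: np.ndarray, estimate: float, ci_level: float
) -> tuple[float, float]:
    """Bias-corrected percentile interval from bootstrap draws.

    z0 = Φ⁻¹(P*(θ* < θ̂)) with ties at midrank; endpoint levels are
    Φ(2z0 + z_{α/2}) and Φ(2z0 + z_{1−α/2}); quantiles use the linear
    (type-7) rule so hand oracles match. Degenerate all-equal draws
    collapse the interval to the point.
    """
    draws = np.asarray(draws, float)
    if np.all(draws == draws[0]):
        return float(draws[0]), float(draws[0])
    alpha = 1.0 - ci_level / 100.0
    z0 = norm.ppf(_midrank_proportion(draws, estimate))
    lo_level = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
    hi_level = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
    lo, hi = np.quantile(draws, [lo_level, hi_level], method="linear")
    return float(lo), float(hi)


def bc_pvalue(draws: np.ndarray, estimate: float) -> float:
    """Two-tailed CI-inversion p: the α at which a BC endpoint touches 0."""
    draws = np.asarray(draws, float)
    if np.all(draws == draws[0]):
        return 0.0 if draws[0] != 0 else 1.0
    z0 = norm.ppf(_midrank_proportion(draws, estimate))
    w = norm.ppf(_midrank_proportion(draws, 0.0))
    tail = norm.cdf(w - 2 * z0)
    return float(2 * min(tail, 1 - tail))


def bc_bootstrap(table: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Fit the path model and attach BC percentile bootstrap CIs/p-values."""
    x, M, y, C = _prepare_arrays(table, spec)
    a, b, c_prime, c_total = _point_estimates(x, M, y, C)
    meds = spec.mediator_names
    result = MediationResult(
        spec=spec,
        a={m: float(a[j]) for j, m in enumerate(meds)},
        b={m: float(b[j]) for j, m in enumerate(meds)},
        indirect={m: float(a[j] * b[j]) for j, m in enumerate(meds)},
        total_indirect=float((a * b).sum()),
        c_prime=c_prime,
        c_total=c_total,
        n_used=len(x),
    )
    draws, n_redrawn = _bootstrap_draws(x, M, y, C, spec)
    estimates = result.effects()
    for name, d in draws.items():
        result.ci[name] = bc_interval(d, estimates[name], spec.ci_level)
        result.pvalues[name] = bc_pvalue(d, estimates[name])
    result.n_boot_redrawn = n_redrawn
    return result


def decide_significance(result: MediationResult) -> dict[str, bool]:
    """Effect → True iff its CI excludes zero (a boundary at 0 is not
    significant)."""
    return {name: (lo > 0) or (hi < 0) for name, (lo, hi) in result.ci.items()}


def bonferroni_level(family_size: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha / family_size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


def age_brain_correlation_screen(
    table: pd.DataFrame,
    x_name: str = "age",
    mediator_names: tuple[str, ...] = DEFAULT_MEDIATORS,
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted exposure–mediator correlations with a Bonferroni
    per-test level over the mediator family."""
    from .ef_components import correlate_with_covariates

    level = bonferroni_level(len(mediator_names), alpha)
    data = table[[x_name, *mediator_names, *covariate_names]].astype(float).dropna()
    cov = data[list(covariate_names)].to_numpy(float) if covariate_names else None
    rows = []
    for m in mediator_names:
        r, p = correlate_with_covariates(
            data[x_name].to_numpy(float), data[m].to_numpy(float), cov
        )
        rows.append(
            {"mediator": m, "r": r, "p": p, "bonferroni_level": level,
             "significant": p < level}
        )
    return pd.DataFrame(rows)


def run_study_models(
    table: pd.DataFrame,
    base_spec: MediationSpec | None = None,
    outcomes: tuple[str, ...] = STUDY_OUTCOMES,
) -> tuple[dict[str, MediationResult], pd.DataFrame]:
    """The study's model set: one bootstrap mediation model per EF outcome
    plus the Bonferroni-screened exposure–mediator correlation family.

    Each model's bootstrap seed is offset by the outcome's position so the
    three models use distinct but reproducible resampling streams.
    """
    base = base_spec or MediationSpec()
    results: dict[str, MediationResult] = {}
    for i, yname in enumerate(outcomes):
        spec = replace(base, y_name=yname, seed=base.seed + i)
        results[yname] = bc_bootstrap(table, spec)
    screen = age_brain_correlation_screen(
        table,
        x_name=base.x_name,
        mediator_names=base.mediator_names,
        covariate_names=base.covariate_names,
    )
    return results, screen
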