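"""Three-equation mediation analysis with bootstrap inference.

Models whether a hyperedge weight ``w`` mediates the effect of an
exposure ``z`` (entorhinal tau SUVR in the motivating study) on an
outcome ``y`` (a cognitive composite score):

    y = i1 + c  z            + e1       (total effect)
    w = i2 + a  z            + e2       (exposure -> mediator)
    y = i3 + c' z + b w      + e3       (direct + mediated)

Optional covariates (age, sex, education, APOE4 status) enter all three
equations. With ordinary least squares and a shared covariate set the
decomposition ``c = c' + a*b`` is an algebraic identity, so total =
direct + indirect holds to numerical precision on every fit. The
significance of the indirect effect ``a*b`` comes from nonparametric case
resampling of subjects with a percentile confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panels import ContractError
from .weighting import WeightTable

__all__ = [
    "MediationInput",
    "MediationResult",
    "fit_mediation",
    "bootstrap_indirect",
    "run_mediation",
    "run_mediation_battery",
]

logger = logging.getLogger(__name__)


@dataclass
class MediationInput:
    """Aligned per-subject exposure, mediator, outcome and covariates."""

    z: np.ndarray
    w: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.z.size
        if self.w.size != n or self.y.size != n:
            raise ContractError("z, w, y must have equal length")
        arrays = [self.z, self.w, self.y]
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ContractError("covariate table length mismatch")
            arrays.append(self.covariates.to_numpy(dtype=float))
        if any(not np.all(np.isfinite(a)) for a in arrays):
            raise ContractError("mediation input contains missing values")

    @property
    def n(self) -> int:
        return self.z.size

    def take(self, idx: np.ndarray) -> "MediationInput":
        cov = None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True)
        return MediationInput(z=self.z[idx], w=self.w[idx], y=self.y[idx], covariates=cov)


@dataclass
class MediationResult:
    """Coefficients, effects and (optionally) bootstrap inference."""

    a: float
    b: float
    c: float
    c_prime: float
    i1: float
    i2: float
    i3: float
    total: float
    direct: float
    indirect: float
    p_total: float
    p_direct: float
    p_a: float
    p_b: float
    ci_indirect: tuple[float, float] | None = None
    p_indirect: float | None = None
    n_boot: int = 0
    seed: int | None = None
    n: int = 0


def _design(z: np.ndarray, covariates: pd.DataFrame | None, *extra: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(z), z, *extra]
    X = np.column_stack(cols)
    if covariates is not None:
        X = np.column_stack([X, covariates.to_numpy(dtype=float)])
    return X


def fit_mediation(inp: MediationInput) -> MediationResult:
    """Fit the three OLS equations and decompose the total effect."""
    # predictors in the full outcome equation: z, w and any covariates
    n_pred = 2 + (0 if inp.covariates is None else inp.covariates.shape[1])
    if inp.n <= n_pred + 1:
        raise ContractError(f"need n > {n_pred + 1} subjects, got {inp.n}")

    X1 = _design(inp.z, inp.covariates)  # y ~ z
    X3 = _design(inp.z, inp.covariates, inp.w)  # y ~ z + w
    for name, X in (("y~z", X1), ("y~z+w", X3)):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ContractError(f"rank-deficient design in equation {name} (collinearity)")

    eq_total = sm.OLS(inp.y, X1).fit()
    eq_med = sm.OLS(inp.w, X1).fit()  # same design: w ~ z (+ covariates)
    eq_full = sm.OLS(inp.y, X3).fit()

    c = float(eq_total.params[1])
    a = float(eq_med.params[1])
    c_prime = float(eq_full.params[1])
    b = float(eq_full.params[2])
    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        i1=float(eq_total.params[0]),
        i2=float(eq_med.params[0]),
        i3=float(eq_full.params[0]),
        total=c,
        direct=c_prime,
        indirect=a * b,
        p_total=float(eq_total.pvalues[1]),
        p_direct=float(eq_full.pvalues[1]),
        p_a=float(eq_med.pvalues[1]),
        p_b=float(eq_full.pvalues[2]),
        n=inp.n,
    )


def _indirect_effect_ols(
    z: np.ndarray, w: np.ndarray, y: np.ndarray, cov: np.ndarray | None
) -> float:
    """a*b from two least-squares fits; raises on rank deficiency."""
    ones = np.ones_like(z)
    X1 = np.column_stack([ones, z] if cov is None else [ones, z, cov])
    X3 = np.column_stack([ones, z, w] if cov is None else [ones, z, w, cov])
    beta_w, _, rank1, _ = np.linalg.lstsq(X1, w, rcond=None)
    beta_y, _, rank3, _ = np.linalg.lstsq(X3, y, rcond=None)
    if rank1 < X1.shape[1] or rank3 < X3.shape[1]:
        raise ContractError("rank-deficient resample")
    return float(beta_w[1] * beta_y[2])


def bootstrap_indirect(
    inp: MediationInput, n_boot: int = 1000, seed: int = 0
) -> tuple[tuple[float, float], float]:
    """Percentile bootstrap CI and two-sided p-value for the indirect effect.

    Subjects are resampled with replacement; for each resample the
    mediator and outcome equations are refit (plain least squares — only
    ``a*b`` is needed per resample) and the product recorded. The CI is
    the [2.5, 97.5] percentile interval; the p-value is the two-sided
    sign-proportion ``2 * min(P(ab <= 0), P(ab >= 0))`` floored at
    ``1/n_boot``. Rank-deficient resamples are redrawn (aborting after
    ``100 * n_boot`` total draws).
    """
    if inp.n < 10:
        raise ContractError("bootstrap needs n >= 10")
    rng = np.random.default_rng(seed)
    cov = None if inp.covariates is None else inp.covariates.to_numpy(dtype=float)
    indirect = np.empty(n_boot, dtype=float)
    draws = 0
    redraws = 0
    got = 0
    while got < n_boot:
        if draws >= 100 * n_boot:
            raise ContractError("bootstrap aborted: too many rank-deficient resamples")
        idx = rng.integers(0, inp.n, size=inp.n)
        draws += 1
        try:
            ab = _indirect_effect_ols(
                inp.z[idx], inp.w[idx], inp.y[idx], None if cov is None else cov[idx]
            )
        except ContractError:
            redraws += 1
            continue
        indirect[got] = ab
        got += 1
    if redraws:
        logger.info("bootstrap redrew %d rank-deficient resamples", redraws)
    lo, hi = np.percentile(indirect, [2.5, 97.5])
    p = 2.0 * min(np.mean(indirect <= 0.0), np.mean(indirect >= 0.0))
    p = float(min(1.0, max(p, 1.0 / n_boot)))
    return (float(lo), float(hi)), p


def run_mediation(
    inp: MediationInput, n_boot: int = 1000, seed: int = 0
) -> MediationResult:
    """Point fit plus bootstrap inference for one (mediator, outcome) pair."""
    res = fit_mediation(inp)
    ci, p = bootstrap_indirect(inp, n_boot=n_boot, seed=seed)
    res.ci_indirect = ci
    res.p_indirect = p
    res.n_boot = n_boot
    res.seed = seed
    return res


def run_mediation_battery(
    weights: WeightTable,
    significant_ids: list[str],
    clinical: pd.DataFrame,
    z_col: str,
    outcomes: list[str],
    covariate_cols: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], MediationResult]:
    """One mediation per (significant hyperedge, outcome).

    ``clinical`` is indexed by subject id and holds the exposure column,
    the outcome columns and any covariates. Subjects are intersected with
    the weight table; subjects missing the exposure or an outcome are
    dropped per outcome with a logged count. Binary covariates (sex,
    APOE4) are expected as 0/1 indicators.
    """
    common = weights.values.index.intersection(clinical.index)
    if common.empty:
        raise ContractError("no subjects shared between weights and clinical table")
    results: dict[tuple[str, str], MediationResult] = {}
    for outcome in outcomes:
        cols = [z_col, outcome] + (covariate_cols or [])
        sub = clinical.loc[common, cols]
        keep = sub.index[sub.notna().all(axis=1)]
        dropped = len(common) - len(keep)
        if dropped:
            logger.info(
                "outcome %s: dropped %d subject(s) with missing exposure/outcome", outcome, dropped
            )
        if keep.empty:
            raise ContractError(f"no complete cases for outcome {outcome!r}")
        cov = (
            sub.loc[keep, covariate_cols].reset_index(drop=True) if covariate_cols else None
        )
        for h in significant_ids:
            inp = MediationInput(
                z=sub.loc[keep, z_col].to_numpy(),
                w=weights.values.loc[keep, h].to_numpy(),
                y=sub.loc[keep, outcome].to_numpy(),
                covariates=cov,
            )
            results[(h, outcome)] = run_mediation(inp, n_boot=n_boot, seed=seed)
    return results
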