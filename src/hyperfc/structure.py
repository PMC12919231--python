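"""Shared hypergraph backbone from multi-subject regional time series.

Each region in turn is treated as a *centroid*: its z-scored series is
regressed on all other regions with a non-negativity-constrained LASSO,

    min_a  1/(2P) ||x_n - X_n a||_2^2 + lam * ||a||_1,   a >= 0,

where ``X_n`` is the subject's timepoints-by-regions matrix with column
``n`` replaced by zeros. The quadratic term is averaged per timepoint (the
scikit-learn convention), which is the scale on which the default penalty
grid [0.01, 0.30] is meaningful for unit-variance data. Per subject this
yields an ``N x N`` non-negative coefficient matrix; thresholding at the
fifth percentile of its positive entries, binarizing, forcing centroid
self-membership and dropping hyperedges with fewer than three regions give
a per-subject incidence matrix. Majority voting (>= 50% of the reference
cohort) then yields the shared backbone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso

from .hypergraph import IncidenceMatrix
from .panels import ContractError, TimeSeriesPanel

__all__ = [
    "CoefficientMatrix",
    "LambdaSelection",
    "StabilityReport",
    "fit_nonneg_lasso",
    "coefficient_matrix",
    "select_lambda_cv",
    "threshold_binarize",
    "filter_min_cardinality",
    "subject_incidence",
    "majority_vote",
    "build_backbone",
    "structure_stability",
    "truncation_stability",
    "default_lambda_grid",
    "contiguous_folds",
]

logger = logging.getLogger(__name__)

#: Convergence settings for the coordinate-descent solver. The tight
#: tolerance keeps sparsity patterns reproducible near the percentile
#: threshold.
_SOLVER_TOL = 1e-10
_SOLVER_MAX_ITER = 100_000


def default_lambda_grid() -> np.ndarray:
    """The default penalty grid: 0.01 to 0.30 in steps of 0.01."""
    return np.round(np.arange(1, 31) * 0.01, 2)


@dataclass
class CoefficientMatrix:
    """Per-subject non-negative LASSO coefficients, one row per centroid."""

    subject_id: str
    entries: np.ndarray  # (N, N), entries >= 0, zero diagonal
    lam: float

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n, m = self.entries.shape
        if n != m:
            raise ContractError("coefficient matrix must be square")
        if np.any(self.entries < 0):
            raise ContractError("coefficient matrix must be non-negative")
        if np.any(np.diagonal(self.entries) != 0):
            raise ContractError("coefficient matrix diagonal must be exactly 0")


@dataclass
class LambdaSelection:
    """Cross-validation summary for the sparsity penalty."""

    grid: np.ndarray
    chosen: float
    cv_train_mse: np.ndarray  # mean per lambda
    cv_train_sd: np.ndarray
    cv_val_mse: np.ndarray
    cv_val_sd: np.ndarray
    folds: int


@dataclass
class StabilityReport:
    """Cell-wise agreement between two backbone structures."""

    jaccard: float
    pearson: float
    n_hyperedges_a: int
    n_hyperedges_b: int


def _check_panel(panel: TimeSeriesPanel) -> None:
    if not panel.zscored:
        raise ContractError("structure inference requires a z-scored panel")


def fit_nonneg_lasso(panel: TimeSeriesPanel, centroid: int, lam: float) -> np.ndarray:
    """Non-negative LASSO coefficients predicting one centroid region.

    Returns a length-N vector ``a >= 0`` with ``a[centroid] == 0`` (the
    centroid's own column of the design is zeroed out, so its coefficient
    can never reduce the residual and the L1 penalty keeps it at 0).
    """
    _check_panel(panel)
    if lam < 0:
        raise ContractError(f"penalty must be non-negative, got {lam}")
    if not 0 <= centroid < panel.n_regions:
        raise ContractError(f"centroid index {centroid} out of range")
    y = panel.data[centroid]
    X = panel.data.T.copy()
    X[:, centroid] = 0.0
    if lam == 0:
        # unpenalised limit: plain NNLS on the zeroed design
        from scipy.optimize import nnls

        coefs, _ = nnls(X, y)
    else:
        model = Lasso(
            alpha=lam,
            positive=True,
            fit_intercept=False,
            tol=_SOLVER_TOL,
            max_iter=_SOLVER_MAX_ITER,
        )
        model.fit(X, y)
        coefs = model.coef_.copy()
    coefs[centroid] = 0.0
    np.clip(coefs, 0.0, None, out=coefs)
    return coefs


def coefficient_matrix(panel: TimeSeriesPanel, lam: float) -> CoefficientMatrix:
    """Fit every region as centroid; row ``n`` holds its coefficient vector."""
    _check_panel(panel)
    n = panel.n_regions
    A = np.empty((n, n), dtype=float)
    for c in range(n):
        A[c] = fit_nonneg_lasso(panel, c, lam)
    return CoefficientMatrix(subject_id=panel.subject_id, entries=A, lam=lam)


def contiguous_folds(n_timepoints: int, folds: int) -> list[np.ndarray]:
    """Contiguous timepoint blocks: fold k = [k*P/folds, (k+1)*P/folds).

    Contiguity respects the temporal autocorrelation of BOLD signals;
    shuffled folds would leak neighbouring timepoints across the split.
    """
    edges = np.linspace(0, n_timepoints, folds + 1).astype(int)
    return [np.arange(edges[k], edges[k + 1]) for k in range(folds)]


def select_lambda_cv(
    panels: list[TimeSeriesPanel],
    grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> LambdaSelection:
    """Choose the penalty by timepoint-fold cross-validation.

    For every candidate penalty, subject and centroid region, the model is
    fit on the training timepoints and scored (mean squared error) on the
    held-out block; the chosen penalty minimises the mean validation MSE
    over all (subject, centroid, fold) cells. Folds are contiguous blocks,
    so the procedure is deterministic; ``seed`` is recorded for provenance.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ContractError("empty penalty grid")
    if folds < 2:
        raise ContractError("need at least 2 folds")
    if not panels:
        raise ContractError("no panels supplied")
    for p in panels:
        _check_panel(p)
        if p.n_timepoints < folds:
            raise ContractError(f"panel {p.subject_id!r} has fewer timepoints than folds")

    train_mse = np.zeros((grid.size,), dtype=float)
    train_sq = np.zeros_like(train_mse)
    val_mse = np.zeros_like(train_mse)
    val_sq = np.zeros_like(train_mse)
    cells = 0
    for panel in panels:
        fold_idx = contiguous_folds(panel.n_timepoints, folds)
        all_idx = np.arange(panel.n_timepoints)
        for centroid in range(panel.n_regions):
            y = panel.data[centroid]
            X = panel.data.T.copy()
            X[:, centroid] = 0.0
            for val in fold_idx:
                train = np.setdiff1d(all_idx, val, assume_unique=True)
                for gi, lam in enumerate(grid):
                    model = Lasso(
                        alpha=lam,
                        positive=True,
                        fit_intercept=False,
                        tol=_SOLVER_TOL,
                        max_iter=_SOLVER_MAX_ITER,
                    )
                    model.fit(X[train], y[train])
                    tr_err = float(np.mean((y[train] - model.predict(X[train])) ** 2))
                    va_err = float(np.mean((y[val] - model.predict(X[val])) ** 2))
                    train_mse[gi] += tr_err
                    train_sq[gi] += tr_err**2
                    val_mse[gi] += va_err
                    val_sq[gi] += va_err**2
        cells += panel.n_regions * folds
    train_mean = train_mse / cells
    val_mean = val_mse / cells
    train_sd = np.sqrt(np.maximum(train_sq / cells - train_mean**2, 0.0))
    val_sd = np.sqrt(np.maximum(val_sq / cells - val_mean**2, 0.0))
    chosen = float(grid[int(np.argmin(val_mean))])
    logger.info("lambda CV over %d candidates: chose %.3g", grid.size, chosen)
    return LambdaSelection(
        grid=grid,
        chosen=chosen,
        cv_train_mse=train_mean,
        cv_train_sd=train_sd,
        cv_val_mse=val_mean,
        cv_val_sd=val_sd,
        folds=folds,
    )


def threshold_binarize(A: CoefficientMatrix, percentile: float = 5.0) -> np.ndarray:
    """Binarize a coefficient matrix at a percentile of its positive entries.

    The threshold is the linear-interpolation percentile of the *strictly
    positive* coefficients (non-negative LASSO leaves many exact zeros;
    including them would make a low percentile identically zero and the
    cut vacuous). Entries below the threshold are dropped, entries at or
    above it become 1; zero entries stay 0.
    """
    if not 0 <= percentile <= 100:
        raise ContractError(f"percentile {percentile} outside [0, 100]")
    vals = A.entries
    positive = vals[vals > 0]
    if positive.size == 0:
        return np.zeros_like(vals, dtype=np.int8)
    t = np.percentile(positive, percentile, method="linear")
    return ((vals > 0) & (vals >= t)).astype(np.int8)


def filter_min_cardinality(Hs: np.ndarray, min_regions: int = 3) -> np.ndarray:
    """Zero out centroid columns with fewer than ``min_regions`` members.

    ``Hs`` is a per-subject ``N x N`` membership matrix with columns
    indexed by centroid region. The centroid's own diagonal cell is forced
    to 1 for every column that has at least one member, then any column
    whose member count (centroid included) falls below ``min_regions`` is
    zeroed entirely. The minimum of three keeps only genuinely high-order
    relations — pairs are the province of ordinary graphs.
    """
    if min_regions < 1:
        raise ContractError("min_regions must be >= 1")
    Hs = np.asarray(Hs)
    if Hs.ndim != 2 or Hs.shape[0] != Hs.shape[1]:
        raise ContractError("per-subject membership matrix must be square")
    out = Hs.astype(np.int8).copy()
    has_member = out.sum(axis=0) > 0
    idx = np.flatnonzero(has_member)
    out[idx, idx] = 1
    small = out.sum(axis=0) < min_regions
    out[:, small] = 0
    return out


def subject_incidence(
    panel: TimeSeriesPanel,
    lam: float,
    percentile: float = 5.0,
    min_regions: int = 3,
) -> np.ndarray:
    """One subject's ``N x N`` binary membership matrix (columns = centroids)."""
    A = coefficient_matrix(panel, lam)
    # rows of A are centroids; columns of the membership matrix are centroids
    binary = threshold_binarize(A, percentile).T
    return filter_min_cardinality(binary, min_regions)


def majority_vote(
    Hs_list: list[np.ndarray],
    quorum: float = 0.5,
    min_regions: int = 3,
    region_labels: list[str] | None = None,
) -> IncidenceMatrix:
    """Consensus backbone across subjects by per-cell majority vote.

    A cell becomes 1 when the fraction of subjects with a 1 there is at
    least ``quorum`` (exactly 50% passes under the default). The
    min-cardinality filter is re-applied to the voted matrix — voting can
    shrink a hyperedge below three members — and all-zero centroid columns
    are dropped, giving an incidence matrix with ``M <= N`` hyperedges
    ordered by centroid index.
    """
    if not Hs_list:
        raise ContractError("empty subject list")
    if not 0 < quorum <= 1:
        raise ContractError(f"quorum {quorum} outside (0, 1]")
    shapes = {np.asarray(h).shape for h in Hs_list}
    if len(shapes) != 1:
        raise ContractError("per-subject matrices differ in shape")
    stack = np.stack([np.asarray(h, dtype=float) for h in Hs_list])
    voted = (stack.mean(axis=0) >= quorum).astype(np.int8)
    voted = filter_min_cardinality(voted, min_regions)
    centroids = np.flatnonzero(voted.sum(axis=0) > 0)
    logger.info(
        "majority vote over %d subjects: %d of %d centroid columns survive",
        len(Hs_list),
        centroids.size,
        voted.shape[1],
    )
    return IncidenceMatrix(
        entries=voted[:, centroids],
        region_labels=region_labels or [f"R{i}" for i in range(voted.shape[0])],
        centroids=centroids.tolist(),
    )


def build_backbone(
    panels: list[TimeSeriesPanel],
    lam: float,
    percentile: float = 5.0,
    min_regions: int = 3,
    quorum: float = 0.5,
) -> IncidenceMatrix:
    """Full structure pipeline: per-subject LASSO -> threshold -> filter -> vote."""
    if not panels:
        raise ContractError("no panels supplied")
    labels = panels[0].region_labels
    for p in panels:
        if p.region_labels != labels:
            raise ContractError("panels disagree on region labels/order")
    Hs_list = [subject_incidence(p, lam, percentile, min_regions) for p in panels]
    return majority_vote(Hs_list, quorum, min_regions, region_labels=labels)


def _full_layout(H: IncidenceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(H, IncidenceMatrix):
        return H.to_full_layout()
    return np.asarray(H, dtype=np.int8)


def structure_stability(Ha: IncidenceMatrix, Hb: IncidenceMatrix) -> StabilityReport:
    """Jaccard index and Pearson correlation between two backbones.

    Both structures are expanded to the full centroid-by-region layout so
    the comparison is cell-wise even when hyperedge counts differ.
    """
    fa, fb = _full_layout(Ha), _full_layout(Hb)
    if fa.shape != fb.shape:
        raise ContractError("backbones cover different region sets")
    a, b = fa.ravel().astype(bool), fb.ravel().astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ContractError("both structures are empty; Jaccard undefined")
    jaccard = np.count_nonzero(a & b) / union
    if (a == a[0]).all() or (b == b[0]).all():
        # constant flattened structure (all ones): correlation undefined
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(a.astype(float), b.astype(float))[0, 1])
    na = Ha.n_hyperedges if isinstance(Ha, IncidenceMatrix) else int((fa.sum(0) > 0).sum())
    nb = Hb.n_hyperedges if isinstance(Hb, IncidenceMatrix) else int((fb.sum(0) > 0).sum())
    return StabilityReport(jaccard=float(jaccard), pearson=pearson, n_hyperedges_a=na, n_hyperedges_b=nb)


def truncation_stability(
    panels: list[TimeSeriesPanel],
    lam: float,
    lengths: list[int],
    percentile: float = 5.0,
    min_regions: int = 3,
    quorum: float = 0.5,
) -> list[tuple[int, StabilityReport]]:
    """Backbone stability under truncated acquisitions.

    For each requested length P', the first P' timepoints of every panel
    are kept (and re-z-scored), the backbone is rebuilt at the *same*
    penalty, and compared cell-wise to the full-length backbone.
    """
    full = build_backbone(panels, lam, percentile, min_regions, quorum)
    out: list[tuple[int, StabilityReport]] = []
    for length in lengths:
        truncated = [p.truncate(length) for p in panels]
        backbone = build_backbone(truncated, lam, percentile, min_regions, quorum)
        report = structure_stability(backbone, full)
        logger.info(
            "truncation P'=%d: %d hyperedges, Jaccard %.3f, r %.3f",
            length,
            report.n_hyperedges_a,
            report.jaccard,
            report.pearson,
        )
        out.append((length, report))
    return out
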