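"""Per-subject hyperedge weights.

The headline weighting scheme scores each hyperedge by the *algebraic
connectivity* (Fiedler value) of the small weighted graph its member
regions induce: edge weights are absolute Pearson correlations between the
member time series, the graph Laplacian is ``L = D - A``, and the weight
is L's second-smallest eigenvalue. Algebraic connectivity is 0 iff the
subgraph is disconnected and reaches ``k`` on the complete unit-weight
graph of ``k`` nodes, so it summarises at once how synchronised and how
robustly integrated the regions of a hyperedge are — without averaging
away the joint structure the hyperedge was built to capture.

Three pairwise baselines (Gaussian similarity kernel, mean Pearson
correlation, squared L2 norm of the centroid's LASSO coefficients) and a
functional-network baseline (mean within-network correlation with each of
the seven Schaefer networks treated as a hyperedge) are provided for
comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist

from .hypergraph import IncidenceMatrix
from .panels import ContractError, TimeSeriesPanel
from .structure import CoefficientMatrix, coefficient_matrix

__all__ = [
    "SubgraphFC",
    "WeightTable",
    "SCHAEFER_NETWORKS",
    "subgraph_fc",
    "algebraic_connectivity",
    "weight_algebraic",
    "weight_gaussian",
    "weight_mean_corr",
    "weight_lasso_l2",
    "weight_fn_mean_corr",
    "parse_network",
    "compute_weight_table",
]

logger = logging.getLogger(__name__)

#: Eigenvalue magnitudes below this are treated as exactly zero when
#: deciding connectivity; matches the numerical-stability tolerance used
#: throughout the weighting stage.
ZERO_TOL = 1e-10

#: Canonical Schaefer 7-network names in atlas order.
SCHAEFER_NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")


@dataclass
class SubgraphFC:
    """Functional-connectivity subgraph induced by one hyperedge.

    ``adjacency`` holds absolute Pearson correlations between member
    series (diagonal forced to 0: self-correlation is not an edge), and
    ``laplacian = diag(rowsums) - adjacency`` is the resulting weighted
    graph Laplacian — symmetric, positive semidefinite, zero row sums.
    """

    member_indices: np.ndarray
    adjacency: np.ndarray
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ContractError("adjacency must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ContractError("adjacency must be symmetric")
        if np.any(np.diagonal(A) != 0):
            raise ContractError("adjacency diagonal must be 0")
        if np.any(A < 0) or np.any(A > 1):
            raise ContractError("adjacency entries must lie in [0, 1]")
        self.adjacency = A
        self.laplacian = np.diag(A.sum(axis=1)) - A

    @property
    def k(self) -> int:
        return self.adjacency.shape[0]


def subgraph_fc(panel: TimeSeriesPanel, members: np.ndarray) -> SubgraphFC:
    """Absolute-correlation subgraph over one hyperedge's member regions."""
    members = np.asarray(members, dtype=int)
    if members.size < 3:
        raise ContractError("a hyperedge subgraph needs at least 3 regions")
    series = panel.data[members]
    if np.any(series.std(axis=1) == 0):
        raise ContractError("constant series in hyperedge members")
    corr = np.corrcoef(series)
    A = np.abs(corr)
    np.clip(A, 0.0, 1.0, out=A)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return SubgraphFC(member_indices=members, adjacency=A)


def algebraic_connectivity(g: SubgraphFC, tol: float = ZERO_TOL) -> float:
    """Fiedler value: second-smallest eigenvalue of the subgraph Laplacian.

    Computed by dense symmetric eigendecomposition — exact at hyperedge
    sizes (k <= 7 in practice; supported up to k = 32). Eigenvalues with
    magnitude below ``tol`` are treated as 0, so a disconnected subgraph
    (zero eigenvalue of multiplicity >= 2) returns exactly 0.0; tiny
    negative values from round-off are clipped to 0.
    """
    if g.k < 2:
        raise ContractError("algebraic connectivity needs at least 2 nodes")
    lam2 = float(eigh(g.laplacian, eigvals_only=True, subset_by_index=(1, 1))[0])
    if abs(lam2) < tol or lam2 < 0:
        return 0.0
    return lam2


def _hyperedge_members(H: IncidenceMatrix) -> list[np.ndarray]:
    return [H.members(m) for m in range(H.n_hyperedges)]


def weight_algebraic(panel: TimeSeriesPanel, H: IncidenceMatrix, tol: float = ZERO_TOL) -> np.ndarray:
    """Algebraic-connectivity weight for every hyperedge of one subject.

    A disconnected hyperedge subgraph gets weight 0 with a logged warning
    (the score carries no comparative information there; callers may drop
    such hyperedges).
    """
    out = np.empty(H.n_hyperedges, dtype=float)
    for m, members in enumerate(_hyperedge_members(H)):
        w = algebraic_connectivity(subgraph_fc(panel, members), tol=tol)
        if w == 0.0:
            logger.warning(
                "hyperedge %s (centroid %d) is disconnected for subject %s; weight 0",
                f"e{H.centroids[m]}",
                H.centroids[m],
                panel.subject_id,
            )
        out[m] = w
    return out


def weight_gaussian(panel: TimeSeriesPanel, H: IncidenceMatrix) -> np.ndarray:
    """Gaussian-similarity-kernel weight per hyperedge.

    ``K[i, j] = exp(-||x_i - x_j||^2 / (2 sigma^2))`` with the bandwidth
    ``sigma`` set by the median heuristic — the median of the raw pairwise
    Euclidean distances among the hyperedge's member series, computed per
    hyperedge and per subject. The weight is the mean kernel value over
    unordered member pairs (mean, not sum, so weights are comparable
    across hyperedge cardinalities). All members identical gives 1.
    """
    out = np.empty(H.n_hyperedges, dtype=float)
    for m, members in enumerate(_hyperedge_members(H)):
        if members.size < 2:
            raise ContractError("Gaussian kernel weight needs >= 2 members")
        d = pdist(panel.data[members], metric="euclidean")
        sigma = float(np.median(d))
        if sigma == 0.0:
            out[m] = 1.0
        else:
            out[m] = float(np.mean(np.exp(-(d**2) / (2.0 * sigma**2))))
    return out


def weight_mean_corr(panel: TimeSeriesPanel, H: IncidenceMatrix) -> np.ndarray:
    """Mean signed Pearson correlation over unordered member pairs."""
    out = np.empty(H.n_hyperedges, dtype=float)
    for m, members in enumerate(_hyperedge_members(H)):
        if members.size < 2:
            raise ContractError("mean-correlation weight needs >= 2 members")
        series = panel.data[members]
        if np.any(series.std(axis=1) == 0):
            raise ContractError("constant series in hyperedge members")
        corr = np.corrcoef(series)
        iu = np.triu_indices(members.size, k=1)
        out[m] = float(np.mean(corr[iu]))
    return out


def weight_lasso_l2(A: CoefficientMatrix, H: IncidenceMatrix) -> np.ndarray:
    """Squared L2 norm of the centroid's LASSO coefficients per hyperedge.

    ``A`` is the subject's coefficient matrix refit at the backbone's
    penalty; for hyperedge ``m`` with centroid ``c`` the weight is
    ``sum_j A[c, j]^2`` over the non-centroid members ``j`` of ``m``.
    """
    if A is None:
        raise ContractError("a coefficient matrix is required")
    if A.entries.shape[0] != H.n_regions:
        raise ContractError("coefficient matrix and incidence matrix disagree on N")
    out = np.empty(H.n_hyperedges, dtype=float)
    for m, members in enumerate(_hyperedge_members(H)):
        c = H.centroids[m]
        others = members[members != c]
        out[m] = float(np.sum(A.entries[c, others] ** 2))
    return out


_LABEL_RE = re.compile(
    r"^(?:\d+[_ ]?)?(?:7Networks[_ ])?(?:LH|RH)[_ ]([A-Za-z]+)", flags=re.IGNORECASE
)


def parse_network(label: str) -> str:
    """Extract the 7-network name from a Schaefer-style region label.

    Accepts the short form (``"LH Vis 1"``) and the long underscore form
    (``"7Networks_LH_Vis_1"``); matching against the canonical network
    names is case-insensitive.
    """
    m = _LABEL_RE.match(label.strip())
    if m:
        token = m.group(1)
        for net in SCHAEFER_NETWORKS:
            if token.lower() == net.lower():
                return net
    raise ContractError(f"cannot parse functional network from label {label!r}")


def weight_fn_mean_corr(
    panel: TimeSeriesPanel, fn_labels: dict[int, str] | None = None
) -> pd.Series:
    """Mean within-network Pearson correlation, one value per network.

    Each of the seven canonical functional networks is treated as one
    hyperedge containing all its regions. ``fn_labels`` maps region index
    to network name; by default it is parsed from the panel's region
    labels. Networks with fewer than 2 regions are an error.
    """
    if fn_labels is None:
        fn_labels = {i: parse_network(lbl) for i, lbl in enumerate(panel.region_labels)}
    networks = [net for net in SCHAEFER_NETWORKS if net in set(fn_labels.values())]
    extra = set(fn_labels.values()) - set(SCHAEFER_NETWORKS)
    if extra:
        raise ContractError(f"unknown functional network(s): {sorted(extra)}")
    values = {}
    for net in networks:
        members = np.array([i for i, n in fn_labels.items() if n == net], dtype=int)
        if members.size < 2:
            raise ContractError(f"network {net} has fewer than 2 regions")
        corr = np.corrcoef(panel.data[members])
        iu = np.triu_indices(members.size, k=1)
        values[net] = float(np.mean(corr[iu]))
    return pd.Series(values, name=panel.subject_id)


@dataclass
class WeightTable:
    """Subjects-by-hyperedges weight matrix for one weighting method."""

    method: str
    values: pd.DataFrame  # index = subject_id, columns = hyperedge ids (or FN names)
    group_labels: pd.Series  # index = subject_id

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ContractError("weight table contains missing values")
        self.group_labels = self.group_labels.reindex(self.values.index)
        if self.group_labels.isna().any():
            raise ContractError("every subject needs a group label")

    @property
    def hyperedge_ids(self) -> list[str]:
        return list(self.values.columns)

    def group(self, label: str) -> pd.DataFrame:
        return self.values.loc[self.group_labels == label]


METHODS = ("algebraic", "gaussian", "mean_corr", "lasso_l2", "fn_mean_corr")


def compute_weight_table(
    panels: list[TimeSeriesPanel],
    H: IncidenceMatrix | None,
    method: str,
    group_labels: dict[str, str],
    lam: float | None = None,
) -> WeightTable:
    """Weight every subject's hyperedges with one method.

    ``lasso_l2`` refits each subject's coefficient matrix at the backbone
    penalty ``lam``; ``fn_mean_corr`` ignores ``H`` and weights the seven
    functional networks parsed from the region labels.
    """
    if method not in METHODS:
        raise ContractError(f"unknown weighting method {method!r}; choose from {METHODS}")
    rows = []
    ids: list[str] | None = None
    for panel in panels:
        if method == "fn_mean_corr":
            s = weight_fn_mean_corr(panel)
            ids = list(s.index)
            rows.append(s.to_numpy())
            continue
        if H is None:
            raise ContractError(f"method {method!r} requires a backbone incidence matrix")
        ids = H.hyperedge_ids()
        if method == "algebraic":
            rows.append(weight_algebraic(panel, H))
        elif method == "gaussian":
            rows.append(weight_gaussian(panel, H))
        elif method == "mean_corr":
            rows.append(weight_mean_corr(panel, H))
        elif method == "lasso_l2":
            if lam is None:
                raise ContractError("lasso_l2 weighting requires the backbone penalty lam")
            A = coefficient_matrix(panel, lam)
            rows.append(weight_lasso_l2(A, H))
    values = pd.DataFrame(rows, index=[p.subject_id for p in panels], columns=ids)
    groups = pd.Series(group_labels, name="group")
    return WeightTable(method=method, values=values, group_labels=groups)
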