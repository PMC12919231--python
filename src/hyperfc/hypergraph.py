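"""Hypergraph data model and incidence/degree/similarity algebra.

A hypergraph HG = (V, E, W) over N brain regions is encoded by a binary
incidence matrix ``H`` of shape ``(N, M)`` with ``H[n, m] = 1`` when region
``n`` belongs to hyperedge ``m``. Each hyperedge is identified by a centroid
region (the region whose regression defined it) and must contain at least
three regions, including the centroid, so that it captures a genuinely
high-order relation rather than a pairwise link.

From ``H`` and a weight vector ``w`` (the diagonal of ``W``) the standard
diagonal degree matrices follow:

* node degree      ``d(v_n)   = sum_m w[m] * H[n, m]``
* hyperedge degree ``delta(e_m) = sum_n H[n, m]``

and the node-by-node similarity matrix

* ``S = H @ diag(w) @ inv(D_e) @ H.T``

whose entries aggregate, per region pair, the weights of the hyperedges
they share, normalised by hyperedge cardinality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panels import ContractError

__all__ = [
    "IncidenceMatrix",
    "HypergraphModel",
    "InvalidHypergraphError",
    "hyperedge_degrees",
    "node_degrees",
    "similarity_matrix",
    "build_model",
]


class InvalidHypergraphError(ValueError):
    """The incidence matrix violates the hypergraph contract."""


@dataclass
class IncidenceMatrix:
    """Binary node-by-hyperedge membership matrix.

    Attributes
    ----------
    entries : ndarray of shape (N, M)
        Binary membership; ``entries[n, m] == 1`` iff region ``n`` is in
        hyperedge ``m``.
    region_labels : list of str
        Ordered region names (row order is fixed by the label file).
    centroids : list of int
        For each hyperedge, the index of its defining centroid region.
        Hyperedges are ordered by centroid index, which makes the matrix
        reproducible and comparable across runs.
    """

    entries: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    centroids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.ndim != 2:
            raise InvalidHypergraphError("incidence matrix must be 2-D")
        vals = np.unique(self.entries)
        if not np.all(np.isin(vals, (0, 1))):
            raise InvalidHypergraphError("incidence entries must be exactly 0 or 1")
        self.entries = self.entries.astype(np.int8)
        n, m = self.entries.shape
        if m > n:
            raise InvalidHypergraphError(f"more hyperedges ({m}) than regions ({n})")
        if not self.region_labels:
            self.region_labels = [f"R{i}" for i in range(n)]
        if len(self.region_labels) != n:
            raise InvalidHypergraphError("region_labels length mismatch")
        if len(self.centroids) != m:
            raise InvalidHypergraphError("one centroid index required per hyperedge")
        if len(set(self.centroids)) != m:
            raise InvalidHypergraphError("centroid indices must be unique")
        for j, c in enumerate(self.centroids):
            if not 0 <= c < n:
                raise InvalidHypergraphError(f"centroid index {c} out of range")
            if self.entries[c, j] != 1:
                raise InvalidHypergraphError(
                    f"centroid {c} is not a member of its own hyperedge {j}"
                )
        if np.any(self.entries.sum(axis=0) < 3):
            raise InvalidHypergraphError("every hyperedge must contain >= 3 regions")

    @property
    def n_regions(self) -> int:
        return self.entries.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.entries.shape[1]

    def members(self, m: int) -> np.ndarray:
        """Region indices belonging to hyperedge ``m``."""
        return np.flatnonzero(self.entries[:, m])

    def hyperedge_ids(self) -> list[str]:
        """Stable identifiers, one per hyperedge, named by centroid region."""
        return [f"e{c}" for c in self.centroids]

    def to_full_layout(self) -> np.ndarray:
        """Expand to the full ``N x N`` centroid-by-region layout.

        Column ``c`` holds hyperedge with centroid ``c``; centroids without a
        surviving hyperedge give zero columns. Used for cell-wise structure
        comparison across backbones with different hyperedge counts.
        """
        full = np.zeros((self.n_regions, self.n_regions), dtype=np.int8)
        for j, c in enumerate(self.centroids):
            full[:, c] = self.entries[:, j]
        return full


@dataclass
class HypergraphModel:
    """Incidence matrix plus derived degree vectors and similarity matrix."""

    incidence: IncidenceMatrix
    weights: np.ndarray
    node_degrees: np.ndarray
    hyperedge_degrees: np.ndarray
    similarity: np.ndarray


def _check_weights(H: IncidenceMatrix, w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != H.n_hyperedges:
        raise ContractError(
            f"weight vector length {w.shape[0]} != number of hyperedges {H.n_hyperedges}"
        )
    return w


def hyperedge_degrees(H: IncidenceMatrix) -> np.ndarray:
    """Hyperedge degrees delta(e_m): number of member regions per hyperedge."""
    deg = H.entries.sum(axis=0).astype(np.int64)
    if np.any(deg == 0):
        raise InvalidHypergraphError("hyperedge with zero members")
    return deg


def node_degrees(H: IncidenceMatrix, w: np.ndarray) -> np.ndarray:
    """Weighted node degrees d(v_n) = sum_m w[m] * H[n, m]."""
    w = _check_weights(H, w)
    return H.entries.astype(float) @ w


def similarity_matrix(H: IncidenceMatrix, w: np.ndarray) -> np.ndarray:
    """Similarity S = H diag(w) D_e^{-1} H^T (symmetric, linear in w).

    ``D_e^{-1}`` is the element-wise reciprocal of the hyperedge degrees;
    degree-0 columns are forbidden upstream so no pseudo-inverse is needed.
    """
    w = _check_weights(H, w)
    deg = hyperedge_degrees(H).astype(float)
    Hf = H.entries.astype(float)
    S = (Hf * (w / deg)) @ Hf.T
    return (S + S.T) / 2.0  # kill 1e-16 asymmetry from summation order


def build_model(H: IncidenceMatrix, w: np.ndarray) -> HypergraphModel:
    """Assemble the full hypergraph model for one weight vector."""
    w = _check_weights(H, w)
    return HypergraphModel(
        incidence=H,
        weights=w,
        node_degrees=node_degrees(H, w),
        hyperedge_degrees=hyperedge_degrees(H),
        similarity=similarity_matrix(H, w),
    )
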