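"""Regional time-series panels.

A panel holds one subject's parcellated BOLD signals: an ``N x P`` matrix
with one row per brain region (e.g. the 100 Schaefer regions) and one
column per timepoint. Downstream structure inference and weighting assume
each regional series has been z-scored to zero mean and unit standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeriesPanel", "zscore_rows", "ContractError"]


class ContractError(ValueError):
    """An input violates a documented precondition."""


def zscore_rows(data: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score each row to zero mean and unit standard deviation.

    Uses the sample standard deviation (``ddof=1``). Constant rows are a
    hard error: their correlation with anything is undefined and every
    downstream quantity in this package builds on correlations.
    """
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1, ddof=ddof)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        bad = np.flatnonzero(~np.isfinite(sd) | (sd == 0))
        raise ContractError(f"constant or non-finite series at row(s) {bad.tolist()}")
    return (data - data.mean(axis=1, keepdims=True)) / sd[:, None]


@dataclass
class TimeSeriesPanel:
    """One subject's ``N x P`` regional time-series matrix.

    Parameters
    ----------
    subject_id : str
        Identifier carried through all outputs.
    data : ndarray of shape (N, P)
        Rows are regions, columns timepoints. No missing values.
    region_labels : list of str
        Ordered region names, one per row.
    zscored : bool
        Whether each row has zero mean and unit (ddof=1) standard deviation.
    """

    subject_id: str
    data: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    zscored: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ContractError("panel data must be a 2-D matrix")
        n, p = self.data.shape
        if n < 3 or p < 2:
            raise ContractError(f"panel needs N >= 3 regions and P >= 2 timepoints, got {n}x{p}")
        if not np.all(np.isfinite(self.data)):
            raise ContractError(f"panel {self.subject_id!r} contains missing/non-finite values")
        if not self.region_labels:
            self.region_labels = [f"R{i}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ContractError("region_labels length does not match number of rows")
        if len(set(self.region_labels)) != n:
            raise ContractError("duplicate region labels")
        if self.zscored:
            mean = np.abs(self.data.mean(axis=1)).max()
            sd = np.abs(self.data.std(axis=1, ddof=1) - 1.0).max()
            if mean > 1e-8 or sd > 1e-6:
                raise ContractError(
                    f"panel {self.subject_id!r} flagged z-scored but rows have "
                    f"max|mean|={mean:.2e}, max|sd-1|={sd:.2e}"
                )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def zscore(self) -> "TimeSeriesPanel":
        """Return a z-scored copy (sample sd, ddof=1)."""
        return replace(self, data=zscore_rows(self.data), zscored=True)

    def truncate(self, n_timepoints: int) -> "TimeSeriesPanel":
        """Keep the first ``n_timepoints`` columns and re-z-score."""
        if not 2 <= n_timepoints <= self.n_timepoints:
            raise ContractError(
                f"truncation length {n_timepoints} outside [2, {self.n_timepoints}]"
            )
        out = replace(self, data=self.data[:, :n_timepoints], zscored=False)
        return out.zscore()
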