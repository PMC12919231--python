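"""File formats: panels, manifests, incidence matrices, weight tables.

Everything is tab-separated text plus JSON sidecars for provenance —
parcellated time series are the entry point, so no binary neuroimaging
formats are involved.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hypergraph import IncidenceMatrix
from .panels import ContractError, TimeSeriesPanel
from .weighting import WeightTable

__all__ = [
    "read_panel",
    "write_panel",
    "read_manifest",
    "write_manifest",
    "write_incidence",
    "read_incidence",
    "write_weight_table",
    "read_weight_table",
    "provenance_record",
]

GROUP_COLUMN = "__group__"


def read_panel(path: str | Path, subject_id: str | None = None, zscore: bool = True) -> TimeSeriesPanel:
    """Read one subject's panel from delimited text.

    First column holds region labels, the remaining columns one timepoint
    each. Missing cells, duplicate labels and (when z-scoring) constant
    rows are explicit parse errors naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ContractError(f"{path}: need at least 2 timepoint columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ContractError(f"{path}: duplicate region label(s) {dup}")
    na = df.isna()
    if na.any().any():
        row = df.index[na.any(axis=1)][0]
        col = df.columns[na.loc[row].to_numpy()][0]
        raise ContractError(f"{path}: missing value at region {row!r}, column {col!r}")
    panel = TimeSeriesPanel(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        region_labels=[str(x) for x in df.index],
    )
    return panel.zscore() if zscore else panel


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        panel.data,
        index=pd.Index(panel.region_labels, name="region"),
        columns=[f"t{j}" for j in range(panel.n_timepoints)],
    )
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest: subject_id, panel_path, cohort_role, group.

    ``cohort_role`` is ``backbone`` (structure inference only) or
    ``analysis`` (group statistics and downstream). Paths are resolved
    relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "panel_path", "cohort_role", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"{path}: manifest missing column(s) {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ContractError(f"{path}: duplicate subject ids")
    bad_role = set(df["cohort_role"]) - {"backbone", "analysis"}
    if bad_role:
        raise ContractError(f"{path}: unknown cohort_role value(s) {sorted(bad_role)}")
    df["panel_path"] = [str((path.parent / p).resolve()) for p in df["panel_path"]]
    for p in df["panel_path"]:
        if not Path(p).exists():
            raise ContractError(f"{path}: panel file not found: {p}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_incidence(H: IncidenceMatrix, path: str | Path, provenance: dict | None = None) -> None:
    """Write the incidence matrix as TSV with a JSON provenance sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        H.entries,
        index=pd.Index(H.region_labels, name="region"),
        columns=H.hyperedge_ids(),
    )
    df.to_csv(path, sep="\t")
    sidecar = {
        "centroids": list(map(int, H.centroids)),
        "n_regions": H.n_regions,
        "n_hyperedges": H.n_hyperedges,
        "provenance": provenance or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_incidence(path: str | Path) -> IncidenceMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        centroids = json.loads(sidecar_path.read_text())["centroids"]
    else:
        # fall back on the e<index> column-naming convention
        centroids = [int(c.lstrip("e")) for c in df.columns]
    return IncidenceMatrix(
        entries=df.to_numpy(),
        region_labels=[str(x) for x in df.index],
        centroids=list(centroids),
    )


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, GROUP_COLUMN, table.group_labels)
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_weight_table(path: str | Path, method: str = "unknown") -> WeightTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if GROUP_COLUMN not in df.columns:
        raise ContractError(f"{path}: weight table lacks the {GROUP_COLUMN} column")
    groups = df.pop(GROUP_COLUMN)
    return WeightTable(method=method, values=df, group_labels=groups)


def provenance_record(config: dict, seeds: dict | None = None) -> dict:
    """Provenance blob attached to every numeric output."""
    import hyperfc

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "config": config,
        "config_sha256_16": digest,
        "seeds": seeds or {},
        "hyperfc_version": hyperfc.__version__,
    }
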