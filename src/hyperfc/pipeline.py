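"""Top-level pipeline: structure -> weights -> stats -> classification/mediation.

Driven by a YAML/dict configuration; every output directory carries a
provenance JSON (config hash, seeds, package version) so any numeric
artifact can be regenerated from its inputs.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import io as hio
from .classify import run_classification
from .mediation import run_mediation_battery
from .panels import ContractError
from .stats import run_group_stats
from .structure import build_backbone, default_lambda_grid, select_lambda_cv
from .weighting import METHODS, compute_weight_table, parse_network

__all__ = ["run_pipeline", "mediation_results_frame"]

logger = logging.getLogger(__name__)

DEFAULTS = {
    "lambda": 0.05,
    "select_lambda": False,
    "lambda_grid": None,
    "cv_folds": 5,
    "percentile": 5.0,
    "min_regions": 3,
    "quorum": 0.5,
    "methods": ["algebraic", "gaussian", "mean_corr", "lasso_l2"],
    "alpha": 0.05,
    "tasks": [],
    "classifier_grid": None,  # None -> the declared default RF grid
    "mediation": None,
    "seed": 0,
}


def mediation_results_frame(results: dict) -> pd.DataFrame:
    """Flatten a mediation battery into one row per (hyperedge, outcome)."""
    rows = []
    for (h, outcome), r in results.items():
        rows.append(
            {
                "hyperedge": h,
                "outcome": outcome,
                "a": r.a,
                "b": r.b,
                "total": r.total,
                "direct": r.direct,
                "indirect": r.indirect,
                "ci_low": None if r.ci_indirect is None else r.ci_indirect[0],
                "ci_high": None if r.ci_indirect is None else r.ci_indirect[1],
                "p_total": r.p_total,
                "p_direct": r.p_direct,
                "p_indirect": r.p_indirect,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the full analysis described by ``config``; return ``out_dir``.

    Config keys (all optional except ``manifest``): lambda / select_lambda /
    lambda_grid / cv_folds, percentile, min_regions, quorum, methods,
    alpha, tasks (list of two-group label pairs; empty list = all pairs),
    mediation ({z, outcomes, covariates, n_boot}), seed.
    """
    cfg = {**DEFAULTS, **config}
    if "manifest" not in cfg:
        raise ContractError("config must declare a manifest path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for method in cfg["methods"]:
        if method not in METHODS:
            raise ContractError(f"unknown weighting method {method!r}")

    manifest = hio.read_manifest(cfg["manifest"])
    panels = {
        row.subject_id: hio.read_panel(row.panel_path, subject_id=row.subject_id)
        for row in manifest.itertuples()
    }
    backbone_ids = manifest.loc[manifest["cohort_role"] == "backbone", "subject_id"]
    analysis = manifest.loc[manifest["cohort_role"] == "analysis"]
    if backbone_ids.empty or analysis.empty:
        raise ContractError("manifest needs both backbone and analysis subjects")
    if "fn_mean_corr" in cfg["methods"]:
        # fail before any computation if the labels cannot be parsed
        for lbl in next(iter(panels.values())).region_labels:
            parse_network(lbl)

    backbone_panels = [panels[s] for s in backbone_ids]
    analysis_panels = [panels[s] for s in analysis["subject_id"]]
    group_labels = dict(zip(analysis["subject_id"], analysis["group"]))

    # --- structure ---------------------------------------------------
    lam = cfg["lambda"]
    selection = None
    if cfg["select_lambda"]:
        grid = cfg["lambda_grid"] or default_lambda_grid()
        selection = _stage("select_lambda")(select_lambda_cv)(
            backbone_panels, grid, folds=cfg["cv_folds"], seed=cfg["seed"]
        )
        lam = selection.chosen
    backbone = _stage("structure")(build_backbone)(
        backbone_panels,
        lam,
        percentile=cfg["percentile"],
        min_regions=cfg["min_regions"],
        quorum=cfg["quorum"],
    )
    prov = hio.provenance_record(cfg, seeds={"seed": cfg["seed"]})
    prov["lambda"] = lam
    prov["lambda_unaveraged_equivalent"] = lam * backbone_panels[0].n_timepoints
    prov["n_backbone_subjects"] = len(backbone_panels)
    hio.write_incidence(backbone, out_dir / "backbone.tsv", provenance=prov)
    if selection is not None:
        pd.DataFrame(
            {
                "lambda": selection.grid,
                "train_mse": selection.cv_train_mse,
                "train_sd": selection.cv_train_sd,
                "val_mse": selection.cv_val_mse,
                "val_sd": selection.cv_val_sd,
            }
        ).to_csv(out_dir / "lambda_cv.tsv", sep="\t", index=False)

    # --- weights + stats ---------------------------------------------
    stats_by_method = {}
    tables = {}
    for method in cfg["methods"]:
        table = _stage(f"weights[{method}]")(compute_weight_table)(
            analysis_panels, backbone, method, group_labels, lam=lam
        )
        tables[method] = table
        hio.write_weight_table(table, out_dir / f"weights_{method}.tsv")
        result = _stage(f"stats[{method}]")(run_group_stats)(table, alpha=cfg["alpha"])
        stats_by_method[method] = result
        result.omnibus.to_csv(out_dir / f"stats_omnibus_{method}.tsv", sep="\t")
        result.posthoc.to_csv(out_dir / f"stats_posthoc_{method}.tsv", sep="\t")

    # --- classification ----------------------------------------------
    groups = sorted(set(group_labels.values()))
    tasks = [tuple(t) for t in cfg["tasks"]] or list(combinations(groups, 2))
    reports = {}
    for method, result in stats_by_method.items():
        sig = result.significant_ids
        if not sig or method == "fn_mean_corr":
            continue
        for task in tasks:
            rep = _stage(f"classify[{method}]")(run_classification)(
                tables[method],
                task,
                significant_ids=sig,
                seed=cfg["seed"],
                grid=cfg["classifier_grid"],
            )
            reports[(method, task)] = rep
            (out_dir / f"classify_{method}_{task[0]}_vs_{task[1]}.json").write_text(
                json.dumps(
                    {
                        "task": list(task),
                        "metrics": rep.metrics,
                        "best_hyperparameters": rep.best_hyperparameters,
                        "feature_importance": rep.feature_importance.to_dict(),
                        "split_seed": rep.split_seed,
                    },
                    indent=2,
                    default=str,
                )
            )

    # --- mediation ----------------------------------------------------
    med_cfg = cfg["mediation"]
    if med_cfg:
        clinical = pd.read_csv(med_cfg["clinical"], sep="\t", index_col=0)
        for method, result in stats_by_method.items():
            sig = result.significant_ids
            if not sig:
                continue
            battery = _stage(f"mediation[{method}]")(run_mediation_battery)(
                tables[method],
                sig,
                clinical,
                z_col=med_cfg.get("z", "tau_suvr"),
                outcomes=med_cfg.get("outcomes", ["memory"]),
                covariate_cols=med_cfg.get("covariates"),
                n_boot=med_cfg.get("n_boot", 1000),
                seed=cfg["seed"],
            )
            mediation_results_frame(battery).to_csv(
                out_dir / f"mediation_{method}.tsv", sep="\t", index=False
            )

    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    logger.info("pipeline complete: outputs in %s", out_dir)
    return out_dir
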