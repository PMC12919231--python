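"""Synthetic fixtures with the statistical structure the pipeline assumes.

Panels follow a latent-factor model: each planted hyperedge ``h`` has one
standard-Gaussian latent series ``f_h`` per subject, and a member region
``i`` observes

    x_i = rho * f_h + sqrt(1 - rho^2) * eps_i,   eps_i ~ N(0, noise_sd^2)

with everything independent across regions and subjects; unassigned
regions are pure noise. The loading ``rho`` directly controls the
within-hyperedge coupling that algebraic connectivity measures, and can
differ per clinical group to plant group effects. All series are z-scored
exactly as real parcellated panels would be. Mediation triples follow the
generative form of the three-equation model: ``z`` standard Gaussian,
``w = a z + noise``, ``y = c' z + b w + noise``.

This emulates the coupling geometry of parcellated BOLD data, not its
dynamics: no temporal autocorrelation, hemodynamics or scanner artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mediation import MediationInput
from .panels import ContractError, TimeSeriesPanel

__all__ = [
    "SimulationConfig",
    "simulate_panels",
    "simulate_mediation",
    "simulate_study",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study-condition description for the synthetic generator.

    ``coupling`` maps ``(hyperedge_index, group)`` to the latent-factor
    loading rho in [0, 1]; a plain float applies to every hyperedge and
    group. ``planted_hyperedges`` are region-index sets of size >= 3.
    """

    n_regions: int = 20
    n_timepoints: int = 192
    n_subjects_per_group: dict[str, int] = field(default_factory=lambda: {"HC": 30})
    planted_hyperedges: list[list[int]] = field(default_factory=list)
    coupling: float | dict[tuple[int, str], float] = 0.8
    noise_sd: float = 0.2
    mediation: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for h in self.planted_hyperedges:
            if len(h) < 3:
                raise ContractError("every planted hyperedge needs >= 3 regions")
            if max(h) >= self.n_regions or min(h) < 0:
                raise ContractError("planted hyperedge region index out of range")
        if self.noise_sd <= 0:
            raise ContractError("noise_sd must be positive")

    def rho(self, hyperedge: int, group: str) -> float:
        if isinstance(self.coupling, dict):
            r = self.coupling.get((hyperedge, group))
            if r is None:
                raise ContractError(f"no coupling for hyperedge {hyperedge}, group {group!r}")
        else:
            r = float(self.coupling)
        if not 0 <= r <= 1:
            raise ContractError(f"coupling rho {r} outside [0, 1]")
        return r


def default_region_labels(n_regions: int) -> list[str]:
    """Schaefer-style labels cycling through the seven networks."""
    from .weighting import SCHAEFER_NETWORKS

    labels = []
    per_net = -(-n_regions // (2 * len(SCHAEFER_NETWORKS)))  # ceil
    i = 0
    for hemi in ("LH", "RH"):
        for net in SCHAEFER_NETWORKS:
            for k in range(per_net):
                if i < n_regions:
                    labels.append(f"{hemi} {net} {k + 1}")
                    i += 1
    return labels


def ground_truth_membership(config: SimulationConfig) -> np.ndarray:
    """Planted membership in the full N x N centroid-by-region layout.

    Every member of a planted hyperedge, used as a centroid, defines the
    same hyperedge, so column ``c`` holds hyperedge members for each
    member centroid ``c``; unassigned-region columns are zero. Regions in
    more than one listed hyperedge are attributed to the first (logged).
    """
    n = config.n_regions
    truth = np.zeros((n, n), dtype=np.int8)
    owner: dict[int, int] = {}
    for hi, members in enumerate(config.planted_hyperedges):
        for r in members:
            if r in owner:
                logger.warning(
                    "region %d listed in hyperedges %d and %d; keeping %d",
                    r,
                    owner[r],
                    hi,
                    owner[r],
                )
                continue
            owner[r] = hi
    for r, hi in owner.items():
        for m in config.planted_hyperedges[hi]:
            if owner.get(m, hi) == hi:
                truth[m, r] = 1
    return truth


def simulate_panels(
    config: SimulationConfig,
) -> tuple[list[TimeSeriesPanel], dict[str, str], np.ndarray]:
    """Generate z-scored panels for every subject of every group.

    Returns the panels, a subject->group map, and the planted membership
    matrix in the full N x N layout. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels = default_region_labels(config.n_regions)
    owner: dict[int, int] = {}
    for hi, members in enumerate(config.planted_hyperedges):
        for r in members:
            owner.setdefault(r, hi)
    panels: list[TimeSeriesPanel] = []
    groups: dict[str, str] = {}
    for group, count in config.n_subjects_per_group.items():
        for s in range(count):
            sid = f"{group}_{s:03d}"
            data = np.empty((config.n_regions, config.n_timepoints))
            factors = rng.standard_normal((len(config.planted_hyperedges), config.n_timepoints))
            for r in range(config.n_regions):
                eps = config.noise_sd * rng.standard_normal(config.n_timepoints)
                if r in owner:
                    rho = config.rho(owner[r], group)
                    data[r] = rho * factors[owner[r]] + np.sqrt(1.0 - rho**2) * eps
                else:
                    data[r] = eps
            panels.append(
                TimeSeriesPanel(subject_id=sid, data=data, region_labels=list(labels)).zscore()
            )
            groups[sid] = group
    return panels, groups, ground_truth_membership(config)


def simulate_mediation(
    a: float,
    b: float,
    c_prime: float,
    n: int,
    noise_sd_w: float = 1.0,
    noise_sd_y: float = 1.0,
    seed: int = 0,
) -> tuple[MediationInput, dict[str, float]]:
    """Mediation triple from the three-equation generative model.

    ``z`` is standard Gaussian, ``w = a z + e_w``, ``y = c' z + b w + e_y``
    with independent Gaussian noise. Returns the data together with the
    ground-truth coefficients (total effect ``c = c' + a b``).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    w = a * z + noise_sd_w * rng.standard_normal(n)
    y = c_prime * z + b * w + noise_sd_y * rng.standard_normal(n)
    truth = {"a": a, "b": b, "c_prime": c_prime, "c": c_prime + a * b, "indirect": a * b}
    return MediationInput(z=z, w=w, y=y), truth


def simulate_study(
    config: SimulationConfig,
    n_backbone: int = 30,
    backbone_group: str = "HC",
) -> dict:
    """Fixture for the full pipeline: backbone cohort + analysis groups.

    The backbone cohort is ``n_backbone`` extra subjects drawn with the
    ``backbone_group`` coupling (they never enter the group analyses,
    mirroring the reference-cohort design). A clinical table with an
    exposure ``tau_suvr``, five cognitive outcomes and covariates is
    generated for the analysis subjects; the exposure is coupled to group
    (higher in more affected groups) so mediation has signal to find.
    """
    rng = np.random.default_rng(config.seed + 1)
    backbone_cfg = SimulationConfig(
        n_regions=config.n_regions,
        n_timepoints=config.n_timepoints,
        n_subjects_per_group={backbone_group: n_backbone},
        planted_hyperedges=config.planted_hyperedges,
        coupling=(
            {
                (hi, backbone_group): config.rho(hi, backbone_group)
                for hi in range(len(config.planted_hyperedges))
            }
            if isinstance(config.coupling, dict)
            else config.coupling
        ),
        noise_sd=config.noise_sd,
        seed=config.seed + 10_000,
    )
    backbone_panels, _, truth = simulate_panels(backbone_cfg)
    for p in backbone_panels:
        p.subject_id = f"bb_{p.subject_id}"
    analysis_panels, groups, _ = simulate_panels(config)

    group_severity = {g: i for i, g in enumerate(config.n_subjects_per_group)}
    rows = []
    for sid, g in groups.items():
        tau = 1.2 + 0.4 * group_severity[g] + 0.15 * rng.standard_normal()
        base = -0.8 * (tau - 1.2)
        rows.append(
            {
                "subject_id": sid,
                "group": g,
                "tau_suvr": tau,
                "memory": base + 0.3 * rng.standard_normal(),
                "executive": base + 0.3 * rng.standard_normal(),
                "language": base + 0.3 * rng.standard_normal(),
                "visual_spatial": base + 0.3 * rng.standard_normal(),
                "adas13": 10.0 - 8.0 * base + 2.0 * rng.standard_normal(),
                "age": 72.0 + 6.0 * rng.standard_normal(),
                "sex": int(rng.integers(0, 2)),
                "education": 16.0 + 2.0 * rng.standard_normal(),
                "apoe4": int(rng.integers(0, 2)),
            }
        )
    clinical = pd.DataFrame(rows).set_index("subject_id")
    return {
        "backbone_panels": backbone_panels,
        "analysis_panels": analysis_panels,
        "groups": groups,
        "truth": truth,
        "clinical": clinical,
    }
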