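"""Per-core and per-patient spatial metrics for CAF/TAEC coupling.

Three quantities, each computed per core and then aggregated per patient:

* **density per 1000** — phenotype count normalized to 1000 total nucleated
  cells (also used for PD-L1⁺ / PD-1⁺ "expression" counts);
* **mean NND** — arithmetic mean over source cells (CAFs) of the Euclidean
  distance in μm to the nearest target cell (TAEC);
* **proximity count** — number of source cells whose nearest target lies
  within a radius (default 30 μm, boundary inclusive), the distance range at
  which direct/paracrine cell–cell interaction is plausible.

A metric that cannot be computed (no source or no target cells in a core)
is *undefined*, never zero: zero would fake extreme proximity. No edge
correction is applied at core borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_model import CellTable, DEFAULT_RULES, PhenotypeRule, assign_phenotypes
from .errors import ConfigError, UndefinedMetricError

DEFAULT_RADIUS_UM = 30.0

AGGREGATIONS = ("mean", "cell_weighted", "pooled")


def density_per_1000(table: CellTable, phenotype: str) -> float:
    """Phenotype density: 1000 × (phenotype count) / (total cell count)."""
    if table.n_cells == 0:
        raise UndefinedMetricError(
            f"density of {phenotype!r} undefined on empty core "
            f"({table.patient_id}, {table.core_id})",
            reason="empty table",
        )
    n = sum(1 for c in table.cells if c.phenotype == phenotype)
    return 1000.0 * n / table.n_cells


def marker_density_per_1000(table: CellTable, marker: str) -> float:
    """Density of marker-positive cells per 1000 cells (e.g. PD-L1⁺)."""
    if table.n_cells == 0:
        raise UndefinedMetricError("density undefined on empty core",
                                   reason="empty table")
    return 1000.0 * table.marker_positive_count(marker) / table.n_cells


def nearest_neighbor_distances(source, target) -> np.ndarray:
    """Distance from each source point to its closest target point (μm).

    Uses a k-d tree; exact (no approximation), so it must agree with the
    all-pairs brute force to machine identity. Coincident points give 0.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 2)
    tgt = np.asarray(target, dtype=float).reshape(-1, 2)
    if len(tgt) == 0:
        raise UndefinedMetricError("no target points", reason="empty target")
    if len(src) == 0:
        return np.empty(0, dtype=float)
    dists, _ = cKDTree(tgt).query(src, k=1)
    return np.asarray(dists, dtype=float)


def mean_nnd(table: CellTable, source_phenotype: str = "CAF",
             target_phenotype: str = "TAEC") -> float:
    """Mean over source cells of the nearest-target distance, in μm."""
    src = table.coords_of(source_phenotype)
    tgt = table.coords_of(target_phenotype)
    if not src:
        raise UndefinedMetricError(
            f"no {source_phenotype!r} cells in core {table.core_id!r}",
            reason="empty source",
        )
    if not tgt:
        raise UndefinedMetricError(
            f"no {target_phenotype!r} cells in core {table.core_id!r}",
            reason="empty target",
        )
    return float(np.mean(nearest_neighbor_distances(src, tgt)))


def proximity_count(table: CellTable, source_phenotype: str = "CAF",
                    target_phenotype: str = "TAEC",
                    radius: float = DEFAULT_RADIUS_UM) -> int:
    """Number of source cells with ≥1 target within ``radius`` (inclusive).

    0 source cells → 0; target absent entirely → 0 (every source has no
    neighbor within any radius).
    """
    if radius <= 0:
        raise ConfigError(f"radius must be > 0, got {radius}")
    src = table.coords_of(source_phenotype)
    tgt = table.coords_of(target_phenotype)
    if not src or not tgt:
        return 0
    d = nearest_neighbor_distances(src, tgt)
    return int(np.sum(d <= radius))


@dataclass
class CoreMetrics:
    """All per-core quantities; undefined metrics are ``None``."""

    patient_id: str
    core_id: str
    n_cells: int
    densities: dict[str, float] = field(default_factory=dict)
    marker_densities: dict[str, float] = field(default_factory=dict)
    mean_nnd: float | None = None
    proximity_count: int | None = None
    proximity_per_1000: float | None = None
    radius: float = DEFAULT_RADIUS_UM
    undefined_reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class PatientMetrics:
    """Per-patient aggregation of core metrics.

    ``n_cores`` records, per metric, how many cores had a defined value;
    ``aggregation`` records the method used.
    """

    patient_id: str
    densities: dict[str, float]
    marker_densities: dict[str, float]
    mean_nnd: float | None
    proximity_count: float | None
    proximity_per_1000: float | None
    radius: float
    n_cores: dict[str, int]
    aggregation: str


def core_metrics(
    table: CellTable,
    rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
    *,
    radius: float = DEFAULT_RADIUS_UM,
    source_phenotype: str = "CAF",
    target_phenotype: str = "TAEC",
    expression_markers: Sequence[str] = ("PDL1", "PD1"),
    already_phenotyped: bool = False,
) -> CoreMetrics:
    """Compute every metric for one core, catching undefined ones."""
    t = table if already_phenotyped else assign_phenotypes(table, rules)
    out = CoreMetrics(t.patient_id, t.core_id, t.n_cells, radius=radius)
    labels = sorted({r.name for r in rules})
    for label in labels:
        try:
            out.densities[label] = density_per_1000(t, label)
        except UndefinedMetricError as e:
            out.undefined_reasons[f"density_{label}"] = e.reason
    for m in expression_markers:
        try:
            out.marker_densities[m] = marker_density_per_1000(t, m)
        except UndefinedMetricError as e:
            out.undefined_reasons[f"density_{m}"] = e.reason
    try:
        out.mean_nnd = mean_nnd(t, source_phenotype, target_phenotype)
    except UndefinedMetricError as e:
        out.undefined_reasons["mean_nnd"] = e.reason
    if out.mean_nnd is not None:
        out.proximity_count = proximity_count(
            t, source_phenotype, target_phenotype, radius
        )
        out.proximity_per_1000 = 1000.0 * out.proximity_count / t.n_cells
    else:
        out.undefined_reasons.setdefault(
            "proximity", out.undefined_reasons.get("mean_nnd", "undefined")
        )
    return out


def _aggregate(values, weights, method):
    pairs = [(v, w) for v, w in zip(values, weights) if v is not None]
    if not pairs:
        return None, 0
    vals = np.array([p[0] for p in pairs], dtype=float)
    wts = np.array([p[1] for p in pairs], dtype=float)
    if method == "mean":
        return float(vals.mean()), len(pairs)
    return float(np.average(vals, weights=wts)), len(pairs)


def patient_metrics(
    cores: Sequence[CellTable],
    rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
    *,
    radius: float = DEFAULT_RADIUS_UM,
    aggregation: str = "mean",
    source_phenotype: str = "CAF",
    target_phenotype: str = "TAEC",
    expression_markers: Sequence[str] = ("PDL1", "PD1"),
) -> PatientMetrics:
    """Aggregate core metrics to one value per patient.

    ``aggregation``:

    * ``"mean"`` (default) — unweighted mean over cores with defined values;
    * ``"cell_weighted"`` — mean weighted by core cell count;
    * ``"pooled"`` — all cells of all cores treated as one point set (cores
      are merged before computing metrics; densities use pooled totals).
    """
    if not cores:
        raise ConfigError("patient_metrics needs at least one core")
    if aggregation not in AGGREGATIONS:
        raise ConfigError(
            f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}"
        )
    pids = {c.patient_id for c in cores}
    if len(pids) != 1:
        raise ConfigError(f"cores from multiple patients: {sorted(pids)}")
    pid = cores[0].patient_id

    if aggregation == "pooled":
        # offset cores along x so merged coordinates stay distinct; distances
        # within a core are unchanged and cross-core pairs are pushed apart
        gap = max(c.width for c in cores) + 10 * radius
        merged_cells = []
        for i, c in enumerate(cores):
            t = assign_phenotypes(c, rules)
            for cell in t.cells:
                merged_cells.append(
                    type(cell)(f"{c.core_id}:{cell.cell_id}", cell.x + i * gap,
                               cell.y, cell.markers, cell.phenotype)
                )
        merged = CellTable(pid, "pooled", gap * len(cores),
                           max(c.height for c in cores), merged_cells)
        cm = core_metrics(merged, rules, radius=radius,
                          source_phenotype=source_phenotype,
                          target_phenotype=target_phenotype,
                          expression_markers=expression_markers,
                          already_phenotyped=True)
        n = {k: len(cores) for k in ("mean_nnd", "proximity", "density")}
        return PatientMetrics(pid, cm.densities, cm.marker_densities,
                              cm.mean_nnd, cm.proximity_count,
                              cm.proximity_per_1000, radius, n, aggregation)

    per_core = [
        core_metrics(c, rules, radius=radius, source_phenotype=source_phenotype,
                     target_phenotype=target_phenotype,
                     expression_markers=expression_markers)
        for c in cores
    ]
    weights = [cm.n_cells for cm in per_core]
    n_cores: dict[str, int] = {}

    densities: dict[str, float] = {}
    labels = sorted({r.name for r in rules})
    for label in labels:
        v, n = _aggregate([cm.densities.get(label) for cm in per_core],
                          weights, aggregation)
        if v is not None:
            densities[label] = v
        n_cores[f"density_{label}"] = n
    marker_densities: dict[str, float] = {}
    for m in expression_markers:
        v, n = _aggregate([cm.marker_densities.get(m) for cm in per_core],
                          weights, aggregation)
        if v is not None:
            marker_densities[m] = v
        n_cores[f"density_{m}"] = n
    nnd, n = _aggregate([cm.mean_nnd for cm in per_core], weights, aggregation)
    n_cores["mean_nnd"] = n
    prox, n = _aggregate([cm.proximity_count for cm in per_core], weights,
                         aggregation)
    prox1000, _ = _aggregate([cm.proximity_per_1000 for cm in per_core],
                             weights, aggregation)
    n_cores["proximity"] = n
    return PatientMetrics(pid, densities, marker_densities, nnd, prox,
                          prox1000, radius, n_cores, aggregation)


def metrics_table(per_patient: Sequence[PatientMetrics]) -> pd.DataFrame:
    """Flatten patient metrics into the package's CSV schema."""
    rows = []
    for pm in per_patient:
        row = {
            "patient_id": pm.patient_id,
            "density_CAF": pm.densities.get("CAF"),
            "density_TAEC": pm.densities.get("TAEC"),
            "density_PDL1": pm.marker_densities.get("PDL1"),
            "density_PD1": pm.marker_densities.get("PD1"),
            "mean_nnd_um": pm.mean_nnd,
            "proximity_raw": pm.proximity_count,
            "proximity_per1000": pm.proximity_per_1000,
            "radius_um": pm.radius,
            "n_cores_nnd": pm.n_cores.get("mean_nnd"),
            "aggregation": pm.aggregation,
        }
        rows.append(row)
    return pd.DataFrame(rows)
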