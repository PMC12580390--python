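"""End-to-end orchestration: cell tables + clinical table → report bundle.

The run mirrors the analysis cascade: phenotype gating → per-core and
per-patient spatial metrics → response-rate contingency tests → group
comparisons of microenvironment metrics → median-split odds ratios →
ROC evaluation of the spatial metrics as response predictors. Outputs are
CSV tables (human-readable numbers rounded: p to 3 decimals, metrics to 1)
plus a machine-readable manifest; a rerun with identical inputs, config and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cell_model import (CellTable, DEFAULT_RULES, PhenotypeRule,
                         parse_cell_table)
from .cohort_stats import (build_contingency, categorical_test, dichotomize,
                           mann_whitney, median_iqr, roc_curve, univariate_or)
from .errors import ConfigError, SpatialTmeError, ValidationError
from .spatial_metrics import (DEFAULT_RADIUS_UM, metrics_table,
                              patient_metrics)
from .synthetic_cohort import (CohortSimConfig, naic_scc_mif_config,
                               paper_scaffold_config, simulate_cohort)

PRESETS = {
    "paper-scaffold": paper_scaffold_config,
    "naic-scc-mif": naic_scc_mif_config,
}

#: Metric columns compared between response groups and fed to OR/ROC.
METRIC_COLUMNS = (
    "density_CAF", "density_TAEC", "density_PDL1", "density_PD1",
    "mean_nnd_um", "proximity_raw", "proximity_per1000",
)


@dataclass
class RunConfig:
    """Everything a run depends on; hashable into the manifest."""

    cells_path: str | None = None
    clinical_path: str | None = None
    simulate_preset: str | None = None
    seed: int = 0
    radius: float = DEFAULT_RADIUS_UM
    aggregation: str = "mean"
    dichotomize_rule: str = "median"
    quartile_convention: str = "linear"
    outcome: str = "MPR"
    roc_metrics: tuple[str, ...] = ("mean_nnd_um", "proximity_raw")
    min_group_size: int = 3
    out_dir: str = "spatialtme_out"

    def validate(self) -> None:
        if self.radius <= 0:
            raise ConfigError("radius must be > 0")
        simulated = self.simulate_preset is not None
        if simulated:
            if self.simulate_preset not in PRESETS:
                raise ConfigError(
                    f"unknown preset {self.simulate_preset!r}; "
                    f"choose from {sorted(PRESETS)}"
                )
        else:
            for p in (self.cells_path, self.clinical_path):
                if p is None:
                    raise ConfigError(
                        "need cells_path and clinical_path (or a preset)"
                    )
                if not Path(p).exists():
                    raise ConfigError(f"input path {p!r} does not exist")


@dataclass
class RunReport:
    patient_metrics: pd.DataFrame
    response_tests: pd.DataFrame
    tme_comparisons: pd.DataFrame
    odds_ratios: pd.DataFrame
    roc_summary: pd.DataFrame
    roc_points: pd.DataFrame
    manifest: dict
    out_dir: Path | None = None


def _fmt_p(p: float) -> str:
    return f"{p:.3f}"


def _fmt_summary(med: float, q1: float, q3: float) -> str:
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def load_inputs(config: RunConfig,
                rules: Sequence[PhenotypeRule] = DEFAULT_RULES):
    """(clinical DataFrame, {patient_id: [CellTable, ...]}) per config."""
    if config.simulate_preset:
        sim = PRESETS[config.simulate_preset](seed=config.seed)
        return simulate_cohort(sim)
    clinical = pd.read_csv(config.clinical_path)
    tables = parse_cell_table(config.cells_path)
    by_patient: dict[str, list[CellTable]] = {}
    for t in tables:
        by_patient.setdefault(t.patient_id, []).append(t)
    return clinical, by_patient


def compute_patient_metrics(clinical: pd.DataFrame,
                            cells: Mapping[str, Sequence[CellTable]],
                            config: RunConfig,
                            rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
                            warnings: list[str] | None = None) -> pd.DataFrame:
    """Per-patient metrics joined onto the clinical table.

    Patients present on only one side are excluded with a warning.
    """
    warnings = warnings if warnings is not None else []
    clinical_ids = set(map(str, clinical["patient_id"]))
    cell_ids = set(cells)
    for pid in sorted(cell_ids - clinical_ids):
        warnings.append(f"patient {pid!r} has cell tables but no clinical row; excluded")
    for pid in sorted(clinical_ids - cell_ids):
        warnings.append(f"patient {pid!r} has no cell tables; excluded from metrics")
    usable = sorted(clinical_ids & cell_ids)
    pms = [patient_metrics(list(cells[pid]), rules, radius=config.radius,
                           aggregation=config.aggregation) for pid in usable]
    mt = metrics_table(pms)
    merged = clinical.copy()
    merged["patient_id"] = merged["patient_id"].astype(str)
    return merged.merge(mt, on="patient_id", how="inner")


def response_tests(clinical: pd.DataFrame,
                   responses: Sequence[str] = ("ORR", "MPR", "pCR"),
                   histology_var: str = "histology",
                   regimen_var: str = "regimen") -> pd.DataFrame:
    """Response-rate tests per regimen subset (histology × response)."""
    subsets = [("All", None)]
    if regimen_var in clinical.columns:
        for r in dict.fromkeys(clinical[regimen_var]):
            subsets.append((str(r), {regimen_var: r}))
    rows = []
    for name, filt in subsets:
        for resp in responses:
            if resp not in clinical.columns:
                continue
            try:
                ct = build_contingency(clinical, resp, histology_var, filt,
                                       row_order=[1, 0])
                res = categorical_test(ct)
                rows.append({
                    "subset": name, "response": resp,
                    "counts": json.dumps(ct.counts.tolist()),
                    "columns": "|".join(ct.col_labels),
                    "method": res.method, "statistic": res.statistic,
                    "p": res.p, "p_printed": _fmt_p(res.p),
                })
            except SpatialTmeError as e:
                rows.append({"subset": name, "response": resp, "counts": "",
                             "columns": "", "method": "failed",
                             "statistic": float("nan"), "p": float("nan"),
                             "p_printed": f"error: {e}"})
    return pd.DataFrame(rows)


def tme_comparisons(pm: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Mann-Whitney comparisons of metrics between responder groups within
    each regimen × histology subset with enough patients per group."""
    rows = []
    outcome = config.outcome
    for (reg, hist), sub in pm.groupby(["regimen", "histology"], sort=False):
        g1 = sub[sub[outcome] == 1]
        g0 = sub[sub[outcome] == 0]
        if len(g1) < config.min_group_size or len(g0) < config.min_group_size:
            continue
        for metric in METRIC_COLUMNS:
            if metric not in sub.columns:
                continue
            x = g1[metric].dropna().to_numpy()
            y = g0[metric].dropna().to_numpy()
            if len(x) == 0 or len(y) == 0:
                continue
            res = mann_whitney(x, y, mode="auto")
            m1 = median_iqr(x, config.quartile_convention)
            m0 = median_iqr(y, config.quartile_convention)
            rows.append({
                "regimen": reg, "histology": hist, "metric": metric,
                f"{outcome}_n": len(x), f"N{outcome}_n": len(y),
                f"{outcome}_summary": _fmt_summary(*m1),
                f"N{outcome}_summary": _fmt_summary(*m0),
                "method": res.method, "U": res.statistic,
                "p": res.p, "p_printed": _fmt_p(res.p),
            })
    return pd.DataFrame(rows)


def odds_ratio_table(pm: pd.DataFrame, config: RunConfig,
                     subset: Mapping[str, object] | None = None,
                     warnings: list[str] | None = None) -> pd.DataFrame:
    """Median-split univariate odds ratios for the outcome (low vs high)."""
    warnings = warnings if warnings is not None else []
    df = pm
    if subset:
        for k, v in subset.items():
            df = df[df[k] == v]
    rows = []
    for metric in METRIC_COLUMNS:
        if metric not in df.columns:
            continue
        vals = df[metric].dropna()
        out = df.loc[vals.index, config.outcome].to_numpy()
        try:
            labels = dichotomize(vals.to_numpy(), config.dichotomize_rule)
            res = univariate_or(labels, out, predictor_positive="low",
                                outcome_positive=1,
                                split_rule=f"{config.dichotomize_rule} split")
            rows.append({
                "variable": f"{metric} (Low vs High)",
                "odds_ratio": res.odds_ratio, "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper, "p": res.p,
                "p_printed": _fmt_p(res.p), "corrected": res.corrected,
                "printed": f"{res.odds_ratio:.2f} "
                           f"({res.ci_lower:.2f}-{res.ci_upper:.2f})",
            })
        except SpatialTmeError as e:
            warnings.append(f"odds ratio for {metric}: {e}")
            rows.append({"variable": f"{metric} (Low vs High)",
                         "odds_ratio": float("nan"),
                         "ci_lower": float("nan"), "ci_upper": float("nan"),
                         "p": float("nan"), "p_printed": "NA",
                         "corrected": False, "printed": "NA"})
    return pd.DataFrame(rows)


def roc_tables(pm: pd.DataFrame, config: RunConfig,
               subset: Mapping[str, object] | None = None,
               warnings: list[str] | None = None):
    """(summary, operating points) for each configured ROC metric."""
    warnings = warnings if warnings is not None else []
    df = pm
    if subset:
        for k, v in subset.items():
            df = df[df[k] == v]
    summaries, points = [], []
    for metric in config.roc_metrics:
        if metric not in df.columns:
            continue
        vals = df[metric].dropna()
        labels = df.loc[vals.index, config.outcome].to_numpy() == 1
        try:
            roc = roc_curve(vals.to_numpy(), labels)
        except SpatialTmeError as e:
            warnings.append(f"ROC for {metric}: {e}")
            continue
        summaries.append({
            "metric": metric, "auc": roc.auc,
            "youden_threshold": roc.youden_threshold,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "orientation_flipped": roc.flipped,
            "n_pos": int(labels.sum()), "n_neg": int((~labels).sum()),
        })
        for t, sens, spec in roc.points:
            points.append({"metric": metric, "threshold": t,
                           "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(summaries), pd.DataFrame(points)


def run_pipeline(config: RunConfig,
                 rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
                 write: bool = True) -> RunReport:
    """Execute the full cascade and (optionally) write the report bundle."""
    config.validate()
    warnings: list[str] = []
    clinical, cells = load_inputs(config, rules)
    pm = compute_patient_metrics(clinical, cells, config, rules, warnings)
    resp = response_tests(clinical)
    comps = tme_comparisons(pm, config)
    # the odds-ratio and ROC analyses target the immunotherapy-treated
    # patients, mirroring the question "what predicts MPR under NAIC?"
    or_subset = {"regimen": "NAIC"} if "regimen" in pm.columns else None
    ors = odds_ratio_table(pm, config, or_subset, warnings)
    roc_subset = dict(or_subset or {})
    if "histology" in pm.columns and (pm.get("histology") == "SCC").any():
        roc_subset["histology"] = "SCC"
    roc_sum, roc_pts = roc_tables(pm, config, roc_subset or None, warnings)

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "package": "spatialtme",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "n_patients_clinical": int(len(clinical)),
        "n_patients_with_metrics": int(len(pm)),
        "n_statistical_tests": int(len(resp) + len(comps) + len(ors)
                                   + len(roc_sum)),
        "warnings": warnings,
    }
    report = RunReport(pm, resp, comps, ors, roc_sum, roc_pts, manifest)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pm.to_csv(out / "patient_metrics.csv", index=False)
        resp.to_csv(out / "response_tests.csv", index=False)
        comps.to_csv(out / "tme_comparisons.csv", index=False)
        ors.to_csv(out / "odds_ratios.csv", index=False)
        roc_sum.to_csv(out / "roc_summary.csv", index=False)
        roc_pts.to_csv(out / "roc_points.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        report.out_dir = out
    return report
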