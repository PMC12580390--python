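"""Synthetic multiplex-IF cohorts with tunable CAF–TAEC spatial coupling.

The generator emulates the structure the analysis assumes, not the imagery:
tissue-microarray cores as rectangular point patterns in μm, with

* endothelial (TAEC) cells laid down either as a homogeneous Poisson
  pattern or as a Thomas-style cluster process (vessel-like clumps:
  uniform parent points with Gaussian offspring scatter);
* fibroblasts (CAFs) of which a fraction κ ∈ [0, 1] is *coupled*: each
  coupled CAF is placed at a uniformly chosen TAEC plus an isotropic
  Gaussian offset of scale σ_couple, the remainder uniform. κ is the single
  dial that moves the mean CAF→TAEC nearest-neighbor distance and the 30 μm
  proximity count; responder groups differ only in their κ distribution;
* tumor (CK⁺) and "other" cells uniform, with PD-L1/PD-1 positivity on the
  appropriate compartments, and an optional per-marker flip noise.

All randomness flows from one master seed through
``numpy.random.SeedSequence(seed, patient_index, core_index)``, so any core
can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cell_model import CellRecord, CellTable, DEFAULT_MARKERS
from .errors import ConfigError

__all__ = [
    "CoreSimConfig", "GroupSpec", "CohortSimConfig",
    "simulate_core", "simulate_cohort", "closed_form_checks",
    "paper_scaffold_config", "naic_scc_mif_config",
]


@dataclass(frozen=True)
class CoreSimConfig:
    """Parameters of one simulated core.

    Fractions are of total cells; the remainder (1 − sum) is "other".
    ``taec_pattern`` is ``"poisson"`` or ``"cluster"``; the cluster pattern
    scatters TAECs around ``n_parents`` uniform parents with isotropic
    Gaussian scale ``cluster_sd`` μm. ``kappa`` is the coupled-CAF fraction
    and ``sigma_couple`` the coupling offset scale in μm.
    """

    width: float = 1000.0
    height: float = 1000.0
    n_cells: int = 2000
    frac_caf: float = 0.45
    frac_taec: float = 0.12
    frac_tumor: float = 0.30
    taec_pattern: str = "cluster"
    n_parents: int = 25
    cluster_sd: float = 30.0
    kappa: float = 0.0
    sigma_couple: float = 15.0
    marker_noise: float = 0.0
    pdl1_rate: float = 0.10
    pd1_rate: float = 0.10
    seed: int | tuple = 0

    def validate(self) -> None:
        total = self.frac_caf + self.frac_taec + self.frac_tumor
        if not (0 <= total <= 1):
            raise ConfigError(f"phenotype fractions sum to {total}, must be <= 1")
        if not (0 <= self.kappa <= 1):
            raise ConfigError(f"kappa must be in [0,1], got {self.kappa}")
        if self.sigma_couple <= 0:
            raise ConfigError("sigma_couple must be > 0")
        if self.taec_pattern not in ("poisson", "cluster"):
            raise ConfigError(f"unknown taec_pattern {self.taec_pattern!r}")
        if not (0 <= self.marker_noise <= 1):
            raise ConfigError("marker_noise must be a probability")
        if self.width <= 0 or self.height <= 0 or self.n_cells < 0:
            raise ConfigError("core geometry invalid")


def _uniform(rng, n, w, h):
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def simulate_core(config: CoreSimConfig, *, patient_id: str = "P1",
                  core_id: str = "C1") -> CellTable:
    """Generate one core as a phenotype-consistent :class:`CellTable`.

    Reproducible: the same config (including seed) yields the identical
    table. Cell counts per compartment are multinomial at the configured
    fractions. Marker flags follow the assigned identity (CAF → α-SMA⁺/CK⁻,
    TAEC → CD31⁺/CK⁻, tumor → CK⁺), then each marker is flipped
    independently with probability ``marker_noise``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    w, h = config.width, config.height
    f_other = 1.0 - config.frac_caf - config.frac_taec - config.frac_tumor
    n_caf, n_taec, n_tumor, n_other = rng.multinomial(
        config.n_cells,
        [config.frac_caf, config.frac_taec, config.frac_tumor, f_other],
    )

    if config.taec_pattern == "poisson" or n_taec == 0:
        taec_xy = _uniform(rng, n_taec, w, h)
    else:
        parents = _uniform(rng, config.n_parents, w, h)
        pick = rng.integers(0, config.n_parents, n_taec)
        taec_xy = _offspring(rng, parents, pick, config.cluster_sd, w, h)

    coupled = rng.random(n_caf) < config.kappa
    caf_xy = _uniform(rng, n_caf, w, h)
    n_coupled = int(coupled.sum())
    if n_coupled and n_taec:
        caf_xy[coupled] = _couple(rng, taec_xy, n_coupled,
                                  config.sigma_couple, w, h)
    tumor_xy = _uniform(rng, n_tumor, w, h)
    other_xy = _uniform(rng, n_other, w, h)

    identities = (["CAF"] * n_caf + ["TAEC"] * n_taec
                  + ["tumor"] * n_tumor + ["other"] * n_other)
    xy = np.vstack([caf_xy, taec_xy, tumor_xy, other_xy])
    order = rng.permutation(len(identities))

    cells = []
    for new_id, i in enumerate(order):
        ident = identities[i]
        markers = dict.fromkeys(DEFAULT_MARKERS, 0)
        if ident == "CAF":
            markers["aSMA"] = 1
        elif ident == "TAEC":
            markers["CD31"] = 1
        elif ident == "tumor":
            markers["CK"] = 1
            if rng.random() < config.pdl1_rate:
                markers["PDL1"] = 1
        else:
            if rng.random() < config.pd1_rate:
                markers["PD1"] = 1
        if config.marker_noise > 0:
            for m in DEFAULT_MARKERS:
                if rng.random() < config.marker_noise:
                    markers[m] = 1 - markers[m]
        cells.append(CellRecord(f"c{new_id:05d}", float(xy[i, 0]),
                                float(xy[i, 1]), markers))
    return CellTable(patient_id, core_id, w, h, cells)


def _offspring(rng, parents, pick, sd, w, h):
    """Offspring points around chosen parents, rejection-resampled into
    bounds (parent kept, offset redrawn)."""
    n = len(pick)
    pts = np.empty((n, 2))
    done = np.zeros(n, dtype=bool)
    while not done.all():
        idx = np.flatnonzero(~done)
        cand = parents[pick[idx]] + rng.normal(0, sd, (len(idx), 2))
        ok = ((cand[:, 0] >= 0) & (cand[:, 0] <= w)
              & (cand[:, 1] >= 0) & (cand[:, 1] <= h))
        pts[idx[ok]] = cand[ok]
        done[idx[ok]] = True
    return pts


def _couple(rng, targets, n, sd, w, h):
    """n points each at a uniformly chosen target + Gaussian offset,
    rejection-resampled (new target and offset) until inside bounds."""
    pick = rng.integers(0, len(targets), n)
    return _offspring(rng, targets, pick, sd, w, h)


def closed_form_checks(lam: float, r: float) -> tuple[float, float]:
    """Poisson-process oracles for validating the spatial metrics.

    For independent sources over a homogeneous Poisson target of intensity
    λ per μm²: the expected nearest-neighbor distance is 1/(2√λ) and the
    probability of a target within radius r is 1 − exp(−λπr²).
    """
    if lam <= 0:
        raise ConfigError("intensity must be > 0")
    return 1.0 / (2.0 * math.sqrt(lam)), 1.0 - math.exp(-lam * math.pi * r * r)


# ---------------------------------------------------------------------------
# Cohort level


@dataclass(frozen=True)
class GroupSpec:
    """One arm × histology cell of the cohort with its response counts.

    Responses are assigned as exact counts (deterministic emulation of a
    printed response table): the first ``n_pcr`` patients are pCR (pCR
    implies MPR), the first ``n_mpr`` are MPR, the first ``n_orr`` are ORR.
    """

    regimen: str  # "NAIC" | "NAC"
    histology: str  # "SCC" | "ADC"
    n: int
    n_mpr: int
    n_orr: int = 0
    n_pcr: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"group {self.regimen}/{self.histology} empty")
        if not (0 <= self.n_pcr <= self.n_mpr <= self.n):
            raise ConfigError("need 0 <= n_pcr <= n_mpr <= n")
        if not (0 <= self.n_orr <= self.n):
            raise ConfigError("need 0 <= n_orr <= n")


@dataclass(frozen=True)
class CohortSimConfig:
    """A cohort: groups, cores per patient, and per-response κ distributions.

    ``kappa_mpr`` / ``kappa_nmpr`` are Beta(a, b) parameters; MPR patients
    should get the *lower* mean κ (weaker CAF–TAEC coupling, hence larger
    nearest-neighbor distances), matching the direction the analysis is
    meant to detect.
    """

    groups: tuple[GroupSpec, ...]
    cores_per_patient: int = 2
    kappa_mpr: tuple[float, float] = (6.0, 4.0)
    kappa_nmpr: tuple[float, float] = (17.0, 3.0)
    core: CoreSimConfig = field(default_factory=CoreSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("cohort needs at least one group")
        for g in self.groups:
            g.validate()
        for a, b in (self.kappa_mpr, self.kappa_nmpr):
            if a <= 0 or b <= 0:
                raise ConfigError("Beta parameters must be > 0")
        if self.cores_per_patient < 1:
            raise ConfigError("cores_per_patient must be >= 1")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, dict[str, list[CellTable]]]:
    """Generate (clinical table, per-patient cell tables) for a cohort.

    The clinical table has one row per patient: patient_id, regimen,
    histology, MPR/ORR/pCR as 0/1, and the κ actually used (for auditing;
    a real export has no such column). Cell tables feed the pipeline
    unchanged.
    """
    config.validate()
    rows = []
    cell_tables: dict[str, list[CellTable]] = {}
    p_index = 0
    for g in config.groups:
        for i in range(g.n):
            pid = f"{g.regimen}-{g.histology}-{i + 1:03d}"
            mpr = int(i < g.n_mpr)
            pcr = int(i < g.n_pcr)
            orr = int(i < g.n_orr)
            a, b = config.kappa_mpr if mpr else config.kappa_nmpr
            kappa_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, p_index))
            )
            kappa = float(kappa_rng.beta(a, b))
            cores = []
            for j in range(config.cores_per_patient):
                core_cfg = replace(config.core, kappa=kappa,
                                   seed=(config.seed, p_index, j))
                cores.append(simulate_core(core_cfg, patient_id=pid,
                                           core_id=f"core{j + 1}"))
            cell_tables[pid] = cores
            rows.append({"patient_id": pid, "regimen": g.regimen,
                         "histology": g.histology, "MPR": mpr, "ORR": orr,
                         "pCR": pcr, "kappa": kappa})
            p_index += 1
    return pd.DataFrame(rows), cell_tables


def paper_scaffold_config(seed: int = 0, **overrides) -> CohortSimConfig:
    """104-patient scaffold: the four regimen × histology groups with the
    response counts of the motivating cohort (NAIC: 22 SCC / 13 ADC; NAC:
    24 SCC / 45 ADC)."""
    groups = (
        GroupSpec("NAIC", "SCC", 22, n_mpr=16, n_orr=13, n_pcr=9),
        GroupSpec("NAIC", "ADC", 13, n_mpr=4, n_orr=6, n_pcr=2),
        GroupSpec("NAC", "SCC", 24, n_mpr=7, n_orr=10, n_pcr=1),
        GroupSpec("NAC", "ADC", 45, n_mpr=9, n_orr=16, n_pcr=1),
    )
    return CohortSimConfig(groups=groups, seed=seed, **overrides)


def naic_scc_mif_config(seed: int = 0, **overrides) -> CohortSimConfig:
    """The small imaged subgroup: 11 chemoimmunotherapy-treated squamous
    patients, 7 responders (MPR) vs 4 non-responders."""
    groups = (GroupSpec("NAIC", "SCC", 11, n_mpr=7, n_orr=7, n_pcr=4),)
    return CohortSimConfig(groups=groups, seed=seed, **overrides)
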