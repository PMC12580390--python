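"""Data model and phenotype gating for per-cell multiplex-IF exports.

Input is the tabular per-cell export of a multiplex immunofluorescence
platform: one row per segmented (DAPI⁺) cell with its centroid in μm and
binary positivity calls for each marker. Cells are gated into phenotypes by
marker-combination rules, e.g. cancer-associated fibroblasts (CAF) as
α-SMA⁺/CK⁻ and tumor-associated endothelial cells (TAEC) as CD31⁺/CK⁻.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError

#: Marker names the default schema expects, in canonical order.
DEFAULT_MARKERS = ("CK", "aSMA", "CD31", "PDL1", "PD1")

#: Default CSV column names for each logical field.
DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "core_id": "core_id",
    "cell_id": "cell_id",
    "x": "x_um",
    "y": "y_um",
    "CK": "ck_pos",
    "aSMA": "asma_pos",
    "CD31": "cd31_pos",
    "PDL1": "pdl1_pos",
    "PD1": "pd1_pos",
}

#: Label given to cells no rule matches.
OTHER_LABEL = "other"


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: centroid in μm and binary marker positivity."""

    cell_id: str
    x: float
    y: float
    markers: Mapping[str, int]
    phenotype: str | None = None


@dataclass
class CellTable:
    """All cells of one tissue-microarray core for one patient.

    ``width`` and ``height`` give the core bounds in μm; every cell centroid
    must lie inside ``[0, width] × [0, height]``.
    """

    patient_id: str
    core_id: str
    width: float
    height: float
    cells: list[CellRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.cells:
            if c.cell_id in seen:
                raise ValidationError(
                    f"duplicate cell_id {c.cell_id!r} in core "
                    f"({self.patient_id}, {self.core_id})"
                )
            seen.add(c.cell_id)
            if not (0 <= c.x <= self.width and 0 <= c.y <= self.height):
                raise ValidationError(
                    f"cell {c.cell_id!r} at ({c.x}, {c.y}) outside core bounds "
                    f"[0,{self.width}]x[0,{self.height}]"
                )

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def phenotype_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.cells:
            label = c.phenotype if c.phenotype is not None else OTHER_LABEL
            counts[label] = counts.get(label, 0) + 1
        return counts

    def coords_of(self, phenotype: str):
        """(n, 2) list of (x, y) for cells with the given phenotype label."""
        return [(c.x, c.y) for c in self.cells if c.phenotype == phenotype]

    def marker_positive_count(self, marker: str) -> int:
        return sum(c.markers.get(marker, 0) for c in self.cells)

    def to_dataframe(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Export back to the tabular schema, with a phenotype column."""
        schema = dict(DEFAULT_SCHEMA if schema is None else schema)
        rows = []
        for c in self.cells:
            row = {
                schema["patient_id"]: self.patient_id,
                schema["core_id"]: self.core_id,
                schema["cell_id"]: c.cell_id,
                schema["x"]: c.x,
                schema["y"]: c.y,
            }
            for m in DEFAULT_MARKERS:
                if m in schema and m in c.markers:
                    row[schema[m]] = c.markers[m]
            row["phenotype"] = c.phenotype if c.phenotype is not None else ""
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhenotypeRule:
    """Gate: a cell gets ``name`` iff all require_positive markers are 1 and
    all require_negative markers are 0."""

    name: str
    require_positive: frozenset[str]
    require_negative: frozenset[str] = frozenset()

    def __init__(self, name: str, require_positive: Iterable[str],
                 require_negative: Iterable[str] = ()):  # noqa: D107
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "require_positive", frozenset(require_positive))
        object.__setattr__(self, "require_negative", frozenset(require_negative))

    def matches(self, markers: Mapping[str, int]) -> bool:
        return all(markers.get(m) == 1 for m in self.require_positive) and all(
            markers.get(m) == 0 for m in self.require_negative
        )


#: The study's operational definitions. Priority order resolves the rare
#: aSMA⁺/CD31⁺/CK⁻ double positive deterministically (CAF wins by default).
DEFAULT_RULES = (
    PhenotypeRule("CAF", require_positive=("aSMA",), require_negative=("CK",)),
    PhenotypeRule("TAEC", require_positive=("CD31",), require_negative=("CK",)),
    PhenotypeRule("tumor", require_positive=("CK",)),
)


def validate_rules(rules: Sequence[PhenotypeRule]) -> list[str]:
    """Return a list of rule-set violations (empty list = valid).

    Checks: empty names, markers required both positive and negative within
    one rule, duplicate rule names, rules with no marker requirement at all.
    """
    report: list[str] = []
    names: set[str] = set()
    for rule in rules:
        if not rule.name:
            report.append("rule with empty name")
        if rule.name in names:
            report.append(f"duplicate rule name {rule.name!r}")
        names.add(rule.name)
        overlap = rule.require_positive & rule.require_negative
        if overlap:
            report.append(
                f"rule {rule.name!r}: markers {sorted(overlap)} required both "
                "positive and negative"
            )
        if not rule.require_positive and not rule.require_negative:
            report.append(f"rule {rule.name!r} has no marker requirements")
    return report


def assign_phenotypes(
    table: CellTable,
    rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
    *,
    count_conflicts: bool = False,
) -> CellTable | tuple[CellTable, int]:
    """Label every cell with the first matching rule, or ``"other"``.

    Rules are applied in the given priority order; the first match wins.
    Idempotent: re-applying the same rules leaves labels unchanged.
    With ``count_conflicts=True`` also returns how many cells matched more
    than one rule (e.g. aSMA⁺/CD31⁺/CK⁻ double positives).
    """
    problems = validate_rules(rules)
    if problems:
        raise ConfigError("invalid rule set: " + "; ".join(problems))
    known = {m for c in table.cells for m in c.markers}
    if table.cells:
        for rule in rules:
            unknown = (rule.require_positive | rule.require_negative) - known
            if unknown:
                raise ConfigError(
                    f"rule {rule.name!r} references unknown marker(s) "
                    f"{sorted(unknown)}"
                )
    n_conflicts = 0
    labeled = []
    for cell in table.cells:
        matching = [r.name for r in rules if r.matches(cell.markers)]
        if len(matching) > 1:
            n_conflicts += 1
        label = matching[0] if matching else OTHER_LABEL
        labeled.append(replace(cell, phenotype=label))
    out = CellTable(table.patient_id, table.core_id, table.width, table.height,
                    labeled)
    return (out, n_conflicts) if count_conflicts else out


def _coerce_binary(value, column: str, line: int) -> int:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"line {line}: marker column {column!r} has non-numeric value "
            f"{value!r}"
        ) from None
    if v not in (0.0, 1.0):
        raise ValidationError(
            f"line {line}: marker column {column!r} has non-binary value "
            f"{value!r} (expected 0 or 1)"
        )
    return int(v)


def parse_cell_table(
    source,
    schema: Mapping[str, str] | None = None,
    *,
    markers: Sequence[str] = DEFAULT_MARKERS,
    width: float | None = None,
    height: float | None = None,
) -> list[CellTable]:
    """Parse a per-cell CSV into one :class:`CellTable` per (patient, core).

    ``source`` is a path or open text stream; ``schema`` maps logical field
    names (patient_id, core_id, cell_id, x, y, and each marker) to column
    names. Coordinates are taken as μm. Core bounds default to the max
    observed coordinate per core unless ``width``/``height`` are given.
    Row order is preserved within each core.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        df = pd.read_csv(source)
    else:
        df = pd.read_csv(io.StringIO(source.read()) if not isinstance(source, io.StringIO) else source)

    needed = ["patient_id", "core_id", "cell_id", "x", "y", *markers]
    for logical in needed:
        col = schema.get(logical)
        if col is None or col not in df.columns:
            raise SchemaError(f"missing mandatory column {col or logical!r}")
    for axis in ("x", "y"):
        col = schema[axis]
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"coordinate column {col!r} is not numeric")

    tables: list[CellTable] = []
    # sort=False keeps first-appearance order of (patient, core) groups
    for (pid, cid), grp in df.groupby(
        [schema["patient_id"], schema["core_id"]], sort=False
    ):
        cells = []
        for idx, row in grp.iterrows():
            line = int(idx) + 2  # header is line 1
            marker_vals = {
                m: _coerce_binary(row[schema[m]], schema[m], line) for m in markers
            }
            x, y = float(row[schema["x"]]), float(row[schema["y"]])
            if not (x >= 0 and y >= 0):
                raise ValidationError(
                    f"line {line}: negative coordinate ({x}, {y})"
                )
            cells.append(CellRecord(str(row[schema["cell_id"]]), x, y, marker_vals))
        w = width if width is not None else max((c.x for c in cells), default=0.0)
        h = height if height is not None else max((c.y for c in cells), default=0.0)
        tables.append(CellTable(str(pid), str(cid), w, h, cells))
    return tables
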