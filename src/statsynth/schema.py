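"""Table schemas, statistics vectors and their extraction.

A :class:`TableSchema` declares the columns of a patient-level table
(ranges, clinical "risky" thresholds, which column is the binary outcome).
From a table conforming to the schema a flat, ordered
:class:`StatisticsVector` is extracted: per-column minimum, maximum and
mean, plus the fraction of values beyond the risky threshold and the odds
ratio of that risk indicator against the outcome for every thresholded
feature column, and the outcome prevalence.  This vector is the only thing
the downstream generator ever sees about a table, so its ordering is a
pure function of the schema.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ColumnSpec",
    "TableSchema",
    "StatisticsVector",
    "Table",
    "SchemaError",
    "ValidationError",
    "extract_statistics",
    "risky_fraction",
    "compute_odds_ratio",
    "perturb_statistics",
    "validate_statistics",
]

COLUMN_KINDS = ("continuous", "count", "binary")
RISKY_DIRECTIONS = ("above", "below")

# Statistic kinds, in the per-column serialization order.
STAT_MIN = "min"
STAT_MAX = "max"
STAT_MEAN = "mean"
STAT_RISKY = "risky_fraction"
STAT_OR = "odds_ratio"
STAT_PREVALENCE = "prevalence"

#: Number of significant digits used when statistics are serialized to CSV.
CSV_PRECISION = 10


class SchemaError(ValueError):
    """A table/schema structural mismatch or an invalid schema."""


class ValidationError(ValueError):
    """Invalid numeric content (non-finite cells, bad vector lengths...)."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declarative description of one table column.

    Parameters
    ----------
    name:
        Column name, unique within a schema.
    kind:
        ``continuous`` (real-valued), ``count`` (non-negative integer) or
        ``binary`` (0/1).
    min_value, max_value:
        Inclusive value range.
    risky_threshold:
        Optional clinical threshold; values strictly beyond it (in
        ``risky_direction``) count as risky.
    risky_direction:
        ``above`` or ``below``; required iff ``risky_threshold`` is set.
    is_outcome:
        Marks the single binary outcome column of the schema.
    """

    name: str
    kind: str
    min_value: float
    max_value: float
    risky_threshold: float | None = None
    risky_direction: str | None = None
    is_outcome: bool = False

    def __post_init__(self) -> None:
        if self.kind not in COLUMN_KINDS:
            raise SchemaError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if not self.min_value <= self.max_value:
            raise SchemaError(f"column {self.name!r}: min_value > max_value")
        if (self.risky_threshold is None) != (self.risky_direction is None):
            raise SchemaError(
                f"column {self.name!r}: risky_threshold and risky_direction "
                "must be given together"
            )
        if self.risky_direction is not None and self.risky_direction not in RISKY_DIRECTIONS:
            raise SchemaError(f"column {self.name!r}: bad risky_direction")
        if self.risky_threshold is not None and not (
            self.min_value <= self.risky_threshold <= self.max_value
        ):
            raise SchemaError(
                f"column {self.name!r}: risky_threshold outside [min, max]"
            )
        if self.is_outcome and self.kind != "binary":
            raise SchemaError(f"outcome column {self.name!r} must be binary")

    @property
    def value_range(self) -> float:
        return self.max_value - self.min_value


@dataclass(frozen=True)
class TableSchema:
    """Ordered collection of :class:`ColumnSpec` with exactly one outcome."""

    columns: tuple[ColumnSpec, ...]
    n_rows_default: int = 766

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names")
        outcomes = [c for c in self.columns if c.is_outcome]
        if len(outcomes) != 1:
            raise SchemaError("schema must have exactly one outcome column")
        if self.n_rows_default < 1:
            raise SchemaError("n_rows_default must be positive")

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def outcome_column(self) -> ColumnSpec:
        return next(c for c in self.columns if c.is_outcome)

    @property
    def outcome_index(self) -> int:
        return next(i for i, c in enumerate(self.columns) if c.is_outcome)

    @property
    def feature_columns(self) -> list[ColumnSpec]:
        return [c for c in self.columns if not c.is_outcome]

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"no column named {name!r}")

    def statistic_menu(self) -> list[tuple[str, str]]:
        """Ordered (column name, statistic kind) pairs defining the vector.

        min/max/mean for every column; risky fraction and odds ratio for
        every thresholded feature column; prevalence for the outcome.
        The order is deterministic given the schema.
        """
        menu: list[tuple[str, str]] = []
        for c in self.columns:
            menu += [(c.name, STAT_MIN), (c.name, STAT_MAX), (c.name, STAT_MEAN)]
            if not c.is_outcome and c.risky_threshold is not None:
                menu += [(c.name, STAT_RISKY), (c.name, STAT_OR)]
            if c.is_outcome:
                menu.append((c.name, STAT_PREVALENCE))
        return menu

    @property
    def stat_dim(self) -> int:
        return len(self.statistic_menu())

    # -- config-file round trip ------------------------------------------
    def to_yaml(self) -> str:
        cols = []
        for c in self.columns:
            d: dict = {"name": c.name, "kind": c.kind, "min": c.min_value, "max": c.max_value}
            if c.risky_threshold is not None:
                d["risky_threshold"] = c.risky_threshold
                d["risky_direction"] = c.risky_direction
            if c.is_outcome:
                d["is_outcome"] = True
            cols.append(d)
        return yaml.safe_dump(
            {"n_rows_default": self.n_rows_default, "columns": cols}, sort_keys=False
        )

    @classmethod
    def from_yaml(cls, text: str) -> "TableSchema":
        raw = yaml.safe_load(text)
        cols = tuple(
            ColumnSpec(
                name=d["name"],
                kind=d["kind"],
                min_value=float(d["min"]),
                max_value=float(d["max"]),
                risky_threshold=(
                    float(d["risky_threshold"]) if "risky_threshold" in d else None
                ),
                risky_direction=d.get("risky_direction"),
                is_outcome=bool(d.get("is_outcome", False)),
            )
            for d in raw["columns"]
        )
        return cls(columns=cols, n_rows_default=int(raw.get("n_rows_default", 766)))


@dataclass
class Table:
    """A numeric patient table bound to a schema (rows = patients)."""

    values: np.ndarray
    schema: TableSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("table values must be a 2-D matrix")
        if self.values.shape[1] != self.schema.n_cols:
            raise SchemaError(
                f"table has {self.values.shape[1]} columns, schema expects "
                f"{self.schema.n_cols}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.schema.column_names.index(name)]

    @property
    def outcome(self) -> np.ndarray:
        return self.values[:, self.schema.outcome_index]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.schema.column_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: TableSchema) -> "Table":
        missing = set(schema.column_names) - set(df.columns)
        if missing:
            raise SchemaError(f"dataframe missing columns: {sorted(missing)}")
        return cls(df[schema.column_names].to_numpy(dtype=float), schema)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: TableSchema) -> "Table":
        return cls.from_dataframe(pd.read_csv(path), schema)

    def check_invariants(self) -> list[str]:
        """Range / outcome invariants; returns human-readable violations."""
        out: list[str] = []
        if not np.all(np.isfinite(self.values)):
            out.append("non-finite cell values")
            return out
        for j, c in enumerate(self.schema.columns):
            col = self.values[:, j]
            if col.min() < c.min_value - 1e-9 or col.max() > c.max_value + 1e-9:
                out.append(f"column {c.name}: values outside [min, max]")
        y = self.outcome
        if not np.isin(y, (0.0, 1.0)).all():
            out.append("outcome column not binary")
        elif not (np.any(y == 0.0) and np.any(y == 1.0)):
            out.append("outcome column lacks one of the classes")
        return out


@dataclass
class StatisticsVector:
    """Ordered, named flat vector of per-column summary statistics.

    ``entries`` follows ``schema.statistic_menu()`` exactly; this is the
    conditioning input of the generator and one row of the statistics CSV.
    """

    schema: TableSchema
    values: np.ndarray
    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            self.entries = self.schema.statistic_menu()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entries),):
            raise ValidationError(
                f"expected {len(self.entries)} statistic values, got "
                f"{self.values.shape}"
            )

    def get(self, column: str, kind: str) -> float:
        try:
            return float(self.values[self.entries.index((column, kind))])
        except ValueError as exc:
            raise KeyError((column, kind)) from exc

    def set(self, column: str, kind: str, value: float) -> None:
        self.values[self.entries.index((column, kind))] = value

    @property
    def names(self) -> list[str]:
        return [f"{c}__{k}" for c, k in self.entries]

    def to_csv_row(self) -> str:
        return ",".join(np.format_float_scientific(v, precision=CSV_PRECISION - 1)
                        for v in self.values)

    @classmethod
    def from_csv_row(cls, row: str, schema: TableSchema) -> "StatisticsVector":
        vals = np.array([float(x) for x in row.strip().split(",")])
        return cls(schema=schema, values=vals)

    def copy(self) -> "StatisticsVector":
        return StatisticsVector(self.schema, self.values.copy(), list(self.entries))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def risky_fraction(values: np.ndarray, threshold: float, direction: str) -> float:
    """Fraction of entries strictly beyond ``threshold`` in ``direction``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("risky_fraction: empty vector")
    if not np.all(np.isfinite(values)):
        raise ValidationError("risky_fraction: non-finite values")
    if direction not in RISKY_DIRECTIONS:
        raise ValidationError(f"risky_fraction: bad direction {direction!r}")
    if direction == "above":
        return float(np.mean(values > threshold))
    return float(np.mean(values < threshold))


def compute_odds_ratio(risky_flags: np.ndarray, outcome_flags: np.ndarray) -> float:
    """Cross-product odds ratio (a*d)/(b*c) of risk indicator vs outcome.

    a = risky cases, b = risky controls, c = non-risky cases,
    d = non-risky controls.  If any cell is zero, 0.5 is added to every
    cell (Haldane–Anscombe correction) so the ratio stays finite.
    """
    r = np.asarray(risky_flags, dtype=float)
    y = np.asarray(outcome_flags, dtype=float)
    if r.shape != y.shape:
        raise ValidationError("compute_odds_ratio: length mismatch")
    if not (np.isin(r, (0.0, 1.0)).all() and np.isin(y, (0.0, 1.0)).all()):
        raise ValidationError("compute_odds_ratio: flags must be binary")
    a = float(np.sum((r == 1) & (y == 1)))
    b = float(np.sum((r == 1) & (y == 0)))
    c = float(np.sum((r == 0) & (y == 1)))
    d = float(np.sum((r == 0) & (y == 0)))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _risky_flags(col: np.ndarray, spec: ColumnSpec) -> np.ndarray:
    if spec.risky_direction == "above":
        return (col > spec.risky_threshold).astype(float)
    return (col < spec.risky_threshold).astype(float)


def extract_statistics(table: Table, schema: TableSchema | None = None) -> StatisticsVector:
    """Extract the schema's full statistic menu from a table.

    Deterministic and invariant to the order of table rows.
    """
    if schema is None:
        schema = table.schema
    if table.schema.column_names != schema.column_names:
        raise SchemaError("table does not conform to schema (column mismatch)")
    X = table.values
    if not np.all(np.isfinite(X)):
        raise ValidationError("extract_statistics: non-finite cell")
    outcome = X[:, schema.outcome_index]
    vals = []
    for col_name, kind in schema.statistic_menu():
        j = schema.column_names.index(col_name)
        spec = schema.columns[j]
        col = X[:, j]
        # reductions run on the sorted column so the result is bit-identical
        # under any permutation of table rows
        sorted_col = np.sort(col)
        if kind == STAT_MIN:
            vals.append(sorted_col[0])
        elif kind == STAT_MAX:
            vals.append(sorted_col[-1])
        elif kind == STAT_MEAN:
            vals.append(sorted_col.mean())
        elif kind == STAT_RISKY:
            vals.append(risky_fraction(col, spec.risky_threshold, spec.risky_direction))
        elif kind == STAT_OR:
            vals.append(compute_odds_ratio(_risky_flags(col, spec), outcome))
        elif kind == STAT_PREVALENCE:
            vals.append(sorted_col.mean())
    return StatisticsVector(schema=schema, values=np.array(vals))


# ---------------------------------------------------------------------------
# perturbation and validation
# ---------------------------------------------------------------------------

def perturb_statistics(
    stats: StatisticsVector, amplitude: float, seed: int
) -> StatisticsVector:
    """Multiplicatively jitter every statistic by up to ``amplitude``.

    Each value v becomes v*(1+u) with u ~ Uniform(-amplitude, +amplitude),
    then the vector is repaired so its invariants hold again: min/max
    clipped to the schema's column range and re-ordered, mean clipped into
    [min, max], fractions clipped to [0, 1], odds ratios floored at 0.
    """
    if amplitude < 0:
        raise ValidationError("perturb_statistics: amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-amplitude, amplitude, size=stats.values.shape)
    out = stats.copy()
    out.values = stats.values * (1.0 + u)
    # invariant repair, column by column
    for c in stats.schema.columns:
        lo = out.get(c.name, STAT_MIN)
        hi = out.get(c.name, STAT_MAX)
        lo = min(max(lo, c.min_value), c.max_value)
        hi = min(max(hi, c.min_value), c.max_value)
        if lo > hi:
            lo, hi = hi, lo
        out.set(c.name, STAT_MIN, lo)
        out.set(c.name, STAT_MAX, hi)
        out.set(c.name, STAT_MEAN, min(max(out.get(c.name, STAT_MEAN), lo), hi))
        for kind in (STAT_RISKY, STAT_PREVALENCE):
            if (c.name, kind) in out.entries:
                out.set(c.name, kind, min(max(out.get(c.name, kind), 0.0), 1.0))
        if (c.name, STAT_OR) in out.entries:
            out.set(c.name, STAT_OR, max(out.get(c.name, STAT_OR), 0.0))
    return out


def validate_statistics(stats: StatisticsVector, schema: TableSchema) -> list[str]:
    """Return a list of invariant violations (empty iff the vector is valid)."""
    out: list[str] = []
    if stats.entries != schema.statistic_menu():
        out.append("entry order does not match the schema's statistic menu")
        return out
    if not np.all(np.isfinite(stats.values)):
        out.append("non-finite statistic value")
        return out
    for c in schema.columns:
        lo = stats.get(c.name, STAT_MIN)
        hi = stats.get(c.name, STAT_MAX)
        mu = stats.get(c.name, STAT_MEAN)
        if not lo <= mu <= hi:
            out.append(f"column {c.name}: violated min <= mean <= max")
        for kind in (STAT_RISKY, STAT_PREVALENCE):
            if (c.name, kind) in stats.entries:
                v = stats.get(c.name, kind)
                if not 0.0 <= v <= 1.0:
                    out.append(f"column {c.name}: {kind} {v} outside [0, 1]")
        if (c.name, STAT_OR) in stats.entries and stats.get(c.name, STAT_OR) < 0:
            out.append(f"column {c.name}: negative odds ratio")
    return out


# ---------------------------------------------------------------------------
# statistics CSV (one header row, one StatisticsVector per row)
# ---------------------------------------------------------------------------

def write_statistics_csv(path, vectors: Sequence[StatisticsVector]) -> None:
    if not vectors:
        raise ValidationError("write_statistics_csv: empty vector list")
    header = ",".join(vectors[0].names)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in vectors:
            fh.write(v.to_csv_row() + "\n")


def read_statistics_csv(path, schema: TableSchema) -> list[StatisticsVector]:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    header = lines[0].split(",")
    expected = [f"{c}__{k}" for c, k in schema.statistic_menu()]
    if header != expected:
        raise SchemaError("statistics CSV header does not match schema")
    return [StatisticsVector.from_csv_row(ln, schema) for ln in lines[1:]]
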