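"""Statistics-constrained random table synthesis and the training corpus.

The generator network is trained on pairs (statistics vector, table).  No
real table is available, so tables are manufactured to order: given a
target statistics vector, each feature column is partitioned into risky /
non-risky sub-ranges, values are sampled uniformly within each sub-range
with the risky count fixed to ``round(fraction * n_rows)``, and an
iterative clip-and-shift then pulls the column mean onto the target
without letting any cell leave its sub-range (so the risky count survives
the adjustment).  The binary outcome column is assigned to match the
target prevalence exactly, with cases placed preferentially on rows whose
risk-indicator pattern points the per-column odds ratios in the target's
direction.

The corpus builder perturbs a base statistics vector n times, synthesizes
one table per perturbed vector and re-extracts the statistics from the
actual tables, so that row i of the statistics CSV is exactly
``extract_statistics(table_i)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .schema import (
    STAT_MAX,
    STAT_MEAN,
    STAT_MIN,
    STAT_OR,
    STAT_PREVALENCE,
    STAT_RISKY,
    ColumnSpec,
    SchemaError,
    StatisticsVector,
    Table,
    TableSchema,
    ValidationError,
    extract_statistics,
    perturb_statistics,
    read_statistics_csv,
    validate_statistics,
    write_statistics_csv,
)

__all__ = [
    "Table",
    "TrainingCorpus",
    "InfeasibleTargetError",
    "synthesize_table",
    "build_training_corpus",
    "make_reference_table",
    "pima_schema",
]

#: Relative (to column range) tolerance of the mean-matching adjustment.
MEAN_TOLERANCE = 0.01


class InfeasibleTargetError(ValueError):
    """A target statistic cannot be realized by any table."""


# ---------------------------------------------------------------------------
# column synthesis
# ---------------------------------------------------------------------------

def _round_half_even(x: float) -> int:
    return int(np.round(x))


def _subrange(spec: ColumnSpec, lo: float, hi: float, risky: bool) -> tuple[float, float]:
    """Value range of the risky / non-risky group within target bounds [lo, hi]."""
    thr = spec.risky_threshold
    eps = 1e-9 * max(spec.value_range, 1.0)
    if spec.risky_direction == "above":
        rng = (thr + eps, hi) if risky else (lo, min(thr, hi))
    else:
        rng = (lo, thr - eps) if risky else (max(thr, lo), hi)
    if spec.kind == "count":
        if spec.risky_direction == "above":
            rng = (np.floor(thr) + 1, np.floor(hi)) if risky else (np.ceil(lo), np.floor(thr))
        else:
            rng = (np.ceil(lo), np.ceil(thr) - 1) if risky else (np.ceil(thr), np.floor(hi))
    return rng


def _adjust_mean(values: np.ndarray, groups: list[np.ndarray],
                 bounds: list[tuple[float, float]], target_mean: float,
                 tol: float, integer: bool, max_iter: int = 200) -> np.ndarray:
    """Shift-and-clip toward ``target_mean`` keeping each group in its bounds.

    Continuous columns are shifted uniformly and re-clipped; integer
    (count) columns are nudged cell by cell in whole units so rounding
    cannot undo the adjustment.  Best effort: stops when the residual is
    within ``tol`` or no cell has room left to move.
    """
    v = values.copy()
    n = v.size
    if not integer:
        for _ in range(max_iter):
            delta = target_mean - v.mean()
            if abs(delta) <= tol:
                break
            for idx, (lo, hi) in zip(groups, bounds):
                if idx.size:
                    v[idx] = np.clip(v[idx] + delta, lo, hi)
        return v

    v = np.round(v)
    for _ in range(max_iter):
        delta = target_mean - v.mean()
        if abs(delta) <= tol:
            break
        need = int(np.round(delta * n))     # whole units still to add
        if need == 0:
            break
        step = 1.0 if need > 0 else -1.0
        room = np.zeros(n, dtype=bool)
        for idx, (lo, hi) in zip(groups, bounds):
            if idx.size:
                room[idx] = v[idx] < hi if step > 0 else v[idx] > lo
        cand = np.flatnonzero(room)
        if cand.size == 0:
            break
        v[cand[: min(abs(need), cand.size)]] += step
    return v


def _synthesize_feature_column(spec: ColumnSpec, target: StatisticsVector,
                               n_rows: int, rng: np.random.Generator) -> np.ndarray:
    lo = target.get(spec.name, STAT_MIN)
    hi = target.get(spec.name, STAT_MAX)
    mean = target.get(spec.name, STAT_MEAN)
    if not (spec.min_value - 1e-9 <= lo <= hi <= spec.max_value + 1e-9):
        raise InfeasibleTargetError(f"column {spec.name}: target bounds outside schema")
    if not lo <= mean <= hi:
        raise InfeasibleTargetError(f"column {spec.name}: target mean outside [min, max]")

    if spec.risky_threshold is None:
        v = rng.uniform(lo, hi, size=n_rows)
        group = [np.arange(n_rows)]
        bnds = [(lo, hi)]
    else:
        frac = target.get(spec.name, STAT_RISKY)
        k = _round_half_even(frac * n_rows)
        r_lo, r_hi = _subrange(spec, lo, hi, risky=True)
        s_lo, s_hi = _subrange(spec, lo, hi, risky=False)
        if r_lo > r_hi:           # risky sub-range empty within target bounds
            k = 0
        if s_lo > s_hi:
            k = n_rows
        k = int(np.clip(k, 0, n_rows))
        v = np.empty(n_rows)
        # scatter the risky rows so risk flags are independent across columns
        perm = rng.permutation(n_rows)
        risky_idx = perm[:k]
        safe_idx = perm[k:]
        if k:
            v[risky_idx] = rng.uniform(r_lo, r_hi, size=k)
        if n_rows - k:
            v[safe_idx] = rng.uniform(s_lo, s_hi, size=n_rows - k)
        group = [risky_idx, safe_idx]
        bnds = [(r_lo, r_hi), (s_lo, s_hi)]

    tol = MEAN_TOLERANCE * max(spec.value_range, 1e-12)
    v = _adjust_mean(v, group, bnds, mean, tol, integer=(spec.kind == "count"))
    return v


def _assign_outcome(features: np.ndarray, schema: TableSchema,
                    target: StatisticsVector, n_rows: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Binary outcome matching target prevalence exactly, with cases
    sampled by a Gumbel-max weighted draw whose log-odds per row is the
    sum of log target odds ratios over its risk flags — so each column's
    realized OR approximates its target without exact matching."""
    oc = schema.outcome_column
    prev = target.get(oc.name, STAT_PREVALENCE)
    n_cases = int(np.clip(_round_half_even(prev * n_rows), 1, n_rows - 1))

    score = np.zeros(n_rows)
    feat_cols = [c for c in schema.columns if not c.is_outcome]
    for j, spec in enumerate(feat_cols):
        if spec.risky_threshold is None or (spec.name, STAT_OR) not in target.entries:
            continue
        odds = max(target.get(spec.name, STAT_OR), 1e-6)
        col = features[:, j]
        if spec.risky_direction == "above":
            flags = col > spec.risky_threshold
        else:
            flags = col < spec.risky_threshold
        score += np.log(odds) * flags
    score += rng.gumbel(0.0, 1.0, size=n_rows)   # weighted draw w/o replacement
    order = np.argsort(-score, kind="stable")
    y = np.zeros(n_rows)
    y[order[:n_cases]] = 1.0
    return y


def synthesize_table(target: StatisticsVector, schema: TableSchema,
                     n_rows: int | None = None, seed: int = 0) -> Table:
    """Build a random table whose extracted statistics approximate ``target``.

    Guarantees: all cells within the target's per-column [min, max]; risky
    counts equal to ``round(fraction * n_rows)`` whenever the sub-range is
    non-empty; column means within 1% of the column range of the target;
    outcome prevalence matched to the nearest count with both classes
    present.  Odds ratios are approximated greedily, not matched exactly.
    """
    if n_rows is None:
        n_rows = schema.n_rows_default
    if n_rows < 2:
        raise ValidationError("synthesize_table: need at least 2 rows")
    problems = validate_statistics(target, schema)
    if problems:
        raise ValidationError(f"invalid target statistics: {problems}")
    rng = np.random.default_rng(seed)
    feat_cols = [c for c in schema.columns if not c.is_outcome]
    features = np.column_stack(
        [_synthesize_feature_column(c, target, n_rows, rng) for c in feat_cols]
    )
    y = _assign_outcome(features, schema, target, n_rows, rng)
    values = np.empty((n_rows, schema.n_cols))
    fj = 0
    for j, c in enumerate(schema.columns):
        if c.is_outcome:
            values[:, j] = y
        else:
            values[:, j] = features[:, fj]
            fj += 1
    return Table(values, schema)


# ---------------------------------------------------------------------------
# training corpus
# ---------------------------------------------------------------------------

@dataclass
class TrainingCorpus:
    """Paired (statistics row, table file) training set on disk.

    Row i of the statistics CSV is exactly the re-extracted statistics of
    table file i (at CSV serialization precision).
    """

    schema: TableSchema
    table_paths: list[Path]
    statistics_path: Path

    @property
    def n_pairs(self) -> int:
        return len(self.table_paths)

    def load_table(self, i: int) -> Table:
        return Table.from_csv(self.table_paths[i], self.schema)

    def load_statistics(self) -> list[StatisticsVector]:
        return read_statistics_csv(self.statistics_path, self.schema)

    def save_manifest(self, path) -> None:
        Path(path).write_text(json.dumps({
            "schema": self.schema.to_yaml(),
            "statistics": str(self.statistics_path),
            "tables": [str(p) for p in self.table_paths],
        }, indent=1))

    @classmethod
    def from_manifest(cls, path) -> "TrainingCorpus":
        raw = json.loads(Path(path).read_text())
        return cls(
            schema=TableSchema.from_yaml(raw["schema"]),
            table_paths=[Path(p) for p in raw["tables"]],
            statistics_path=Path(raw["statistics"]),
        )


def build_training_corpus(base: StatisticsVector, schema: TableSchema,
                          n_tables: int = 10_000, amplitude: float = 0.01,
                          seed: int = 0, out_dir: str | Path = "corpus",
                          n_rows: int | None = None) -> TrainingCorpus:
    """Perturb ``base`` n_tables times, synthesize one table per vector,
    re-extract statistics from the actual tables and write everything to
    ``out_dir`` (one CSV per table + one statistics CSV + manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    width = max(len(str(n_tables - 1)), 5)
    table_paths: list[Path] = []
    extracted: list[StatisticsVector] = []
    for i in range(n_tables):
        pseed = int(rng.integers(0, 2**31 - 1))
        tseed = int(rng.integers(0, 2**31 - 1))
        target = perturb_statistics(base, amplitude, seed=pseed)
        try:
            table = synthesize_table(target, schema, n_rows=n_rows, seed=tseed)
        except (InfeasibleTargetError, ValidationError) as exc:
            raise InfeasibleTargetError(f"corpus table {i}: {exc}") from exc
        path = out_dir / f"table_{i:0{width}d}.csv"
        table.to_csv(path)
        table_paths.append(path)
        # re-read so stored statistics match the file bit-for-bit
        extracted.append(extract_statistics(Table.from_csv(path, schema)))
    stats_path = out_dir / "statistics.csv"
    write_statistics_csv(stats_path, extracted)
    corpus = TrainingCorpus(schema, table_paths, stats_path)
    corpus.save_manifest(out_dir / "manifest.json")
    return corpus


# ---------------------------------------------------------------------------
# PIMA-like reference fixture
# ---------------------------------------------------------------------------

def pima_schema() -> TableSchema:
    """Nine-column diabetes-study schema (766 rows by default).

    Risky thresholds are clinically plausible fixture parameters
    (e.g. glucose above 140 mg/dL, BMI above 30), not published values.
    """
    c = ColumnSpec
    return TableSchema(columns=(
        c("Pregnancies", "count", 0, 17, 6, "above"),
        c("Glucose", "continuous", 40, 200, 140, "above"),
        c("BloodPressure", "continuous", 20, 122, 90, "above"),
        c("SkinThickness", "continuous", 5, 99, 40, "above"),
        c("Insulin", "continuous", 10, 850, 200, "above"),
        c("BMI", "continuous", 15, 67, 30, "above"),
        c("DiabetesPedigreeFunction", "continuous", 0.05, 2.5, 1.0, "above"),
        c("Age", "count", 21, 81, 50, "above"),
        c("Outcome", "binary", 0, 1, is_outcome=True),
    ), n_rows_default=766)


def _generic_reference_table(schema: TableSchema, rng: np.random.Generator) -> Table:
    """Plausible random table for an arbitrary schema: uniform marginals,
    Bernoulli(0.35) outcome with both classes forced present."""
    n = schema.n_rows_default
    cols = []
    for c in schema.columns:
        if c.is_outcome:
            y = (rng.uniform(size=n) < 0.35).astype(float)
            if y.sum() == 0:
                y[0] = 1.0
            if y.sum() == n:
                y[0] = 0.0
            cols.append(y)
        else:
            v = rng.uniform(c.min_value, c.max_value, size=n)
            if c.kind == "count":
                v = np.round(v)
            cols.append(v)
    return Table(np.column_stack(cols), schema)


def make_reference_table(schema: TableSchema | None = None, seed: int = 0) -> Table:
    """Synthetic stand-in for the real diabetes table used as ground truth.

    Emulates the marginal shapes of the well-known Pima-Indians diabetes
    data (766 patients, 8 features + binary outcome) with the outcome
    generated from a logistic model on glucose, BMI and age so that the
    per-column odds ratios are epidemiologically sensible.  It is a
    synthetic fixture, not the real dataset.
    """
    if schema is None:
        schema = pima_schema()
    rng = np.random.default_rng(seed)
    n = schema.n_rows_default
    if [c.name for c in schema.columns] != [c.name for c in pima_schema().columns]:
        return _generic_reference_table(schema, rng)

    def clipped(x, name):
        c = schema.column(name)
        return np.clip(x, c.min_value, c.max_value)

    preg = clipped(rng.poisson(3.8, n), "Pregnancies")
    glucose = clipped(rng.normal(121, 31, n), "Glucose")
    bp = clipped(rng.normal(72, 12, n), "BloodPressure")
    skin = clipped(rng.normal(29, 10, n), "SkinThickness")
    insulin = clipped(rng.lognormal(4.7, 0.8, n), "Insulin")
    bmi = clipped(rng.normal(32, 7, n), "BMI")
    dpf = clipped(rng.lognormal(-0.85, 0.6, n), "DiabetesPedigreeFunction")
    age = clipped(np.round(21 + rng.gamma(2.0, 6.0, n)), "Age")

    z = (-9.8 + 0.035 * glucose + 0.09 * bmi + 0.035 * age
         + 0.6 * dpf + 0.04 * preg)
    outcome = (rng.uniform(size=n) < 1 / (1 + np.exp(-z))).astype(float)
    if outcome.sum() == 0:
        outcome[np.argmax(z)] = 1.0
    if outcome.sum() == n:
        outcome[np.argmin(z)] = 0.0

    cols = {
        "Pregnancies": preg.astype(float), "Glucose": glucose,
        "BloodPressure": bp, "SkinThickness": skin, "Insulin": insulin,
        "BMI": bmi, "DiabetesPedigreeFunction": dpf,
        "Age": age.astype(float), "Outcome": outcome,
    }
    values = np.column_stack([cols[c.name] for c in schema.columns])
    return Table(values, schema)
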