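"""Synthetic datamarts, cohort-query semantics and toy algorithms.

The platform ships with everything needed to exercise a full deployment
without any real hospital data:

* **Synthetic datamarts** — seeded generators producing byte-stable CSV
  tables from a declarative schema.  Every generated row carries a unique
  sentinel pseudonym (``SBX-SENTINEL-xxxxxxxx``); end-to-end tests scan all
  GUI-bound traffic for these sentinels to assert that patient-level rows
  never leave the hospital zone (the mediation property).
* **OMOP-lite** — a minimal two-table subset of the OMOP Common Data Model
  (person + condition_occurrence) with referential integrity, enough to
  exercise join queries.
* **Cohort queries** — conjunctions of field predicates, optionally joined
  across the OMOP-lite tables, used to select a datamart subcohort at
  submission time.
* **Toy algorithms** — runnable scripts that emit only aggregates, matching
  the platform's share-results-not-data principle: a row counter, a
  per-column summariser and a configurable sleeper (for load-balancing and
  parallelism tests).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rwdsandbox.errors import ContractError, QueryError

SENTINEL_PREFIX = "SBX-SENTINEL-"
OPERATORS = ("=", "!=", "<", "<=", ">", ">=", "in")


# -- cohort queries -------------------------------------------------------

@dataclass(frozen=True)
class Predicate:
    fld: str
    op: str
    literal: object

    def __post_init__(self):
        if self.op not in OPERATORS:
            raise ContractError(f"unknown operator {self.op!r}")


@dataclass(frozen=True)
class JoinSpec:
    left_table: str
    right_table: str
    key: str


@dataclass
class CohortQuery:
    """A conjunction of predicates, optionally over two joined tables.

    Predicate fields are written ``name`` for single-table queries and
    ``table.name`` when a join is present.
    """

    predicates: list[Predicate] = field(default_factory=list)
    join: JoinSpec | None = None


def _column(frame: pd.DataFrame, name: str) -> pd.Series:
    if name not in frame.columns:
        raise QueryError(f"unknown field {name!r}")
    return frame[name]


def _mask(frame: pd.DataFrame, pred: Predicate) -> pd.Series:
    col = _column(frame, pred.fld)
    lit = pred.literal
    try:
        if pred.op == "in":
            if not isinstance(lit, (list, tuple, set)):
                raise QueryError(f"'in' literal for {pred.fld!r} must be a list")
            return col.isin(list(lit))
        if pred.op in ("<", "<=", ">", ">=") and col.dtype.kind in "ifu" \
                and isinstance(lit, str):
            raise QueryError(
                f"type mismatch: ordering {pred.fld!r} ({col.dtype}) "
                f"against string {lit!r}")
        if pred.op == "=":
            return col == lit
        if pred.op == "!=":
            return col != lit
        if pred.op == "<":
            return col < lit
        if pred.op == "<=":
            return col <= lit
        if pred.op == ">":
            return col > lit
        return col >= lit
    except TypeError as exc:
        raise QueryError(f"type mismatch on field {pred.fld!r}: {exc}") from exc


def apply_cohort_query(tables: pd.DataFrame | dict[str, pd.DataFrame],
                       query: CohortQuery) -> pd.DataFrame:
    """Rows satisfying every predicate, input order preserved.

    With a join, the two tables are inner-joined on the key and predicates
    apply to the joined frame with ``table.field`` column names.
    """
    if query.join is not None:
        if not isinstance(tables, dict):
            raise QueryError("join query requires a dict of tables")
        j = query.join
        for t in (j.left_table, j.right_table):
            if t not in tables:
                raise QueryError(f"unknown table {t!r}")
        left = tables[j.left_table].add_prefix(f"{j.left_table}.")
        right = tables[j.right_table].add_prefix(f"{j.right_table}.")
        frame = left.merge(right, left_on=f"{j.left_table}.{j.key}",
                           right_on=f"{j.right_table}.{j.key}", how="inner")
    else:
        frame = tables if isinstance(tables, pd.DataFrame) else None
        if frame is None:
            raise QueryError("single-table query requires a DataFrame")
    mask = pd.Series(True, index=frame.index)
    for pred in query.predicates:
        mask &= _mask(frame, pred)
    return frame[mask]


# -- synthetic datamarts --------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """One generated column.

    kinds: ``sentinel`` (unique pseudonym), ``numeric`` (normal with
    ``mean``/``sd``, rounded to 2 decimals), ``integer`` (uniform
    ``low``..``high``), ``categorical`` (``categories`` with optional
    ``weights``), ``date`` (uniform day in ``start_year``..``end_year``).
    """

    name: str
    kind: str
    params: tuple = ()  # ((key, value), ...) — hashable for frozen dataclass

    def p(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class SyntheticSchema:
    name: str
    fields: tuple[FieldSpec, ...]
    seed: int = 0


def default_patient_schema(seed: int = 0) -> SyntheticSchema:
    """A curated analysis-ready table of the kind a hospital would expose:
    pseudonymised id, demographics, one biomarker, one visit date."""
    return SyntheticSchema(
        name="patients",
        seed=seed,
        fields=(
            FieldSpec("person_id", "sentinel"),
            FieldSpec("age", "numeric", (("mean", 62.0), ("sd", 12.0))),
            FieldSpec("gender", "categorical",
                      (("categories", ("F", "M")), ("weights", (0.54, 0.46)))),
            FieldSpec("biomarker", "numeric", (("mean", 4.2), ("sd", 1.1))),
            FieldSpec("visit_year", "integer", (("low", 2015), ("high", 2023))),
        ),
    )


def generate_datamart(schema: SyntheticSchema, n_rows: int,
                      seed: int | None = None) -> pd.DataFrame:
    """Deterministic synthetic table: same schema+seed ⇒ identical bytes."""
    if n_rows < 0:
        raise ContractError("n_rows must be >= 0")
    rng = np.random.default_rng(schema.seed if seed is None else seed)
    cols: dict[str, object] = {}
    for fs in schema.fields:
        p = fs.p()
        if fs.kind == "sentinel":
            ints = rng.integers(0, 2**32, size=n_rows, dtype=np.uint64)
            cols[fs.name] = [f"{SENTINEL_PREFIX}{i:08x}-{v:08x}"
                             for i, v in enumerate(ints)]
        elif fs.kind == "numeric":
            vals = rng.normal(p.get("mean", 0.0), p.get("sd", 1.0), size=n_rows)
            cols[fs.name] = np.round(vals, 2)
        elif fs.kind == "integer":
            cols[fs.name] = rng.integers(p.get("low", 0), p.get("high", 100) + 1,
                                         size=n_rows)
        elif fs.kind == "categorical":
            cats = list(p["categories"])
            w = p.get("weights")
            cols[fs.name] = rng.choice(cats, size=n_rows,
                                       p=list(w) if w else None)
        elif fs.kind == "date":
            y0, y1 = p.get("start_year", 2015), p.get("end_year", 2023)
            days = rng.integers(0, (y1 - y0 + 1) * 365, size=n_rows)
            base = pd.Timestamp(f"{y0}-01-01")
            cols[fs.name] = [(base + pd.Timedelta(int(d), "D")).date().isoformat()
                             for d in days]
        else:
            raise ContractError(f"unknown field kind {fs.kind!r}")
    return pd.DataFrame(cols, columns=[fs.name for fs in schema.fields])


def to_csv_bytes(frame: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode()


def generate_omop_lite(n_patients: int, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Minimal OMOP CDM subset: person + condition_occurrence.

    Every condition row references an existing person (referential
    integrity); conditions per person are Poisson-distributed (mean 2).
    """
    if n_patients < 0:
        raise ContractError("n_patients must be >= 0")
    rng = np.random.default_rng(seed)
    person = pd.DataFrame({
        "person_id": np.arange(1, n_patients + 1),
        "gender": rng.choice(["F", "M"], size=n_patients),
        "year_of_birth": rng.integers(1930, 2005, size=n_patients),
    })
    concepts = [201826, 316866, 443392, 4329847]  # a tiny toy vocabulary
    rows = []
    cid = 1
    for pid in person["person_id"]:
        for _ in range(rng.poisson(2.0)):
            start = pd.Timestamp("2018-01-01") + pd.Timedelta(
                int(rng.integers(0, 2000)), "D")
            rows.append((cid, int(pid), int(rng.choice(concepts)),
                         start.date().isoformat()))
            cid += 1
    condition = pd.DataFrame(
        rows, columns=["condition_occurrence_id", "person_id",
                       "condition_concept_id", "condition_start_date"],
    )
    return {"person": person, "condition_occurrence": condition}


# -- toy algorithms -------------------------------------------------------

_ROW_COUNTER = """\
import pandas as pd
import os
df = pd.read_csv("data.csv")
os.makedirs("results", exist_ok=True)
with open("results/row_count.txt", "w") as fh:
    fh.write(str(len(df)) + "\\n")
print("counted", len(df), "rows")
"""

_SUMMARISER = """\
import json, os
import pandas as pd
df = pd.read_csv("data.csv")
os.makedirs("results", exist_ok=True)
summary = {}
for col in df.columns:
    if pd.api.types.is_numeric_dtype(df[col]):
        summary[col] = {"mean": float(df[col].mean()), "n": int(df[col].count())}
    else:
        counts = df[col].value_counts()
        # aggregate-only: suppress identifying low-count categories
        summary[col] = {"n_distinct": int(counts.size),
                        "top_counts": {str(k): int(v) for k, v in
                                       counts.head(5).items() if v >= 5}}
with open("results/summary.json", "w") as fh:
    json.dump(summary, fh, indent=1, sort_keys=True)
print("summarised", len(df.columns), "columns")
"""

_SLEEPER = """\
import json, os, time
duration = 0.2
if os.path.exists("settings.json"):
    with open("settings.json") as fh:
        duration = float(json.load(fh).get("duration", duration))
time.sleep(duration)
os.makedirs("results", exist_ok=True)
with open("results/slept.txt", "w") as fh:
    fh.write(f"{duration}\\n")
"""

TOY_ALGORITHMS = {
    "alg-row-counter": ("row_counter.py", _ROW_COUNTER,
                        "Count the rows of the input table"),
    "alg-summariser": ("summariser.py", _SUMMARISER,
                       "Per-column mean / top category counts"),
    "alg-sleeper": ("sleeper.py", _SLEEPER,
                    "Sleep for settings['duration'] seconds"),
}


def toy_algorithm_catalog(dest_dir: str) -> dict[str, str]:
    """Write the runnable toy scripts under ``dest_dir``; returns
    item_id -> script path, ready to register in the local repository."""
    os.makedirs(dest_dir, exist_ok=True)
    out = {}
    for item_id, (fname, source, _desc) in TOY_ALGORITHMS.items():
        path = os.path.join(dest_dir, fname)
        with open(path, "w") as fh:
            fh.write(source)
        out[item_id] = path
    return out
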