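"""Symptom-disease knowledge base: schema, IO, validation, derived statistics.

The knowledge base is a small relational database of six tables:

* ``symptoms``       (symptom_id, description, observed_part) — what an owner
  can notice, tagged with one of the *observed* body parts/behaviours (the
  owner-facing vocabulary, e.g. eye, nose, feces).
* ``diseases``       (disease_id, description, appeared_part) — diseases tagged
  with the body system on which they manifest (the clinician-facing
  *appeared-part* vocabulary).
* ``associations``   (id, disease_id, symptom_id) — which symptoms a disease
  can present.
* ``observed_parts`` / ``appeared_parts`` — the two part vocabularies.
* ``part_map``       (observed_part -> appeared_part) — how the owner-facing
  parts project onto the clinical ones; every observed part maps to exactly
  one appeared part.

From the association table a binary disease x symptom incidence matrix is
derived; every engine works from it and from the per-disease symptom
profiles (L1-normalised incidence rows).

Canonical on-disk format is a directory of UTF-8 CSV files with header rows;
a single JSON file and an SQLite database are isomorphic alternates.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SymptomRecord",
    "DiseaseRecord",
    "KnowledgeBase",
    "Query",
    "Violation",
    "KBLoadError",
    "KBValidationError",
    "QueryError",
    "load_kb",
    "write_kb",
    "validate_kb",
    "eligible_targets",
    "symptom_stats",
]

CSV_FILES = {
    "symptoms": ("symptoms.csv", ["symptom_id", "description", "observed_part"]),
    "diseases": ("diseases.csv", ["disease_id", "description", "appeared_part"]),
    "associations": ("associations.csv", ["id", "disease_id", "symptom_id"]),
    "observed_parts": ("observed_parts.csv", ["part_id", "label"]),
    "appeared_parts": ("appeared_parts.csv", ["part_id", "label"]),
    "part_map": ("part_map.csv", ["observed_part", "appeared_part"]),
}

MAX_QUERY_LEN = 20


class KBLoadError(Exception):
    """A table is missing or unreadable."""


class KBValidationError(Exception):
    """The loaded tables violate the schema invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "\n".join(f"  - {v}" for v in violations)
        super().__init__(f"knowledge base failed validation:\n{lines}")


class QueryError(Exception):
    """A query does not satisfy the query invariants."""


@dataclass(frozen=True)
class SymptomRecord:
    symptom_id: int
    description: str
    observed_part: int


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: int
    description: str
    appeared_part: int


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which table, which row, which rule."""

    table: str
    row: object
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.table}] row {self.row}: {self.rule} — {self.message}"


@dataclass(frozen=True)
class Query:
    """An owner's query: ordered (observed_part, symptom_id) pairs.

    The observed part is what the owner selected in the part-first workflow;
    it must agree with the symptom's registered observed part (checked by
    :meth:`validate_against`).
    """

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.entries) <= MAX_QUERY_LEN:
            raise QueryError(
                f"query must have 1..{MAX_QUERY_LEN} entries, got {len(self.entries)}"
            )
        sids = [s for _, s in self.entries]
        if len(set(sids)) != len(sids):
            raise QueryError("duplicate symptom_id in query")

    @property
    def symptom_ids(self) -> tuple[int, ...]:
        return tuple(s for _, s in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, kb: "KnowledgeBase") -> None:
        for part, sid in self.entries:
            rec = kb.symptom_by_id.get(sid)
            if rec is None:
                raise KeyError(f"query symptom {sid} not in knowledge base")
            if rec.observed_part != part:
                raise QueryError(
                    f"symptom {sid} is registered on observed part "
                    f"{rec.observed_part}, query says {part}"
                )


@dataclass
class KnowledgeBase:
    symptoms: list[SymptomRecord]
    diseases: list[DiseaseRecord]
    associations: list[tuple[int, int, int]]  # (id, disease_id, symptom_id)
    observed_parts: dict[int, str]
    appeared_parts: dict[int, str]
    part_map: dict[int, int] = field(default_factory=dict)

    # ---- derived indexes (cached; dataclass equality ignores them) ----

    @cached_property
    def symptom_ids(self) -> np.ndarray:
        return np.array(sorted(s.symptom_id for s in self.symptoms), dtype=int)

    @cached_property
    def disease_ids(self) -> np.ndarray:
        return np.array(sorted(d.disease_id for d in self.diseases), dtype=int)

    @cached_property
    def symptom_by_id(self) -> dict[int, SymptomRecord]:
        return {s.symptom_id: s for s in self.symptoms}

    @cached_property
    def disease_by_id(self) -> dict[int, DiseaseRecord]:
        return {d.disease_id: d for d in self.diseases}

    @cached_property
    def symptom_index(self) -> dict[int, int]:
        return {int(s): i for i, s in enumerate(self.symptom_ids)}

    @cached_property
    def disease_index(self) -> dict[int, int]:
        return {int(d): i for i, d in enumerate(self.disease_ids)}

    @cached_property
    def incidence_matrix(self) -> np.ndarray:
        """Binary (n_diseases x n_symptoms) matrix; rows/cols in ascending id order."""
        inc = np.zeros((len(self.disease_ids), len(self.symptom_ids)), dtype=np.int8)
        di, si = self.disease_index, self.symptom_index
        for _, z, s in self.associations:
            inc[di[z], si[s]] = 1
        return inc

    @cached_property
    def incidence(self) -> pd.DataFrame:
        """Incidence as a DataFrame indexed by (disease_id, symptom_id)."""
        return pd.DataFrame(
            self.incidence_matrix,
            index=pd.Index(self.disease_ids, name="disease_id"),
            columns=pd.Index(self.symptom_ids, name="symptom_id"),
        )

    @cached_property
    def disease_symptoms(self) -> dict[int, frozenset[int]]:
        sets: dict[int, set[int]] = {int(d): set() for d in self.disease_ids}
        for _, z, s in self.associations:
            sets[z].add(s)
        return {z: frozenset(ss) for z, ss in sets.items()}

    @cached_property
    def profiles(self) -> np.ndarray:
        """Per-disease L1-normalised symptom profile (rows of the incidence matrix)."""
        inc = self.incidence_matrix.astype(float)
        sums = inc.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            prof = np.where(sums > 0, inc / sums, 0.0)
        return prof

    @cached_property
    def profile_sq_norms(self) -> np.ndarray:
        return np.einsum("ij,ij->i", self.profiles, self.profiles)

    @cached_property
    def disease_appeared(self) -> np.ndarray:
        """appeared_part per disease, aligned with ``disease_ids``."""
        return np.array(
            [self.disease_by_id[int(z)].appeared_part for z in self.disease_ids],
            dtype=int,
        )

    def mapped_part(self, observed_part: int) -> int:
        """Project an observed part onto its appeared part via ``part_map``."""
        try:
            return self.part_map[observed_part]
        except KeyError:
            raise KeyError(f"observed part {observed_part} has no part_map entry")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_kb(kb: KnowledgeBase) -> list[Violation]:
    """Check every schema invariant; returns a (possibly empty) violation list.

    Violations are data, not exceptions: an empty list means the KB is valid.
    """
    out: list[Violation] = []

    seen: set[int] = set()
    for s in kb.symptoms:
        if s.symptom_id < 1:
            out.append(Violation("symptoms", s.symptom_id, "non-positive id",
                                 "symptom_id must be a positive integer"))
        if s.symptom_id in seen:
            out.append(Violation("symptoms", s.symptom_id, "duplicate id",
                                 "symptom_id occurs more than once"))
        seen.add(s.symptom_id)
        if s.observed_part not in kb.observed_parts:
            out.append(Violation("symptoms", s.symptom_id, "unknown part",
                                 f"observed_part {s.observed_part} not in vocabulary"))

    seen = set()
    for d in kb.diseases:
        if d.disease_id < 1:
            out.append(Violation("diseases", d.disease_id, "non-positive id",
                                 "disease_id must be a positive integer"))
        if d.disease_id in seen:
            out.append(Violation("diseases", d.disease_id, "duplicate id",
                                 "disease_id occurs more than once"))
        seen.add(d.disease_id)
        if d.appeared_part not in kb.appeared_parts:
            out.append(Violation("diseases", d.disease_id, "unknown part",
                                 f"appeared_part {d.appeared_part} not in vocabulary"))

    sym_ids = {s.symptom_id for s in kb.symptoms}
    dis_ids = {d.disease_id for d in kb.diseases}
    seen = set()
    seen_pairs: set[tuple[int, int]] = set()
    for aid, z, s in kb.associations:
        if aid in seen:
            out.append(Violation("associations", aid, "duplicate id",
                                 "association id occurs more than once"))
        seen.add(aid)
        if (z, s) in seen_pairs:
            out.append(Violation("associations", aid, "duplicate pair",
                                 f"(disease {z}, symptom {s}) already associated"))
        seen_pairs.add((z, s))
        if z not in dis_ids:
            out.append(Violation("associations", aid, "dangling foreign key",
                                 f"disease_id {z} not in diseases"))
        if s not in sym_ids:
            out.append(Violation("associations", aid, "dangling foreign key",
                                 f"symptom_id {s} not in symptoms"))

    for op in kb.observed_parts:
        if op not in kb.part_map:
            out.append(Violation("part_map", op, "missing mapping",
                                 f"observed part {op} has no appeared-part image"))
    for op, ap in kb.part_map.items():
        if op not in kb.observed_parts:
            out.append(Violation("part_map", op, "unknown part",
                                 f"observed part {op} not in vocabulary"))
        if ap not in kb.appeared_parts:
            out.append(Violation("part_map", op, "unknown part",
                                 f"appeared part {ap} not in vocabulary"))

    return out


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

def eligible_targets(kb: KnowledgeBase, min_symptoms: int = 5) -> list[int]:
    """Diseases with at least ``min_symptoms`` associated symptoms, ascending id."""
    if min_symptoms < 1:
        raise ValueError("min_symptoms must be >= 1")
    counts = kb.incidence_matrix.sum(axis=1)
    return [int(z) for z, c in zip(kb.disease_ids, counts) if c >= min_symptoms]


def symptom_stats(kb: KnowledgeBase, symptom_id: int) -> tuple[int, int]:
    """(number of diseases containing the symptom,
    number of distinct appeared parts among those diseases)."""
    if symptom_id not in kb.symptom_index:
        raise KeyError(f"unknown symptom {symptom_id}")
    col = kb.incidence_matrix[:, kb.symptom_index[symptom_id]]
    has = col.astype(bool)
    n_diseases = int(has.sum())
    n_parts = int(np.unique(kb.disease_appeared[has]).size) if n_diseases else 0
    return n_diseases, n_parts


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "csv-dir"
    if path.suffix.lower() == ".json":
        return "json"
    if path.suffix.lower() in {".sqlite", ".db", ".sqlite3"}:
        return "sqlite"
    raise KBLoadError(f"cannot infer knowledge-base format from {path}")


def _from_frames(frames: dict[str, pd.DataFrame]) -> KnowledgeBase:
    sym = frames["symptoms"]
    dis = frames["diseases"]
    assoc = frames["associations"]
    kb = KnowledgeBase(
        symptoms=[
            SymptomRecord(int(r.symptom_id), str(r.description), int(r.observed_part))
            for r in sym.itertuples(index=False)
        ],
        diseases=[
            DiseaseRecord(int(r.disease_id), str(r.description), int(r.appeared_part))
            for r in dis.itertuples(index=False)
        ],
        associations=[
            (int(r.id), int(r.disease_id), int(r.symptom_id))
            for r in assoc.itertuples(index=False)
        ],
        observed_parts={
            int(r.part_id): str(r.label)
            for r in frames["observed_parts"].itertuples(index=False)
        },
        appeared_parts={
            int(r.part_id): str(r.label)
            for r in frames["appeared_parts"].itertuples(index=False)
        },
        part_map={
            int(r.observed_part): int(r.appeared_part)
            for r in frames["part_map"].itertuples(index=False)
        },
    )
    return kb


def _to_frames(kb: KnowledgeBase) -> dict[str, pd.DataFrame]:
    return {
        "symptoms": pd.DataFrame(
            [(s.symptom_id, s.description, s.observed_part) for s in kb.symptoms],
            columns=CSV_FILES["symptoms"][1],
        ),
        "diseases": pd.DataFrame(
            [(d.disease_id, d.description, d.appeared_part) for d in kb.diseases],
            columns=CSV_FILES["diseases"][1],
        ),
        "associations": pd.DataFrame(
            kb.associations, columns=CSV_FILES["associations"][1]
        ),
        "observed_parts": pd.DataFrame(
            sorted(kb.observed_parts.items()), columns=CSV_FILES["observed_parts"][1]
        ),
        "appeared_parts": pd.DataFrame(
            sorted(kb.appeared_parts.items()), columns=CSV_FILES["appeared_parts"][1]
        ),
        "part_map": pd.DataFrame(
            sorted(kb.part_map.items()), columns=CSV_FILES["part_map"][1]
        ),
    }


def load_kb(path, format: str | None = None, validate: bool = True) -> KnowledgeBase:
    """Load a knowledge base from a CSV directory, a JSON file, or SQLite.

    Raises :class:`KBLoadError` if a table is missing and
    :class:`KBValidationError` (listing offending rows) if invariants fail.
    """
    path = Path(path)
    if not path.exists():
        raise KBLoadError(f"no such path: {path}")
    fmt = format or _infer_format(path)

    frames: dict[str, pd.DataFrame] = {}
    if fmt == "csv-dir":
        for table, (fname, cols) in CSV_FILES.items():
            f = path / fname
            if not f.exists():
                raise KBLoadError(f"missing table '{table}' (expected {fname})")
            df = pd.read_csv(f, dtype={c: str for c in cols if c == "description" or c == "label"})
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise KBLoadError(f"table '{table}' lacks columns {missing}")
            frames[table] = df
    elif fmt == "json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        for table, (_, cols) in CSV_FILES.items():
            if table not in raw:
                raise KBLoadError(f"missing table '{table}' in {path.name}")
            frames[table] = pd.DataFrame(raw[table], columns=cols)
    elif fmt == "sqlite":
        con = sqlite3.connect(path)
        try:
            have = {
                r[0] for r in
                con.execute("SELECT name FROM sqlite_master WHERE type='table'")
            }
            for table, (_, cols) in CSV_FILES.items():
                if table not in have:
                    raise KBLoadError(f"missing table '{table}' in {path.name}")
                frames[table] = pd.read_sql_query(f"SELECT * FROM {table}", con)[cols]
        finally:
            con.close()
    else:
        raise KBLoadError(f"unknown format '{fmt}'")

    kb = _from_frames(frames)
    if validate:
        violations = validate_kb(kb)
        if violations:
            raise KBValidationError(violations)
    return kb


def write_kb(kb: KnowledgeBase, path, format: str = "csv-dir") -> Path:
    """Write the knowledge base in the requested format; returns the path."""
    path = Path(path)
    frames = _to_frames(kb)
    if format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        for table, (fname, _) in CSV_FILES.items():
            frames[table].to_csv(path / fname, index=False)
    elif format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {t: frames[t].values.tolist() for t in CSV_FILES}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
    elif format == "sqlite":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            for table in CSV_FILES:
                frames[table].to_sql(table, con, index=False)
            con.commit()
        finally:
            con.close()
    else:
        raise ValueError(f"unknown format '{format}'")
    return path
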