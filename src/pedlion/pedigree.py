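"""Studbook pedigree container, parsing, validation and reference extraction.

A studbook is a registry of a captive population: one row per animal with its
identifier, sire and dam identifiers, sex, birth date, current location and a
flag marking membership in the *reference population* (the living animals for
which diversity parameters are reported).

Conventions
-----------
* An animal whose two parents are both unrecorded is a **founder**: it is
  assumed unrelated to every other founder and non-inbred.
* An animal with exactly one recorded parent gets a unique **phantom founder**
  filling the empty slot, so that founder contributions stay well defined
  without inventing relatedness between animals.
* A parent identifier that never appears as a row of its own is materialised
  as a founder record (it is a named, recorded ancestor) with a warning.
"""

from __future__ import annotations

import datetime as _dt
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "ValidationReport",
    "PedigreeError",
    "CycleError",
    "parse_pedigree",
    "validate",
    "write_pedigree",
    "MISSING_TOKENS",
    "ACCEPTED_COLUMNS",
]

#: tokens interpreted as "no parent recorded" (configurable in parse_pedigree)
MISSING_TOKENS = ("0", "", "NA", "NULL")

ACCEPTED_COLUMNS = ("id", "sire", "dam", "sex", "birth_date", "location", "is_reference")
REQUIRED_COLUMNS = ("id", "sire", "dam")

_SEX_ALIASES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
    "u": "unknown", "unknown": "unknown", "": "unknown", "3": "unknown",
}

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", ""}


class PedigreeError(ValueError):
    """Hard error while building or parsing a pedigree."""


class CycleError(PedigreeError):
    """The ancestry graph contains a cycle; no topological order exists."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One studbook row: a single animal."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    birth_date: _dt.date | None = None
    location: str | None = None
    is_reference: bool = False
    is_phantom: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("animal id must be a non-empty token")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"animal {self.id!r} recorded as its own parent")
        if self.sex not in ("male", "female", "unknown"):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")


@dataclass
class ValidationReport:
    """Findings of :func:`validate`; an empty ``errors`` list means accepted."""

    errors: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    warnings: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "errors": [{"rule": r, "ids": list(ids)} for r, ids in self.errors],
            "warnings": [{"rule": r, "ids": list(ids)} for r, ids in self.warnings],
        }


def _phantom_id(child: str, slot: str) -> str:
    return f"~{child}.{slot}"


class Pedigree:
    """Validated, canonically ordered collection of :class:`PedigreeRecord`.

    Records are stored in input row order (appended founder/phantom records
    last); :attr:`topological_order` indexes them so that every parent
    precedes all of its offspring.
    """

    def __init__(self, records: Sequence[PedigreeRecord], *, warnings: Sequence[tuple[str, tuple[str, ...]]] = ()):
        self._warnings: list[tuple[str, tuple[str, ...]]] = list(warnings)
        records = list(records)

        seen: dict[str, int] = {}
        for i, rec in enumerate(records):
            if rec.id in seen:
                raise PedigreeError(f"duplicate animal id {rec.id!r}")
            seen[rec.id] = i

        # materialise referenced-but-undefined parents as founder records
        undeclared: list[str] = []
        for rec in list(records):
            for slot, pid in (("sire", rec.sire), ("dam", rec.dam)):
                if pid is not None and pid not in seen:
                    sex = "male" if slot == "sire" else "female"
                    newrec = PedigreeRecord(id=pid, sex=sex)
                    seen[pid] = len(records)
                    records.append(newrec)
                    undeclared.append(pid)
        if undeclared:
            self._warnings.append(("undeclared_parent", tuple(undeclared)))

        # unique phantom founder per single missing parent slot
        phantoms: list[PedigreeRecord] = []
        for i, rec in enumerate(records):
            if (rec.sire is None) != (rec.dam is None):
                slot = "sire" if rec.sire is None else "dam"
                pid = _phantom_id(rec.id, slot)
                if pid in seen:
                    raise PedigreeError(f"phantom id collision for {pid!r}")
                phantom = PedigreeRecord(
                    id=pid, sex="male" if slot == "sire" else "female", is_phantom=True
                )
                seen[pid] = len(records) + len(phantoms)
                phantoms.append(phantom)
                records[i] = replace(rec, **{slot: pid})
        records.extend(phantoms)

        self.records: tuple[PedigreeRecord, ...] = tuple(records)
        self._index: dict[str, int] = {r.id: i for i, r in enumerate(records)}

        n = len(records)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, rec in enumerate(records):
            if rec.sire is not None:
                self.sire_idx[i] = self._index[rec.sire]
            if rec.dam is not None:
                self.dam_idx[i] = self._index[rec.dam]

        # ancestry graph: edge parent -> child
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    g.add_edge(int(p), i)
        self._graph = g
        try:
            order = list(nx.lexicographical_topological_sort(g, key=lambda i: records[i].id))
            self._topo: tuple[int, ...] | None = tuple(order)
            self._cycle: list[str] | None = None
        except nx.NetworkXUnfeasible:
            self._topo = None
            cyc = nx.find_cycle(g)
            self._cycle = sorted({records[u].id for u, _ in cyc})

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal: str) -> bool:
        return animal in self._index

    def __iter__(self):
        return iter(self.records)

    def index(self, animal: str) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise PedigreeError(f"unknown animal id {animal!r}") from None

    def record(self, animal: str) -> PedigreeRecord:
        return self.records[self.index(animal)]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def real_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records if not r.is_phantom)

    @property
    def founders(self) -> frozenset[str]:
        """Animals with both parents unrecorded, phantoms included."""
        return frozenset(
            r.id for i, r in enumerate(self.records)
            if self.sire_idx[i] < 0 and self.dam_idx[i] < 0
        )

    @property
    def reference_ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.records if r.is_reference)

    @property
    def parse_warnings(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        return tuple(self._warnings)

    @property
    def has_cycle(self) -> bool:
        return self._topo is None

    @property
    def topological_order(self) -> tuple[int, ...]:
        """Record indices ordered so every parent precedes its offspring."""
        if self._topo is None:
            raise CycleError(f"ancestry cycle through {self._cycle}")
        return self._topo

    # -- graph operations ---------------------------------------------------

    def ancestor_closure(self, animals: Iterable[str]) -> frozenset[str]:
        """The given animals plus every ancestor of them (a fixed point)."""
        stack = [self.index(a) for a in animals]
        seen: set[int] = set(stack)
        while stack:
            i = stack.pop()
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0 and int(p) not in seen:
                    seen.add(int(p))
                    stack.append(int(p))
        return frozenset(self.records[i].id for i in seen)

    def subset(self, animals: Iterable[str]) -> "Pedigree":
        """Pedigree restricted to an ancestor-closed id set (input order kept)."""
        keep = set(animals)
        missing = keep - set(self.ids)
        if missing:
            raise PedigreeError(f"unknown animal ids {sorted(missing)!r}")
        if keep != set(self.ancestor_closure(keep)):
            raise PedigreeError("subset must be ancestor-closed")
        recs = [r for r in self.records if r.id in keep]
        return Pedigree(recs)

    def extract_reference(self) -> "Pedigree":
        """Reference animals plus the closed ancestor set needed to analyse them."""
        ref = self.reference_ids
        if not ref:
            raise PedigreeError("no animal is flagged as reference population")
        return self.subset(self.ancestor_closure(ref))

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Writable table of non-phantom records; phantom slots become missing."""
        rows = []
        for rec in self.records:
            if rec.is_phantom:
                continue
            sire = rec.sire if rec.sire is None or not self.record(rec.sire).is_phantom else None
            dam = rec.dam if rec.dam is None or not self.record(rec.dam).is_phantom else None
            rows.append({
                "id": rec.id,
                "sire": sire if sire is not None else "0",
                "dam": dam if dam is not None else "0",
                "sex": rec.sex,
                "birth_date": rec.birth_date.isoformat() if rec.birth_date else "0",
                "location": rec.location if rec.location is not None else "0",
                "is_reference": int(rec.is_reference),
            })
        return pd.DataFrame(rows, columns=list(ACCEPTED_COLUMNS))

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# parsing

_YEAR_RE = re.compile(r"^\d{4}$")


def _parse_date(token: str, missing: frozenset[str]) -> tuple[_dt.date | None, bool]:
    """Parse an ISO date; a bare year resolves to July 1 (flagged)."""
    if token in missing or token == "":
        return None, False
    if _YEAR_RE.match(token):
        return _dt.date(int(token), 7, 1), True
    try:
        return _dt.date.fromisoformat(token), False
    except ValueError:
        raise PedigreeError(f"unparseable birth date {token!r}") from None


def parse_pedigree(path_or_buffer, *, missing: Iterable[str] = MISSING_TOKENS, sep: str | None = None) -> Pedigree:
    """Read a delimited studbook file (comma or tab autodetected) into a Pedigree.

    Required columns: ``id``, ``sire``, ``dam``; optional: ``sex``,
    ``birth_date``, ``location``, ``is_reference``.  Tokens listed in
    *missing* encode an unrecorded value.
    """
    missing = frozenset(str(m) for m in missing)
    df = pd.read_csv(
        path_or_buffer, sep=sep, engine="python", dtype=str, keep_default_na=False
    )
    df.columns = [c.strip().lower() for c in df.columns]
    unknown = [c for c in df.columns if c not in ACCEPTED_COLUMNS]
    if unknown:
        raise PedigreeError(
            f"unknown column(s) {unknown!r}; accepted columns are {list(ACCEPTED_COLUMNS)!r}"
        )
    absent = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if absent:
        raise PedigreeError(f"missing required column(s) {absent!r}")

    warnings: list[tuple[str, tuple[str, ...]]] = []
    year_only: list[str] = []
    records: list[PedigreeRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rid = d["id"].strip()
        sire = d["sire"].strip()
        dam = d["dam"].strip()
        sex_tok = d.get("sex", "").strip().lower()
        if sex_tok not in _SEX_ALIASES:
            raise PedigreeError(f"unrecognised sex token {sex_tok!r} for animal {rid!r}")
        date_tok = d.get("birth_date", "").strip()
        bdate, was_year = _parse_date(date_tok, missing)
        if was_year:
            year_only.append(rid)
        loc = d.get("location", "").strip()
        if loc in missing:
            loc = ""
        ref_tok = d.get("is_reference", "").strip().lower()
        if ref_tok in _TRUE_TOKENS:
            is_ref = True
        elif ref_tok in _FALSE_TOKENS:
            is_ref = False
        else:
            raise PedigreeError(f"unrecognised reference flag {ref_tok!r} for animal {rid!r}")
        records.append(PedigreeRecord(
            id=rid,
            sire=None if sire in missing else sire,
            dam=None if dam in missing else dam,
            sex=_SEX_ALIASES[sex_tok],
            birth_date=bdate,
            location=loc or None,
            is_reference=is_ref,
        ))
    if year_only:
        warnings.append(("year_only_birth_date", tuple(year_only)))
    return Pedigree(records, warnings=warnings)


def write_pedigree(ped: Pedigree, path, sep: str = "\t") -> None:
    ped.write(path, sep=sep)


def loads(text: str, **kwargs) -> Pedigree:
    """Parse a pedigree from a string (convenience for tests and docs)."""
    return parse_pedigree(io.StringIO(text), **kwargs)


# ---------------------------------------------------------------------------
# validation


def validate(ped: Pedigree, mode: str = "permissive") -> ValidationReport:
    """Check structural consistency; permissive mode downgrades sex/date
    violations to warnings (zoo studbooks contain known inconsistencies)."""
    if mode not in ("strict", "permissive"):
        raise PedigreeError(f"unknown validation mode {mode!r}")
    report = ValidationReport()
    report.warnings.extend(ped.parse_warnings)

    if ped.has_cycle:
        report.errors.append(("ancestry_cycle", tuple(ped._cycle or ())))

    # sex-role consistency: same id used both as sire and as dam, or a parent
    # whose recorded sex contradicts its role
    sires = {r.sire for r in ped.records if r.sire is not None}
    dams = {r.dam for r in ped.records if r.dam is not None}
    both = sorted(sires & dams)
    conflicts = sorted(
        {p for p in sires if ped.record(p).sex == "female"}
        | {p for p in dams if ped.record(p).sex == "male"}
    )
    for rule, ids in (("sire_and_dam", both), ("parent_sex_conflict", conflicts)):
        if ids:
            finding = (rule, tuple(ids))
            (report.errors if mode == "strict" else report.warnings).append(finding)

    # birth-date ordering: offspring born after both parents when dates known
    bad_dates = []
    for i, rec in enumerate(ped.records):
        if rec.birth_date is None:
            continue
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                pb = ped.records[int(p)].birth_date
                if pb is not None and rec.birth_date <= pb:
                    bad_dates.append(rec.id)
                    break
    if bad_dates:
        finding = ("birth_before_parent", tuple(sorted(set(bad_dates))))
        (report.errors if mode == "strict" else report.warnings).append(finding)

    return report
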