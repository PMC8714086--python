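"""Generation intervals along the four parent-offspring pathways.

The generation interval is the mean age of a parent at the birth of its
offspring, tabulated separately for the father-son, father-daughter,
mother-son and mother-daughter pathways plus an overall row.  Two
offspring-selection modes are supported:

* ``reproducers_only`` — count only offspring that themselves left offspring
  in the pedigree (the interval over animals reared for reproduction, the
  quantity entering rate-of-inbreeding arguments);
* ``all_offspring`` — every parent-offspring pair with known dates.

Ages are computed in years of 365.25 days.  Pairs with a missing birth date
are excluded and counted; negative ages (data errors validation should have
caught) are excluded with their own count rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

__all__ = ["IntervalTable", "generation_intervals", "PATHWAYS"]

PATHWAYS = ("father-son", "father-daughter", "mother-son", "mother-daughter")
DAYS_PER_YEAR = 365.25


@dataclass
class IntervalTable:
    mode: str
    table: pd.DataFrame          # rows: pathways + "total"; cols: n, mean, sd
    n_missing_date: int          # pairs dropped for a missing birth date
    n_negative_age: int          # pairs dropped for a negative parental age
    n_unknown_sex: int           # pairs dropped for unsexed offspring

    def __getitem__(self, pathway: str) -> pd.Series:
        return self.table.loc[pathway]


def generation_intervals(ped: Pedigree, mode: str = "all_offspring") -> IntervalTable:
    """Mean parental age at offspring birth per pathway, in years."""
    if mode not in ("all_offspring", "reproducers_only"):
        raise PedigreeError(f"unknown interval mode {mode!r}")

    has_offspring = {r.sire for r in ped.records if r.sire is not None}
    has_offspring |= {r.dam for r in ped.records if r.dam is not None}

    ages: dict[str, list[float]] = {p: [] for p in PATHWAYS}
    n_missing = n_negative = n_unsexed = 0
    for i, rec in enumerate(ped.records):
        if rec.is_phantom:
            continue
        if mode == "reproducers_only" and rec.id not in has_offspring:
            continue
        for role, p in (("father", int(ped.sire_idx[i])), ("mother", int(ped.dam_idx[i]))):
            if p < 0 or ped.records[p].is_phantom:
                continue
            parent = ped.records[p]
            if rec.sex == "unknown":
                n_unsexed += 1
                continue
            if rec.birth_date is None or parent.birth_date is None:
                n_missing += 1
                continue
            age = (rec.birth_date - parent.birth_date).days / DAYS_PER_YEAR
            if age < 0:
                n_negative += 1
                continue
            child = "son" if rec.sex == "male" else "daughter"
            ages[f"{role}-{child}"].append(age)

    rows = []
    all_ages: list[float] = []
    for p in PATHWAYS:
        a = np.asarray(ages[p])
        all_ages.extend(ages[p])
        rows.append({
            "pathway": p,
            "n": a.size,
            "mean": float(a.mean()) if a.size else np.nan,
            "sd": float(a.std(ddof=1)) if a.size > 1 else (0.0 if a.size == 1 else np.nan),
        })
    a = np.asarray(all_ages)
    rows.append({
        "pathway": "total",
        "n": a.size,
        "mean": float(a.mean()) if a.size else np.nan,
        "sd": float(a.std(ddof=1)) if a.size > 1 else (0.0 if a.size == 1 else np.nan),
    })
    table = pd.DataFrame(rows).set_index("pathway")
    return IntervalTable(mode=mode, table=table, n_missing_date=n_missing,
                         n_negative_age=n_negative, n_unknown_sex=n_unsexed)
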