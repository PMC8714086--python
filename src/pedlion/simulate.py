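"""Synthetic studbook generator with known ground truth.

Breeds a discrete-generation captive population forward from unrelated
founders, recording everything an estimator could be asked to recover:
per-animal inbreeding (from an internally maintained relationship matrix),
per-generation mean inbreeding and its rate of increase, realised effective
size, and exact founder contributions to the reference population.  Parent
records can then be censored on a per-generation schedule, emulating the
steep completeness decay of real studbooks, *after* the truth is recorded.

Modes
-----
* ideal population (``constant_size=N``): exactly N offspring per
  generation, N/2 of each sex, parents drawn uniformly at random — Wright's
  idealised population with separate sexes, expected rate of inbreeding
  1/(2N) per generation.
* demographic mode: monogamous couples formed per mating policy
  (``random``, ``full_sib_bias`` — few large sibships, or ``min_kinship`` —
  couples paired by lowest current kinship), litter sizes Poisson.

One integer seed fully determines the output; per-stage substreams are
derived from it deterministically.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import completeness as _comp
from .pedigree import Pedigree, PedigreeError, PedigreeRecord

__all__ = ["SimConfig", "SimTruth", "simulate", "censor", "study_shape", "STUDY_SHAPE_CONFIG"]


@dataclass(frozen=True)
class SimConfig:
    n_founders: int = 20
    n_generations: int = 5
    offspring_mean: float = 2.0          # Poisson litter mean per couple
    sex_ratio: float = 0.5               # probability an offspring is male
    mating: str = "random"               # random | full_sib_bias | min_kinship
    constant_size: int | None = None     # ideal-population mode: fixed N per generation
    n_locations: int = 0
    transfer_prob: float = 0.0
    missing_parent_schedule: tuple[float, ...] = ()   # deletion prob by generation
    reference_generations: int = 2       # reference = animals of the last g generations
    reference_fraction: float = 1.0
    mean_parental_age: float = 6.5       # years; lions breed around this age
    age_sd: float = 1.0
    start_year: int = 1970
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise PedigreeError("need at least two founders")
        if not (0.0 < self.sex_ratio < 1.0):
            raise PedigreeError("sex ratio must be in (0, 1)")
        if self.mating not in ("random", "full_sib_bias", "min_kinship"):
            raise PedigreeError(f"unknown mating policy {self.mating!r}")
        for p in self.missing_parent_schedule:
            if not (0.0 <= p <= 1.0):
                raise PedigreeError("censoring probabilities must be in [0, 1]")
        if not (0.0 < self.reference_fraction <= 1.0):
            raise PedigreeError("reference fraction must be in (0, 1]")


@dataclass
class SimTruth:
    generation: pd.Series                 # per animal (founders = 0)
    F: pd.Series                          # realised inbreeding per animal
    founder_contributions: pd.Series      # exact gene-flow shares to the reference
    mean_F_by_generation: pd.Series
    delta_f_by_generation: np.ndarray     # (Fbar_t - Fbar_{t-1}) / (1 - Fbar_{t-1})
    ne_by_generation: np.ndarray          # 1 / (2 dF) per step (inf where dF = 0)
    schedule: tuple[float, ...]


class _Extinction(PedigreeError):
    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}: a sex died out")
        self.generation = generation


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate(config: SimConfig) -> tuple[Pedigree, SimTruth]:
    """Breed a synthetic studbook; returns (pedigree, ground truth).

    Censoring per ``missing_parent_schedule`` is applied after the truth is
    recorded, so the truth always describes the complete pedigree.
    """
    rng_breed, rng_sex, rng_date, rng_loc, rng_ref, rng_cens = _spawn(config.seed, 6)

    ids: list[str] = []
    sires: list[int] = []
    dams: list[int] = []
    sexes: list[str] = []
    gens: list[int] = []
    locs: list[int] = []

    cap = 4 * config.n_founders + 64
    A = np.zeros((cap, cap))
    contrib = np.zeros((cap, config.n_founders))

    def grow(need: int) -> None:
        nonlocal A, contrib, cap
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        A2 = np.zeros((new_cap, new_cap))
        A2[:cap, :cap] = A
        C2 = np.zeros((new_cap, config.n_founders))
        C2[:cap] = contrib
        A, contrib, cap = A2, C2, new_cap

    def add(sire: int, dam: int, sex: str, gen: int, loc: int) -> int:
        i = len(ids)
        grow(i + 1)
        ids.append(f"L{i + 1:04d}")
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        gens.append(gen)
        locs.append(loc)
        if sire < 0:
            A[i, i] = 1.0
            contrib[i, i] = 1.0  # founders are added first, index == founder slot
        else:
            row = 0.5 * (A[sire, :i] + A[dam, :i])
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + 0.5 * A[sire, dam]
            contrib[i] = 0.5 * (contrib[sire] + contrib[dam])
        return i

    # founders: guaranteed both sexes, near-even split
    n_m = max(1, min(config.n_founders - 1, round(config.n_founders * config.sex_ratio)))
    founder_sexes = ["male"] * n_m + ["female"] * (config.n_founders - n_m)
    rng_sex.shuffle(founder_sexes)
    for k in range(config.n_founders):
        loc = int(rng_loc.integers(config.n_locations)) if config.n_locations else -1
        add(-1, -1, founder_sexes[k], 0, loc)

    def offspring_sexes(n: int) -> list[str]:
        if config.constant_size:
            half = n // 2
            s = ["male"] * half + ["female"] * (n - half)
            rng_sex.shuffle(s)
            return s
        return ["male" if rng_sex.random() < config.sex_ratio else "female"
                for _ in range(n)]

    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sexes[i] == "male"]
        females = [i for i in prev if sexes[i] == "female"]
        if not males or not females:
            raise _Extinction(g)

        matings: list[tuple[int, int]] = []  # one (sire, dam) per offspring
        if config.constant_size:
            n = config.constant_size
            ms = rng_breed.integers(len(males), size=n)
            fs = rng_breed.integers(len(females), size=n)
            matings = [(males[a], females[b]) for a, b in zip(ms, fs)]
        else:
            mm = list(rng_breed.permutation(males))
            ff = list(rng_breed.permutation(females))
            n_couples = min(len(mm), len(ff))
            couples = list(zip(mm[:n_couples], ff[:n_couples]))
            litter_mean = config.offspring_mean
            if config.mating == "full_sib_bias":
                k = max(1, round(0.25 * n_couples))
                litter_mean = config.offspring_mean * n_couples / k
                couples = couples[:k]
            elif config.mating == "min_kinship":
                couples = _min_kinship_couples(males, females, A, len(ids))
            for s, d in couples:
                for _ in range(int(rng_breed.poisson(litter_mean))):
                    matings.append((s, d))

        if not matings:
            raise _Extinction(g)
        sx = offspring_sexes(len(matings))
        cur = []
        for (s, d), sex in zip(matings, sx):
            loc = locs[d]
            if config.n_locations and rng_loc.random() < config.transfer_prob:
                loc = int(rng_loc.integers(config.n_locations))
            cur.append(add(s, d, sex, g, loc))
        prev = cur

    n = len(ids)
    gen_arr = np.array(gens)

    # reference: (a fraction of) the animals of the last reference_generations
    last = max(1, config.n_generations + 1 - config.reference_generations)
    is_ref = np.zeros(n, dtype=bool)
    pool = np.nonzero(gen_arr >= last)[0]
    if config.reference_fraction < 1.0 and pool.size:
        take = max(1, int(round(config.reference_fraction * pool.size)))
        pool = np.sort(rng_ref.choice(pool, size=take, replace=False))
    is_ref[pool] = True

    # birth dates: generation clock plus per-animal age noise
    date0 = _dt.date(config.start_year, 7, 1)
    bdates: list[_dt.date] = []
    for i in range(n):
        eps = rng_date.normal(0.0, config.age_sd) if config.age_sd > 0 else 0.0
        days = round((gen_arr[i] * config.mean_parental_age + eps) * 365.25)
        bdates.append(date0 + _dt.timedelta(days=int(max(0, days))))

    records = [
        PedigreeRecord(
            id=ids[i],
            sire=ids[sires[i]] if sires[i] >= 0 else None,
            dam=ids[dams[i]] if dams[i] >= 0 else None,
            sex=sexes[i],
            birth_date=bdates[i],
            location=f"loc{locs[i] + 1:02d}" if locs[i] >= 0 else None,
            is_reference=bool(is_ref[i]),
        )
        for i in range(n)
    ]
    ped = Pedigree(records)

    # ground truth (from the generator's own bookkeeping, not the analysis code)
    F = pd.Series(np.diag(A[:n, :n]) - 1.0, index=ids)
    ref_idx = np.nonzero(is_ref)[0]
    q = contrib[ref_idx].mean(axis=0) if ref_idx.size else contrib[:n].mean(axis=0)
    q_series = pd.Series(q, index=ids[: config.n_founders])
    meanF = pd.Series(F.to_numpy()).groupby(gen_arr).mean()
    meanF.index.name = "generation"
    mf = meanF.to_numpy()
    with np.errstate(divide="ignore"):
        dfg = (mf[1:] - mf[:-1]) / (1.0 - mf[:-1])
        ne = np.where(dfg > 0, 1.0 / (2.0 * dfg), np.inf)

    truth = SimTruth(
        generation=pd.Series(gen_arr, index=ids),
        F=F,
        founder_contributions=q_series,
        mean_F_by_generation=meanF,
        delta_f_by_generation=dfg,
        ne_by_generation=ne,
        schedule=tuple(config.missing_parent_schedule),
    )

    if config.missing_parent_schedule:
        ped = censor(ped, config.missing_parent_schedule,
                     seed=int(rng_cens.integers(2 ** 31)),
                     generations=truth.generation)
    return ped, truth


def _min_kinship_couples(males, females, A, n) -> list[tuple[int, int]]:
    pairs = sorted(
        ((A[m, f] / 2.0, m, f) for m in males for f in females),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used: set[int] = set()
    couples = []
    for _, m, f in pairs:
        if m not in used and f not in used:
            couples.append((m, f))
            used.add(m)
            used.add(f)
    return couples


def censor(ped: Pedigree, schedule, seed: int = 0,
           generations: pd.Series | None = None) -> Pedigree:
    """Delete parent links independently per a per-generation schedule.

    ``schedule[g]`` is the probability that each parent link of an animal of
    generation g is removed (the deleted parent becomes unrecorded).  When
    *generations* is not given, an animal's generation is its maximum number
    of generations traced in the uncensored pedigree.  Entries beyond the
    schedule keep the last probability.
    """
    schedule = list(schedule)
    if not schedule:
        return ped
    if generations is None:
        generations = _comp.max_generations(ped)
    rng = np.random.default_rng(seed)
    out: list[PedigreeRecord] = []
    for rec in ped.records:
        if rec.is_phantom:
            continue
        g = int(generations.get(rec.id, 0))
        p = schedule[min(g, len(schedule) - 1)]
        sire, dam = rec.sire, rec.dam
        if sire is not None and ped.record(sire).is_phantom:
            sire = None
        if dam is not None and ped.record(dam).is_phantom:
            dam = None
        if sire is not None and rng.random() < p:
            sire = None
        if dam is not None and rng.random() < p:
            dam = None
        out.append(replace(rec, sire=sire, dam=dam))
    return Pedigree(out)


#: study-shaped preset: ~450 animals over 7 ancestor generations, ~20% of
#: them a living reference population spread over a dozen locations, and a
#: censoring schedule that makes completeness fall steeply with depth.
STUDY_SHAPE_CONFIG = SimConfig(
    n_founders=44,
    n_generations=6,
    offspring_mean=2.3,
    mating="random",
    n_locations=12,
    transfer_prob=0.15,
    missing_parent_schedule=(0.0, 0.95, 0.8, 0.55, 0.35, 0.2, 0.1),
    reference_generations=2,
    reference_fraction=0.6,
    mean_parental_age=6.5,
    age_sd=2.0,
    seed=0,
)

STUDY_SHAPE_TOTAL = 454
STUDY_SHAPE_REFERENCE = 98


def study_shape(seed: int = 0) -> tuple[Pedigree, SimTruth]:
    """Simulate a studbook with the shape of the published study: 454 animals,
    a 98-animal reference population, heavy missing-parent censoring.

    The simulated population is trimmed of childless, non-reference animals
    (and the reference flag re-sampled) to hit the target counts exactly;
    seeds for which the population comes up short are re-drawn
    deterministically.
    """
    base = STUDY_SHAPE_CONFIG
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        sim_seed = int(rng.integers(2 ** 31))
        try:
            ped, truth = simulate(replace(base, seed=sim_seed))
        except _Extinction:
            continue
        real = [r for r in ped.records if not r.is_phantom]
        if len(real) < STUDY_SHAPE_TOTAL:
            continue
        parents = {r.sire for r in real} | {r.dam for r in real}
        parents.discard(None)
        childless = [r.id for r in real if r.id not in parents]
        surplus = len(real) - STUDY_SHAPE_TOTAL
        drop = set()
        for rid in sorted(childless, key=lambda x: (ped.record(x).is_reference, x)):
            if len(drop) == surplus:
                break
            drop.add(rid)
        if len(drop) < surplus:
            continue
        kept = [r for r in real if r.id not in drop]
        ref = [r.id for r in kept if r.is_reference]
        if len(ref) < STUDY_SHAPE_REFERENCE:
            continue
        keep_ref = set(np.random.default_rng(sim_seed).choice(
            sorted(ref), size=STUDY_SHAPE_REFERENCE, replace=False))

        def strip(pid):  # phantom parents become unrecorded again
            return None if pid is None or ped.record(pid).is_phantom else pid

        final = [replace(r, sire=strip(r.sire), dam=strip(r.dam),
                         is_reference=r.id in keep_ref) for r in kept]
        return Pedigree(final), truth
    raise PedigreeError("could not realise the study-shaped preset from this seed")
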