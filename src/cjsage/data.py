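"""Encounter-history and breeding-record data model, validation, I/O and preprocessing.

The analysis operates on left-truncated adult encounter histories: each marked
bird enters the data at its first observation *as an adult* (its first breeding
observation), and detections are recorded annually until the end of its
population's monitoring window.  Birds ringed as nestlings that are later
recaptured enter with a known age (first adult observation year minus fledging
year); birds first captured as adults enter either as plumage-aged 1-year-olds
(known age 1) or with unknown age.  Nestlings never recaptured as adults carry
no adult information and are excluded.

Populations are demographically independent and may have disjoint monitoring
windows, so occasions are stored as 1-based indices within each population's
own window alongside the absolute calendar years.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Population",
    "EncounterHistory",
    "BreedingRecord",
    "RawRingingRecord",
    "StudyDataset",
    "MArray",
    "SchemaError",
    "age_class",
    "interval_age_classes",
    "apply_left_truncation",
    "assign_age_classes",
    "build_m_array",
    "read_encounters",
    "write_encounters",
    "read_breeding",
    "write_breeding",
    "load_study",
    "read_populations_yaml",
]

RING_AGES = ("nestling", "yearling", "adult_unknown")
SEXES = ("female", "male")


class SchemaError(ValueError):
    """Input data violating the encounter/breeding schema, with row context."""


@dataclass(frozen=True)
class Population:
    """A monitored breeding population with its own span of annual occasions."""

    label: str
    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError(f"population {self.label}: last_year < first_year")

    @property
    def n_occasions(self) -> int:
        return self.last_year - self.first_year + 1

    def occasion(self, year: int) -> int:
        """1-based occasion index of a calendar year within this window."""
        if not (self.first_year <= year <= self.last_year):
            raise ValueError(
                f"year {year} outside window {self.first_year}-{self.last_year} "
                f"of population {self.label}"
            )
        return year - self.first_year + 1


@dataclass(frozen=True)
class EncounterHistory:
    """One adult's detection record, conditioned on its first adult capture.

    ``detections`` runs from ``entry_occasion`` to the population's final
    occasion; its first element is always 1.  ``age_at_entry`` is in whole
    years (>= 1, adults only) or ``None`` for unknown-age recruits.
    """

    individual_id: str
    population_id: str
    sex: str
    entry_occasion: int
    age_at_entry: int | None
    detections: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"{self.individual_id}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.entry_occasion < 1:
            raise SchemaError(f"{self.individual_id}: entry_occasion must be >= 1")
        if self.age_at_entry is not None and self.age_at_entry < 1:
            raise SchemaError(f"{self.individual_id}: known age_at_entry must be >= 1 (adults only)")
        if len(self.detections) == 0 or self.detections[0] != 1:
            raise SchemaError(f"{self.individual_id}: first detection element must be 1")
        if any(d not in (0, 1) for d in self.detections):
            raise SchemaError(f"{self.individual_id}: detections must be 0/1")

    @property
    def known_age(self) -> bool:
        return self.age_at_entry is not None

    @property
    def n_occasions_observed(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class BreedingRecord:
    """An individual-year binary breeding outcome (>= 1 fledgling produced)."""

    individual_id: str
    population_id: str
    year: int  # 1-based occasion index within the population window
    success: int
    age: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.success not in (0, 1):
            raise SchemaError(f"{self.individual_id}: breeding success must be 0 or 1")
        if self.age is not None and self.age < 1:
            raise SchemaError(f"{self.individual_id}: breeding age must be >= 1 when known")


@dataclass(frozen=True)
class RawRingingRecord:
    """Pre-truncation record: ringing info plus adult detections over the window.

    ``detections`` is aligned to the population window (index 0 = first year)
    and contains adult observations only; the ringing of a nestling is not an
    adult detection.  ``sex`` may be None only for nestlings never recaptured.
    """

    individual_id: str
    population_id: str
    sex: str | None
    ring_year: int
    ring_age: str  # nestling | yearling | adult_unknown
    detections: tuple[int, ...]


@dataclass
class StudyDataset:
    """Validated container for a multi-population ringing study."""

    populations: dict[str, Population]
    histories: list[EncounterHistory] = field(default_factory=list)
    breeding: list[BreedingRecord] = field(default_factory=list)
    age_class_cap: int = 5
    n_nestlings_ringed: int = 0
    n_nestlings_recaptured: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for h in self.histories:
            pop = self.populations.get(h.population_id)
            if pop is None:
                raise SchemaError(f"{h.individual_id}: unknown population {h.population_id!r}")
            expected = pop.n_occasions - h.entry_occasion + 1
            if len(h.detections) != expected:
                raise SchemaError(
                    f"{h.individual_id}: detections length {len(h.detections)} != "
                    f"{expected} (entry {h.entry_occasion}, window {pop.n_occasions})"
                )
            prev = seen.get(h.individual_id)
            if prev is not None and prev != h.population_id:
                raise SchemaError(
                    f"{h.individual_id}: observed in populations {prev!r} and "
                    f"{h.population_id!r}; populations are demographically independent"
                )
            seen[h.individual_id] = h.population_id
        for r in self.breeding:
            pop = self.populations.get(r.population_id)
            if pop is None:
                raise SchemaError(f"{r.individual_id}: unknown population {r.population_id!r}")
            if not (1 <= r.year <= pop.n_occasions):
                raise SchemaError(
                    f"{r.individual_id}: breeding year {r.year} outside population window"
                )

    @property
    def n_known_age(self) -> int:
        return sum(h.known_age for h in self.histories)

    @property
    def n_unknown_age(self) -> int:
        return sum(not h.known_age for h in self.histories)

    def histories_for(self, population_id: str) -> list[EncounterHistory]:
        return [h for h in self.histories if h.population_id == population_id]


@dataclass
class MArray:
    """Reduced m-array: releases by occasion crossed with first reencounter.

    ``m[r, c]`` (1-based occasions, stored 0-based) counts individuals released
    at occasion r whose next reencounter is at occasion c > r; recaptured birds
    re-enter the release cohort of their recapture occasion.
    """

    m: np.ndarray  # (K, K) with m[r-1, c-1]
    releases: np.ndarray  # (K,)
    never_seen: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        m, rel, ns = self.m, self.releases, self.never_seen
        if (m < 0).any() or (rel < 0).any() or (ns < 0).any():
            raise ValueError("m-array entries must be non-negative")
        if not np.array_equal(m.sum(axis=1) + ns, rel):
            raise ValueError("m-array rows must sum with never_seen to releases")


def age_class(age: int, cap: int) -> int:
    """Pool ages above the cap into the terminal class (e.g. '5+')."""
    if cap < 2:
        raise ValueError("age_class_cap must be >= 2")
    return min(age, cap)


def interval_age_classes(history: EncounterHistory, cap: int) -> list[int | None]:
    """Age class governing each annual survival interval after entry.

    Interval k spans occasions ``entry+k`` to ``entry+k+1``; a bird entering at
    age a is age a+k at the start of that interval.  Unknown-age birds get
    ``None`` throughout (they use the unknown-age predictor).
    """
    n_int = len(history.detections) - 1
    if history.age_at_entry is None:
        return [None] * n_int
    return [age_class(history.age_at_entry + k, cap) for k in range(n_int)]


def assign_age_classes(dataset: StudyDataset, cap: int) -> StudyDataset:
    """Return the dataset with ``age_class_cap`` set (ages pooled at ``cap``)."""
    if cap < 2:
        raise ValueError("age_class_cap must be >= 2")
    return StudyDataset(
        populations=dataset.populations,
        histories=list(dataset.histories),
        breeding=list(dataset.breeding),
        age_class_cap=cap,
        n_nestlings_ringed=dataset.n_nestlings_ringed,
        n_nestlings_recaptured=dataset.n_nestlings_recaptured,
    )


def apply_left_truncation(
    raw_records: Iterable[RawRingingRecord],
    populations: dict[str, Population] | Sequence[Population],
    age_class_cap: int = 5,
) -> StudyDataset:
    """Convert raw ringing/resighting records into left-truncated histories.

    The first adult observation becomes the year of initial marking.  Known age
    at entry is (first adult observation year - fledging year) for
    nestling-ringed birds and 1 for birds plumage-aged as 1-year-olds when
    first captured; other adult recruits are of unknown age.  Ringed nestlings
    never observed as adults are dropped (their count is retained on the
    dataset for the juvenile-return diagnostic).

    Idempotent: applying it to records derived from an already truncated
    dataset reproduces that dataset.
    """
    if not isinstance(populations, dict):
        populations = {p.label: p for p in populations}
    histories: list[EncounterHistory] = []
    n_nest = 0
    n_nest_recap = 0
    for rec in raw_records:
        pop = populations.get(rec.population_id)
        if pop is None:
            raise SchemaError(f"{rec.individual_id}: unknown population {rec.population_id!r}")
        if rec.ring_age not in RING_AGES:
            raise SchemaError(f"{rec.individual_id}: ring_age must be one of {RING_AGES}")
        if len(rec.detections) != pop.n_occasions:
            raise SchemaError(
                f"{rec.individual_id}: raw detections length {len(rec.detections)} != "
                f"window length {pop.n_occasions}"
            )
        det = np.asarray(rec.detections, dtype=int)
        ring_occ = pop.occasion(rec.ring_year)
        if rec.ring_age == "nestling":
            n_nest += 1
            adult_occs = np.flatnonzero(det)
            if adult_occs.size == 0:
                continue  # never recaptured as an adult
            entry = int(adult_occs[0]) + 1
            if entry <= ring_occ:
                raise SchemaError(
                    f"{rec.individual_id}: adult observation at occasion {entry} "
                    f"precedes or coincides with nestling ringing year"
                )
            n_nest_recap += 1
            age_at_entry: int | None = entry - ring_occ
        else:
            adult_occs = np.flatnonzero(det)
            if adult_occs.size == 0 or int(adult_occs[0]) + 1 != ring_occ:
                raise SchemaError(
                    f"{rec.individual_id}: adult-ringed bird must be detected in its "
                    f"ringing year {rec.ring_year}"
                )
            entry = ring_occ
            age_at_entry = 1 if rec.ring_age == "yearling" else None
        if rec.sex is None:
            raise SchemaError(f"{rec.individual_id}: adults must be sexed")
        histories.append(
            EncounterHistory(
                individual_id=rec.individual_id,
                population_id=rec.population_id,
                sex=rec.sex,
                entry_occasion=entry,
                age_at_entry=age_at_entry,
                detections=tuple(int(x) for x in det[entry - 1 :]),
            )
        )
    return StudyDataset(
        populations=dict(populations),
        histories=histories,
        age_class_cap=age_class_cap,
        n_nestlings_ringed=n_nest,
        n_nestlings_recaptured=n_nest_recap,
    )


def _history_to_raw(h: EncounterHistory, pop: Population) -> RawRingingRecord:
    """Inverse of truncation for serialization; known-age entries are written as
    nestling-ringed in their implied fledging year."""
    full = np.zeros(pop.n_occasions, dtype=int)
    full[h.entry_occasion - 1 :] = h.detections
    if h.age_at_entry is None:
        ring_age = "adult_unknown"
        ring_year = pop.first_year + h.entry_occasion - 1
    elif h.age_at_entry == 1 and h.entry_occasion - 1 < 1:
        # entered at age 1 in the window's first year: fledging year precedes the
        # window, so only the plumage-aged label can carry the age
        ring_age = "yearling"
        ring_year = pop.first_year + h.entry_occasion - 1
    else:
        ring_age = "nestling"
        ring_year = pop.first_year + h.entry_occasion - 1 - h.age_at_entry
        if ring_year < pop.first_year:
            # fledged before the window opened; representable only as yearling if age 1
            if h.age_at_entry == 1:
                ring_age = "yearling"
                ring_year = pop.first_year + h.entry_occasion - 1
            else:
                raise SchemaError(
                    f"{h.individual_id}: known age {h.age_at_entry} implies ringing "
                    f"before the population window; cannot serialize"
                )
    return RawRingingRecord(
        individual_id=h.individual_id,
        population_id=h.population_id,
        sex=h.sex,
        ring_year=ring_year,
        ring_age=ring_age,
        detections=tuple(int(x) for x in full),
    )


# ---------------------------------------------------------------------------
# m-array construction

def build_m_array(dataset: StudyDataset, population_id: str) -> MArray:
    """Reduce one population's histories to the release/first-reencounter m-array."""
    pop = dataset.populations.get(population_id)
    if pop is None:
        raise KeyError(f"unknown population {population_id!r}")
    K = pop.n_occasions
    m = np.zeros((K, K), dtype=int)
    releases = np.zeros(K, dtype=int)
    for h in dataset.histories_for(population_id):
        occs = [h.entry_occasion + i for i, d in enumerate(h.detections) if d == 1]
        for r, c in zip(occs, occs[1:]):
            m[r - 1, c - 1] += 1
        for r in occs[:-1]:
            releases[r - 1] += 1
        if occs[-1] < K:
            releases[occs[-1] - 1] += 1  # final release, never reencountered
    never_seen = releases - m.sum(axis=1)
    return MArray(m=m, releases=releases, never_seen=never_seen)


# ---------------------------------------------------------------------------
# CSV / YAML / .inp I/O

_ENC_COLS = ["individual_id", "population_id", "sex", "ring_year", "ring_age", "detections"]
_BRD_COLS = ["individual_id", "population_id", "year", "success"]


def read_populations_yaml(path: str | Path) -> dict[str, Population]:
    """Read population windows from YAML: {populations: {label: {first_year, last_year}}}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pops = {}
    for label, win in doc["populations"].items():
        pops[label] = Population(label=str(label), first_year=int(win["first_year"]),
                                 last_year=int(win["last_year"]))
    return pops


def read_encounters(
    path: str | Path,
    populations: dict[str, Population],
    format: str = "csv",
    age_class_cap: int = 5,
    inp_groups: Sequence[dict] | None = None,
    inp_population: str | None = None,
) -> StudyDataset:
    """Read encounter histories and return a validated, left-truncated dataset.

    CSV rows follow the raw ringing schema (``individual_id, population_id, sex,
    ring_year, ring_age, detections``) with the detection string spanning the
    population's full window.  The MARK ``.inp`` dialect is one history string
    per line, whitespace, one frequency column per group, and a semicolon
    terminator; ``inp_groups`` maps group columns to sex/ring_age labels.
    """
    if format == "inp":
        return _read_inp(path, populations, inp_groups, inp_population, age_class_cap)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    raw: list[RawRingingRecord] = []
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        missing = set(_ENC_COLS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            det_str = row["detections"].strip()
            if not set(det_str) <= {"0", "1"}:
                raise SchemaError(f"{path} row {i}: malformed detection string {det_str!r}")
            sex = row["sex"].strip() or None
            if sex is not None and sex not in SEXES:
                raise SchemaError(f"{path} row {i}: unknown sex {sex!r}")
            try:
                raw.append(
                    RawRingingRecord(
                        individual_id=row["individual_id"].strip(),
                        population_id=row["population_id"].strip(),
                        sex=sex,
                        ring_year=int(row["ring_year"]),
                        ring_age=row["ring_age"].strip(),
                        detections=tuple(int(c) for c in det_str),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise SchemaError(f"{path} row {i}: {exc}") from exc
    try:
        return apply_left_truncation(raw, populations, age_class_cap=age_class_cap)
    except SchemaError:
        raise


def write_encounters(dataset: StudyDataset, path: str | Path) -> None:
    """Write histories in the raw CSV schema (round-trips with read_encounters)."""
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(_ENC_COLS)
        for h in dataset.histories:
            rec = _history_to_raw(h, dataset.populations[h.population_id])
            w.writerow(
                [rec.individual_id, rec.population_id, rec.sex, rec.ring_year,
                 rec.ring_age, "".join(str(d) for d in rec.detections)]
            )


def read_breeding(path: str | Path, populations: dict[str, Population]) -> list[BreedingRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        missing = set(_BRD_COLS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    BreedingRecord(
                        individual_id=row["individual_id"].strip(),
                        population_id=row["population_id"].strip(),
                        year=int(row["year"]),
                        success=int(row["success"]),
                    )
                )
            except (ValueError, SchemaError) as exc:
                raise SchemaError(f"{path} row {i}: {exc}") from exc
    return records


def write_breeding(records: Iterable[BreedingRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(_BRD_COLS)
        for r in records:
            w.writerow([r.individual_id, r.population_id, r.year, r.success])


def annotate_breeding(dataset: StudyDataset) -> StudyDataset:
    """Fill breeding-record age and sex by joining against the histories.

    The age of an individual at breeding year t is age_at_entry + (t - entry);
    unknown-age individuals stay unknown.  Records of individuals without a
    history keep age and sex unknown only if sex was given; otherwise they are
    rejected (breeding birds are observed, hence sexed).
    """
    by_id = {h.individual_id: h for h in dataset.histories}
    out = []
    for r in dataset.breeding:
        h = by_id.get(r.individual_id)
        if h is None:
            if r.sex is None:
                raise SchemaError(f"{r.individual_id}: breeding record without history or sex")
            out.append(r)
            continue
        age = None
        if h.age_at_entry is not None:
            age = h.age_at_entry + (r.year - h.entry_occasion)
            if age < 1:
                raise SchemaError(
                    f"{r.individual_id}: breeding year {r.year} precedes adult entry"
                )
        out.append(replace(r, age=age, sex=h.sex))
    return StudyDataset(
        populations=dataset.populations,
        histories=list(dataset.histories),
        breeding=out,
        age_class_cap=dataset.age_class_cap,
        n_nestlings_ringed=dataset.n_nestlings_ringed,
        n_nestlings_recaptured=dataset.n_nestlings_recaptured,
    )


def load_study(
    encounters_path: str | Path,
    populations: dict[str, Population] | str | Path,
    breeding_path: str | Path | None = None,
    age_class_cap: int = 5,
) -> StudyDataset:
    """Read encounters (+ optional breeding records) into one annotated dataset."""
    if not isinstance(populations, dict):
        populations = read_populations_yaml(populations)
    ds = read_encounters(encounters_path, populations, age_class_cap=age_class_cap)
    if breeding_path is not None:
        ds.breeding = read_breeding(breeding_path, populations)
        ds.validate()
        ds = annotate_breeding(ds)
    return ds


def _read_inp(
    path: str | Path,
    populations: dict[str, Population],
    groups: Sequence[dict] | None,
    population_id: str | None,
    age_class_cap: int,
) -> StudyDataset:
    """Parse the common MARK .inp dialect: 'HISTORY f1 [f2 ...];' per line.

    ``groups[k]`` gives the attributes of frequency column k, e.g.
    ``{"sex": "male", "ring_age": "adult_unknown"}``; ``population_id`` names
    the population whose window the history strings span.  Histories here are
    adult capture histories (first 1 = first adult capture), so ring_age is
    ``yearling`` or ``adult_unknown``.
    """
    if population_id is None or population_id not in populations:
        raise SchemaError(".inp input requires a valid inp_population")
    if not groups:
        raise SchemaError(".inp input requires inp_groups mapping frequency columns")
    pop = populations[population_id]
    raw: list[RawRingingRecord] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("/*")[0].strip()
            if not line:
                continue
            if not line.endswith(";"):
                raise SchemaError(f"{path} line {lineno}: missing ';' terminator")
            parts = line[:-1].split()
            hist, freqs = parts[0], parts[1:]
            if len(freqs) != len(groups):
                raise SchemaError(
                    f"{path} line {lineno}: {len(freqs)} frequency columns, "
                    f"expected {len(groups)}"
                )
            if len(hist) != pop.n_occasions or not set(hist) <= {"0", "1"}:
                raise SchemaError(f"{path} line {lineno}: malformed history {hist!r}")
            det = tuple(int(c) for c in hist)
            if sum(det) == 0:
                continue
            first = det.index(1) + 1
            for grp, f in zip(groups, freqs):
                for _ in range(int(f)):
                    counter += 1
                    raw.append(
                        RawRingingRecord(
                            individual_id=f"{population_id}_inp{counter}",
                            population_id=population_id,
                            sex=grp["sex"],
                            ring_year=pop.first_year + first - 1,
                            ring_age=grp.get("ring_age", "adult_unknown"),
                            detections=det,
                        )
                    )
    return apply_left_truncation(raw, populations, age_class_cap=age_class_cap)
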