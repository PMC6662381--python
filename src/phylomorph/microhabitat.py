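"""Microhabitat classification schemes for salamander species.

Species records carry a primary and optional secondary microhabitat out of
six categories — arboreal (A), cave (C), fossorial (F), saxicolous (S),
terrestrial (T), aquatic (W) — plus an arboreality status from an external
obligate/facultative survey. Six schemes collapse each record to one state:

========  =====================================================================
scheme    rule
========  =====================================================================
6-M       majority rule: the primary category
6-L       lenient: a species that is terrestrial plus something else is
          assigned the non-terrestrial category
7-M/7-L   as 6-M/6-L but species whose two categories are {T, W} become
          semiaquatic (SA)
6-McM     as 6-M, but arboreal = only species flagged obligate arboreal;
          facultative/none arboreal-primary species fall back to their
          secondary (or T)
6-McL     as 6-L, but arboreal additionally includes every species flagged
          obligate or facultative
========  =====================================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("A", "C", "F", "S", "T", "W")
SEMIAQUATIC = "SA"
SCHEMES = ("6-M", "6-L", "7-M", "7-L", "6-McM", "6-McL")
MCENTIRE_STATUSES = ("obligate", "facultative", "none")

__all__ = [
    "CATEGORIES",
    "SEMIAQUATIC",
    "SCHEMES",
    "MicrohabitatRecord",
    "SchemeAssignment",
    "apply_scheme",
    "read_records",
]


@dataclass(frozen=True)
class MicrohabitatRecord:
    species: str
    primary: str
    secondary: str | None = None
    mcentire_status: str = "none"

    def __post_init__(self):
        if self.primary not in CATEGORIES:
            raise ValueError(f"{self.species}: unknown primary category {self.primary!r}")
        if self.secondary is not None:
            if self.secondary not in CATEGORIES:
                raise ValueError(f"{self.species}: unknown secondary category {self.secondary!r}")
            if self.secondary == self.primary:
                raise ValueError(f"{self.species}: secondary equals primary")
        if self.mcentire_status not in MCENTIRE_STATUSES:
            raise ValueError(f"{self.species}: unknown status {self.mcentire_status!r}")


@dataclass(frozen=True)
class SchemeAssignment:
    scheme_id: str
    states: dict  # species -> category

    @property
    def state_labels(self) -> tuple:
        base = CATEGORIES + ((SEMIAQUATIC,) if self.scheme_id in ("7-M", "7-L") else ())
        present = set(self.states.values())
        return tuple(s for s in base if s in present)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.states), "state": list(self.states.values())}
        )


def _lenient(rec: MicrohabitatRecord) -> str:
    """Primary, except T+other -> the other category."""
    if rec.primary == "T" and rec.secondary is not None:
        return rec.secondary
    if rec.secondary == "T":
        return rec.primary
    if rec.secondary is not None and rec.primary != "T":
        # two non-terrestrial categories: keep primary, but flag it
        logger.warning(
            "%s: two non-terrestrial categories (%s, %s); keeping primary",
            rec.species, rec.primary, rec.secondary,
        )
    return rec.primary


def _classify(rec: MicrohabitatRecord, scheme_id: str) -> str:
    majority = scheme_id in ("6-M", "7-M", "6-McM")
    state = rec.primary if majority else _lenient(rec)

    if scheme_id in ("7-M", "7-L"):
        cats = {rec.primary, rec.secondary} if rec.secondary else {rec.primary}
        if cats == {"T", "W"}:
            return SEMIAQUATIC
        return state

    # "none" means the species was not covered by the external arboreal
    # survey, so its own classification stands under the Mc schemes
    if scheme_id == "6-McM":
        if rec.mcentire_status == "obligate":
            return "A"
        if rec.mcentire_status == "facultative" and state == "A":
            # surveyed but only facultatively arboreal: demote
            return rec.secondary if rec.secondary is not None else "T"
        return state
    if scheme_id == "6-McL":
        if rec.mcentire_status in ("obligate", "facultative"):
            return "A"
        return state
    return state


def apply_scheme(records, scheme_id: str) -> SchemeAssignment:
    """Collapse primary/secondary microhabitat records to one state per species."""
    if scheme_id not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme_id!r}; choose from {SCHEMES}")
    states = {}
    for rec in records:
        if rec.species in states:
            raise ValueError(f"duplicate species {rec.species!r}")
        states[rec.species] = _classify(rec, scheme_id)
    return SchemeAssignment(scheme_id=scheme_id, states=states)


def read_records(path) -> list[MicrohabitatRecord]:
    """Read a species microhabitat table (CSV with columns
    species, primary, secondary, mcentire_status; the last two optional)."""
    df = pd.read_csv(path)
    required = {"species", "primary"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        sec = row.get("secondary")
        if pd.isna(sec) or sec == "":
            sec = None
        status = row.get("mcentire_status", "none")
        if pd.isna(status) or status == "":
            status = "none"
        records.append(
            MicrohabitatRecord(
                species=str(row["species"]).strip().replace(" ", "_"),
                primary=str(row["primary"]).strip(),
                secondary=sec if sec is None else str(sec).strip(),
                mcentire_status=str(status).strip(),
            )
        )
    return records
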