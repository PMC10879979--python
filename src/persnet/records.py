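"""Typed records for participants, alters, ego networks, and cohorts.

An *ego network* is the personal network of one survey respondent (the ego /
index person): the people they named (alters), each alter's attributes, and
the symmetric alter–alter tie matrix.  The ego is implicitly tied to every
alter by construction of the elicitation, so the ego row/column is not
stored.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from persnet.codebook import GROUPS, TIMEPOINTS

#: Soft cap on network size; above this a validation warning is issued.
MAX_ALTERS = 25


@dataclass
class AlterRecord:
    """One network member (alter) and their surveyed attributes.

    Missing (optional / unanswered) values are ``None``.  Behavior flags are
    booleans; ``negative_influence`` is the ego's perception that this alter
    exerts a negative influence on their health.
    """

    alter_id: str
    relationship: str
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    contact_freq: Optional[str] = None
    years_known: Optional[float] = None
    distance_gt_15mi: Optional[bool] = None
    drinks: Optional[bool] = None
    smokes: Optional[bool] = None
    nonexerciser: Optional[bool] = None
    bad_diet: Optional[bool] = None
    negative_influence: Optional[bool] = None

    def validate(self) -> list[str]:
        issues = []
        if self.age is not None and self.age < 0:
            issues.append(f"alter {self.alter_id}: negative age {self.age}")
        if self.years_known is not None and self.years_known < 0:
            issues.append(
                f"alter {self.alter_id}: negative years_known {self.years_known}"
            )
        return issues


@dataclass
class EgoNetwork:
    """One participant's personal network at one timepoint.

    ``ties`` is a square boolean matrix over ``alters`` (same order), with a
    zero diagonal and symmetric entries; the ego is excluded from the matrix.
    """

    participant_id: str
    timepoint: str
    alters: list[AlterRecord] = field(default_factory=list)
    ties: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))

    def __post_init__(self) -> None:
        self.ties = np.asarray(self.ties, dtype=bool)

    @property
    def size(self) -> int:
        return len(self.alters)

    @property
    def alter_ids(self) -> list[str]:
        return [a.alter_id for a in self.alters]

    def validate(self) -> list[str]:
        issues = []
        n = self.size
        if self.timepoint not in TIMEPOINTS:
            issues.append(f"unknown timepoint {self.timepoint!r}")
        if self.ties.shape != (n, n):
            issues.append(
                f"tie matrix shape {self.ties.shape} does not match {n} alters"
            )
            return issues  # shape is a precondition for the remaining checks
        if n and not np.array_equal(self.ties, self.ties.T):
            bad = np.argwhere(self.ties != self.ties.T)
            i, j = bad[0]
            issues.append(
                "tie matrix not symmetric: "
                f"({self.alters[i].alter_id}, {self.alters[j].alter_id})"
            )
        if n and self.ties.diagonal().any():
            issues.append("tie matrix has nonzero diagonal (self-tie)")
        ids = self.alter_ids
        if len(set(ids)) != len(ids):
            issues.append("duplicate alter_id within network")
        if n > MAX_ALTERS:
            issues.append(f"network has {n} alters (> soft cap {MAX_ALTERS})")
        for alter in self.alters:
            issues.extend(alter.validate())
        return issues

    def tie_count(self) -> int:
        """Number of alter–alter ties (ego's ties excluded)."""
        return int(np.triu(self.ties, 1).sum())

    def subnetwork(self, keep: Iterable[int]) -> "EgoNetwork":
        """Return the network restricted to the alter indices in ``keep``."""
        keep = list(keep)
        return EgoNetwork(
            participant_id=self.participant_id,
            timepoint=self.timepoint,
            alters=[self.alters[i] for i in keep],
            ties=self.ties[np.ix_(keep, keep)].copy(),
        )


@dataclass
class ParticipantRecord:
    """Covariates and identifiers for one participant at one assessment."""

    participant_id: str
    group: str  # pwMS | control
    timepoint: str
    assessment_date: Optional[dt.date] = None
    cohort_id: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    ethnicity: Optional[str] = None
    disease_duration: Optional[float] = None  # years since first symptom; pwMS only
    employment: Optional[str] = None
    education: Optional[str] = None
    occupation: Optional[str] = None
    income_bracket: Optional[int] = None  # ordered 1..9
    married: Optional[bool] = None
    lives_alone: Optional[bool] = None
    elapsed_years: Optional[float] = None  # between paired assessments (1–4)

    def validate(self) -> list[str]:
        issues = []
        pid = self.participant_id
        if self.group not in GROUPS:
            issues.append(f"{pid}: unknown group {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            issues.append(f"{pid}: unknown timepoint {self.timepoint!r}")
        if self.disease_duration is not None and self.group == "control":
            issues.append(f"{pid}: disease_duration present for a control")
        if self.income_bracket is not None and self.income_bracket not in range(1, 10):
            issues.append(f"{pid}: income_bracket {self.income_bracket} not in 1..9")
        if self.elapsed_years is not None and not (1 <= self.elapsed_years <= 4):
            issues.append(f"{pid}: elapsed_years {self.elapsed_years} not in [1, 4]")
        if self.age is not None and self.age < 0:
            issues.append(f"{pid}: negative age")
        return issues


@dataclass
class ProSet:
    """Patient-reported outcomes at one assessment.

    PDDS (0 normal – 8 bedbound) and MSRS-R (0–32 symptom-burden sum) are
    specific to pwMS; the PROMIS Physical Function T-score (population mean
    50) applies to everyone.
    """

    pdds: Optional[float] = None
    msrs_r: Optional[float] = None
    promis_pf: Optional[float] = None

    def validate(self, group: str = "pwMS") -> list[str]:
        issues = []
        if self.pdds is not None and not (0 <= self.pdds <= 8):
            issues.append(f"pdds {self.pdds} outside 0–8")
        if self.msrs_r is not None and not (0 <= self.msrs_r <= 32):
            issues.append(f"msrs_r {self.msrs_r} outside 0–32")
        if group == "control" and (self.pdds is not None or self.msrs_r is not None):
            issues.append("MS-specific PRO present for a control")
        return issues


@dataclass
class CohortEntry:
    participant: ParticipantRecord
    network: EgoNetwork
    pros: ProSet

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant.participant_id, self.participant.timepoint)


@dataclass
class CohortTable:
    """All (participant, network, PRO) entries of a study export.

    A participant may contribute several prepandemic assessments (repeat
    baselines); at most one pandemic assessment per participant is allowed.
    Longitudinal linkage picks the most proximal prepandemic baseline.
    """

    entries: list[CohortEntry] = field(default_factory=list)

    def __iter__(self) -> Iterator[CohortEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entry: CohortEntry) -> None:
        self.entries.append(entry)

    def validate(self) -> list[str]:
        issues = []
        seen: set[tuple] = set()
        for e in self.entries:
            pid, tp = e.key
            k = (pid, tp, e.participant.assessment_date)
            if k in seen:
                issues.append(f"duplicate entry {k}")
            seen.add(k)
            issues.extend(e.participant.validate())
            issues.extend(f"{pid}/{tp}: {m}" for m in e.network.validate())
            issues.extend(f"{pid}/{tp}: {m}" for m in e.pros.validate(e.participant.group))
        pandemic = [e.key for e in self.entries if e.participant.timepoint == "pandemic"]
        if len(pandemic) != len(set(pandemic)):
            issues.append("participant with more than one pandemic assessment")
        return issues

    def select(
        self,
        group: Optional[str] = None,
        timepoint: Optional[str] = None,
    ) -> "CohortTable":
        out = [
            e
            for e in self.entries
            if (group is None or e.participant.group == group)
            and (timepoint is None or e.participant.timepoint == timepoint)
        ]
        return CohortTable(out)

    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.participant.participant_id, None)
        return list(seen)
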