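"""Reading, validating, and assembling PERSNET-style survey exports.

The expected export dialect is three UTF-8 CSV files:

* ``participants.csv`` — one row per (participant_id, timepoint[, date])
  with covariates and PRO scores;
* ``alters.csv`` — one row per alter with attributes;
* ``ties.csv`` — one row per alter–alter tie
  (``participant_id, timepoint, alter_id_1, alter_id_2[, tied]``).

Ties are undirected: a pair listed in either orientation is a tie; listing
both orientations is allowed only if they agree.  Missing values are empty
cells (many survey questions were optional).  Structural problems (bad
header, contradictory ties, duplicate keys) raise; soft issues (out-of-range
values, oversized networks) are emitted as warnings with row numbers.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from persnet.codebook import Codebook, default_codebook
from persnet.records import (
    AlterRecord,
    CohortEntry,
    CohortTable,
    EgoNetwork,
    ParticipantRecord,
    ProSet,
)

logger = logging.getLogger(__name__)


class CohortFormatError(ValueError):
    """Malformed file: missing or misnamed header columns."""


class CohortValidationError(ValueError):
    """Rows violate structural invariants (symmetry, duplicates, ordering)."""


PARTICIPANT_COLUMNS = [
    "participant_id",
    "timepoint",
    "assessment_date",
    "group",
    "cohort_id",
    "age",
    "sex",
    "race",
    "ethnicity",
    "disease_duration",
    "employment",
    "education",
    "occupation",
    "income_bracket",
    "married",
    "lives_alone",
    "pdds",
    "msrs_r",
    "promis_pf",
]

ALTER_COLUMNS = [
    "participant_id",
    "timepoint",
    "alter_id",
    "relationship",
    "age",
    "sex",
    "race",
    "contact_freq",
    "years_known",
    "distance_gt_15mi",
    "drinks",
    "smokes",
    "nonexerciser",
    "bad_diet",
    "negative_influence",
]

TIE_COLUMNS = ["participant_id", "timepoint", "alter_id_1", "alter_id_2"]

_REQUIRED = {
    "participants": ["participant_id", "timepoint", "group"],
    "alters": ["participant_id", "timepoint", "alter_id", "relationship"],
    "ties": TIE_COLUMNS,
}


def _opt(value):
    """Missing CSV cell -> None."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return value


def _opt_bool(value) -> Optional[bool]:
    v = _opt(value)
    if v is None:
        return None
    if isinstance(v, str):
        v = v.strip().lower()
        if v in ("true", "1", "yes"):
            return True
        if v in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot interpret {value!r} as boolean")
    return bool(int(v))


def _opt_float(value) -> Optional[float]:
    v = _opt(value)
    return None if v is None else float(v)


def _opt_date(value) -> Optional[dt.date]:
    v = _opt(value)
    if v is None:
        return None
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v).strip())


def _check_header(df: pd.DataFrame, kind: str, path) -> None:
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: {kind} file missing columns {missing}")


def read_cohort(
    participants_table: str | Path,
    alters_table: str | Path,
    ties_table: str | Path,
    codebook: Codebook | None = None,
) -> CohortTable:
    """Parse the three-file export into a validated :class:`CohortTable`.

    Raises :class:`CohortFormatError` for malformed headers and
    :class:`CohortValidationError` for contradictory ties, ties naming
    unknown alters, or duplicate keys; soft validation issues are reported
    as warnings with the offending row numbers.
    """
    cb = codebook or default_codebook()
    rename = {v: k for k, v in cb.column_map.items()}
    parts = pd.read_csv(participants_table).rename(columns=rename)
    alters = pd.read_csv(alters_table).rename(columns=rename)
    ties = pd.read_csv(ties_table).rename(columns=rename)
    _check_header(parts, "participants", participants_table)
    _check_header(alters, "alters", alters_table)
    _check_header(ties, "ties", ties_table)

    def key_of(row) -> tuple:
        return (str(row["participant_id"]), str(row["timepoint"]))

    # alters per network, preserving file order
    alters_by_key: dict[tuple, list[AlterRecord]] = {}
    for i, row in alters.iterrows():
        rec = AlterRecord(
            alter_id=str(row["alter_id"]),
            relationship=str(row["relationship"]),
            age=_opt_float(row.get("age")),
            sex=_opt(row.get("sex")),
            race=_opt(row.get("race")),
            contact_freq=_opt(row.get("contact_freq")),
            years_known=_opt_float(row.get("years_known")),
            distance_gt_15mi=_opt_bool(row.get("distance_gt_15mi")),
            drinks=_opt_bool(row.get("drinks")),
            smokes=_opt_bool(row.get("smokes")),
            nonexerciser=_opt_bool(row.get("nonexerciser")),
            bad_diet=_opt_bool(row.get("bad_diet")),
            negative_influence=_opt_bool(row.get("negative_influence")),
        )
        alters_by_key.setdefault(key_of(row), []).append(rec)

    # tie pairs per network; detect contradictory orientations
    tie_state: dict[tuple, dict[frozenset, tuple[bool, int]]] = {}
    problems: list[str] = []
    for i, row in ties.iterrows():
        a, b = str(row["alter_id_1"]), str(row["alter_id_2"])
        rowno = i + 2  # 1-based with header line
        if a == b:
            problems.append(f"ties row {rowno}: self-tie ({a}, {b})")
            continue
        tied = True
        if "tied" in ties.columns:
            tied = bool(_opt_bool(row["tied"]))
        pair = frozenset((a, b))
        seen = tie_state.setdefault(key_of(row), {})
        if pair in seen and seen[pair][0] != tied:
            problems.append(
                f"ties row {rowno}: pair ({a}, {b}) contradicts row {seen[pair][1]}"
            )
        else:
            seen[pair] = (tied, rowno)
    if problems:
        raise CohortValidationError("; ".join(problems))

    cohort = CohortTable()
    soft_issues: list[str] = []
    for i, row in parts.iterrows():
        rowno = i + 2
        key = key_of(row)
        participant = ParticipantRecord(
            participant_id=key[0],
            group=str(row["group"]),
            timepoint=key[1],
            assessment_date=_opt_date(row.get("assessment_date")),
            cohort_id=None if _opt(row.get("cohort_id")) is None else str(row["cohort_id"]),
            age=_opt_float(row.get("age")),
            sex=_opt(row.get("sex")),
            race=_opt(row.get("race")),
            ethnicity=_opt(row.get("ethnicity")),
            disease_duration=_opt_float(row.get("disease_duration")),
            employment=_opt(row.get("employment")),
            education=_opt(row.get("education")),
            occupation=_opt(row.get("occupation")),
            income_bracket=None
            if _opt(row.get("income_bracket")) is None
            else int(row["income_bracket"]),
            married=_opt_bool(row.get("married")),
            lives_alone=_opt_bool(row.get("lives_alone")),
        )
        pros = ProSet(
            pdds=_opt_float(row.get("pdds")),
            msrs_r=_opt_float(row.get("msrs_r")),
            promis_pf=_opt_float(row.get("promis_pf")),
        )
        net_alters = alters_by_key.pop(key, [])
        ids = [a.alter_id for a in net_alters]
        index = {aid: j for j, aid in enumerate(ids)}
        n = len(ids)
        mat = np.zeros((n, n), dtype=bool)
        for pair, (tied, tie_rowno) in tie_state.pop(key, {}).items():
            if not tied:
                continue
            a, b = tuple(pair)
            if a not in index or b not in index:
                raise CohortValidationError(
                    f"ties row {tie_rowno}: unknown alter in pair ({a}, {b}) "
                    f"for participant {key[0]}/{key[1]}"
                )
            mat[index[a], index[b]] = mat[index[b], index[a]] = True
        network = EgoNetwork(
            participant_id=key[0], timepoint=key[1], alters=net_alters, ties=mat
        )
        entry = CohortEntry(participant=participant, network=network, pros=pros)
        issues = participant.validate() + network.validate() + pros.validate(participant.group)
        soft_issues.extend(f"participants row {rowno}: {m}" for m in issues)
        cohort.add(entry)

    orphans = sorted(set(alters_by_key) | set(tie_state))
    if orphans:
        raise CohortValidationError(
            f"alter/tie rows for unknown participants: {orphans[:5]}"
        )
    dup = cohort.validate()
    structural = [m for m in dup if m.startswith("duplicate") or "more than one" in m]
    if structural:
        raise CohortValidationError("; ".join(structural))
    for msg in soft_issues:
        warnings.warn(msg, stacklevel=2)
    return cohort


def write_cohort(cohort: CohortTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the three-file CSV export; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prows, arows, trows = [], [], []
    for e in cohort:
        p, net, pro = e.participant, e.network, e.pros
        prows.append(
            {
                "participant_id": p.participant_id,
                "timepoint": p.timepoint,
                "assessment_date": p.assessment_date.isoformat()
                if p.assessment_date
                else None,
                "group": p.group,
                "cohort_id": p.cohort_id,
                "age": p.age,
                "sex": p.sex,
                "race": p.race,
                "ethnicity": p.ethnicity,
                "disease_duration": p.disease_duration,
                "employment": p.employment,
                "education": p.education,
                "occupation": p.occupation,
                "income_bracket": p.income_bracket,
                "married": None if p.married is None else int(p.married),
                "lives_alone": None if p.lives_alone is None else int(p.lives_alone),
                "pdds": pro.pdds,
                "msrs_r": pro.msrs_r,
                "promis_pf": pro.promis_pf,
            }
        )
        for a in net.alters:
            arows.append(
                {
                    "participant_id": p.participant_id,
                    "timepoint": p.timepoint,
                    "alter_id": a.alter_id,
                    "relationship": a.relationship,
                    "age": a.age,
                    "sex": a.sex,
                    "race": a.race,
                    "contact_freq": a.contact_freq,
                    "years_known": a.years_known,
                    "distance_gt_15mi": None
                    if a.distance_gt_15mi is None
                    else int(a.distance_gt_15mi),
                    "drinks": None if a.drinks is None else int(a.drinks),
                    "smokes": None if a.smokes is None else int(a.smokes),
                    "nonexerciser": None if a.nonexerciser is None else int(a.nonexerciser),
                    "bad_diet": None if a.bad_diet is None else int(a.bad_diet),
                    "negative_influence": None
                    if a.negative_influence is None
                    else int(a.negative_influence),
                }
            )
        ids = net.alter_ids
        for i, j in zip(*np.triu_indices(net.size, 1)):
            if net.ties[i, j]:
                trows.append(
                    {
                        "participant_id": p.participant_id,
                        "timepoint": p.timepoint,
                        "alter_id_1": ids[i],
                        "alter_id_2": ids[j],
                    }
                )
    paths = {
        "participants": out / "participants.csv",
        "alters": out / "alters.csv",
        "ties": out / "ties.csv",
    }
    pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS).to_csv(paths["participants"], index=False)
    pd.DataFrame(arows, columns=ALTER_COLUMNS).to_csv(paths["alters"], index=False)
    pd.DataFrame(trows, columns=TIE_COLUMNS).to_csv(paths["ties"], index=False)
    return paths


def export_graphml(net: EgoNetwork, path: str | Path) -> None:
    """Write one ego network (ego node + alters + ties) as GraphML."""
    G = nx.Graph()
    G.add_node("ego", role="ego")
    for a in net.alters:
        G.add_node(a.alter_id, role="alter", relationship=a.relationship)
        G.add_edge("ego", a.alter_id)
    ids = net.alter_ids
    for i, j in zip(*np.triu_indices(net.size, 1)):
        if net.ties[i, j]:
            G.add_edge(ids[i], ids[j])
    nx.write_graphml(G, path)


# ---------------------------------------------------------------------------
# covariate encoding and screening


def dichotomize_race_ethnicity(
    race: Optional[str], ethnicity: Optional[str]
) -> Optional[str]:
    """Collapse race × ethnicity to {"non-Hispanic White", "other"}.

    Only (White, non-Hispanic) maps to "non-Hispanic White"; every other
    codebook combination — including "not sure" answers — maps to "other".
    If either answer is missing the result is missing (``None``).
    """
    if race is None or ethnicity is None:
        return None
    if race == "white" and ethnicity == "non_hispanic":
        return "non-Hispanic White"
    return "other"


#: Candidate covariates considered for screening, with their numeric
#: encodings.  Monotone ordinal/binary codings keep a single Pearson r per
#: candidate, as the screening rule requires.
CANDIDATE_COVARIATES = (
    "age",
    "sex_woman",
    "race_ethnicity_white_nh",
    "disease_duration",
    "employed",
    "education",
    "occupation_professional",
    "income",
    "married",
    "lives_alone",
)


def encode_covariates(cohort: CohortTable, codebook: Codebook | None = None) -> pd.DataFrame:
    """Numeric covariate encodings, one row per cohort entry.

    Encodings: income bracket -> ordinal 1–9; employment -> binary employed
    for wages/self-employed; education -> ordinal 1–6; occupation -> binary
    professional/managerial (business owner, executive/manager,
    professional); sex -> woman indicator; race × ethnicity -> non-Hispanic
    White indicator; married / lives_alone -> indicators.  PRO scores, group
    and identifiers ride along for downstream model assembly.
    """
    cb = codebook or default_codebook()
    edu_rank = {code: i + 1 for i, code in enumerate(cb.education_codes)}
    prof = {"business_owner", "executive_manager", "professional"}
    rows = []
    for e in cohort:
        p = e.participant
        dich = dichotomize_race_ethnicity(p.race, p.ethnicity)
        rows.append(
            {
                "participant_id": p.participant_id,
                "timepoint": p.timepoint,
                "group": p.group,
                "cohort_id": p.cohort_id,
                "age": p.age,
                "sex_woman": None if p.sex is None else float(p.sex == "woman"),
                "race_ethnicity_white_nh": None
                if dich is None
                else float(dich == "non-Hispanic White"),
                "disease_duration": p.disease_duration,
                "employed": None
                if p.employment is None
                else float(p.employment in cb.employed_codes),
                "education": None if p.education is None else float(edu_rank[p.education]),
                "occupation_professional": None
                if p.occupation is None
                else float(p.occupation in prof),
                "income": None if p.income_bracket is None else float(p.income_bracket),
                "married": None if p.married is None else float(p.married),
                "lives_alone": None if p.lives_alone is None else float(p.lives_alone),
                "elapsed_years": p.elapsed_years,
                "pdds": e.pros.pdds,
                "msrs_r": e.pros.msrs_r,
                "promis_pf": e.pros.promis_pf,
            }
        )
    return pd.DataFrame(rows).astype({"age": float})


OUTCOME_NAMES = ("pdds", "msrs_r", "promis_pf")


def screen_covariates(
    cohort: CohortTable,
    candidates: Sequence[str] = CANDIDATE_COVARIATES,
    outcomes: Sequence[str] = OUTCOME_NAMES,
    presence_threshold: float = 0.70,
    r_threshold: float = 0.10,
    p_threshold: float = 0.05,
    codebook: Codebook | None = None,
) -> pd.DataFrame:
    """Screen candidate covariates against all three PROs in pwMS.

    A candidate is selected iff it is present (non-missing) in more than
    70% of pwMS AND has |Pearson r| >= 0.1 with nominal significance
    (p < .05) for *all* outcomes.  Returns one row per candidate with the
    presence fraction, per-outcome r and p, and the selection flag; constant
    candidates are excluded and flagged.
    """
    df = encode_covariates(cohort.select(group="pwMS"), codebook)
    if df.empty:
        raise ValueError("no pwMS entries to screen on")
    rows = []
    for cand in candidates:
        x = pd.to_numeric(df[cand], errors="coerce")
        presence = float(x.notna().mean())
        row: dict = {"covariate": cand, "presence": presence, "note": ""}
        selected = presence > presence_threshold
        for out in outcomes:
            y = pd.to_numeric(df[out], errors="coerce")
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                row[f"r_{out}"] = np.nan
                row[f"p_{out}"] = np.nan
                row["note"] = "constant or insufficient data"
                selected = False
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            row[f"r_{out}"] = float(r)
            row[f"p_{out}"] = float(p)
            selected = selected and abs(r) >= r_threshold and p < p_threshold
        row["selected"] = bool(selected)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# longitudinal linkage


@dataclass
class LongitudinalPair:
    """One participant's (most proximal prepandemic, pandemic) record pair."""

    participant_id: str
    prepandemic: CohortEntry
    pandemic: CohortEntry
    elapsed_years: float


def link_timepoints(cohort: CohortTable) -> list[LongitudinalPair]:
    """Pair each participant's pandemic record with the closest earlier baseline.

    Participants lacking either timepoint are excluded (count logged).  When
    several prepandemic baselines exist, the most proximal one (latest date
    before the pandemic assessment) is used; elapsed time is days/365.25
    rounded to 2 decimals.  A pandemic record dated before its baseline is
    an ordering error.
    """
    by_pid: dict[str, dict[str, list[CohortEntry]]] = {}
    for e in cohort:
        by_pid.setdefault(e.participant.participant_id, {}).setdefault(
            e.participant.timepoint, []
        ).append(e)
    pairs: list[LongitudinalPair] = []
    excluded = 0
    for pid, tps in by_pid.items():
        pres = tps.get("prepandemic", [])
        pans = tps.get("pandemic", [])
        if not pres or not pans:
            excluded += 1
            continue
        pan = pans[0]
        if len(pres) == 1:
            base = pres[0]
        else:
            dated = [e for e in pres if e.participant.assessment_date is not None]
            if len(dated) != len(pres):
                raise CohortValidationError(
                    f"{pid}: multiple baselines require assessment dates"
                )
            base = max(dated, key=lambda e: e.participant.assessment_date)
        elapsed = np.nan
        d0 = base.participant.assessment_date
        d1 = pan.participant.assessment_date
        if d0 is not None and d1 is not None:
            if d1 < d0:
                raise CohortValidationError(
                    f"{pid}: pandemic record ({d1}) predates baseline ({d0})"
                )
            elapsed = round((d1 - d0).days / 365.25, 2)
        elif base.participant.elapsed_years is not None:
            elapsed = base.participant.elapsed_years
        pan.participant.elapsed_years = None if np.isnan(elapsed) else elapsed
        pairs.append(
            LongitudinalPair(
                participant_id=pid,
                prepandemic=base,
                pandemic=pan,
                elapsed_years=elapsed,
            )
        )
    logger.info(
        "link_timepoints: %d participants paired, %d excluded (missing a timepoint)",
        len(pairs),
        excluded,
    )
    return pairs
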