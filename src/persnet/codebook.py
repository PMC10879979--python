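"""Survey codebook: category labels, kin relationship codes, column mappings.

The PERSNET-style export uses coded categorical answers.  The codebook names
the valid levels for each coded field, declares which relationship codes
count as "kin" (family), and allows column-name remapping for dialects of
the export.  A codebook can be loaded from a YAML/JSON mapping so that site-
specific exports can be ingested without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

# Relationship codes (PERSNET-style).  The survey does not constrain the set;
# these are the codes the generator emits and the default kin definition.
RELATIONSHIP_CODES = (
    "spouse",
    "partner",
    "parent",
    "child",
    "sibling",
    "other_family",
    "friend",
    "coworker",
    "neighbor",
    "professional",
    "other",
)

DEFAULT_KIN_CODES = frozenset(
    {"spouse", "partner", "parent", "child", "sibling", "other_family"}
)

# 7-level race coding used by the survey.
RACE_CODES = (
    "african_american",
    "native",
    "asian",
    "white",
    "multiracial",
    "other",
    "not_sure",
)

ETHNICITY_CODES = ("hispanic", "non_hispanic", "not_sure")

SEX_CODES = ("woman", "man", "other_unknown")

CONTACT_FREQ_CODES = ("daily", "weekly", "monthly", "less", "unknown")

EMPLOYMENT_CODES = (
    "employed_wages",
    "self_employed",
    "out_of_work_looking",
    "out_of_work_not_looking",
    "homemaker",
    "student",
    "military",
    "retired",
    "unable_to_work",
)

# Employment codes that count as "employed" under the binary encoding used
# for covariate screening and regression adjustment.
EMPLOYED_CODES = frozenset({"employed_wages", "self_employed"})

EDUCATION_CODES = (
    "some_high_school",
    "high_school_graduate",
    "some_college",
    "associate_degree",
    "bachelors_degree",
    "graduate_degree",
)

OCCUPATION_CODES = (
    "business_owner",
    "executive_manager",
    "professional",
    "sales_clerical",
    "service_worker",
    "laborer",
    "machine_operator",
    "mechanic_skilled",
    "other",
)

TIMEPOINTS = ("prepandemic", "pandemic")

GROUPS = ("pwMS", "control")


@dataclass(frozen=True)
class Codebook:
    """Category levels and semantic code sets for a survey export dialect."""

    kin_codes: frozenset[str] = DEFAULT_KIN_CODES
    relationship_codes: tuple[str, ...] = RELATIONSHIP_CODES
    race_codes: tuple[str, ...] = RACE_CODES
    ethnicity_codes: tuple[str, ...] = ETHNICITY_CODES
    sex_codes: tuple[str, ...] = SEX_CODES
    contact_freq_codes: tuple[str, ...] = CONTACT_FREQ_CODES
    employment_codes: tuple[str, ...] = EMPLOYMENT_CODES
    employed_codes: frozenset[str] = EMPLOYED_CODES
    education_codes: tuple[str, ...] = EDUCATION_CODES
    occupation_codes: tuple[str, ...] = OCCUPATION_CODES
    # Column remapping: {canonical_name: name_in_file}.
    column_map: dict[str, str] = field(default_factory=dict)

    @property
    def n_race_levels(self) -> int:
        """Number of race levels used to normalize the race diversity index.

        ``not_sure`` is a non-response, not a race category, so it does not
        count toward the number of possible categories.
        """
        return len([c for c in self.race_codes if c != "not_sure"])

    def is_kin(self, relationship: str) -> bool:
        return relationship in self.kin_codes

    def resolve_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


def default_codebook() -> Codebook:
    return Codebook()


def load_codebook(path: str | Path) -> Codebook:
    """Load a codebook from a YAML (or JSON — YAML superset) mapping.

    Only keys present in the file override the defaults; list-valued keys
    replace the default tuples, ``kin_codes``/``employed_codes`` become sets.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"codebook file {path} must contain a mapping")
    kwargs: dict = {}
    for key in (
        "relationship_codes",
        "race_codes",
        "ethnicity_codes",
        "sex_codes",
        "contact_freq_codes",
        "employment_codes",
        "education_codes",
        "occupation_codes",
    ):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("kin_codes", "employed_codes"):
        if key in raw:
            kwargs[key] = frozenset(raw[key])
    if "column_map" in raw:
        kwargs["column_map"] = dict(raw["column_map"])
    unknown = set(raw) - set(kwargs)
    if unknown:
        raise ValueError(f"unknown codebook keys: {sorted(unknown)}")
    return replace(Codebook(), **kwargs)
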