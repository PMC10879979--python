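"""Structural and compositional metrics of egocentric networks.

Six structural features are computed from the alter–alter tie matrix:

* **size** — number of alters (the ego is never counted);
* **density** — alter–alter ties over possible ties, ego's ties excluded;
* **constraint** — Burt's aggregate constraint of the ego, on a 0–100 scale:
  with proportional tie weights :math:`p_{ij} = z_{ij} / \\sum_q z_{iq}`
  over each node's ties (the ego is tied to every alter by construction),

  .. math:: C = \\sum_j \\Bigl(p_{ij} + \\sum_{q \\ne i,j} p_{iq} p_{qj}\\Bigr)^2

  High constraint means the ego's contacts are concentrated in a tightly
  interconnected (redundant) group;
* **effective size** — Burt's number of non-redundant alters, which for a
  binary symmetric network equals :math:`n - 2t/n` with ``t`` the number of
  alter–alter ties;
* **max degree / mean degree** — of alters within the alter–alter graph.

Twelve compositional features summarize who the alters are: percentage of
kin, SD of alter ages, normalized Blau diversity of sex and race, and the
percentages with given contact frequency, relationship duration, distance,
health behaviors, and perceived negative health influence.  Percentages use
non-missing denominators.  Undefined values (degenerate networks, fully
missing attributes) are returned as ``nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from persnet.codebook import Codebook, default_codebook
from persnet.records import CohortTable, EgoNetwork

#: Feature columns in report order (6 structural + 12 compositional).
FEATURE_NAMES = (
    "size",
    "density",
    "constraint",
    "effective_size",
    "max_degree",
    "mean_degree",
    "pct_kin",
    "sd_age",
    "diversity_sex",
    "diversity_race",
    "pct_contact_weekly_or_less",
    "pct_known_lt6y",
    "pct_live_gt15mi",
    "pct_drink",
    "pct_smoke",
    "pct_nonexerciser",
    "pct_bad_diet",
    "pct_negative_influence",
)

#: Features reported as 0–100 in tables but entered as 0–1 proportions in
#: regression models (so a coefficient is "per 0→1 change").
PERCENT_FEATURES = tuple(f for f in FEATURE_NAMES if f.startswith("pct_")) + (
    "diversity_sex",
    "diversity_race",
)


@dataclass
class NetworkFeatures:
    """The 18 features of one ego network (``nan`` where undefined)."""

    size: float
    density: float
    constraint: float
    effective_size: float
    max_degree: float
    mean_degree: float
    pct_kin: float
    sd_age: float
    diversity_sex: float
    diversity_race: float
    pct_contact_weekly_or_less: float
    pct_known_lt6y: float
    pct_live_gt15mi: float
    pct_drink: float
    pct_smoke: float
    pct_nonexerciser: float
    pct_bad_diet: float
    pct_negative_influence: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# ---------------------------------------------------------------------------
# structural metrics


def density(net: EgoNetwork) -> float:
    """Alter–alter ties divided by possible ties; ``nan`` for size < 2."""
    n = net.size
    if n < 2:
        return math.nan
    return net.tie_count() / (n * (n - 1) / 2)


def _full_adjacency(net: EgoNetwork) -> np.ndarray:
    """Adjacency over ego + alters, ego at index 0, tied to every alter."""
    n = net.size
    z = np.zeros((n + 1, n + 1))
    z[0, 1:] = 1.0
    z[1:, 0] = 1.0
    z[1:, 1:] = net.ties
    return z


def burt_constraint(net: EgoNetwork) -> float:
    """Burt's aggregate constraint of the ego, reported ×100.

    ``nan`` for an empty network.  A dyad (single alter) has constraint 100;
    a star (no alter–alter ties) over ``n`` alters has constraint ``100/n``.
    """
    n = net.size
    if n == 0:
        return math.nan
    z = _full_adjacency(net)
    p = z / z.sum(axis=1, keepdims=True)  # every row has the ego tie, sum > 0
    # indirect investment through shared contacts q (q != ego, q != j)
    indirect = p[0, 1:] @ p[1:, 1:]
    c = float(np.sum((p[0, 1:] + indirect) ** 2))
    return 100.0 * c


def effective_size(net: EgoNetwork) -> float:
    """Burt effective size: ``n - 2t/n`` for binary symmetric ties."""
    n = net.size
    if n == 0:
        return math.nan
    return n - 2.0 * net.tie_count() / n


def degree_stats(net: EgoNetwork) -> tuple[float, float]:
    """(max, mean) alter degree in the alter–alter graph (ego excluded)."""
    n = net.size
    if n == 0:
        return math.nan, math.nan
    deg = net.ties.sum(axis=1)
    return float(deg.max()), float(deg.mean())


# ---------------------------------------------------------------------------
# compositional metrics


def diversity_index(values: Sequence[Optional[str]], n_categories_possible: int) -> float:
    """Normalized Blau heterogeneity on a 0–100 scale.

    ``(1 - sum p_k^2) / (1 - 1/K)`` over the non-missing category
    proportions, ``K = n_categories_possible`` (2 for sex, the number of
    codebook race levels for race).  0 means a single category; 100 means a
    balanced mix.  Capped at 100 (more observed categories than ``K`` would
    otherwise exceed the normalizer); ``nan`` if all values are missing.
    """
    if n_categories_possible < 2:
        raise ValueError("need at least 2 possible categories")
    present = [v for v in values if v is not None]
    if not present:
        return math.nan
    _, counts = np.unique(present, return_counts=True)
    p = counts / counts.sum()
    blau = 1.0 - float(np.sum(p**2))
    score = 100.0 * blau / (1.0 - 1.0 / n_categories_possible)
    return min(score, 100.0)


def _pct(flags: Iterable[Optional[bool]]) -> float:
    known = [f for f in flags if f is not None]
    if not known:
        return math.nan
    return 100.0 * sum(known) / len(known)


def compositional_percentages(
    net: EgoNetwork, kin_codes: frozenset[str] | set[str]
) -> dict[str, float]:
    """The 9 percentage fields plus SD of alter age.

    Each percentage counts alters with the attribute over alters with a
    *non-missing* value for it ("unknown" contact frequency is treated as
    missing).  ``pct_contact_weekly_or_less`` counts contact at weekly
    frequency or rarer; ``pct_known_lt6y`` counts relationships younger than
    6 years.  ``sd_age`` is the sample SD of non-missing alter ages (``nan``
    with fewer than 2 ages).
    """
    alters = net.alters
    ages = [a.age for a in alters if a.age is not None]
    sd_age = float(np.std(ages, ddof=1)) if len(ages) >= 2 else math.nan
    return {
        "pct_kin": _pct([a.relationship in kin_codes for a in alters]),
        "sd_age": sd_age,
        "pct_contact_weekly_or_less": _pct(
            [
                None
                if a.contact_freq in (None, "unknown")
                else a.contact_freq in ("weekly", "monthly", "less")
                for a in alters
            ]
        ),
        "pct_known_lt6y": _pct(
            [None if a.years_known is None else a.years_known < 6 for a in alters]
        ),
        "pct_live_gt15mi": _pct([a.distance_gt_15mi for a in alters]),
        "pct_drink": _pct([a.drinks for a in alters]),
        "pct_smoke": _pct([a.smokes for a in alters]),
        "pct_nonexerciser": _pct([a.nonexerciser for a in alters]),
        "pct_bad_diet": _pct([a.bad_diet for a in alters]),
        "pct_negative_influence": _pct([a.negative_influence for a in alters]),
    }


def compute_all_features(
    net: EgoNetwork, codebook: Codebook | None = None
) -> NetworkFeatures:
    """All 18 features for one network; deterministic, order-invariant."""
    cb = codebook or default_codebook()
    max_deg, mean_deg = degree_stats(net)
    comp = compositional_percentages(net, cb.kin_codes)
    return NetworkFeatures(
        size=float(net.size),
        density=density(net),
        constraint=burt_constraint(net),
        effective_size=effective_size(net),
        max_degree=max_deg,
        mean_degree=mean_deg,
        diversity_sex=diversity_index([a.sex for a in net.alters], 2)
        if any(a.sex is not None for a in net.alters)
        else math.nan,
        diversity_race=diversity_index(
            [a.race if a.race != "not_sure" else None for a in net.alters],
            cb.n_race_levels,
        )
        if any(a.race not in (None, "not_sure") for a in net.alters)
        else math.nan,
        **comp,
    )


# ---------------------------------------------------------------------------
# cohort-level table


def features_table(cohort: CohortTable, codebook: Codebook | None = None) -> pd.DataFrame:
    """One row per (participant, timepoint) with the 18 features.

    Index columns ``participant_id``, ``timepoint``, ``group`` are included;
    undefined metrics are NaN (empty cells on CSV export).
    """
    cb = codebook or default_codebook()
    rows = []
    for e in cohort:
        feats = compute_all_features(e.network, cb).as_dict()
        rows.append(
            {
                "participant_id": e.participant.participant_id,
                "timepoint": e.participant.timepoint,
                "group": e.participant.group,
                **feats,
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "timepoint", "group", *FEATURE_NAMES])


def to_regression_scale(features: pd.DataFrame) -> pd.DataFrame:
    """Convert report-scale features (0–100 percents) to model scale (0–1).

    Descriptive tables use 0–100 percentages; regressions consume 0–1
    proportions so that a coefficient measures the effect of moving from a
    network with none to a network with all members having the attribute.
    Constraint stays on its 0–100 scale; counts and SDs are unchanged.
    """
    out = features.copy()
    for col in PERCENT_FEATURES:
        if col in out.columns:
            out[col] = out[col] / 100.0
    return out
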