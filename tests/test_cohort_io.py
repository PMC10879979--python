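"""Survey-export parsing, covariate encoding/screening, timepoint linkage."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from persnet.cohort_io import (
    CANDIDATE_COVARIATES,
    CohortFormatError,
    CohortValidationError,
    dichotomize_race_ethnicity,
    encode_covariates,
    link_timepoints,
    read_cohort,
    screen_covariates,
    write_cohort,
)
from persnet.codebook import ETHNICITY_CODES, RACE_CODES, default_codebook
from persnet.records import (
    AlterRecord,
    CohortEntry,
    CohortTable,
    EgoNetwork,
    ParticipantRecord,
    ProSet,
)
from persnet.synthetic import GeneratorConfig, simulate_cohort


def write_fixture(tmp_path, participants, alters, ties):
    paths = {}
    for name, rows in (("participants", participants), ("alters", alters), ("ties", ties)):
        p = tmp_path / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[name] = p
    return paths


PARTICIPANT = {
    "participant_id": "p1",
    "timepoint": "pandemic",
    "assessment_date": "2020-06-01",
    "group": "pwMS",
    "cohort_id": "1",
    "age": 50,
    "sex": "woman",
    "race": "white",
    "ethnicity": "non_hispanic",
    "disease_duration": 12.5,
    "employment": "employed_wages",
    "education": "graduate_degree",
    "occupation": "professional",
    "income_bracket": 7,
    "married": 1,
    "lives_alone": 0,
    "pdds": 2,
    "msrs_r": 8,
    "promis_pf": 45.1,
}
ALTERS = [
    {"participant_id": "p1", "timepoint": "pandemic", "alter_id": a, "relationship": r}
    for a, r in (("a1", "spouse"), ("a2", "friend"), ("a3", "parent"))
]
TIES = [
    {"participant_id": "p1", "timepoint": "pandemic", "alter_id_1": "a1", "alter_id_2": "a2"},
    {"participant_id": "p1", "timepoint": "pandemic", "alter_id_1": "a2", "alter_id_2": "a3"},
]


class TestReadCohort:
    def test_hand_written_fixture_round_trips(self, tmp_path):
        paths = write_fixture(tmp_path, [PARTICIPANT], ALTERS, TIES)
        cohort = read_cohort(paths["participants"], paths["alters"], paths["ties"])
        assert len(cohort) == 1
        net = cohort.entries[0].network
        assert net.size == 3
        assert net.tie_count() == 2
        assert net.ties[0, 1] and net.ties[1, 2] and not net.ties[0, 2]
        assert cohort.entries[0].participant.assessment_date == dt.date(2020, 6, 1)

    def test_contradictory_tie_orientations_rejected(self, tmp_path):
        ties = [
            dict(TIES[0], tied=1),
            {**TIES[0], "alter_id_1": "a2", "alter_id_2": "a1", "tied": 0},
        ]
        paths = write_fixture(tmp_path, [PARTICIPANT], ALTERS, ties)
        with pytest.raises(CohortValidationError, match=r"contradicts"):
            read_cohort(paths["participants"], paths["alters"], paths["ties"])

    def test_missing_income_retained_as_missing(self, tmp_path):
        row = dict(PARTICIPANT)
        row["income_bracket"] = None
        paths = write_fixture(tmp_path, [row], ALTERS, TIES)
        cohort = read_cohort(paths["participants"], paths["alters"], paths["ties"])
        assert cohort.entries[0].participant.income_bracket is None
        assert cohort.entries[0].participant.age == 50

    def test_malformed_header_raises_format_error(self, tmp_path):
        bad = {k: v for k, v in PARTICIPANT.items() if k != "group"}
        paths = write_fixture(tmp_path, [bad], ALTERS, TIES)
        with pytest.raises(CohortFormatError, match="group"):
            read_cohort(paths["participants"], paths["alters"], paths["ties"])

    def test_tie_naming_unknown_alter_rejected(self, tmp_path):
        ties = TIES + [
            {"participant_id": "p1", "timepoint": "pandemic",
             "alter_id_1": "a1", "alter_id_2": "zz"}
        ]
        paths = write_fixture(tmp_path, [PARTICIPANT], ALTERS, ties)
        with pytest.raises(CohortValidationError, match="unknown alter"):
            read_cohort(paths["participants"], paths["alters"], paths["ties"])

    def test_out_of_range_pro_warns_but_keeps_row(self, tmp_path):
        row = dict(PARTICIPANT, msrs_r=40)
        paths = write_fixture(tmp_path, [row], ALTERS, TIES)
        with pytest.warns(UserWarning, match="msrs_r"):
            cohort = read_cohort(paths["participants"], paths["alters"], paths["ties"])
        assert len(cohort) == 1

    def test_simulated_cohort_round_trip(self, tmp_path):
        sim = simulate_cohort(
            GeneratorConfig.cross_sectional(n_pwms=6, n_controls=4), seed=42
        )
        write_cohort(sim.cohort, tmp_path)
        back = read_cohort(
            tmp_path / "participants.csv", tmp_path / "alters.csv", tmp_path / "ties.csv"
        )
        assert len(back) == len(sim.cohort)
        for orig, rt in zip(sim.cohort, back):
            assert orig.participant == rt.participant
            assert orig.pros.promis_pf == pytest.approx(rt.pros.promis_pf)
            assert orig.network.alter_ids == rt.network.alter_ids
            assert np.array_equal(orig.network.ties, rt.network.ties)
            assert orig.network.alters == rt.network.alters


class TestDichotomize:
    @pytest.mark.parametrize(
        "race,eth,expected",
        [
            ("white", "non_hispanic", "non-Hispanic White"),
            ("white", "hispanic", "other"),
            ("asian", "non_hispanic", "other"),
            ("not_sure", "not_sure", "other"),
        ],
    )
    def test_examples(self, race, eth, expected):
        assert dichotomize_race_ethnicity(race, eth) == expected

    def test_partitions_full_codebook(self):
        values = {
            dichotomize_race_ethnicity(r, e)
            for r in RACE_CODES
            for e in ETHNICITY_CODES
        }
        assert values == {"non-Hispanic White", "other"}
        n_white = sum(
            dichotomize_race_ethnicity(r, e) == "non-Hispanic White"
            for r in RACE_CODES
            for e in ETHNICITY_CODES
        )
        assert n_white == 1  # exactly (white, non_hispanic)

    def test_missing_propagates(self):
        assert dichotomize_race_ethnicity(None, "non_hispanic") is None


def _pwms_entry(pid, age, income=5, duration=10.0, pros=None, employment="employed_wages"):
    participant = ParticipantRecord(
        participant_id=pid,
        group="pwMS",
        timepoint="pandemic",
        age=age,
        sex="woman",
        race="white",
        ethnicity="non_hispanic",
        disease_duration=duration,
        employment=employment,
        education="bachelors_degree",
        occupation="professional",
        income_bracket=income,
        married=True,
        lives_alone=False,
    )
    net = EgoNetwork(pid, "pandemic", [AlterRecord("a1", "friend")], np.zeros((1, 1), bool))
    return CohortEntry(participant, net, pros or ProSet())


def screening_cohort(n=150, income_missing_frac=0.0, seed=0):
    """Age drives all three PROs; disease duration drives only MSRS-R."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        age = float(rng.normal(50, 12))
        duration = float(rng.gamma(4, 4))
        pros = ProSet(
            pdds=0.08 * age + rng.normal(0, 1.5),
            msrs_r=0.15 * age + 0.8 * duration + rng.normal(0, 3),
            promis_pf=-0.3 * age + rng.normal(0, 6),
        )
        income = None if rng.random() < income_missing_frac else int(rng.integers(1, 10))
        # make income correlate strongly with every PRO when present
        if income is not None:
            income = int(np.clip(round(pros.msrs_r / 4 + pros.pdds), 1, 9))
        entries.append(_pwms_entry(f"p{i}", age, income=income, duration=duration, pros=pros))
    return CohortTable(entries)


class TestScreening:
    def test_age_selected_and_matches_direct_correlations(self):
        cohort = screening_cohort()
        report = screen_covariates(cohort).set_index("covariate")
        assert bool(report.loc["age", "selected"])
        # oracle: direct Pearson on the encoded table
        df = encode_covariates(cohort)
        for outcome in ("pdds", "msrs_r", "promis_pf"):
            r, p = stats.pearsonr(df["age"], df[outcome])
            assert report.loc["age", f"r_{outcome}"] == pytest.approx(r)
            assert report.loc["age", f"p_{outcome}"] == pytest.approx(p)

    def test_low_presence_excludes_despite_strong_correlation(self):
        cohort = screening_cohort(income_missing_frac=0.4)
        report = screen_covariates(cohort).set_index("covariate")
        assert report.loc["income", "presence"] < 0.70
        assert not bool(report.loc["income", "selected"])
        # correlation itself is strong on the observed subset
        assert abs(report.loc["income", "r_msrs_r"]) > 0.3

    def test_single_outcome_association_is_not_enough(self):
        cohort = screening_cohort()
        report = screen_covariates(cohort).set_index("covariate")
        # disease duration drives MSRS-R only
        assert report.loc["disease_duration", "p_msrs_r"] < 0.05
        assert not bool(report.loc["disease_duration", "selected"])

    def test_constant_covariate_flagged_and_excluded(self):
        cohort = screening_cohort()
        for e in cohort:
            e.participant.married = True
        report = screen_covariates(cohort).set_index("covariate")
        assert not bool(report.loc["married", "selected"])
        assert report.loc["married", "note"] == "constant or insufficient data"

    def test_invariant_to_row_order_and_affine_rescaling(self):
        cohort = screening_cohort()
        base = screen_covariates(cohort).set_index("covariate")
        shuffled = CohortTable(list(reversed(cohort.entries)))
        reordered = screen_covariates(shuffled).set_index("covariate")
        pd.testing.assert_frame_equal(
            base.sort_index(), reordered.sort_index(), check_like=True
        )
        for e in cohort:
            e.participant.age = 3.0 * e.participant.age + 7.0
        rescaled = screen_covariates(cohort).set_index("covariate")
        for outcome in ("pdds", "msrs_r", "promis_pf"):
            assert abs(rescaled.loc["age", f"r_{outcome}"]) == pytest.approx(
                abs(base.loc["age", f"r_{outcome}"])
            )
            assert rescaled.loc["age", f"p_{outcome}"] == pytest.approx(
                base.loc["age", f"p_{outcome}"]
            )

    def test_report_covers_all_candidates(self):
        report = screen_covariates(screening_cohort())
        assert set(report["covariate"]) == set(CANDIDATE_COVARIATES)


def _entry_at(pid, timepoint, date, group="pwMS"):
    participant = ParticipantRecord(
        participant_id=pid, group=group, timepoint=timepoint,
        assessment_date=date, age=50.0,
    )
    net = EgoNetwork(pid, timepoint, [AlterRecord("a1", "friend")], np.zeros((1, 1), bool))
    return CohortEntry(participant, net, ProSet())


class TestLinkTimepoints:
    def test_most_proximal_baseline_chosen(self):
        cohort = CohortTable([
            _entry_at("p1", "prepandemic", dt.date(2017, 5, 1)),
            _entry_at("p1", "prepandemic", dt.date(2019, 5, 1)),
            _entry_at("p1", "pandemic", dt.date(2020, 8, 1)),
        ])
        pairs = link_timepoints(cohort)
        assert len(pairs) == 1
        assert pairs[0].prepandemic.participant.assessment_date == dt.date(2019, 5, 1)
        assert pairs[0].elapsed_years == pytest.approx(
            round((dt.date(2020, 8, 1) - dt.date(2019, 5, 1)).days / 365.25, 2)
        )

    def test_participants_missing_a_timepoint_excluded(self):
        cohort = CohortTable(
            [
                _entry_at("p1", "prepandemic", dt.date(2019, 1, 1)),
                _entry_at("p1", "pandemic", dt.date(2020, 6, 1)),
                _entry_at("p2", "pandemic", dt.date(2020, 6, 1)),
                _entry_at("p3", "prepandemic", dt.date(2018, 6, 1)),
                _entry_at("p4", "prepandemic", dt.date(2018, 6, 1)),
                _entry_at("p4", "pandemic", dt.date(2020, 4, 1)),
                _entry_at("p5", "prepandemic", dt.date(2017, 2, 1)),
                _entry_at("p5", "pandemic", dt.date(2020, 5, 1)),
            ]
        )
        pairs = link_timepoints(cohort)
        assert sorted(p.participant_id for p in pairs) == ["p1", "p4", "p5"]

    def test_pandemic_record_predating_baseline_is_an_error(self):
        cohort = CohortTable([
            _entry_at("p1", "prepandemic", dt.date(2021, 1, 1)),
            _entry_at("p1", "pandemic", dt.date(2020, 6, 1)),
        ])
        with pytest.raises(CohortValidationError, match="predates"):
            link_timepoints(cohort)

    def test_elapsed_years_lands_on_pandemic_record(self):
        cohort = CohortTable([
            _entry_at("p1", "prepandemic", dt.date(2018, 6, 1)),
            _entry_at("p1", "pandemic", dt.date(2020, 6, 1)),
        ])
        pairs = link_timepoints(cohort)
        assert pairs[0].pandemic.participant.elapsed_years == pytest.approx(2.0)


class TestInterop:
    def test_graphml_export_round_trips_structure(self, tmp_path):
        import networkx as nx

        from persnet.cohort_io import export_graphml
        from tests.conftest import make_network

        net = make_network(3, [(0, 1)], relationships=["spouse", "friend", "friend"])
        path = tmp_path / "ego.graphml"
        export_graphml(net, path)
        G = nx.read_graphml(path)
        assert set(G.nodes) == {"ego", "a1", "a2", "a3"}
        assert G.number_of_edges() == 3 + 1  # ego ties + one alter-alter tie
        assert G.nodes["a1"]["relationship"] == "spouse"

    def test_yaml_codebook_overrides_kin_codes_and_columns(self, tmp_path):
        from persnet.codebook import load_codebook

        cfg = tmp_path / "codebook.yaml"
        cfg.write_text(
            "kin_codes: [spouse, parent]\n"
            "column_map: {participant_id: subject_id}\n"
        )
        cb = load_codebook(cfg)
        assert cb.kin_codes == frozenset({"spouse", "parent"})
        assert not cb.is_kin("sibling")
        assert cb.resolve_column("participant_id") == "subject_id"
        with pytest.raises(ValueError, match="unknown codebook keys"):
            bad = tmp_path / "bad.yaml"
            bad.write_text("nonsense: 1\n")
            load_codebook(bad)
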