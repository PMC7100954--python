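"""Study records: parsing, validation, encoding, observation cases, occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msmpub.records import (
    COVARIATE_NAMES,
    Collaboration,
    Funding,
    ObservationCase,
    PathType,
    SchemaError,
    Status,
    ValidationError,
    count_state_occupancy,
    derive_observation_case,
    encode_covariates,
    impute_sample_size,
    load_studies,
    write_studies,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# Record validation

def test_event_year_before_approval_rejected():
    with pytest.raises(ValidationError, match="precedes approval"):
        make_record(completion_year=1999)


def test_event_year_after_followup_rejected():
    with pytest.raises(ValidationError, match="after end of follow-up"):
        make_record(publication_year=2012)


def test_publication_cannot_precede_intermediate_event():
    with pytest.raises(ValidationError, match="precedes"):
        make_record(completion_year=2006, publication_year=2004)


@pytest.mark.parametrize("status", list(Status))
@pytest.mark.parametrize("field", ["completion_year", "discontinuation_year"])
def test_intermediate_year_requires_matching_status(status, field):
    """Exhaustive status x year-field compatibility (at most one intermediate)."""
    kwargs = {
        "status": status,
        "completion_year": None,
        "discontinuation_year": None,
        "publication_year": None,
        field: 2003,
    }
    compatible = (status is Status.COMPLETED and field == "completion_year") or (
        status is Status.DISCONTINUED and field == "discontinuation_year"
    )
    if compatible:
        make_record(**kwargs)
    else:
        with pytest.raises(ValidationError):
            make_record(**kwargs)


def test_both_intermediate_years_rejected():
    with pytest.raises(ValidationError, match="both"):
        make_record(completion_year=2003, discontinuation_year=2004)


# ---------------------------------------------------------------------------
# CSV round trip

def _write_csv(path, rows, header):
    lines = [",".join(header)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


_HEADER = [
    "study_id", "approval_year", "followup_end_year", "status",
    "completion_year", "discontinuation_year", "publication_year",
    "rct", "sample_size", "funding", "industry_involved",
    "collaboration", "primary_outcome",
]


def test_load_studies_well_formed(tmp_path):
    f = tmp_path / "studies.csv"
    _write_csv(
        f,
        [
            ["A", 2000, 2011, "completed", 2003, "", 2005, 1, 120, "commercial", 0, "single_centre", 1],
            ["B", 2001, 2010, "discontinued", "", 2004, "", 0, "", "noncommercial", 0, "multi_national", 0],
            ["C", 2002, 2010, "unclear", "", "", "", 1, 40, "not_reported", 1, "multi_international", 1],
        ],
        _HEADER,
    )
    records = load_studies(f)
    assert len(records) == 3
    assert records[0].completion_year == 2003
    assert records[1].sample_size is None
    assert records[2].collaboration is Collaboration.MULTI_INTERNATIONAL


def test_load_studies_invalid_row_diagnostics(tmp_path):
    f = tmp_path / "bad.csv"
    _write_csv(
        f,
        [["A", 2000, 2011, "completed", 1999, "", "", 1, 10, "commercial", 0, "single_centre", 1]],
        _HEADER,
    )
    with pytest.raises(ValidationError, match="study_id=A"):
        load_studies(f)


def test_load_studies_missing_column(tmp_path):
    f = tmp_path / "missing.csv"
    _write_csv(f, [["A", 2000]], ["study_id", "approval_year"])
    with pytest.raises(SchemaError, match="missing required column"):
        load_studies(f)


def test_load_studies_schema_mapping(tmp_path):
    f = tmp_path / "mapped.csv"
    header = list(_HEADER)
    header[header.index("status")] = "study_status"
    _write_csv(
        f,
        [["A", 2000, 2011, "completed", 2003, "", "", 1, 10, "commercial", 0, "single_centre", 1]],
        header,
    )
    records = load_studies(f, schema_config={"columns": {"status": "study_status"}})
    assert records[0].status is Status.COMPLETED


def test_round_trip_preserves_records(tmp_path, fixture_cohort):
    records = fixture_cohort[0]
    out = tmp_path / "cohort.csv"
    write_studies(records, out)
    reloaded = load_studies(out)
    assert reloaded == records
    # a second write reproduces the file byte-for-byte
    out2 = tmp_path / "cohort2.csv"
    write_studies(reloaded, out2)
    assert out.read_bytes() == out2.read_bytes()


# ---------------------------------------------------------------------------
# Sample-size imputation and covariate encoding

def test_impute_median_of_observed():
    recs = [
        make_record(study_id="A", sample_size=3),
        make_record(study_id="B", sample_size=120),
        make_record(study_id="C", sample_size=3900),
        make_record(study_id="D", sample_size=None),
    ]
    out, value, n_imputed = impute_sample_size(recs)
    assert value == 120 and n_imputed == 1
    assert out[3].sample_size == 120


def test_impute_even_count_median():
    recs = [make_record(study_id=s, sample_size=n) for s, n in
            zip("ABCD", [10, 20, 30, 40])] + [
        make_record(study_id="E", sample_size=None),
        make_record(study_id="F", sample_size=None),
    ]
    out, value, n_imputed = impute_sample_size(recs)
    assert value == 25 and n_imputed == 2
    assert out[4].sample_size == 25 and out[5].sample_size == 25


def test_impute_noop_and_all_missing():
    recs = [make_record(study_id="A", sample_size=50)]
    out, _, n = impute_sample_size(recs)
    assert n == 0 and out == recs
    with pytest.raises(ValidationError):
        impute_sample_size([make_record(sample_size=None)])


def test_encode_reference_levels_map_to_zeros():
    cv = encode_covariates(make_record(rct=False, primary_outcome=False))
    assert cv.log_sample_size == pytest.approx(math.log(120))
    assert (
        cv.rct, cv.funding_commercial, cv.funding_not_reported, cv.industry,
        cv.primary_outcome, cv.collab_multi_national, cv.collab_multi_international,
    ) == (0, 0, 0, 0, 0, 0, 0)


@pytest.mark.parametrize(
    "funding,expected",
    [
        (Funding.COMMERCIAL, (1, 0)),
        (Funding.NONCOMMERCIAL, (0, 0)),
        (Funding.NOT_REPORTED, (0, 1)),
    ],
)
def test_encode_funding_dummies(funding, expected):
    cv = encode_covariates(make_record(funding=funding))
    assert (cv.funding_commercial, cv.funding_not_reported) == expected


@pytest.mark.parametrize(
    "collab,expected",
    [
        (Collaboration.SINGLE_CENTRE, (0, 0)),
        (Collaboration.MULTI_NATIONAL, (1, 0)),
        (Collaboration.MULTI_INTERNATIONAL, (0, 1)),
    ],
)
def test_encode_collaboration_dummies(collab, expected):
    cv = encode_covariates(make_record(collaboration=collab))
    assert (cv.collab_multi_national, cv.collab_multi_international) == expected


def test_encode_requires_sample_size():
    with pytest.raises(ValidationError, match="missing"):
        encode_covariates(make_record(sample_size=None))


# ---------------------------------------------------------------------------
# Observation cases

def test_known_years_map_to_unit_intervals():
    case = derive_observation_case(make_record())
    assert case.path is PathType.COMPLETED_PUBLISHED
    assert (case.intermediate_lower, case.intermediate_upper) == (3.0, 4.0)
    assert (case.absorbing_lower, case.absorbing_upper) == (5.0, 6.0)


def test_unknown_completion_bounded_by_publication():
    rec = make_record(
        approval_year=2001, followup_end_year=2010, completion_year=None,
        publication_year=2006,
    )
    case = derive_observation_case(rec)
    assert (case.intermediate_lower, case.intermediate_upper) == (0.0, 6.0)
    assert (case.absorbing_lower, case.absorbing_upper) == (5.0, 6.0)


def test_unclear_status_default_and_censor_variant():
    rec = make_record(
        status=Status.UNCLEAR, completion_year=None, publication_year=None
    )
    case = derive_observation_case(rec)
    assert case.path is PathType.UNPUBLISHED_UNKNOWN
    assert case.absorbing_upper == 11.0
    legacy = derive_observation_case(rec, unclear="censor_approved")
    assert legacy.path is PathType.CENSORED_IN_APPROVED
    assert legacy.absorbing_upper == 11.0


def test_ongoing_censored_in_approved():
    rec = make_record(status=Status.ONGOING, completion_year=None, publication_year=None)
    case = derive_observation_case(rec)
    assert case.path is PathType.CENSORED_IN_APPROVED


def test_published_ongoing_is_invalid():
    rec = make_record(status=Status.ONGOING, completion_year=None, publication_year=2005)
    with pytest.raises(ValidationError, match="published"):
        derive_observation_case(rec)


record_strategy = st.builds(
    lambda ay, fu_len, status, ev_off, pub_off, ev_known, published, rct, size, funding, collab, po: _valid_record(
        ay, fu_len, status, ev_off, pub_off, ev_known, published, rct, size, funding, collab, po
    ),
    ay=st.integers(2000, 2002),
    fu_len=st.integers(1, 12),
    status=st.sampled_from(list(Status)),
    ev_off=st.integers(0, 12),
    pub_off=st.integers(0, 12),
    ev_known=st.booleans(),
    published=st.booleans(),
    rct=st.booleans(),
    size=st.integers(3, 3900),
    funding=st.sampled_from(list(Funding)),
    collab=st.sampled_from(list(Collaboration)),
    po=st.booleans(),
)


def _valid_record(ay, fu_len, status, ev_off, pub_off, ev_known, published, rct, size, funding, collab, po):
    fe = ay + fu_len
    kwargs = dict(
        study_id="H", approval_year=ay, followup_end_year=fe, status=status,
        completion_year=None, discontinuation_year=None, publication_year=None,
        rct=rct, sample_size=size, funding=funding, collaboration=collab,
        primary_outcome=po,
    )
    if status in (Status.COMPLETED, Status.DISCONTINUED):
        ev_year = min(ay + ev_off, fe)
        if published:
            kwargs["publication_year"] = min(max(ay + pub_off, ev_year), fe)
        if ev_known:
            field = (
                "completion_year" if status is Status.COMPLETED else "discontinuation_year"
            )
            kwargs[field] = ev_year if not published else min(ev_year, kwargs["publication_year"])
    return make_record(**kwargs)


@given(record=record_strategy)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_derive_observation_case_total_on_valid_records(record):
    """Every valid record maps to exactly one path with coherent bounds."""
    case = derive_observation_case(record)
    assert isinstance(case.path, PathType)
    if case.path in (PathType.CENSORED_IN_APPROVED, PathType.UNPUBLISHED_UNKNOWN):
        assert case.absorbing_upper >= 0
        return
    a, b = case.intermediate_lower, case.intermediate_upper
    assert 0 <= a < b <= case.absorbing_upper + 1
    if case.path in (PathType.COMPLETED_PUBLISHED, PathType.DISCONTINUED_PUBLISHED):
        assert case.absorbing_upper - case.absorbing_lower == pytest.approx(1.0)
        assert b <= case.absorbing_upper


# ---------------------------------------------------------------------------
# Occupancy

def test_occupancy_reference_percentages():
    """Counts as printed for a 806-study cohort give 63% / 25% / 49%."""
    records = []
    idx = 0

    def add(n, **kwargs):
        nonlocal idx
        for _ in range(n):
            records.append(make_record(study_id=f"R{idx}", **kwargs))
            idx += 1

    add(363, status=Status.COMPLETED, completion_year=2003, publication_year=2005)
    add(576 - 363, status=Status.COMPLETED, completion_year=2003, publication_year=None)
    add(32, status=Status.DISCONTINUED, completion_year=None,
        discontinuation_year=2003, publication_year=2005)
    add(128 - 32, status=Status.DISCONTINUED, completion_year=None,
        discontinuation_year=2003, publication_year=None)
    add(41, status=Status.ONGOING, completion_year=None, publication_year=None)
    add(61, status=Status.UNCLEAR, completion_year=None, publication_year=None)

    occ = count_state_occupancy(records)
    assert occ.n_total == 806
    assert occ.pct_published_given_completed == 63
    assert occ.pct_published_given_discontinued == 25
    assert occ.pct_published_overall == 49
    assert occ.n_published == 395


def test_occupancy_conserves_studies(fixture_cohort):
    records = fixture_cohort[0]
    occ = count_state_occupancy(records)
    assert (
        occ.n_completed + occ.n_discontinued + occ.n_ongoing + occ.n_unclear
        == occ.n_total == len(records)
    )
    assert occ.n_published == occ.n_published_after_completed + occ.n_published_after_discontinued


def test_occupancy_empty():
    occ = count_state_occupancy([])
    assert occ.n_total == 0
    assert occ.pct_published_overall is None
    assert occ.pct_published_given_completed is None
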