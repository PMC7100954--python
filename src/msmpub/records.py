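r"""Study-level event histories and their reduction to censoring patterns.

The analysis unit is a clinical study followed from the calendar year of its
research-ethics-committee (REC) approval.  Each study moves through a
progressive four-state graph

    Approved --> Completed ----> Published
            \--> Discontinued -/

with *Published* absorbing.  Source data carry only calendar years, so an
event recorded in year ``y`` is known to have happened somewhere in the
half-open interval ``[y - approval_year, y - approval_year + 1)`` on the
years-since-approval clock.  For most studies the year of the intermediate
transition (completion or discontinuation) is unknown altogether: the study
is known to have reached the state, but the transition time is only bounded
by the follow-up window (and, for published studies, by the publication
year, since publication cannot precede the end of the study).

This module defines the validated per-study record (:class:`StudyRecord`),
the covariate encoding used by every downstream model
(:class:`CovariateVector`), and the reduction of a record to its likelihood
contribution pattern (:class:`ObservationCase`), together with CSV input /
output and the descriptive state-occupancy summary.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Status",
    "Funding",
    "Collaboration",
    "PathType",
    "StudyRecord",
    "CovariateVector",
    "ObservationCase",
    "OccupancySummary",
    "ValidationError",
    "SchemaError",
    "COVARIATE_NAMES",
    "load_studies",
    "write_studies",
    "impute_sample_size",
    "encode_covariates",
    "derive_observation_case",
    "count_state_occupancy",
]


class ValidationError(ValueError):
    """A study record (or derived quantity) violates a domain invariant."""


class SchemaError(ValueError):
    """The input table does not match the configured schema."""


class Status(str, enum.Enum):
    COMPLETED = "completed"
    DISCONTINUED = "discontinued"
    ONGOING = "ongoing"
    UNCLEAR = "unclear"


class Funding(str, enum.Enum):
    COMMERCIAL = "commercial"
    NONCOMMERCIAL = "noncommercial"
    NOT_REPORTED = "not_reported"


class Collaboration(str, enum.Enum):
    SINGLE_CENTRE = "single_centre"
    MULTI_NATIONAL = "multi_national"
    MULTI_INTERNATIONAL = "multi_international"


class PathType(str, enum.Enum):
    CENSORED_IN_APPROVED = "censored_in_approved"
    COMPLETED_CENSORED = "completed_censored"
    COMPLETED_PUBLISHED = "completed_published"
    DISCONTINUED_CENSORED = "discontinued_censored"
    DISCONTINUED_PUBLISHED = "discontinued_published"
    #: state at end of follow-up unknown; all that is observed is the
    #: absence of a publication by the censoring time
    UNPUBLISHED_UNKNOWN = "unpublished_unknown"


#: Column order of the encoded design row.  Reference categories are
#: non-RCT, non-commercial funding, no industry involvement, no primary
#: outcome and single-centre collaboration.
COVARIATE_NAMES = (
    "log_sample_size",
    "rct",
    "funding_commercial",
    "funding_not_reported",
    "industry",
    "primary_outcome",
    "collab_multi_national",
    "collab_multi_international",
)


@dataclass(frozen=True)
class StudyRecord:
    """One study's yearly event history plus covariates.

    Event years are calendar years.  ``followup_end_year`` is the last year
    covered by the publication search / applicant survey for the study's
    cohort; every non-missing event year must lie in
    ``[approval_year, followup_end_year]``.
    """

    study_id: str
    approval_year: int
    followup_end_year: int
    status: Status
    completion_year: int | None = None
    discontinuation_year: int | None = None
    publication_year: int | None = None
    rct: bool = False
    sample_size: float | None = None
    funding: Funding = Funding.NONCOMMERCIAL
    industry_involved: bool = False
    collaboration: Collaboration = Collaboration.SINGLE_CENTRE
    primary_outcome: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", Status(self.status))
        object.__setattr__(self, "funding", Funding(self.funding))
        object.__setattr__(self, "collaboration", Collaboration(self.collaboration))
        sid = self.study_id
        if self.followup_end_year < self.approval_year:
            raise ValidationError(
                f"{sid}: follow-up end {self.followup_end_year} precedes "
                f"approval {self.approval_year}"
            )
        for name in ("completion_year", "discontinuation_year", "publication_year"):
            y = getattr(self, name)
            if y is None:
                continue
            if y < self.approval_year:
                raise ValidationError(f"{sid}: {name} {y} precedes approval year")
            if y > self.followup_end_year:
                raise ValidationError(f"{sid}: {name} {y} after end of follow-up")
        if self.completion_year is not None and self.discontinuation_year is not None:
            raise ValidationError(f"{sid}: both completion and discontinuation year set")
        if self.completion_year is not None and self.status is not Status.COMPLETED:
            raise ValidationError(f"{sid}: completion_year set but status is {self.status.value}")
        if self.discontinuation_year is not None and self.status is not Status.DISCONTINUED:
            raise ValidationError(
                f"{sid}: discontinuation_year set but status is {self.status.value}"
            )
        ev = self.intermediate_event_year
        if self.publication_year is not None and ev is not None and self.publication_year < ev:
            raise ValidationError(
                f"{sid}: publication year {self.publication_year} precedes "
                f"intermediate event year {ev}"
            )
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValidationError(f"{sid}: sample size must be positive")

    @property
    def intermediate_event_year(self) -> int | None:
        if self.completion_year is not None:
            return self.completion_year
        return self.discontinuation_year

    @property
    def published(self) -> bool:
        return self.publication_year is not None


@dataclass(frozen=True)
class CovariateVector:
    """Encoded design row shared by all regression models.

    Sample size enters as its natural logarithm; all other terms are 0/1
    dummies against the reference categories listed in
    :data:`COVARIATE_NAMES`.
    """

    log_sample_size: float
    rct: int
    funding_commercial: int
    funding_not_reported: int
    industry: int
    primary_outcome: int
    collab_multi_national: int
    collab_multi_international: int

    def __post_init__(self) -> None:
        if self.funding_commercial and self.funding_not_reported:
            raise ValidationError("funding dummies are mutually exclusive")
        if self.collab_multi_national and self.collab_multi_international:
            raise ValidationError("collaboration dummies are mutually exclusive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in COVARIATE_NAMES], dtype=float)


@dataclass(frozen=True)
class ObservationCase:
    """A study reduced to its likelihood contribution pattern.

    Times are years since approval.  ``intermediate_lower/upper`` bound the
    time of the intermediate transition (half-open interval; equal to the
    unit interval ``[y, y+1)`` when the event year is known).  For the
    ``*_published`` paths ``absorbing_lower/upper`` is the publication-year
    interval ``[p, p+1)``; for censored paths both absorbing bounds equal
    the censoring time.

    Two extensions beyond the yearly data support fully-observed
    continuous-time variants used for model checking: ``intermediate_exact``
    (``intermediate_lower == intermediate_upper`` is the exact transition
    time) and ``absorbing_exact`` (exact publication time).

    A study whose intermediate event falls in the final follow-up year has
    ``intermediate_upper == censoring time + 1``: the reporting of the event
    extends knowledge to the end of that calendar year even though at-risk
    observation for the publication transition ends at the censoring time.
    """

    path: PathType
    covariates: CovariateVector
    intermediate_lower: float | None = None
    intermediate_upper: float | None = None
    absorbing_lower: float | None = None
    absorbing_upper: float | None = None
    intermediate_exact: bool = False
    absorbing_exact: bool = False
    study_id: str = ""

    def __post_init__(self) -> None:
        p = self.path
        if p in (PathType.CENSORED_IN_APPROVED, PathType.UNPUBLISHED_UNKNOWN):
            if self.absorbing_upper is None or self.absorbing_upper < 0:
                raise ValidationError(f"{self.study_id}: invalid censoring time")
            return
        a, b = self.intermediate_lower, self.intermediate_upper
        if a is None or b is None or a < 0:
            raise ValidationError(f"{self.study_id}: missing intermediate interval")
        if self.intermediate_exact:
            if a != b:
                raise ValidationError(f"{self.study_id}: exact intermediate needs a == b")
        elif not a < b:
            raise ValidationError(f"{self.study_id}: empty intermediate interval [{a}, {b})")
        al, au = self.absorbing_lower, self.absorbing_upper
        if al is None or au is None:
            raise ValidationError(f"{self.study_id}: missing absorbing bounds")
        if p in (PathType.COMPLETED_PUBLISHED, PathType.DISCONTINUED_PUBLISHED):
            if self.absorbing_exact:
                if al != au:
                    raise ValidationError(f"{self.study_id}: exact publication needs al == au")
            elif not math.isclose(au - al, 1.0):
                raise ValidationError(
                    f"{self.study_id}: publication interval must have width 1"
                )
            if b > au + 1e-12:
                raise ValidationError(
                    f"{self.study_id}: intermediate upper bound {b} exceeds "
                    f"publication bound {au}"
                )
        else:  # *_censored
            if al != au:
                raise ValidationError(f"{self.study_id}: censored path needs al == au")
            if b > au + 1 + 1e-12:
                raise ValidationError(
                    f"{self.study_id}: intermediate interval extends past follow-up"
                )

    @property
    def censoring_time(self) -> float | None:
        if self.path in (
            PathType.CENSORED_IN_APPROVED,
            PathType.UNPUBLISHED_UNKNOWN,
            PathType.COMPLETED_CENSORED,
            PathType.DISCONTINUED_CENSORED,
        ):
            return self.absorbing_upper
        return None

    @property
    def initial_transition(self) -> int | None:
        """Index of the transition out of Approved (0 = A->C, 1 = A->D)."""
        if self.path in (PathType.COMPLETED_CENSORED, PathType.COMPLETED_PUBLISHED):
            return 0
        if self.path in (PathType.DISCONTINUED_CENSORED, PathType.DISCONTINUED_PUBLISHED):
            return 1
        return None


# ---------------------------------------------------------------------------
# CSV input / output

_REQUIRED_COLUMNS = (
    "study_id",
    "approval_year",
    "followup_end_year",
    "status",
    "rct",
    "funding",
    "industry_involved",
    "collaboration",
    "primary_outcome",
)
_OPTIONAL_COLUMNS = (
    "completion_year",
    "discontinuation_year",
    "publication_year",
    "sample_size",
)

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def _parse_bool(value, column: str, sid: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"{sid}: cannot parse boolean {column}={value!r}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def load_studies(
    table_path,
    schema_config: Mapping[str, str] | None = None,
    *,
    on_invalid: str = "raise",
) -> list[StudyRecord]:
    """Read a per-study CSV table into validated :class:`StudyRecord` objects.

    Parameters
    ----------
    table_path : path-like
        Comma-separated, UTF-8, header row required; empty cell = missing.
    schema_config : mapping, optional
        Maps canonical field names (``study_id`` etc.) to the CSV column
        names actually present.  Unmapped fields default to their canonical
        name.
    on_invalid : {"raise", "skip"}
        Whether rows violating record invariants abort the load (with all
        per-row diagnostics collected into one error) or are dropped with a
        warning each.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    colmap = {name: name for name in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS}
    if schema_config:
        mapping = schema_config.get("columns", schema_config)
        for canonical, actual in mapping.items():
            if canonical not in colmap:
                raise SchemaError(f"unknown canonical field {canonical!r} in schema config")
            colmap[canonical] = actual
    df = pd.read_csv(table_path, dtype=object, keep_default_na=True)
    missing = [colmap[c] for c in _REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        def get(field):
            col = colmap[field]
            return row[col] if col in df.columns else None

        sid = str(get("study_id"))
        try:
            def year(field):
                v = get(field)
                return None if _is_missing(v) else int(float(v))

            size = get("sample_size")
            record = StudyRecord(
                study_id=sid,
                approval_year=year("approval_year"),
                followup_end_year=year("followup_end_year"),
                status=Status(str(get("status")).strip().lower()),
                completion_year=year("completion_year"),
                discontinuation_year=year("discontinuation_year"),
                publication_year=year("publication_year"),
                rct=_parse_bool(get("rct"), "rct", sid),
                sample_size=None if _is_missing(size) else float(size),
                funding=Funding(str(get("funding")).strip().lower()),
                industry_involved=_parse_bool(get("industry_involved"), "industry_involved", sid),
                collaboration=Collaboration(str(get("collaboration")).strip().lower()),
                primary_outcome=_parse_bool(get("primary_outcome"), "primary_outcome", sid),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            msg = f"row {idx} (study_id={sid}): {exc}"
            if on_invalid == "raise":
                problems.append(msg)
                continue
            warnings.warn(f"skipping invalid {msg}", stacklevel=2)
            continue
        records.append(record)
    if problems:
        raise ValidationError("invalid rows:\n" + "\n".join(problems))
    return records


def write_studies(records: Iterable[StudyRecord], table_path) -> None:
    """Write validated records back to the standard CSV layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "approval_year": r.approval_year,
                "followup_end_year": r.followup_end_year,
                "status": r.status.value,
                "completion_year": r.completion_year,
                "discontinuation_year": r.discontinuation_year,
                "publication_year": r.publication_year,
                "rct": int(r.rct),
                "sample_size": r.sample_size,
                "funding": r.funding.value,
                "industry_involved": int(r.industry_involved),
                "collaboration": r.collaboration.value,
                "primary_outcome": int(r.primary_outcome),
            }
        )
    df = pd.DataFrame(rows)
    # stable column order
    order = [
        "study_id", "approval_year", "followup_end_year", "status",
        "completion_year", "discontinuation_year", "publication_year",
        "rct", "sample_size", "funding", "industry_involved",
        "collaboration", "primary_outcome",
    ]
    for col in ("completion_year", "discontinuation_year", "publication_year", "sample_size"):
        if col in df.columns:
            df[col] = df[col].astype("Float64")
    df[order].to_csv(table_path, index=False)


# ---------------------------------------------------------------------------
# Covariates

def impute_sample_size(
    records: Sequence[StudyRecord],
) -> tuple[list[StudyRecord], float, int]:
    """Replace missing planned sample sizes by the median of observed ones.

    Returns ``(records, imputed_value, n_imputed)``.
    """
    observed = [r.sample_size for r in records if r.sample_size is not None]
    if not observed:
        raise ValidationError("cannot impute sample size: no observed values")
    med = float(np.median(observed))
    if med.is_integer():
        med = int(med)
    out = []
    n_imputed = 0
    for r in records:
        if r.sample_size is None:
            out.append(dataclasses.replace(r, sample_size=med))
            n_imputed += 1
        else:
            out.append(r)
    return out, med, n_imputed


def encode_covariates(record: StudyRecord) -> CovariateVector:
    """Encode a record's covariates as the standard design row."""
    if record.sample_size is None:
        raise ValidationError(
            f"{record.study_id}: sample size missing; impute before encoding"
        )
    if record.sample_size <= 0:
        raise ValidationError(f"{record.study_id}: sample size must be positive")
    return CovariateVector(
        log_sample_size=math.log(record.sample_size),
        rct=int(record.rct),
        funding_commercial=int(record.funding is Funding.COMMERCIAL),
        funding_not_reported=int(record.funding is Funding.NOT_REPORTED),
        industry=int(record.industry_involved),
        primary_outcome=int(record.primary_outcome),
        collab_multi_national=int(record.collaboration is Collaboration.MULTI_NATIONAL),
        collab_multi_international=int(
            record.collaboration is Collaboration.MULTI_INTERNATIONAL
        ),
    )


def design_matrix(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Stack encoded covariate rows into a design DataFrame."""
    arr = np.array([encode_covariates(r).as_array() for r in records])
    return pd.DataFrame(arr, columns=list(COVARIATE_NAMES))


# ---------------------------------------------------------------------------
# Observation cases

def derive_observation_case(
    record: StudyRecord, unclear: str = "unknown_state"
) -> ObservationCase:
    """Reduce a record to its interval-censored likelihood pattern.

    Times are years since approval; a year-``y`` event maps to the unit
    interval ``[y - approval, y - approval + 1)``.  An intermediate event of
    known occurrence but unknown year is bounded by ``[0, U)`` where ``U``
    is the end of follow-up, tightened to the right edge of the publication
    interval for published studies (publication cannot precede study end).

    Studies with status ``ongoing`` reported themselves still running and
    are right-censored in the Approved state at end of follow-up.  For
    studies with ``unclear`` status (no survey response, no publication
    found) the only observed fact is the absence of a publication; by
    default they contribute the probability of being unpublished in *any*
    state at end of follow-up (``unclear="unknown_state"``).  Passing
    ``unclear="censor_approved"`` instead censors them in Approved like
    ongoing studies, which ignores the possibility that they completed or
    were discontinued unobserved.
    """
    if unclear not in ("unknown_state", "censor_approved"):
        raise ValueError("unclear must be 'unknown_state' or 'censor_approved'")
    ay = record.approval_year
    horizon = float(record.followup_end_year - ay)
    cov = encode_covariates(record)

    if record.status in (Status.ONGOING, Status.UNCLEAR):
        if record.published:
            raise ValidationError(
                f"{record.study_id}: published but status is {record.status.value}"
            )
        if record.status is Status.UNCLEAR and unclear == "unknown_state":
            path = PathType.UNPUBLISHED_UNKNOWN
        else:
            path = PathType.CENSORED_IN_APPROVED
        return ObservationCase(
            path=path,
            covariates=cov,
            absorbing_lower=horizon,
            absorbing_upper=horizon,
            study_id=record.study_id,
        )

    completed = record.status is Status.COMPLETED
    ev = record.intermediate_event_year
    p = float(record.publication_year - ay) if record.published else None

    if ev is not None:
        a = float(ev - ay)
        b = a + 1.0
    else:
        a = 0.0
        b = min(p + 1.0, horizon) if record.published else horizon
        # An event known to have occurred by a degenerate follow-up window
        # still took place within the first reporting year.
        b = max(b, 1.0)

    if record.published:
        path = PathType.COMPLETED_PUBLISHED if completed else PathType.DISCONTINUED_PUBLISHED
        return ObservationCase(
            path=path,
            covariates=cov,
            intermediate_lower=a,
            intermediate_upper=b,
            absorbing_lower=p,
            absorbing_upper=p + 1.0,
            study_id=record.study_id,
        )
    path = PathType.COMPLETED_CENSORED if completed else PathType.DISCONTINUED_CENSORED
    return ObservationCase(
        path=path,
        covariates=cov,
        intermediate_lower=a,
        intermediate_upper=b,
        absorbing_lower=horizon,
        absorbing_upper=horizon,
        study_id=record.study_id,
    )


# ---------------------------------------------------------------------------
# Occupancy summary

def _pct(numerator: int, denominator: int) -> int | None:
    """Percentage rounded to nearest integer, ties away from zero."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class OccupancySummary:
    """Counts of studies entering each state with conditional publication rates."""

    n_total: int
    n_completed: int
    n_discontinued: int
    n_ongoing: int
    n_unclear: int
    n_published_after_completed: int
    n_published_after_discontinued: int

    @property
    def n_published(self) -> int:
        return self.n_published_after_completed + self.n_published_after_discontinued

    @property
    def pct_published_given_completed(self) -> int | None:
        return _pct(self.n_published_after_completed, self.n_completed)

    @property
    def pct_published_given_discontinued(self) -> int | None:
        return _pct(self.n_published_after_discontinued, self.n_discontinued)

    @property
    def pct_published_overall(self) -> int | None:
        return _pct(self.n_published, self.n_total)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_completed": self.n_completed,
            "n_discontinued": self.n_discontinued,
            "n_ongoing": self.n_ongoing,
            "n_unclear": self.n_unclear,
            "n_published_after_completed": self.n_published_after_completed,
            "n_published_after_discontinued": self.n_published_after_discontinued,
            "n_published": self.n_published,
            "pct_published_given_completed": self.pct_published_given_completed,
            "pct_published_given_discontinued": self.pct_published_given_discontinued,
            "pct_published_overall": self.pct_published_overall,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format(self) -> str:
        d = self.to_dict()
        lines = [
            "State occupancy",
            "---------------",
            f"Studies analysed            {d['n_total']:>6}",
            f"  completed                 {d['n_completed']:>6}",
            f"  discontinued              {d['n_discontinued']:>6}",
            f"  ongoing                   {d['n_ongoing']:>6}",
            f"  status unclear            {d['n_unclear']:>6}",
            f"Published after completion  {d['n_published_after_completed']:>6}"
            f"  ({d['pct_published_given_completed']}% of completed)",
            f"Published after discontinu. {d['n_published_after_discontinued']:>6}"
            f"  ({d['pct_published_given_discontinued']}% of discontinued)",
            f"Published overall           {d['n_published']:>6}"
            f"  ({d['pct_published_overall']}% of analysed)",
        ]
        return "\n".join(lines)


def count_state_occupancy(records: Sequence[StudyRecord]) -> OccupancySummary:
    """Tally terminal state occupancy; every record lands in exactly one cell."""
    n_completed = n_discontinued = n_ongoing = n_unclear = 0
    pub_completed = pub_discontinued = 0
    for r in records:
        if r.status is Status.COMPLETED:
            n_completed += 1
            pub_completed += int(r.published)
        elif r.status is Status.DISCONTINUED:
            n_discontinued += 1
            pub_discontinued += int(r.published)
        elif r.status is Status.ONGOING:
            n_ongoing += 1
        else:
            n_unclear += 1
    return OccupancySummary(
        n_total=len(records),
        n_completed=n_completed,
        n_discontinued=n_discontinued,
        n_ongoing=n_ongoing,
        n_unclear=n_unclear,
        n_published_after_completed=pub_completed,
        n_published_after_discontinued=pub_discontinued,
    )
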