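"""Reading raw laboratory-record files and grouping rows into cases.

Raw exports are delimited text with one row per ordered test.  Of the
typical column layout (service date, requisition number, patient health
card number, name, sex, birth date, test sequence, test code, description,
result, normal range, ...) only three columns are consumed: the patient
identifier (``PNUM``), the service date (``SDTE``) and the test code
(``TEST``).  Rows are grouped into :class:`PatientCase` objects either per
patient or per visit (patient + service date); within a case a test counts
once no matter how often it was billed, because every probability downstream
is defined over *cases*, not record lines.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, TextIO

from labrec.errors import EmptyInputError, FormatError, InputError

log = logging.getLogger(__name__)

#: Canonical required columns and their default header spellings.
REQUIRED_COLUMNS = ("PNUM", "SDTE", "TEST")


@dataclass(frozen=True)
class LabRecord:
    """One raw record line: a patient took a test on a date.

    ``service_date`` is ``None`` when the raw field did not parse; such
    records are usable for per-patient grouping but not per-visit.
    """

    patient_id: str
    service_date: date | None
    test_code: str


@dataclass(frozen=True)
class PatientCase:
    """One analysis unit (a patient, or one visit) and its set of tests."""

    case_id: str
    taken_tests: frozenset[str]
    patient_id: str = ""

    @property
    def k(self) -> int:
        """Number of distinct tests taken in this case."""
        return len(self.taken_tests)


@dataclass(frozen=True)
class TestUniverse:
    """The ordered catalogue of all distinct test codes, sorted by code."""

    tests: tuple[str, ...]

    @property
    def M(self) -> int:
        return len(self.tests)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tests)}

    def __contains__(self, code: str) -> bool:
        return code in set(self.tests)

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "TestUniverse":
        return cls(tests=tuple(sorted(set(codes))))


@dataclass
class ReaderConfig:
    """Dialect of the raw file: delimiter, date format, header aliases.

    ``delimiter=None`` autodetects comma vs tab from the header line.
    ``aliases`` maps the canonical names PNUM/SDTE/TEST to the actual
    header spellings if they differ.
    """

    delimiter: str | None = None
    date_format: str = "%Y-%m-%d"
    aliases: dict[str, str] = field(default_factory=dict)

    def column(self, canonical: str) -> str:
        return self.aliases.get(canonical, canonical)


def _sniff_delimiter(header_line: str) -> str:
    try:
        return csv.Sniffer().sniff(header_line, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in header_line else ","


def parse_lab_records(
    stream: TextIO, config: ReaderConfig | None = None
) -> list[LabRecord]:
    """Parse a delimited lab-record file into :class:`LabRecord` objects.

    Rows missing any of the three required fields (after whitespace
    trimming) are skipped; the skip count is reported through logging.
    Unparseable dates are kept with ``service_date=None`` — per-visit
    grouping will drop them later.

    Raises
    ------
    InputError
        If the stream cannot be read.
    FormatError
        If the header lacks a required column.
    """
    config = config or ReaderConfig()
    try:
        header_line = stream.readline()
    except (OSError, UnicodeDecodeError) as exc:
        raise InputError(f"cannot read input stream: {exc}") from exc
    if not header_line.strip():
        raise FormatError("input has no header row")

    delim = config.delimiter or _sniff_delimiter(header_line)
    reader = csv.reader(io.StringIO(header_line), delimiter=delim)
    header = [h.strip() for h in next(reader)]
    positions: dict[str, int] = {}
    for canonical in REQUIRED_COLUMNS:
        name = config.column(canonical)
        if name not in header:
            raise FormatError(f"missing column {name}")
        positions[canonical] = header.index(name)

    records: list[LabRecord] = []
    skipped = 0
    try:
        rows = csv.reader(stream, delimiter=delim)
        for row in rows:
            if not row or all(not c.strip() for c in row):
                continue
            try:
                pnum = row[positions["PNUM"]].strip()
                sdte = row[positions["SDTE"]].strip()
                test = row[positions["TEST"]].strip()
            except IndexError:
                skipped += 1
                continue
            if not pnum or not sdte or not test:
                skipped += 1
                continue
            try:
                when: date | None = datetime.strptime(
                    sdte, config.date_format
                ).date()
            except ValueError:
                when = None
            records.append(LabRecord(pnum, when, test))
    except (OSError, UnicodeDecodeError) as exc:
        raise InputError(f"cannot read input stream: {exc}") from exc

    if skipped:
        log.info("parse_lab_records: skipped %d incomplete rows", skipped)
    parse_lab_records.last_skip_count = skipped  # type: ignore[attr-defined]
    return records


def group_into_cases(
    records: list[LabRecord], unit: str = "visit"
) -> tuple[list[PatientCase], TestUniverse]:
    """Group records into cases and collect the test universe.

    ``unit="patient"`` groups by patient id; ``unit="visit"`` groups by
    (patient id, service date) and drops records whose date failed to parse
    (logged).  The universe is the sorted set of all test codes observed in
    the grouped records.
    """
    if not records:
        raise EmptyInputError("no records to group")
    if unit not in ("patient", "visit"):
        raise ValueError(f"unknown grouping unit {unit!r}")

    groups: dict[tuple[str, ...], set[str]] = {}
    dropped = 0
    for rec in records:
        if unit == "visit":
            if rec.service_date is None:
                dropped += 1
                continue
            key = (rec.patient_id, rec.service_date.isoformat())
        else:
            key = (rec.patient_id,)
        groups.setdefault(key, set()).add(rec.test_code)
    if dropped:
        log.info("group_into_cases: dropped %d records with unparseable dates", dropped)
    if not groups:
        raise EmptyInputError("all records dropped during grouping")

    cases = [
        PatientCase(case_id="|".join(key), taken_tests=frozenset(tests), patient_id=key[0])
        for key, tests in sorted(groups.items())
    ]
    universe = TestUniverse.from_codes(t for c in cases for t in c.taken_tests)
    return cases, universe


def write_case_file(cases: list[PatientCase], stream: TextIO) -> None:
    """Write the normalized case format: ``case_id<TAB>code,code,...``."""
    for case in cases:
        stream.write(f"{case.case_id}\t{','.join(sorted(case.taken_tests))}\n")


def read_case_file(stream: TextIO) -> list[PatientCase]:
    """Read the normalized case format written by :func:`write_case_file`."""
    cases = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        case_id, _, codes = line.partition("\t")
        if not codes:
            raise FormatError(f"malformed case line: {line!r}")
        cases.append(
            PatientCase(
                case_id=case_id,
                taken_tests=frozenset(c.strip() for c in codes.split(",") if c.strip()),
                patient_id=case_id.split("|")[0],
            )
        )
    if not cases:
        raise EmptyInputError("case file contains no cases")
    return cases
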