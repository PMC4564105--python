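"""Core record types and tab-separated count-table I/O.

A count table holds one row per sequenced measurement: an individual at a
culture passage (0 = uncultured blood), with the total number of amplicon
reads and the number of reads carrying the variant allele.  Files are
UTF-8, tab-separated, header row mandatory, ``.`` decimal separator, no
quoting.  Unknown extra columns survive a read/write round-trip verbatim.
"""

from __future__ import annotations

import csv
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path

from .errors import FormatError, ValidationError

__all__ = [
    "Cohort",
    "Disease",
    "Component",
    "AmpliconSample",
    "CohortTable",
    "read_count_table",
    "write_count_table",
    "load_table1_fixture",
]


class Cohort(str, Enum):
    WM_FAMILY = "WM_FAMILY"
    MM_FAMILY = "MM_FAMILY"
    REFERENCE = "REFERENCE"


class Disease(str, Enum):
    WM = "WM"
    MGUS = "MGUS"
    MM = "MM"
    OTHER = "OTHER"


class Component(str, Enum):
    IgM = "IgM"
    IgG = "IgG"
    IgA = "IgA"
    NONE = "NONE"


REQUIRED_COLUMNS = (
    "sample_id",
    "individual_id",
    "family_id",
    "cohort",
    "disease",
    "component",
    "passage",
    "replicate",
    "total_reads",
    "alt_reads",
)


@dataclass(frozen=True)
class AmpliconSample:
    """One deep-sequencing measurement of the variant locus.

    ``family_id`` may be empty (individuals with letter identifiers carry
    no family number).  ``extra`` holds unknown columns as opaque text
    annotations preserved on round-trip.
    """

    sample_id: str
    individual_id: str
    family_id: str
    cohort: Cohort
    disease: Disease
    component: Component
    passage: int
    total_reads: int
    alt_reads: int
    replicate: int = 1
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.passage < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: passage must be >= 0, got {self.passage}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}"
            )
        if self.total_reads < 0 or self.alt_reads < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: read counts must be non-negative"
            )
        if self.alt_reads > self.total_reads:
            raise ValidationError(
                f"sample {self.sample_id!r}: alt_reads ({self.alt_reads}) exceeds "
                f"total_reads ({self.total_reads})"
            )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.individual_id, self.passage, self.replicate)


@dataclass(frozen=True)
class CohortTable:
    """An ordered, validated collection of :class:`AmpliconSample` records."""

    samples: tuple[AmpliconSample, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        seen: dict[tuple[str, int, int], str] = {}
        for s in self.samples:
            if s.key in seen:
                raise ValidationError(
                    f"duplicate (individual, passage, replicate) key {s.key}: "
                    f"samples {seen[s.key]!r} and {s.sample_id!r}"
                )
            seen[s.key] = s.sample_id

    def __iter__(self) -> Iterator[AmpliconSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> AmpliconSample:
        return self.samples[i]

    def individuals(self) -> list[str]:
        """Unique individual ids in first-appearance order."""
        out: list[str] = []
        for s in self.samples:
            if s.individual_id not in out:
                out.append(s.individual_id)
        return out

    def subset(
        self,
        *,
        cohort: Cohort | None = None,
        passage: int | None = None,
        individual_id: str | None = None,
    ) -> "CohortTable":
        kept = [
            s
            for s in self.samples
            if (cohort is None or s.cohort == cohort)
            and (passage is None or s.passage == passage)
            and (individual_id is None or s.individual_id == individual_id)
        ]
        return CohortTable(tuple(kept), provenance=self.provenance)


def _parse_int(value: str, column: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"line {line_no}: column {column!r} must be an integer, got {value!r}"
        ) from None


def _parse_enum(enum_cls, value: str, column: str, line_no: int):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise FormatError(
            f"line {line_no}: column {column!r} must be one of [{allowed}], got {value!r}"
        ) from None


def read_count_table(path: str | Path) -> CohortTable:
    """Read a tab-separated count table into a validated :class:`CohortTable`.

    Raises :class:`FormatError` for a missing or duplicated required column
    and :class:`ValidationError` (naming the offending row) for invariant
    violations such as ``alt_reads > total_reads``.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
        for col in REQUIRED_COLUMNS:
            n = header.count(col)
            if n == 0:
                raise FormatError(f"{path}: missing required column {col!r}")
            if n > 1:
                raise FormatError(f"{path}: duplicate required column {col!r}")
        extra_cols = [c for c in header if c not in REQUIRED_COLUMNS]
        idx = {c: header.index(c) for c in header}

        samples = []
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {line_no} has {len(row)} fields, expected {len(header)}"
                )
            get = lambda c: row[idx[c]]
            try:
                sample = AmpliconSample(
                    sample_id=get("sample_id"),
                    individual_id=get("individual_id"),
                    family_id=get("family_id"),
                    cohort=_parse_enum(Cohort, get("cohort"), "cohort", line_no),
                    disease=_parse_enum(Disease, get("disease"), "disease", line_no),
                    component=_parse_enum(Component, get("component"), "component", line_no),
                    passage=_parse_int(get("passage"), "passage", line_no),
                    replicate=_parse_int(get("replicate"), "replicate", line_no),
                    total_reads=_parse_int(get("total_reads"), "total_reads", line_no),
                    alt_reads=_parse_int(get("alt_reads"), "alt_reads", line_no),
                    extra={c: get(c) for c in extra_cols},
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {line_no}: {exc}") from None
            samples.append(sample)
    return CohortTable(tuple(samples), provenance=str(path))


def write_count_table(table: CohortTable, path: str | Path) -> None:
    """Write ``table`` so that :func:`read_count_table` reproduces it field-for-field."""
    path = Path(path)
    extra_cols: list[str] = []
    for s in table:
        for c in s.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    header = list(REQUIRED_COLUMNS) + extra_cols
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for s in table:
            writer.writerow(
                [
                    s.sample_id,
                    s.individual_id,
                    s.family_id,
                    s.cohort.value,
                    s.disease.value,
                    s.component.value,
                    s.passage,
                    s.replicate,
                    s.total_reads,
                    s.alt_reads,
                ]
                + [s.extra.get(c, "") for c in extra_cols]
            )


def load_table1_fixture() -> CohortTable:
    """The bundled 19-individual x 3-passage published count table.

    The ``af_pct`` extra column carries the allele fraction (in percent,
    2 decimals) as printed in the source publication.
    """
    ref = resources.files("ampliclone").joinpath("data/table1.tsv")
    with resources.as_file(ref) as p:
        table = read_count_table(p)
    return replace(table, provenance="bundled fixture: published count table")
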