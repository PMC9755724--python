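"""Protein FASTA and exon-map I/O.

Proteins are plain amino-acid sequences (20 standard letters plus ``X``);
exon architectures are ordered, non-overlapping, labeled intervals on
0-based half-open *protein* coordinates.  All region sizes downstream are
therefore in amino acids.

The exon-map format is a TSV with header columns
``record_id  exon_label  start  end`` (one interval per row, ``#`` comments
allowed).  Exon labels are opaque tokens — ``"4a"``, ``"4a-L"``, ``"6p"``
need no special parsing; ordering comes from coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "ExonInterval",
    "ExonMap",
    "ValidationReport",
    "SeqFormatError",
    "read_fasta",
    "write_fasta",
    "read_exon_map",
    "write_exon_map",
    "validate_annotation",
]

#: Residue alphabet accepted throughout: the 20 standard amino acids plus X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class SeqFormatError(ValueError):
    """Raised for malformed FASTA or exon-map input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identity metadata.

    Parameters
    ----------
    record_id:
        Short unique token (the first whitespace-delimited word of the
        FASTA header).
    residues:
        Uppercase amino-acid string over the 20 standard letters plus X.
    species_label:
        Free-text species name, optional.
    source_accession:
        Database accession the sequence was taken from, optional
        (e.g. ``"ENST00000415613.6"``).
    """

    record_id: str
    residues: str
    species_label: str = ""
    source_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be nonempty")
        if not self.residues:
            raise ValueError(f"{self.record_id}: residues must be nonempty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.record_id}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonInterval:
    """A labeled half-open interval [start, end) on protein coordinates."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("exon label must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"exon {self.label!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonMap:
    """Ordered, non-overlapping exon intervals for one protein record.

    Intervals must be sorted by start and non-overlapping, with unique
    labels.  Unannotated inter-exon stretches are permitted (they surface
    as warnings in :func:`validate_annotation`, not errors, because exon
    assignment can legitimately be uncertain in distant species).
    """

    record_id: str
    intervals: tuple[ExonInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        labels = [iv.label for iv in self.intervals]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"{self.record_id}: duplicate exon labels {dupes}")
        prev_end = -1
        prev = None
        for iv in self.intervals:
            if prev is not None and iv.start < prev_end:
                raise ValueError(
                    f"{self.record_id}: exon {iv.label!r} [{iv.start},{iv.end}) "
                    f"overlaps or precedes {prev.label!r} [{prev.start},{prev.end})"
                )
            prev_end, prev = iv.end, iv
        object.__setattr__(
            self, "_by_label", {iv.label: iv for iv in self.intervals}
        )

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> ExonInterval:
        return self._by_label[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(iv.label for iv in self.intervals)

    @property
    def span(self) -> int:
        """End coordinate of the last interval (0 for an empty map)."""
        return self.intervals[-1].end if self.intervals else 0


@dataclass
class ValidationReport:
    """Outcome of checking an exon map against its protein record."""

    record_id: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_header_metadata(description: str) -> dict[str, str]:
    """Parse ``species=...;accession=...`` key-values after the record id."""
    meta: dict[str, str] = {}
    parts = description.split(None, 1)
    if len(parts) < 2:
        return meta
    for chunk in parts[1].split(";"):
        chunk = chunk.strip()
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            meta[key.strip()] = value.strip()
    return meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The first token of each header becomes ``record_id``; the remainder is
    scanned for ``species=…;accession=…`` key-value metadata.  Illegal
    residue characters raise :class:`SeqFormatError` naming the offending
    record and line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    # Track header line numbers so residue errors can cite a location.
    header_lines: dict[str, int] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                token = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                if not token:
                    raise SeqFormatError(f"{path}:{lineno}: empty FASTA header")
                header_lines.setdefault(token, lineno)
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header_metadata(rec.description)
        residues = str(rec.seq).upper()
        lineno = header_lines.get(rec.id, 0)
        if rec.id in seen:
            raise SeqFormatError(f"{path}:{lineno}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        bad = set(residues) - _VALID_RESIDUES
        if bad:
            raise SeqFormatError(
                f"{path}:{lineno}: record {rec.id!r} contains illegal "
                f"residue character(s) {sorted(bad)}"
            )
        if not residues:
            raise SeqFormatError(f"{path}:{lineno}: record {rec.id!r} is empty")
        records.append(
            ProteinRecord(
                record_id=rec.id,
                residues=residues,
                species_label=meta.get("species", ""),
                source_accession=meta.get("accession"),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA.

    ``read_fasta(write_fasta(x))`` reproduces ``x`` exactly, metadata
    included.
    """
    seq_records = []
    for rec in records:
        desc_parts = []
        if rec.species_label:
            desc_parts.append(f"species={rec.species_label}")
        if rec.source_accession:
            desc_parts.append(f"accession={rec.source_accession}")
        seq_records.append(
            SeqRecord(
                Seq(rec.residues),
                id=rec.record_id,
                description=";".join(desc_parts),
            )
        )
    with Path(path).open("w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


_EXON_MAP_COLUMNS = ["record_id", "exon_label", "start", "end"]


def read_exon_map(path: str | Path) -> dict[str, ExonMap]:
    """Read exon maps from TSV, grouped and validated per record_id.

    Overlapping intervals, ``end <= start`` or unsorted rows raise
    :class:`SeqFormatError` listing the offending rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype={"record_id": str, "exon_label": str}
        )
    except pd.errors.EmptyDataError:
        raise SeqFormatError(f"{path}: empty file (expected a header row)")
    missing = [c for c in _EXON_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise SeqFormatError(f"{path}: missing column(s) {missing}")
    maps: dict[str, ExonMap] = {}
    for record_id, group in df.groupby("record_id", sort=False):
        intervals = []
        for row in group.itertuples():
            try:
                intervals.append(
                    ExonInterval(str(row.exon_label), int(row.start), int(row.end))
                )
            except ValueError as exc:
                raise SeqFormatError(f"{path}: row {row.Index + 2}: {exc}") from exc
        try:
            maps[str(record_id)] = ExonMap(str(record_id), tuple(intervals))
        except ValueError as exc:
            raise SeqFormatError(f"{path}: {exc}") from exc
    return maps


def write_exon_map(maps: Iterable[ExonMap], path: str | Path) -> None:
    """Write exon maps in the TSV exchange format."""
    rows = [
        (m.record_id, iv.label, iv.start, iv.end)
        for m in maps
        for iv in m.intervals
    ]
    df = pd.DataFrame(rows, columns=_EXON_MAP_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def validate_annotation(record: ProteinRecord, exon_map: ExonMap) -> ValidationReport:
    """Check an exon map against its protein record.

    Intervals running past the protein end are errors; uncovered residue
    ranges are warnings.  ``report.ok`` is true iff there are no errors.
    """
    if exon_map.record_id != record.record_id:
        raise ValueError(
            f"map record_id {exon_map.record_id!r} != record {record.record_id!r}"
        )
    report = ValidationReport(record.record_id)
    n = len(record)
    for iv in exon_map.intervals:
        if iv.end > n:
            report.errors.append(
                f"exon {iv.label!r} [{iv.start},{iv.end}) exceeds protein length {n}"
            )
    covered_end = 0
    for iv in exon_map.intervals:
        if iv.start > covered_end:
            report.warnings.append(f"uncovered [{covered_end},{iv.start})")
        covered_end = max(covered_end, iv.end)
    if covered_end < n:
        report.warnings.append(f"uncovered [{covered_end},{n})")
    return report
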