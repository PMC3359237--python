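"""Readers, writers and the collapsed-tag data model.

Everything downstream of preprocessing consumes :class:`Tag` objects — unique
small-RNA sequences with per-library (per-organ) read counts — grouped in a
:class:`LibrarySet`.  Sequences are held internally in the RNA alphabet
(``ACGU``); DNA input is accepted and converted on read.  Coordinates are
0-based half-open internally and 1-based inclusive in emitted reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

DEFAULT_LIBRARIES = ("LL", "RL", "SL", "FL")

_RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class ParseError(ValueError):
    """Raised when an input file does not parse in the named format."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U.

    Raises ``ValueError`` if the result contains symbols outside ``ACGU``.
    """
    s = seq.upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU symbols after normalization: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Render an internal RNA string in the DNA alphabet (U -> T)."""
    return seq.replace("U", "T")


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base Phred scores."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Tag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def libraries_detected(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)


class LibrarySet:
    """An ordered set of organ libraries and their collapsed tags."""

    def __init__(self, libraries: Sequence[str] = DEFAULT_LIBRARIES,
                 tags: Iterable[Tag] = ()) -> None:
        self.libraries = list(libraries)
        self._tags: dict[str, Tag] = {}
        for tag in tags:
            self.add(tag)

    def add(self, tag: Tag) -> None:
        unknown = set(tag.counts) - set(self.libraries)
        if unknown:
            raise ValueError(f"unknown libraries in tag counts: {sorted(unknown)}")
        existing = self._tags.get(tag.sequence)
        if existing is None:
            self._tags[tag.sequence] = Tag(tag.sequence, dict(tag.counts))
        else:
            for lib, c in tag.counts.items():
                existing.counts[lib] = existing.counts.get(lib, 0) + c

    def __len__(self) -> int:
        return len(self._tags)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._tags

    def __iter__(self):
        return iter(self.sorted_tags())

    def get(self, sequence: str) -> Tag | None:
        return self._tags.get(sequence)

    def sorted_tags(self) -> list[Tag]:
        """Deterministic order: descending total, then lexicographic sequence."""
        return sorted(self._tags.values(), key=lambda t: (-t.total(), t.sequence))

    def library_sizes(self) -> dict[str, int]:
        sizes = {lib: 0 for lib in self.libraries}
        for tag in self._tags.values():
            for lib, c in tag.counts.items():
                sizes[lib] += c
        return sizes

    def subset(self, keep: Iterable[str]) -> "LibrarySet":
        keep = set(keep)
        return LibrarySet(self.libraries,
                          (t for t in self._tags.values() if t.sequence in keep))

    def without(self, drop: Iterable[str]) -> "LibrarySet":
        drop = set(drop)
        return LibrarySet(self.libraries,
                          (t for t in self._tags.values() if t.sequence not in drop))


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA or FASTQ (Sanger quality) into normalized records.

    T/U and case normalization is applied; record order is preserved; an
    empty file yields an empty list.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), format):
            qual = rec.letter_annotations.get("phred_quality")
            records.append(SequenceRecord(rec.id, str(rec.seq),
                                          list(qual) if qual is not None else None))
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
    except ValueError as exc:  # Biopython signals malformed records as ValueError
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path,
                    format: str = "fasta", dna: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            seq = to_dna(rec.sequence) if dna else rec.sequence
            if format == "fasta":
                fh.write(f">{rec.id}\n{seq}\n")
            elif format == "fastq":
                qual = rec.quality or [40] * len(seq)
                qstr = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{rec.id}\n{seq}\n+\n{qstr}\n")
            else:
                raise ValueError(f"unsupported format: {format!r}")


def collapse_to_tags(reads_per_library: Mapping[str, Iterable[SequenceRecord]],
                     libraries: Sequence[str] = DEFAULT_LIBRARIES) -> LibrarySet:
    """Group preprocessed reads into unique sequence tags with frequencies.

    Per-library read counts are conserved exactly: the sum of tag counts in a
    library equals the number of input reads for that library.
    """
    unknown = set(reads_per_library) - set(libraries)
    if unknown:
        raise ValueError(f"unknown library names: {sorted(unknown)}")
    libset = LibrarySet(libraries)
    for lib, reads in reads_per_library.items():
        for read in reads:
            libset.add(Tag(read.sequence, {lib: 1}))
    return libset


_COLLAPSED_HEADER = re.compile(r"^(?P<name>\S+)_x(?P<count>\d+)$")


def write_collapsed_fasta(libset: LibrarySet, library: str, path: str | Path) -> None:
    """Export one library's tags in the ``>tagN_xCOUNT`` collapsed dialect."""
    if library not in libset.libraries:
        raise ValueError(f"unknown library {library!r}")
    with open(path, "w") as fh:
        n = 0
        for tag in libset.sorted_tags():
            c = tag.count(library)
            if c > 0:
                n += 1
                fh.write(f">tag{n}_x{c}\n{tag.sequence}\n")


def read_collapsed_fasta(path: str | Path, library: str,
                         libraries: Sequence[str] = DEFAULT_LIBRARIES) -> LibrarySet:
    """Import a ``>tagN_xCOUNT`` collapsed FASTA as one library of a LibrarySet."""
    libset = LibrarySet(libraries)
    for rec in read_sequences(path, "fasta"):
        m = _COLLAPSED_HEADER.match(rec.id)
        if not m:
            raise ParseError(f"{path}: header {rec.id!r} not in tagN_xCOUNT dialect")
        libset.add(Tag(rec.sequence, {library: int(m.group("count"))}))
    return libset


def write_table(rows: Iterable[Mapping[str, object]], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as a tab-separated table with a header row.

    Rows are written in input order (callers sort by their stated key).
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("columns required for an empty row set")
        columns = list(rows[0].keys())
    for i, row in enumerate(rows):
        if set(row.keys()) != set(columns):
            raise ValueError(f"row {i} columns differ from header")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read back a TSV written by :func:`write_table` (all values as strings)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty table")
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        if len(vals) != len(header):
            raise ParseError(f"{path}: ragged row: {ln!r}")
        out.append(dict(zip(header, vals)))
    return out
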