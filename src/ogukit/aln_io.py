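"""Reading sequence alignments into per-sample hit groups.

An alignment file is treated as a mapping from query sequences (reads) to
subject genomes.  Three text formats are supported: SAM, BLAST tabular
(``-outfmt 6``) and a plain two-column query-to-subject map; each may be
stored plain or compressed with gzip, bzip2 or LZMA.  Input may be
multiplexed (sample encoded in the read identifier) or per-sample (one file
per sample, sample taken from the filename stem).

The unit of evidence is the hit itself: CIGAR strings, mapping qualities and
alignment scores are deliberately ignored.
"""

from __future__ import annotations

import bz2
import gzip
import lzma
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "HitGroup",
    "AlignmentSource",
    "AlignmentParseError",
    "open_stream",
    "parse_sam",
    "parse_blast6",
    "parse_map",
    "demultiplex",
    "read_hitgroups",
    "sample_name_from_path",
]


class AlignmentParseError(ValueError):
    """Raised when an alignment file violates its declared format."""


@dataclass(frozen=True)
class HitGroup:
    """One query sequence with the set of genomes it aligned to.

    ``k = len(subjects)`` is the multi-mapping multiplicity used for 1/k
    count apportionment downstream.
    """

    query_id: str
    sample_id: str
    subjects: frozenset[str]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError(f"hit group {self.query_id!r} has no subjects")

    @property
    def k(self) -> int:
        return len(self.subjects)


# Magic bytes → decompressor. Extension fallback below.
_MAGIC = [
    (b"\x1f\x8b", "gzip"),
    (b"BZh", "bzip2"),
    (b"\xfd7zXZ\x00", "lzma"),
]
_EXT_COMPRESSION = {".gz": "gzip", ".bz2": "bzip2", ".xz": "lzma", ".lzma": "lzma"}
_OPENERS = {"gzip": gzip.open, "bzip2": bz2.open, "lzma": lzma.open, "none": open}

#: filename extensions recognised as alignment formats (for per-sample naming)
FORMAT_EXTENSIONS = {
    ".sam": "sam",
    ".blast6": "blast6",
    ".b6": "blast6",
    ".b6o": "blast6",
    ".map": "map",
    ".tsv": "map",
    ".txt": "map",
}


@dataclass
class AlignmentSource:
    """A single alignment input and how to interpret it.

    ``format`` and ``compression`` may be left as ``"auto"`` to be detected
    from magic bytes / filename; at open time both must resolve.
    """

    path: str
    format: str = "auto"
    compression: str = "auto"
    demux: bool = False
    demux_delimiter: str = "_"
    sample_id: str | None = None
    paths: tuple[str, ...] = field(default_factory=tuple)


def detect_compression(path: str) -> str:
    """Sniff compression from magic bytes, falling back to the extension."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(6)
    except OSError as exc:
        raise AlignmentParseError(f"cannot read alignment file {path!r}: {exc}") from exc
    for magic, name in _MAGIC:
        if head.startswith(magic):
            return name
    return _EXT_COMPRESSION.get(os.path.splitext(path)[1].lower(), "none")


def open_stream(source: AlignmentSource | str) -> IO[str]:
    """Open an alignment file as a decoded text stream.

    Compression is auto-detected by magic bytes, with the filename extension
    as a fallback; a corrupt compressed body raises
    :class:`AlignmentParseError` naming the path when read.
    """
    if isinstance(source, str):
        source = AlignmentSource(path=source)
    comp = source.compression
    if comp in (None, "auto"):
        comp = detect_compression(source.path)
    if comp not in _OPENERS:
        raise AlignmentParseError(
            f"unknown compression {comp!r} for {source.path!r}"
        )
    try:
        return _OPENERS[comp](source.path, "rt")
    except OSError as exc:
        raise AlignmentParseError(f"cannot open {source.path!r}: {exc}") from exc


def _read_all_lines(stream: Iterable[str], path: str) -> Iterator[str]:
    try:
        for line in stream:
            yield line
    except (OSError, EOFError, gzip.BadGzipFile, lzma.LZMAError) as exc:
        raise AlignmentParseError(f"corrupt or truncated input {path!r}: {exc}") from exc


def _truncate_subject(subject: str) -> str:
    # FASTA header convention: id ends at first whitespace
    return subject.split()[0] if subject else subject


def parse_sam(lines: Iterable[str]) -> Iterator[tuple[str, frozenset[str]]]:
    """Parse SAM text into ``(query_id, subjects)`` groups.

    Header lines are skipped; unmapped records (FLAG 0x4 or RNAME ``*``)
    contribute nothing.  Paired mates share a QNAME in SAM, so a ``/1`` or
    ``/2`` suffix derived from FLAG bits 0x40/0x80 keeps each aligned mate a
    distinct query.  Records of one query are assumed consecutive (aligner
    output order); this is verified and a violation is an error.
    """
    current: str | None = None
    subjects: set[str] = set()
    seen: set[str] = set()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise AlignmentParseError(
                f"SAM record at line {lineno} has {len(fields)} fields (expected >= 11)"
            )
        qname, flag_str, rname = fields[0], fields[1], fields[2]
        try:
            flag = int(flag_str)
        except ValueError:
            raise AlignmentParseError(
                f"SAM record at line {lineno}: non-integer FLAG {flag_str!r}"
            ) from None
        if flag & 0x40:
            qname += "/1"
        elif flag & 0x80:
            qname += "/2"
        if flag & 0x4 or rname == "*":
            continue
        if qname != current:
            if current is not None and subjects:
                yield current, frozenset(subjects)
            if qname in seen:
                raise AlignmentParseError(
                    f"SAM records for query {qname!r} are not consecutive "
                    f"(line {lineno}); sort or group the file by query"
                )
            seen.add(qname)
            current = qname
            subjects = set()
        subjects.add(_truncate_subject(rname))
    if current is not None and subjects:
        yield current, frozenset(subjects)


def parse_blast6(lines: Iterable[str]) -> Iterator[tuple[str, frozenset[str]]]:
    """Parse BLAST tabular (-outfmt 6) lines: column 1 query, column 2 subject.

    Hits for one query need not be adjacent; the whole file is accumulated
    before groups are emitted.
    """
    groups: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise AlignmentParseError(
                f"BLAST tabular line {lineno} has fewer than 2 columns"
            )
        groups.setdefault(fields[0], set()).add(_truncate_subject(fields[1]))
    for query, subs in groups.items():
        yield query, frozenset(subs)


def parse_map(lines: Iterable[str]) -> Iterator[tuple[str, frozenset[str]]]:
    """Parse a plain two-column query<TAB>subject mapping.

    Multiple lines per query are allowed and need not be adjacent.
    """
    groups: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise AlignmentParseError(
                f"mapping line {lineno} has {len(fields)} fields (expected 2)"
            )
        groups.setdefault(fields[0], set()).add(_truncate_subject(fields[1]))
    for query, subs in groups.items():
        yield query, frozenset(subs)


_PARSERS = {"sam": parse_sam, "blast6": parse_blast6, "map": parse_map}


def detect_format(path: str) -> str:
    """Infer the alignment format from the filename (compression stripped)."""
    stem = path
    root, ext = os.path.splitext(stem)
    if ext.lower() in _EXT_COMPRESSION:
        stem = root
    ext = os.path.splitext(stem)[1].lower()
    if ext in FORMAT_EXTENSIONS:
        return FORMAT_EXTENSIONS[ext]
    raise AlignmentParseError(
        f"cannot infer alignment format of {path!r}; declare format explicitly"
    )


def sample_name_from_path(path: str) -> str:
    """Filename stem with known compression and alignment extensions removed."""
    name = os.path.basename(path)
    root, ext = os.path.splitext(name)
    if ext.lower() in _EXT_COMPRESSION:
        name = root
        root, ext = os.path.splitext(name)
    if ext.lower() in FORMAT_EXTENSIONS:
        name = root
    return name


def demultiplex(query_id: str, delimiter: str = "_") -> tuple[str | None, str]:
    """Split a read identifier into ``(sample_id, trimmed_query_id)``.

    The sample is the substring before the *first* delimiter.  If the
    delimiter does not occur, returns ``(None, query_id)`` and the caller
    falls back to the per-file sample name.
    """
    if not query_id:
        raise ValueError("empty query identifier")
    if not delimiter:
        raise ValueError("demultiplexing delimiter must be nonempty")
    head, sep, tail = query_id.partition(delimiter)
    if not sep or not head or not tail:
        return None, query_id
    return head, tail


def read_hitgroups(source: AlignmentSource | str) -> Iterator[HitGroup]:
    """Read an alignment source into a stream of :class:`HitGroup`.

    In demultiplexed mode the sample is parsed out of each read identifier;
    otherwise all reads belong to one sample named after the file.
    """
    if isinstance(source, str):
        source = AlignmentSource(path=source)
    fmt = source.format
    if fmt in (None, "auto"):
        fmt = detect_format(source.path)
    if fmt not in _PARSERS:
        raise AlignmentParseError(f"unknown alignment format {fmt!r}")
    file_sample = source.sample_id or sample_name_from_path(source.path)
    stream = open_stream(source)
    try:
        for query, subjects in _PARSERS[fmt](_read_all_lines(stream, source.path)):
            if source.demux:
                sample, trimmed = demultiplex(query, source.demux_delimiter)
                if sample is None:
                    sample, trimmed = file_sample, query
            else:
                sample, trimmed = file_sample, query
            yield HitGroup(query_id=trimmed, sample_id=sample, subjects=subjects)
    finally:
        stream.close()
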