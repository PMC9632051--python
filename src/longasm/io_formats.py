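"""Readers and writers for on-disk assembly artifacts.

Reads come in as FASTA/FASTQ (optionally gzipped); pairwise overlaps are
stored as PAF-compatible TSV with extra tags; layouts as a simple TSV
dialect; contigs go out as FASTA.  All coordinates are 0-based half-open,
on disk and in memory.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

_VALID_SEQ = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input record cannot be parsed or validated."""


class ValidationError(ValueError):
    """Raised when a record violates a format invariant."""


@dataclass
class Read:
    """A raw input read.

    read_id is a dense 0-based index assigned in input order; seq is
    uppercase DNA over {A,C,G,T,N}.
    """

    read_id: int
    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


# Edit scripts are run-length encoded strings such as "120=1X3I2D".
# Ops consume: '=' and 'X' one base of both query and target; 'D' one base of
# the query only; 'I' one base of the target only.
_SCRIPT_RUN = re.compile(r"(\d+)([=XID])")


def parse_script(script: str) -> List[Tuple[int, str]]:
    """Decode an edit script into (length, op) runs; validates the text."""
    runs = _SCRIPT_RUN.findall(script)
    if "".join(f"{n}{op}" for n, op in runs) != script:
        raise ParseError(f"malformed edit script: {script!r}")
    return [(int(n), op) for n, op in runs]


def script_spans(script: str) -> Tuple[int, int]:
    """(query bases, target bases) consumed by an edit script."""
    q = t = 0
    for n, op in parse_script(script):
        if op in "=X":
            q += n
            t += n
        elif op == "D":
            q += n
        else:
            t += n
    return q, t


def script_columns(script: str) -> Tuple[int, int]:
    """(match columns, total alignment columns) of an edit script."""
    match = total = 0
    for n, op in parse_script(script):
        total += n
        if op == "=":
            match += n
    return match, total


@dataclass
class OverlapRecord:
    """A pairwise overlap between two reads, in raw-read coordinates.

    Coordinates are 0-based half-open on the forward strand of each read.
    For strand '-', the edit script describes query[qstart:qend] against the
    reverse complement of target[tstart:tend].
    """

    qid: int
    tid: int
    strand: str  # '+' or '-'
    qstart: int
    qend: int
    tstart: int
    tend: int
    qlen: int
    tlen: int
    score: int
    identity: float
    edit_script: str

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValidationError(
                f"query interval [{self.qstart},{self.qend}) out of range "
                f"for length {self.qlen} (qid={self.qid})"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValidationError(
                f"target interval [{self.tstart},{self.tend}) out of range "
                f"for length {self.tlen} (tid={self.tid})"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity {self.identity} outside [0,1]")
        if self.edit_script:
            qspan, tspan = script_spans(self.edit_script)
            if qspan != self.qend - self.qstart or tspan != self.tend - self.tstart:
                raise ValidationError(
                    f"edit script spans ({qspan},{tspan}) disagree with "
                    f"intervals for pair ({self.qid},{self.tid})"
                )

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart

    @property
    def tspan(self) -> int:
        return self.tend - self.tstart


@dataclass
class LayoutEntry:
    """One read tile in a unitig layout.

    role 'path' marks backbone-defining reads of the unitig walk;
    'contained' reads are placed inside a container for consensus depth
    only.
    """

    read_id: int
    strand: str
    offset: int  # start position on the unitig, bases
    kept_start: int  # trimmed interval actually used, read coordinates
    kept_end: int
    role: str = "path"


@dataclass
class LayoutUnitig:
    unitig_id: str
    entries: List[LayoutEntry] = field(default_factory=list)

    @property
    def length(self) -> int:
        if not self.entries:
            return 0
        return max(e.offset + (e.kept_end - e.kept_start) for e in self.entries)


@dataclass
class LayoutFile:
    unitigs: List[LayoutUnitig] = field(default_factory=list)

    def validate(self, reads: Optional[Sequence[Read]] = None) -> None:
        by_id = {r.read_id: r for r in reads} if reads is not None else None
        for utg in self.unitigs:
            prev = -1
            for e in utg.entries:
                if e.offset < prev:
                    raise ValidationError(
                        f"offsets decrease in unitig {utg.unitig_id}"
                    )
                prev = e.offset
                if e.strand not in "+-":
                    raise ValidationError(f"bad strand for read {e.read_id}")
                if by_id is not None:
                    if e.read_id not in by_id:
                        raise ValidationError(
                            f"unitig {utg.unitig_id} references unknown "
                            f"read {e.read_id}"
                        )
                    if not (0 <= e.kept_start < e.kept_end <= by_id[e.read_id].length):
                        raise ValidationError(
                            f"kept interval of read {e.read_id} outside read"
                        )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(handle) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        return "empty"
    raise ParseError(f"cannot determine sequence format from leading {first!r}")


def read_sequences(path, fmt: str = "auto") -> List[Read]:
    """Load reads from FASTA/FASTQ (gzip transparent), assigning dense ids.

    Lowercase is uppercased and U mapped to T.  A record whose sequence
    contains characters outside {A,C,G,T,N} raises ParseError naming it.
    """
    reads: List[Read] = []
    with _open_text(path) as handle:
        if fmt == "auto":
            fmt = _sniff_format(handle)
            if fmt == "empty":
                return reads
        for rec in SeqIO.parse(handle, fmt):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ParseError(f"empty sequence for record {rec.id!r}")
            if not _VALID_SEQ.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ParseError(
                    f"record {rec.id!r} contains invalid characters {bad}"
                )
            reads.append(Read(read_id=len(reads), name=rec.id, seq=seq))
    return reads


# ---------------------------------------------------------------------------
# Overlap TSV (PAF-compatible columns + tags)
# ---------------------------------------------------------------------------

def write_overlaps(path, records: Iterable[OverlapRecord]) -> None:
    """Write overlap records as PAF rows with AS (score) and cg (script) tags.

    The name columns carry the integer read ids so the file round-trips
    without access to the read set.
    """
    with _open_text(path, "wt") as out:
        for rec in records:
            rec.validate()
            nmatch, ncols = script_columns(rec.edit_script) if rec.edit_script else (0, 0)
            fields = [
                str(rec.qid), str(rec.qlen), str(rec.qstart), str(rec.qend),
                rec.strand,
                str(rec.tid), str(rec.tlen), str(rec.tstart), str(rec.tend),
                str(nmatch), str(ncols), "255",
                f"AS:i:{rec.score}",
                f"ZI:f:{rec.identity:.6f}",
                f"cg:Z:{rec.edit_script}",
            ]
            out.write("\t".join(fields) + "\n")


def read_overlaps(path) -> List[OverlapRecord]:
    records: List[OverlapRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"line {lineno}: fewer than 12 PAF columns")
            tags = {}
            for tag in cols[12:]:
                key, typ, val = tag.split(":", 2)
                tags[key] = val
            rec = OverlapRecord(
                qid=int(cols[0]), qlen=int(cols[1]),
                qstart=int(cols[2]), qend=int(cols[3]),
                strand=cols[4],
                tid=int(cols[5]), tlen=int(cols[6]),
                tstart=int(cols[7]), tend=int(cols[8]),
                score=int(tags.get("AS", "0")),
                identity=float(tags.get("ZI", "0")),
                edit_script=tags.get("cg", ""),
            )
            rec.validate()
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Layout TSV
# ---------------------------------------------------------------------------

def write_layout(path, layout: LayoutFile) -> None:
    layout.validate()
    with _open_text(path, "wt") as out:
        for utg in layout.unitigs:
            out.write(
                f"U\t{utg.unitig_id}\t{len(utg.entries)}\t{utg.length}\n"
            )
            for e in utg.entries:
                out.write(
                    f"R\t{e.read_id}\t{e.strand}\t{e.offset}"
                    f"\t{e.kept_start}\t{e.kept_end}\t{e.role}\n"
                )


def read_layout(path) -> LayoutFile:
    layout = LayoutFile()
    current: Optional[LayoutUnitig] = None
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if cols[0] == "U":
                current = LayoutUnitig(unitig_id=cols[1])
                layout.unitigs.append(current)
            elif cols[0] == "R":
                if current is None:
                    raise ParseError(f"line {lineno}: R line before any U line")
                current.entries.append(LayoutEntry(
                    read_id=int(cols[1]), strand=cols[2], offset=int(cols[3]),
                    kept_start=int(cols[4]), kept_end=int(cols[5]),
                    role=cols[6] if len(cols) > 6 else "path",
                ))
            else:
                raise ParseError(f"line {lineno}: unknown record type {cols[0]!r}")
    layout.validate()
    return layout


def write_contigs(path, contigs: Iterable[Tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as FASTA, 80 columns per line."""
    with _open_text(path, "wt") as out:
        for name, seq in contigs:
            out.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")
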