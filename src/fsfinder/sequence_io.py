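"""Sequence input/output and elementary DNA arithmetic.

Reads and writes FASTA (via Biopython) and GFF3, and provides the small
set of sequence operations the frameshift pipeline relies on: GC content,
reverse complementation and stop-to-stop ORF enumeration.

Coordinate convention: 1-based inclusive everywhere (GFF3-compatible);
conversion to 0-based indices happens only at array boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

ALPHABET = "ACGTN"
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# any character outside the 5-letter alphabet collapses to N on ingest
_SANITIZE = {c: c if c in ALPHABET else "N" for c in map(chr, range(65, 91))}
_SANITIZE["U"] = "T"

_BASE_TO_INT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_INT[ord(_b)] = _i


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


class UndefinedGCError(ValueError):
    """GC content is undefined for empty or all-N sequences."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid characters in sequence {self.id!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Annotation:
    """A CDS interval on a sequence, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature: str = "CDS"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Orf:
    """A maximal stop-free interval in one reading frame.

    Coordinates are 1-based inclusive on the forward strand regardless of
    ``strand``; ``frame`` is the frame index on the reading strand.
    """

    start: int
    end: int
    frame: int
    strand: str
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def sanitize(seq: str) -> str:
    """Uppercase, map U->T and any other non-ACGTN character to N."""
    return "".join(_SANITIZE.get(c, "N") for c in seq.upper())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, sanitized)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty FASTA file")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: line 1 does not start with '>'")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        records.append(SequenceRecord(id=rec.id, seq=sanitize(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and N as -1."""
    return _BASE_TO_INT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_percent(seq: str) -> float:
    """GC content in percent; N is excluded from numerator and denominator."""
    if not seq:
        raise UndefinedGCError("GC content undefined for an empty sequence")
    ints = seq_to_ints(seq)
    valid = ints >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UndefinedGCError("GC content undefined for an all-N sequence")
    n_gc = int(((ints == 1) | (ints == 2)).sum())
    return 100.0 * n_gc / n_valid


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _orfs_one_strand(seq: str, min_len: int, strand: str) -> list[Orf]:
    L = len(seq)
    out: list[Orf] = []
    for frame in range(3):
        # 0-based codon start indices for this frame
        stops = [i for i in range(frame, L - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        bounds = [frame - 3] + stops + [None]  # sentinel for the right edge
        for k in range(len(bounds) - 1):
            left_stop = bounds[k]
            right_stop = bounds[k + 1]
            lo = left_stop + 3  # first codon index after the stop
            trunc_left = k == 0
            if right_stop is None:
                # run to the last complete codon of this frame
                hi = frame + 3 * ((L - frame) // 3) - 1
                trunc_right = True
            else:
                hi = right_stop - 1
                trunc_right = False
            if hi < lo:
                continue
            length = hi - lo + 1
            if length < min_len:
                continue
            if strand == "+":
                out.append(Orf(lo + 1, hi + 1, frame, "+", trunc_left, trunc_right))
            else:
                # reflect to forward coordinates
                out.append(Orf(L - hi, L - lo, frame, "-", trunc_right, trunc_left))
    return out


def enumerate_orfs(seq: str, min_len: int = 90) -> list[Orf]:
    """All maximal stop-to-stop open intervals >= min_len in all six frames.

    Intervals that run off either end of the fragment are reported with
    truncation flags; metagenomic fragments routinely clip genes, so
    truncated ORFs are first-class.
    """
    if min_len < 3 or min_len % 3:
        raise ValueError("min_len must be >= 3 and a multiple of 3")
    orfs = _orfs_one_strand(seq, min_len, "+")
    orfs += _orfs_one_strand(revcomp(seq), min_len, "-")
    return sorted(orfs, key=lambda o: (o.start, o.end, o.strand, o.frame))


def read_gff3_cds(path: str | Path) -> list[Annotation]:
    """Read CDS features from a GFF3 file."""
    anns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, _attrs = parts
            if ftype != "CDS":
                continue
            anns.append(Annotation(seqid, int(start), int(end), strand))
    return anns


def write_gff3(
    path: str | Path,
    seq_lengths: dict[str, int],
    genes: Sequence,
    frameshifts: Sequence,
) -> None:
    """Write gene and frameshift calls as GFF3.

    Frameshifts are point features of type ``frameshift`` with attributes
    fs_type (insertion|deletion-like), score and filters_passed.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid in sorted(seq_lengths):
            fh.write(f"##sequence-region {sid} 1 {seq_lengths[sid]}\n")
        rows = []
        for i, g in enumerate(genes, 1):
            attrs = f"ID=gene{i}"
            if getattr(g, "truncated_left", False) or getattr(g, "truncated_right", False):
                attrs += ";partial=true"
            rows.append(
                (g.fragment_id, g.start, g.end, "fsfinder", "gene",
                 f"{g.log_odds_score:.3f}", g.strand, attrs)
            )
        for i, fs in enumerate(frameshifts, 1):
            fs_type = "insertion" if fs.fs_shift > 0 else "deletion-like"
            passed = ",".join(sorted(set("I II III".split()) - set(fs.filters_failed))) or "."
            attrs = (
                f"ID=fs{i};fs_type={fs_type};filters_passed={passed}"
            )
            rows.append(
                (fs.fragment_id, fs.pos, fs.pos, "fsfinder", "frameshift",
                 f"{fs.score:.3f}", fs.strand, attrs)
            )
        rows.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
        for sid, start, end, src, ftype, score, strand, attrs in rows:
            fh.write(f"{sid}\t{src}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}\n")
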