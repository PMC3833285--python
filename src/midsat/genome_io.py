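"""Sequence and interval I/O: multi-scaffold FASTA in, FASTA/BED6 out.

All internal coordinates are 0-based half-open; BED6 on disk uses the same
convention, so no shifting happens anywhere in the package.  1-based
coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_CLEAN = frozenset("ACGTN")


@dataclass
class Genome:
    """Ordered collection of uppercase DNA scaffolds over {A,C,G,T,N}."""

    scaffolds: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.scaffolds.items())

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __getitem__(self, scaffold_id: str) -> str:
        return self.scaffolds[scaffold_id]

    def add(self, scaffold_id: str, sequence: str) -> None:
        if not scaffold_id:
            raise ValidationError("scaffold id must be non-empty")
        if scaffold_id in self.scaffolds:
            raise FormatError(f"duplicate scaffold id {scaffold_id!r}")
        if not sequence:
            raise FormatError(f"scaffold {scaffold_id!r} has an empty sequence")
        self.scaffolds[scaffold_id] = sequence


def sanitize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase a sequence and map everything outside A/C/G/T/N to N.

    Returns the cleaned sequence and the number of substituted characters.
    """
    seq = seq.upper()
    if all(c in _CLEAN for c in seq):
        return seq, 0
    cleaned = "".join(c if c in _CLEAN else "N" for c in seq)
    return cleaned, sum(1 for a, b in zip(seq, cleaned) if a != b)


def read_fasta(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Sequences are uppercased; IUPAC ambiguity codes and any other non-ACGTN
    characters are mapped to N (count logged).  Empty records, duplicate ids
    and record-less files are rejected.
    """
    path = Path(path)
    genome = Genome()
    n_subst = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq, subst = sanitize_sequence(str(record.seq))
        n_subst += subst
        genome.add(record.id, seq)
    if len(genome) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if n_subst:
        logger.info("%s: %d non-ACGTN characters mapped to N", path, n_subst)
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


#: BED6 record: (scaffold, start, end, name, score, strand)
Interval = tuple[str, int, int, str, float, str]


def write_intervals(records: Iterable[Interval], path: str | Path) -> None:
    """Write BED6 (0-based half-open) records."""
    lines = []
    for scaffold, start, end, name, score, strand in records:
        if not 0 <= start < end:
            raise ValidationError(
                f"invalid interval {scaffold}:{start}-{end} (need 0 <= start < end)"
            )
        lines.append(f"{scaffold}\t{start}\t{end}\t{name}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_intervals(path: str | Path) -> list[Interval]:
    """Read BED6 records written by :func:`write_intervals`."""
    records: list[Interval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected >= 6 BED fields")
        scaffold, start, end, name, score, strand = fields[:6]
        records.append(
            (scaffold, int(start), int(end), name, float(score), strand)
        )
    return records
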