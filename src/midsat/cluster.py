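"""Tiling decomposition of a repeat-cluster locus against a monomer consensus.

A cluster region is decomposed by repeatedly taking the best remaining local
alignment of the consensus against unannotated sequence, masking it, and
classifying each match:

* ``full``           - matched segment exactly the consensus length
* ``full_variant``   - length within a small tolerance of the consensus
                       (or any other partial match not fitting the classes below)
* ``truncated5p``    - alignment starts well into the consensus and runs to
                       its 3' end (a 5'-deleted copy)
* ``short_fragment`` - a short (<= ``short_max``) piece of the consensus
* ``spacer``         - unannotated sequence between matches

The segments tile the region exactly: no overlap, full coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .consensus import ConsensusUnit, make_aligner
from .enzymes import iupac_compatible
from .errors import ValidationError

CLASSES = ("full", "full_variant", "truncated5p", "short_fragment", "spacer")


@dataclass
class Segment:
    start: int
    end: int
    klass: str
    identity: float
    cons_start: int
    cons_end: int
    downstream_hexamer: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterAnnotation:
    region_length: int
    consensus_length: int
    segments: list[Segment] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for seg in self.segments:
            counts[seg.klass] += 1
        return counts

    def validate_partition(self) -> None:
        """Segments must tile [0, region_length) without overlap."""
        pos = 0
        for seg in sorted(self.segments, key=lambda s: s.start):
            if seg.start != pos:
                raise ValidationError(
                    f"segment tiling broken at {pos} (next segment at {seg.start})"
                )
            pos = seg.end
        if pos != self.region_length:
            raise ValidationError(
                f"segments end at {pos}, region length {self.region_length}"
            )


def _classify(seg_len: int, cons_start: int, cons_end: int, cons_len: int,
              length_tolerance: int, trunc5_min: int, short_max: int) -> str:
    if seg_len <= short_max:
        return "short_fragment"
    if cons_start >= trunc5_min and cons_end >= cons_len - 3:
        return "truncated5p"
    if seg_len == cons_len:
        return "full"
    return "full_variant"


def tile_cluster(
    region_seq: str,
    consensus: ConsensusUnit | str,
    min_identity: float = 80.0,
    min_match: int = 20,
    length_tolerance: int = 3,
    trunc5_min: int = 8,
    short_max: int = 35,
) -> ClusterAnnotation:
    """Greedily tile ``region_seq`` with local matches of the consensus monomer.

    Matches are taken in descending score order (leftmost on ties) until the
    best remaining match falls below ``min_identity`` percent identity or
    ``min_match`` bp; everything unmatched becomes spacer.
    """
    if not region_seq:
        raise ValidationError("empty region sequence")
    cons = consensus.sequence if isinstance(consensus, ConsensusUnit) else consensus
    if not cons:
        raise ValidationError("empty consensus")
    cons_len = len(cons)
    # stiff gap opening keeps local matches from chaining across spacer
    # sequence, which would outscore clean short fragments at low identity
    aligner = make_aligner("local")
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    ann = ClusterAnnotation(region_length=len(region_seq), consensus_length=cons_len)
    free: list[tuple[int, int]] = [(0, len(region_seq))]

    while True:
        best = None  # (score, interval start, alignment, interval)
        for lo, hi in free:
            if hi - lo < min_match:
                continue
            alignments = aligner.align(region_seq[lo:hi], cons)
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            aln = alignments[0]
            if best is None or alignments.score > best[0] or (
                alignments.score == best[0] and lo < best[1]
            ):
                best = (alignments.score, lo, aln, (lo, hi))
        if best is None:
            break
        score, lo, aln, interval = best
        ilo, ihi = interval
        tblocks, qblocks = aln.aligned
        rs, re = int(tblocks[0][0]) + lo, int(tblocks[-1][1]) + lo
        cs, ce = int(qblocks[0][0]), int(qblocks[-1][1])
        matches = 0
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            for off in range(te - ts):
                if iupac_compatible(region_seq[lo + ts + off], cons[qs + off]):
                    matches += 1
        columns = aln.length
        # rescue small edge trims: local alignment drops terminal consensus
        # columns whose region base is mutated, which would otherwise turn an
        # exact full-length copy into a spurious length variant
        if 0 < cs <= length_tolerance:
            j = min(cs, rs - ilo)
            for off in range(j):
                if iupac_compatible(region_seq[rs - j + off], cons[cs - j + off]):
                    matches += 1
            rs, cs, columns = rs - j, cs - j, columns + j
        if 0 < cons_len - ce <= length_tolerance:
            j = min(cons_len - ce, ihi - re)
            for off in range(j):
                if iupac_compatible(region_seq[re + off], cons[ce + off]):
                    matches += 1
            re, ce, columns = re + j, ce + j, columns + j
        identity = 100.0 * matches / columns
        seg_len = re - rs
        if identity < min_identity or seg_len < min_match:
            break
        klass = _classify(seg_len, cs, ce, cons_len,
                          length_tolerance, trunc5_min, short_max)
        hexamer = region_seq[re : re + 6] if klass == "short_fragment" else ""
        ann.segments.append(
            Segment(rs, re, klass, round(identity, 2), cs, ce, hexamer)
        )
        free.remove(interval)
        if rs - ilo > 0:
            free.append((ilo, rs))
        if ihi - re > 0:
            free.append((re, ihi))
        free.sort()

    for lo, hi in free:
        if hi > lo:
            ann.segments.append(Segment(lo, hi, "spacer", 0.0, 0, 0))
    ann.segments.sort(key=lambda s: s.start)
    # merge adjacent spacers created by interval splitting
    merged: list[Segment] = []
    for seg in ann.segments:
        if (merged and seg.klass == "spacer" and merged[-1].klass == "spacer"
                and merged[-1].end == seg.start):
            merged[-1].end = seg.end
        else:
            merged.append(seg)
    ann.segments = merged
    ann.validate_partition()
    return ann


def summarize_cluster(annotation: ClusterAnnotation) -> dict:
    """Per-class counts plus the length histogram of full_variant segments."""
    hist = Counter(
        seg.length for seg in annotation.segments if seg.klass == "full_variant"
    )
    return {
        "counts": annotation.summary,
        "full_variant_lengths": dict(sorted(hist.items())),
        "short_fragment_hexamers": [
            seg.downstream_hexamer
            for seg in annotation.segments
            if seg.klass == "short_fragment"
        ],
    }
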