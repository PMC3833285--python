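"""In silico restriction digestion and fragment-length distribution diagrams.

The central computation: locate every theoretical recognition site of an
enzyme on each scaffold, cut the (linear) molecule, and aggregate the multiset
of fragment lengths genome-wide.  Tandem repeats carrying a recognition site
produce sharp peaks in the resulting length distribution at the monomer length
or its sub-fragments; fragments whose combined mass (length x count) is small
stay below gel detection level.  Peaks called per enzyme are intersected
across enzymes: same-size fragments produced by unrelated recognition
sequences are the signature of a tandemly repeated unit.

Fragment bookkeeping uses a linear-molecule model including the two terminal
(scaffold-end) fragments, so mass is conserved exactly:
``sum(L * counts[L]) == genome length``.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enzymes import IUPAC_SETS, Enzyme, reverse_complement
from .errors import ValidationError
from .genome_io import Genome


@dataclass
class CutSet:
    """Sorted, deduplicated top-strand cut positions on one scaffold.

    Cuts are 0-based between-base coordinates: a cut at position c separates
    sequence[:c] from sequence[c:].
    """

    scaffold: str
    cuts: list[int]

    def __post_init__(self) -> None:
        cuts = self.cuts
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValidationError("cut positions must be strictly increasing")
        if cuts and cuts[0] < 0:
            raise ValidationError("negative cut position")


def _pattern_to_regex(recognition: str) -> str:
    # Genome N is excluded automatically: expansion sets contain only ACGT.
    return "".join(
        "[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in recognition
    )


def find_sites(sequence: str, enzyme: Enzyme, scaffold: str = "") -> CutSet:
    """All top-strand cut positions of ``enzyme`` in ``sequence``.

    Overlapping site occurrences each produce a cut; coincident cut positions
    are collapsed.  Non-palindromic enzymes are additionally scanned with the
    reverse-complement pattern, cuts mapped back to top-strand coordinates.
    """
    cuts: set[int] = set()
    pattern = re.compile("(?=" + _pattern_to_regex(enzyme.recognition) + ")")
    for m in pattern.finditer(sequence):
        cuts.add(m.start() + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.recognition)
        rc_offset = len(enzyme.recognition) - enzyme.cut_offset
        pattern_rc = re.compile("(?=" + _pattern_to_regex(rc) + ")")
        for m in pattern_rc.finditer(sequence):
            cuts.add(m.start() + rc_offset)
    return CutSet(scaffold, sorted(cuts))


def fragment_lengths(cuts: CutSet, scaffold_length: int) -> list[int]:
    """Fragment lengths of a linear molecule cut at ``cuts``.

    Terminal fragments (sequence start to first cut, last cut to sequence end)
    are included; zero-length fragments are dropped.
    """
    if cuts.cuts and cuts.cuts[-1] > scaffold_length:
        raise ValidationError("cut position beyond scaffold end")
    boundaries = [0] + list(cuts.cuts) + [scaffold_length]
    return [b - a for a, b in zip(boundaries, boundaries[1:]) if b > a]


@dataclass
class FragmentDistribution:
    """Per-length fragment counts of a whole-genome digestion."""

    counts: dict[int, int]
    enzyme: str
    total_bp: int
    n_fragments: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_fragments = sum(self.counts.values())

    def mass(self, length: int) -> int:
        """Combined mass (bp) of all fragments of the given length."""
        return length * self.counts.get(length, 0)

    def to_frame(self, max_length: int | None = None) -> pd.DataFrame:
        """Length/count/mass table, ascending length."""
        lengths = sorted(self.counts)
        if max_length is not None:
            lengths = [L for L in lengths if L <= max_length]
        return pd.DataFrame(
            {
                "length": lengths,
                "count": [self.counts[L] for L in lengths],
                "mass": [self.mass(L) for L in lengths],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, enzyme: str | None = None) -> "FragmentDistribution":
        df = pd.read_csv(path, sep="\t")
        counts = dict(zip(df["length"].astype(int), df["count"].astype(int)))
        total = int(sum(L * c for L, c in counts.items()))
        return cls(counts=counts, enzyme=enzyme or "?", total_bp=total)


def digest_genome(genome: Genome, enzyme: Enzyme) -> FragmentDistribution:
    """Digest every scaffold with ``enzyme`` and pool fragment lengths."""
    if len(genome) == 0:
        raise ValidationError("cannot digest an empty genome")
    counts: dict[int, int] = {}
    for scaffold, seq in genome:
        cuts = find_sites(seq, enzyme, scaffold)
        for L in fragment_lengths(cuts, len(seq)):
            counts[L] = counts.get(L, 0) + 1
    return FragmentDistribution(counts=counts, enzyme=enzyme.name,
                                total_bp=genome.total_length)


@dataclass
class Peak:
    """A distinct peak in a fragment-length distribution diagram."""

    length: int
    count: int
    mass: int
    prominence: float


def detect_peaks(
    dist: FragmentDistribution,
    min_count: int = 100,
    window: int = 5,
    min_prominence: float = 5.0,
) -> list[Peak]:
    """Call distinct peaks in a fragment-length distribution.

    A length L is a peak iff its count is at least ``min_count``, exceeds
    every other count within +-``window`` bp (ties broken toward smaller L),
    and is at least ``min_prominence`` times the median count over that window
    (absent lengths count as zero).  Returned sorted by descending count.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    counts = dist.counts
    peaks: list[Peak] = []
    for L, c in counts.items():
        if c < min_count:
            continue
        neighbours = []
        is_max = True
        for off in range(-window, window + 1):
            if off == 0:
                continue
            c2 = counts.get(L + off, 0)
            neighbours.append(c2)
            # ties toward smaller L: a smaller neighbour with an equal count wins
            if (off < 0 and c2 >= c) or (off > 0 and c2 > c):
                is_max = False
                break
        if not is_max:
            continue
        background = statistics.median(neighbours)
        if c < min_prominence * background:
            continue
        prominence = c / background if background > 0 else float("inf")
        peaks.append(Peak(length=L, count=c, mass=dist.mass(L), prominence=prominence))
    peaks.sort(key=lambda p: (-p.count, p.length))
    return peaks


def predict_visible_bands(
    dist: FragmentDistribution, mass_fraction_threshold: float = 0.0005
) -> list[int]:
    """Lengths whose combined mass reaches the gel detection threshold.

    Models band visibility on a stained gel: a 1 bp bin appears as a band only
    if its fragments' combined mass is at least ``mass_fraction_threshold`` of
    the total digested DNA.  Abundant but very short fragments (e.g. a 36 bp
    monomer sub-fragment) fall below this level and are absent from the gel
    even though the distribution diagram shows them clearly.
    """
    if not 0 < mass_fraction_threshold < 1:
        raise ValidationError("mass_fraction_threshold must be in (0, 1)")
    cutoff = mass_fraction_threshold * dist.total_bp
    return sorted(L for L in dist.counts if dist.mass(L) >= cutoff)


def cross_enzyme_candidates(
    peaksets: dict[str, list[Peak]], tolerance_bp: int = 5
) -> list[tuple[int, list[str]]]:
    """Cluster peak lengths across enzymes; report lengths seen with >= 2 enzymes.

    Same-size fragments in digests with unrelated recognition sequences
    indicate a tandemly repeated unit.  Peak lengths are clustered by
    single linkage within ``tolerance_bp``; each cluster supported by at
    least two distinct enzymes yields a candidate whose length is the median
    of the member lengths.  Returned sorted by descending support, then length.
    """
    if len(peaksets) < 2:
        raise ValidationError("need peak sets from at least two enzymes")
    members: list[tuple[int, str]] = []
    for enzyme, peaks in peaksets.items():
        for p in peaks:
            length = p.length if isinstance(p, Peak) else int(p)
            members.append((length, enzyme))
    members.sort()
    candidates: list[tuple[int, list[str]]] = []
    cluster: list[tuple[int, str]] = []

    def _flush() -> None:
        enzymes = sorted({e for _, e in cluster})
        if len(enzymes) >= 2:
            length = int(round(statistics.median([L for L, _ in cluster])))
            candidates.append((length, enzymes))

    for item in members:
        if cluster and item[0] - cluster[-1][0] > tolerance_bp:
            _flush()
            cluster = []
        cluster.append(item)
    if cluster:
        _flush()
    candidates.sort(key=lambda c: (-len(c[1]), c[0]))
    return candidates


def plot_distribution(
    dist: FragmentDistribution,
    path,
    min_length: int = 1,
    max_length: int = 2000,
    ordinate: str = "count",
) -> None:
    """Write a PNG histogram of the distribution diagram (1 bp bins)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lengths = np.arange(min_length, max_length + 1)
    if ordinate == "count":
        values = np.array([dist.counts.get(int(L), 0) for L in lengths])
    elif ordinate == "mass":
        values = np.array([dist.mass(int(L)) for L in lengths])
    else:
        raise ValidationError("ordinate must be 'count' or 'mass'")
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.fill_between(lengths, values, step="mid", lw=0.5)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel(f"fragment {ordinate}")
    ax.set_title(f"In silico digestion: {dist.enzyme}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
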