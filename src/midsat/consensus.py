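"""IUPAC consensus monomers, restriction-site maps and percent identity.

A consensus monomer summarises a stack of aligned repeat units column by
column with IUPAC ambiguity codes: a base appearing in at least 25% of units
enters the column's code set, unless one base alone reaches 75%, in which case
the column is that base.  A 50/50 G/C column therefore becomes S, A/T becomes
W, A/C becomes M — exactly the codes that appear in published satellite
consensi.

Because interior units of a head-to-tail array are effectively circular, the
restriction map of a monomer is computed on the circularised sequence: the
sites of an enzyme split the monomer into fragments whose lengths sum to the
monomer length (e.g. two Kzo9I/GATC sites 36 bp apart on a 154 bp monomer
predict 36 + 118 bp digestion fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from Bio.Align import PairwiseAligner, substitution_matrices

from .enzymes import (
    IUPAC_SETS,
    SET_TO_CODE,
    Enzyme,
    iupac_compatible,
    reverse_complement,
)
from .errors import ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

ALIGN_ALPHABET = "ACGTRYSWKMBDHVN"


@lru_cache(maxsize=None)
def _iupac_matrix() -> substitution_matrices.Array:
    """+1 for IUPAC-compatible character pairs, -1 otherwise."""
    m = substitution_matrices.Array(alphabet=ALIGN_ALPHABET, dims=2)
    for a in ALIGN_ALPHABET:
        for b in ALIGN_ALPHABET:
            m[a, b] = 1.0 if IUPAC_SETS[a] & IUPAC_SETS[b] else -1.0
    return m


def make_aligner(mode: str = "global", gap: float = -2.0) -> PairwiseAligner:
    """Pairwise aligner with IUPAC-aware +1/-1 scoring and linear gap cost."""
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _iupac_matrix()
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def profile_to_code(freqs: np.ndarray, inclusion: float = 0.25,
                    majority: float = 0.75) -> str:
    """IUPAC code for one consensus column given A/C/G/T frequencies."""
    total = freqs.sum()
    if total <= 0:
        return "N"
    norm = freqs / total
    top = int(np.argmax(norm))
    if norm[top] >= majority:
        return BASES[top]
    included = frozenset(BASES[i] for i in range(4) if norm[i] >= inclusion)
    if not included:
        included = frozenset([BASES[top]])
    return SET_TO_CODE[included]


@dataclass
class ConsensusUnit:
    """An IUPAC-coded monomer consensus with per-column base frequencies."""

    sequence: str
    column_profiles: np.ndarray  # shape (length, 4), A/C/G/T counts or weights

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, sequence: str) -> "ConsensusUnit":
        """Wrap a plain (possibly degenerate) sequence as a consensus.

        Ambiguity codes contribute fractional weight over their expansion set.
        """
        profiles = np.zeros((len(sequence), 4))
        for i, c in enumerate(sequence):
            exp = IUPAC_SETS.get(c)
            if exp is None:
                raise ValidationError(f"non-IUPAC character {c!r} in consensus")
            for b in exp:
                profiles[i, _BASE_INDEX[b]] = 1.0 / len(exp)
        return cls(sequence=sequence, column_profiles=profiles)


def build_consensus(units: list[str], inclusion: float = 0.25,
                    majority: float = 0.75,
                    max_gap_fraction: float = 0.5) -> ConsensusUnit:
    """Column-wise IUPAC consensus of pre-aligned, equal-length unit strings.

    ``units`` may contain '-' gap characters; a column whose gap fraction
    exceeds ``max_gap_fraction`` is dropped.  Degenerate characters in the
    input contribute fractional weight over their expansion set, so a
    consensus of consensi is well defined.
    """
    if len(units) < 2:
        raise ValidationError("need at least two units to build a consensus")
    lengths = {len(u) for u in units}
    if len(lengths) != 1:
        raise ValidationError("units must be pre-aligned to equal length")
    n_cols = lengths.pop()
    n_units = len(units)
    seq_chars: list[str] = []
    kept_profiles: list[np.ndarray] = []
    for j in range(n_cols):
        freqs = np.zeros(4)
        gaps = 0
        for u in units:
            c = u[j]
            if c == "-":
                gaps += 1
                continue
            exp = IUPAC_SETS.get(c)
            if exp is None:
                raise ValidationError(f"invalid character {c!r} in unit column {j}")
            w = 1.0 / len(exp)
            for b in exp:
                freqs[_BASE_INDEX[b]] += w
        if gaps / n_units > max_gap_fraction:
            continue
        seq_chars.append(profile_to_code(freqs, inclusion, majority))
        kept_profiles.append(freqs)
    if not seq_chars:
        raise ValidationError("all columns were gap-dominated")
    return ConsensusUnit("".join(seq_chars), np.array(kept_profiles))


@dataclass
class SiteMap:
    """Restriction sites and predicted circular fragments on a monomer."""

    consensus: ConsensusUnit
    sites: dict[str, list[int]] = field(default_factory=dict)
    fragments: dict[str, list[int]] = field(default_factory=dict)

    def is_uncut(self, enzyme_name: str) -> bool:
        return not self.sites.get(enzyme_name)


def _circular_site_starts(sequence: str, enzyme: Enzyme) -> list[int]:
    """Site start positions on the circularised monomer (IUPAC vs IUPAC)."""
    L = len(sequence)
    rec = enzyme.recognition
    patterns = [rec] if enzyme.is_palindromic else [rec, reverse_complement(rec)]
    extended = sequence + sequence[: len(rec) - 1]
    starts: set[int] = set()
    for pat in patterns:
        for i in range(L):
            if all(iupac_compatible(pat[j], extended[i + j]) for j in range(len(pat))):
                starts.add(i)
    return sorted(starts)


def map_sites(consensus: ConsensusUnit, enzymes: list[Enzyme]) -> SiteMap:
    """Locate enzyme sites on the circularised monomer and predict fragments.

    Matching uses intersection semantics (the expansion sets of the pattern
    character and the — possibly degenerate — consensus character must
    intersect).  Predicted fragments are the circular gaps between successive
    cut positions; with one site the whole monomer length is returned, with no
    sites the fragment list is empty and the monomer is flagged uncut.
    """
    sm = SiteMap(consensus=consensus)
    L = consensus.length
    for enzyme in enzymes:
        starts = _circular_site_starts(consensus.sequence, enzyme)
        sm.sites[enzyme.name] = starts
        cuts = sorted({(s + enzyme.cut_offset) % L for s in starts})
        if not cuts:
            sm.fragments[enzyme.name] = []
        elif len(cuts) == 1:
            sm.fragments[enzyme.name] = [L]
        else:
            gaps = [b - a for a, b in zip(cuts, cuts[1:])]
            gaps.append(L - cuts[-1] + cuts[0])
            sm.fragments[enzyme.name] = sorted(gaps)
    return sm


def percent_identity(a: str, b: str, gap: float = -2.0) -> float:
    """Global-alignment percent identity of two (possibly degenerate) strings.

    Scoring: match +1, mismatch -1, gap -2; identity is IUPAC-compatible
    matches over alignment columns, in percent.
    """
    if not a or not b:
        raise ValidationError("percent_identity requires non-empty sequences")
    aligner = make_aligner("global", gap)
    alignment = aligner.align(a, b)[0]
    ga, gb = alignment[0], alignment[1]
    matches = sum(
        1
        for x, y in zip(ga, gb)
        if x != "-" and y != "-" and iupac_compatible(x, y)
    )
    return 100.0 * matches / alignment.length
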