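"""Restriction enzymes and IUPAC degenerate-site semantics.

A restriction enzyme is modelled as a named IUPAC recognition sequence plus the
0-based position of the top-strand cut within that site (REBASE style, e.g.
HpaII C^CGG has ``cut_offset=1``).  The built-in panel covers the enzymes used
for medium-sized tandem-repeat discovery in *Drosophila*: MspI/HpaII, RsaI,
FatI, Kzo9I, AluI/AluBI, AspS9I and Bme18I — all palindromic under IUPAC
expansion, so double-strand recognition reduces to a top-strand scan.

Degenerate-base semantics: a pattern character matches a genome base iff the
base is in the character's expansion set.  A genome letter ``N`` (assembly
gap / unknown base) matches **nothing**, including pattern ``N`` — this keeps
N-runs in draft assemblies from fabricating recognition sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import FormatError, ValidationError

#: Expansion sets of the 15 IUPAC nucleotide codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: expansion set -> IUPAC code.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

GENOME_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC codes included."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValidationError(f"non-IUPAC character in sequence: {exc}") from exc


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff ``base`` is in the expansion set of ``pattern_char``.

    ``base`` must be one of A/C/G/T/N; genome N matches no pattern character.
    """
    if pattern_char not in IUPAC_SETS:
        raise ValidationError(f"invalid IUPAC pattern character: {pattern_char!r}")
    if base not in GENOME_ALPHABET:
        raise ValidationError(f"invalid genome base: {base!r}")
    if base == "N":
        return False
    return base in IUPAC_SETS[pattern_char]


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the expansion sets of two IUPAC characters intersect.

    Used when both strings may be degenerate (e.g. an enzyme pattern scanned
    against an IUPAC consensus monomer).
    """
    if a not in IUPAC_SETS or b not in IUPAC_SETS:
        raise ValidationError(f"invalid IUPAC character in pair ({a!r}, {b!r})")
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def is_palindromic(recognition: str) -> bool:
    """Whether a recognition sequence equals its IUPAC reverse complement."""
    return recognition == reverse_complement(recognition)


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site plus top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int
    is_palindromic: bool = field(default=None)  # derived in __post_init__

    def __post_init__(self) -> None:
        rec = self.recognition
        if not rec or any(c not in IUPAC_SETS for c in rec):
            raise ValidationError(
                f"{self.name}: recognition {rec!r} contains non-IUPAC characters"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise ValidationError(
                f"{self.name}: cut_offset {self.cut_offset} outside [0, {len(rec)}]"
            )
        derived = is_palindromic(rec)
        if self.is_palindromic is None:
            object.__setattr__(self, "is_palindromic", derived)
        elif self.is_palindromic != derived:
            raise ValidationError(
                f"{self.name}: is_palindromic={self.is_palindromic} but derived "
                f"value is {derived}"
            )

    def __len__(self) -> int:
        return len(self.recognition)


def _parse_table(lines, origin: str) -> dict[str, Enzyme]:
    enzymes: dict[str, Enzyme] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(
                f"{origin}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        name, recognition, offset_s = fields
        try:
            offset = int(offset_s)
        except ValueError:
            raise FormatError(
                f"{origin}:{lineno}: cut_offset {offset_s!r} is not an integer"
            ) from None
        if name in enzymes:
            raise FormatError(f"{origin}:{lineno}: duplicate enzyme name {name!r}")
        try:
            enzymes[name] = Enzyme(name, recognition.upper(), offset)
        except ValidationError as exc:
            raise ValidationError(f"{origin}:{lineno}: {exc}") from exc
    if not enzymes:
        raise FormatError(f"{origin}: no enzyme rows found")
    return enzymes


def load_enzyme_table(source: str | Path | None = None) -> dict[str, Enzyme]:
    """Load an enzyme table, keyed by name.

    With no ``source`` the built-in panel shipped with the package is returned;
    otherwise ``source`` is a TSV with columns ``name  recognition  cut_offset``
    ('#' comments allowed).
    """
    if source is None:
        text = (resources.files("midsat") / "data" / "enzymes.tsv").read_text()
        return _parse_table(text.splitlines(), "builtin enzyme table")
    path = Path(source)
    return _parse_table(path.read_text().splitlines(), str(path))
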