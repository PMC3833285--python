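"""Seeded synthetic genomes with planted tandem arrays and truncated remnants.

Every pipeline stage is testable without downloads: the generator plants
head-to-tail tandem arrays (optionally mutated copy by copy), interspersed
5'-truncated copies of a unit (transposon-remnant style) and records every
planted feature as a ground-truth interval.  Identical specs (same seed)
produce byte-identical output.

Noise model: substitutions are uniform over the three alternative bases;
indels are single-base with equal insertion/deletion probability.  IUPAC
ambiguity codes in a planted unit are resolved independently per copy,
uniformly over the code's expansion set, so polymorphic consensus columns are
reproduced in the planted copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import IUPAC_SETS, iupac_match
from .errors import PlacementError, ValidationError
from .genome_io import Genome, Interval

BASES = "ACGT"

#: Published consensus of the 172 bp tandem-repeat family clustered near the
#: *apterous* gene of *Drosophila virilis* (IUPAC codes mark polymorphic
#: columns).  Used by :func:`make_paper_like_genome` as a realistic degenerate
#: planted unit.
APTEROUS_CONSENSUS_172 = (
    "TACCATSAAATATCCTACATAGACATAGGTCGAAAATTCCCAACCCCATAACTCGGCCAAAACTCAACCG"
    "ATTTTCATAAGGTWTAMMTTTTTGTTCATGGTTTGACCTCWATATCAATCTGGCATATAAATCTGACAAC"
    "TTTATTTTTGGTCAAAATTCATGTGAAAATGG"
)

#: Recognition patterns whose placement is controlled when building clean units.
_PANEL_PATTERNS = ("CCGG", "GTAC", "CATG", "GATC", "AGCT", "GGNCC", "GGWCC")


@dataclass
class ArraySpec:
    """One planted head-to-tail tandem array."""

    unit: str | None = None          # explicit unit (IUPAC allowed) ...
    period: int | None = None        # ... or a random unit of this length
    copies: int = 10
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    label: str = "array"

    def __post_init__(self) -> None:
        if (self.unit is None) == (self.period is None):
            raise ValidationError("ArraySpec needs exactly one of unit/period")
        if self.copies < 1:
            raise ValidationError("copies must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 0.25:
                raise ValidationError("mutation rates must be in [0, 0.25]")


@dataclass
class RemnantSpec:
    """Interspersed 5'-prefix copies of a unit stack (truncated-copy style)."""

    unit: str
    keep_fraction: float = 0.6
    copies: int = 1
    substitution_rate: float = 0.0
    label: str = "remnant"

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValidationError("keep_fraction must be in (0, 1]")
        if self.copies < 1:
            raise ValidationError("copies must be >= 1")


@dataclass
class SynthSpec:
    """A reproducible synthetic scaffold: background plus planted features."""

    seed: int
    background_length: int
    gc_content: float = 0.4
    arrays: list[ArraySpec] = field(default_factory=list)
    remnants: list[RemnantSpec] = field(default_factory=list)
    scaffold_id: str = "synth1"
    min_separation: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValidationError("gc_content must be in (0, 1)")
        if self.background_length < 1:
            raise ValidationError("background_length must be positive")
        for a in self.arrays:
            period = a.period if a.period is not None else len(a.unit)
            if not 1 <= period <= self.background_length:
                raise ValidationError("array period outside [1, background_length]")


def random_background(rng: np.random.Generator, length: int,
                      gc_content: float = 0.4) -> str:
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    draws = rng.choice(list("ACGT"), size=length,
                       p=[p_at, p_gc, p_gc, p_at])
    return "".join(draws)


def resolve_iupac(unit: str, rng: np.random.Generator) -> str:
    """Resolve ambiguity codes uniformly over their expansion sets."""
    out = []
    for c in unit:
        if c in BASES:
            out.append(c)
        else:
            exp = IUPAC_SETS.get(c)
            if not exp:
                raise ValidationError(f"invalid unit character {c!r}")
            out.append(sorted(exp)[rng.integers(len(exp))])
    return "".join(out)


def mutate(seq: str, substitution_rate: float, indel_rate: float,
           rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions then single-base indels."""
    chars = list(seq)
    if substitution_rate > 0:
        mask = rng.random(len(chars)) < substitution_rate
        for i in np.nonzero(mask)[0]:
            alternatives = [b for b in BASES if b != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
    if indel_rate > 0:
        out: list[str] = []
        for c in chars:
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(c)
                out.append(BASES[rng.integers(4)])  # insertion after
            else:
                out.append(c)
        chars = out
    return "".join(chars)


def _build_array(spec: ArraySpec, rng: np.random.Generator) -> str:
    if spec.unit is not None:
        base_unit = spec.unit.upper()
    else:
        base_unit = random_background(rng, spec.period, 0.5)
    copies = []
    for _ in range(spec.copies):
        copy = resolve_iupac(base_unit, rng)
        copies.append(mutate(copy, spec.substitution_rate, spec.indel_rate, rng))
    return "".join(copies)


def generate(spec: SynthSpec) -> tuple[Genome, list[Interval]]:
    """Build the synthetic scaffold and its planted-truth intervals (BED6-style)."""
    rng = np.random.default_rng(spec.seed)
    background = random_background(rng, spec.background_length, spec.gc_content)

    features: list[tuple[str, str]] = []
    for a in spec.arrays:
        period = a.period if a.period is not None else len(a.unit)
        name = (f"{a.label};period={period};copies={a.copies};"
                f"sub={a.substitution_rate};indel={a.indel_rate}")
        features.append((_build_array(a, rng), name))
    for r in spec.remnants:
        kept = max(1, int(round(len(r.unit) * r.keep_fraction)))
        for _ in range(r.copies):
            seq = mutate(resolve_iupac(r.unit[:kept], rng),
                         r.substitution_rate, 0.0, rng)
            features.append((seq, f"{r.label};kept={kept}"))

    n = len(features)
    positions = _place(rng, n, spec.background_length, spec.min_separation)
    order = rng.permutation(n)
    scaffold_parts: list[str] = []
    truth: list[Interval] = []
    cursor = 0
    offset = 0
    for point, idx in zip(positions, order):
        seq, name = features[idx]
        scaffold_parts.append(background[cursor:point])
        gstart = point + offset
        scaffold_parts.append(seq)
        truth.append((spec.scaffold_id, gstart, gstart + len(seq), name, 0, "+"))
        offset += len(seq)
        cursor = point
    scaffold_parts.append(background[cursor:])
    genome = Genome()
    genome.add(spec.scaffold_id, "".join(scaffold_parts))
    truth.sort(key=lambda t: t[1])
    return genome, truth


def _place(rng: np.random.Generator, n: int, background_length: int,
           min_separation: int) -> list[int]:
    if n == 0:
        return []
    if (n + 1) * min_separation >= background_length:
        raise PlacementError(
            f"cannot place {n} features {min_separation} bp apart in a "
            f"{background_length} bp background; enlarge the background"
        )
    for _ in range(200):
        pts = np.sort(rng.integers(min_separation,
                                   background_length - min_separation + 1, n))
        if n == 1 or np.diff(pts).min() >= min_separation:
            return pts.tolist()
    raise PlacementError(
        "could not place features without overlap; enlarge the background"
    )


# ---------------------------------------------------------------------------
# clean unit construction

def _pattern_occurrences(circular_seq: str, unit_len: int) -> list[tuple[str, int]]:
    """(pattern, start) for every panel-pattern occurrence on the circular unit."""
    hits = []
    for pat in _PANEL_PATTERNS:
        for i in range(unit_len):
            window = circular_seq[i : i + len(pat)]
            if len(window) == len(pat) and all(
                iupac_match(p, b) for p, b in zip(pat, window)
            ):
                hits.append((pat, i))
    return hits


def make_clean_unit(rng: np.random.Generator, length: int,
                    sites: list[tuple[str, int]],
                    max_rounds: int = 500) -> str:
    """A random unit carrying exactly the requested recognition sites.

    ``sites`` lists (motif, position) to implant; every other panel-pattern
    occurrence — checked circularly, i.e. across the head-to-tail junction —
    is scrubbed by re-randomising a base outside the implanted ranges.
    """
    implanted_ranges = [(pos, pos + len(motif)) for motif, pos in sites]
    implanted_keys = {(motif, pos) for motif, pos in sites}

    def _implant(chars: list[str]) -> None:
        for motif, pos in sites:
            chars[pos : pos + len(motif)] = list(motif)

    chars = list(random_background(rng, length, 0.5))
    _implant(chars)
    for _ in range(max_rounds):
        circ = "".join(chars) + "".join(chars[:6])
        extra = [
            (pat, i)
            for pat, i in _pattern_occurrences(circ, length)
            if (pat, i) not in implanted_keys
        ]
        # implanted CATG/GATC etc. may legitimately double as another pattern
        # only via overlap; anything overlapping an implant entirely is fatal
        extra = [
            (pat, i)
            for pat, i in extra
            if not any(lo <= i and i + len(pat) <= hi for lo, hi in implanted_ranges)
        ]
        if not extra:
            expected = {(motif, pos) for motif, pos in sites}
            found = set(_pattern_occurrences(circ, length))
            if expected <= found:
                return "".join(chars)
        pat, i = extra[0] if extra else (None, None)
        if pat is None:
            # implant destroyed: rebuild from scratch
            chars = list(random_background(rng, length, 0.5))
            _implant(chars)
            continue
        free = [
            (i + j) % length
            for j in range(len(pat))
            if not any(lo <= (i + j) % length < hi for lo, hi in implanted_ranges)
        ]
        if not free:
            chars = list(random_background(rng, length, 0.5))
            _implant(chars)
            continue
        j = free[rng.integers(len(free))]
        chars[j] = BASES[rng.integers(4)]
        _implant(chars)
    raise ValidationError("could not construct a clean unit; relax the site layout")


# ---------------------------------------------------------------------------
# the three-family fixture

def make_paper_like_genome(seed: int) -> tuple[Genome, list[Interval]]:
    """~2 Mb two-scaffold fixture with three planted repeat families.

    * 225 bp unit: one CCGG (HpaII/MspI), one GTAC (RsaI), two CATG (FatI);
      low divergence, so digestion gives a sharp 225 bp peak.
    * 154 bp unit: two GATC (Kzo9I) sites placed 36 bp apart circularly plus
      one AGCT (AluI); a sub-family carries only the first GATC (single base
      change), so Kzo9I yields 36 + 118 bp fragments and residual intact
      154 bp fragments, while AluI yields 154 bp.  Truncated 5' remnants of
      this unit are interspersed outside arrays.
    * 172 bp unit: the published degenerate consensus, planted at 8-10%
      substitution plus 1% indels; high divergence keeps it out of the
      digestion diagrams while the tandem census still shows it.
    """
    rng = np.random.default_rng(seed)
    u225 = make_clean_unit(rng, 225, [("CCGG", 20), ("GTAC", 80),
                                      ("CATG", 130), ("CATG", 190)])
    u154 = make_clean_unit(rng, 154, [("GATC", 10), ("GATC", 46), ("AGCT", 100)])
    # sub-family with the second Kzo9I site destroyed by one substitution
    u154b = u154[:46] + "AATC" + u154[50:]

    def _copies(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    fam225 = [ArraySpec(unit=u225, copies=_copies(20, 35),
                        substitution_rate=0.01, label="fam225")
              for _ in range(15)]
    fam154a = [ArraySpec(unit=u154, copies=_copies(20, 40),
                         substitution_rate=0.008, label="fam154")
               for _ in range(14)]
    fam154b = [ArraySpec(unit=u154b, copies=_copies(20, 35),
                         substitution_rate=0.008, label="fam154single")
               for _ in range(8)]
    fam172 = [ArraySpec(unit=APTEROUS_CONSENSUS_172, copies=_copies(18, 30),
                        substitution_rate=float(rng.uniform(0.08, 0.10)),
                        indel_rate=0.01, label="fam172")
              for _ in range(15)]
    pool = fam225 + fam154a + fam154b + fam172
    all_arrays = [pool[i] for i in rng.permutation(len(pool))]
    half = len(all_arrays) // 2

    genome = Genome()
    truth: list[Interval] = []
    for sid, arrays, n_remnants in (
        ("scf1", all_arrays[:half], 15),
        ("scf2", all_arrays[half:], 15),
    ):
        spec = SynthSpec(
            seed=int(rng.integers(2**31)),
            background_length=1_000_000,
            gc_content=0.4,
            arrays=arrays,
            remnants=[RemnantSpec(unit=u154, keep_fraction=0.6,
                                  copies=n_remnants, substitution_rate=0.02,
                                  label="helitron_remnant")],
            scaffold_id=sid,
            min_separation=1500,
        )
        part, part_truth = generate(spec)
        genome.add(sid, part[sid])
        truth.extend(part_truth)
    return genome, truth
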