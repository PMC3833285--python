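"""Detection of medium-sized tandem arrays (40-500 bp units) and their census.

The scanner is a purpose-built k-mer-lag detector: positions whose k-mer
recurs at a lag d within the period range are seed matches; seed matches with
compatible lag that fall close together are clustered into candidate arrays;
candidates are verified by walking unit boundaries with an approximate
matcher (edlib) and aligning adjacent units globally.  An array is reported
with its period (median segmented unit length), fractional copy number, mean
adjacent-unit identity and a per-array IUPAC consensus.

This is deliberately not a reimplementation of Tandem Repeats Finder's
probabilistic model; it is validated by planted-truth recovery on synthetic
genomes rather than by matching any particular TRF parameterisation.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .consensus import (
    _BASE_INDEX,
    ConsensusUnit,
    build_consensus,
    make_aligner,
    percent_identity,
    profile_to_code,
)
from .enzymes import iupac_compatible
from .errors import ValidationError
from .genome_io import Genome


@dataclass
class TandemArray:
    """A detected head-to-tail repeat array on one scaffold."""

    scaffold: str
    start: int
    end: int
    period: int
    copy_number: float
    mean_adjacent_identity: float
    array_consensus: str
    n_units: int
    column_profiles: np.ndarray = field(repr=False, default=None)

    @property
    def score(self) -> float:
        """Ranking score for overlap resolution."""
        return self.copy_number * self.mean_adjacent_identity


# ---------------------------------------------------------------------------
# seeding

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _seed_matches(seq: str, min_period: int, max_period: int, k: int):
    """(position, lag) pairs where the k-mer at ``position`` recurs ``lag``
    bases upstream, min_period <= lag <= max_period.

    Only consecutive occurrences of each k-mer are paired, so within a clean
    tandem array the reported lag is the repeat period itself.
    """
    n = len(seq)
    if n < k + min_period:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    # polynomial k-mer codes; windows containing N are invalidated
    acc = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        acc = acc * 4 + np.where(valid[j : n - k + 1 + j], codes[j : n - k + 1 + j], 0)
        ok &= valid[j : n - k + 1 + j]
    acc[~ok] = -1
    positions = np.nonzero(ok)[0]
    if positions.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    kmers = acc[positions]
    order = np.argsort(kmers, kind="stable")  # stable => positions ascending
    sk, sp = kmers[order], positions[order]
    same = sk[1:] == sk[:-1]
    lags = sp[1:] - sp[:-1]
    mask = same & (lags >= min_period) & (lags <= max_period)
    return sp[1:][mask], lags[mask]


def _cluster_seeds(pos: np.ndarray, lag: np.ndarray, max_period: int, k: int,
                   min_copies: int):
    """Group seed matches into candidate regions (start, end, period estimate)."""
    order = np.argsort(pos, kind="stable")
    pos, lag = pos[order], lag[order]
    active: list[dict] = []
    closed: list[dict] = []
    for p, d in zip(pos.tolist(), lag.tolist()):
        keep = []
        for c in active:
            (closed if p - c["last"] > max_period + 64 else keep).append(c)
        active = keep
        best = None
        for c in active:
            tol = max(3, int(0.08 * c["d0"]))
            if abs(d - c["d0"]) <= tol and p - c["last"] <= c["d0"] + 64:
                if best is None or abs(d - c["d0"]) < abs(d - best["d0"]):
                    best = c
        if best is None:
            active.append({"d0": d, "lags": [d], "pmin": p, "pmax": p, "last": p})
        else:
            best["lags"].append(d)
            best["pmax"] = p
            best["last"] = p
    closed.extend(active)
    candidates = []
    for c in closed:
        if len(c["lags"]) < 2:
            continue
        period = int(round(statistics.median(c["lags"])))
        start = max(0, c["pmin"] - period)
        end = c["pmax"] + k
        if end - start < 0.8 * min_copies * period:
            continue
        candidates.append((start, end, period))
    return candidates


# ---------------------------------------------------------------------------
# verification

def _edge_extend(seq: str, start: int, end: int, period: int) -> tuple[int, int]:
    """Extend array bounds by partial-unit homology with the adjacent copy."""
    j, mism, best = 0, 0, 0
    while start - j - 1 >= 0 and j < period:
        if seq[start - j - 1] != seq[start - j - 1 + period]:
            mism += 1
        j += 1
        if mism > max(2.0, 0.25 * j):
            break
        if seq[start - j] == seq[start - j + period]:
            best = j
    start -= best
    j, mism, best = 0, 0, 0
    n = len(seq)
    while end + j < n and j < period:
        if seq[end + j] != seq[end + j - period]:
            mism += 1
        j += 1
        if mism > max(2.0, 0.25 * j):
            break
        if seq[end + j - 1] == seq[end + j - 1 - period]:
            best = j
    return start, end + best


def _segment_units(seq: str, cand_start: int, cand_end: int, period: int,
                   min_identity: float) -> list[int] | None:
    """Walk unit boundaries left and right from the candidate start.

    Uses an anchor unit as template and locates each successive copy with an
    infix (edlib HW) alignment inside a slack window, which keeps boundaries
    in phase in the presence of small indels.  Returns boundary positions.
    """
    n = len(seq)
    d = period
    s0 = min(max(0, cand_start), n - d)
    template = seq[s0 : s0 + d]
    if len(template) < d or "N" in template:
        return None
    max_ed = int((1.0 - min_identity / 100.0) * d * 1.2) + 1
    slack = max(8, int(0.12 * d))

    def _locate(exp: int) -> int | None:
        lo = max(0, exp - slack)
        hi = min(n, exp + slack + d)
        if hi - lo < d - slack:
            return None
        res = edlib.align(template, seq[lo:hi], mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_ed:
            return None
        st = lo + res["locations"][0][0]
        if abs(st - exp) > slack:
            return None
        return st

    bounds = [s0]
    exp = s0 + d
    while bounds[-1] + d <= cand_end + slack:
        st = _locate(exp)
        if st is None or st <= bounds[-1] + d // 2:
            break
        bounds.append(st)
        exp = st + d
    exp = bounds[0] - d
    while exp >= -slack:
        st = _locate(exp)
        if st is None or st >= bounds[0] - d // 2:
            break
        bounds.insert(0, st)
        exp = st - d
    return bounds


def _stack_profile(units: list[str], period: int) -> np.ndarray:
    """Column base counts of units projected onto the first unit's coordinates."""
    profile = np.zeros((period, 4))
    template = units[0][:period]
    aligner = make_aligner("global")
    for u in units:
        if len(u) == period:
            for i, c in enumerate(u):
                idx = _BASE_INDEX.get(c)
                if idx is not None:
                    profile[i, idx] += 1.0
            continue
        aln = aligner.align(template, u)[0]
        tblocks, qblocks = aln.aligned
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            for off in range(te - ts):
                idx = _BASE_INDEX.get(u[qs + off])
                if idx is not None:
                    profile[ts + off, idx] += 1.0
    return profile


def _verify_candidate(seq: str, scaffold: str, cand, min_period: int,
                      max_period: int, min_copies: int,
                      min_identity: float) -> TandemArray | None:
    cand_start, cand_end, period_est = cand
    bounds = _segment_units(seq, cand_start, cand_end, period_est, min_identity)
    if bounds is None or len(bounds) < 2:
        return None
    end_full = min(len(seq), bounds[-1] + period_est)
    units = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
    units.append(seq[bounds[-1] : end_full])
    # trim terminal units that no longer resemble their neighbour
    idents = [percent_identity(a, b) for a, b in zip(units, units[1:])]
    while idents and idents[0] < min_identity:
        units.pop(0)
        bounds.pop(0)
        idents.pop(0)
    while idents and idents[-1] < min_identity:
        units.pop()
        idents.pop()
        end_full = bounds[len(units) - 1] + len(units[-1]) if units else end_full
    if len(units) < min_copies or not idents:
        return None
    mean_ident = float(np.mean(idents))
    if mean_ident < min_identity:
        return None
    period = int(round(statistics.median([len(u) for u in units])))
    if not min_period <= period <= max_period:
        return None
    start = bounds[0]
    end = bounds[0] + sum(len(u) for u in units)
    start, end = _edge_extend(seq, start, end, period)
    if end - start < 0.8 * min_copies * period:
        return None
    profile = _stack_profile(units, period)
    cons = "".join(profile_to_code(profile[i]) for i in range(period))
    return TandemArray(
        scaffold=scaffold,
        start=start,
        end=end,
        period=period,
        copy_number=round((end - start) / period, 2),
        mean_adjacent_identity=round(mean_ident, 2),
        array_consensus=cons,
        n_units=len(units),
        column_profiles=profile,
    )


def _resolve_overlaps(arrays: list[TandemArray]) -> list[TandemArray]:
    """Greedy selection by copy_number x identity; ties go leftmost."""
    chosen: dict[str, list[TandemArray]] = {}
    out: list[TandemArray] = []
    for arr in sorted(arrays, key=lambda a: (-a.score, a.start)):
        taken = chosen.setdefault(arr.scaffold, [])
        if any(arr.start < t.end and t.start < arr.end for t in taken):
            continue
        taken.append(arr)
        out.append(arr)
    out.sort(key=lambda a: (a.scaffold, a.start))
    return out


def scan_tandem_arrays(
    genome: Genome,
    min_period: int = 40,
    max_period: int = 500,
    min_copies: int = 3,
    min_identity: float = 75.0,
    k: int = 12,
) -> list[TandemArray]:
    """Scan every scaffold for tandem arrays with unit length in the period range.

    Returns maximal non-overlapping arrays with at least ``min_copies`` copies
    and mean adjacent-unit identity of at least ``min_identity`` percent.
    """
    if min(min_period, max_period, min_copies, k) <= 0:
        raise ValidationError("scan parameters must be positive")
    if min_period < k:
        raise ValidationError(f"min_period ({min_period}) must be >= k ({k})")
    if max_period < min_period:
        raise ValidationError("max_period must be >= min_period")
    arrays: list[TandemArray] = []
    for scaffold, seq in genome:
        pos, lag = _seed_matches(seq, min_period, max_period, k)
        for cand in _cluster_seeds(pos, lag, max_period, k, min_copies):
            arr = _verify_candidate(
                seq, scaffold, cand, min_period, max_period, min_copies,
                min_identity,
            )
            if arr is not None:
                arrays.append(arr)
    return _resolve_overlaps(arrays)


# ---------------------------------------------------------------------------
# census and pooled consensus

def census(arrays: list[TandemArray],
           bins: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Per-period census of repeat units and clusters.

    With ``bins=None`` each observed period is its own bin; otherwise each
    (lo, hi) range (inclusive) pools the arrays whose period falls inside.
    ``unit_count`` sums round(copy_number) over member arrays; ``cluster_count``
    is the number of member arrays.
    """
    columns = ["bin", "period_lo", "period_hi", "unit_count", "cluster_count"]
    rows = []
    if bins is None:
        periods = sorted({a.period for a in arrays})
        bins = [(p, p) for p in periods]
        labels = [str(p) for p in periods]
    else:
        labels = [f"{lo}-{hi}" if lo != hi else str(lo) for lo, hi in bins]
    for (lo, hi), label in zip(bins, labels):
        members = [a for a in arrays if lo <= a.period <= hi]
        rows.append(
            {
                "bin": label,
                "period_lo": lo,
                "period_hi": hi,
                "unit_count": int(sum(round(a.copy_number) for a in members)),
                "cluster_count": len(members),
            }
        )
    return pd.DataFrame(rows, columns=columns).set_index("bin")


def _best_rotation(ref: str, other: str) -> int:
    """Circular offset of ``other`` maximising IUPAC-compatible matches to ``ref``."""
    L = min(len(ref), len(other))
    best_r, best_m = 0, -1
    doubled = other + other
    for r in range(len(other)):
        m = sum(
            1 for j in range(L) if iupac_compatible(ref[j], doubled[r + j])
        )
        if m > best_m:
            best_r, best_m = r, m
    return best_r


def pool_consensus(arrays: list[TandemArray],
                   period_range: tuple[int, int]) -> ConsensusUnit:
    """Assemble one consensus from the per-array consensi in a period range.

    Each array's consensus is rotated to the circular offset that best matches
    the first array's consensus, projected onto its columns by global
    alignment where lengths differ, and the stack is condensed column-wise
    into IUPAC codes.
    """
    lo, hi = period_range
    sel = [a for a in arrays if lo <= a.period <= hi]
    if not sel:
        raise ValidationError(f"no arrays with period in [{lo}, {hi}]")
    if len(sel) == 1:
        return ConsensusUnit(sel[0].array_consensus, sel[0].column_profiles)
    ref = sel[0].array_consensus
    stack = [ref]
    aligner = make_aligner("global")
    for arr in sel[1:]:
        c = arr.array_consensus
        r = _best_rotation(ref, c)
        rotated = c[r:] + c[:r]
        if len(rotated) == len(ref):
            stack.append(rotated)
            continue
        aln = aligner.align(ref, rotated)[0]
        projected = ["-"] * len(ref)
        tblocks, qblocks = aln.aligned
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            for off in range(te - ts):
                projected[ts + off] = rotated[qs + off]
        stack.append("".join(projected))
    return build_consensus(stack)
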