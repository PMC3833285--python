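"""End-to-end repeat-discovery workflow and combined report.

Runs, for a genome: per-enzyme in silico digestion and peak calling,
cross-enzyme peak concordance, the tandem-array scan with per-period census,
a pooled consensus per candidate repeat family, and a restriction-site map of
each family consensus with predicted-versus-observed fragment lengths.
Outputs are a machine-readable TSV per stage plus one Markdown report; given
identical inputs and parameters the outputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import digest as dg
from . import tandem as td
from .consensus import ConsensusUnit, map_sites
from .enzymes import Enzyme, load_enzyme_table
from .errors import PipelineError
from .genome_io import Genome, read_fasta, write_intervals

logger = logging.getLogger(__name__)


@dataclass
class Family:
    """A candidate tandem-repeat family discovered by the pipeline."""

    period: int
    unit_count: int
    cluster_count: int
    consensus: ConsensusUnit
    site_fragments: dict[str, list[int]] = field(default_factory=dict)
    observed_peaks: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class PipelineResult:
    genome_bp: int
    distributions: dict[str, dg.FragmentDistribution]
    peaks: dict[str, list[dg.Peak]]
    candidates: list[tuple[int, list[str]]]
    arrays: list[td.TandemArray]
    census: pd.DataFrame
    families: list[Family]


def _family_periods(census_df: pd.DataFrame, min_units: int) -> list[int]:
    """Representative periods of census groups, pooling periods within 2 bp."""
    df = census_df.sort_values("period_lo")
    groups: list[list[tuple[int, int]]] = []
    for _, row in df.iterrows():
        p, units = int(row["period_lo"]), int(row["unit_count"])
        if groups and p - groups[-1][-1][0] <= 2:
            groups[-1].append((p, units))
        else:
            groups.append([(p, units)])
    reps = []
    for group in groups:
        total = sum(u for _, u in group)
        if total >= min_units:
            rep = max(group, key=lambda x: x[1])[0]
            reps.append((rep, total))
    reps.sort(key=lambda x: -x[1])
    return [p for p, _ in reps]


def run_pipeline(
    genome: Genome | str | Path,
    enzymes: list[str | Enzyme],
    out_dir: str | Path,
    enzyme_table: str | Path | None = None,
    peak_params: dict | None = None,
    scan_params: dict | None = None,
    peak_tolerance_bp: int = 5,
    min_family_units: int = 50,
) -> PipelineResult:
    """Run digestion, peak concordance, tandem scan and consensus site mapping.

    ``enzymes`` may mix names (resolved against the enzyme table) and Enzyme
    objects.  All stage outputs land in ``out_dir``; errors carry the stage
    name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peak_params = dict(peak_params or {})
    scan_params = dict(scan_params or {})

    try:
        if not isinstance(genome, Genome):
            genome = read_fasta(genome)
    except Exception as exc:
        raise PipelineError(f"stage=load_genome: {exc}") from exc

    try:
        table = load_enzyme_table(enzyme_table)
        enzyme_objs = [e if isinstance(e, Enzyme) else table[e] for e in enzymes]
    except KeyError as exc:
        raise PipelineError(f"stage=load_enzymes: unknown enzyme {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"stage=load_enzymes: {exc}") from exc

    distributions: dict[str, dg.FragmentDistribution] = {}
    peaks: dict[str, list[dg.Peak]] = {}
    try:
        for enzyme in enzyme_objs:
            dist = dg.digest_genome(genome, enzyme)
            dist.write_tsv(out / f"dist_{enzyme.name}.tsv")
            distributions[enzyme.name] = dist
            peaks[enzyme.name] = dg.detect_peaks(dist, **peak_params)
    except Exception as exc:
        raise PipelineError(f"stage=digest: {exc}") from exc

    try:
        candidates = (
            dg.cross_enzyme_candidates(peaks, peak_tolerance_bp)
            if len(peaks) >= 2
            else []
        )
    except Exception as exc:
        raise PipelineError(f"stage=candidates: {exc}") from exc

    try:
        arrays = td.scan_tandem_arrays(genome, **scan_params)
        census_df = td.census(arrays)
        census_df.to_csv(out / "census.tsv", sep="\t")
        write_intervals(
            [
                (a.scaffold, a.start, a.end,
                 f"period={a.period};copies={a.copy_number};"
                 f"identity={a.mean_adjacent_identity}",
                 round(a.mean_adjacent_identity), "+")
                for a in arrays
            ],
            out / "arrays.bed",
        )
    except Exception as exc:
        raise PipelineError(f"stage=scan: {exc}") from exc

    families: list[Family] = []
    try:
        for period in _family_periods(census_df, min_family_units):
            sel = [a for a in arrays if abs(a.period - period) <= 2]
            cons = td.pool_consensus(arrays, (period - 2, period + 2))
            sm = map_sites(cons, enzyme_objs)
            fam = Family(
                period=period,
                unit_count=int(sum(round(a.copy_number) for a in sel)),
                cluster_count=len(sel),
                consensus=cons,
            )
            for enzyme in enzyme_objs:
                predicted = sm.fragments[enzyme.name]
                fam.site_fragments[enzyme.name] = predicted
                fam.observed_peaks[enzyme.name] = sorted(
                    p.length
                    for p in peaks[enzyme.name]
                    if any(abs(p.length - f) <= 2 for f in predicted)
                )
            families.append(fam)
    except Exception as exc:
        raise PipelineError(f"stage=consensus: {exc}") from exc

    result = PipelineResult(
        genome_bp=genome.total_length,
        distributions=distributions,
        peaks=peaks,
        candidates=candidates,
        arrays=arrays,
        census=census_df,
        families=families,
    )
    try:
        _write_report(result, out, peak_params, scan_params)
    except Exception as exc:
        raise PipelineError(f"stage=report: {exc}") from exc
    return result


def _write_report(result: PipelineResult, out: Path,
                  peak_params: dict, scan_params: dict) -> None:
    rows = []
    for fam in result.families:
        rows.append(
            {
                "period": fam.period,
                "unit_count": fam.unit_count,
                "cluster_count": fam.cluster_count,
                "consensus": fam.consensus.sequence,
                "predicted_fragments": ";".join(
                    f"{e}:{','.join(map(str, fr)) or 'uncut'}"
                    for e, fr in fam.site_fragments.items()
                ),
                "observed_peaks": ";".join(
                    f"{e}:{','.join(map(str, ob)) or '-'}"
                    for e, ob in fam.observed_peaks.items()
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=["period", "unit_count", "cluster_count", "consensus",
                 "predicted_fragments", "observed_peaks"],
    ).to_csv(out / "families.tsv", sep="\t", index=False)

    lines = ["# midsat combined report", ""]
    lines.append(f"Genome size: {result.genome_bp} bp")
    lines.append(f"Parameters: peaks={peak_params or 'defaults'}, "
                 f"scan={scan_params or 'defaults'}")
    lines.append("")
    lines.append("## Digestion peaks per enzyme")
    for enzyme, pk in result.peaks.items():
        listed = ", ".join(f"{p.length} bp (n={p.count})" for p in pk[:8])
        lines.append(f"- **{enzyme}**: {listed or 'no distinct peaks'}")
    lines.append("")
    lines.append("## Cross-enzyme same-size candidates")
    if result.candidates:
        for length, supporters in result.candidates:
            lines.append(f"- {length} bp, supported by {', '.join(supporters)}")
    else:
        lines.append("- none")
    lines.append("")
    lines.append("## Candidate tandem-repeat families")
    if not result.families:
        lines.append("- none")
    for fam in result.families:
        lines.append(f"### {fam.period} bp family")
        lines.append(f"- units: {fam.unit_count} in {fam.cluster_count} clusters")
        lines.append(f"- consensus ({fam.consensus.length} bp): "
                     f"`{fam.consensus.sequence}`")
        for enzyme, fr in fam.site_fragments.items():
            obs = fam.observed_peaks[enzyme]
            lines.append(
                f"- {enzyme}: predicted "
                f"{', '.join(map(str, fr)) if fr else 'uncut'}"
                f" | observed peaks {', '.join(map(str, obs)) if obs else '-'}"
            )
        lines.append("")
    (out / "report.md").write_text("\n".join(lines) + "\n")
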