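"""Tiered window-based metagenomic identification and quantification.

First pass: genomes are screened on breadth of coverage (coverage rate
strictly > 40% and covered bases strictly > 500 kb by default).  Second
pass: each candidate genome is cut into 10-kb windows; unique-mapped reads
increment their window's count directly, while each multimapped read is
split across its hit genomes with weights proportional to those genomes'
unique-read support (uniform when no genome has unique support).  Windows
with extreme counts are trimmed before the per-genome mean depth, and
relative abundance normalizes mean depths across the identified genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from linkread.platform_io import BarcodedAlignment

DEFAULT_WINDOW_SIZE = 10_000
DEFAULT_MIN_COVERAGE_RATE = 0.40
DEFAULT_MIN_COVERED_BASES = 500_000
DEFAULT_TRIM_PERCENTILES = (5.0, 95.0)


class QuantificationError(RuntimeError):
    pass


@dataclass
class GenomeCoverage:
    genome_id: str
    coverage_rate: float
    covered_bases: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.covered_bases > self.genome_length:
            raise ValueError("covered_bases exceeds genome length")


@dataclass
class WindowProfile:
    genome_id: str
    window_index: int
    window_start: int  # 1-based
    l: int  # effective window size in bases (final window may be short)
    U: int
    M_contrib: float

    @property
    def rc_u(self) -> float:
        return self.U / self.l

    @property
    def rc_m(self) -> float:
        return self.M_contrib / self.l

    @property
    def rc_w(self) -> float:
        return self.rc_u + self.rc_m


def compute_genome_coverage(
    alignments: Iterable[BarcodedAlignment],
    genome_lengths: Mapping[str, int],
) -> List[GenomeCoverage]:
    """Breadth of coverage per genome from first-round primary alignments
    (multimapped reads included — screening happens before deconvolution)."""
    intervals: Dict[str, List[Tuple[int, int]]] = {g: [] for g in genome_lengths}
    for aln in alignments:
        if not aln.is_primary or aln.reference_name not in intervals:
            continue
        glen = genome_lengths[aln.reference_name]
        start = aln.position
        end = min(aln.position + aln.aligned_bases - 1, glen)
        intervals[aln.reference_name].append((start, end))

    out = []
    for genome_id, ivals in intervals.items():
        glen = genome_lengths[genome_id]
        covered = 0
        if ivals:
            ivals.sort()
            cur_s, cur_e = ivals[0]
            for s, e in ivals[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    covered += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            covered += cur_e - cur_s + 1
        out.append(
            GenomeCoverage(
                genome_id=genome_id,
                coverage_rate=covered / glen,
                covered_bases=covered,
                genome_length=glen,
            )
        )
    return out


def first_pass_filter(
    coverages: Sequence[GenomeCoverage],
    min_rate: float = DEFAULT_MIN_COVERAGE_RATE,
    min_bases: int = DEFAULT_MIN_COVERED_BASES,
) -> List[str]:
    """Candidate genomes: coverage rate > ``min_rate`` AND covered bases >
    ``min_bases`` (both strict)."""
    return [
        c.genome_id
        for c in coverages
        if c.coverage_rate > min_rate and c.covered_bases > min_bases
    ]


def multiread_weights(
    hit_genomes: Sequence[str],
    unique_counts: Mapping[str, float],
    genome_lengths: Optional[Mapping[str, int]] = None,
    mode: str = "counts",
) -> Dict[str, float]:
    """Split one multimapped read across its N hit genomes.

    ``mode="counts"`` (default): weight_j = U_j / sum_k U_k over the hit set,
    with the uniform 1/N fallback when no hit genome has unique support.
    ``mode="rates"`` divides each genome's unique count by its length first.
    Weights always sum to exactly 1.
    """
    if len(hit_genomes) < 2:
        raise ValueError("multiread weights need >= 2 hit genomes")
    if mode == "rates":
        if genome_lengths is None:
            raise ValueError("rates mode requires genome lengths")
        support = {g: unique_counts.get(g, 0.0) / genome_lengths[g] for g in hit_genomes}
    elif mode == "counts":
        support = {g: float(unique_counts.get(g, 0.0)) for g in hit_genomes}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = sum(support.values())
    n = len(hit_genomes)
    if total == 0:
        return {g: 1.0 / n for g in hit_genomes}
    return {g: support[g] / total for g in hit_genomes}


def window_counts(
    alignments: Iterable[BarcodedAlignment],
    candidate_genomes: Sequence[str],
    genome_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    weight_mode: str = "counts",
) -> List[WindowProfile]:
    """Windowed read counting with multimapping reweighting.

    Every mapped read (each mate counts as one read unit) is assigned to the
    window containing its leftmost aligned base.  A read whose hit set,
    restricted to the candidate genomes, has exactly one genome adds 1 to
    that window's U; a read hitting several candidate genomes adds its
    weight for genome j (renormalized over the candidate hit set) to its
    window on each hit genome.  The final window of a genome keeps its true
    (short) length for rate denominators.
    """
    candidates = set(candidate_genomes)
    # group records per read unit (query name + mate)
    by_read: Dict[Tuple[str, int], List[BarcodedAlignment]] = {}
    for aln in alignments:
        if aln.reference_name not in candidates:
            continue
        if aln.position > genome_lengths[aln.reference_name]:
            raise QuantificationError(
                f"read {aln.read_id} maps beyond {aln.reference_name}"
            )
        by_read.setdefault((aln.read_id, aln.mate), []).append(aln)

    unique_reads: List[BarcodedAlignment] = []
    multi_reads: List[List[BarcodedAlignment]] = []
    unique_counts: Dict[str, int] = {g: 0 for g in candidates}
    for records in by_read.values():
        hit_genomes = {a.reference_name for a in records}
        if len(hit_genomes) == 1:
            primary = next(
                (a for a in records if a.is_primary), records[0]
            )
            unique_reads.append(primary)
            unique_counts[primary.reference_name] += 1
        else:
            multi_reads.append(records)

    # window scaffolding
    windows: Dict[str, List[WindowProfile]] = {}
    for g in candidates:
        glen = genome_lengths[g]
        n_win = max(1, -(-glen // window_size))
        windows[g] = [
            WindowProfile(
                genome_id=g,
                window_index=i,
                window_start=i * window_size + 1,
                l=min(window_size, glen - i * window_size),
                U=0,
                M_contrib=0.0,
            )
            for i in range(n_win)
        ]

    def _window_of(genome: str, position: int) -> WindowProfile:
        return windows[genome][(position - 1) // window_size]

    for aln in unique_reads:
        _window_of(aln.reference_name, aln.position).U += 1

    for hits in multi_reads:
        hit_genomes = sorted({a.reference_name for a in hits})
        weights = multiread_weights(
            hit_genomes, unique_counts, genome_lengths, mode=weight_mode
        )
        seen = set()
        for a in hits:
            if a.reference_name in seen:
                continue
            seen.add(a.reference_name)
            _window_of(a.reference_name, a.position).M_contrib += weights[
                a.reference_name
            ]

    return [w for g in sorted(windows) for w in windows[g]]


def genome_depth(
    genome_windows: Sequence[WindowProfile],
    trim_percentiles: Tuple[float, float] = DEFAULT_TRIM_PERCENTILES,
) -> float:
    """Mean RC(W) after removing extreme windows.

    Windows whose RC(W) lies outside the [lo, hi] percentile range of the
    genome's *nonzero* window RC(W) distribution are removed; if trimming
    removes everything, the untrimmed mean is returned.
    """
    if not genome_windows:
        raise QuantificationError("no windows for genome")
    rc = np.array([w.rc_w for w in genome_windows], dtype=float)
    nonzero = rc[rc > 0]
    if nonzero.size == 0:
        return 0.0
    lo, hi = np.percentile(nonzero, trim_percentiles)
    kept = rc[(rc >= lo) & (rc <= hi)]
    if kept.size == 0:
        return float(rc.mean())
    return float(kept.mean())


def relative_abundance(depths: Mapping[str, float]) -> Dict[str, Tuple[float, float]]:
    """Normalize per-genome depths into relative abundances.

    Returns ``{genome_id: (depth, relative_abundance)}``; abundances sum to 1.
    """
    total = sum(depths.values())
    if total <= 0:
        raise QuantificationError("all genome depths are zero")
    return {g: (d, d / total) for g, d in depths.items()}


def quantify(
    first_pass: Iterable[BarcodedAlignment],
    second_pass: Iterable[BarcodedAlignment],
    genome_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_rate: float = DEFAULT_MIN_COVERAGE_RATE,
    min_bases: int = DEFAULT_MIN_COVERED_BASES,
    weight_mode: str = "counts",
) -> Tuple[Dict[str, Tuple[float, float]], List[GenomeCoverage], List[WindowProfile]]:
    """Full tiered quantification.

    Returns (abundance table, first-pass coverages, window profiles).
    """
    coverages = compute_genome_coverage(first_pass, genome_lengths)
    candidates = first_pass_filter(coverages, min_rate, min_bases)
    if not candidates:
        raise QuantificationError("no genome passes the first-pass filter")
    profiles = window_counts(
        second_pass, candidates, genome_lengths, window_size, weight_mode
    )
    by_genome: Dict[str, List[WindowProfile]] = {}
    for w in profiles:
        by_genome.setdefault(w.genome_id, []).append(w)
    depths = {g: genome_depth(ws) for g, ws in by_genome.items()}
    return relative_abundance(depths), coverages, profiles


def write_abundance_tsv(
    table: Mapping[str, Tuple[float, float]],
    coverages: Sequence[GenomeCoverage],
    path: str | Path,
) -> Path:
    cov = {c.genome_id: c for c in coverages}
    path = Path(path)
    with open(path, "w") as out:
        out.write(
            "genome_id\tdepth\trelative_abundance\tcoverage_rate\tcovered_bases\n"
        )
        for g in sorted(table):
            depth, ab = table[g]
            c = cov.get(g)
            out.write(
                f"{g}\t{depth:.6g}\t{ab:.6g}\t"
                f"{c.coverage_rate:.6g}\t{c.covered_bases}\n"
                if c
                else f"{g}\t{depth:.6g}\t{ab:.6g}\tNA\tNA\n"
            )
    return path
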