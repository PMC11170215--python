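"""Long-fragment reconstruction from co-barcoded alignments.

Unique-mapped proper pairs give the insert-size model; pairs whose mates are
too far apart (outer distance > mu + 3*sigma) or on different references are
discarded; the survivors act as seeds which are merged per (barcode,
reference) whenever consecutive seeds lie within ``max_gap`` (200 kb by
default) — equivalent to single-linkage clustering of seed intervals at that
distance cutoff.  The resulting fragments summarize into the five standard
library-quality statistics (C_R, C_F, N_F/P, mu_FL, W-mu_FL).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from linkread.platform_io import NULL_BARCODE, BarcodedAlignment

#: Default maximum distance (bases) for extending co-barcoded seeds.
DEFAULT_MAX_GAP = 200_000

#: Upper-tail fraction trimmed from observed insert sizes before fitting.
INSERT_TRIM_PERCENTILE = 99.5


class ModelError(ValueError):
    """No usable read pairs for the requested estimate."""


@dataclass
class InsertSizeModel:
    mu_pe: float
    sigma_pe: float
    n_pairs_used: int

    def __post_init__(self) -> None:
        if self.sigma_pe < 0 or self.n_pairs_used < 1:
            raise ValueError("invalid insert-size model")

    @property
    def max_distance(self) -> float:
        """Pair-distance cutoff: mu + 3*sigma (pairs strictly above are
        removed)."""
        return self.mu_pe + 3.0 * self.sigma_pe


@dataclass
class Fragment:
    """A reconstructed long DNA molecule."""

    barcode: str
    reference_name: str
    start: int  # 1-based inclusive, leftmost aligned base
    end: int  # 1-based inclusive, rightmost aligned base
    n_read_pairs: int
    aligned_read_bases: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_read_pairs < 1 or self.aligned_read_bases < 1:
            raise ValueError("fragments need at least one read pair")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LibraryStats:
    """The five library-quality statistics over a fragment set."""

    c_r: float  # mean over fragments of aligned_read_bases / length
    c_f: float  # sum of fragment lengths / genome length
    n_fp: float  # mean fragments per barcode
    mu_fl: float  # unweighted mean fragment length (bases)
    w_mu_fl: float  # length-weighted mean fragment length (bases)
    n_fragments: int

    def __post_init__(self) -> None:
        # Cauchy-Schwarz: sum(L^2)/sum(L) >= mean(L); allow float slack
        if self.w_mu_fl < self.mu_fl - 1e-6:
            raise ValueError("length-weighted mean below unweighted mean")


def _pair_key(aln: BarcodedAlignment) -> str:
    return aln.read_id


def estimate_insert_model(
    alignments: Iterable[BarcodedAlignment],
    trim_percentile: float = INSERT_TRIM_PERCENTILE,
) -> InsertSizeModel:
    """Fit the insert-size distribution from unique-mapped proper pairs.

    Each pair contributes its outer distance (|TLEN|) once.  Sizes above the
    ``trim_percentile`` percentile are discarded before computing the mean
    and population standard deviation.
    """
    sizes: Dict[str, int] = {}
    for aln in alignments:
        if not (aln.is_unique and aln.is_proper_pair and aln.insert_size > 0):
            continue
        sizes.setdefault(_pair_key(aln), aln.insert_size)
    if not sizes:
        raise ModelError("no unique-mapped proper pairs to estimate insert sizes")
    data = np.array(list(sizes.values()), dtype=float)
    cutoff = np.percentile(data, trim_percentile, method="higher")
    data = data[data <= cutoff]
    return InsertSizeModel(
        mu_pe=float(data.mean()),
        sigma_pe=float(data.std()),  # population convention (ddof=0)
        n_pairs_used=len(data),
    )


def filter_pairs(
    alignments: Iterable[BarcodedAlignment], model: InsertSizeModel
) -> List[BarcodedAlignment]:
    """Drop pairs whose outer distance exceeds mu + 3*sigma (strictly) or
    whose mates map to different references.  Surviving records unchanged."""
    out = []
    threshold = model.max_distance
    for aln in alignments:
        if (
            aln.mate_reference_name is not None
            and aln.mate_reference_name != aln.reference_name
        ):
            continue
        if aln.insert_size > threshold:
            continue
        out.append(aln)
    return out


def reconstruct_fragments(
    alignments: Iterable[BarcodedAlignment],
    max_gap: int = DEFAULT_MAX_GAP,
) -> List[Fragment]:
    """Merge co-barcoded seed alignments into long fragments.

    Within each (barcode, reference) group, seeds sorted by coordinate are
    chained while the gap between the current fragment end and the next seed
    start is <= ``max_gap``; this greedy extension equals single-linkage
    clustering of the seed intervals at cutoff ``max_gap``.  Barcode-less
    records are ignored.
    """
    groups: Dict[Tuple[str, str], List[BarcodedAlignment]] = {}
    for aln in alignments:
        if aln.barcode == NULL_BARCODE or not aln.is_primary:
            continue
        groups.setdefault((aln.barcode, aln.reference_name), []).append(aln)

    fragments: List[Fragment] = []
    for (barcode, ref), group in sorted(groups.items()):
        group.sort(key=lambda a: (a.position, a.read_id))
        cur_start: Optional[int] = None
        cur_end = 0
        cur_bases = 0
        cur_reads: set[str] = set()
        for aln in group:
            a_start = aln.position
            a_end = aln.position + aln.aligned_bases - 1
            if cur_start is None:
                cur_start, cur_end = a_start, a_end
                cur_bases = aln.aligned_bases
                cur_reads = {aln.read_id}
            elif a_start - cur_end <= max_gap:
                cur_end = max(cur_end, a_end)
                cur_bases += aln.aligned_bases
                cur_reads.add(aln.read_id)
            else:
                fragments.append(
                    Fragment(barcode, ref, cur_start, cur_end,
                             len(cur_reads), cur_bases)
                )
                cur_start, cur_end = a_start, a_end
                cur_bases = aln.aligned_bases
                cur_reads = {aln.read_id}
        if cur_start is not None:
            fragments.append(
                Fragment(barcode, ref, cur_start, cur_end, len(cur_reads), cur_bases)
            )
    return fragments


def compute_library_stats(
    fragments: Sequence[Fragment],
    genome_length: Optional[int] = None,
    min_pairs_per_fragment: int = 1,
) -> LibraryStats:
    """Compute C_R, C_F, N_F/P, mu_FL, W-mu_FL over the fragment set.

    ``genome_length`` defaults to the footprint convention used for
    metagenomes: the sum of (max fragment end) over references carrying at
    least one fragment.  ``min_pairs_per_fragment`` drops sparse fragments
    before any statistic is computed (singleton seeds inflate N_F/P).
    """
    kept = [f for f in fragments if f.n_read_pairs >= min_pairs_per_fragment]
    if not kept:
        raise ModelError("no fragments survive the min-pairs filter")
    if genome_length is None:
        ref_span: Dict[str, int] = {}
        for f in kept:
            ref_span[f.reference_name] = max(ref_span.get(f.reference_name, 0), f.end)
        genome_length = sum(ref_span.values())
    lengths = np.array([f.length for f in kept], dtype=float)
    c_r = float(np.mean([f.aligned_read_bases / f.length for f in kept]))
    n_barcodes = len({f.barcode for f in kept})
    return LibraryStats(
        c_r=c_r,
        c_f=float(lengths.sum() / genome_length),
        n_fp=len(kept) / n_barcodes,
        mu_fl=float(lengths.mean()),
        w_mu_fl=float((lengths**2).sum() / lengths.sum()),
        n_fragments=len(kept),
    )


def write_fragments_tsv(fragments: Sequence[Fragment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write(
            "barcode\treference_name\tstart\tend\tlength\tn_read_pairs\t"
            "aligned_read_bases\n"
        )
        for f in fragments:
            out.write(
                f"{f.barcode}\t{f.reference_name}\t{f.start}\t{f.end}\t"
                f"{f.length}\t{f.n_read_pairs}\t{f.aligned_read_bases}\n"
            )
    return path
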