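"""Metagenomic SNV filtering and longitudinal strain-frequency-change
detection.

SNVs from quality-reporting callers (FreeBayes, SAMtools) are kept only when
total depth >= 6, alternative-allele support >= 2, and quality >= 15;
inStrain output is taken as-is because it carries no quality scores.

For strain dynamics, minor alleles are anchored in a designated reference
sample, minor-allele frequencies (MAF) are tabulated per sample, and SNVs of
one species are clustered (k-means, cluster count chosen by the
Calinski-Harabasz index) in pairwise-sample MAF space.  A cluster whose mean
MAF rises from below 0.5 in the reference sample to above 0.5 in the target
sample marks a strain frequency change: the minor allele became the major
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

import pysam

#: Caller-level filter thresholds (strict "less than"/"below" removals).
MIN_TOTAL_DEPTH = 6
MIN_ALT_SUPPORT = 2
MIN_QUALITY = 15.0

#: Minor-allele read support required for a site to enter the MAF matrix
#: ("exceeding 2", i.e. >= 3).
MIN_MINOR_SUPPORT = 3

QUALITY_FILTERED_CALLERS = frozenset({"freebayes", "samtools"})
KNOWN_CALLERS = QUALITY_FILTERED_CALLERS | {"instrain"}


@dataclass
class SnvRecord:
    genome_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    total_depth: int
    alt_support: int
    quality: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.alt_support > self.total_depth:
            raise ValueError("alt_support cannot exceed total_depth")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.genome_id, self.position, self.ref_allele, self.alt_allele)


@dataclass
class StrainShiftEvent:
    genome_id: str
    cluster_id: int
    snv_count: int
    sample_pair: Tuple[str, str]
    mean_maf_reference: float
    mean_maf_target: float
    crossed: bool

    @property
    def delta(self) -> float:
        return self.mean_maf_target - self.mean_maf_reference


def parse_vcf_snvs(
    path: str | Path, sample_id: str, genome_from: str = "contig"
) -> List[SnvRecord]:
    """Read biallelic SNVs from a VCF.

    Multi-allelic rows are split; non-SNV alleles are dropped.  Depth comes
    from FORMAT/INFO DP, alt support from AD (or AO for FreeBayes-style
    output).  ``genome_from`` selects the genome id source: the contig name
    (default) or everything before the last ``_`` in the contig name.
    """
    records: List[SnvRecord] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for row in vcf:
                if row.ref is None or len(row.ref) != 1 or not row.alts:
                    continue
                sample = row.samples[0] if row.samples else None
                depth = None
                if sample is not None and "DP" in sample and sample["DP"] is not None:
                    depth = int(sample["DP"])
                elif "DP" in row.info:
                    depth = int(row.info["DP"])
                ad = None
                if sample is not None and "AD" in sample and sample["AD"] is not None:
                    ad = list(sample["AD"])
                genome = row.contig
                if genome_from == "prefix" and "_" in genome:
                    genome = genome.rsplit("_", 1)[0]
                for i, alt in enumerate(row.alts):
                    if alt is None or len(alt) != 1 or alt == row.ref:
                        continue
                    if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                        alt_support = int(ad[i + 1])
                    elif sample is not None and "AO" in sample:
                        ao = sample["AO"]
                        ao = ao if isinstance(ao, tuple) else (ao,)
                        alt_support = int(ao[i]) if ao[i] is not None else 0
                    else:
                        alt_support = 0
                    records.append(
                        SnvRecord(
                            genome_id=genome,
                            position=row.pos,
                            ref_allele=row.ref,
                            alt_allele=alt,
                            total_depth=depth if depth is not None else alt_support,
                            alt_support=alt_support,
                            quality=float(row.qual) if row.qual is not None else 0.0,
                            sample_id=sample_id,
                        )
                    )
    finally:
        pysam.set_verbosity(save)
    return records


def filter_snvs(
    records: Iterable[SnvRecord],
    caller: str,
    min_depth: int = MIN_TOTAL_DEPTH,
    min_alt_support: int = MIN_ALT_SUPPORT,
    min_quality: float = MIN_QUALITY,
) -> List[SnvRecord]:
    """Caller-aware SNV quality filter.

    FreeBayes/SAMtools records survive only with total depth >= ``min_depth``,
    alt support >= ``min_alt_support`` and quality >= ``min_quality``;
    inStrain records pass unconditionally (no quality scores to filter on).
    """
    caller = caller.lower()
    if caller not in KNOWN_CALLERS:
        raise ValueError(f"unknown caller {caller!r}; expected one of {sorted(KNOWN_CALLERS)}")
    if caller == "instrain":
        return list(records)
    return [
        r
        for r in records
        if r.total_depth >= min_depth
        and r.alt_support >= min_alt_support
        and r.quality >= min_quality
    ]


@dataclass
class MafMatrix:
    """SNV-by-sample minor-allele-frequency matrix for one genome set.

    ``values`` is indexed by SNV key (genome, position, ref, alt) with one
    column per sample; NaN marks sites absent from a sample.  The minor
    allele of each row is fixed by the reference sample (frequency <= 0.5
    there; ties resolve to the alternative allele), so cells of other samples
    may exceed 0.5.
    """

    values: pd.DataFrame
    reference_sample: str
    minor_is_alt: pd.Series  # bool per row
    n_rows_dropped_no_reference: int = 0

    def rows_for(self, genome_id: str) -> pd.DataFrame:
        mask = [k[0] == genome_id for k in self.values.index]
        return self.values.loc[mask]


def build_maf_matrix(
    samples: Mapping[str, Sequence[SnvRecord]],
    reference_sample: str,
    min_minor_support: int = MIN_MINOR_SUPPORT,
) -> MafMatrix:
    """Merge per-sample SNVs into the combined minor-allele-frequency matrix.

    A site enters the matrix when at least one sample supports its minor
    allele with >= ``min_minor_support`` reads; sites missing from the
    reference sample are dropped (counted).
    """
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} not provided")
    if not any(len(v) for v in samples.values()):
        raise ValueError("no SNV records supplied")

    # (key -> sample -> (alt_count, total))
    counts: Dict[Tuple, Dict[str, Tuple[int, int]]] = {}
    for sample_id, recs in samples.items():
        for r in recs:
            counts.setdefault(r.key, {})[sample_id] = (r.alt_support, r.total_depth)

    sample_ids = list(samples)
    rows = []
    index = []
    minor_flags = []
    dropped = 0
    for key, per_sample in counts.items():
        if reference_sample not in per_sample:
            dropped += 1
            continue
        ref_alt, ref_total = per_sample[reference_sample]
        if ref_total == 0:
            dropped += 1
            continue
        # minor allele fixed by the reference sample; tie (0.5) -> alt
        minor_is_alt = ref_alt <= ref_total - ref_alt
        cells = []
        minor_supports = []
        for s in sample_ids:
            if s not in per_sample:
                cells.append(np.nan)
                continue
            alt, total = per_sample[s]
            minor = alt if minor_is_alt else total - alt
            cells.append(minor / total if total else np.nan)
            minor_supports.append(minor)
        if not any(ms >= min_minor_support for ms in minor_supports):
            continue
        rows.append(cells)
        index.append(key)
        minor_flags.append(minor_is_alt)

    values = pd.DataFrame(
        rows, index=pd.Index(index, tupleize_cols=False), columns=sample_ids,
        dtype=float,
    )
    return MafMatrix(
        values=values,
        reference_sample=reference_sample,
        minor_is_alt=pd.Series(minor_flags, index=values.index, dtype=bool),
        n_rows_dropped_no_reference=dropped,
    )


def cluster_maf(
    pair_matrix: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
) -> Tuple[np.ndarray, int]:
    """k-means over SNV rows in pairwise MAF space, cluster count chosen by
    the Calinski-Harabasz index.

    ``pair_matrix`` is (n_snvs, 2) with complete values.  Returns
    ``(labels, chosen_k)``; degenerate inputs (all rows identical) collapse
    to a single cluster with ``chosen_k == 1``.
    """
    X = np.asarray(pair_matrix, dtype=float)
    if X.ndim != 2 or np.isnan(X).any():
        raise ValueError("pair matrix must be 2-D and complete (no NaN)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete SNV rows to cluster")
    if np.allclose(X, X[0]):
        return np.zeros(n, dtype=int), 1

    best_labels = np.zeros(n, dtype=int)
    best_k = 1
    best_score = -np.inf
    for k in k_range:
        if k >= n or k < 2:
            continue
        km = KMeans(
            n_clusters=k, n_init=n_restarts, random_state=seed,
            max_iter=300, tol=1e-6,
        ).fit(X)
        if len(set(km.labels_)) < 2:
            continue
        score = calinski_harabasz_score(X, km.labels_)
        if score > best_score:
            best_score, best_k, best_labels = score, k, km.labels_
    return best_labels, best_k


def detect_strain_shift(
    labels: np.ndarray,
    pair_matrix: np.ndarray,
    sample_pair: Tuple[str, str],
    genome_id: str = "",
    cross_threshold: float = 0.5,
) -> List[StrainShiftEvent]:
    """Summarize each SNV cluster of a sample pair into a shift event.

    ``crossed`` is true when the cluster's mean MAF is strictly below the
    threshold in the reference sample and strictly above it in the target
    sample (the minor allele became the major allele).  Events are sorted by
    |delta MAF| descending.
    """
    X = np.asarray(pair_matrix, dtype=float)
    labels = np.asarray(labels)
    events = []
    for cid in sorted(set(labels.tolist())):
        members = X[labels == cid]
        mean_ref = float(members[:, 0].mean())
        mean_tgt = float(members[:, 1].mean())
        events.append(
            StrainShiftEvent(
                genome_id=genome_id,
                cluster_id=int(cid),
                snv_count=int(members.shape[0]),
                sample_pair=sample_pair,
                mean_maf_reference=mean_ref,
                mean_maf_target=mean_tgt,
                crossed=mean_ref < cross_threshold and mean_tgt > cross_threshold,
            )
        )
    events.sort(key=lambda e: abs(e.delta), reverse=True)
    return events


def analyze_sample_pair(
    matrix: MafMatrix,
    target_sample: str,
    genome_id: str,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
) -> Optional[Tuple[List[StrainShiftEvent], np.ndarray, int]]:
    """Cluster one species' SNVs in (reference, target) MAF space and call
    shift events.  Returns None (species skipped) when fewer than 3 rows are
    complete in both samples."""
    rows = matrix.rows_for(genome_id)[[matrix.reference_sample, target_sample]]
    rows = rows.dropna()
    if len(rows) < 3:
        return None
    X = rows.to_numpy()
    labels, k = cluster_maf(X, k_range=k_range, seed=seed)
    events = detect_strain_shift(
        labels, X, (matrix.reference_sample, target_sample), genome_id
    )
    return events, labels, k
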