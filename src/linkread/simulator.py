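"""Linked-read library simulator.

Generates barcoded paired-end reads from one or more reference sequences
under the standard linked-read parameterization:

* ``c_f``  — target physical coverage of the genome by long fragments,
* ``c_r``  — target short-read coverage within each fragment,
* ``n_fp`` — mean number of fragments per partition (per barcode),
* ``mu_fl``— mean long-fragment length in kb.

The simulator emits a unified barcoded FASTQ pair, a ground-truth SAM with
true coordinates and BX tags, and a truth-fragment table, so every
downstream module can be exercised without external sequencing data.

Distribution choices (fragment lengths exponential with mean ``mu_fl``,
fragments-per-partition zero-truncated Poisson, read pairs uniform within
the fragment) are declared, configurable stand-ins; see :class:`SimConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

from linkread.platform_io import (
    NULL_BARCODE,
    PRESETS,
    LinkedReadRecord,
    write_unified_fastq,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Phred+33 quality characters used by the simple error model.
_Q_GOOD = chr(35 + 33)  # Q35 for correct bases
_Q_ERR = chr(20 + 33)  # Q20 at injected-error positions


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters.

    ``mu_fl`` is in kb to match how linked-read library statistics are
    conventionally quoted; everything else is in bases.
    """

    c_f: float = 500.0
    c_r: float = 0.2
    n_fp: float = 16.0
    mu_fl: float = 20.0
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.0
    barcode_error_rate: float = 0.0
    platform: str = "tenx"
    fragment_length_law: str = "exponential"  # or "fixed"
    min_fragment_length: int = 1000
    barcode_pool: Optional[Sequence[str]] = None
    abundance_mu_ln: float = 0.0
    abundance_sigma_ln: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_f < 0 or self.c_r < 0:
            raise ValueError("coverages must be >= 0")
        if self.n_fp < 1:
            raise ValueError("n_fp must be >= 1")
        if self.mu_fl <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be > 0")
        if self.fragment_length_law not in ("exponential", "fixed"):
            raise ValueError(f"unknown fragment length law {self.fragment_length_law}")
        if self.platform not in PRESETS:
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass
class TruthFragment:
    """A simulated long DNA fragment (the ground truth that fragment
    reconstruction tries to recover)."""

    fragment_id: str
    barcode: str
    genome_id: str
    reference_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_read_pairs: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthAlignment:
    """True placement of one simulated read."""

    read_id: str
    mate: int
    barcode: str
    reference_name: str
    position: int  # 1-based leftmost
    is_reverse: bool
    insert_size: int  # signed TLEN
    sequence: str
    qualities: str


def sample_abundances(
    genome_ids: Sequence[str],
    mu_ln: float = 0.0,
    sigma_ln: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> Dict[str, float]:
    """Draw i.i.d. lognormal relative abundances, normalized to sum to 1."""
    if not genome_ids:
        raise ValueError("need at least one genome")
    if sigma_ln < 0:
        raise ValueError("sigma_ln must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.lognormal(mu_ln, sigma_ln, size=len(genome_ids))
    draws /= draws.sum()
    return {g: float(a) for g, a in zip(genome_ids, draws)}


def _zero_truncated_poisson(lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if lam == 1.0:
        # stLFR-style idealization: exactly one fragment per barcode.
        return np.ones(n, dtype=int)
    out = rng.poisson(lam, size=n)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(lam, size=int(zeros.sum()))


def _random_barcode_pool(n: int, length: int, rng: np.random.Generator) -> List[str]:
    bases = np.array(list("ACGT"))
    pool: set[str] = set()
    while len(pool) < n:
        draw = bases[rng.integers(0, 4, size=(n - len(pool), length))]
        pool.update("".join(row) for row in draw)
    return sorted(pool)


def sample_fragments(
    genomes: Mapping[str, str],
    config: SimConfig,
    abundances: Optional[Mapping[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[TruthFragment]:
    """Sample long fragments from every genome and assign partition barcodes.

    The number of fragments per genome is ``round(c_f_g * G / (mu_fl*1000))``
    where ``c_f_g`` scales the configured physical coverage by the genome's
    relative abundance (times the genome count, so a flat profile reproduces
    ``c_f`` on every genome).  Fragment lengths follow the configured law
    truncated to ``[min_fragment_length, G]``; start positions are uniform.
    Fragments are pooled across genomes, shuffled, and grouped into
    partitions of zero-truncated Poisson(``n_fp``) size, one fresh barcode
    per partition.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean_len = config.mu_fl * 1000.0
    seed_seq = np.random.SeedSequence(rng.integers(0, 2**63 - 1))
    sub_rngs = [np.random.default_rng(s) for s in seed_seq.spawn(len(genomes))]

    fragments: List[TruthFragment] = []
    n_genomes = len(genomes)
    for (genome_id, seq), g_rng in zip(genomes.items(), sub_rngs):
        glen = len(seq)
        scale = abundances[genome_id] * n_genomes if abundances else 1.0
        n_frags = int(round(config.c_f * scale * glen / mean_len))
        if n_frags == 0:
            continue
        min_len = min(config.min_fragment_length, glen)
        if config.fragment_length_law == "fixed":
            lengths = np.full(n_frags, int(round(mean_len)))
        else:
            # exponential conditioned on >= min_len (memoryless: shift)
            lengths = min_len + g_rng.exponential(mean_len, size=n_frags)
        lengths = np.minimum(lengths.astype(int), glen)
        lengths = np.maximum(lengths, 1)
        starts = g_rng.integers(1, glen - lengths + 2)
        for i, (s, L) in enumerate(zip(starts, lengths)):
            fragments.append(
                TruthFragment(
                    fragment_id=f"{genome_id}_f{i}",
                    barcode=NULL_BARCODE,
                    genome_id=genome_id,
                    reference_name=genome_id,
                    start=int(s),
                    end=int(s + L - 1),
                )
            )

    if not fragments:
        return fragments

    order = rng.permutation(len(fragments))
    sizes = _zero_truncated_poisson(config.n_fp, len(fragments), rng)
    boundaries = np.cumsum(sizes)
    n_partitions = int(np.searchsorted(boundaries, len(fragments)) + 1)

    if config.barcode_pool is not None:
        pool = list(config.barcode_pool)
        if len(pool) < n_partitions:
            raise SimulationError(
                f"barcode pool of {len(pool)} too small for {n_partitions} "
                "partitions; supply a larger pool"
            )
        pool = [pool[i] for i in rng.permutation(len(pool))[:n_partitions]]
    else:
        pool = _random_barcode_pool(
            n_partitions, PRESETS[config.platform].barcode_length, rng
        )

    part = 0
    consumed = 0
    for idx in order:
        if consumed >= sizes[part]:
            part += 1
            consumed = 0
        fragments[idx].barcode = pool[part]
        consumed += 1
    return fragments


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _inject_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> Tuple[str, str]:
    """Apply i.i.d. substitutions; returns (sequence, qualities)."""
    n = len(seq)
    if error_rate <= 0:
        return seq, _Q_GOOD * n
    hits = np.nonzero(rng.random(n) < error_rate)[0]
    if hits.size == 0:
        return seq, _Q_GOOD * n
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    qual = np.full(n, ord(_Q_GOOD), dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
        qual[i] = ord(_Q_ERR)
    return arr.tobytes().decode(), qual.tobytes().decode()


def mutate_barcode(
    barcode: str, error_rate: float, rng: np.random.Generator
) -> str:
    """Apply per-base substitution errors to a barcode string."""
    seq, _ = _inject_errors(barcode, error_rate, rng)
    return seq


def generate_reads(
    fragments: Sequence[TruthFragment],
    genomes: Mapping[str, str],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[LinkedReadRecord], List[TruthAlignment], int]:
    """Draw read pairs from each fragment.

    Per fragment the pair count is ``round(c_r * L / (2*read_length))``; pair
    start positions are uniform within the fragment with insert sizes from a
    Normal(``insert_mean``, ``insert_sd``) truncated to
    ``[2*read_length, L]``.  Returns (FASTQ records, truth alignments,
    number of fragments dropped for being shorter than one insert).
    Fragments' ``n_read_pairs`` fields are updated in place.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    records: List[LinkedReadRecord] = []
    truth: List[TruthAlignment] = []
    n_dropped = 0

    for frag in fragments:
        L = frag.length
        n_pairs = int(round(config.c_r * L / (2.0 * rl)))
        if n_pairs == 0:
            frag.n_read_pairs = 0
            continue
        if L < 2 * rl:
            n_dropped += 1
            frag.n_read_pairs = 0
            continue
        seq = genomes[frag.genome_id]
        inserts = np.clip(
            rng.normal(config.insert_mean, config.insert_sd, size=n_pairs),
            2 * rl,
            L,
        ).astype(int)
        starts = frag.start + rng.integers(0, L - inserts + 1)
        frag.n_read_pairs = n_pairs
        fastq_bc = (
            mutate_barcode(frag.barcode, config.barcode_error_rate, rng)
            if config.barcode_error_rate > 0 and frag.barcode != NULL_BARCODE
            else frag.barcode
        )
        for i, (s, ins) in enumerate(zip(starts, inserts)):
            rid = f"{frag.fragment_id}_p{i}"
            fwd = seq[s - 1 : s - 1 + rl]
            rev_start = s + ins - rl  # 1-based leftmost of the reverse mate
            rev = _revcomp(seq[rev_start - 1 : rev_start - 1 + rl])
            fwd, fq = _inject_errors(fwd, config.error_rate, rng)
            rev, rq = _inject_errors(rev, config.error_rate, rng)
            records.append(
                LinkedReadRecord(rid, 1, fwd, fq, fastq_bc, config.platform)
            )
            records.append(
                LinkedReadRecord(rid, 2, rev, rq, fastq_bc, config.platform)
            )
            truth.append(
                TruthAlignment(rid, 1, frag.barcode, frag.reference_name,
                               int(s), False, int(ins), fwd, fq)
            )
            truth.append(
                TruthAlignment(rid, 2, frag.barcode, frag.reference_name,
                               int(rev_start), True, -int(ins), rev, rq)
            )
    return records, truth, n_dropped


def write_truth_sam(
    truth: Sequence[TruthAlignment],
    genomes: Mapping[str, str],
    path: str | Path,
    read_length: int,
) -> Path:
    """Write truth alignments as a plain-text SAM with BX tags."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genomes.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(genomes)}
        for ta in truth:
            a = pysam.AlignedSegment(out.header)
            a.query_name = ta.read_id
            a.flag = (
                0x1 | 0x2
                | (0x10 if ta.is_reverse else 0x20)
                | (0x40 if ta.mate == 1 else 0x80)
            )
            a.reference_id = tid[ta.reference_name]
            a.reference_start = ta.position - 1
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.next_reference_id = a.reference_id
            a.next_reference_start = ta.position - 1 + ta.insert_size - (
                read_length if ta.insert_size > 0 else -read_length
            )
            # mate leftmost: for R1 (fwd, +ins) mate starts at pos+ins-rl;
            # for R2 (rev, -ins) mate starts at pos-(|ins|-rl)
            a.template_length = ta.insert_size
            a.query_sequence = (
                _revcomp(ta.sequence) if ta.is_reverse else ta.sequence
            )
            a.query_qualities = pysam.qualitystring_to_array(
                ta.qualities[::-1] if ta.is_reverse else ta.qualities
            )
            a.set_tag("BX", ta.barcode, "Z")
            out.write(a)
    return path


def write_fragment_table(
    fragments: Sequence[TruthFragment], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write(
            "fragment_id\tbarcode\tgenome_id\treference_name\tstart\tend\t"
            "length\tn_read_pairs\n"
        )
        for f in fragments:
            out.write(
                f"{f.fragment_id}\t{f.barcode}\t{f.genome_id}\t"
                f"{f.reference_name}\t{f.start}\t{f.end}\t{f.length}\t"
                f"{f.n_read_pairs}\n"
            )
    return path


def simulate(
    genomes: Mapping[str, str],
    config: SimConfig,
    out_dir: str | Path,
    abundances: Optional[Mapping[str, float]] = None,
) -> Dict[str, str]:
    """Run the full simulation and write all artifacts to ``out_dir``.

    Returns a manifest mapping artifact names to paths, also written as
    ``manifest.json`` together with the realized parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if abundances is None and config.abundance_sigma_ln > 0 and len(genomes) > 1:
        abundances = sample_abundances(
            list(genomes), config.abundance_mu_ln, config.abundance_sigma_ln, rng
        )

    fragments = sample_fragments(genomes, config, abundances, rng)
    records, truth, n_dropped = generate_reads(fragments, genomes, config, rng)

    r1 = [r for r in records if r.mate == 1]
    r2 = [r for r in records if r.mate == 2]
    paths = {
        "r1": str(write_unified_fastq(r1, out_dir / "reads_R1.fq")),
        "r2": str(write_unified_fastq(r2, out_dir / "reads_R2.fq")),
        "truth_sam": str(
            write_truth_sam(truth, genomes, out_dir / "truth.sam", config.read_length)
        ),
        "fragments": str(
            write_fragment_table(fragments, out_dir / "truth_fragments.tsv")
        ),
    }

    total_glen = sum(len(s) for s in genomes.values())
    live = [f for f in fragments if f.n_read_pairs > 0]
    barcodes = {f.barcode for f in fragments}
    realized = {
        "n_fragments": len(fragments),
        "n_partitions": len(barcodes),
        "n_read_pairs": len(truth) // 2,
        "n_fragments_dropped": n_dropped,
        "realized_c_f": sum(f.length for f in fragments) / total_glen,
        "realized_mu_fl_kb": (
            float(np.mean([f.length for f in fragments])) / 1000.0
            if fragments
            else 0.0
        ),
        "realized_n_fp": len(fragments) / len(barcodes) if barcodes else 0.0,
        "realized_c_r": (
            float(
                np.mean(
                    [f.n_read_pairs * 2 * config.read_length / f.length for f in live]
                )
            )
            if live
            else 0.0
        ),
        "abundances": dict(abundances) if abundances else None,
    }
    manifest = {"paths": paths, "config": asdict(config), "realized": realized}
    manifest["config"]["barcode_pool"] = (
        None if config.barcode_pool is None else len(config.barcode_pool)
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest"] = str(out_dir / "manifest.json")
    return paths
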