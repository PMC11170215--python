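"""Unified barcoded-read representation and platform-specific FASTQ parsing.

Raw linked reads from 10x Genomics, stLFR, and TELL-seq store their partition
barcode in different places (an inline R1 prefix, the R2 tail, a separate
index read).  This module converts each layout into a single representation:
a FASTQ record whose comment carries a ``BX:Z:<barcode>`` token, matching the
SAM ``BX`` tag convention so that aligner-propagated tags stay compatible.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

#: Sentinel for "no barcode".  Records carrying it are kept in the stream but
#: excluded from every barcode-grouped computation downstream.
NULL_BARCODE = "NA"

_BARCODE_ALPHABET = frozenset("ACGTN")


class FastqFormatError(ValueError):
    """Malformed FASTQ content (truncated record, bad BX token, ...)."""


class LayoutError(ValueError):
    """A barcode layout segment does not fit inside its source read."""


@dataclass(frozen=True)
class LayoutSegment:
    """One piece of the barcode, cut from a source read.

    ``offset`` is 0-based from the read start; negative offsets count from the
    read end (``-30`` = thirtieth-to-last base), which is how tail-anchored
    stLFR segments are expressed without knowing the read length up front.
    """

    source: str  # one of {"R1", "R2", "I1"}
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.source not in ("R1", "R2", "I1"):
            raise LayoutError(f"unknown segment source {self.source!r}")
        if self.length < 0:
            raise LayoutError("segment length must be >= 0")


@dataclass(frozen=True)
class PlatformSpec:
    """Barcode layout of one linked-read platform."""

    name: str
    barcode_length: int
    barcode_layout: tuple[LayoutSegment, ...]
    whitelist_available: bool

    def __post_init__(self) -> None:
        total = sum(seg.length for seg in self.barcode_layout)
        if total != self.barcode_length:
            raise LayoutError(
                f"layout segments sum to {total}, expected {self.barcode_length}"
            )


#: Built-in layouts.  The per-platform barcode lengths are fixed (16 bp for
#: 10x Genomics, 18 bp for TELL-seq, 30 bp for stLFR); offsets are presets the
#: user may override with a custom :class:`PlatformSpec`.
PRESETS: dict[str, PlatformSpec] = {
    "tenx": PlatformSpec(
        name="tenx",
        barcode_length=16,
        barcode_layout=(LayoutSegment("R1", 0, 16),),
        whitelist_available=True,
    ),
    "stlfr": PlatformSpec(
        name="stlfr",
        barcode_length=30,
        barcode_layout=(
            LayoutSegment("R2", -30, 10),
            LayoutSegment("R2", -20, 10),
            LayoutSegment("R2", -10, 10),
        ),
        whitelist_available=True,
    ),
    "tellseq": PlatformSpec(
        name="tellseq",
        barcode_length=18,
        barcode_layout=(LayoutSegment("I1", 0, 18),),
        whitelist_available=False,
    ),
}


@dataclass
class LinkedReadRecord:
    """A single sequenced read plus its partition barcode."""

    read_id: str
    mate: int
    sequence: str
    qualities: str
    barcode: str = NULL_BARCODE
    platform: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    @property
    def has_barcode(self) -> bool:
        return self.barcode != NULL_BARCODE


@dataclass
class BarcodedAlignment:
    """A mapped read with its barcode — the unit fragment reconstruction and
    quantification operate on."""

    read_id: str
    barcode: str
    reference_name: str
    position: int  # 1-based leftmost mapped coordinate
    mapq: int
    is_unique: bool
    aligned_bases: int
    mate: int = 1
    is_primary: bool = True
    mate_position: Optional[int] = None
    mate_reference_name: Optional[str] = None
    is_proper_pair: bool = False
    insert_size: int = 0  # |TLEN|; 0 when unavailable
    hit_references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (SAM 1-based)")
        if self.aligned_bases < 1:
            raise ValueError("mapped records must align >= 1 base")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_fastq(path: str | Path) -> Iterator[tuple[str, str, str, str]]:
    """Yield (id, comment, sequence, qualities) tuples; gzip-transparent."""
    with pysam.FastxFile(str(path)) as fx:
        for i, entry in enumerate(fx):
            if entry.sequence is None or entry.quality is None:
                raise FastqFormatError(f"{path}: truncated record at index {i}")
            yield entry.name, entry.comment or "", entry.sequence, entry.quality


def _cut_segment(seq: str, qual: str, seg: LayoutSegment, path_hint: str) -> str:
    start = seg.offset if seg.offset >= 0 else len(seq) + seg.offset
    end = start + seg.length
    if start < 0 or end > len(seq):
        raise LayoutError(
            f"{path_hint}: segment {seg.source}[{seg.offset}:+{seg.length}] "
            f"outside read of length {len(seq)}"
        )
    return seq[start:end]


def _strip_segments(
    seq: str, qual: str, segments: Sequence[LayoutSegment]
) -> tuple[str, str]:
    """Remove inline barcode bases from a payload read."""
    cut = sorted(
        (
            (seg.offset if seg.offset >= 0 else len(seq) + seg.offset, seg.length)
            for seg in segments
        ),
        reverse=True,
    )
    for start, length in cut:
        seq = seq[:start] + seq[start + length :]
        qual = qual[:start] + qual[start + length :]
    return seq, qual


def convert_to_unified(
    r1_path: str | Path,
    r2_path: str | Path,
    spec: PlatformSpec,
    i1_path: str | Path | None = None,
) -> Iterator[LinkedReadRecord]:
    """Convert raw platform reads into the unified barcoded representation.

    The barcode is assembled by concatenating the spec's layout segments in
    order.  Inline segments (those cut from R1/R2) are removed from the
    payload sequence; index-read (I1) segments leave the payloads untouched.
    Both mates of a pair receive identical barcodes, and pairs are conserved.
    """
    needs_i1 = any(seg.source == "I1" for seg in spec.barcode_layout)
    if needs_i1 and i1_path is None:
        raise LayoutError(f"platform {spec.name!r} requires an I1 index read file")

    r1_iter = _read_fastq(r1_path)
    r2_iter = _read_fastq(r2_path)
    i1_iter = _read_fastq(i1_path) if needs_i1 else None

    index = 0
    while True:
        try:
            r1 = next(r1_iter)
        except StopIteration:
            # R2 must be exhausted too
            try:
                next(r2_iter)
            except StopIteration:
                return
            raise FastqFormatError(f"{r2_path}: more records than {r1_path}")
        try:
            r2 = next(r2_iter)
        except StopIteration:
            raise FastqFormatError(
                f"{r2_path}: truncated at record index {index}"
            ) from None
        reads = {"R1": r1, "R2": r2}
        if i1_iter is not None:
            try:
                reads["I1"] = next(i1_iter)
            except StopIteration:
                raise FastqFormatError(
                    f"{i1_path}: truncated at record index {index}"
                ) from None

        pieces = []
        for seg in spec.barcode_layout:
            _, _, seq, qual = reads[seg.source]
            pieces.append(_cut_segment(seq, qual, seg, str(seg.source)))
        barcode = "".join(pieces) if pieces and sum(map(len, pieces)) else NULL_BARCODE
        if barcode != NULL_BARCODE and not set(barcode) <= _BARCODE_ALPHABET:
            barcode = NULL_BARCODE

        for mate, key in ((1, "R1"), (2, "R2")):
            name, _, seq, qual = reads[key]
            inline = [
                seg
                for seg in spec.barcode_layout
                if seg.source == key and barcode != NULL_BARCODE
            ]
            if inline:
                seq, qual = _strip_segments(seq, qual, inline)
            yield LinkedReadRecord(
                read_id=name,
                mate=mate,
                sequence=seq,
                qualities=qual,
                barcode=barcode,
                platform=spec.name,
            )
        index += 1


def write_unified_fastq(
    records: Iterable[LinkedReadRecord], path: str | Path
) -> Path:
    """Serialize records to unified FASTQ.

    The barcode is written as a ``BX:Z:<seq>`` token in the header comment;
    barcode-less records omit the token.  The mate is appended to the read id
    as ``/1`` or ``/2`` so that a single (possibly interleaved) file
    round-trips losslessly.
    """
    path = Path(path)
    with _open_text(path, "wt") as out:
        for rec in records:
            header = f"@{rec.read_id}/{rec.mate}"
            if rec.has_barcode:
                header += f" BX:Z:{rec.barcode}"
            out.write(f"{header}\n{rec.sequence}\n+\n{rec.qualities}\n")
    return path


def read_unified_fastq(
    path: str | Path, platform: Optional[str] = None
) -> Iterator[LinkedReadRecord]:
    """Parse unified FASTQ back into records (inverse of
    :func:`write_unified_fastq`)."""
    line_no = 0
    for name, comment, seq, qual in _read_fastq(path):
        line_no += 4
        barcode = NULL_BARCODE
        for token in comment.split():
            if token.startswith("BX:Z:"):
                barcode = token[5:]
                if not barcode or not set(barcode) <= _BARCODE_ALPHABET:
                    raise FastqFormatError(
                        f"{path}: malformed BX token {token!r} near line {line_no - 3}"
                    )
                break
        if name.endswith("/1") or name.endswith("/2"):
            read_id, mate = name[:-2], int(name[-1])
        else:
            read_id, mate = name, 1
        yield LinkedReadRecord(
            read_id=read_id,
            mate=mate,
            sequence=seq,
            qualities=qual,
            barcode=barcode,
            platform=platform,
        )


def load_barcoded_alignments(
    path: str | Path,
    include_secondary: bool = True,
) -> Iterator[BarcodedAlignment]:
    """Stream barcode-tagged alignments from a SAM/BAM file.

    Unmapped records are not yielded.  Secondary/supplementary hits are
    yielded (``is_primary=False``, unless ``include_secondary`` is off) and
    always contribute to each read's hit set: a read reported on more than
    one reference or location gets ``is_unique=False`` on every one of its
    records, with the full ``hit_references`` tuple attached.

    Primary records missing a BX tag are skipped and counted; a single
    summary warning is logged.  Secondary records inherit the primary's
    barcode when their own BX tag is absent.
    """
    # Hit sets need the whole file, so collect in one pass and yield after;
    # desk-scale SAM inputs fit comfortably in memory.
    rows: list[tuple] = []
    hit_sets: dict[tuple[str, int], set[tuple[str, int]]] = {}
    primary_bx: dict[tuple[str, int], str] = {}
    n_missing_bx = 0

    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped:
                    continue
                mate = 2 if aln.is_read2 else 1
                key = (aln.query_name, mate)
                hit_sets.setdefault(key, set()).add(
                    (aln.reference_name, aln.reference_start)
                )
                is_primary = not (aln.is_secondary or aln.is_supplementary)
                barcode = str(aln.get_tag("BX")) if aln.has_tag("BX") else None
                if is_primary:
                    if barcode is None:
                        n_missing_bx += 1
                        continue
                    primary_bx[key] = barcode
                elif not include_secondary:
                    continue
                rows.append(
                    (
                        key,
                        barcode,
                        is_primary,
                        aln.reference_name,
                        aln.reference_start + 1,
                        aln.mapping_quality,
                        aln.query_alignment_length or 1,
                        (aln.next_reference_start + 1)
                        if aln.next_reference_start >= 0
                        else None,
                        aln.next_reference_name,
                        aln.is_proper_pair,
                        abs(aln.template_length),
                    )
                )
    finally:
        pysam.set_verbosity(save)

    if n_missing_bx:
        logger.warning(
            "%s: skipped %d mapped record(s) without a BX tag", path, n_missing_bx
        )

    for (
        key,
        barcode,
        is_primary,
        rname,
        pos,
        mapq,
        aligned,
        mate_pos,
        mate_rname,
        proper,
        tlen,
    ) in rows:
        if barcode is None:
            barcode = primary_bx.get(key, NULL_BARCODE)
        hits = hit_sets[key]
        refs = tuple(sorted({ref for ref, _ in hits}))
        yield BarcodedAlignment(
            read_id=key[0],
            barcode=barcode,
            reference_name=rname,
            position=pos,
            mapq=mapq,
            is_unique=len(hits) == 1,
            aligned_bases=aligned,
            mate=key[1],
            is_primary=is_primary,
            mate_position=mate_pos,
            mate_reference_name=mate_rname,
            is_proper_pair=proper,
            insert_size=tlen,
            hit_references=refs,
        )
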