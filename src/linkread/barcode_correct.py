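"""Barcode error correction.

Two modes mirror how the platforms ship:

* whitelist mode (10x Genomics, stLFR): an observed barcode within Hamming
  distance 1 of exactly one whitelist entry is rewritten to that entry;
  anything at distance >= 2 from every entry, or equidistant (d=1) from
  several entries, is nulled.
* count mode (TELL-seq, which has no whitelist): barcodes supported by a
  single read are rescued onto a unique distance-1 neighbour supported by
  multiple reads; everything else is left alone.

N bases count as mismatches at their position; indels are not modeled
(barcodes are fixed-length codes).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

from linkread.platform_io import NULL_BARCODE, LinkedReadRecord

_BASES = "ACGT"

#: Correction outcome labels.
EXACT = "exact"
CORRECTED = "corrected"
UNCORRECTABLE = "uncorrectable"
AMBIGUOUS = "ambiguous"


def hamming1_neighbors(barcode: str) -> Iterable[str]:
    """All strings at Hamming distance exactly 1 (substitutions over ACGT)."""
    for i, orig in enumerate(barcode):
        for base in _BASES:
            if base != orig:
                yield barcode[:i] + base + barcode[i + 1 :]


@dataclass
class Whitelist:
    """Set of valid barcodes with Hamming-distance-<=1 lookup."""

    entries: frozenset[str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("whitelist is empty")
        lengths = {len(e) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"whitelist entries have mixed lengths: {sorted(lengths)}")
        self.length = lengths.pop()

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_iterable(cls, barcodes: Iterable[str]) -> "Whitelist":
        return cls(entries=frozenset(barcodes))

    @classmethod
    def from_file(cls, path: str | Path) -> "Whitelist":
        """One barcode per line, plain text, optionally gzipped."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            entries = frozenset(line.strip() for line in fh if line.strip())
        return cls(entries=entries)

    def neighbors_in(self, barcode: str) -> list[str]:
        """Whitelist entries at Hamming distance exactly 1 from ``barcode``."""
        return [nb for nb in hamming1_neighbors(barcode) if nb in self.entries]


def correct_with_whitelist(
    barcode: str, whitelist: Whitelist
) -> Tuple[str, str]:
    """Correct one barcode against a whitelist.

    Returns ``(corrected_or_null, status)`` where status is one of
    ``exact``, ``corrected``, ``ambiguous``, ``uncorrectable``.
    """
    if len(barcode) != whitelist.length:
        raise ValueError(
            f"barcode length {len(barcode)} != whitelist length {whitelist.length}"
        )
    if barcode in whitelist:
        return barcode, EXACT
    # N is not in the substitution alphabet, so an N position is handled by
    # trying each ACGT replacement — exactly the distance-1 semantics.
    hits = {nb for nb in hamming1_neighbors(barcode) if nb in whitelist}
    if len(hits) == 1:
        return next(iter(hits)), CORRECTED
    if len(hits) > 1:
        return NULL_BARCODE, AMBIGUOUS
    return NULL_BARCODE, UNCORRECTABLE


def correct_without_whitelist(
    counts: Mapping[str, int]
) -> Dict[str, str]:
    """Count-based correction for whitelist-less platforms.

    A barcode seen on exactly one read is rewritten to a multi-read barcode
    at Hamming distance exactly 1, provided that neighbour is unique;
    multi-read barcodes and ambiguous singletons map to themselves.
    """
    if not counts:
        raise ValueError("empty barcode count table")
    multi = {bc for bc, n in counts.items() if n >= 2}
    mapping: Dict[str, str] = {}
    for bc, n in counts.items():
        if n != 1:
            mapping[bc] = bc
            continue
        partners = {nb for nb in hamming1_neighbors(bc) if nb in multi}
        mapping[bc] = partners.pop() if len(partners) == 1 else bc
    return mapping


def correct_records(
    records: Iterable[LinkedReadRecord], whitelist: Whitelist
) -> Tuple[list[LinkedReadRecord], Dict[str, int]]:
    """Apply whitelist correction to a record stream.

    Both mates of a pair share a barcode, so each raw barcode is corrected
    once and the result applied to every read carrying it.  Returns the
    corrected records plus a status tally
    ``{exact, corrected, ambiguous, uncorrectable}`` counted per read.
    """
    cache: Dict[str, Tuple[str, str]] = {}
    stats = {EXACT: 0, CORRECTED: 0, AMBIGUOUS: 0, UNCORRECTABLE: 0}
    out = []
    for rec in records:
        if not rec.has_barcode:
            out.append(rec)
            continue
        if rec.barcode not in cache:
            cache[rec.barcode] = correct_with_whitelist(rec.barcode, whitelist)
        corrected, status = cache[rec.barcode]
        stats[status] += 1
        out.append(
            LinkedReadRecord(
                read_id=rec.read_id,
                mate=rec.mate,
                sequence=rec.sequence,
                qualities=rec.qualities,
                barcode=corrected,
                platform=rec.platform,
            )
        )
    return out, stats


def whitelist_rate(
    records: Iterable[LinkedReadRecord],
    whitelist: Whitelist,
    n_raw_barcoded: int | None = None,
) -> float | None:
    """Fraction of raw-barcoded reads whose (corrected) barcode is on the
    whitelist.

    ``records`` is a corrected stream.  The denominator is the number of
    reads that carried a non-null barcode *before* correction; pass it via
    ``n_raw_barcoded`` when correction may have nulled some barcodes
    (otherwise reads still carrying a barcode are counted).  Returns ``None``
    when the denominator is zero.
    """
    n_barcoded = 0
    n_on_list = 0
    for rec in records:
        if rec.barcode == NULL_BARCODE:
            continue
        n_barcoded += 1
        if rec.barcode in whitelist:
            n_on_list += 1
    denom = n_raw_barcoded if n_raw_barcoded is not None else n_barcoded
    if denom == 0:
        return None
    return n_on_list / denom
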