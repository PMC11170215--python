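"""MAG quality tiers and machine-readable run summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence

TIERS = ("near_complete", "high", "medium", "low")

#: Tier thresholds (percent).  near_complete and high use strict >90 / <5;
#: medium uses inclusive >=50 with strict <10.
NEAR_COMPLETE_COMPLETENESS = 90.0
NEAR_COMPLETE_CONTAMINATION = 5.0
NEAR_COMPLETE_MIN_TRNAS = 18
MEDIUM_COMPLETENESS = 50.0
MEDIUM_CONTAMINATION = 10.0


@dataclass
class BinQuality:
    bin_id: str
    completeness: float
    contamination: float
    has_5s: bool = False
    has_16s: bool = False
    has_23s: bool = False
    trna_count: int = 0
    tier: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")
        if self.trna_count < 0:
            raise ValueError("trna_count must be >= 0")
        self.tier = classify_mag(
            self.completeness,
            self.contamination,
            self.has_5s,
            self.has_16s,
            self.has_23s,
            self.trna_count,
        )


def classify_mag(
    completeness: float,
    contamination: float,
    has_5s: bool = False,
    has_16s: bool = False,
    has_23s: bool = False,
    trna_count: int = 0,
) -> str:
    """Assign a MAG quality tier.

    Rules are checked in order (first match wins), making tiers disjoint:

    * near_complete: completeness > 90, contamination < 5, all of the 5S,
      16S and 23S rRNAs detected, and at least 18 tRNAs;
    * high: completeness > 90 and contamination < 5;
    * medium: completeness >= 50 and contamination < 10;
    * low: everything else.
    """
    if not 0 <= completeness <= 100:
        raise ValueError("completeness must be in [0, 100]")
    if contamination < 0:
        raise ValueError("contamination must be >= 0")
    if (
        completeness > NEAR_COMPLETE_COMPLETENESS
        and contamination < NEAR_COMPLETE_CONTAMINATION
        and has_5s
        and has_16s
        and has_23s
        and trna_count >= NEAR_COMPLETE_MIN_TRNAS
    ):
        return "near_complete"
    if (
        completeness > NEAR_COMPLETE_COMPLETENESS
        and contamination < NEAR_COMPLETE_CONTAMINATION
    ):
        return "high"
    if completeness >= MEDIUM_COMPLETENESS and contamination < MEDIUM_CONTAMINATION:
        return "medium"
    return "low"


def summarize_run(
    preprocess: Optional[Mapping[str, Any]] = None,
    library: Optional[Mapping[str, Any]] = None,
    quant: Optional[Mapping[str, Any]] = None,
    snv: Optional[Mapping[str, Any]] = None,
    strain: Optional[Sequence[Mapping[str, Any]]] = None,
    top_n_abundances: int = 20,
) -> Dict[str, Any]:
    """Aggregate module outputs into one deterministic JSON-ready summary.

    Absent sections are omitted; an error is raised when nothing is present.
    """
    summary: Dict[str, Any] = {}
    if preprocess is not None:
        summary["preprocess"] = dict(sorted(preprocess.items()))
    if library is not None:
        summary["library"] = dict(sorted(library.items()))
    if quant is not None:
        top = sorted(quant.items(), key=lambda kv: -float(kv[1]))[:top_n_abundances]
        summary["quant"] = {g: v for g, v in top}
    if snv is not None:
        snv = dict(snv)
        if "pre" in snv and "post" in snv and snv["post"] > snv["pre"]:
            raise ValueError("post-filter SNV count exceeds pre-filter count")
        summary["snv"] = dict(sorted(snv.items()))
    if strain is not None:
        summary["strain"] = [dict(sorted(e.items())) for e in strain]
    if not summary:
        raise ValueError(
            "no module artifacts supplied (expected at least one of "
            "preprocess/library/quant/snv/strain)"
        )
    return summary


def write_summary(summary: Mapping[str, Any], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return path
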