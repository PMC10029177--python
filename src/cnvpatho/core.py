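"""Genomic coordinate types and interval arithmetic.

All coordinates are 0-based half-open internally, so ``length == end - start``
holds exactly and adjacency means zero overlap (BED semantics). Source tables
in 1-based inclusive convention are converted at parse time by the readers.

Chromosome names are normalized by stripping a leading ``chr`` prefix, since
the public CNV resources mix both conventions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix for cross-resource comparison."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:[{self.start},{self.end}) rejected"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class CNVType(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


class Label(str, enum.Enum):
    """ACMG five-tier clinical significance, plus unknown for unlabelled calls."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain_significance"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"
    UNKNOWN = "unknown"


#: five-tier classes ordered from least to most pathogenic
FIVE_TIER_ORDER: tuple[Label, ...] = (
    Label.BENIGN,
    Label.LIKELY_BENIGN,
    Label.UNCERTAIN,
    Label.LIKELY_PATHOGENIC,
    Label.PATHOGENIC,
)

_BENIGN_GROUP = frozenset({Label.BENIGN, Label.LIKELY_BENIGN})
_PATHOGENIC_GROUP = frozenset({Label.PATHOGENIC, Label.LIKELY_PATHOGENIC})


def labels_conflict(a: Label, b: Label) -> bool:
    """True when one label is benign/likely-benign and the other pathogenic/likely-pathogenic.

    Uncertain significance conflicts with neither group (ACMG reading).
    """
    return (a in _BENIGN_GROUP and b in _PATHOGENIC_GROUP) or (
        a in _PATHOGENIC_GROUP and b in _BENIGN_GROUP
    )


@dataclass
class CNVRecord:
    """A copy-number variant call: interval + type + clinical label + provenance."""

    interval: GenomicInterval
    cnv_type: CNVType
    label: Label = Label.UNKNOWN
    source: str = ""
    record_id: str = ""
    attrs: dict[str, Any] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.interval.length


def interval_length(iv: GenomicInterval) -> int:
    """Span in bp: end − start (half-open convention)."""
    return iv.end - iv.start


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases between two intervals; 0 across chromosomes or when disjoint."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); symmetric, in [0, 1].

    Equals 1.0 iff the intervals are identical on the same chromosome.
    Different chromosomes give 0 rather than an error, which keeps
    all-pairs scans simple.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)
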