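"""Post-caller exclusion rules for SNV, indel and CNV-segment candidates.

The rules are applied exactly as stated (strict exclusion inequalities, so
records sitting on a boundary are retained):

SNVs excluded when tumor VAF < 10%, when the matched normal shows more than
five variant reads or > 10% VAF, or when the annotation is neither
protein-coding nor splice-site.

Indels excluded when tumor support < 6 reads, when the matched normal has
any supporting reads or < 14 total reads, when a replacement's deleted and
inserted sequences have equal length, or on annotation as above.

CNV segments are classified gain (ratio > 1.3) / loss (ratio < 0.7) /
neutral, neutral segments dropped, proximal (< 1 Mbp gap) same-direction
segments merged per chromosome (exon counts summed, gene lists unioned,
ratio = exon-count-weighted mean), and only merged segments spanning more
than `min_exons` exons retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

__all__ = [
    "SnvRecord",
    "IndelRecord",
    "CnvSegment",
    "filter_snvs",
    "filter_indels",
    "triage_cnv_segments",
]

CODING_ANNOTATIONS = {"protein-coding", "splice-site"}


@dataclass(frozen=True)
class SnvRecord:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    tumor_vaf: float
    normal_variant_reads: int
    normal_vaf: float
    annotation: str

    def __post_init__(self) -> None:
        for name in ("tumor_vaf", "normal_vaf"):
            v = getattr(self, name)
            if v is None or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.normal_variant_reads is None or self.normal_variant_reads < 0:
            raise ValueError("normal_variant_reads must be a non-negative count")


@dataclass(frozen=True)
class IndelRecord:
    chrom: str
    pos: int
    type: str  # deletion | insertion | replacement
    tumor_support_reads: int
    normal_support_reads: int
    normal_total_reads: int
    deletion_len: int
    inserted_len: int
    annotation: str

    def __post_init__(self) -> None:
        if self.type not in ("deletion", "insertion", "replacement"):
            raise ValueError(f"unknown indel type {self.type!r}")
        if min(self.deletion_len, self.inserted_len) < 0:
            raise ValueError("indel lengths must be >= 0")
        if self.normal_support_reads > self.normal_total_reads:
            raise ValueError("normal support exceeds normal total reads")


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int  # 0-based half-open (BED)
    end: int
    n_exons: int
    ratio: float
    direction: Optional[str] = None  # gain | loss | neutral; derived from ratio
    genes: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start ({self.start}..{self.end})")
        if self.n_exons < 0 or self.ratio < 0:
            raise ValueError("n_exons and ratio must be non-negative")


def filter_snvs(records: Sequence[SnvRecord]):
    """Returns (retained records, per-record reason codes).

    Reason codes align with the input; "retained" marks kept records,
    otherwise the single primary (first-failing) exclusion reason.
    """
    retained, reasons = [], []
    for rec in records:
        if rec.tumor_vaf < 0.10:
            reasons.append("tumor_vaf_below_10pct")
        elif rec.normal_variant_reads > 5:
            reasons.append("normal_variant_reads_above_5")
        elif rec.normal_vaf > 0.10:
            reasons.append("normal_vaf_above_10pct")
        elif rec.annotation not in CODING_ANNOTATIONS:
            reasons.append("non_coding_annotation")
        else:
            reasons.append("retained")
            retained.append(rec)
    return retained, reasons


def filter_indels(records: Sequence[IndelRecord]):
    """Returns (retained records, per-record reason codes)."""
    retained, reasons = [], []
    for rec in records:
        if rec.tumor_support_reads < 6:
            reasons.append("tumor_support_below_6")
        elif rec.normal_support_reads > 0:
            reasons.append("normal_support_present")
        elif rec.normal_total_reads < 14:
            reasons.append("normal_total_below_14")
        elif rec.type == "replacement" and rec.deletion_len == rec.inserted_len:
            reasons.append("same_length_replacement")
        elif rec.annotation not in CODING_ANNOTATIONS:
            reasons.append("non_coding_annotation")
        else:
            reasons.append("retained")
            retained.append(rec)
    return retained, reasons


def classify_direction(ratio: float, gain_ratio: float = 1.3, loss_ratio: float = 0.7) -> str:
    if ratio > gain_ratio:
        return "gain"
    if ratio < loss_ratio:
        return "loss"
    return "neutral"


def _merge_pair(a: CnvSegment, b: CnvSegment) -> CnvSegment:
    n = a.n_exons + b.n_exons
    ratio = (
        (a.ratio * a.n_exons + b.ratio * b.n_exons) / n if n > 0 else (a.ratio + b.ratio) / 2
    )
    genes = tuple(dict.fromkeys(a.genes + b.genes))
    return CnvSegment(
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        n_exons=n,
        ratio=ratio,
        direction=a.direction,
        genes=genes,
    )


def triage_cnv_segments(
    segments: Sequence[CnvSegment],
    min_exons: int = 100,
    merge_gap: float = 1_000_000,
    gain_ratio: float = 1.3,
    loss_ratio: float = 0.7,
) -> List[CnvSegment]:
    """Classify, merge proximal same-direction segments, and size-filter.

    Merging precedes the exon-count filter so small proximal fragments can
    jointly clear it. Retention requires n_exons > min_exons (strictly).
    Overlapping same-direction segments merge with a warning; overlapping
    segments of opposite direction are an error.
    """
    classified = [
        replace(s, direction=classify_direction(s.ratio, gain_ratio, loss_ratio))
        for s in segments
    ]
    # overlapping opposite-direction segments are contradictory input
    by_chrom: dict = {}
    for s in sorted(classified, key=lambda s: (s.chrom, s.start, s.end)):
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end and a.direction != b.direction and "neutral" not in (
                a.direction, b.direction
            ):
                raise ValueError(
                    f"overlapping segments of opposite direction on {chrom}: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )
    kept = [s for s in classified if s.direction != "neutral"]
    merged: List[CnvSegment] = []
    key = lambda s: (s.chrom, s.direction)
    groups: dict = {}
    for s in sorted(kept, key=lambda s: (s.chrom, s.direction, s.start)):
        groups.setdefault(key(s), []).append(s)
    for segs in groups.values():
        current = segs[0]
        for nxt in segs[1:]:
            gap = nxt.start - current.end
            if gap < merge_gap:
                if gap < 0:
                    warnings.warn(
                        f"overlapping same-direction segments merged on {current.chrom}"
                    )
                current = _merge_pair(current, nxt)
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    result = [s for s in merged if s.n_exons > min_exons]
    return sorted(result, key=lambda s: (s.chrom, s.start))
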