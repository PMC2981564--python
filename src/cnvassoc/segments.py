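"""Sample QC and segment-level processing of raw copy-number calls.

Raw caller output covers each chromosome wall-to-wall with integer
copy-number segments, many of them low-confidence fragments. Processing has
three steps: drop samples whose array call rate is below threshold, absorb
each low-confidence segment into its nearest confident neighbour (adopting
that neighbour's copy number), and finally keep only confident non-diploid
segments as the variant calls that feed the catalogue.

The merge rule is per-segment nearest-confident-neighbour, with distance
measured as the genomic gap in bp between segment ends (intervening
segments' spans count toward the distance); equidistant neighbours resolve
upstream (lower coordinate). A chromosome with no confident segment at all
has nothing to merge into, so its segments are dropped with a warning. The
union of covered base pairs is never changed by merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

from .errors import ValidationError
from .model import (
    SampleMeta,
    SegmentCall,
    VariantCall,
    chrom_sort_key,
    is_autosome,
    validate_non_overlapping,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ProcessingConfig:
    """Thresholds for sample QC and confidence filtering.

    confidence_threshold
        Segments with confidence >= this value count as confident; the
        boundary value itself is kept (only calls strictly below are merged).
    min_call_rate
        Samples with array call rate strictly below this fraction are
        discarded.
    """

    confidence_threshold: float = 5.0
    min_call_rate: float = 0.98

    def __post_init__(self) -> None:
        if self.confidence_threshold <= 0:
            raise ValidationError("confidence_threshold must be > 0")
        if not 0 < self.min_call_rate <= 1:
            raise ValidationError("min_call_rate must be in (0, 1]")


def qc_filter_samples(
    samples: Sequence[SampleMeta], config: ProcessingConfig = ProcessingConfig()
) -> tuple[list[SampleMeta], list[tuple[SampleMeta, str]]]:
    """Split samples into (retained, dropped-with-reason) by call rate.

    A call rate exactly at the threshold is retained: the rule discards
    samples *below* the minimum.
    """
    retained: list[SampleMeta] = []
    dropped: list[tuple[SampleMeta, str]] = []
    for s in samples:
        if s.call_rate >= config.min_call_rate:
            retained.append(s)
        else:
            reason = (
                f"call_rate {s.call_rate:.4f} < {config.min_call_rate:.4f}"
            )
            dropped.append((s, reason))
            logger.info("dropping sample %s: %s", s.sample_id, reason)
    return retained, dropped


def _gap(left_end: int, right_start: int) -> int:
    """bp between two intervals; 0 when contiguous, negative never occurs."""
    return right_start - left_end - 1


def _merge_chromosome(
    segs: list[SegmentCall], threshold: float
) -> list[SegmentCall]:
    confident = [s.confidence >= threshold for s in segs]
    if not any(confident):
        logger.warning(
            "chromosome %s of sample %s has no confident segment; "
            "dropping %d segments",
            segs[0].chrom, segs[0].sample_id, len(segs),
        )
        return []
    conf_idx = [i for i, c in enumerate(confident) if c]

    # assign every low-confidence segment to its nearest confident neighbour
    donor: list[int] = list(range(len(segs)))
    for i, seg in enumerate(segs):
        if confident[i]:
            continue
        left = max((j for j in conf_idx if j < i), default=None)
        right = min((j for j in conf_idx if j > i), default=None)
        if left is None:
            donor[i] = right
        elif right is None:
            donor[i] = left
        else:
            gap_left = _gap(segs[left].end, seg.start)
            gap_right = _gap(seg.end, segs[right].start)
            donor[i] = left if gap_left <= gap_right else right

    # Rewrite each absorbed segment with its donor's CN and confidence, then
    # coalesce contiguous pieces that trace back to the same donor so that a
    # segment absorbed by a contiguous neighbour simply extends it. Distinct
    # confident segments are never coalesced with each other, even when
    # their CN and confidence happen to coincide.
    out: list[SegmentCall] = []
    out_donor: list[int] = []
    for i, seg in enumerate(segs):
        d = segs[donor[i]]
        piece = SegmentCall(
            seg.sample_id, seg.chrom, seg.start, seg.end,
            d.copy_number, d.confidence,
        )
        if out and out[-1].end + 1 == piece.start and out_donor[-1] == donor[i]:
            prev = out[-1]
            out[-1] = SegmentCall(
                prev.sample_id, prev.chrom, prev.start, piece.end,
                prev.copy_number, prev.confidence,
            )
        else:
            out.append(piece)
            out_donor.append(donor[i])
    return out


def merge_low_confidence(
    segments: Sequence[SegmentCall],
    config: ProcessingConfig = ProcessingConfig(),
) -> list[SegmentCall]:
    """Absorb low-confidence segments into confident neighbours.

    ``segments`` must belong to a single sample, be sorted, and be
    non-overlapping. Every returned segment has confidence >= the threshold
    and the union of covered base pairs per chromosome is unchanged, except
    for chromosomes with no confident segment, which are dropped entirely.
    """
    segs = list(segments)
    if not segs:
        return []
    if len({s.sample_id for s in segs}) > 1:
        raise ValidationError("merge_low_confidence expects a single sample")
    validate_non_overlapping(segs)
    out: list[SegmentCall] = []
    for _, group in groupby(segs, key=lambda s: s.chrom):
        out.extend(_merge_chromosome(list(group), config.confidence_threshold))
    return out


def merge_all_samples(
    segments: Iterable[SegmentCall],
    config: ProcessingConfig = ProcessingConfig(),
) -> list[SegmentCall]:
    """Apply :func:`merge_low_confidence` sample by sample."""
    out: list[SegmentCall] = []
    ordered = sorted(
        segments, key=lambda s: (s.sample_id, chrom_sort_key(s.chrom), s.start)
    )
    for _, group in groupby(ordered, key=lambda s: s.sample_id):
        out.extend(merge_low_confidence(list(group), config))
    return out


def extract_variants(
    segments: Iterable[SegmentCall],
    config: ProcessingConfig = ProcessingConfig(),
) -> list[VariantCall]:
    """Confident, non-diploid, autosomal segments become variant calls."""
    return [
        VariantCall(
            s.sample_id, s.chrom, s.start, s.end, s.copy_number, s.confidence
        )
        for s in segments
        if s.confidence >= config.confidence_threshold
        and s.copy_number != 2
        and is_autosome(s.chrom)
    ]
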