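"""Core domain types shared by every pipeline stage.

Coordinates are 1-based inclusive throughout the package; BED input is
converted at the I/O boundary. Region length is therefore ``end - start + 1``.
Only autosomes ("1".."22") are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError

#: Autosome names in genome order; all other chromosomes are out of scope.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

_AUTOSOME_ORDER = {c: i for i, c in enumerate(AUTOSOMES)}


def chrom_sort_key(chrom: str) -> int:
    """Genome-order sort key for an autosome name."""
    return _AUTOSOME_ORDER[chrom]


def is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOME_ORDER


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; does not validate autosome membership."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


class Cohort(str, Enum):
    """Study group labels. Twin samples carry a pair id linking co-twins."""

    CTRL = "Ctrl"
    T1D = "T1D"
    TWIN_AFFECTED = "TwinAffected"
    TWIN_UNAFFECTED = "TwinUnaffected"
    RA = "RA"
    MS = "MS"


TWIN_COHORTS = frozenset({Cohort.TWIN_AFFECTED, Cohort.TWIN_UNAFFECTED})


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """One subject: id, cohort, optional twin pairing, array call rate."""

    sample_id: str
    cohort: Cohort
    twin_pair_id: str | None = None
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValidationError(
                f"call_rate {self.call_rate} for {self.sample_id!r} not in [0, 1]"
            )
        is_twin = self.cohort in TWIN_COHORTS
        if is_twin and not self.twin_pair_id:
            raise ValidationError(
                f"twin sample {self.sample_id!r} has no twin_pair_id"
            )
        if not is_twin and self.twin_pair_id:
            raise ValidationError(
                f"non-twin sample {self.sample_id!r} has twin_pair_id "
                f"{self.twin_pair_id!r}"
            )


@dataclass(frozen=True, slots=True)
class SegmentCall:
    """One contiguous copy-number segment of one sample.

    ``confidence`` is the caller's per-segment confidence score (larger is
    more confident); segments below the configured threshold are merged into
    confident neighbours before any downstream analysis.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    confidence: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end} "
                f"for sample {self.sample_id!r}"
            )
        if self.copy_number < 0 or int(self.copy_number) != self.copy_number:
            raise ValidationError(
                f"copy_number must be a non-negative integer, got "
                f"{self.copy_number!r}"
            )
        if self.confidence < 0:
            raise ValidationError(
                f"confidence must be >= 0, got {self.confidence!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class VariantCall:
    """A confident non-diploid segment: the unit of presence/absence analysis."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    confidence: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number == 2:
            raise ValidationError("VariantCall cannot have copy_number 2")
        if self.copy_number < 0:
            raise ValidationError("copy_number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class RegionSource(str, Enum):
    LIBRARY = "library"
    NOVEL = "novel"


@dataclass(frozen=True, slots=True)
class CnpRegion:
    """A catalogue entry: a known CNP or a novel CNV region (CNVR)."""

    region_id: str
    chrom: str
    start: int
    end: int
    source: RegionSource = RegionSource.LIBRARY

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad region interval {self.region_id}: "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Overlap in bp with a 1-based inclusive interval (0 if none)."""
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start) + 1)


class ProbeMap:
    """Sorted probe positions per chromosome.

    Positions are 1-based; within one chromosome they are stored sorted and
    deduplicated so that probe counts in a span can be answered with a pair
    of binary searches.
    """

    def __init__(self, positions: Mapping[str, Iterable[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.unique(np.asarray(list(pos), dtype=np.int64))
            if arr.size and arr[0] < 1:
                raise ValidationError(
                    f"probe position < 1 on chromosome {chrom}"
                )
            self._pos[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._pos, key=chrom_sort_key)

    @property
    def n_probes(self) -> int:
        return sum(a.size for a in self._pos.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of probes with position in [start, end] on ``chrom``."""
        arr = self._pos.get(chrom)
        if arr is None:
            return 0
        lo = int(np.searchsorted(arr, start, side="left"))
        hi = int(np.searchsorted(arr, end, side="right"))
        return hi - lo


def sort_segments(segments: Iterable[SegmentCall]) -> list[SegmentCall]:
    """Sort by (sample, chromosome genome order, start)."""
    return sorted(
        segments,
        key=lambda s: (s.sample_id, chrom_sort_key(s.chrom), s.start),
    )


def validate_non_overlapping(segments: list[SegmentCall]) -> None:
    """Require sorted per-sample, per-chromosome segments to be disjoint."""
    prev: SegmentCall | None = None
    for seg in segments:
        if (
            prev is not None
            and seg.sample_id == prev.sample_id
            and seg.chrom == prev.chrom
            and seg.start <= prev.end
        ):
            raise ValidationError(
                f"overlapping segments for sample {seg.sample_id!r} on "
                f"chromosome {seg.chrom}: {prev.start}-{prev.end} and "
                f"{seg.start}-{seg.end}"
            )
        prev = seg
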