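"""Cataloguing variant calls against a CNP library and novel-CNVR clustering.

Each confident variant call is assigned to the known copy-number
polymorphism (CNP) it overlaps most (>= 1 bp, largest overlap wins, ties to
the lexicographically lower region id). Calls overlapping no library region
are "novel" and are clustered per chromosome by single linkage: calls whose
spans overlap, or whose gap is at most ``max_novel_gap``, join one cluster;
each cluster becomes one CNV region (CNVR) spanning its members. The gap
default of 1 Mb reflects the distance over which a single variant can still
perturb gene regulation.

Regions finally pass a size/probe filter: strictly longer than
``min_region_length`` bp and containing at least ``min_probes`` array probe
positions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ValidationError
from .model import (
    CnpRegion,
    ProbeMap,
    RegionSource,
    VariantCall,
    chrom_sort_key,
)

NOVEL = "novel"


@dataclass(frozen=True, slots=True)
class CatalogueConfig:
    """Novel-clustering gap and the region size/probe filter.

    max_novel_gap
        Maximum bp gap between novel calls joined into one CNVR (default
        1 Mb).
    min_region_length
        Regions must be strictly longer than this many bp (default 1,000).
    min_probes
        Regions must contain at least this many probe positions (default 3).
    """

    max_novel_gap: int = 1_000_000
    min_region_length: int = 1_000
    min_probes: int = 3

    def __post_init__(self) -> None:
        if min(self.max_novel_gap, self.min_region_length, self.min_probes) <= 0:
            raise ValidationError("catalogue parameters must all be positive")


@dataclass(frozen=True, slots=True)
class CataloguedCall:
    """A variant call attributed to one catalogue region."""

    variant: VariantCall
    region_id: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValidationError("overlap_bp must be >= 1")


@dataclass(frozen=True)
class CnvRegionSummary:
    """A catalogue region together with its member calls and variant class."""

    region: CnpRegion
    variant_class: str  # "amplification" | "deletion" | "both"
    member_calls: tuple[CataloguedCall, ...] = field(default=())

    @property
    def n_samples_with_call(self) -> int:
        return len({c.variant.sample_id for c in self.member_calls})


class LibraryIndex:
    """Per-chromosome interval index over library regions."""

    def __init__(self, library: Iterable[CnpRegion]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.regions: dict[str, CnpRegion] = {}
        for r in library:
            if r.region_id in self.regions:
                raise ValidationError(f"duplicate region_id {r.region_id!r}")
            self.regions[r.region_id] = r
            # interval tree is half-open; +1 converts the inclusive end
            self._trees[r.chrom].addi(r.start, r.end + 1, r)

    def overlapping(self, chrom: str, start: int, end: int) -> list[CnpRegion]:
        return [iv.data for iv in self._trees[chrom].overlap(start, end + 1)]


def assign_to_cnp(
    variant: VariantCall, library: LibraryIndex | Sequence[CnpRegion]
) -> str:
    """Id of the library region overlapping the call most, or ``"novel"``.

    Largest overlap in bp wins; exact ties resolve to the lower region id.
    """
    index = library if isinstance(library, LibraryIndex) else LibraryIndex(library)
    hits = index.overlapping(variant.chrom, variant.start, variant.end)
    if not hits:
        return NOVEL
    best = min(
        hits,
        key=lambda r: (
            -r.overlap_bp(variant.chrom, variant.start, variant.end),
            r.region_id,
        ),
    )
    return best.region_id


def catalogue_calls(
    variants: Iterable[VariantCall],
    library: Sequence[CnpRegion] | LibraryIndex,
) -> tuple[list[CataloguedCall], list[VariantCall]]:
    """Split calls into (library-catalogued, novel) in one pass."""
    index = library if isinstance(library, LibraryIndex) else LibraryIndex(library)
    catalogued: list[CataloguedCall] = []
    novel: list[VariantCall] = []
    for v in variants:
        rid = assign_to_cnp(v, index)
        if rid == NOVEL:
            novel.append(v)
        else:
            region = index.regions[rid]
            catalogued.append(
                CataloguedCall(v, rid, region.overlap_bp(v.chrom, v.start, v.end))
            )
    return catalogued, novel


def cluster_novel(
    novel_calls: Sequence[VariantCall],
    config: CatalogueConfig = CatalogueConfig(),
    *,
    id_prefix: str = "A",
) -> list[CnpRegion]:
    """Single-linkage clustering of novel calls into CNVRs.

    Calls on one chromosome whose spans overlap or lie within
    ``max_novel_gap`` bp of each other join one cluster; the cluster's CNVR
    spans min(start)..max(end). Region ids are assigned in genome order
    (``A1``, ``A2``, ...). Output regions on one chromosome are pairwise
    separated by more than the gap.
    """
    ordered = sorted(novel_calls, key=lambda v: (chrom_sort_key(v.chrom), v.start))
    regions: list[CnpRegion] = []
    spans: list[tuple[str, int, int]] = []
    for v in ordered:
        if (
            spans
            and spans[-1][0] == v.chrom
            and v.start - spans[-1][2] - 1 <= config.max_novel_gap
        ):
            chrom, s, e = spans[-1]
            spans[-1] = (chrom, s, max(e, v.end))
        else:
            spans.append((v.chrom, v.start, v.end))
    for k, (chrom, s, e) in enumerate(spans, start=1):
        regions.append(
            CnpRegion(f"{id_prefix}{k}", chrom, s, e, RegionSource.NOVEL)
        )
    return regions


def classify_region(calls: Sequence[CataloguedCall]) -> str:
    """"deletion" if all member CN < 2, "amplification" if all > 2, else "both"."""
    if not calls:
        raise ValidationError("classify_region requires at least one call")
    cns = {c.variant.copy_number for c in calls}
    if all(cn < 2 for cn in cns):
        return "deletion"
    if all(cn > 2 for cn in cns):
        return "amplification"
    return "both"


def summarize_regions(
    catalogued: Iterable[CataloguedCall],
    regions: Sequence[CnpRegion],
) -> list[CnvRegionSummary]:
    """Group catalogued calls by region; regions without calls are skipped."""
    by_region: dict[str, list[CataloguedCall]] = defaultdict(list)
    for c in catalogued:
        by_region[c.region_id].append(c)
    out: list[CnvRegionSummary] = []
    for region in regions:
        members = by_region.get(region.region_id)
        if not members:
            continue
        out.append(
            CnvRegionSummary(region, classify_region(members), tuple(members))
        )
    return out


def filter_regions(
    regions: Sequence[CnpRegion],
    probe_map: ProbeMap,
    config: CatalogueConfig = CatalogueConfig(),
) -> list[CnpRegion]:
    """Keep regions strictly longer than the minimum with enough probes."""
    if probe_map is None:
        raise ValidationError("filter_regions requires a probe map")
    return [
        r
        for r in regions
        if r.length > config.min_region_length
        and probe_map.count_in(r.chrom, r.start, r.end) >= config.min_probes
    ]
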