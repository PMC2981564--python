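"""CNP assignment, novel CNVR clustering (with connected-components oracle),
region classification and size/probe filtering."""

import numpy as np
import networkx as nx
import pytest

from cnvassoc import (
    CatalogueConfig,
    CnpRegion,
    ProbeMap,
    ValidationError,
    VariantCall,
    assign_to_cnp,
    classify_region,
    cluster_novel,
    filter_regions,
)
from cnvassoc.catalogue import CataloguedCall, catalogue_calls
from cnvassoc.simulate import table_planted_regions

CFG = CatalogueConfig()


def var(start, end, cn=1, chrom="6", sample="s1"):
    return VariantCall(sample, chrom, start, end, cn, 9.0)


CNP934 = CnpRegion("CNP934", "6", 32_700_999, 32_710_085)


# ---------------------------------------------------------------------------
# assignment

def test_call_inside_cnp_is_assigned():
    assert assign_to_cnp(var(32_702_000, 32_705_000), [CNP934]) == "CNP934"


def test_call_with_no_overlap_is_novel():
    assert assign_to_cnp(var(40_000_000, 40_001_000), [CNP934]) == "novel"


def test_largest_overlap_wins():
    lib = [
        CnpRegion("CNP_A", "6", 1_000, 1_499),   # 500 bp overlap
        CnpRegion("CNP_B", "6", 1_500, 5_000),   # 1,500 bp overlap
    ]
    assert assign_to_cnp(var(1_000, 2_999), lib) == "CNP_B"


def test_overlap_tie_goes_to_lower_region_id():
    lib = [
        CnpRegion("CNP_B", "6", 1_000, 1_499),
        CnpRegion("CNP_A", "6", 1_500, 1_999),
    ]
    assert assign_to_cnp(var(1_000, 1_999), lib) == "CNP_A"


def test_every_call_maps_to_library_or_novel_cluster():
    lib = [CNP934]
    calls = [
        var(32_702_000, 32_705_000),            # library hit
        var(50_000_000, 50_005_000),            # novel
        var(50_900_000, 50_905_000, sample="s2"),  # joins the same cluster
    ]
    catalogued, novel = catalogue_calls(calls, lib)
    regions = cluster_novel(novel, CFG)
    assert len(catalogued) + len(novel) == len(calls)
    re_catalogued, leftover = catalogue_calls(novel, regions)
    assert leftover == []


# ---------------------------------------------------------------------------
# clustering

def test_cluster_spanning_calls_forms_single_cnvr():
    """Overlapping and nearby calls across samples fuse into one CNVR whose
    span covers the outermost breakpoints."""
    calls = [
        var(18_491_920, 18_600_000, chrom="15", sample="s1"),
        var(18_550_000, 18_900_000, chrom="15", sample="s2"),
        var(19_400_000, 19_803_369, chrom="15", sample="s3"),
    ]
    (region,) = cluster_novel(calls, CFG)
    assert (region.start, region.end) == (18_491_920, 19_803_369)
    assert region.length == 1_311_450


def test_calls_two_megabases_apart_form_two_cnvrs():
    calls = [var(1_000, 2_000, chrom="3"), var(2_001_000, 2_002_000, chrom="3")]
    regions = cluster_novel(calls, CFG)
    assert len(regions) == 2


def test_single_call_cluster_is_identity():
    (region,) = cluster_novel([var(10_000, 20_000, chrom="9")], CFG)
    assert (region.start, region.end) == (10_000, 20_000)


def test_cluster_ids_assigned_in_genome_order():
    calls = [
        var(5_000_000, 5_001_000, chrom="10"),
        var(1_000, 2_000, chrom="2"),
    ]
    regions = cluster_novel(calls, CFG)
    assert [(r.region_id, r.chrom) for r in regions] == [("A1", "2"), ("A2", "10")]


def _cluster_oracle(calls, max_gap):
    """Connected components of the overlap-or-near graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, a in enumerate(calls):
        for j, b in enumerate(calls[:i]):
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end) - 1
            if gap <= max_gap:
                g.add_edge(i, j)
    spans = []
    for comp in nx.connected_components(g):
        members = [calls[i] for i in comp]
        spans.append(
            (
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
            )
        )
    return sorted(spans)


@pytest.mark.parametrize("seed", range(8))
def test_clustering_matches_connected_components_oracle(seed):
    rng = np.random.default_rng(seed)
    calls = []
    for _ in range(int(rng.integers(1, 21))):
        chrom = str(rng.choice(["1", "2"]))
        start = int(rng.integers(1, 10_000_000))
        length = int(rng.integers(1, 500_000))
        calls.append(var(start, start + length - 1, chrom=chrom))
    regions = cluster_novel(calls, CFG)
    got = sorted((r.chrom, r.start, r.end) for r in regions)
    assert got == _cluster_oracle(calls, CFG.max_novel_gap)
    # clusters on one chromosome stay separated by more than the gap
    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for group in by_chrom.values():
        group.sort(key=lambda r: r.start)
        for a, b in zip(group, group[1:]):
            assert b.start - a.end - 1 > CFG.max_novel_gap


# ---------------------------------------------------------------------------
# classification

def _catalogued(cns):
    return [
        CataloguedCall(var(1_000, 2_000, cn=cn, sample=f"s{i}"), "R", 1_001)
        for i, cn in enumerate(cns)
    ]


@pytest.mark.parametrize(
    "cns,expected",
    [([0, 1], "deletion"), ([3], "amplification"), ([1, 3], "both"), ([4, 3], "amplification")],
)
def test_classify_region(cns, expected):
    assert classify_region(_catalogued(cns)) == expected


def test_classify_region_empty_is_error():
    with pytest.raises(ValidationError):
        classify_region([])


# ---------------------------------------------------------------------------
# filtering

def test_region_passing_both_filters_is_retained():
    """A 1,398 bp region covered by 3 probes survives the size/probe filter."""
    region = CnpRegion("CNP1303", "8", 51_194_577, 51_195_974)
    probes = ProbeMap({"8": [51_194_600, 51_195_000, 51_195_900]})
    assert region.length == 1_398
    assert filter_regions([region], probes, CFG) == [region]


def test_short_region_dropped_despite_probes():
    region = CnpRegion("R", "8", 1_000, 1_899)  # 900 bp
    probes = ProbeMap({"8": [1_100, 1_200, 1_300, 1_400, 1_500]})
    assert filter_regions([region], probes, CFG) == []


def test_region_with_too_few_probes_dropped():
    region = CnpRegion("R", "8", 1_000, 5_999)  # 5,000 bp
    probes = ProbeMap({"8": [1_100, 1_200]})
    assert filter_regions([region], probes, CFG) == []


def test_missing_probe_map_is_error():
    with pytest.raises(ValidationError):
        filter_regions([CNP934], None, CFG)


def test_all_reported_regions_pass_filter_with_adequate_probes():
    """The nine reported differential regions all exceed 1 kb, so with >= 3
    in-span probes each, the filter keeps all nine."""
    regions = [p.as_region() for p in table_planted_regions()]
    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).extend(
            np.linspace(r.start, r.end, 3).astype(int)
        )
    probes = ProbeMap(by_chrom)
    assert len(filter_regions(regions, probes, CFG)) == 9
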