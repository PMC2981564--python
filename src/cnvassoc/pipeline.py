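"""End-to-end orchestration of the CNV association analysis.

Stage order is fixed: sample QC -> low-confidence merge -> variant
extraction -> cataloguing against the CNP library (novel calls clustered
into CNVRs) -> presence matrix over the full region universe -> case-vs-
control and twin-vs-control association -> cross-cohort overlap ->
permutation test on the overlap count -> twin-pair discordance ->
size/probe filtering for the final report table. A fixed configuration and
seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .association import (
    AssociationConfig,
    AssociationResult,
    AssociationTableRow,
    PermutationResult,
    PresenceMatrix,
    associate,
    build_presence_matrix,
    chi_square_presence,
    cohort_frequency,
    overlap_across_cohorts,
    permutation_overlap_test,
    significance_stars,
    twin_discordant_variants,
    twin_pairs_from_manifest,
)
from .catalogue import (
    CataloguedCall,
    CatalogueConfig,
    CnvRegionSummary,
    catalogue_calls,
    cluster_novel,
    filter_regions,
    summarize_regions,
)
from .errors import ValidationError
from .io import write_association_table
from .model import (
    CnpRegion,
    Cohort,
    ProbeMap,
    SampleMeta,
    SegmentCall,
    TWIN_COHORTS,
)
from .segments import (
    ProcessingConfig,
    extract_variants,
    merge_all_samples,
    qc_filter_samples,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineResult:
    """Everything a pipeline run produces, in memory."""

    retained_samples: list[SampleMeta]
    dropped_samples: list[tuple[SampleMeta, str]]
    regions: list[CnpRegion]  # library + novel CNVRs
    summaries: list[CnvRegionSummary]
    matrix: PresenceMatrix
    results_case: dict[str, AssociationResult]
    results_twin: dict[str, AssociationResult]
    shared_enriched: list[str]
    shared_depleted: list[str]
    permutation: PermutationResult | None
    twin_discordance: pd.DataFrame | None
    table_rows: list[AssociationTableRow]

    @property
    def overlap_count(self) -> int:
        return len(self.shared_enriched)


def _cohort_ids(samples: Sequence[SampleMeta], *cohorts: Cohort) -> list[str]:
    wanted = set(cohorts)
    return [s.sample_id for s in samples if s.cohort in wanted]


def run_pipeline(
    samples: Sequence[SampleMeta],
    calls: Sequence[SegmentCall],
    library: Sequence[CnpRegion],
    probe_map: ProbeMap,
    proc_config: ProcessingConfig = ProcessingConfig(),
    cat_config: CatalogueConfig = CatalogueConfig(),
    assoc_config: AssociationConfig = AssociationConfig(),
    *,
    run_permutation: bool = True,
) -> PipelineResult:
    """Run the full analysis and return all intermediate and final results."""
    retained, dropped = qc_filter_samples(samples, proc_config)
    logger.info(
        "QC: retained %d samples, dropped %d", len(retained), len(dropped)
    )
    retained_ids = {s.sample_id for s in retained}
    kept_calls = [c for c in calls if c.sample_id in retained_ids]

    merged = merge_all_samples(kept_calls, proc_config)
    variants = extract_variants(merged, proc_config)
    logger.info(
        "merge: %d segments -> %d, variants: %d",
        len(kept_calls), len(merged), len(variants),
    )

    catalogued, novel_calls = catalogue_calls(variants, library)
    novel_regions = cluster_novel(novel_calls, cat_config)
    regions = list(library) + novel_regions
    # attribute every call (library hits and novel members) to its region
    all_catalogued, leftover = catalogue_calls(variants, regions)
    if leftover:
        raise ValidationError(
            f"{len(leftover)} variant calls mapped to no region after "
            "novel clustering"
        )
    summaries = summarize_regions(all_catalogued, regions)
    logger.info(
        "catalogue: %d library regions, %d novel CNVRs, %d calls placed",
        len(library), len(novel_regions), len(all_catalogued),
    )

    matrix = build_presence_matrix(variants, regions, retained)
    ctrl_ids = _cohort_ids(retained, Cohort.CTRL)
    case_ids = _cohort_ids(retained, Cohort.T1D)
    twin_ids = _cohort_ids(retained, *TWIN_COHORTS)
    results_case = associate(matrix, case_ids, ctrl_ids, assoc_config)
    results_twin = associate(matrix, twin_ids, ctrl_ids, assoc_config)
    shared_enriched, shared_depleted = overlap_across_cohorts(
        results_case, results_twin
    )
    logger.info(
        "association: %d enriched-in-both, %d depleted-in-both",
        len(shared_enriched), len(shared_depleted),
    )

    permutation = None
    if run_permutation:
        permutation = permutation_overlap_test(
            matrix,
            (len(ctrl_ids), len(case_ids), len(twin_ids)),
            len(shared_enriched),
            assoc_config,
        )
        logger.info(
            "permutation: observed %d, p = %.4g",
            permutation.observed_overlap, permutation.p_value,
        )

    twin_disc = None
    pairs = twin_pairs_from_manifest(retained)
    if pairs:
        twin_disc = twin_discordant_variants(matrix, pairs)

    table_rows = build_table_rows(
        summaries,
        results_case,
        results_twin,
        shared_enriched + shared_depleted,
        probe_map,
        cat_config,
    )
    return PipelineResult(
        retained, dropped, regions, summaries, matrix,
        results_case, results_twin, shared_enriched, shared_depleted,
        permutation, twin_disc, table_rows,
    )


def build_table_rows(
    summaries: Sequence[CnvRegionSummary],
    results_case: Mapping[str, AssociationResult],
    results_twin: Mapping[str, AssociationResult],
    selected_ids: Sequence[str],
    probe_map: ProbeMap,
    cat_config: CatalogueConfig,
) -> list[AssociationTableRow]:
    """Final report rows: the overlap regions that pass the size/probe filter."""
    by_id = {s.region.region_id: s for s in summaries}
    selected = [by_id[rid].region for rid in selected_ids if rid in by_id]
    kept = {r.region_id for r in filter_regions(selected, probe_map, cat_config)}
    rows: list[AssociationTableRow] = []
    for rid in selected_ids:
        if rid not in kept:
            continue
        s = by_id[rid]
        rc, rt = results_case[rid], results_twin[rid]
        rows.append(
            AssociationTableRow(
                region=s.region,
                variant_class=s.variant_class,
                freq_ctrl=rc.ctrl.freq,
                freq_case=rc.case.freq,
                p_case=rc.p_value_vs_ctrl,
                freq_twin=rt.case.freq,
                p_twin=rt.p_value_vs_ctrl,
            )
        )
    return rows


def breakpoint_track(
    region_id: str, summaries: Sequence[CnvRegionSummary]
) -> pd.DataFrame:
    """Per-sample start/end/CN rows for one region's member calls."""
    for s in summaries:
        if s.region.region_id == region_id:
            if not s.member_calls:
                raise ValidationError(f"region {region_id!r} has no calls")
            rows = [
                {
                    "sample_id": c.variant.sample_id,
                    "start": c.variant.start,
                    "end": c.variant.end,
                    "copy_number": c.variant.copy_number,
                }
                for c in sorted(
                    s.member_calls, key=lambda c: (c.variant.start, c.variant.end)
                )
            ]
            return pd.DataFrame(rows)
    raise ValidationError(f"unknown region {region_id!r}")


DEFAULT_POOLING: dict[str, tuple[Cohort, ...]] = {
    "T1D_pooled": (Cohort.T1D, Cohort.TWIN_AFFECTED, Cohort.TWIN_UNAFFECTED),
    "RA": (Cohort.RA,),
    "MS": (Cohort.MS,),
}


def compare_cohorts(
    matrix: PresenceMatrix,
    samples: Sequence[SampleMeta],
    region_ids: Sequence[str],
    pooling: Mapping[str, tuple[Cohort, ...]] | None = None,
) -> pd.DataFrame:
    """Frequency of each region in Ctrl and each pooled cohort, with the
    chi-square p versus Ctrl and a significance tier (*, **, ***).

    The default pooling merges the unrelated cases with both members of
    every twin pair into one at-risk group, and keeps RA and MS separate;
    cohorts absent from the manifest are skipped.
    """
    pooling = dict(pooling) if pooling is not None else dict(DEFAULT_POOLING)
    ctrl_ids = _cohort_ids(samples, Cohort.CTRL)
    if not ctrl_ids:
        raise ValidationError("compare_cohorts requires a Ctrl cohort")
    f_ctrl = cohort_frequency(matrix, ctrl_ids)
    rows = []
    for rid in region_ids:
        row: dict[str, object] = {
            "region_id": rid,
            "Ctrl_freq": float(f_ctrl.at[rid, "freq"]),
        }
        for name, cohorts in pooling.items():
            ids = _cohort_ids(samples, *cohorts)
            if not ids:
                continue
            f = cohort_frequency(matrix, ids)
            k = int(f.at[rid, "n_present"])
            k_ctrl = int(f_ctrl.at[rid, "n_present"])
            p = chi_square_presence(
                k, k_ctrl, len(ids) - k, len(ctrl_ids) - k_ctrl
            )
            row[f"{name}_freq"] = float(f.at[rid, "freq"])
            row[f"{name}_p"] = p
            row[f"{name}_sig"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk outputs

def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    proc_config: ProcessingConfig,
    cat_config: CatalogueConfig,
    assoc_config: AssociationConfig,
) -> None:
    """Write the association table, permutation report, twin discordance
    table, catalogue summary and a machine-readable run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_association_table(result.table_rows, outdir / "association_table.tsv")

    cat_rows = [
        {
            "region_id": s.region.region_id,
            "chrom": s.region.chrom,
            "start": s.region.start,
            "end": s.region.end,
            "source": s.region.source.value,
            "variant_class": s.variant_class,
            "n_samples_with_call": s.n_samples_with_call,
        }
        for s in result.summaries
    ]
    pd.DataFrame(
        cat_rows,
        columns=[
            "region_id", "chrom", "start", "end", "source",
            "variant_class", "n_samples_with_call",
        ],
    ).to_csv(outdir / "catalogue.tsv", sep="\t", index=False)

    if result.permutation is not None:
        perm = result.permutation
        hist: dict[str, int] = {}
        for c in perm.null_counts:
            hist[str(c)] = hist.get(str(c), 0) + 1
        with open(outdir / "permutation.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "observed": perm.observed_overlap,
                    "n_permutations": len(perm.null_counts),
                    "seed": perm.rng_seed,
                    "p_value": perm.p_value,
                    "null_histogram": dict(sorted(hist.items(), key=lambda kv: int(kv[0]))),
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    if result.twin_discordance is not None:
        result.twin_discordance.rename_axis("region_id").to_csv(
            outdir / "twin_discordance.tsv", sep="\t"
        )

    manifest = {
        "package": "cnvassoc",
        "version": __version__,
        "processing": asdict(proc_config),
        "catalogue": asdict(cat_config),
        "association": asdict(assoc_config),
        "n_samples_retained": len(result.retained_samples),
        "n_samples_dropped": len(result.dropped_samples),
        "n_regions": len(result.regions),
        "shared_enriched": result.shared_enriched,
        "shared_depleted": result.shared_depleted,
    }
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
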