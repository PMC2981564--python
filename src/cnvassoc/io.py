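"""Readers and writers for the pipeline's file formats.

All on-disk tables are UTF-8 with a header line. Segment calls and the
association table are tab-delimited; the cohort manifest and qPCR replicate
tables are comma-delimited. The CNP library is accepted either as BED
(0-based half-open) or as a 1-based inclusive TSV, selected by a flag;
internally everything is 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .model import (
    AUTOSOMES,
    Cohort,
    CnpRegion,
    ProbeMap,
    RegionSource,
    SampleMeta,
    SegmentCall,
    TWIN_COHORTS,
    is_autosome,
    normalize_chrom,
    sort_segments,
    validate_non_overlapping,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample_id", "cohort", "twin_pair_id", "call_rate"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_number", "confidence"]
PROBE_COLUMNS = ["probe_id", "chrom", "position"]


# ---------------------------------------------------------------------------
# coordinate conventions

def bed_to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`bed_to_one_based`."""
    return start - 1, end


# ---------------------------------------------------------------------------
# manifest

def read_manifest(path: str | Path) -> list[SampleMeta]:
    """Read a cohort manifest CSV into validated :class:`SampleMeta` rows.

    Raises :class:`FormatError` on duplicate sample ids or unknown cohort
    labels, and :class:`ValidationError` when a twin pair lacks either its
    affected or unaffected member.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"duplicate sample_id(s) in manifest: {dups}")

    valid = {c.value for c in Cohort}
    samples: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        label = str(row.cohort).strip()
        if label not in valid:
            raise FormatError(
                f"unknown cohort label {label!r} for sample "
                f"{row.sample_id!r}; expected one of {sorted(valid)}"
            )
        pair = getattr(row, "twin_pair_id", None)
        pair = None if pair is None or pd.isna(pair) or pair == "" else str(pair)
        rate = getattr(row, "call_rate", None)
        if rate is None or pd.isna(rate) or rate == "":
            logger.warning(
                "sample %s has no call_rate; assuming 1.0", row.sample_id
            )
            rate = 1.0
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                cohort=Cohort(label),
                twin_pair_id=pair,
                call_rate=float(rate),
            )
        )
    validate_twin_pairs(samples)
    return samples


def validate_twin_pairs(samples: Sequence[SampleMeta]) -> None:
    """Each twin_pair_id must map to exactly one affected + one unaffected."""
    pairs: dict[str, list[Cohort]] = {}
    for s in samples:
        if s.cohort in TWIN_COHORTS:
            pairs.setdefault(s.twin_pair_id, []).append(s.cohort)
    for pair_id, cohorts in pairs.items():
        if sorted(c.value for c in cohorts) != ["TwinAffected", "TwinUnaffected"]:
            raise ValidationError(
                f"twin pair {pair_id!r} must have exactly one affected and "
                f"one unaffected member, got {[c.value for c in cohorts]}"
            )


def write_manifest(samples: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "cohort": s.cohort.value,
            "twin_pair_id": s.twin_pair_id or "",
            "call_rate": repr(s.call_rate),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# segment calls

def read_segment_calls(path: str | Path) -> list[SegmentCall]:
    """Read a raw segment-call TSV; autosomes only, sorted and validated.

    Non-autosomal rows (X, Y, M, ...) are skipped with a logged warning.
    Overlapping segments within one sample raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment table {path} missing columns {missing}")

    calls: list[SegmentCall] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        if not is_autosome(chrom):
            n_skipped += 1
            continue
        try:
            start, end = int(row.start), int(row.end)
            cn = int(row.copy_number)
            conf = float(row.confidence)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"bad segment row {tuple(row)}: {exc}") from exc
        if start > end:
            raise FormatError(
                f"segment start > end ({start} > {end}) for sample "
                f"{row.sample_id!r}"
            )
        try:
            calls.append(
                SegmentCall(str(row.sample_id), chrom, start, end, cn, conf)
            )
        except ValidationError as exc:
            raise FormatError(str(exc)) from exc
    if n_skipped:
        logger.warning(
            "skipped %d non-autosomal segment rows in %s", n_skipped, path
        )
    calls = sort_segments(calls)
    validate_non_overlapping(calls)
    return calls


def write_segment_calls(calls: Iterable[SegmentCall], path: str | Path) -> None:
    """Write segments as TSV. ``repr`` floats survive a read round-trip."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.copy_number}\t{c.confidence!r}\n"
            )


# ---------------------------------------------------------------------------
# CNP library

def read_cnp_library(
    path: str | Path, *, zero_based: bool = False
) -> list[CnpRegion]:
    """Read the reference CNP library.

    With ``zero_based=True`` the file is BED-like (0-based half-open,
    columns chrom,start,end,region_id, no header); otherwise a 1-based
    inclusive TSV with a header carrying the same column names.
    """
    if zero_based:
        df = pd.read_csv(
            path, sep=r"\s+", dtype=str, header=None,
            names=["chrom", "start", "end", "region_id"], comment="#",
        )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [
            c for c in ("chrom", "start", "end", "region_id")
            if c not in df.columns
        ]
        if missing:
            raise FormatError(f"CNP library {path} missing columns {missing}")
    if df.empty:
        logger.warning("CNP library %s is empty", path)
        return []
    if df["region_id"].duplicated().any():
        dups = sorted(df.loc[df["region_id"].duplicated(), "region_id"])
        raise FormatError(f"duplicate region_id(s) in CNP library: {dups}")

    regions: list[CnpRegion] = []
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        start, end = int(row.start), int(row.end)
        if zero_based:
            start, end = bed_to_one_based(start, end)
        regions.append(
            CnpRegion(str(row.region_id), chrom, start, end, RegionSource.LIBRARY)
        )
    return regions


def write_cnp_library(regions: Iterable[CnpRegion], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\tregion_id\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# probe map

def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"probe map {path} missing columns {missing}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"duplicate probe_id(s) in {path}")
    by_chrom: dict[str, list[int]] = {}
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        if is_autosome(chrom):
            by_chrom.setdefault(chrom, []).append(int(row.position))
    return ProbeMap(by_chrom)


def write_probe_map(probes: ProbeMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PROBE_COLUMNS) + "\n")
        i = 0
        for chrom in probes.chromosomes:
            for pos in probes.positions(chrom):
                fh.write(f"p{i}\t{chrom}\t{int(pos)}\n")
                i += 1


# ---------------------------------------------------------------------------
# association table

def format_p(p: float) -> str:
    """Render a p-value the way the result tables print it.

    Two decimals by default; values that would print as 0.00 get three
    decimals; anything smaller falls back to one-significant-digit
    scientific notation.
    """
    s = f"{p:.2f}"
    if s == "0.00":
        s = f"{p:.3f}"
    if s == "0.000":
        s = f"{p:.0e}"
    return s


def write_association_table(rows, path: str | Path) -> None:
    """Write the per-region association table (one row per region).

    ``rows`` are :class:`cnvassoc.association.AssociationTableRow`.
    Frequencies are printed as integer percents, p-values via
    :func:`format_p`.
    """
    header = [
        "CNP_ID", "Chr", "Start", "End", "Class",
        "Ctrl%", "T1D%", "p_T1D", "Twin%", "p_Twin",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        row.region.region_id,
                        row.region.chrom,
                        str(row.region.start),
                        str(row.region.end),
                        row.variant_class,
                        str(round(100 * row.freq_ctrl)),
                        str(round(100 * row.freq_case)),
                        format_p(row.p_case),
                        str(round(100 * row.freq_twin)),
                        format_p(row.p_twin),
                    ]
                )
                + "\n"
            )
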