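"""Cohort-level association statistics on presence/absence of CNVs.

A subject "has" a region's CNV when any of their confident non-diploid
calls overlaps the region by at least 1 bp; every statistic here operates
on that boolean presence matrix. A region is *enriched* in a case cohort
when its frequency there exceeds ``min_freq`` (strictly) and is at least
``min_fold`` times the control frequency; *depleted* is the mirror image.
Per-region significance is a Yates-corrected chi-square on the 2x2
present/absent x cohort table. The cross-cohort overlap count gets a
permutation p-value: group labels are reshuffled (sizes fixed), the number
of regions enriched in both non-control groups is recounted, and
``p = #(null >= observed) / n_permutations`` with no smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency

from .errors import ValidationError
from .model import CnpRegion, Cohort, SampleMeta, VariantCall

logger = logging.getLogger(__name__)

ENRICHED = "enriched"
DEPLETED = "depleted"
NEITHER = "neither"


@dataclass(frozen=True, slots=True)
class AssociationConfig:
    """Enrichment thresholds and permutation settings.

    min_freq
        Case frequency must strictly exceed this fraction (default 0.40).
    min_fold
        Case frequency must be at least this multiple of the control
        frequency (default 1.5; the boundary fold itself qualifies).
    n_permutations
        Label permutations for the overlap test (default 1,000).
    rng_seed
        Seed for the permutation RNG; fixed seed gives bit-identical output.
    """

    min_freq: float = 0.40
    min_fold: float = 1.5
    n_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_freq < 1:
            raise ValidationError("min_freq must be in (0, 1)")
        if self.min_fold < 1:
            raise ValidationError("min_fold must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


@dataclass(frozen=True, slots=True)
class CohortStats:
    n_present: int
    n_total: int

    @property
    def freq(self) -> float:
        return self.n_present / self.n_total


@dataclass(frozen=True, slots=True)
class AssociationResult:
    """Per-region case-versus-control comparison."""

    region_id: str
    case: CohortStats
    ctrl: CohortStats
    fold_vs_ctrl: float  # inf when ctrl frequency is 0 and case is not
    status: str  # enriched | depleted | neither
    p_value_vs_ctrl: float


@dataclass(frozen=True)
class PermutationResult:
    observed_overlap: int
    null_counts: tuple[int, ...]
    p_value: float
    rng_seed: int


@dataclass(frozen=True)
class AssociationTableRow:
    """One row of the combined result table (control/case/twin columns)."""

    region: CnpRegion
    variant_class: str
    freq_ctrl: float
    freq_case: float
    p_case: float
    freq_twin: float
    p_twin: float


class PresenceMatrix:
    """Samples x regions boolean matrix backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("presence matrix has duplicate labels")
        self.df = df.astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def regions(self) -> list[str]:
        return list(self.df.columns)

    def present(self, sample_id: str, region_id: str) -> bool:
        return bool(self.df.at[sample_id, region_id])

    def values(self) -> np.ndarray:
        return self.df.to_numpy()


def build_presence_matrix(
    variants: Iterable[VariantCall],
    regions: Sequence[CnpRegion],
    samples: Sequence[SampleMeta],
) -> PresenceMatrix:
    """True iff a sample has >= 1 confident variant overlapping the region.

    Samples without any call get an all-false row; a variant from a sample
    absent from the manifest is an error.
    """
    sample_ids = [s.sample_id for s in samples]
    idx = {sid: i for i, sid in enumerate(sample_ids)}
    ridx = {r.region_id: j for j, r in enumerate(regions)}
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r.region_id)
    cells = np.zeros((len(sample_ids), len(regions)), dtype=bool)
    for v in variants:
        if v.sample_id not in idx:
            raise ValidationError(
                f"variant call from unknown sample {v.sample_id!r}"
            )
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(v.start, v.end + 1):
            cells[idx[v.sample_id], ridx[iv.data]] = True
    return PresenceMatrix(
        pd.DataFrame(cells, index=sample_ids, columns=[r.region_id for r in regions])
    )


def cohort_frequency(
    matrix: PresenceMatrix, cohort_samples: Sequence[str]
) -> pd.DataFrame:
    """Per-region (n_present, n_total, freq) over the given samples."""
    if len(cohort_samples) == 0:
        raise ValidationError("cohort_frequency requires a non-empty cohort")
    sub = matrix.df.loc[list(cohort_samples)]
    n_present = sub.sum(axis=0).astype(int)
    n_total = len(cohort_samples)
    return pd.DataFrame(
        {
            "n_present": n_present,
            "n_total": n_total,
            "freq": n_present / n_total,
        }
    )


def classify_enrichment(
    freq_case: float,
    freq_ctrl: float,
    config: AssociationConfig = AssociationConfig(),
) -> str:
    """Classify one region from its case and control frequencies.

    Enriched: case frequency strictly above ``min_freq`` and at least
    ``min_fold`` times the control frequency (a zero control frequency with
    a qualifying case frequency is enriched). Depleted is symmetric with
    the roles swapped; anything else is neither.
    """
    if freq_case > config.min_freq and freq_case >= config.min_fold * freq_ctrl:
        return ENRICHED
    if freq_ctrl > config.min_freq and freq_ctrl >= config.min_fold * freq_case:
        return DEPLETED
    return NEITHER


def chi_square_presence(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p for the 2x2 table [[a, b], [c, d]] (present/absent rows
    x group columns), Pearson chi-square with Yates continuity correction
    at 1 df. A zero row or column margin means there is no variance to
    test; that returns p = 1.0 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("chi-square counts must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning(
            "degenerate 2x2 table %s: zero margin, returning p=1.0",
            table.tolist(),
        )
        return 1.0
    _, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)


def associate(
    matrix: PresenceMatrix,
    case_ids: Sequence[str],
    ctrl_ids: Sequence[str],
    config: AssociationConfig = AssociationConfig(),
) -> dict[str, AssociationResult]:
    """Case-vs-control frequencies, fold, status and chi-square p per region."""
    f_case = cohort_frequency(matrix, case_ids)
    f_ctrl = cohort_frequency(matrix, ctrl_ids)
    out: dict[str, AssociationResult] = {}
    for rid in matrix.regions:
        case = CohortStats(int(f_case.at[rid, "n_present"]), len(case_ids))
        ctrl = CohortStats(int(f_ctrl.at[rid, "n_present"]), len(ctrl_ids))
        if ctrl.freq == 0:
            fold = inf if case.freq > 0 else 1.0
        else:
            fold = case.freq / ctrl.freq
        status = classify_enrichment(case.freq, ctrl.freq, config)
        n_present = case.n_present + ctrl.n_present
        if n_present == 0 or n_present == case.n_total + ctrl.n_total:
            p = 1.0  # no variance anywhere: nothing to test
        else:
            p = chi_square_presence(
                case.n_present,
                ctrl.n_present,
                case.n_total - case.n_present,
                ctrl.n_total - ctrl.n_present,
            )
        out[rid] = AssociationResult(rid, case, ctrl, fold, status, p)
    return out


def overlap_across_cohorts(
    results_a: Mapping[str, AssociationResult],
    results_b: Mapping[str, AssociationResult],
) -> tuple[list[str], list[str]]:
    """Regions enriched in both result sets, and depleted in both.

    Both result sets must cover the same region universe.
    """
    if set(results_a) != set(results_b):
        raise ValidationError(
            "overlap_across_cohorts requires identical region universes"
        )
    shared_enriched = sorted(
        rid
        for rid, res in results_a.items()
        if res.status == ENRICHED and results_b[rid].status == ENRICHED
    )
    shared_depleted = sorted(
        rid
        for rid, res in results_a.items()
        if res.status == DEPLETED and results_b[rid].status == DEPLETED
    )
    return shared_enriched, shared_depleted


def twin_discordant_variants(
    matrix: PresenceMatrix,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-region counts of pairs discordant toward each disease status.

    ``pairs`` are (affected_sample_id, unaffected_sample_id) tuples. For
    each region the affected-only column counts pairs where only the
    affected twin carries the variant, and symmetrically for
    unaffected-only. Concordant pairs contribute to neither.
    """
    known = set(matrix.samples)
    for aff, unaff in pairs:
        if aff not in known or unaff not in known:
            raise ValidationError(
                f"incomplete twin pair ({aff!r}, {unaff!r}) in presence matrix"
            )
    aff_rows = matrix.df.loc[[a for a, _ in pairs]].to_numpy()
    unaff_rows = matrix.df.loc[[u for _, u in pairs]].to_numpy()
    return pd.DataFrame(
        {
            "affected_only": (aff_rows & ~unaff_rows).sum(axis=0),
            "unaffected_only": (~aff_rows & unaff_rows).sum(axis=0),
        },
        index=matrix.regions,
    )


def twin_pairs_from_manifest(
    samples: Sequence[SampleMeta],
) -> list[tuple[str, str]]:
    """(affected, unaffected) sample-id pairs, sorted by pair id."""
    by_pair: dict[str, dict[Cohort, str]] = {}
    for s in samples:
        if s.twin_pair_id is not None:
            by_pair.setdefault(s.twin_pair_id, {})[s.cohort] = s.sample_id
    pairs = []
    for pid in sorted(by_pair):
        members = by_pair[pid]
        if set(members) != {Cohort.TWIN_AFFECTED, Cohort.TWIN_UNAFFECTED}:
            raise ValidationError(f"twin pair {pid!r} is incomplete")
        pairs.append(
            (members[Cohort.TWIN_AFFECTED], members[Cohort.TWIN_UNAFFECTED])
        )
    return pairs


def _count_enriched_both(
    X: np.ndarray,
    ctrl_rows: np.ndarray,
    case_rows: np.ndarray,
    twin_rows: np.ndarray,
    config: AssociationConfig,
) -> int:
    f_ctrl = X[ctrl_rows].mean(axis=0)
    f_case = X[case_rows].mean(axis=0)
    f_twin = X[twin_rows].mean(axis=0)
    enriched_case = (f_case > config.min_freq) & (
        f_case >= config.min_fold * f_ctrl
    )
    enriched_twin = (f_twin > config.min_freq) & (
        f_twin >= config.min_fold * f_ctrl
    )
    return int((enriched_case & enriched_twin).sum())


def permutation_overlap_test(
    matrix: PresenceMatrix,
    group_sizes: tuple[int, int, int],
    observed_overlap: int,
    config: AssociationConfig = AssociationConfig(),
) -> PermutationResult:
    """Permutation null for the count of regions enriched in both disease
    groups versus control.

    ``group_sizes`` is (n_ctrl, n_case, n_twin); their sum must equal the
    number of samples in the matrix. Each permutation reassigns samples to
    the three groups uniformly at random with sizes fixed and recounts the
    regions enriched (per :func:`classify_enrichment`) in both non-control
    groups relative to the permuted control group. The p-value is the
    fraction of permutations with a count >= the observed one.
    """
    n_ctrl, n_case, n_twin = group_sizes
    X = matrix.values()
    if n_ctrl + n_case + n_twin != X.shape[0]:
        raise ValidationError(
            f"group sizes {group_sizes} do not sum to the "
            f"{X.shape[0]} samples in the matrix"
        )
    if min(group_sizes) < 1:
        raise ValidationError("all three groups must be non-empty")
    rng = np.random.default_rng(config.rng_seed)
    Xf = X.astype(np.float64)
    null_counts = np.empty(config.n_permutations, dtype=np.int64)
    for i in range(config.n_permutations):
        perm = rng.permutation(X.shape[0])
        null_counts[i] = _count_enriched_both(
            Xf,
            perm[:n_ctrl],
            perm[n_ctrl : n_ctrl + n_case],
            perm[n_ctrl + n_case :],
            config,
        )
    p = float((null_counts >= observed_overlap).sum() / config.n_permutations)
    return PermutationResult(
        observed_overlap, tuple(int(c) for c in null_counts), p, config.rng_seed
    )


def significance_stars(p: float) -> str:
    """Tiered significance marker: * p<0.05, ** p<0.005, *** p<0.0005."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""
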