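"""Synthetic study generator with known ground truth.

Emulates the structure of raw array copy-number output: every chromosome of
every sample is tiled wall-to-wall with integer-CN segments carrying
confidence scores. Baseline genome is diploid (explicit CN=2 segments, so
the merge logic is exercised); planted regions carry non-diploid calls at
per-cohort frequencies; low-confidence "sliver" fragments are injected at a
configurable rate to emulate the fragmented, noisy segments real callers
emit. Twin pairs share all calls except at explicitly designated discordant
regions.

Carrier selection supports two modes. ``exact`` (default) plants
``round_half_up(freq * n)`` carriers chosen at random, so every generated
cohort hits its target frequency exactly and region status is recoverable
deterministically; ``binomial`` draws each sample independently with
probability ``freq``, which is the right mode for sampling-noise and
calibration studies.

All stochastic choices flow from one ``numpy`` Generator seeded by
``rng_seed``; a fixed seed reproduces the study bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    AUTOSOMES,
    Cohort,
    CnpRegion,
    ProbeMap,
    RegionSource,
    SampleMeta,
    SegmentCall,
    chrom_sort_key,
)
from .qpcr import NO_AMPLIFICATION_CT, QpcrMeasurement

#: Fast default genome: 22 autosomes of 50 Mb.
GENOME_FAST: dict[str, int] = {c: 50_000_000 for c in AUTOSOMES}

#: Real autosome lengths of the hg18 (NCBI36) assembly.
GENOME_HG18: dict[str, int] = {
    "1": 247_249_719, "2": 242_951_149, "3": 199_501_827, "4": 191_273_063,
    "5": 180_857_866, "6": 170_899_992, "7": 158_821_424, "8": 146_274_826,
    "9": 140_273_252, "10": 135_374_737, "11": 134_452_384, "12": 132_349_534,
    "13": 114_142_980, "14": 106_368_585, "15": 100_338_915, "16": 88_827_254,
    "17": 78_774_742, "18": 76_117_153, "19": 63_811_651, "20": 62_435_964,
    "21": 46_944_323, "22": 49_691_432,
}


@dataclass(frozen=True, slots=True)
class PlantedRegion:
    """A ground-truth differential region with per-cohort carrier freqs."""

    region_id: str
    chrom: str
    start: int
    end: int
    variant_class: str  # "deletion" | "amplification" | "both"
    freq_ctrl: float
    freq_case: float
    freq_twin: float
    in_library: bool = True

    def __post_init__(self) -> None:
        for f in (self.freq_ctrl, self.freq_case, self.freq_twin):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"frequency {f} not in [0, 1]")
        if self.variant_class not in ("deletion", "amplification", "both"):
            raise ValidationError(
                f"unknown variant_class {self.variant_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def as_region(self) -> CnpRegion:
        return CnpRegion(
            self.region_id, self.chrom, self.start, self.end,
            RegionSource.LIBRARY if self.in_library else RegionSource.NOVEL,
        )


#: The nine differential regions used as the default planted truth:
#: real coordinates, classes and cohort frequencies of the study's
#: reported enriched/depleted regions (five deletions enriched in cases,
#: three deletions plus one mixed-class novel CNVR depleted).
_TABLE_REGIONS: tuple[tuple[str, str, int, int, str, float, float, float, bool], ...] = (
    ("CNP253",  "2",  87_600_933, 87_609_093, "deletion", 0.42, 0.72, 0.70, True),
    ("CNP934",  "6",  32_700_999, 32_710_085, "deletion", 0.42, 0.89, 0.65, True),
    ("CNP1162", "7", 133_435_735, 133_449_694, "deletion", 0.37, 0.78, 0.80, True),
    ("CNP1303", "8",  51_194_577, 51_195_974, "deletion", 0.21, 0.61, 0.50, True),
    ("CNP1956", "13", 71_375_556, 71_378_557, "deletion", 0.58, 0.89, 0.95, True),
    ("CNP1102", "7",  66_266_764, 66_282_667, "deletion", 0.68, 0.39, 0.10, True),
    ("CNP1879", "12", 98_319_424, 98_322_865, "deletion", 0.47, 0.22, 0.10, True),
    ("A588",    "15", 18_491_920, 19_803_369, "both",     0.58, 0.33, 0.10, False),
    ("CNP2240", "17", 15_483_886, 15_487_515, "deletion", 0.42, 0.22, 0.00, True),
)


def table_planted_regions(
    genome: Mapping[str, int] = GENOME_HG18,
) -> list[PlantedRegion]:
    """The default planted truth, rescaled to fit genomes shorter than hg18.

    Under hg18 lengths the real coordinates are used verbatim; under a
    shorter genome model each region keeps its length and is moved to the
    proportional position on its chromosome.
    """
    out: list[PlantedRegion] = []
    for rid, chrom, start, end, cls, fc, fd, ft, in_lib in _TABLE_REGIONS:
        clen = genome[chrom]
        if end > clen:
            length = end - start + 1
            scale = clen / GENOME_HG18[chrom]
            start = max(1, int((start - 1) * scale) + 1)
            end = min(clen, start + length - 1)
        out.append(PlantedRegion(rid, chrom, start, end, cls, fc, fd, ft, in_lib))
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level knobs for the generator.

    Defaults mirror the emulated study: cohorts of 19 controls, 18 cases
    and 10 twin pairs, a 1,320-region CNP library, confident-call
    confidences uniform on [5.5, 20], sliver confidences uniform on [0, 5),
    and a 10% per-chromosome fragmentation rate.
    """

    rng_seed: int = 0
    n_ctrl: int = 19
    n_case: int = 18
    n_twin_pairs: int = 10
    genome: Mapping[str, int] = field(default_factory=lambda: dict(GENOME_FAST))
    n_library_cnps: int = 1320
    planted: tuple[PlantedRegion, ...] | None = None  # None -> table defaults
    library_size_range: tuple[int, int] = (1_000, 100_000)
    confident_confidence: tuple[float, float] = (5.5, 20.0)
    sliver_confidence: tuple[float, float] = (0.0, 5.0)
    fragmentation_rate: float = 0.1
    sliver_length: tuple[int, int] = (1_000, 10_000)
    probe_spacing: int = 5_000
    probes_per_region: int = 5
    carrier_sampling: str = "exact"  # "exact" | "binomial"
    discordant_regions: tuple[tuple[str, str], ...] = ()
    # each entry: (region_id, "affected" | "unaffected") — which co-twin
    # carries the variant in every pair

    def __post_init__(self) -> None:
        if self.carrier_sampling not in ("exact", "binomial"):
            raise ValidationError(
                f"carrier_sampling must be 'exact' or 'binomial', "
                f"got {self.carrier_sampling!r}"
            )
        if not 0.0 <= self.fragmentation_rate <= 1.0:
            raise ValidationError("fragmentation_rate must be in [0, 1]")

    def planted_regions(self) -> list[PlantedRegion]:
        if self.planted is not None:
            return list(self.planted)
        return table_planted_regions(self.genome)


@dataclass(frozen=True)
class SimulatedStudy:
    """Everything a pipeline run needs, plus the ground truth."""

    samples: list[SampleMeta]
    calls: list[SegmentCall]
    library: list[CnpRegion]
    probe_map: ProbeMap
    truth: pd.DataFrame  # bool, samples x planted region ids
    planted: list[PlantedRegion]


# ---------------------------------------------------------------------------
# library and probe map

def generate_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CnpRegion]:
    """Place ``n_library_cnps`` disjoint regions uniformly on the genome.

    Sizes are log-uniform over ``library_size_range``. Regions avoid the
    planted spans (planted library regions are added afterwards with their
    own ids, novel planted spans stay free so the calls there are truly
    novel). Raises when the requested regions cannot be placed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    chroms = sorted(config.genome, key=chrom_sort_key)
    lengths = np.array([config.genome[c] for c in chroms], dtype=np.float64)
    planted = config.planted_regions()

    # allocate counts per chromosome proportional to length (largest remainder)
    n = config.n_library_cnps
    quota = lengths / lengths.sum() * n
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    for i in np.argsort(-(quota - counts))[:remainder]:
        counts[i] += 1

    lo, hi = config.library_size_range
    occupied: dict[str, list[tuple[int, int]]] = {
        c: sorted(
            (p.start, p.end) for p in planted if p.chrom == c
        )
        for c in chroms
    }
    regions: list[CnpRegion] = []
    k = 0
    for chrom, count in zip(chroms, counts):
        clen = config.genome[chrom]
        placed = 0
        attempts = 0
        max_attempts = 1000 * max(1, count)
        spans = occupied[chrom]
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise ValidationError(
                    f"cannot place {count} library regions on "
                    f"chromosome {chrom} (length {clen})"
                )
            size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
            size = max(lo, min(hi, size))
            if size >= clen:
                continue
            start = int(rng.integers(1, clen - size + 1))
            end = start + size - 1
            if any(s <= end and start <= e for s, e in spans):
                continue
            spans.append((start, end))
            spans.sort()
            k += 1
            regions.append(
                CnpRegion(f"CNP_S{k:04d}", chrom, start, end, RegionSource.LIBRARY)
            )
            placed += 1
    regions.extend(p.as_region() for p in planted if p.in_library)
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start))
    return regions


def generate_probe_map(
    config: SimulationConfig, library: Sequence[CnpRegion]
) -> ProbeMap:
    """Background probe grid plus targeted probes inside every region.

    Mirrors a genotyping array's design: evenly spaced background probes at
    ``probe_spacing`` plus ``probes_per_region`` probes inside each library
    region and each planted span, so catalogued regions are identifiable by
    consecutive probes.
    """
    positions: dict[str, list[np.ndarray]] = {}
    for chrom in sorted(config.genome, key=chrom_sort_key):
        clen = config.genome[chrom]
        grid = np.arange(config.probe_spacing, clen, config.probe_spacing)
        positions[chrom] = [grid]
    targets = [(r.chrom, r.start, r.end) for r in library]
    targets += [
        (p.chrom, p.start, p.end)
        for p in config.planted_regions()
        if not p.in_library
    ]
    for chrom, start, end in targets:
        inside = np.linspace(start, end, config.probes_per_region)
        positions[chrom].append(np.round(inside).astype(np.int64))
    return ProbeMap(
        {c: np.concatenate(parts) for c, parts in positions.items()}
    )


# ---------------------------------------------------------------------------
# carriers and per-sample genomes

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_carriers(
    rng: np.random.Generator,
    ids: Sequence[str],
    freq: float,
    mode: str = "exact",
) -> set[str]:
    """Choose which samples carry a planted variant.

    ``exact`` plants round-half-up(freq * n) carriers at random positions;
    ``binomial`` draws each sample independently with probability ``freq``.
    """
    ids = list(ids)
    if mode == "exact":
        k = _round_half_up(freq * len(ids))
        chosen = rng.choice(len(ids), size=k, replace=False) if k else []
        return {ids[int(i)] for i in chosen}
    if mode == "binomial":
        draws = rng.random(len(ids))
        return {sid for sid, u in zip(ids, draws) if u < freq}
    raise ValidationError(f"unknown carrier sampling mode {mode!r}")


def _planted_call_interval(
    rng: np.random.Generator, p: PlantedRegion
) -> tuple[int, int]:
    """The genomic interval of one carrier's call for a planted region.

    Library CNPs are called at the full region span (the caller's
    predefined-region genotyping). Novel regions emit partial, varying
    sub-spans — the breakpoint heterogeneity seen in real CNVRs — of
    10-60% of the region length, uniformly placed.
    """
    if p.in_library:
        return p.start, p.end
    frac = rng.uniform(0.1, 0.6)
    length = max(1, int(round(frac * p.length)))
    start = int(rng.integers(p.start, p.end - length + 2))
    return start, start + length - 1


def _planted_call_cn(rng: np.random.Generator, variant_class: str) -> int:
    if variant_class == "deletion":
        return int(rng.integers(0, 2))  # 0 or 1
    if variant_class == "amplification":
        return 3
    return int(rng.choice([1, 3]))  # "both": mixture across carriers


def _build_sample_segments(
    rng: np.random.Generator,
    sample_id: str,
    genome: Mapping[str, int],
    calls: Sequence[tuple[str, int, int, int]],  # (chrom, start, end, cn)
    config: SimulationConfig,
) -> list[SegmentCall]:
    """Tile every chromosome with CN2 baseline around the planted calls,
    then inject low-confidence slivers strictly inside baseline segments."""
    clo, chi = config.confident_confidence
    slo, shi = config.sliver_confidence
    smin, smax = config.sliver_length
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, cn in calls:
        by_chrom.setdefault(chrom, []).append((start, end, cn))
    segments: list[SegmentCall] = []
    for chrom in sorted(genome, key=chrom_sort_key):
        clen = genome[chrom]
        pieces: list[tuple[int, int, int, bool]] = []  # start, end, cn, is_variant
        cursor = 1
        for start, end, cn in sorted(by_chrom.get(chrom, [])):
            if start > cursor:
                pieces.append((cursor, start - 1, 2, False))
            pieces.append((start, end, cn, True))
            cursor = end + 1
        if cursor <= clen:
            pieces.append((cursor, clen, 2, False))

        # inject at most one sliver per chromosome, interior to a baseline
        # piece so the merge step always has flanking confident CN2 donors
        if rng.random() < config.fragmentation_rate:
            candidates = [
                i for i, (s, e, _, is_v) in enumerate(pieces)
                if not is_v and (e - s + 1) > smax + 2
            ]
            if candidates:
                i = int(rng.choice(candidates))
                s, e, cn, _ = pieces[i]
                slen = int(rng.integers(smin, smax + 1))
                sstart = int(rng.integers(s + 1, e - slen))
                scn = int(rng.choice([0, 1, 3]))
                sconf = float(rng.uniform(slo, shi))
                left = (s, sstart - 1, 2, False)
                sliver = (sstart, sstart + slen - 1, scn, None)
                right = (sstart + slen, e, 2, False)
                pieces[i : i + 1] = [left, sliver, right]
                segments_chrom = []
                for ps, pe, pcn, flag in pieces:
                    conf = sconf if flag is None else float(rng.uniform(clo, chi))
                    segments_chrom.append(
                        SegmentCall(sample_id, chrom, ps, pe, pcn, conf)
                    )
                segments.extend(segments_chrom)
                continue
        for ps, pe, pcn, _ in pieces:
            segments.append(
                SegmentCall(
                    sample_id, chrom, ps, pe, pcn, float(rng.uniform(clo, chi))
                )
            )
    return segments


# ---------------------------------------------------------------------------
# cohorts

def _make_unrelated(
    rng: np.random.Generator,
    config: SimulationConfig,
    planted: Sequence[PlantedRegion],
) -> tuple[list[SampleMeta], list[SegmentCall], pd.DataFrame]:
    samples = [
        SampleMeta(f"Ctrl{i + 1:02d}", Cohort.CTRL, None,
                   float(rng.uniform(0.986, 0.999)))
        for i in range(config.n_ctrl)
    ] + [
        SampleMeta(f"T1D{i + 1:02d}", Cohort.T1D, None,
                   float(rng.uniform(0.986, 0.999)))
        for i in range(config.n_case)
    ]
    ctrl_ids = [s.sample_id for s in samples if s.cohort is Cohort.CTRL]
    case_ids = [s.sample_id for s in samples if s.cohort is Cohort.T1D]
    all_ids = ctrl_ids + case_ids
    truth = pd.DataFrame(
        False, index=all_ids, columns=[p.region_id for p in planted]
    )
    per_sample_calls: dict[str, list[tuple[str, int, int, int]]] = {
        sid: [] for sid in all_ids
    }
    for p in planted:
        carriers = sample_carriers(
            rng, ctrl_ids, p.freq_ctrl, config.carrier_sampling
        ) | sample_carriers(rng, case_ids, p.freq_case, config.carrier_sampling)
        for sid in all_ids:  # fixed iteration order keeps the RNG stream stable
            if sid in carriers:
                start, end = _planted_call_interval(rng, p)
                cn = _planted_call_cn(rng, p.variant_class)
                per_sample_calls[sid].append((p.chrom, start, end, cn))
                truth.at[sid, p.region_id] = True
    calls: list[SegmentCall] = []
    for sid in all_ids:
        calls.extend(
            _build_sample_segments(
                rng, sid, config.genome, per_sample_calls[sid], config
            )
        )
    return samples, calls, truth


def generate_cohort(
    config: SimulationConfig,
    library: Sequence[CnpRegion] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SampleMeta], list[SegmentCall], pd.DataFrame]:
    """Control + case samples with planted calls; returns (manifest rows,
    segment calls, truth table)."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    return _make_unrelated(rng, config, config.planted_regions())


def generate_twin_pairs(
    config: SimulationConfig,
    library: Sequence[CnpRegion] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SampleMeta], list[SegmentCall], pd.DataFrame]:
    """Monozygotic twin pairs: co-twins share every call except at the
    configured discordant regions, where exactly one twin per pair carries.

    Pair-level carrier frequency equals ``freq_twin``, so the cohort-level
    (individual) frequency matches it too.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    planted = config.planted_regions()
    discordant = dict(config.discordant_regions)
    for rid, side in discordant.items():
        if side not in ("affected", "unaffected"):
            raise ValidationError(
                f"discordant side for {rid!r} must be 'affected' or "
                f"'unaffected', got {side!r}"
            )

    samples: list[SampleMeta] = []
    pair_ids = [f"P{i + 1:02d}" for i in range(config.n_twin_pairs)]
    for pid in pair_ids:
        rate_a = float(rng.uniform(0.986, 0.999))
        rate_b = float(rng.uniform(0.986, 0.999))
        samples.append(
            SampleMeta(f"Twin{pid}a", Cohort.TWIN_AFFECTED, pid, rate_a)
        )
        samples.append(
            SampleMeta(f"Twin{pid}b", Cohort.TWIN_UNAFFECTED, pid, rate_b)
        )
    all_ids = [s.sample_id for s in samples]
    truth = pd.DataFrame(
        False, index=all_ids, columns=[p.region_id for p in planted]
    )
    per_sample_calls: dict[str, list[tuple[str, int, int, int]]] = {
        sid: [] for sid in all_ids
    }
    for p in planted:
        side = discordant.get(p.region_id)
        carrier_pairs = sample_carriers(
            rng, pair_ids, p.freq_twin, config.carrier_sampling
        )
        for pid in pair_ids:
            if pid not in carrier_pairs:
                continue
            start, end = _planted_call_interval(rng, p)
            cn = _planted_call_cn(rng, p.variant_class)
            if side is None:
                members = [f"Twin{pid}a", f"Twin{pid}b"]
            elif side == "affected":
                members = [f"Twin{pid}a"]
            else:
                members = [f"Twin{pid}b"]
            for sid in members:
                per_sample_calls[sid].append((p.chrom, start, end, cn))
                truth.at[sid, p.region_id] = True
    calls: list[SegmentCall] = []
    for sid in all_ids:
        calls.extend(
            _build_sample_segments(
                rng, sid, config.genome, per_sample_calls[sid], config
            )
        )
    return samples, calls, truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full study bundle: library, probe map, all three cohorts, truth."""
    rng = np.random.default_rng(config.rng_seed)
    planted = config.planted_regions()
    library = generate_library(config, rng)
    probe_map = generate_probe_map(config, library)
    samples_u, calls_u, truth_u = generate_cohort(config, library, rng)
    samples_t, calls_t, truth_t = generate_twin_pairs(config, library, rng)
    return SimulatedStudy(
        samples=samples_u + samples_t,
        calls=calls_u + calls_t,
        library=library,
        probe_map=probe_map,
        truth=pd.concat([truth_u, truth_t]),
        planted=planted,
    )


# ---------------------------------------------------------------------------
# qPCR

def generate_qpcr(
    truth_cns: Mapping[tuple[str, str], int],
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    base_ct: float = 25.0,
) -> list[QpcrMeasurement]:
    """Replicate Ct values for known integer copy numbers.

    Target Ct is ``base_ct - log2(CN / 2)`` plus Gaussian noise; a copy
    number of zero never amplifies and is emitted as the sentinel Ct of
    40. Reference Ct is ``base_ct`` plus independent noise.
    """
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasurement] = []
    for (sample_id, assay_id), cn in truth_cns.items():
        if cn < 0:
            raise ValidationError(f"truth copy number {cn} < 0")
        if cn == 0:
            target = tuple([NO_AMPLIFICATION_CT] * n_replicates)
        else:
            mu = base_ct - math.log2(cn / 2.0)
            target = tuple(
                float(mu + rng.normal(0.0, noise_sd)) for _ in range(n_replicates)
            )
        reference = tuple(
            float(base_ct + rng.normal(0.0, noise_sd))
            for _ in range(n_replicates)
        )
        out.append(QpcrMeasurement(sample_id, assay_id, target, reference))
    return out
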