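"""Copy-number estimation from qPCR replicate Ct values (ddCt method).

Each measurement is a set of replicate cycle-threshold (Ct) values for a
target assay multiplexed with a reference assay (e.g. RNase P, assumed two
copies). With amplification efficiency assumed to be exactly 2 per cycle:

    dCt  = mean(target Ct) - mean(reference Ct)
    ddCt = dCt - calibrator dCt          (calibrator assumed CN = 2)
    CN   = 2 * 2**(-ddCt)

The integer call is the nearest non-negative integer (half away from
zero), with a confidence in [0, 1] that shrinks as the real-valued
estimate drifts from the integer and as replicate dCt spread grows. The
calibrator dCt is the per-assay median of sample dCt values, anchoring the
cohort mode at two copies; no designated reference sample is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

QPCR_COLUMNS = ["sample_id", "assay_id", "well", "target_ct", "reference_ct"]

#: Ct emitted when the target fails to amplify (copy number zero).
NO_AMPLIFICATION_CT = 40.0


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate target/reference Ct values for one sample on one assay."""

    sample_id: str
    assay_id: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.target_ct) < 2 or len(self.reference_ct) < 2:
            raise ValidationError(
                f"{self.sample_id}/{self.assay_id}: need >= 2 replicates"
            )
        if len(self.target_ct) != len(self.reference_ct):
            raise ValidationError(
                f"{self.sample_id}/{self.assay_id}: target and reference "
                "replicate counts differ"
            )
        if min(*self.target_ct, *self.reference_ct) <= 0:
            raise ValidationError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_ct) - np.mean(self.reference_ct))

    @property
    def replicate_delta_ct(self) -> tuple[float, ...]:
        return tuple(t - r for t, r in zip(self.target_ct, self.reference_ct))


@dataclass(frozen=True, slots=True)
class QpcrResult:
    sample_id: str
    assay_id: str
    delta_ct: float
    delta_delta_ct: float
    cn_estimate: float
    cn_integer: int
    confidence: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def estimate_copy_number(
    m: QpcrMeasurement, calibrator_delta_ct: float
) -> QpcrResult:
    """ddCt copy-number estimate against a calibrator dCt of copy number 2.

    The confidence is the product of a rounding-error factor
    ``1 - 2*|CN - round(CN)|`` (1 when the estimate sits exactly on an
    integer, 0 at the midpoint) and a replicate-consistency factor
    ``exp(-var(replicate dCt))`` (population variance).
    """
    ddct = m.delta_ct - calibrator_delta_ct
    cn_est = 2.0 * 2.0 ** (-ddct)
    cn_int = max(0, _round_half_away(cn_est))
    rounding_factor = max(0.0, 1.0 - 2.0 * abs(cn_est - cn_int))
    spread = float(np.var(m.replicate_delta_ct))  # ddof=0: defined for 2 reps
    confidence = rounding_factor * math.exp(-spread)
    return QpcrResult(
        m.sample_id, m.assay_id, m.delta_ct, ddct, cn_est, cn_int, confidence
    )


def choose_calibrator(measurements: Sequence[QpcrMeasurement]) -> float:
    """Median per-sample dCt of one assay, the assumed copy-number-2 anchor."""
    if len(measurements) < 3:
        raise ValidationError(
            "choose_calibrator needs >= 3 samples to anchor the mode"
        )
    assays = {m.assay_id for m in measurements}
    if len(assays) > 1:
        raise ValidationError(
            f"calibrator must be chosen per assay, got {sorted(assays)}"
        )
    return float(median(m.delta_ct for m in measurements))


def call_assay(measurements: Sequence[QpcrMeasurement]) -> list[QpcrResult]:
    """Calibrate one assay and call every sample on it."""
    cal = choose_calibrator(measurements)
    return [estimate_copy_number(m, cal) for m in measurements]


def agreement(
    array_calls: Mapping[tuple[str, str], int],
    qpcr_calls: Mapping[tuple[str, str], int],
) -> tuple[dict[int, tuple[int, int, float]], float]:
    """Percent agreement between array and qPCR integer calls.

    Keys are (sample_id, region/assay id). Returns a per-array-CN-class
    mapping ``cn -> (n_agree, n_total, percent)`` over the shared keys,
    plus the overall percent agreement.
    """
    shared = sorted(set(array_calls) & set(qpcr_calls))
    if not shared:
        raise ValidationError("agreement requires overlapping call sets")
    per_class: dict[int, list[int]] = {}
    n_agree_total = 0
    for key in shared:
        cn = int(array_calls[key])
        agree = int(array_calls[key] == qpcr_calls[key])
        bucket = per_class.setdefault(cn, [0, 0])
        bucket[0] += agree
        bucket[1] += 1
        n_agree_total += agree
    out = {
        cn: (n_agree, n_total, 100.0 * n_agree / n_total)
        for cn, (n_agree, n_total) in sorted(per_class.items())
    }
    return out, 100.0 * n_agree_total / len(shared)


# ---------------------------------------------------------------------------
# I/O

def read_qpcr_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a replicate-level CSV (one row per well) into measurements."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"qPCR table {path} missing columns {missing}")
    grouped: dict[tuple[str, str], tuple[list[float], list[float]]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.sample_id), str(row.assay_id))
        tgt, ref = grouped.setdefault(key, ([], []))
        tgt.append(float(row.target_ct))
        ref.append(float(row.reference_ct))
    return [
        QpcrMeasurement(sid, aid, tuple(tgt), tuple(ref))
        for (sid, aid), (tgt, ref) in grouped.items()
    ]


def write_qpcr_results(
    results: Iterable[QpcrResult], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "assay_id": r.assay_id,
            "delta_ct": repr(r.delta_ct),
            "delta_delta_ct": repr(r.delta_delta_ct),
            "cn_estimate": repr(r.cn_estimate),
            "cn_integer": r.cn_integer,
            "confidence": repr(r.confidence),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
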