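"""Termination efficacy (TTE) and factor-dependency (TQRR) statistics.

TTE measures how completely transcription stops across a TTS quadruplet::

    TTE = 1 - reads[+2] / reads[-2]

so TTE = 1 is complete termination and negative values are excess
readthrough.  TQRR compares the (+2/-2) readthrough ratio between the
wild-type and a termination-factor depletion condition::

    TQRR = (WT[+2] / WT[-2]) / (dep[+2] / dep[-2])

TQRR < 1 means readthrough increased upon depletion, i.e. termination of
that TU depends on the factor (aCPSF1/FttA in the archaeal system this
package models).

Class boundaries follow the published convention: TTE groups high (> 60 %),
medium (30-60 %), low (< 30 %); dependency classes highly (TQRR ≤ 0.6),
moderately (0.6 < TQRR < 1) and non-dependent (TQRR ≥ 1).  The boundary
values 0.3/0.6, unassigned by strict inequalities, join the higher class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "UndefinedMetricError",
    "TerminationMetrics",
    "ReporterMeasurement",
    "compute_tte",
    "compute_tqrr",
    "classify_tte",
    "classify_dependency",
    "reporter_tte",
    "reporter_ta_ratio",
    "annotate_metrics",
    "metrics_to_frame",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric is undefined because a required count is zero."""


@dataclass
class TerminationMetrics:
    """Per-TU/TTS termination statistics (one record per called TTS)."""

    tu_id: str
    pos: int | None = None
    is_primary: bool = True
    tte_wt: float | None = None
    tte_dep: float | None = None
    tqrr: float | None = None
    tte_group: str | None = None
    dependency_class: str | None = None
    factor_dependent: bool | None = None  # tqrr < 1
    u4_count: int | None = None
    u4_group: str | None = None
    utr3_len: int | None = None


@dataclass(frozen=True)
class ReporterMeasurement:
    """Dual-reporter transcript abundances for one strain/terminator."""

    strain: str
    ta_luciferase: float
    ta_mcherry: float

    def __post_init__(self) -> None:
        if self.ta_luciferase <= 0:
            raise UndefinedMetricError(
                f"{self.strain}: luciferase abundance must be positive")
        if self.ta_mcherry < 0:
            raise ValueError(f"{self.strain}: negative mCherry abundance")


def compute_tte(reads_m2: float, reads_p2: float) -> float:
    """``1 - reads[+2]/reads[-2]``; negative readthrough values are kept."""
    if reads_m2 == 0:
        raise UndefinedMetricError("TTE undefined: zero count at the -2 site")
    return 1.0 - reads_p2 / reads_m2

def compute_tqrr(wt_m2: float, wt_p2: float,
                 dep_m2: float, dep_p2: float) -> float:
    """``(wt_p2/wt_m2) / (dep_p2/dep_m2)``; 0 when the WT readthrough is 0."""
    if wt_m2 == 0:
        raise UndefinedMetricError("TQRR undefined: zero WT count at -2")
    if dep_m2 == 0:
        raise UndefinedMetricError("TQRR undefined: zero depletion count at -2")
    if dep_p2 == 0:
        raise UndefinedMetricError("TQRR undefined: zero depletion count at +2")
    return (wt_p2 / wt_m2) / (dep_p2 / dep_m2)


def classify_tte(tte: float) -> str:
    """high iff TTE ≥ 0.6; medium iff 0.3 ≤ TTE < 0.6; low otherwise."""
    if tte >= 0.6:
        return "high"
    if tte >= 0.3:
        return "medium"
    return "low"


def classify_dependency(tqrr: float) -> str:
    """highly iff TQRR ≤ 0.6; moderately iff 0.6 < TQRR < 1; non iff ≥ 1."""
    if tqrr <= 0.6:
        return "highly"
    if tqrr < 1.0:
        return "moderately"
    return "non"


def reporter_tte(m: ReporterMeasurement) -> float:
    """Reporter-assay TTE: ``1 - TA(mCherry)/TA(luciferase)``."""
    return 1.0 - m.ta_mcherry / m.ta_luciferase


def reporter_ta_ratio(wt: ReporterMeasurement,
                      dep: ReporterMeasurement) -> float:
    """Reporter-assay dependency: WT mCherry/luciferase ratio over depletion's."""
    dep_ratio = dep.ta_mcherry / dep.ta_luciferase
    if dep_ratio == 0:
        raise UndefinedMetricError(
            "TA ratio undefined: zero depletion mCherry/luciferase ratio")
    return (wt.ta_mcherry / wt.ta_luciferase) / dep_ratio


def annotate_metrics(records: Iterable, wt_condition: str = "WT",
                     dep_condition: str | None = "dep",
                     ) -> list[TerminationMetrics]:
    """Compute TTE/TQRR and class labels for called-TTS records.

    ``records`` are :class:`~termtte.tts_caller.TTSRecord` objects whose
    ``quadruplet`` holds (-2, -1, +1, +2) counts per condition.  TUs with a
    zero denominator get ``None`` metrics and are excluded from group
    statistics downstream (they are counted in the run summary).
    """
    out = []
    for rec in records:
        m = TerminationMetrics(tu_id=rec.tu_id, pos=rec.pos,
                               is_primary=rec.is_primary,
                               utr3_len=rec.utr3_len)
        wt = rec.quadruplet.get(wt_condition)
        if wt is not None:
            try:
                m.tte_wt = compute_tte(wt[0], wt[3])
                m.tte_group = classify_tte(m.tte_wt)
            except UndefinedMetricError:
                pass
        dep = (rec.quadruplet.get(dep_condition)
               if dep_condition is not None else None)
        if dep is not None:
            try:
                m.tte_dep = compute_tte(dep[0], dep[3])
            except UndefinedMetricError:
                pass
            if wt is not None:
                try:
                    m.tqrr = compute_tqrr(wt[0], wt[3], dep[0], dep[3])
                    m.dependency_class = classify_dependency(m.tqrr)
                    m.factor_dependent = m.tqrr < 1
                except UndefinedMetricError:
                    pass
        out.append(m)
    return out


def metrics_to_frame(metrics: Sequence[TerminationMetrics]) -> pd.DataFrame:
    """Tabulate metrics records (None → NaN) for TSV output and statistics."""
    return pd.DataFrame([vars(m) for m in metrics])
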