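"""Per-nucleus ER positivity, the per-duct dynamic range, and case summaries.

ER staining of each retained nucleus is quantified as the mean optical
density of nuclear DAB.  A nucleus is *positive* when that mean OD reaches
the detectability threshold tau.  The staining-quality statistic for a duct
is its dynamic range,

    DR = (highest positive mean nuclear DAB OD
          - lowest positive mean nuclear DAB OD) * 100,

defined only when the duct holds at least ``min_positive_per_duct`` positive
nuclei (default 2; a range needs two points).  Normal luminal epithelium
expresses ER across a wide biological range, so a duct whose DR collapses
toward zero is evidence of a staining artefact rather than biology; cases
whose median DR falls in the extreme lower tail of a reference (control)
distribution are flagged for repeat testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import NucleusObject

__all__ = [
    "QuantParams",
    "DuctMeasurement",
    "CaseMeasurement",
    "QCResult",
    "REPEAT_TEST_RECOMMENDATION",
    "classify_positive",
    "duct_dynamic_range",
    "summarize_case",
    "qc_flag",
    "ducts_to_dataframe",
    "write_ducts_csv",
    "case_to_dict",
    "write_cases_json",
]

REPEAT_TEST_RECOMMENDATION = "repeat ER IHC testing"


@dataclass(frozen=True)
class QuantParams:
    """ER positivity threshold tau (mean nuclear DAB OD) and duct validity rule."""

    positivity_threshold: float = 0.10  #: tau; boundary inclusive
    min_positive_per_duct: int = 2

    def __post_init__(self) -> None:
        if self.positivity_threshold < 0:
            raise ValueError("positivity_threshold must be >= 0")
        if self.min_positive_per_duct < 2:
            raise ValueError("min_positive_per_duct must be >= 2")


@dataclass(frozen=True)
class DuctMeasurement:
    region_id: str
    positive_count: int
    min_positive_od: float  #: nan when invalid
    max_positive_od: float
    dynamic_range: float  #: (max - min) * 100; nan when invalid
    mean_nuclear_dab: float  #: mean of mean nuclear DAB OD over positive nuclei
    valid: bool


@dataclass(frozen=True)
class CaseMeasurement:
    case_id: str
    cohort: str  #: one of {low_er, control, tma} in the study design; free-form here
    ducts: tuple[DuctMeasurement, ...]
    n_valid_ducts: int
    case_median_dr: float  #: nan when uninterpretable
    case_dr_range: tuple[float, float]
    interpretable: bool  #: False when no duct has a valid dynamic range


@dataclass(frozen=True)
class QCResult:
    flagged: bool
    threshold: float  #: reference-distribution quantile value compared against
    recommendation: str | None


def classify_positive(nucleus: NucleusObject, params: QuantParams = QuantParams()) -> bool:
    """True iff the retained nucleus has mean DAB OD >= tau (boundary inclusive)."""
    if nucleus.exclusion_code != "none":
        raise ValueError(
            f"nucleus {nucleus.label} was excluded ({nucleus.exclusion_code}); "
            "only retained nuclei enter ER quantification"
        )
    return nucleus.mean_dab_od >= params.positivity_threshold


def duct_dynamic_range(
    nuclei: Iterable[NucleusObject],
    params: QuantParams = QuantParams(),
    region_id: str = "duct",
) -> DuctMeasurement:
    """Measure one duct: positive count and dynamic range over positive nuclei.

    With fewer than ``min_positive_per_duct`` positive nuclei the duct is
    marked invalid and its dynamic range reported as missing (nan).
    """
    positives = [n.mean_dab_od for n in nuclei if classify_positive(n, params)]
    count = len(positives)
    if count < params.min_positive_per_duct:
        return DuctMeasurement(region_id, count, math.nan, math.nan,
                               math.nan, math.nan, valid=False)
    lo, hi = min(positives), max(positives)
    return DuctMeasurement(
        region_id=region_id,
        positive_count=count,
        min_positive_od=lo,
        max_positive_od=hi,
        dynamic_range=(hi - lo) * 100.0,
        mean_nuclear_dab=float(np.mean(positives)),
        valid=True,
    )


def summarize_case(
    ducts: Sequence[DuctMeasurement],
    case_id: str,
    cohort: str,
) -> CaseMeasurement:
    """Median and range of the dynamic range over a case's valid ducts.

    A case with zero valid ducts is flagged uninterpretable — the analogue of
    excluding cases without internal control epithelium.
    """
    valid = [d for d in ducts if d.valid]
    if not valid:
        return CaseMeasurement(case_id, cohort, tuple(ducts), 0,
                               math.nan, (math.nan, math.nan), interpretable=False)
    drs = np.array([d.dynamic_range for d in valid])
    return CaseMeasurement(
        case_id=case_id,
        cohort=cohort,
        ducts=tuple(ducts),
        n_valid_ducts=len(valid),
        case_median_dr=float(np.median(drs)),
        case_dr_range=(float(drs.min()), float(drs.max())),
        interpretable=True,
    )


def qc_flag(
    case: CaseMeasurement,
    reference: Sequence[float],
    quantile: float = 0.05,
) -> QCResult:
    """Flag a case whose median DR sits below a low quantile of a reference set.

    ``reference`` is a distribution of per-case median dynamic ranges from
    control material; a flagged case carries the recommendation to repeat the
    ER IHC test.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference distribution is empty")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    threshold = float(np.quantile(ref, quantile))
    flagged = bool(case.case_median_dr < threshold)
    return QCResult(flagged, threshold,
                    REPEAT_TEST_RECOMMENDATION if flagged else None)


# ---------------------------------------------------------------------------
# I/O


def ducts_to_dataframe(ducts: Sequence[DuctMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [d.region_id for d in ducts],
            "positive_count": [d.positive_count for d in ducts],
            "min_positive_od": [d.min_positive_od for d in ducts],
            "max_positive_od": [d.max_positive_od for d in ducts],
            "dynamic_range": [d.dynamic_range for d in ducts],
            "valid": [d.valid for d in ducts],
        }
    )


def write_ducts_csv(path, ducts: Sequence[DuctMeasurement]) -> None:
    ducts_to_dataframe(ducts).to_csv(path, index=False)


def case_to_dict(case: CaseMeasurement) -> dict:
    def _none_if_nan(x: float):
        return None if isinstance(x, float) and math.isnan(x) else x

    return {
        "case_id": case.case_id,
        "cohort": case.cohort,
        "n_ducts": len(case.ducts),
        "n_valid_ducts": case.n_valid_ducts,
        "case_median_dr": _none_if_nan(case.case_median_dr),
        "case_dr_range": [_none_if_nan(v) for v in case.case_dr_range],
        "interpretable": case.interpretable,
    }


def write_cases_json(path, cases: Sequence[CaseMeasurement]) -> None:
    Path(path).write_text(json.dumps([case_to_dict(c) for c in cases], indent=2))
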