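"""Published clinical summary figures that anchor the synthetic generator.

The raw slide images behind the low-ER staining-quality study are withheld
for patient privacy, so the pipeline's cohort-level behaviour is validated
against the printed cohort summaries instead: prevalence of low-ER reports,
cohort sizes, per-case duct counts, per-duct positive counts, and the pooled
per-duct dynamic-range medians and ranges.  These constants are study inputs
(used for generator calibration and report annotation), never substitutes
for values the pipeline computes.
"""

from __future__ import annotations

__all__ = [
    "ER_TESTED_CARCINOMAS",
    "LOW_ER_REPORTED",
    "low_er_prevalence_percent",
    "PUBLISHED_MEDIAN_DR",
    "PUBLISHED_DR_RANGE",
    "PUBLISHED_N_CASES",
]

#: Invasive breast carcinomas ER-tested over the study window, and how many
#: were reported as low (1-10%) ER.
ER_TESTED_CARCINOMAS = 3786
LOW_ER_REPORTED = 40

#: Pooled per-duct dynamic-range medians by cohort.
PUBLISHED_MEDIAN_DR = {"low_er": 16.5, "control": 30.8, "tma": 114.0}

#: Pooled per-duct dynamic-range (min, max) by cohort.
PUBLISHED_DR_RANGE = {"low_er": (2.0, 240.0),
                      "control": (3.0, 475.0),
                      "tma": (38.3, 212.0)}

PUBLISHED_N_CASES = {"low_er": 21, "control": 34, "tma": 10}


def low_er_prevalence_percent() -> float:
    """Percentage of ER-tested carcinomas reported as low (1-10%) ER."""
    return 100.0 * LOW_ER_REPORTED / ER_TESTED_CARCINOMAS
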