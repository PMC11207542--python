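"""Wet-lab assay metrics: mRNA encapsulation efficiency and hemolysis.

Both are simple ratios of background-corrected readings; calibration-curve
conversion from raw fluorescence/absorbance to concentration is the caller's
responsibility.  CSV helpers summarize replicate rows to per-sample
mean +- SD.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["encapsulation_efficiency", "hemolysis_percent",
           "summarize_encapsulation", "summarize_hemolysis"]

logger = logging.getLogger(__name__)


def encapsulation_efficiency(total_mrna, free_mrna):
    """Percent of mRNA encapsulated: EE% = 100 (total - free) / total.

    ``total_mrna`` is the concentration after particle disruption (detergent),
    ``free_mrna`` the unencapsulated concentration of the intact sample; the
    difference is the protected payload.  Broadcasts over array inputs.
    """
    total = np.asarray(total_mrna, dtype=float)
    free = np.asarray(free_mrna, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total mRNA must be > 0")
    if np.any(free < 0):
        raise ValueError("free mRNA must be >= 0")
    if np.any(free > total):
        raise ValueError("free mRNA exceeds total mRNA: check calibration")
    ee = 100.0 * (total - free) / total
    if ee.ndim == 0:
        return float(ee)
    return ee


def hemolysis_percent(sample_abs, negative_abs, positive_abs):
    """Hemolysis relative to controls: H% = 100 (A_s - A_neg)/(A_pos - A_neg).

    The positive control (full lysis, detergent) defines 100%, the negative
    control (buffer) 0%.  Readings below the negative control clip to 0%
    (logged); values above 100% are kept with a warning.
    """
    sample = np.asarray(sample_abs, dtype=float)
    neg = np.asarray(negative_abs, dtype=float)
    pos = np.asarray(positive_abs, dtype=float)
    if np.any(pos <= neg):
        raise ValueError("degenerate controls: positive must exceed negative")
    h = 100.0 * (sample - neg) / (pos - neg)
    n_below = int(np.sum(h < 0))
    if n_below:
        logger.info("hemolysis_percent: clipped %d readings below the "
                    "negative control to 0%%", n_below)
    h = np.maximum(h, 0.0)
    if np.any(h > 100.0):
        warnings.warn("hemolysis above the positive control (> 100%)",
                      RuntimeWarning)
    if h.ndim == 0:
        return float(h)
    return h


def summarize_encapsulation(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample EE mean +- SD from replicate rows.

    Expects columns ``sample``, ``total_mrna``, ``free_mrna``.
    """
    ee = encapsulation_efficiency(df["total_mrna"], df["free_mrna"])
    out = (pd.DataFrame({"sample": df["sample"], "ee_percent": ee})
           .groupby("sample")["ee_percent"]
           .agg(mean="mean", sd="std", n="count")
           .reset_index())
    return out


def summarize_hemolysis(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample hemolysis mean +- SD from replicate rows.

    Expects columns ``sample``, ``absorbance``, ``negative_control``,
    ``positive_control``.
    """
    h = hemolysis_percent(df["absorbance"], df["negative_control"],
                          df["positive_control"])
    out = (pd.DataFrame({"sample": df["sample"], "hemolysis_percent": h})
           .groupby("sample")["hemolysis_percent"]
           .agg(mean="mean", sd="std", n="count")
           .reset_index())
    return out
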