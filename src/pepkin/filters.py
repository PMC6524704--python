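"""Class-level filtering before differential analysis.

Two filters are applied in sequence:

1. **Low abundance** — a class below ``min_spectra`` (default 5) in every
   sample is discarded; spectral counting is too sparse to quantify it
   over time.
2. **Constancy** — among the remaining classes, those varying by less
   than ``min_variation`` (default 0.5, i.e. 50%) between their minimal
   and maximal per-timepoint mean abundance are set aside as "constant";
   they can be reintegrated after profiling.

The surviving "testable" classes proceed to the Poisson-GLM time-course
test. The three statuses partition the input classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_aggregate import ClassAbundanceMatrix

__all__ = [
    "filter_low_abundance",
    "filter_constant",
    "apply_filters",
    "FilterOutcome",
]

from dataclasses import dataclass


def filter_low_abundance(
    matrix: ClassAbundanceMatrix,
    threshold: int = 5,
    mode: str = "max",
) -> tuple[ClassAbundanceMatrix, list[str]]:
    """Split classes into (kept, discarded) by spectral abundance.

    With ``mode='max'`` (default) a class is discarded iff its count is
    below *threshold* in every sample, i.e. max over samples < threshold.
    ``mode='total'`` discards on the summed count instead — an alternative
    reading of "fewer than N spectra" kept behind this switch.
    """
    if mode == "max":
        stat = matrix.counts.max(axis=1)
    elif mode == "total":
        stat = matrix.counts.sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = stat >= threshold
    kept = matrix.subset(matrix.counts.index[keep])
    discarded = list(matrix.counts.index[~keep])
    return kept, discarded


def variation_ratio(timepoint_means: pd.Series) -> float:
    """Relative spread (max - min) / min of per-timepoint mean abundances.

    Infinite when the minimum mean is zero but the maximum is not (a class
    appearing or vanishing is maximally non-constant); zero for an
    all-zero class.
    """
    lo = float(timepoint_means.min())
    hi = float(timepoint_means.max())
    if lo == 0.0:
        return 0.0 if hi == 0.0 else np.inf
    return (hi - lo) / lo


def filter_constant(
    matrix: ClassAbundanceMatrix,
    min_variation: float = 0.5,
) -> tuple[ClassAbundanceMatrix, list[str]]:
    """Split classes into (testable, constant) by temporal variation.

    Variation is computed on per-timepoint means across replicates; a
    class is "constant" iff its variation ratio is below *min_variation*.
    Requires at least two timepoints.
    """
    means = matrix.timepoint_means()
    if means.shape[1] < 2:
        raise ValueError("constancy filter needs at least two timepoints")
    ratios = means.apply(variation_ratio, axis=1)
    testable = matrix.subset(means.index[ratios >= min_variation])
    constant = list(means.index[ratios < min_variation])
    return testable, constant


@dataclass(frozen=True)
class FilterOutcome:
    """Result of both filters plus a per-class report.

    ``report`` has one row per input class with its status
    (``discarded_low_abundance`` / ``constant`` / ``testable``), the max
    count over samples, and the variation ratio of per-timepoint means.
    """

    testable: ClassAbundanceMatrix
    constant: list[str]
    discarded: list[str]
    report: pd.DataFrame


def apply_filters(
    matrix: ClassAbundanceMatrix,
    min_spectra: int = 5,
    min_variation: float = 0.5,
    abundance_mode: str = "max",
) -> FilterOutcome:
    """Run the abundance then the constancy filter; build the report."""
    kept, discarded = filter_low_abundance(matrix, min_spectra, abundance_mode)
    testable, constant = filter_constant(kept, min_variation)

    max_count = matrix.counts.max(axis=1)
    ratios = matrix.timepoint_means().apply(variation_ratio, axis=1)
    status = pd.Series("testable", index=matrix.counts.index, dtype=object)
    status[discarded] = "discarded_low_abundance"
    status[constant] = "constant"
    report = pd.DataFrame(
        {
            "status": status,
            "max_count": max_count,
            "variation_ratio": ratios,
        }
    )
    report.index.name = "class"
    return FilterOutcome(
        testable=testable, constant=constant, discarded=discarded, report=report
    )
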