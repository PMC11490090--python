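"""Classical multiple-testing adjustments across the tested entries.

Thin wrappers around statsmodels' ``multipletests`` with the array-in /
array-out contract the result tables expect.  Bonferroni multiplies each
p-value by the number of tests J (capped at 1); Benjamini-Hochberg is the
standard step-up procedure with the cumulative-minimum tie handling.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bonferroni", "benjamini_hochberg"]


def _as_pvector(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bonferroni(p) -> np.ndarray:
    """Bonferroni adjustment: min(p * J, 1), elementwise."""
    arr = _as_pvector(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="bonferroni")[1]


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = _as_pvector(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]
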