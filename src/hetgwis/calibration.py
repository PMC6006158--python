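"""Genomic-inflation estimation and QQ-plot data for p-value vectors.

The inflation factor follows the standard genomic-control convention:
every p-value is mapped to the corresponding chi-square(1) upper-tail
quantile and the median (optionally mean) of those quantiles is divided
by its null expectation.  This convention is df-agnostic, so it applies
unchanged to p-values coming from 3-DF tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exceptions import ValidationError

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


@dataclass
class InflationReport:
    lambda_vif: float
    n_pvalues: int
    qq_points: tuple[np.ndarray, np.ndarray]  # (expected, observed) -log10 p, sorted ascending
    df_convention: int = 1
    method: str = "median"


def _clean(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size and (p.min() <= 0.0 or p.max() > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def qq_table(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (expected, observed) -log10 p pairs using (i - 0.5)/n positions."""
    p = _clean(pvalues)
    if p.size < 1:
        raise ValidationError("no finite p-values")
    n = p.size
    expected = -np.log10((np.arange(n, 0, -1) - 0.5) / n)  # ascending
    observed = -np.log10(np.sort(p)[::-1])                 # ascending
    return expected, observed


def genomic_inflation(pvalues, method: str = "median") -> InflationReport:
    """Genomic-control inflation factor of a genome-wide p-value vector.

    Requires at least 100 p-values for a stable median.  ``method`` may
    be ``"median"`` (default, robust) or ``"mean"``.
    """
    p = _clean(pvalues)
    if p.size < 100:
        raise ValidationError(f"need >= 100 p-values for a stable estimate, got {p.size}")
    q = stats.chi2.isf(p, 1)
    if method == "median":
        lam = float(np.median(q)) / CHI2_1_MEDIAN
    elif method == "mean":
        lam = float(np.mean(q))  # E[chi2(1)] = 1
    else:
        raise ValidationError(f"unknown method {method!r}")
    return InflationReport(lambda_vif=lam, n_pvalues=int(p.size),
                           qq_points=qq_table(p), method=method)
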