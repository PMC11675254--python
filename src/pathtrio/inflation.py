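"""Genomic inflation factor and QQ-plot coordinates for TDT results.

Lambda is the median observed 1-df chi-square statistic divided by the
null median (~0.4549); values near 1 indicate no systematic inflation.
Only informative SNPs (at least one heterozygous-parent transmission)
enter either computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .tdt import TdtResult

#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = float(chi2_dist.ppf(0.5, df=1))


def genomic_lambda(results: list[TdtResult]) -> float:
    """Median-based genomic inflation factor over informative SNPs."""
    chi2 = np.array([r.chi2 for r in results if r.n_informative > 0])
    if chi2.size == 0:
        raise ValueError("no informative SNPs: lambda is undefined")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def qq_coordinates(results: list[TdtResult]) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p-values (informative SNPs) sorted ascending are paired with
    uniform quantiles i/(n+1), i = 1..n, so -log10 never hits infinity.
    Rows are ordered by the expected quantile, smallest p first.
    """
    p = np.sort(np.array([r.p for r in results if r.n_informative > 0]))
    if p.size == 0:
        raise ValueError("no informative SNPs")
    expected = np.arange(1, p.size + 1) / (p.size + 1.0)
    return pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(p),
        }
    )
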