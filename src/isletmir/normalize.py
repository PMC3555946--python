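"""Median-of-ratios library normalization.

Libraries differ in sequencing depth by orders of magnitude, so raw counts
are not comparable. For each library l an inflation factor

    i_l = median_g( n_gl / GM_g )

is computed over features g, where GM_g is the geometric mean of feature g's
counts across libraries (the size-factor estimator of Anders & Huber).
Features with a zero count in any library have GM_g = 0 and are excluded
from factor estimation. Normalized expression is n_gl / i_l on the linear
scale, or log2((n_gl + pseudocount) / i_l); with the default pseudocount of
0, zero counts map to NaN ("below detection"), and downstream correlation
steps must use pairwise-complete observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def inflation_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-library median-of-ratios inflation factors.

    Raises ``ValueError`` when no feature is strictly positive in every
    library (the geometric mean, and hence the estimator, is undefined).
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "inflation factors undefined: no feature has strictly positive "
            "counts in every library"
        )
    log_gm = np.log(positive).mean(axis=1)
    gm = np.exp(log_gm)
    ratios = positive.div(gm, axis=0)
    factors = ratios.median(axis=0)
    factors.name = "inflation_factor"
    return factors


def log2_normalize(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 0.0
) -> pd.DataFrame:
    """log2((n_gl + pseudocount) / i_l); zeros become NaN when pseudocount=0.

    The pseudocount policy is recorded in ``DataFrame.attrs``.
    """
    if (factors <= 0).any():
        raise ValueError("inflation factors must be positive")
    shifted = (counts + pseudocount).div(factors, axis=1)
    with np.errstate(divide="ignore"):
        out = np.log2(shifted)
    out = out.where(shifted > 0)  # -inf -> NaN sentinel (below detection)
    out.attrs["pseudocount"] = pseudocount
    return out


def normalized_linear(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Depth-adjusted linear-scale counts n_gl / i_l (feeds the >=1000
    expression filter and the specificity score)."""
    if (factors <= 0).any():
        raise ValueError("inflation factors must be positive")
    return counts.div(factors, axis=1)
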