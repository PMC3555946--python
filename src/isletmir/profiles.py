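"""Summaries of miRNA expression profiles.

Covers the headline bookkeeping of a profiling study: which miRNAs are
expressed above background in each sample group, how many are shared between
groups, how concentrated ("complex") a profile is, and the fold enrichment
of a miRNA between two preparations of differing cellular composition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def expressed_features(counts: pd.DataFrame, min_total: float = 100.0) -> set[str]:
    """Features expressed above background: more than ``min_total`` summed
    raw reads across the group's libraries (a feature at exactly the
    threshold counts as expressed)."""
    totals = counts.sum(axis=1)
    return set(totals.index[totals >= min_total])


def shared_accounting(
    group_a: set[str], group_b: set[str]
) -> dict[str, int]:
    """Expressed / unique / shared counts for two sample groups."""
    return {
        "n_a": len(group_a),
        "n_b": len(group_b),
        "n_unique": len(group_a | group_b),
        "n_shared": len(group_a & group_b),
    }


def complexity(counts: pd.Series | pd.DataFrame, mass: float = 0.9) -> int:
    """Number of top-abundance features jointly carrying ``mass`` of all
    reads (the cumulative-abundance complexity statistic; a 'medium
    complexity' small RNA library needs only a few dozen)."""
    totals = counts.sum(axis=1) if isinstance(counts, pd.DataFrame) else counts
    total = float(totals.sum())
    if total <= 0:
        return 0
    frac = np.sort(totals.to_numpy())[::-1] / total
    return int(np.searchsorted(np.cumsum(frac), mass) + 1)


def fold_enrichment(fraction_enriched: float, fraction_bulk: float) -> float:
    """Abundance fold ratio of a miRNA between an enriched preparation and
    the bulk tissue (e.g. miR-375 at 42% of beta-cell vs 27% of islet
    reads -> ~1.5-fold)."""
    if fraction_bulk <= 0:
        raise ValueError("bulk fraction must be positive")
    return fraction_enriched / fraction_bulk


def expected_enrichment(purity_enriched: float, fraction_cells_in_bulk: float) -> float:
    """Fold enrichment expected if the miRNA were confined to the sorted cell
    type: sorted-preparation purity divided by that cell type's share of the
    bulk tissue (0.90 / 0.50 = 1.8 for beta-cells in islets). An observed
    ratio approaching this bound indicates expression predominantly in the
    sorted cells."""
    if fraction_cells_in_bulk <= 0:
        raise ValueError("bulk cell fraction must be positive")
    return purity_enriched / fraction_cells_in_bulk
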