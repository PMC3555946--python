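"""Tissue-specificity scoring with redundant-profile merging and a
permutation FDR.

The specificity score of miRNA m in profile t is its normalized expression
there divided by its summed expression across all profiles — the fraction of
all observed reads for m attributable to t. A score > 0.5 (strictly) defines
tissue-specificity; since each row sums to 1, at most one profile can be
called per miRNA.

Because near-identical tissue profiles (here, islets and FACS-enriched
beta-cells) would split a specific miRNA's reads and dilute its score,
profiles are first merged: a Spearman correlation matrix is computed over
log2 expression, tissues whose correlation-matrix rows lie within Euclidean
distance 0.25 under single linkage are averaged (arithmetic mean of the
linear vectors), and scoring runs on the merged panel.

The permutation FDR is computed against a designated reference profile:
under the null each miRNA's expression vector is independently permuted
across profiles, and the expected number of score>0.5 calls landing in the
reference estimates the false calls among the observed reference calls.
(A single row's score multiset is invariant under permuting that row, so
counting null calls over *all* profiles would trivially reproduce the
observed count; anchoring to a reference is what gives the permutation
leverage.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

DEFAULT_MIN_TOTAL = 1000.0
DEFAULT_CUT_HEIGHT = 0.25
DEFAULT_SCORE_CUTOFF = 0.5


@dataclass
class ProfileSet:
    """Named expression profiles over a shared miRNA index, with the list of
    original tissues merged into each profile."""

    profiles: pd.DataFrame  # miRNA x profile, linear normalized expression
    provenance: dict[str, list[str]]


@dataclass
class FDRReport:
    threshold: float
    reference: str
    n_observed: int
    n_expected_null: float
    fdr: float | None  # None when no calls were observed
    n_permutations: int


def average_by_tissue(
    normalized: pd.DataFrame, library_tissues: dict[str, str]
) -> pd.DataFrame:
    """Collapse per-library normalized counts to per-tissue profiles
    (arithmetic mean over each tissue's libraries)."""
    groups = pd.Series(library_tissues)
    missing = set(normalized.columns) - set(groups.index)
    if missing:
        raise ValueError(f"libraries without a tissue label: {sorted(missing)}")
    return normalized.T.groupby(groups).mean().T


def filter_min_expression(
    panel: pd.DataFrame, min_total: float = DEFAULT_MIN_TOTAL
) -> pd.DataFrame:
    """Keep miRNAs observed at least ``min_total`` times across the panel's
    normalized values (background suppression)."""
    return panel[panel.sum(axis=1) >= min_total]


def profile_correlation(panel: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise profile correlation over the shared miRNA index.

    Computed on log2 values with pairwise-complete observations (zeros are
    below detection and excluded pair-by-pair). A profile that is constant
    on its observed values has no defined correlation and raises.
    """
    if panel.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    with np.errstate(divide="ignore"):
        logs = np.log2(panel.where(panel > 0))
    corr = logs.corr(method=method, min_periods=3)
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"correlation undefined for profiles: {bad}")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def merge_similar_profiles(
    corr: pd.DataFrame,
    panel: pd.DataFrame,
    height: float = DEFAULT_CUT_HEIGHT,
) -> ProfileSet:
    """Average tissues closer than ``height`` under single linkage.

    Distance is the Euclidean distance between the tissues' rows of the
    correlation matrix. A single-linkage dendrogram cut below ``height`` is
    exactly the set of connected components of the graph with edges
    d < height, which is how the merge is computed. Merged profiles are the
    arithmetic means of their members' linear expression vectors.
    """
    tissues = list(corr.columns)
    dist = squareform(pdist(corr.values))
    adj = csr_matrix((dist < height) & ~np.eye(len(tissues), dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    merged = {}
    provenance: dict[str, list[str]] = {}
    for comp in range(n_comp):
        members = [tissues[i] for i in np.flatnonzero(labels == comp)]
        name = "+".join(members)
        merged[name] = panel[members].mean(axis=1)
        provenance[name] = members
    profiles = pd.DataFrame(merged)
    return ProfileSet(profiles=profiles, provenance=provenance)


def specificity_scores(profiles: ProfileSet | pd.DataFrame) -> pd.DataFrame:
    """Fractional expression per miRNA across profiles; rows sum to 1.

    Rows with zero total expression are undefined and returned as NaN.
    """
    df = profiles.profiles if isinstance(profiles, ProfileSet) else profiles
    if df.shape[1] < 2:
        raise ValueError("need at least 2 merged profiles")
    totals = df.sum(axis=1)
    scores = df.div(totals, axis=0)
    scores[totals == 0] = np.nan
    return scores


def call_specific(
    table: pd.DataFrame, cutoff: float = DEFAULT_SCORE_CUTOFF
) -> list[tuple[str, str]]:
    """(miRNA, profile) pairs with score strictly above ``cutoff``.

    With cutoff >= 0.5 and rows summing to 1, each miRNA yields at most one
    call.
    """
    hits = table.stack()
    hits = hits[hits > cutoff]
    return sorted(hits.index.tolist())


def permutation_fdr(
    table: pd.DataFrame,
    reference: str,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    n_permutations: int = 10000,
    seed: int = 0,
) -> FDRReport:
    """Permutation FDR for specificity calls in ``reference``.

    Each permutation independently shuffles every miRNA's score vector across
    profiles; the expected false calls is the mean number of calls landing in
    the reference profile per permutation, and FDR = expected / observed
    (undefined when nothing is observed).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if reference not in table.columns:
        raise ValueError(f"unknown reference profile: {reference}")
    rng = np.random.default_rng(seed)
    values = table.values
    M, T = values.shape
    observed = int((table[reference] > cutoff).sum())
    # permuting a row uniformly sends a uniformly random entry to the
    # reference column; sample that entry directly for each row
    picks = rng.integers(0, T, size=(n_permutations, M))
    landed = values[np.arange(M)[None, :], picks]
    with np.errstate(invalid="ignore"):
        null_calls = (landed > cutoff).sum(axis=1)
    expected = float(null_calls.mean())
    fdr = expected / observed if observed > 0 else None
    return FDRReport(
        threshold=cutoff,
        reference=reference,
        n_observed=observed,
        n_expected_null=expected,
        fdr=fdr,
        n_permutations=n_permutations,
    )
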