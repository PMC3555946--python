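"""LD-proxy expansion and variant/interval overlap.

GWAS lead variants tag association signals whose causal allele may be any
variant in strong LD with the lead, so leads are expanded to all variants
with haplotype r^2 > 0.8 before intersecting with miRNA precursor and
predicted target-site intervals. r^2 is computed on phased haplotypes:

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B))

which equals the squared Pearson correlation of the two {0,1} haplotype
columns. Variant positions are 1-based on input (VCF convention) and
converted to 0-based internally; intervals are 0-based half-open.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DEFAULT_R2_MIN = 0.8


def r_squared(panel: pd.DataFrame, a: str, b: str) -> float:
    """Squared haplotype correlation between variants ``a`` and ``b``.

    Raises on a monomorphic variant (r^2 undefined).
    """
    for v in (a, b):
        if v not in panel.columns:
            raise ValueError(f"variant not in panel: {v}")
    x = panel[a].to_numpy(dtype=float)
    y = panel[b].to_numpy(dtype=float)
    pa, pb = x.mean(), y.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        mono = a if va == 0 else b
        raise ValueError(f"variant {mono} is monomorphic; r^2 undefined")
    pab = (x * y).mean()
    return float((pab - pa * pb) ** 2 / (va * vb))


def ld_proxies(
    leads: Sequence[str],
    panel: pd.DataFrame,
    r2_min: float = DEFAULT_R2_MIN,
) -> pd.DataFrame:
    """Expand leads to all panel variants with r^2 strictly above ``r2_min``.

    Returns one row per variant in the closure (leads included, annotated as
    their own best lead with r^2 = 1), with the best lead and its r^2.
    Monomorphic panel variants can never qualify and are skipped; a
    monomorphic or absent lead raises, naming it.
    """
    X = panel.to_numpy(dtype=float)
    p = X.mean(axis=0)
    var = p * (1 - p)
    cols = list(panel.columns)
    col_idx = {c: i for i, c in enumerate(cols)}
    lead_set = set(leads)
    best: dict[str, tuple[str, float]] = {}
    for lead in leads:
        if lead not in col_idx:
            raise ValueError(f"lead variant not in panel: {lead}")
        i = col_idx[lead]
        if var[i] == 0:
            raise ValueError(f"lead variant {lead} is monomorphic; r^2 undefined")
        cov = (X * X[:, [i]]).mean(axis=0) - p * p[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(var > 0, cov**2 / (var * var[i]), 0.0)
        best[lead] = (lead, 1.0)
        for j in np.flatnonzero(r2 > r2_min):
            v = cols[j]
            if v in lead_set:
                continue  # each lead remains its own entry
            if v not in best or float(r2[j]) > best[v][1]:
                best[v] = (lead, float(r2[j]))
    rows = [
        {"variant": v, "lead": lead, "r2": r2} for v, (lead, r2) in best.items()
    ]
    out = pd.DataFrame(rows, columns=["variant", "lead", "r2"])
    return out.sort_values("variant", ignore_index=True)


def overlap_variants(
    variants: pd.DataFrame, intervals: pd.DataFrame
) -> pd.DataFrame:
    """All (variant, interval) overlap pairs.

    A variant at 1-based position p overlaps [start, end) iff
    start <= p-1 < end. Output is deterministic: sorted by
    (chrom, pos, feature name).
    """
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.name
        )
    rows = []
    for v in variants.itertuples(index=False):
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.at(v.pos - 1):
            rows.append((v.id, v.chrom, v.pos, iv.data, iv.begin, iv.end))
    out = pd.DataFrame(
        rows, columns=["variant", "chrom", "pos", "feature_id", "start", "end"]
    )
    return out.sort_values(
        ["chrom", "pos", "feature_id"], ignore_index=True
    )


def count_locus_hits(
    overlaps: pd.DataFrame, locus_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse variant-interval pairs to distinct (locus, variant) hits.

    Returns one row per locus with its distinct variant count; the number of
    rows is the number of independent loci hit.
    """
    if overlaps.empty:
        return pd.DataFrame(columns=["locus", "n_variants"])
    df = overlaps.assign(locus=overlaps["feature_id"].map(locus_map))
    if df["locus"].isna().any():
        missing = df.loc[df["locus"].isna(), "feature_id"].unique().tolist()
        raise ValueError(f"intervals without a locus id: {missing}")
    hits = df[["locus", "variant"]].drop_duplicates()
    out = (
        hits.groupby("locus")["variant"].nunique().rename("n_variants").reset_index()
    )
    return out.sort_values("locus", ignore_index=True)
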