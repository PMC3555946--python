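"""Read assignment and fractional counting against the three-tier reference.

Cleaned reads are aligned exhaustively (Hamming distance, no indels) against
three consecutive references — contaminants, miRNA hairpins + other ncRNAs,
genome. Contaminant hits short-circuit and the read is excluded. Otherwise
the winning class is chosen by priority miRNA > ncRNA > genome, minimum-
mismatch hits are kept within the winning class, and a read tied between k
features contributes 1/k to each. Hairpin hits are subclassified as mature /
star / hairpin-only using the annotated sub-intervals extended by ``pad``
bases either side.

The exhaustive aligner is deliberately simple: every position on every
reference sequence is scanned, which makes the counting semantics — the part
that actually determines the expression profile — directly checkable against
a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .simulate import HairpinRecord, ReferenceBundle

PAD = 3
_COMP = str.maketrans("ACGTN", "TGCAN")

_CATEGORY_RANK = {"mature": 0, "star": 1, "hairpin_only": 2}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    ref_class: str  # contaminant | mirna | ncrna | genome
    ref_id: str
    start: int  # 0-based offset on the forward reference strand
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class ReadAssignment:
    read_id: str
    category: str  # mature | star | hairpin_only | ncrna | genome | contaminant | unmapped
    targets: list[tuple[str, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.targets)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def align_simple(
    sequence: str,
    references: Sequence[tuple[str, str]],
    max_mismatches: int = 1,
    ref_class: str = "genome",
    both_strands: bool = False,
) -> list[AlignmentHit]:
    """All alignments of ``sequence`` with Hamming distance <= max_mismatches.

    Exhaustive over every offset of every reference; the reverse strand is
    searched (via the read's reverse complement) when ``both_strands`` is set.
    """
    hits: list[AlignmentHit] = []
    queries = [(sequence, "+")]
    if both_strands:
        queries.append((reverse_complement(sequence), "-"))
    for query, strand in queries:
        q = _encode(query)
        L = len(q)
        for ref_id, ref_seq in references:
            if len(ref_seq) < L:
                continue
            windows = sliding_window_view(_encode(ref_seq), L)
            mm = (windows != q).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mismatches):
                hits.append(
                    AlignmentHit(
                        ref_class=ref_class,
                        ref_id=ref_id,
                        start=int(pos),
                        strand=strand,
                        mismatches=int(mm[pos]),
                    )
                )
    return hits


def classify_hairpin_hit(
    hit: AlignmentHit, read_length: int, hairpin: HairpinRecord, pad: int = PAD
) -> str:
    """mature / star / hairpin_only for a hit on a hairpin.

    The aligned interval must lie entirely within the mature (or star)
    interval extended by ``pad`` bases either side; mature is checked first.
    """
    lo, hi = hit.start, hit.start + read_length
    for _, s, e in hairpin.mature_intervals:
        if s - pad <= lo and hi <= e + pad:
            return "mature"
    for _, s, e in hairpin.star_intervals:
        if s - pad <= lo and hi <= e + pad:
            return "star"
    return "hairpin_only"


def assign_read(
    read_id: str,
    read_length: int,
    contaminant_hits: Sequence[AlignmentHit],
    mirna_hits: Sequence[AlignmentHit],
    ncrna_hits: Sequence[AlignmentHit],
    genome_hits: Sequence[AlignmentHit],
    hairpins: Mapping[str, HairpinRecord],
    pad: int = PAD,
) -> ReadAssignment:
    """Resolve one read's hits into a categorized, 1/k-weighted assignment.

    Tier order: contaminant short-circuits; then class priority
    miRNA > ncRNA > genome; minimum mismatch applies within the winning
    class; k counts distinct surviving features. For miRNA, a feature is a
    (hairpin, region) pair like ``mir-01:mature``; when tied targets span
    regions the read's category is the best region present
    (mature > star > hairpin_only).
    """
    if contaminant_hits:
        return ReadAssignment(read_id=read_id, category="contaminant")
    for hit_set, ref_class in ((mirna_hits, "mirna"), (ncrna_hits, "ncrna")):
        if hit_set:
            best = min(h.mismatches for h in hit_set)
            survivors = [h for h in hit_set if h.mismatches == best]
            if ref_class == "mirna":
                features = {
                    f"{h.ref_id}:{classify_hairpin_hit(h, read_length, hairpins[h.ref_id], pad)}"
                    for h in survivors
                }
                category = min(
                    (f.rsplit(":", 1)[1] for f in features),
                    key=_CATEGORY_RANK.__getitem__,
                )
            else:
                features = {h.ref_id for h in survivors}
                category = "ncrna"
            k = len(features)
            return ReadAssignment(
                read_id=read_id,
                category=category,
                targets=[(f, 1.0 / k) for f in sorted(features)],
            )
    if genome_hits:
        best = min(h.mismatches for h in genome_hits)
        features = {h.ref_id for h in genome_hits if h.mismatches == best}
        k = len(features)
        return ReadAssignment(
            read_id=read_id,
            category="genome",
            targets=[(f, 1.0 / k) for f in sorted(features)],
        )
    return ReadAssignment(read_id=read_id, category="unmapped")


def align_and_assign(
    reads: Iterable[tuple[str, str]],
    bundle: ReferenceBundle,
    max_mismatches: int = 1,
    pad: int = PAD,
) -> list[ReadAssignment]:
    """Run the three-tier search for a library of cleaned reads.

    Contaminant / hairpin / ncRNA tiers are sense-only (small RNA libraries
    are stranded); the genome tier searches both strands. Identical sequences
    share one alignment, so duplicated reads cost nothing extra.
    """
    hairpin_refs = [(hp.id, hp.sequence) for hp in bundle.hairpins]
    hairpins = bundle.hairpin_map()
    cache: dict[str, ReadAssignment] = {}
    out: list[ReadAssignment] = []
    for read_id, seq in reads:
        template = cache.get(seq)
        if template is None:
            cont = align_simple(
                seq, bundle.contaminants, max_mismatches, ref_class="contaminant"
            )
            mirna = (
                align_simple(seq, hairpin_refs, max_mismatches, ref_class="mirna")
                if not cont
                else []
            )
            ncrna = (
                align_simple(seq, bundle.ncrnas, max_mismatches, ref_class="ncrna")
                if not cont
                else []
            )
            genome = (
                align_simple(
                    seq, bundle.genome, max_mismatches, ref_class="genome",
                    both_strands=True,
                )
                if not (cont or mirna or ncrna)
                else []
            )
            template = assign_read(
                read_id, len(seq), cont, mirna, ncrna, genome, hairpins, pad
            )
            cache[seq] = template
        out.append(
            ReadAssignment(
                read_id=read_id,
                category=template.category,
                targets=list(template.targets),
            )
        )
    return out


@dataclass
class CountMatrix:
    """Features x libraries fractional counts with per-feature categories."""

    counts: pd.DataFrame
    categories: pd.Series  # feature -> category label

    MIRNA_CATEGORIES = ("mature", "star", "hairpin_only")

    def mirna_counts(self) -> pd.DataFrame:
        keep = self.categories[self.categories.isin(self.MIRNA_CATEGORIES)].index
        return self.counts.loc[keep]


def build_count_matrix(
    assignments_by_library: Mapping[str, Sequence[ReadAssignment]],
) -> CountMatrix:
    """Accumulate 1/k weights into a features x libraries matrix.

    Mature, star and hairpin-only targets of the same hairpin are distinct
    features. Contaminant and unmapped reads contribute nothing, so each
    library's column sum equals its number of mapped, non-contaminant reads.
    """
    libraries = list(assignments_by_library)
    acc: dict[str, dict[str, float]] = {}
    cats: dict[str, str] = {}
    for lib, assignments in assignments_by_library.items():
        for a in assignments:
            for feature, weight in a.targets:
                acc.setdefault(feature, dict.fromkeys(libraries, 0.0))[lib] += weight
                if feature not in cats:
                    if ":" in feature and a.category in CountMatrix.MIRNA_CATEGORIES:
                        cats[feature] = feature.rsplit(":", 1)[1]
                    else:
                        cats[feature] = a.category
    features = sorted(acc)
    counts = pd.DataFrame(
        [[acc[f][lib] for lib in libraries] for f in features],
        index=features,
        columns=libraries,
        dtype=float,
    )
    categories = pd.Series({f: cats[f] for f in features}, name="category")
    return CountMatrix(counts=counts, categories=categories.loc[features])


def filter_background(matrix: CountMatrix, min_total: float = 100.0) -> CountMatrix:
    """Drop features seen fewer than ``min_total`` times across all
    libraries; a feature at exactly the threshold is retained."""
    keep = matrix.counts.sum(axis=1) >= min_total
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        categories=matrix.categories.loc[keep],
    )


def assignment_summary(
    assignments_by_library: Mapping[str, Sequence[ReadAssignment]],
) -> pd.DataFrame:
    """Reads per category per library (the per-library mapping report)."""
    rows = {}
    for lib, assignments in assignments_by_library.items():
        counts: dict[str, int] = {}
        for a in assignments:
            counts[a.category] = counts.get(a.category, 0) + 1
        rows[lib] = counts
    return pd.DataFrame(rows).fillna(0).astype(int).T
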