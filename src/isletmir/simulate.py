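"""Synthetic inputs for every stage of the pipeline.

Real small RNA libraries, the multi-tissue expression panel, and the GWAS
summary statistics behind the original analysis are not redistributable, so
this module generates stand-ins with the statistical structure the downstream
methods assume:

* small RNA read libraries dominated by ~22 nt mature miRNA inserts, with 3'
  adaptor read-through, adaptor-dimer and linker contamination, N-rich reads,
  and multi-mapping mature sequences shared between hairpins;
* a tissue expression panel of "medium complexity" (a heavy-tailed log-normal
  abundance spectrum in which the top quartile of miRNAs carries ~90% of
  reads), with a planted subset of tissue-specific miRNAs and one pair of
  near-duplicate tissue profiles;
* GWAS summary statistics over a block-structured haplotype panel, with
  association signal planted into designated target-gene sets.

Every generator is a pure function of its ``SimulationConfig``: the same
config yields byte-identical outputs. Ground truth (planted specificity,
planted enriched sets, true abundances) is returned alongside the data so
recovery tests never re-derive truth from the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Illumina TruSeq small RNA 3' adaptor.
DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"
#: Illumina small RNA 5' linker; linker+adaptor chimeras survive clipping and
#: exercise the contaminant alignment tier.
DEFAULT_LINKER = "GTTCAGAGTTCTACAGTCCGACGATC"

DEFAULT_TISSUES = (
    "islet",
    "beta_cell",
    "liver",
    "muscle",
    "brain",
    "kidney",
    "spleen",
    "adipose",
)


@dataclass(frozen=True)
class HairpinRecord:
    """A miRNA precursor with mature/star sub-intervals (0-based half-open)."""

    id: str
    sequence: str
    mature_intervals: tuple[tuple[str, int, int], ...]
    star_intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        names = [n for n, _, _ in self.mature_intervals] + [
            n for n, _, _ in self.star_intervals
        ]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate interval names in hairpin {self.id}")
        for name, start, end in self.mature_intervals + self.star_intervals:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"interval {name} [{start},{end}) outside hairpin {self.id}"
                )

    def subsequence(self, start: int, end: int) -> str:
        return self.sequence[start:end]


@dataclass(frozen=True)
class ReferenceBundle:
    """The three-tier reference stack: contaminants, hairpins+ncRNAs, genome."""

    contaminants: tuple[tuple[str, str], ...]
    hairpins: tuple[HairpinRecord, ...]
    ncrnas: tuple[tuple[str, str], ...]
    genome: tuple[tuple[str, str], ...]

    def hairpin_map(self) -> dict[str, HairpinRecord]:
        return {hp.id: hp for hp in self.hairpins}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the pipeline is meant to reproduce at desk scale."""

    seed: int = 0

    # --- read libraries -------------------------------------------------
    n_hairpins: int = 30
    reads_per_library: int = 10000
    n_libraries: int = 3
    read_length: int = 50  # 50 bp sequencing reads; short inserts read through
    adaptor_sequence: str = DEFAULT_ADAPTOR
    linker_sequence: str = DEFAULT_LINKER
    dimer_fraction: float = 0.05
    linker_fraction: float = 0.02
    n_read_fraction: float = 0.02
    star_fraction: float = 0.05
    library_depth_sd: float = 0.5  # log-normal spread of library sizes

    # --- tissue panel ---------------------------------------------------
    n_tissues: int = 8
    n_libraries_per_tissue: int = 3
    n_panel_mirnas: int = 150
    mean_library_reads: int = 50000
    abundance_concentration: float = 1.96  # sigma of log-normal weights
    tissue_noise_sd: float = 1.3
    duplicate_tissue_noise_sd: float = 0.15
    panel_depth_sd: float = 0.8
    planted_specific: Mapping[str, str] | None = None  # None -> default plan
    n_planted_specific: int = 12
    planted_fraction: tuple[float, float] = (0.85, 0.95)

    # --- GWAS -----------------------------------------------------------
    n_variants: int = 12000
    n_genes: int = 6000
    n_haplotypes: int = 200
    ld_block_size: int = 10  # mean Poisson block size
    ld_mutation_prob: float = 0.015
    n_gene_sets: int = 40
    set_size_range: tuple[int, int] = (400, 500)
    planted_enriched_sets: tuple[str, ...] = tuple(
        f"set{i:02d}" for i in range(1, 13)
    )
    planted_gene_pool_size: int = 800
    effect_inflation: float = 6.0

    def tissues(self) -> tuple[str, ...]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES[: self.n_tissues]
        extra = tuple(
            f"tissue{i:02d}" for i in range(len(DEFAULT_TISSUES), self.n_tissues)
        )
        return DEFAULT_TISSUES + extra

    def duplicate_pair(self) -> tuple[str, str]:
        """The near-duplicate tissue pair (the islet / beta-cell analogue)."""
        t = self.tissues()
        return t[0], t[1]

    def planted_plan(self) -> dict[str, str]:
        """Planted tissue-specific miRNAs: round-robin over the non-duplicate
        tissues, so merging the duplicate pair never dilutes a planted call."""
        if self.planted_specific is not None:
            plan = dict(self.planted_specific)
            unknown = set(plan.values()) - set(self.tissues())
            if unknown:
                raise ValueError(f"planted tissues not generated: {sorted(unknown)}")
            return plan
        hosts = self.tissues()[2:]
        if not hosts:
            hosts = self.tissues()
        return {
            f"panel-mir-{i + 1:03d}": hosts[i % len(hosts)]
            for i in range(self.n_planted_specific)
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(BASES[rng.integers(0, 4, length)]).decode()


def make_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the three-tier reference stack.

    Each hairpin carries one mature and one star interval (mature lengths
    20-24 nt); the first two hairpins share an identical mature sequence to
    exercise fractional 1/k counting; the genome embeds each hairpin in random
    flanking sequence; contaminants include the adaptor, an adaptor dimer, the
    5' linker, and a linker+adaptor chimera.
    """
    if config.n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    rng = np.random.default_rng([config.seed, 0])

    hairpins = []
    # mature miRNA lengths peak sharply at 22 nt
    lengths = np.array([20, 21, 22, 23, 24])
    length_p = np.array([0.05, 0.2, 0.5, 0.2, 0.05])
    for i in range(config.n_hairpins):
        mature_len = int(rng.choice(lengths, p=length_p))
        star_len = int(rng.choice(lengths, p=length_p))
        m_start = 8
        m_end = m_start + mature_len
        s_start = m_end + 10
        s_end = s_start + star_len
        length = s_end + 8
        seq = _random_seq(rng, length)
        hp_id = f"mir-{i + 1:02d}"
        hairpins.append(
            HairpinRecord(
                id=hp_id,
                sequence=seq,
                mature_intervals=((f"{hp_id}-mat", m_start, m_end),),
                star_intervals=((f"{hp_id}-star", s_start, s_end),),
            )
        )

    if config.n_hairpins >= 2:
        # plant a shared mature sequence between the first two hairpins
        donor = hairpins[0]
        recip = hairpins[1]
        _, ds, de = donor.mature_intervals[0]
        shared = donor.sequence[ds:de]
        _, rs, _ = recip.mature_intervals[0]
        new_seq = recip.sequence[:rs] + shared + recip.sequence[rs + len(shared):]
        new_seq = new_seq[: len(recip.sequence)].ljust(len(recip.sequence), "A")
        name = recip.mature_intervals[0][0]
        hairpins[1] = HairpinRecord(
            id=recip.id,
            sequence=new_seq,
            mature_intervals=((name, rs, rs + len(shared)),),
            star_intervals=recip.star_intervals,
        )

    adaptor = config.adaptor_sequence
    linker = config.linker_sequence
    contaminants = (
        ("adaptor", adaptor),
        ("adaptor_dimer", adaptor + adaptor),
        ("linker", linker),
        ("linker_adaptor", linker + adaptor),
    )
    ncrnas = tuple((f"ncrna-{i + 1:02d}", _random_seq(rng, 80)) for i in range(5))
    genome = tuple(
        (
            f"contig-{hp.id}",
            _random_seq(rng, 60) + hp.sequence + _random_seq(rng, 60),
        )
        for hp in hairpins
    )
    return ReferenceBundle(
        contaminants=contaminants,
        hairpins=tuple(hairpins),
        ncrnas=ncrnas,
        genome=genome,
    )


_JITTER = np.array([-2, -1, 0, 1, 2])
_JITTER_P = np.array([0.05, 0.15, 0.6, 0.15, 0.05])


def simulate_reads(
    bundle: ReferenceBundle,
    abundances: Mapping[str, float],
    config: SimulationConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Simulate per-library small RNA reads.

    Reads are mature (or, at ``star_fraction``, star) hairpin inserts with
    +/-1-2 nt end jitter, followed by the 3' adaptor and downstream library
    sequence, truncated to ``read_length``. Pure adaptor dimers, 5'
    linker+adaptor chimeras and N-rich reads are injected at the configured
    fractions; library sizes are drawn log-normally around
    ``reads_per_library`` so the normalization step has depth differences to
    remove.
    """
    if not abundances:
        raise ValueError("empty abundance map")
    weights = np.array([float(abundances.get(hp.id, 0.0)) for hp in bundle.hairpins])
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("abundance weights must be nonnegative and not all zero")
    probs = weights / weights.sum()

    rng = np.random.default_rng([config.seed, 1])
    adaptor = config.adaptor_sequence
    tail = adaptor + config.linker_sequence + "A" * config.read_length
    libraries: dict[str, list[tuple[str, str]]] = {}
    for lib_idx in range(config.n_libraries):
        lib_id = f"lib{lib_idx + 1}"
        size = max(
            1,
            int(
                round(
                    config.reads_per_library
                    * float(np.exp(config.library_depth_sd * rng.standard_normal()))
                )
            ),
        )
        n_dimer = rng.binomial(size, config.dimer_fraction)
        n_linker = rng.binomial(size, config.linker_fraction)
        n_nrich = rng.binomial(size, config.n_read_fraction)
        n_mirna = max(0, size - n_dimer - n_linker - n_nrich)

        reads: list[str] = []
        hp_choice = rng.choice(len(bundle.hairpins), size=n_mirna, p=probs)
        use_star = rng.random(n_mirna) < config.star_fraction
        jit5 = rng.choice(_JITTER, size=n_mirna, p=_JITTER_P)
        jit3 = rng.choice(_JITTER, size=n_mirna, p=_JITTER_P)
        for j in range(n_mirna):
            hp = bundle.hairpins[hp_choice[j]]
            _, start, end = (
                hp.star_intervals[0] if use_star[j] else hp.mature_intervals[0]
            )
            start = int(np.clip(start + jit5[j], 0, len(hp.sequence) - 1))
            end = int(np.clip(end + jit3[j], start + 1, len(hp.sequence)))
            insert = hp.sequence[start:end]
            reads.append((insert + tail)[: config.read_length])
        for _ in range(n_dimer):
            reads.append((adaptor + adaptor + tail)[: config.read_length])
        for _ in range(n_linker):
            reads.append((config.linker_sequence + tail)[: config.read_length])
        for _ in range(n_nrich):
            base = _random_seq(rng, config.read_length)
            n_mask = rng.random(config.read_length) < 0.6
            reads.append(
                "".join("N" if m else b for m, b in zip(n_mask, base))
            )
        order = rng.permutation(len(reads))
        libraries[lib_id] = [
            (f"{lib_id}_r{i + 1:06d}", reads[k]) for i, k in enumerate(order)
        ]
    return libraries


@dataclass
class TissuePanelSim:
    """Raw panel counts plus the ground truth used by recovery tests."""

    counts: pd.DataFrame  # miRNA x library raw counts
    library_tissues: dict[str, str]
    true_fractions: pd.DataFrame  # miRNA x tissue, rows sum to 1
    planted: dict[str, str]
    duplicate_pair: tuple[str, str]


def simulate_tissue_panel(config: SimulationConfig) -> TissuePanelSim:
    """Simulate the multi-tissue miRNA count panel.

    Global miRNA abundances are log-normal with sigma
    ``abundance_concentration`` (heavy-tailed: a minority of miRNAs dominates
    each library); per-tissue factors are log-normal with sigma
    ``tissue_noise_sd``; the first two tissues are near-duplicates (the second
    reuses the first's factors with small extra noise). Planted miRNAs place
    85-95% of their cross-tissue expression in the designated tissue and are
    boosted in abundance so they survive the downstream expression filter.
    """
    if config.n_tissues < 3:
        raise ValueError("n_tissues must be >= 3")
    rng = np.random.default_rng([config.seed, 2])
    tissues = config.tissues()
    T = config.n_tissues
    M = config.n_panel_mirnas
    mirnas = [f"panel-mir-{i + 1:03d}" for i in range(M)]
    planted = config.planted_plan()
    missing = set(planted) - set(mirnas)
    if missing:
        raise ValueError(f"planted miRNAs outside the panel: {sorted(missing)}")

    weights = np.exp(config.abundance_concentration * rng.standard_normal(M))
    boost = 2.0 * float(np.quantile(weights, 0.85))
    for m in planted:
        weights[mirnas.index(m)] = max(weights[mirnas.index(m)], boost)

    log_factors = config.tissue_noise_sd * rng.standard_normal((M, T))
    # near-duplicate pair: second tissue echoes the first
    log_factors[:, 1] = (
        log_factors[:, 0]
        + config.duplicate_tissue_noise_sd * rng.standard_normal(M)
    )
    expr = weights[:, None] * np.exp(log_factors)

    mean_factor = float(np.exp(config.tissue_noise_sd**2 / 2))
    lo, hi = config.planted_fraction
    for m, tissue in planted.items():
        i = mirnas.index(m)
        t = tissues.index(tissue)
        frac = rng.uniform(lo, hi)
        rest = np.exp(0.3 * rng.standard_normal(T))
        rest[t] = 0.0
        rest = (1.0 - frac) * rest / rest.sum()
        rest[t] = frac
        expr[i] = weights[i] * mean_factor * T * rest

    true_fractions = pd.DataFrame(
        expr / expr.sum(axis=1, keepdims=True), index=mirnas, columns=list(tissues)
    )

    lib_cols = []
    lib_tissue = {}
    counts = {}
    for t_idx, tissue in enumerate(tissues):
        composition = expr[:, t_idx] / expr[:, t_idx].sum()
        for l_idx in range(config.n_libraries_per_tissue):
            lib = f"{tissue}_l{l_idx + 1}"
            depth = config.mean_library_reads * float(
                np.exp(config.panel_depth_sd * rng.standard_normal())
            )
            counts[lib] = rng.poisson(depth * composition)
            lib_cols.append(lib)
            lib_tissue[lib] = tissue
    counts_df = pd.DataFrame(counts, index=mirnas, columns=lib_cols, dtype=float)
    return TissuePanelSim(
        counts=counts_df,
        library_tissues=lib_tissue,
        true_fractions=true_fractions,
        planted=dict(planted),
        duplicate_pair=config.duplicate_pair(),
    )


@dataclass
class GwasSim:
    """Synthetic GWAS inputs plus ground truth."""

    variants: pd.DataFrame  # id, chrom, pos (1-based), ref, alt, pvalue
    haplotypes: pd.DataFrame  # {0,1}, rows = haplotypes, columns = variant ids
    genes: pd.DataFrame  # gene_id, chrom, start, end, span_bp, n_variants, n_proxies
    gene_sets: dict[str, list[str]]
    intervals: pd.DataFrame  # BED-like: precursor / target_site / gene features
    truth: dict = field(default_factory=dict)


def simulate_gwas(config: SimulationConfig) -> GwasSim:
    """Simulate variants, an LD haplotype panel, gene annotations and target
    gene sets.

    Variants carry uniform association p-values under the null; for genes in
    the planted pool (the union of the planted sets' members) p-values are
    deflated as ``u ** effect_inflation``. The haplotype panel has Poisson-
    sized LD blocks: each block member copies a founder column with per-site
    mutation probability ``ld_mutation_prob``, and one member per block is an
    exact copy (r^2 = 1). Gene confounders (span, variant count, LD proxy
    count) are emitted for the enrichment adjustment.
    """
    if config.n_variants < config.n_genes:
        raise ValueError("n_variants must be >= n_genes")
    rng = np.random.default_rng([config.seed, 3])
    G, V, H = config.n_genes, config.n_variants, config.n_haplotypes

    spans = np.exp(rng.normal(9.0, 0.6, G)).astype(int) + 500
    gaps = rng.integers(500, 3000, G)
    starts = np.concatenate([[0], np.cumsum(spans + gaps)[:-1]])
    ends = starts + spans
    gene_ids = [f"g{i + 1:04d}" for i in range(G)]
    genome_end = int(ends[-1] + 1000)

    # one guaranteed variant per gene, the rest uniform over the region
    pos_in_gene = starts + (rng.random(G) * spans).astype(int)
    pos_extra = rng.integers(0, genome_end, V - G)
    pos0 = np.concatenate([pos_in_gene, pos_extra])  # 0-based
    pos0 = np.sort(pos0)
    # de-duplicate positions to keep (chrom,pos) unique per variant
    dup = np.flatnonzero(np.diff(pos0) == 0)
    while dup.size:
        pos0[dup + 1] += 1
        pos0 = np.sort(pos0)
        dup = np.flatnonzero(np.diff(pos0) == 0)
    var_ids = [f"rs{i + 1:06d}" for i in range(V)]

    # LD blocks
    block_ids = np.empty(V, dtype=int)
    hap = np.empty((H, V), dtype=np.int8)
    i = 0
    block = 0
    while i < V:
        size = int(rng.poisson(config.ld_block_size)) + 1
        size = min(size, V - i)
        founder = (rng.random(H) < rng.uniform(0.1, 0.5)).astype(np.int8)
        for j in range(size):
            if j == 0:
                col = founder.copy()
            elif j == 1:
                col = founder.copy()  # exact copy: guaranteed r^2 = 1 proxy
            else:
                flip = rng.random(H) < config.ld_mutation_prob
                col = founder ^ flip.astype(np.int8)
            hap[:, i + j] = col
            block_ids[i + j] = block
        i += size
        block += 1
    block_sizes = np.bincount(block_ids)

    # variant -> gene assignment (genes are disjoint)
    gene_of_variant = np.full(V, -1)
    gi = np.searchsorted(starts, pos0, side="right") - 1
    inside = (gi >= 0) & (pos0 < ends[np.clip(gi, 0, G - 1)])
    gene_of_variant[inside] = gi[inside]

    # planted gene pool and sets
    planted_sets = tuple(config.planted_enriched_sets)
    set_ids = [f"set{i + 1:02d}" for i in range(config.n_gene_sets)]
    unknown = set(planted_sets) - set(set_ids)
    if unknown:
        raise ValueError(f"planted set ids not generated: {sorted(unknown)}")
    pool = (
        rng.choice(G, min(config.planted_gene_pool_size, G), replace=False)
        if planted_sets
        else np.array([], dtype=int)
    )
    pool_set = set(pool.tolist())
    lo, hi = config.set_size_range
    gene_sets: dict[str, list[str]] = {}
    for sid in set_ids:
        size = int(rng.integers(lo, hi + 1))
        if sid in planted_sets:
            members = rng.choice(pool, min(size, len(pool)), replace=False)
        else:
            members = rng.choice(G, size, replace=False)
        gene_sets[sid] = sorted(gene_ids[k] for k in members)

    pvals = rng.uniform(0.0, 1.0, V)
    if pool_set and config.effect_inflation != 1.0:
        in_pool = np.isin(gene_of_variant, pool)
        pvals[in_pool] = pvals[in_pool] ** config.effect_inflation
    pvals = np.clip(pvals, 1e-300, 1.0)

    ref = np.array(list("ACGT"))[rng.integers(0, 4, V)]
    alt_off = rng.integers(1, 4, V)
    alt = np.array(list("ACGT"))[
        (np.searchsorted(np.array(list("ACGT")), ref) + alt_off) % 4
    ]
    variants = pd.DataFrame(
        {
            "id": var_ids,
            "chrom": "chr1",
            "pos": pos0 + 1,  # 1-based, VCF convention
            "ref": ref,
            "alt": alt,
            "pvalue": pvals,
        }
    )
    haplotypes = pd.DataFrame(
        hap, index=[f"hap{i + 1:03d}" for i in range(H)], columns=var_ids
    )

    n_var_per_gene = np.bincount(
        gene_of_variant[gene_of_variant >= 0], minlength=G
    )
    proxies = np.zeros(G, dtype=int)
    for v in range(V):
        g = gene_of_variant[v]
        if g >= 0:
            proxies[g] += block_sizes[block_ids[v]] - 1
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr1",
            "start": starts,
            "end": ends,
            "span_bp": spans,
            "n_variants": n_var_per_gene,
            "n_proxies": proxies,
        }
    )

    # interval annotations: miRNA precursors and predicted target sites
    n_prec, n_ts = 8, 10
    prec_anchor = rng.choice(V, n_prec, replace=False)
    ts_anchor = rng.choice(V, n_ts, replace=False)
    rows = []
    for k, v in enumerate(prec_anchor):
        p = int(pos0[v])
        rows.append(
            ("chr1", max(0, p - 40), p + 41, f"precursor-{k + 1:02d}", "precursor",
             "+", f"locus-{k % 6 + 1}")
        )
    for k, v in enumerate(ts_anchor):
        p = int(pos0[v])
        rows.append(
            ("chr1", max(0, p - 11), p + 12, f"site-{k + 1:02d}", "target_site",
             "+" if k % 2 == 0 else "-", f"locus-{k % 6 + 1}")
        )
    intervals = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "feature_type", "strand", "locus"],
    )

    truth = {
        "pool_genes": sorted(gene_ids[k] for k in pool),
        "planted_sets": list(planted_sets),
        "block_ids": dict(zip(var_ids, block_ids.tolist())),
        "gene_of_variant": {
            var_ids[v]: (gene_ids[gene_of_variant[v]] if gene_of_variant[v] >= 0 else None)
            for v in range(V)
        },
    }
    return GwasSim(
        variants=variants,
        haplotypes=haplotypes,
        genes=genes,
        gene_sets=gene_sets,
        intervals=intervals,
        truth=truth,
    )
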