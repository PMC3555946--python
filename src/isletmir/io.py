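"""Readers and writers for the plain-text formats used across the pipeline.

FASTA/FASTQ go through Biopython; tabular formats (count matrices, hairpin
coordinate tables, haplotype panels, gene sets, BED intervals) through pandas.
Coordinates in the hairpin table and BED files are 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs with flat dummy Phred+33 qualities."""
    def _records():
        for name, seq in reads:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


HAIRPIN_TABLE_COLUMNS = ["hairpin_id", "name", "type", "start", "end"]


def write_hairpin_table(hairpins, path: str | os.PathLike) -> None:
    """Mature/star sub-coordinates of each hairpin, 0-based half-open."""
    rows = []
    for hp in hairpins:
        for name, start, end in hp.mature_intervals:
            rows.append((hp.id, name, "mature", start, end))
        for name, start, end in hp.star_intervals:
            rows.append((hp.id, name, "star", start, end))
    pd.DataFrame(rows, columns=HAIRPIN_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hairpin_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


BED_COLUMNS = ["chrom", "start", "end", "name", "feature_type", "strand", "locus"]


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    intervals.loc[:, [c for c in BED_COLUMNS if c in intervals.columns]].to_csv(
        path, sep="\t", index=False
    )


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path: str | os.PathLike) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_haplotypes(panel: pd.DataFrame, path: str | os.PathLike) -> None:
    panel.to_csv(path, sep="\t", index_label="haplotype")


def read_haplotypes(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="haplotype")


def write_gene_sets(sets: Mapping[str, Sequence[str]], path: str | os.PathLike) -> None:
    rows = [(set_id, g) for set_id, genes in sets.items() for g in genes]
    pd.DataFrame(rows, columns=["set_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | os.PathLike) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {set_id: list(sub["gene_id"]) for set_id, sub in df.groupby("set_id", sort=True)}
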