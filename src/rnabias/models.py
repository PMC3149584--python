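"""Shared containers for gene models, covariates, counts and expression.

Coordinate convention: annotation files (GTF/GFF3) use 1-based inclusive
coordinates on disk; everything in memory is 0-based half-open, the
convention pyranges/pysam use.  Exons of a transcript are stored sorted by
start and must not overlap each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the 16 dinucleotides in the fixed column order used throughout
DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]

#: all 18 bias covariates, in fixed order: log length, GC, then dinucleotides
COVARIATE_COLUMNS = ["log_length", "gc"] + DINUCLEOTIDES

UNIT_KINDS = ("transcript", "gene", "sino")


@dataclass
class Gene:
    gene_id: str
    chromosome: str
    strand: str
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class GeneModelSet:
    """Genes -> transcripts -> exon intervals, plus spliced cDNA sequences.

    ``transcripts`` maps transcript_id to a sorted list of ``(start, end)``
    exon intervals in 0-based half-open genomic coordinates.  ``sequences``
    maps transcript_id to the spliced cDNA (minus-strand transcripts are
    reverse-complemented, i.e. given 5'->3').
    """

    genes: dict[str, Gene]
    transcripts: dict[str, list[tuple[int, int]]]
    sequences: dict[str, str]
    transcript_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcript_gene:
            self.transcript_gene = {
                tid: g.gene_id for g in self.genes.values() for tid in g.transcript_ids
            }

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """Genomic span (chromosome, min exon start, max exon end) of a gene."""
        g = self.genes[gene_id]
        starts, ends = [], []
        for tid in g.transcript_ids:
            for s, e in self.transcripts[tid]:
                starts.append(s)
                ends.append(e)
        return g.chromosome, min(starts), max(ends)

    def validate(self) -> None:
        for tid, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"transcript {tid!r} has no exons")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"transcript {tid!r} has overlapping/unsorted exons")
            if tid in self.sequences:
                total = sum(e - s for s, e in exons)
                if len(self.sequences[tid]) != total:
                    raise ValueError(
                        f"transcript {tid!r}: sequence length {len(self.sequences[tid])}"
                        f" != summed exon length {total}"
                    )


@dataclass
class BiasCovariateTable:
    """Per-unit values of the 18 bias covariates.

    ``table`` is indexed by unit id with columns ``COVARIATE_COLUMNS``:
    natural-log cDNA length (nt), GC fraction, and the 16 overlapping
    dinucleotide frequencies.
    """

    table: pd.DataFrame
    unit_kind: str

    @property
    def unit_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def X(self) -> np.ndarray:
        return self.table[COVARIATE_COLUMNS].to_numpy(float)

    def lengths(self) -> pd.Series:
        """cDNA lengths in nt, recovered from the log-length column."""
        return np.exp(self.table["log_length"]).round().astype(int)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="unit_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, unit_kind: str = "gene") -> "BiasCovariateTable":
        df = pd.read_csv(path, sep="\t", index_col="unit_id")
        return cls(table=df[COVARIATE_COLUMNS], unit_kind=unit_kind)


@dataclass
class CountTable:
    """Read-start counts per unit per lane plus per-lane mapped-read totals.

    Counts are not constrained to sum below ``total_mapped``: reads whose
    start falls where two units' exons overlap are counted in both.
    """

    counts: pd.DataFrame  # units x lanes, nonnegative ints
    total_mapped: pd.Series  # per lane

    @property
    def unit_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lanes(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc["__total_mapped__"] = self.total_mapped
        out.to_csv(path, sep="\t", index_label="unit_id")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="unit_id")
        totals = df.loc["__total_mapped__"]
        counts = df.drop(index="__total_mapped__").astype(int)
        return cls(counts=counts, total_mapped=totals.astype(int))


@dataclass
class ExpressionTable:
    """Per-unit expression (RPKM by construction, or externally supplied FPKM)."""

    Y: pd.DataFrame  # units x samples, nonnegative
    lengths: pd.Series  # cDNA length per unit, nt

    @property
    def unit_ids(self) -> list[str]:
        return list(self.Y.index)

    def to_tsv(self, path) -> None:
        out = self.Y.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="unit_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col="unit_id")
        return cls(Y=df.drop(columns="length"), lengths=df["length"])
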