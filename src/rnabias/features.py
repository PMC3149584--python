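"""Gene-model loading and gene-level sequence covariates.

The bias covariates attached to every analysis unit are the natural log of
cDNA length, the GC fraction, and the 16 overlapping dinucleotide
frequencies of the spliced cDNA.  Units come in three flavours:

* ``transcript`` — each transcript is its own unit;
* ``gene`` — one row per gene, taking the median across that gene's
  isoforms *independently per covariate* (median length is log-transformed
  after the median; the 16 median frequencies are deliberately not
  renormalised);
* ``sino`` — gene units restricted to single-isoform non-overlapping
  (SINO) genes, i.e. genes with exactly one transcript whose genomic span
  intersects no other gene's span on the same chromosome (strand ignored).

Positions containing ``N`` are excluded from both numerator and
denominator of GC content, and dinucleotide windows containing ``N`` are
skipped.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter

import numpy as np
import pandas as pd
import pyranges as pr
from pyfaidx import Fasta

from .models import (
    COVARIATE_COLUMNS,
    DINUCLEOTIDES,
    BiasCovariateTable,
    Gene,
    GeneModelSet,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence over {A,C,G,T,N}; N positions are ignored.

    Raises ``ValueError`` when no valid (non-N) base exists.
    """
    seq = sequence.upper()
    counts = Counter(seq)
    valid = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if valid == 0:
        raise ValueError("gc_content undefined: sequence has no non-N base")
    return (counts["G"] + counts["C"]) / valid


def dinucleotide_frequencies(sequence: str) -> np.ndarray:
    """Frequencies of the 16 overlapping dinucleotides, in AA..TT order.

    Windows of width 2 stepped by 1; windows containing N are skipped and
    the denominator shrinks accordingly.  Raises ``ValueError`` when no
    valid window exists.
    """
    seq = sequence.upper()
    counts = Counter(zip(seq, seq[1:]))
    valid = sum(v for (a, b), v in counts.items() if a in "ACGT" and b in "ACGT")
    if valid == 0:
        raise ValueError("dinucleotide_frequencies undefined: no valid window")
    return np.array([counts[(d[0], d[1])] / valid for d in DINUCLEOTIDES])


def _read_exon_table(annotation_path: str) -> pd.DataFrame:
    path = str(annotation_path)
    if path.endswith((".gff", ".gff3")):
        df = pr.read_gff3(path, as_df=True)
    else:
        df = pr.read_gtf(path, as_df=True)
    df = df[df["Feature"] == "exon"]
    if df.empty:
        raise ValueError(f"no exon features found in {path!r}")
    for col in ("gene_id", "transcript_id"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(f"exon features in {path!r} lack a {col} attribute")
    return df


def load_gene_models(annotation_path, genome_path) -> GeneModelSet:
    """Parse a GTF/GFF3 annotation and extract spliced cDNA sequences.

    Input coordinates are 1-based inclusive on disk and converted to
    0-based half-open in memory.  Minus-strand transcripts get the reverse
    complement of their concatenated exon sequence.
    """
    exons = _read_exon_table(annotation_path)
    fasta = Fasta(str(genome_path), sequence_always_upper=True, rebuild=False)

    genes: dict[str, Gene] = {}
    transcripts: dict[str, list[tuple[int, int]]] = {}
    sequences: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}

    for row in exons.itertuples(index=False):
        start, end = int(row.Start), int(row.End)
        if end < start:
            raise ValueError(
                f"exon with end < start for transcript {row.transcript_id!r}"
            )
        strand = str(row.Strand)
        if strand not in {"+", "-"}:
            raise ValueError(f"unknown strand symbol {strand!r}")
        tid, gid, chrom = str(row.transcript_id), str(row.gene_id), str(row.Chromosome)
        transcripts.setdefault(tid, []).append((start, end))
        tx_meta[tid] = (gid, chrom, strand)

    for tid, (gid, chrom, strand) in tx_meta.items():
        gene = genes.setdefault(gid, Gene(gene_id=gid, chromosome=chrom, strand=strand))
        gene.transcript_ids.append(tid)
        exon_list = sorted(transcripts[tid])
        transcripts[tid] = exon_list
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom!r} missing from genome FASTA")
        seq = "".join(str(fasta[chrom][s:e]) for s, e in exon_list)
        sequences[tid] = reverse_complement(seq) if strand == "-" else seq

    models = GeneModelSet(genes=genes, transcripts=transcripts, sequences=sequences)
    models.validate()
    return models


def find_sino_genes(models: GeneModelSet) -> set[str]:
    """Single-isoform non-overlapping genes.

    A gene qualifies when it has exactly one transcript and its genomic
    span (min exon start to max exon end) intersects no other gene's span
    on the same chromosome, irrespective of strand.
    """
    spans = {gid: models.gene_span(gid) for gid in models.genes}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (chrom, s, e) in spans.items():
        by_chrom.setdefault(chrom, []).append((s, e, gid))

    overlapping: set[str] = set()
    for intervals in by_chrom.values():
        intervals.sort()
        active: list[tuple[int, str]] = []  # (end, gid); half-open: touching spans ok
        for s, e, gid in intervals:
            active = [(ae, agid) for ae, agid in active if ae > s]
            for _, agid in active:
                overlapping.add(agid)
                overlapping.add(gid)
            active.append((e, gid))

    return {
        gid
        for gid, g in models.genes.items()
        if len(g.transcript_ids) == 1 and gid not in overlapping
    }


def _transcript_raw_features(models: GeneModelSet, tids) -> pd.DataFrame:
    rows = {}
    for tid in tids:
        seq = models.sequences[tid]
        rows[tid] = np.concatenate(
            [[float(len(seq)), gc_content(seq)], dinucleotide_frequencies(seq)]
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["length", "gc"] + DINUCLEOTIDES
    )


def gene_covariates(models: GeneModelSet, unit_kind: str = "gene") -> BiasCovariateTable:
    """The 18 bias covariates per unit, under the requested unit definition.

    Gene units take the per-covariate median across the gene's isoforms
    (length median is taken on the nt scale, then logged); the resulting
    dinucleotide medians need not sum to 1.
    """
    if unit_kind not in {"transcript", "gene", "sino"}:
        raise ValueError(f"unknown unit_kind {unit_kind!r}")

    if unit_kind == "transcript":
        raw = _transcript_raw_features(models, models.sequences.keys())
        raw = raw.sort_index()
    else:
        gene_ids = sorted(models.genes)
        if unit_kind == "sino":
            keep = find_sino_genes(models)
            gene_ids = [g for g in gene_ids if g in keep]
        skipped = 0
        rows = {}
        for gid in gene_ids:
            tids = models.genes[gid].transcript_ids
            if not tids:
                skipped += 1
                continue
            tx = _transcript_raw_features(models, tids)
            rows[gid] = tx.median(axis=0)
        if skipped:
            warnings.warn(f"excluded {skipped} genes with zero transcripts")
            logger.warning("excluded %d genes with zero transcripts", skipped)
        raw = pd.DataFrame.from_dict(rows, orient="index")

    table = raw.copy()
    table.insert(0, "log_length", np.log(raw["length"]))
    table = table.drop(columns="length")[COVARIATE_COLUMNS]
    return BiasCovariateTable(table=table, unit_kind=unit_kind)
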