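"""Read-start counting and RPKM conversion.

A read is assigned by its start position — the 5' end in sequencing
orientation, i.e. the leftmost aligned base for forward alignments and the
rightmost for reverse-strand alignments.  Every unit with at least one
exon containing that position is incremented, so reads falling where two
genes' exons overlap are double counted rather than split probabilistically.
Every reported alignment of a multi-mapped read contributes one count.
"""

from __future__ import annotations

import logging

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .models import CountTable, ExpressionTable, GeneModelSet

logger = logging.getLogger(__name__)


def _unit_exons(models: GeneModelSet, unit_kind: str):
    """Yield (unit_id, chromosome, exon list) under the chosen unit definition."""
    if unit_kind == "transcript":
        for tid, exons in models.transcripts.items():
            gid = models.transcript_gene[tid]
            yield tid, models.genes[gid].chromosome, exons
    elif unit_kind in {"gene", "sino"}:
        from .features import find_sino_genes

        keep = find_sino_genes(models) if unit_kind == "sino" else None
        for gid, gene in models.genes.items():
            if keep is not None and gid not in keep:
                continue
            exons = [ex for tid in gene.transcript_ids for ex in models.transcripts[tid]]
            yield gid, gene.chromosome, exons
    else:
        raise ValueError(f"unknown unit_kind {unit_kind!r}")


def _build_exon_index(models: GeneModelSet, unit_kind: str):
    trees: dict[str, IntervalTree] = {}
    unit_ids: list[str] = []
    for uid, chrom, exons in _unit_exons(models, unit_kind):
        unit_ids.append(uid)
        tree = trees.setdefault(chrom, IntervalTree())
        for s, e in exons:
            if e > s:
                tree.addi(s, e, uid)
    return trees, sorted(unit_ids)


def read_start_position(aln: pysam.AlignedSegment) -> int:
    """0-based position of the 5' end in sequencing orientation."""
    return aln.reference_end - 1 if aln.is_reverse else aln.reference_start


def iter_alignments(alignments):
    """Accept a SAM/BAM path, an open AlignmentFile, or an iterable of segments."""
    if isinstance(alignments, (str,)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_read_starts(
    alignments, models: GeneModelSet, unit_kind: str = "gene", lane: str = "lane1"
) -> CountTable:
    """Count mapped reads whose start position falls in a unit's exons.

    ``total_mapped`` is the number of mapped alignment records processed,
    including those starting outside any exon.  Alignments on chromosomes
    absent from the models are skipped and tallied in a warning counter.
    """
    trees, unit_ids = _build_exon_index(models, unit_kind)
    counts = dict.fromkeys(unit_ids, 0)
    total = 0
    skipped_chrom = 0
    for aln in iter_alignments(alignments):
        if aln.is_unmapped:
            continue
        total += 1
        chrom = aln.reference_name
        tree = trees.get(chrom)
        if tree is None:
            skipped_chrom += 1
            continue
        pos = read_start_position(aln)
        for hit in {iv.data for iv in tree.at(pos)}:
            counts[hit] += 1
    if skipped_chrom:
        logger.warning("skipped %d alignments on unknown chromosomes", skipped_chrom)
    frame = pd.DataFrame({lane: pd.Series(counts, dtype=int)}).loc[unit_ids]
    return CountTable(counts=frame, total_mapped=pd.Series({lane: total}))


def rpkm(counts: CountTable, lengths: pd.Series) -> ExpressionTable:
    """Reads per kilobase of cDNA per million mapped reads.

    Y_i = C_i * 1e9 / (N * L_i), per lane, with N the lane's mapped total.
    """
    lengths = lengths.reindex(counts.unit_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing lengths for units (e.g. {missing})")
    if (lengths <= 0).any():
        raise ValueError("unit lengths must be positive")
    if (counts.total_mapped <= 0).any():
        raise ValueError("total_mapped must be positive in every lane")
    Y = counts.counts * 1e9
    Y = Y.div(counts.total_mapped, axis=1).div(lengths.astype(float), axis=0)
    return ExpressionTable(Y=Y, lengths=lengths)


def merge_lanes(tables: list[CountTable], k: int | None = None) -> CountTable:
    """Element-wise sum of counts and mapped totals over the first ``k`` lanes."""
    if k is None:
        k = len(tables)
    if not 1 <= k <= len(tables):
        raise ValueError(f"k={k} outside 1..{len(tables)}")
    first = tables[0]
    for t in tables[1:k]:
        if t.unit_ids != first.unit_ids:
            raise ValueError("mismatched unit_ids across lanes")
    merged = sum(t.counts.sum(axis=1) for t in tables[:k])
    total = int(sum(t.total_mapped.sum() for t in tables[:k]))
    name = f"merged_1_{k}"
    return CountTable(
        counts=pd.DataFrame({name: merged.astype(int)}),
        total_mapped=pd.Series({name: total}),
    )
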