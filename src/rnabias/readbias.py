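"""Dinucleotide composition at mapped-read start positions.

Library preparation (notably random-hexamer priming) leaves a fingerprint
in which reference dinucleotides mapped reads start on.  This module
tallies, for each mapped alignment, the two *reference* bases at the
read's 5' start in sequencing orientation (reverse-complemented for
reverse-strand alignments) and reports the percentage distribution over
the 16 dinucleotides, split into uniquely mapped and multi-mapped reads.
Reference bases rather than read bases are used so sequencing errors do
not blur the profile.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd
import pysam
from pyfaidx import Fasta

from .features import reverse_complement
from .models import DINUCLEOTIDES

logger = logging.getLogger(__name__)

READ_CLASSES = ("unique", "multi")


@dataclass
class ReadStartProfile:
    """Percentage of each start dinucleotide per read class.

    ``percentages`` is a 16 x classes DataFrame (columns only for classes
    that actually contain reads; empty classes are absent, not zero).
    """

    percentages: pd.DataFrame
    counts: pd.DataFrame
    read_counts: dict[str, int]
    skipped: int = 0

    def to_tsv(self, path) -> None:
        rows = []
        for cls in self.percentages.columns:
            for d in DINUCLEOTIDES:
                rows.append(
                    {
                        "dinuc": d,
                        "read_type": cls,
                        "percent": round(self.percentages.loc[d, cls], 4),
                        "count": int(self.counts.loc[d, cls]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _classify(aln: pysam.AlignedSegment, name_counts: Counter | None) -> str:
    if aln.has_tag("NH"):
        return "unique" if aln.get_tag("NH") == 1 else "multi"
    if name_counts is not None:
        return "unique" if name_counts[aln.query_name] <= 1 else "multi"
    return "unique"


def read_start_dinucleotide_profile(alignments, genome_path) -> ReadStartProfile:
    """Tally reference dinucleotides at read starts, by unique/multi class.

    Reads are classified by the NH tag when present, else by counting
    records sharing a query name.  Each alignment of a multi-mapped read
    contributes one tally.  Starts within one base of a chromosome end
    (no room for a dinucleotide) and windows containing N are skipped.
    """
    fasta = Fasta(str(genome_path), sequence_always_upper=True, rebuild=False)

    records = list(_open_records(alignments))
    has_nh = any(a.has_tag("NH") for a in records[:100])
    name_counts = None if has_nh else Counter(a.query_name for a in records)

    tallies: dict[str, Counter] = {c: Counter() for c in READ_CLASSES}
    skipped = 0
    for aln in records:
        chrom = aln.reference_name
        if chrom not in fasta:
            skipped += 1
            continue
        chrom_len = len(fasta[chrom])
        if aln.is_reverse:
            end = aln.reference_end  # exclusive; 5' base is end-1
            if end < 2 or end > chrom_len:
                skipped += 1
                continue
            dinuc = reverse_complement(str(fasta[chrom][end - 2 : end]))
        else:
            start = aln.reference_start
            if start < 0 or start + 2 > chrom_len:
                skipped += 1
                continue
            dinuc = str(fasta[chrom][start : start + 2])
        if "N" in dinuc:
            skipped += 1
            continue
        tallies[_classify(aln, name_counts)][dinuc] += 1
    if skipped:
        logger.warning("skipped %d alignments (chromosome edge / N / unknown)", skipped)

    read_counts = {c: sum(t.values()) for c, t in tallies.items()}
    present = [c for c in READ_CLASSES if read_counts[c] > 0]
    counts = pd.DataFrame(
        {c: [tallies[c][d] for d in DINUCLEOTIDES] for c in present},
        index=DINUCLEOTIDES,
    )
    percentages = 100.0 * counts / counts.sum(axis=0)
    return ReadStartProfile(
        percentages=percentages, counts=counts, read_counts=read_counts, skipped=skipped
    )


def _open_records(alignments):
    if isinstance(alignments, str) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from (a for a in fh if not a.is_unmapped)
    else:
        yield from (a for a in alignments if not a.is_unmapped)
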