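"""Synthetic transcriptomes, biased counts and toy alignments.

The generator produces data with the statistical structure the correction
method assumes, so every stage of the pipeline can be exercised without
downloads:

* random transcript sequences from a first-order (two-state GC/AT) Markov
  chain tuned to a per-gene target GC, with log-normal cDNA lengths,
  optional extra isoforms (exon skipping) and optional genomic overlaps
  between neighbouring genes;
* true log expression levels drawn independently of all sequence
  covariates;
* per-lane read counts Poisson-sampled with rate
  depth_l * exp(true_log_expr_i) * L_i * B_i, where the multiplicative
  bias B_i = exp(beta_L*logL + f_GC(GC) + sum_d gamma_d * freq_d)
  emulates the length-, GC- (linear and quadratic) and dinucleotide-
  dependent trends seen in real data;
* toy single-end alignments whose start positions inside exons are drawn
  proportionally to configurable start-dinucleotide weights, emulating
  priming bias.

All stages are deterministic given their seed; GTF/FASTA/SAM output is
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .features import gene_covariates, reverse_complement
from .models import DINUCLEOTIDES, BiasCovariateTable, CountTable, Gene, GeneModelSet

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMP_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space


@dataclass
class BiasSpec:
    """Coefficients of the multiplicative (log-scale) count bias.

    ``length_exponent`` multiplies log length; ``gc_linear`` and
    ``gc_quadratic`` apply to (GC - gc_center); ``dinucleotide`` maps
    dinucleotides to linear coefficients on their frequencies.  All-zero
    coefficients give unbiased sampling.
    """

    length_exponent: float = 0.0
    gc_linear: float = 0.0
    gc_quadratic: float = 0.0
    gc_center: float = 0.5
    dinucleotide: dict[str, float] = field(default_factory=dict)

    def log_bias(self, covariates: pd.DataFrame) -> pd.Series:
        g = covariates["gc"] - self.gc_center
        out = (
            self.length_exponent * covariates["log_length"]
            + self.gc_linear * g
            + self.gc_quadratic * g**2
        )
        for d, coef in self.dinucleotide.items():
            out = out + coef * covariates[d]
        return out

    def planted_covariates(self) -> list[str]:
        out = []
        if self.length_exponent != 0:
            out.append("log_length")
        if self.gc_linear != 0 or self.gc_quadratic != 0:
            out.append("gc")
        out.extend(d for d, c in self.dinucleotide.items() if c != 0)
        return out


#: canonical planted bias: negative length trend plus a quadratic GC trend,
#: the two dominant shapes reported for real libraries.  Magnitudes are set
#: so the bias contributes a clearly visible share of log-expression
#: variance (bias sd ~0.7 vs true-expression sd 1.5), comparable to the
#: multi-log-unit trends seen in strongly biased libraries.
DEFAULT_PLANTED_BIAS = BiasSpec(length_exponent=-0.8, gc_linear=6.0, gc_quadratic=-15.0)


@dataclass
class SimulationTruth:
    seed: int
    gene_table: pd.DataFrame  # per gene: chrom, strand, start, end, length, gc_target
    true_log_expr: pd.Series
    bias_spec: BiasSpec
    covariates: BiasCovariateTable
    genome: dict[str, str]
    lane_depths: np.ndarray | None = None


def _markov_states(rng: np.random.Generator, length: int, gc: float, rho: float):
    """Two-state (S=G/C vs W=A/T) Markov chain with stationary GC ``gc``.

    Vectorised: with p_sw = gc(1-rho) <= p_ss = gc + rho(1-gc), a uniform
    draw u decides S when u < p_sw, W when u >= p_ss, and copies the
    previous state in between — a last-decided-value scan.
    """
    p_ss = gc + rho * (1 - gc)
    p_sw = gc * (1 - rho)
    u = rng.random(length)
    decided_s = u < p_sw
    copy = (u >= p_sw) & (u < p_ss)
    copy[0] = False
    decided_s[0] = u[0] < gc
    idx = np.arange(length)
    last = np.maximum.accumulate(np.where(copy, -1, idx))
    return decided_s[last]


def _markov_sequence(
    rng: np.random.Generator,
    length: int,
    gc: float,
    rho: float,
    gc_tolerance: float | None = None,
    max_attempts: int = 8,
) -> str:
    """Random sequence from the GC/AT Markov chain.

    With ``gc_tolerance`` set, up to ``max_attempts`` candidate sequences
    are drawn and the one with realized GC closest to the target is kept
    (stopping early once within tolerance), so the generator delivers the
    GC composition it was asked for even at moderate lengths.
    ``rho`` is the first-order autocorrelation of the GC state, giving the
    dinucleotide frequencies signal beyond what GC alone implies.
    """
    attempts = 1 if gc_tolerance is None else max_attempts
    best_states, best_dev = None, np.inf
    for _ in range(attempts):
        states = _markov_states(rng, length, gc, rho)
        dev = abs(states.mean() - gc)
        if dev < best_dev:
            best_states, best_dev = states, dev
        if gc_tolerance is not None and best_dev <= gc_tolerance:
            break
    within = rng.integers(0, 2, size=length)  # G vs C, A vs T
    idx = np.where(
        best_states, np.where(within == 0, 1, 2), np.where(within == 0, 0, 3)
    )
    return "".join(_BASES[idx])


def _split_exons(rng: np.random.Generator, length: int, n_exons: int) -> list[int]:
    """Random partition of cDNA length into exon chunk lengths (each >= 20)."""
    n_exons = min(n_exons, max(1, length // 40))
    if n_exons == 1:
        return [length]
    cuts = np.sort(rng.choice(np.arange(20, length - 20), size=n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [length]]))
    if (sizes < 2).any():
        return [length]
    return sizes.tolist()


def simulate_transcriptome(
    n_genes: int = 2000,
    seed: int = 0,
    length_lognormal_params: tuple[float, float] = (7.3, 0.6),
    gc_range: tuple[float, float] = (0.35, 0.65),
    isoform_rate: float = 0.0,
    overlap_rate: float = 0.0,
    n_exons_range: tuple[int, int] = (1, 5),
    intron_length: int = 200,
    spacer_length: int = 300,
    markov_rho: float = 0.2,
    expr_params: tuple[float, float] = (0.0, 1.5),
    bias_spec: BiasSpec | None = None,
    genes_per_chromosome: int = 200,
    min_length: int = 200,
    max_length: int = 20000,
) -> tuple[GeneModelSet, SimulationTruth]:
    """Generate a synthetic annotated transcriptome with known truth.

    Genes are laid out sequentially on chromosomes with intergenic
    spacers; with probability ``overlap_rate`` a gene is instead placed as
    a single-exon gene overlapping its predecessor's exons (to exercise
    SINO detection and double counting), and with probability
    ``isoform_rate`` a multi-exon gene gets a second, exon-skipping
    isoform.  True log expression is drawn N(mu, sd) = ``expr_params``
    independently of all sequence covariates.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0 < gc_range[0] <= gc_range[1] < 1:
        raise ValueError(f"infeasible gc_range {gc_range}")
    rng = np.random.default_rng(seed)
    bias_spec = bias_spec if bias_spec is not None else BiasSpec()

    genes: dict[str, Gene] = {}
    transcripts: dict[str, list[tuple[int, int]]] = {}
    sequences: dict[str, str] = {}
    chrom_parts: dict[str, list[str]] = {}
    gene_rows = []

    chrom_cursor: dict[str, int] = {}
    prev_gene: dict[str, tuple[int, int, list[tuple[int, int]]]] = {}

    width = len(str(n_genes))
    for i in range(n_genes):
        gid = f"G{i + 1:0{width}d}"
        chrom = f"chr{i // genes_per_chromosome + 1}"
        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.setdefault(chrom, 0)
        strand = "+" if rng.random() < 0.5 else "-"

        make_overlap = (
            overlap_rate > 0 and chrom in prev_gene and rng.random() < overlap_rate
        )
        if make_overlap:
            # single exon carved out of the predecessor's first exon region
            ps, pe, pexons = prev_gene[chrom]
            ex_s, ex_e = pexons[0]
            length = min(400, ex_e - ex_s)
            start = ex_s
            end = start + length
            tid = f"{gid}.t1"
            genes[gid] = Gene(gene_id=gid, chromosome=chrom, strand=strand,
                              transcript_ids=[tid])
            transcripts[tid] = [(start, end)]
            gene_rows.append((gid, chrom, strand, start, end, length, np.nan, True))
            continue

        target_gc = rng.uniform(*gc_range)
        length = int(np.clip(
            np.round(rng.lognormal(*length_lognormal_params)), min_length, max_length
        ))
        cdna = _markov_sequence(rng, length, target_gc, markov_rho, gc_tolerance=0.015)
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        chunk_sizes = _split_exons(rng, length, n_exons)

        # cDNA chunks in 5'->3' order; genomic layout depends on strand
        chunks = []
        pos = 0
        for size in chunk_sizes:
            chunks.append(cdna[pos : pos + size])
            pos += size
        if strand == "+":
            genomic_chunks = chunks
        else:
            genomic_chunks = [reverse_complement(c) for c in reversed(chunks)]

        spacer = _markov_sequence(rng, spacer_length, 0.5, 0.0)
        parts.append(spacer)
        cursor += spacer_length
        gene_start = cursor
        exons = []
        for j, gch in enumerate(genomic_chunks):
            if j > 0:
                intron = _markov_sequence(rng, intron_length, 0.5, 0.0)
                parts.append(intron)
                cursor += intron_length
            exons.append((cursor, cursor + len(gch)))
            parts.append(gch)
            cursor += len(gch)
        gene_end = cursor
        chrom_cursor[chrom] = cursor

        tid = f"{gid}.t1"
        genes[gid] = Gene(gene_id=gid, chromosome=chrom, strand=strand,
                          transcript_ids=[tid])
        transcripts[tid] = exons
        sequences[tid] = cdna
        prev_gene[chrom] = (gene_start, gene_end, exons)
        gene_rows.append((gid, chrom, strand, gene_start, gene_end, length,
                          target_gc, False))

        if isoform_rate > 0 and len(exons) >= 3 and rng.random() < isoform_rate:
            # exon-skipping isoform: drop one internal exon
            skip = int(rng.integers(1, len(exons) - 1))
            tid2 = f"{gid}.t2"
            genes[gid].transcript_ids.append(tid2)
            transcripts[tid2] = [e for j, e in enumerate(exons) if j != skip]
            if strand == "+":
                kept = [c for j, c in enumerate(chunks) if j != skip]
            else:
                kept_genomic = [
                    c for j, c in enumerate(genomic_chunks) if j != skip
                ]
                kept = [reverse_complement(c) for c in reversed(kept_genomic)]
            sequences[tid2] = "".join(kept)

    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    # overlap genes: sequence read back from the assembled genome
    for gid, g in genes.items():
        for tid in g.transcript_ids:
            if tid in sequences:
                continue
            seq = "".join(genome[g.chromosome][s:e] for s, e in transcripts[tid])
            sequences[tid] = reverse_complement(seq) if g.strand == "-" else seq

    models = GeneModelSet(genes=genes, transcripts=transcripts, sequences=sequences)
    models.validate()

    gene_table = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "length",
                 "gc_target", "overlap_gene"],
    ).set_index("gene_id")
    true_log_expr = pd.Series(
        rng.normal(expr_params[0], expr_params[1], size=n_genes),
        index=gene_table.index,
        name="true_log_expr",
    )
    covariates = gene_covariates(models, "gene")
    truth = SimulationTruth(
        seed=seed,
        gene_table=gene_table,
        true_log_expr=true_log_expr,
        bias_spec=bias_spec,
        covariates=covariates,
        genome=genome,
    )
    return models, truth


def simulate_counts(
    truth: SimulationTruth,
    n_lanes: int = 1,
    seed: int = 0,
    reads_per_lane: float = 1_000_000,
    lane_depths: np.ndarray | None = None,
    overdispersion: float = 0.0,
) -> list[CountTable]:
    """Poisson counts per gene per lane under the planted multiplicative bias.

    Rates are depth_l * exp(true_log_expr_i) * L_i * B_i; by default the
    per-lane depth multiplier is set so a lane's expected total equals
    ``reads_per_lane``.  ``overdispersion`` > 0 switches to gamma-mixed
    Poisson (negative binomial) with that squared coefficient of
    variation.
    """
    rng = np.random.default_rng(seed)
    cov = truth.covariates.table.loc[truth.true_log_expr.index]
    lengths = np.exp(cov["log_length"])
    log_b = truth.bias_spec.log_bias(cov)
    base_rate = np.exp(truth.true_log_expr + log_b) * lengths
    if lane_depths is None:
        lane_depths = np.full(n_lanes, reads_per_lane / base_rate.sum())
    else:
        lane_depths = np.asarray(lane_depths, float)
        if (lane_depths < 0).any():
            raise ValueError("negative lane depth")
        n_lanes = len(lane_depths)
    truth.lane_depths = lane_depths

    tables = []
    for l, depth in enumerate(lane_depths):
        rate = depth * base_rate.to_numpy()
        if overdispersion > 0:
            rate = rate * rng.gamma(1 / overdispersion, overdispersion, size=len(rate))
        counts = rng.poisson(rate)
        name = f"lane{l + 1}"
        tables.append(
            CountTable(
                counts=pd.DataFrame({name: counts}, index=cov.index),
                total_mapped=pd.Series({name: int(counts.sum())}),
            )
        )
    return tables


# ---------------------------------------------------------------------------
# toy alignments with start-dinucleotide preference


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def simulate_alignments(
    models: GeneModelSet,
    genome: dict[str, str],
    start_dinuc_weights: dict[str, float] | np.ndarray,
    n_reads: int = 10000,
    seed: int = 0,
    read_length: int = 36,
    multi_fraction: float = 0.0,
    out_sam=None,
):
    """Draw reads starting in exons with dinucleotide-weighted start positions.

    For each candidate (position, strand) the weight is that of the
    reference dinucleotide at the read's 5' start in sequencing
    orientation.  A ``multi_fraction`` of reads is emitted as NH=2 pairs
    of records at independently drawn positions.  Returns a list of
    pysam.AlignedSegment; with ``out_sam`` also writes a SAM file.
    """
    if isinstance(start_dinuc_weights, dict):
        w = np.array([start_dinuc_weights.get(d, 0.0) for d in DINUCLEOTIDES])
    else:
        w = np.asarray(start_dinuc_weights, float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)

    chroms = sorted(genome)
    enc = {c: _encode(genome[c]) for c in chroms}
    cand_chrom, cand_pos, cand_strand, cand_w = [], [], [], []
    skipped_short = 0
    for ci, chrom in enumerate(chroms):
        positions = set()
        for gid, g in models.genes.items():
            if g.chromosome != chrom:
                continue
            for tid in g.transcript_ids:
                span = models.gene_span(gid)
                if span[2] - span[1] < read_length:
                    skipped_short += 1
                    continue
                for s, e in models.transcripts[tid]:
                    positions.update(range(s, e))
        if not positions:
            continue
        pos = np.array(sorted(positions))
        b = enc[chrom]
        n = len(b)
        # forward: read [p, p+rl) fully on chromosome, dinuc = b[p], b[p+1]
        ok_f = pos + read_length <= n
        pf = pos[ok_f]
        code_f = 4 * b[pf] + b[pf + 1]
        valid_f = (b[pf] >= 0) & (b[pf + 1] >= 0)
        pf, code_f = pf[valid_f], code_f[valid_f]
        # reverse: leftmost position q - rl + 1 >= 0 where q is the 5' base;
        # oriented dinuc = comp(b[q]), comp(b[q-1])
        ok_r = pos - read_length + 1 >= 0
        qr = pos[ok_r]
        valid_r = (b[qr] >= 0) & (b[qr - 1] >= 0)
        qr = qr[valid_r]
        code_r = 4 * _COMP_INDEX[b[qr]] + _COMP_INDEX[b[qr - 1]]
        for p_arr, c_arr, strand in ((pf, code_f, 0), (qr, code_r, 1)):
            cand_chrom.append(np.full(len(p_arr), ci))
            cand_pos.append(p_arr)
            cand_strand.append(np.full(len(p_arr), strand))
            cand_w.append(w[c_arr])

    cand_chrom = np.concatenate(cand_chrom)
    cand_pos = np.concatenate(cand_pos)
    cand_strand = np.concatenate(cand_strand)
    cand_w = np.concatenate(cand_w).astype(float)
    if cand_w.sum() == 0:
        raise ValueError("no candidate start position has positive weight")
    prob = cand_w / cand_w.sum()

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
        }
    )
    n_multi = int(round(n_reads * multi_fraction))
    draws = rng.choice(len(prob), size=n_reads + n_multi, p=prob)
    records = []
    for i in range(n_reads):
        picks = [draws[i]]
        nh = 1
        if i < n_multi:
            picks.append(draws[n_reads + i])
            nh = 2
        for j, d in enumerate(picks):
            ci, strand = int(cand_chrom[d]), int(cand_strand[d])
            chrom = chroms[ci]
            q5 = int(cand_pos[d])
            left = q5 if strand == 0 else q5 - read_length + 1
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{i + 1}"
            a.reference_id = ci
            a.reference_start = left
            a.flag = 16 if strand else 0
            if j > 0:
                a.flag |= 256  # secondary record of a multi-mapped read
            a.mapping_quality = 255
            a.cigarstring = f"{read_length}M"
            seq = genome[chrom][left : left + read_length]
            a.query_sequence = reverse_complement(seq) if strand else seq
            a.set_tag("NH", nh)
            records.append(a)

    if out_sam is not None:
        with pysam.AlignmentFile(str(out_sam), "wh", header=header) as fh:
            for a in records:
                fh.write(a)
    return records


# ---------------------------------------------------------------------------
# writers so simulated fixtures round-trip through the package's own readers


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(models: GeneModelSet, path) -> None:
    """Emit exon features with gene_id/transcript_id, 1-based inclusive."""
    with open(path, "w") as fh:
        for gid in sorted(models.genes):
            g = models.genes[gid]
            for tid in g.transcript_ids:
                for s, e in models.transcripts[tid]:
                    fh.write(
                        f"{g.chromosome}\trnabias_sim\texon\t{s + 1}\t{e}\t.\t"
                        f'{g.strand}\t.\tgene_id "{gid}"; transcript_id "{tid}";\n'
                    )


def write_truth_tsv(truth: SimulationTruth, path) -> None:
    out = truth.gene_table.copy()
    out["true_log_expr"] = truth.true_log_expr
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
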