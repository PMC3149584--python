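import pytest

import rnabias as rb
from rnabias.models import Gene, GeneModelSet


@pytest.fixture(scope="session")
def toy_models():
    """One plus-strand and one minus-strand gene on a 10 nt chromosome."""
    genome = {"chr1": "ACGTACGTAC"}
    genes = {
        "gplus": Gene("gplus", "chr1", "+", ["tplus"]),
        "gminus": Gene("gminus", "chr1", "-", ["tminus"]),
    }
    transcripts = {"tplus": [(0, 4), (6, 10)], "tminus": [(0, 4), (6, 10)]}
    spliced = genome["chr1"][0:4] + genome["chr1"][6:10]  # "ACGT"+"GTAC"
    sequences = {
        "tplus": spliced,
        "tminus": rb.reverse_complement(spliced),
    }
    models = GeneModelSet(genes=genes, transcripts=transcripts, sequences=sequences)
    return models, genome


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated transcriptome with isoforms and overlaps, plus counts."""
    models, truth = rb.simulate_transcriptome(
        n_genes=150, seed=42, isoform_rate=0.3, overlap_rate=0.1
    )
    return models, truth


@pytest.fixture(scope="session")
def sim_files(tmp_path_factory, sim_small):
    """The small simulation written out as GTF + FASTA."""
    models, truth = sim_small
    d = tmp_path_factory.mktemp("simfiles")
    gtf, fa = d / "ann.gtf", d / "genome.fa"
    rb.write_gtf(models, gtf)
    rb.write_fasta(truth.genome, fa)
    return gtf, fa


@pytest.fixture(scope="session")
def biased_run():
    """Canonical planted-bias simulation plus a correction run (seed 1)."""
    models, truth = rb.simulate_transcriptome(
        n_genes=2000, seed=1, bias_spec=rb.DEFAULT_PLANTED_BIAS
    )
    lanes = rb.simulate_counts(truth, n_lanes=1, seed=101)
    expr = rb.rpkm(rb.merge_lanes(lanes), truth.covariates.lengths())
    corrected = rb.correct_expression(expr, truth.covariates)
    return truth, expr, corrected


def write_sam(path, genome, records):
    """Minimal SAM writer for hand-built test alignments.

    ``records`` are dicts with qname, flag, chrom, pos (0-based), cigar,
    seq and optional nh.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in sorted(genome.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for r in records:
            tags = f"\tNH:i:{r['nh']}" if "nh" in r else ""
            fh.write(
                f"{r['qname']}\t{r['flag']}\t{r['chrom']}\t{r['pos'] + 1}\t255\t"
                f"{r['cigar']}\t*\t0\t0\t{r['seq']}\t*{tags}\n"
            )
    return path
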