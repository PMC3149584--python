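import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rnabias as rb
from rnabias.models import DINUCLEOTIDES, Gene, GeneModelSet

SEQ = st.text(alphabet="ACGT", min_size=2, max_size=200)


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("GGCC", 1.0), ("ATNNGC", 0.5), ("AAAA", 0.0), ("aTgC", 0.5)],
)
def test_gc_content_examples(seq, expected):
    assert rb.gc_content(seq) == pytest.approx(expected)


def test_gc_content_undefined_for_all_n():
    with pytest.raises(ValueError):
        rb.gc_content("NNN")


def test_dinucleotide_frequencies_examples():
    freqs = dict(zip(DINUCLEOTIDES, rb.dinucleotide_frequencies("ATAT")))
    assert freqs["AT"] == pytest.approx(2 / 3)
    assert freqs["TA"] == pytest.approx(1 / 3)
    assert sum(v for k, v in freqs.items() if k not in ("AT", "TA")) == 0

    freqs = dict(zip(DINUCLEOTIDES, rb.dinucleotide_frequencies("AAAA")))
    assert freqs["AA"] == 1.0

    with pytest.raises(ValueError):
        rb.dinucleotide_frequencies("ANA")  # no N-free window


def test_dinucleotide_frequencies_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    # independent sliding-window counter
    counts = {d: 0 for d in DINUCLEOTIDES}
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    expected = np.array([counts[d] / (len(seq) - 1) for d in DINUCLEOTIDES])
    np.testing.assert_allclose(rb.dinucleotide_frequencies(seq), expected, atol=1e-15)


@given(SEQ)
@settings(derandomize=True, max_examples=50)
def test_dinucleotide_frequencies_sum_to_one(seq):
    assert rb.dinucleotide_frequencies(seq).sum() == pytest.approx(1.0, abs=1e-9)


@given(SEQ)
@settings(derandomize=True, max_examples=50)
def test_gc_is_strand_symmetric(seq):
    assert rb.gc_content(seq) == pytest.approx(
        rb.gc_content(rb.reverse_complement(seq))
    )


class TestLoadGeneModels:
    def _write(self, tmp_path, gtf_text, fasta_text):
        gtf = tmp_path / "a.gtf"
        fa = tmp_path / "g.fa"
        gtf.write_text(gtf_text)
        fa.write_text(fasta_text)
        return gtf, fa

    def test_plus_strand_splicing(self, tmp_path):
        gtf, fa = self._write(
            tmp_path,
            'chr1\tx\texon\t1\t4\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t7\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
            ">chr1\nACGTACGTAC\n",
        )
        models = rb.load_gene_models(gtf, fa)
        assert models.sequences["t"] == "ACGTGTAC"
        assert models.transcripts["t"] == [(0, 4), (6, 10)]

    def test_minus_strand_reverse_complement(self, tmp_path):
        gtf, fa = self._write(
            tmp_path,
            'chr1\tx\texon\t1\t4\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t7\t10\t.\t-\t.\tgene_id "g"; transcript_id "t";\n',
            ">chr1\nACGTACGTAC\n",
        )
        models = rb.load_gene_models(gtf, fa)
        assert models.sequences["t"] == "GTACACGT"

    def test_missing_chromosome_is_hard_error(self, tmp_path):
        gtf, fa = self._write(
            tmp_path,
            'chrX\tx\texon\t1\t4\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
            ">chr1\nACGTACGTAC\n",
        )
        with pytest.raises(ValueError, match="chrX"):
            rb.load_gene_models(gtf, fa)

    def test_roundtrip_of_simulated_transcriptome(self, sim_small, sim_files):
        models, truth = sim_small
        gtf, fa = sim_files
        loaded = rb.load_gene_models(gtf, fa)
        assert set(loaded.sequences) == set(models.sequences)
        for tid, seq in models.sequences.items():
            assert loaded.sequences[tid] == seq


class TestGeneCovariates:
    def test_gene_length_is_median_of_isoforms(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=n)) for n in (1000, 2000)]
        models = GeneModelSet(
            genes={"g": Gene("g", "chr1", "+", ["t1", "t2"])},
            transcripts={"t1": [(0, 1000)], "t2": [(2000, 4000)]},
            sequences={"t1": seqs[0], "t2": seqs[1]},
        )
        table = rb.gene_covariates(models, "gene").table
        assert table.loc["g", "log_length"] == pytest.approx(np.log(1500))

    def test_single_isoform_gene_equals_transcript_row(self, sim_small):
        models, _ = sim_small
        gene_tab = rb.gene_covariates(models, "gene").table
        tx_tab = rb.gene_covariates(models, "transcript").table
        singles = [
            g for g, gn in models.genes.items() if len(gn.transcript_ids) == 1
        ]
        assert singles
        for gid in singles[:20]:
            tid = models.genes[gid].transcript_ids[0]
            np.testing.assert_allclose(gene_tab.loc[gid], tx_tab.loc[tid])

    def test_three_isoform_gene_per_column_median_oracle(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=n)) for n in (300, 500, 900)]
        models = GeneModelSet(
            genes={"g": Gene("g", "chr1", "+", ["a", "b", "c"])},
            transcripts={"a": [(0, 300)], "b": [(1000, 1500)], "c": [(2000, 2900)]},
            sequences=dict(zip("abc", seqs)),
        )
        row = rb.gene_covariates(models, "gene").table.loc["g"]
        assert row["log_length"] == pytest.approx(np.log(500))
        assert row["gc"] == pytest.approx(np.median([rb.gc_content(s) for s in seqs]))
        for i, d in enumerate(DINUCLEOTIDES):
            med = np.median([rb.dinucleotide_frequencies(s)[i] for s in seqs])
            assert row[d] == pytest.approx(med)
        # per-column medians need not form a normalized frequency vector
        assert row[DINUCLEOTIDES].sum() != pytest.approx(1.0, abs=1e-12)

    def test_transcript_dinucleotide_rows_sum_to_one(self, sim_small):
        models, _ = sim_small
        tx = rb.gene_covariates(models, "transcript").table
        np.testing.assert_allclose(tx[DINUCLEOTIDES].sum(axis=1), 1.0, atol=1e-9)


class TestSinoGenes:
    @staticmethod
    def _mk(genes_spec):
        """genes_spec: {gid: list of (tid, exons)} all on chr1 plus strand."""
        genes, transcripts, sequences = {}, {}, {}
        for gid, tx in genes_spec.items():
            genes[gid] = Gene(gid, "chr1", "+", [t for t, _ in tx])
            for tid, exons in tx:
                transcripts[tid] = exons
                sequences[tid] = "A" * sum(e - s for s, e in exons)
        return GeneModelSet(genes=genes, transcripts=transcripts, sequences=sequences)

    def test_toy_example(self):
        models = self._mk(
            {
                "A": [("A.1", [(1, 100)])],
                "B": [("B.1", [(500, 900)]), ("B.2", [(500, 700)])],
                "C": [("C.1", [(850, 1000)])],
            }
        )
        assert rb.find_sino_genes(models) == {"A"}

    def test_all_disjoint_single_isoform(self):
        models = self._mk(
            {f"g{i}": [(f"g{i}.t", [(i * 100, i * 100 + 50)])] for i in range(10)}
        )
        assert rb.find_sino_genes(models) == {f"g{i}" for i in range(10)}

    def test_matches_all_pairs_oracle_on_simulation(self, sim_small):
        models, _ = sim_small
        spans = {g: models.gene_span(g) for g in models.genes}
        oracle = set()
        for g, (c, s, e) in spans.items():
            if len(models.genes[g].transcript_ids) != 1:
                continue
            clash = any(
                g != h and c == hc and s < he and hs < e
                for h, (hc, hs, he) in spans.items()
            )
            if not clash:
                oracle.add(g)
        assert rb.find_sino_genes(models) == oracle
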