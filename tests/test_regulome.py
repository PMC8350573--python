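"""Promoter extraction, PWM scanning, and binding-evidence filtering."""

import numpy as np
import networkx as nx
import pytest

from prionome.regulome import (
    PWM,
    evidence_pairs,
    extract_promoters,
    filter_by_binding,
    promoters_to_fasta,
    read_promoters_fasta,
    read_pwm_counts,
    scan_binding_sites,
    write_pwm_counts,
)
from prionome.synthetic_data import (
    gen_genome_with_promoters,
    write_genome_fasta,
    write_gff3,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq):
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def write_inputs(tmp_path, contig, genes):
    """genes: (gene_id, start1, end1, strand) rows on chromosome chr1."""
    fasta = tmp_path / "genome.fa"
    fasta.write_text(">chr1\n" + contig + "\n")
    gff = tmp_path / "genes.gff3"
    lines = ["##gff-version 3"]
    for gid, start, end, strand in genes:
        lines.append("\t".join(
            ["chr1", "test", "gene", str(start), str(end), ".", strand, ".",
             f"ID={gid}"]))
        lines.append("\t".join(
            ["chr1", "test", "mRNA", str(start), str(end), ".", strand, ".",
             f"ID={gid}.1;Parent={gid}"]))
    gff.write_text("\n".join(lines) + "\n")
    return gff, fasta


@pytest.fixture(scope="module")
def contig():
    rng = np.random.default_rng(77)
    return "".join(rng.choice(list("ACGT"), size=8000))


class TestExtractPromoters:
    def test_plus_strand_geometry(self, tmp_path, contig):
        # TSS at 1-based 5,001: promoter covers 1-based 3,501..5,200
        gff, fasta = write_inputs(tmp_path, contig, [("gA", 5001, 6000, "+")])
        promoter = extract_promoters(gff, fasta)[0]
        assert (promoter.start, promoter.end) == (3500, 5200)
        assert len(promoter.sequence) == 1700
        assert promoter.sequence == contig[3500:5200]
        assert not promoter.truncated

    def test_minus_strand_is_reverse_complement(self, tmp_path, contig):
        gff, fasta = write_inputs(tmp_path, contig, [("gB", 2001, 2600, "-")])
        promoter = extract_promoters(gff, fasta)[0]
        # TSS = gene end (2,600); window is 200 down + 1,500 up of it
        assert (promoter.start, promoter.end) == (2400, 4100)
        assert promoter.sequence == naive_revcomp(contig[2400:4100])
        assert len(promoter.sequence) == 1700

    def test_truncation_at_contig_start(self, tmp_path, contig):
        # TSS 100 bp into the contig: only 100 up + 200 down remain
        gff, fasta = write_inputs(tmp_path, contig, [("gC", 101, 900, "+")])
        promoter = extract_promoters(gff, fasta)[0]
        assert promoter.truncated
        assert len(promoter.sequence) == 300

    def test_longest_mrna_defines_tss(self, tmp_path, contig):
        gff = tmp_path / "iso.gff3"
        gff.write_text("\n".join([
            "##gff-version 3",
            "chr1\tt\tgene\t4000\t6000\t.\t+\t.\tID=gD",
            "chr1\tt\tmRNA\t4500\t6000\t.\t+\t.\tID=gD.1;Parent=gD",
            "chr1\tt\tmRNA\t4000\t6000\t.\t+\t.\tID=gD.2;Parent=gD",
        ]) + "\n")
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\n" + contig + "\n")
        promoter = extract_promoters(gff, fasta)[0]
        # the longer mRNA starts at 4,000 -> TSS0 = 3,999
        assert (promoter.start, promoter.end) == (2499, 4199)

    def test_missing_chromosome_is_error(self, tmp_path, contig):
        gff, _ = write_inputs(tmp_path, contig, [("gE", 5001, 6000, "+")])
        fasta = tmp_path / "other.fa"
        fasta.write_text(">chr9\n" + contig + "\n")
        with pytest.raises(ValueError, match="chr1"):
            extract_promoters(gff, fasta)

    def test_interior_promoters_exactly_1700(self, tmp_path):
        genome, genes, _ = gen_genome_with_promoters(
            10, motif="TGACGTCATG", planted_target_ids=[], seed=3)
        fasta = tmp_path / "g.fa"
        gff = tmp_path / "g.gff3"
        write_genome_fasta(genome, fasta)
        write_gff3(genes, gff)
        promoters = extract_promoters(gff, fasta)
        assert len(promoters) == 10
        assert all(len(p.sequence) == 1700 for p in promoters)
        assert not any(p.truncated for p in promoters)

    def test_fasta_round_trip(self, tmp_path, contig):
        gff, fasta = write_inputs(
            tmp_path, contig,
            [("gA", 5001, 6000, "+"), ("gB", 2001, 2600, "-")])
        promoters = extract_promoters(gff, fasta)
        out = tmp_path / "promoters.fa"
        promoters_to_fasta(promoters, out)
        assert read_promoters_fasta(out) == promoters


MOTIF = "TGACGTCATG"


@pytest.fixture(scope="module")
def pwm():
    counts = np.ones((4, len(MOTIF)))
    for j, base in enumerate(MOTIF):
        counts["ACGT".index(base), j] = 12
    return PWM.from_counts(counts, name="tfbs")


class TestPWMScan:
    MOTIF = MOTIF

    def _promoter(self, sequence, gene_id="gX"):
        from prionome.regulome import PromoterRegion
        return PromoterRegion(gene_id, "chr1", "+", 0, len(sequence),
                              sequence, False)

    def test_planted_consensus_found_at_offset(self, pwm):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1700))
        seq = seq[:400] + self.MOTIF + seq[400 + len(self.MOTIF):]
        hits = scan_binding_sites(self._promoter(seq), pwm,
                                  pwm.max_score - 1e-9)
        assert [(h.offset, h.strand) for h in hits] == [(400, "+")]

    def test_reverse_complement_hit_reported_minus(self, pwm):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=1700))
        rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                     for b in reversed(self.MOTIF))
        seq = seq[:700] + rc + seq[700 + len(rc):]
        hits = scan_binding_sites(self._promoter(seq), pwm,
                                  pwm.max_score - 1e-9)
        assert [(h.offset, h.strand) for h in hits] == [(700, "-")]

    def test_windows_with_n_are_skipped(self, pwm):
        seq = self.MOTIF.replace("C", "N", 1) + "A" * 50
        hits = scan_binding_sites(self._promoter(seq), pwm, -1e9)
        assert all(h.offset >= 1 for h in hits)

    def test_hit_count_matches_naive_enumeration(self, pwm):
        rng = np.random.default_rng(7)
        # dinucleotide-ish shuffle: permute a motif-rich sequence
        base = (self.MOTIF * 30 +
                "".join(rng.choice(list("ACGT"), size=500)))
        seq = "".join(rng.permutation(list(base)))
        threshold = 0.6 * pwm.max_score
        hits = scan_binding_sites(self._promoter(seq), pwm, threshold)
        expected = 0
        for off in range(len(seq) - len(self.MOTIF) + 1):
            window = seq[off:off + len(self.MOTIF)]
            for oriented in (window, naive_revcomp(window)):
                score = sum(
                    pwm.log_odds["ACGT".index(b), j]
                    for j, b in enumerate(oriented)
                )
                expected += score >= threshold
        assert len(hits) == expected

    def test_counts_file_round_trip(self, pwm, tmp_path):
        counts = np.ones((4, len(self.MOTIF)))
        for j, base in enumerate(self.MOTIF):
            counts["ACGT".index(base), j] = 12
        path = tmp_path / "pwm.txt"
        write_pwm_counts(counts, path, name="tfbs")
        loaded = read_pwm_counts(path)
        assert loaded.name == "tfbs"
        assert loaded.consensus == self.MOTIF
        assert np.allclose(loaded.log_odds, pwm.log_odds)


class TestBindingFilter:
    def _network(self):
        g = nx.Graph()
        g.add_node("tf1", roles=frozenset({"TF"}))
        g.add_node("prlp1", roles=frozenset({"PrLP"}))
        g.add_node("prlp2", roles=frozenset({"PrLP"}))
        g.add_edge("tf1", "prlp1", sign=1, layer=2, evidence_filtered=False)
        g.add_edge("tf1", "prlp2", sign=-1, layer=2, evidence_filtered=False)
        g.add_edge("prlp1", "prlp2", sign=1, layer=1, evidence_filtered=False)
        return g

    def test_supported_tf_edge_kept_and_flagged(self):
        filtered = filter_by_binding(self._network(), {("tf1", "prlp1")})
        assert filtered.has_edge("tf1", "prlp1")
        assert filtered.edges["tf1", "prlp1"]["evidence_filtered"]

    def test_unsupported_tf_edge_dropped(self):
        filtered = filter_by_binding(self._network(), {("tf1", "prlp1")})
        assert not filtered.has_edge("tf1", "prlp2")

    def test_non_tf_edge_passes_unflagged(self):
        filtered = filter_by_binding(self._network(), set())
        assert filtered.has_edge("prlp1", "prlp2")
        assert not filtered.edges["prlp1", "prlp2"]["evidence_filtered"]

    def test_output_subset_and_idempotent(self):
        network = self._network()
        pairs = {("tf1", "prlp1")}
        once = filter_by_binding(network, pairs)
        twice = filter_by_binding(once, pairs)
        assert set(once.edges) <= set(network.edges)
        assert set(twice.edges) == set(once.edges)

    def test_input_graph_unchanged(self):
        network = self._network()
        filter_by_binding(network, set())
        assert network.number_of_edges() == 3

    def test_evidence_pairs_helper(self):
        from prionome.regulome import BindingEvidence
        pairs = evidence_pairs([
            BindingEvidence("tf1", "g1"),
            BindingEvidence("tf1", "g1", source="scan", offset=3, score=1.0),
        ])
        assert pairs == {("tf1", "g1")}
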