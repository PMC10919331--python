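import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import gotoh_global_score
from pleoprophage import build_synteny_map, call_orfs, pairwise_identity, revcomp
from pleoprophage.orfs import _make_aligner, plot_synteny


def random_protein(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestCallOrfs:
    def test_minimal_orf_translation(self):
        orfs = call_orfs("NNNATGAAATAANNN", "linear", min_aa=1)
        assert len(orfs) == 1
        assert orfs[0].translation == "MK"
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (3, 12, "+")

    def test_strand_symmetry(self):
        g = "NNNATGAAACCCGGGTAANNN"
        fwd = call_orfs(g, "linear", min_aa=1)
        rev = call_orfs(revcomp(g), "linear", min_aa=1)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].translation == rev[0].translation
        n = len(g)
        assert (rev[0].start, rev[0].end) == (n - fwd[0].end, n - fwd[0].start)
        assert rev[0].strand == "-"

    def test_alternative_starts_translate_as_met(self):
        for start in ("ATG", "GTG", "TTG"):
            orfs = call_orfs("NN" + start + "GCTAAATAG" + "NN", "linear", min_aa=1)
            assert orfs and orfs[0].translation.startswith("M")

    def test_nested_same_frame_orfs_collapse_to_longest(self):
        # two in-frame ATGs before one stop: a single ORF from the upstream start
        g = "ATGGCCATGAAATAA"
        orfs = call_orfs(g, "linear", min_aa=1)
        plus = [o for o in orfs if o.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start == 0 and plus[0].translation == "MAMK"

    def test_min_aa_threshold(self):
        g = "ATG" + "GCA" * 29 + "TAA"  # 30-aa product (M + 29 x A)
        assert call_orfs(g, "linear", min_aa=31) == []
        assert any(o.translation == "M" + "A" * 29 for o in call_orfs(g, "linear", min_aa=30))

    def test_circular_origin_spanning_orf(self):
        # ATG CCC | origin | AAA TAA read across the junction
        g = "AAATAAGG" + "ATGCCC"
        orfs = call_orfs(g, "circular", min_aa=1)
        assert any(o.translation == "MPK" and o.start == 8 and o.end == 20 for o in orfs)
        assert all(o.translation != "MPK" for o in call_orfs(g, "linear", min_aa=1))

    def test_orfs_numbered_in_genome_order(self):
        g = "ATGAAATAA" + "CCC" + "ATGGGGTGA"
        orfs = call_orfs(g, "linear", min_aa=1)
        starts = [o.start for o in orfs]
        assert starts == sorted(starts)
        assert [o.index for o in orfs] == list(range(1, len(orfs) + 1))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        ident, cov = pairwise_identity("MKVLAWWK", "MKVLAWWK")
        assert ident == 100.0 and cov == 1.0

    def test_single_substitution(self):
        ident, _ = pairwise_identity("AAAA", "AATA")
        assert ident == pytest.approx(75.0)

    def test_symmetry(self):
        a, b = random_protein(1, 60), random_protein(2, 55)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MK")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_alignment_score_matches_independent_gotoh_dp(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
        b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
        aligner = _make_aligner()
        assert aligner.score(a, b) == pytest.approx(gotoh_global_score(a, b))

    def test_reported_identity_is_consistent_with_returned_alignment(self):
        # recompute matches/columns from the aligner's own alignment strings
        a, b = random_protein(7, 50), random_protein(8, 50)
        ident, cov = pairwise_identity(a, b)
        aligner = _make_aligner()
        x, y = (b, a) if (b, a) < (a, b) else (a, b)
        aln = aligner.align(x, y)[0]
        sx, sy = str(aln[0]), str(aln[1])
        lo, hi = 0, len(sx)
        while lo < hi and (sx[lo] == "-" or sy[lo] == "-"):
            lo += 1
        while hi > lo and (sx[hi - 1] == "-" or sy[hi - 1] == "-"):
            hi -= 1
        matches = sum(p == q and p != "-" for p, q in zip(sx[lo:hi], sy[lo:hi]))
        assert ident == pytest.approx(100.0 * matches / (hi - lo))


def _toy_genomes():
    rng = np.random.default_rng(42)
    orf_seqs = []
    for _ in range(4):
        n_codons = int(rng.integers(40, 70))
        codons = []
        for _ in range(n_codons):
            c = "".join(rng.choice(list("ACGT"), 3))
            while c in ("TAA", "TAG", "TGA", "ATG", "GTG", "TTG"):
                c = "".join(rng.choice(list("ACGT"), 3))
            codons.append(c)
        orf_seqs.append("ATG" + "".join(codons) + "TAA")
    spacer = "TAATAGTGA"  # in-frame stops keep planted ORFs stop-anchored
    genome_a = spacer + spacer.join(orf_seqs) + spacer
    # forward-strand start coordinate of each planted ORF
    starts, pos = [], len(spacer)
    for s in orf_seqs:
        starts.append(pos)
        pos += len(s) + len(spacer)
    return genome_a, orf_seqs, spacer, starts


class TestSyntenyMap:
    def test_identical_genomes_link_every_orf_at_100(self):
        genome_a, _, _, _ = _toy_genomes()
        orfs_a = call_orfs(genome_a, "linear", min_aa=30, genome_id="A")
        orfs_b = call_orfs(genome_a, "linear", min_aa=30, genome_id="B")
        links = build_synteny_map(["A", "B"], [orfs_a, orfs_b])
        assert len(links) == len(orfs_a)
        assert all(ln.identity == 100.0 for ln in links)
        assert all(ln.orf_a.index == ln.orf_b.index for ln in links)

    def test_replaced_orf_drops_its_link(self):
        genome_a, orf_seqs, spacer, starts = _toy_genomes()
        rng = np.random.default_rng(99)
        # replace the second planted ORF with unrelated random codons of the same length
        replaced = list(orf_seqs)
        body_len = len(orf_seqs[1]) - 6
        codons = []
        for _ in range(body_len // 3):
            c = "".join(rng.choice(list("ACGT"), 3))
            while c in ("TAA", "TAG", "TGA"):
                c = "".join(rng.choice(list("ACGT"), 3))
            codons.append(c)
        replaced[1] = "ATG" + "".join(codons) + "TAA"
        genome_b = spacer + spacer.join(replaced) + spacer
        orfs_a = call_orfs(genome_a, "linear", min_aa=30, genome_id="A")
        orfs_b = call_orfs(genome_b, "linear", min_aa=30, genome_id="B")
        links = build_synteny_map(["A", "B"], [orfs_a, orfs_b], min_identity=50)
        planted_idx = {o.start: o.index for o in orfs_a if o.strand == "+" and o.start in set(starts)}
        full_identity_a = {ln.orf_a.index for ln in links if ln.identity == 100.0}
        # planted ORFs 1, 3, 4 still link perfectly; the replaced one does not
        for pos in (starts[0], starts[2], starts[3]):
            assert planted_idx[pos] in full_identity_a
        linked_a = {ln.orf_a.index for ln in links}
        assert planted_idx[starts[1]] not in linked_a

    def test_reciprocal_best_yields_at_most_one_link_per_orf(self):
        genome_a, _, _, _ = _toy_genomes()
        orfs_a = call_orfs(genome_a, "linear", min_aa=30, genome_id="A")
        orfs_b = call_orfs(genome_a, "linear", min_aa=30, genome_id="B")
        links = build_synteny_map(["A", "B"], [orfs_a, orfs_b], min_identity=0, min_coverage=0)
        assert len({ln.orf_a.index for ln in links}) == len(links)
        assert len({ln.orf_b.index for ln in links}) == len(links)

    def test_empty_orf_lists_give_empty_map_and_valid_plot(self, tmp_path):
        links = build_synteny_map(["A", "B"], [[], []])
        assert links == []
        out = tmp_path / "syn.svg"
        plot_synteny(["A", "B"], [1000, 1000], [[], []], links, str(out))
        assert out.read_text().lstrip().startswith("<?xml")

    def test_fewer_than_two_genomes_rejected(self):
        with pytest.raises(ValueError):
            build_synteny_map(["A"], [[]])
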