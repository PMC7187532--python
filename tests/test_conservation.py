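import itertools

import numpy as np
import pytest

from circkit.classify import classify_records
from circkit.consensus import merge_calls
from circkit.conservation import (
    AlignmentScoring,
    align_flanks,
    build_ortholog_groups,
    extract_bsj_flanks,
    liftover_interval,
    ns_by_locus,
    reciprocal_best_hits,
    restrict_to_ortholog_genes,
    RbhPair,
)
from circkit.core import CircRecord, CoordinateMap, GeneModel, GenomeRef, MapBlock, reverse_complement

from oracles import best_group_score_oracle, local_align_oracle


def circ(start, end, strand="+", sp="hsa", host=None):
    r = CircRecord(species_code=sp, chrom="chr1", start=start, end=end, strand=strand)
    r.host_gene = host
    return r


class TestRestriction:
    def test_cross_product(self):
        a = [circ(0, 10, host="gA"), circ(20, 30, host="gA")]
        b = [circ(0, 10, sp="mmu", host="gB"),
             circ(20, 30, sp="mmu", host="gB"),
             circ(40, 50, sp="mmu", host="gB")]
        pairs = restrict_to_ortholog_genes(a, b, [("gA", "gB")])
        assert len(pairs) == 6

    def test_circ_free_partner_drops_pair(self):
        a = [circ(0, 10, host="gA")]
        assert restrict_to_ortholog_genes(a, [], [("gA", "gB")]) == []

    def test_empty_pair_list(self):
        assert restrict_to_ortholog_genes([circ(0, 10, host="gA")],
                                          [circ(0, 10, sp="mmu", host="gB")], []) == []


class TestLiftover:
    def test_identity(self):
        cmap = CoordinateMap([MapBlock("chr1", 0, 1000, "chr1", 0, 1000, "+")])
        assert liftover_interval("chr1", 10, 60, cmap) == ("chr1", 10, 60, "+")

    def test_offset_block(self):
        cmap = CoordinateMap([MapBlock("chr1", 0, 1000, "chr2", 100, 1100, "+")])
        assert liftover_interval("chr1", 10, 60, cmap) == ("chr2", 110, 160, "+")

    def test_outside_blocks_is_none(self):
        cmap = CoordinateMap([MapBlock("chr1", 0, 100, "chr1", 0, 100, "+")])
        assert liftover_interval("chr1", 500, 600, cmap) is None
        assert liftover_interval("chr1", 50, 150, cmap) is None  # end unmapped

    def test_minus_strand_block(self):
        cmap = CoordinateMap([MapBlock("chr1", 0, 100, "chr9", 200, 300, "-")])
        # position p maps to 299 - p; interval [10, 20) -> [280, 290)
        assert liftover_interval("chr1", 10, 20, cmap) == ("chr9", 280, 290, "-")

    def test_malformed_block_rejected(self):
        with pytest.raises(ValueError):
            MapBlock("chr1", 0, 100, "chr1", 0, 90, "+")


class TestFlankExtraction:
    @pytest.fixture()
    def genome(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
        return GenomeRef("hsa", {"chr1": seq})

    @pytest.fixture()
    def gene(self):
        return GeneModel(
            "g1", "G1", "chr1", "+",
            transcripts={"t1": [(100, 300), (500, 700), (900, 1100)]},
        )

    def test_plus_strand_slices(self, genome, gene):
        c = circ(100, 700, host="g1")
        flank = extract_bsj_flanks(c, genome, gene=gene)
        assert len(flank.sequence) == 100
        assert flank.sequence[:50] == genome.fetch("chr1", 650, 700)  # donor side
        assert flank.sequence[50:] == genome.fetch("chr1", 100, 150)  # acceptor side
        assert (flank.len_upstream, flank.len_downstream) == (50, 50)

    def test_short_terminal_exon(self, genome):
        gene = GeneModel(
            "g2", "G2", "chr1", "+",
            transcripts={"t1": [(100, 130), (500, 700)]},  # 30 nt first exon
        )
        c = circ(100, 700, host="g2")
        flank = extract_bsj_flanks(c, genome, gene=gene)
        assert len(flank.sequence) == 80
        assert (flank.len_upstream, flank.len_downstream) == (50, 30)

    def test_minus_strand_mirrors_plus(self, genome):
        gene_plus = GeneModel("gp", "GP", "chr1", "+",
                              transcripts={"t": [(100, 300), (500, 700)]})
        gene_minus = GeneModel("gm", "GM", "chr1", "-",
                               transcripts={"t": [(100, 300), (500, 700)]})
        plus = extract_bsj_flanks(circ(100, 700), genome, gene=gene_plus)
        minus = extract_bsj_flanks(circ(100, 700, strand="-"), genome, gene=gene_minus)
        # minus flank = revcomp(acceptor-side of plus) + revcomp(donor-side of plus)
        assert minus.sequence == (
            reverse_complement(plus.sequence[50:]) + reverse_complement(plus.sequence[:50])
        )

    def test_unknown_cirexons_error(self, genome):
        with pytest.raises(Exception, match="classif"):
            extract_bsj_flanks(circ(100, 700), genome, gene=None)


class TestAligner:
    def test_self_alignment(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100)])
        hit = align_flanks(seq, seq)
        assert hit.score == pytest.approx(100.0)
        assert hit.identity == pytest.approx(1.0)
        assert hit.aligned_length == 100

    def test_dissimilar_sequences_low_score(self):
        hit = align_flanks("ACGT", "TTTT")
        assert hit.score <= 1.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            align_flanks("", "ACGT")

    def test_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(bases[rng.integers(0, 4, size=int(rng.integers(4, 30)))])
            b = "".join(bases[rng.integers(0, 4, size=int(rng.integers(4, 30)))])
            assert align_flanks(a, b).score == pytest.approx(align_flanks(b, a).score)

    def test_matches_exhaustive_recursion_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(40):
            a = "".join(bases[rng.integers(0, 4, size=int(rng.integers(1, 10)))])
            b = "".join(bases[rng.integers(0, 4, size=int(rng.integers(1, 10)))])
            hit = align_flanks(a, b)
            assert hit.score == pytest.approx(local_align_oracle(a, b))


def _flank_dict(circs, genomes, genes_by_sp):
    out = {}
    for c in circs:
        gene = genes_by_sp[c.species_code][c.host_gene]
        out[c.locus_key] = extract_bsj_flanks(c, genomes[c.species_code], gene=gene)
    return out


class TestRbh:
    def test_single_identical_pair(self, bundle):
        sp_a, sp_b = bundle.cfg.species[:2]
        # one circle each side with identical flanks -> one RBH pair
        recs = {}
        for sp in (sp_a, sp_b):
            rs = merge_calls(bundle.calls[sp], bundle.samples[sp])
            classify_records(rs, bundle.genes[sp], bundle.repeats[sp])
            recs[sp] = rs
        ga = [r for r in recs[sp_a] if r.host_gene == f"{sp_a}_g1"]
        gb = [r for r in recs[sp_b] if r.host_gene == f"{sp_b}_g1"]
        cands = restrict_to_ortholog_genes(ga, gb, [(f"{sp_a}_g1", f"{sp_b}_g1")])
        genes_by_sp = {sp: {g.gene_id: g for g in bundle.genes[sp]} for sp in (sp_a, sp_b)}
        fa = _flank_dict(ga, bundle.genomes, genes_by_sp)
        fb = _flank_dict(gb, bundle.genomes, genes_by_sp)
        pairs = reciprocal_best_hits(cands, fa, fb)
        assert len(pairs) == 1

    def test_non_reciprocal_best_hit_dropped(self):
        a1 = circ(0, 10, host="gA")
        b1 = circ(0, 10, sp="mmu", host="gB")
        b2 = circ(20, 30, sp="mmu", host="gB")
        flanks_a = {a1.locus_key: _FakeFlank("ACGTACGTACGT")}
        flanks_b = {
            b1.locus_key: _FakeFlank("ACGTACGTAAAA"),  # A's best
            b2.locus_key: _FakeFlank("ACGTACGTACGT"),  # identical to A
        }
        # B1's best is A (only candidate), A's best is B2 -> no pair with B1
        pairs = reciprocal_best_hits(
            [(a1, b1), (a1, b2)], flanks_a, flanks_b,
            min_identity=0.0, min_aln_len=0,
        )
        assert [(p.circ_a, p.circ_b) for p in pairs] == [(a1.locus_key, b2.locus_key)]

    def test_tied_best_hits_disqualify(self):
        a1 = circ(0, 10, host="gA")
        b1 = circ(0, 10, sp="mmu", host="gB")
        b2 = circ(20, 30, sp="mmu", host="gB")
        same = "ACGTACGTACGT"
        flanks_a = {a1.locus_key: _FakeFlank(same)}
        flanks_b = {b1.locus_key: _FakeFlank(same), b2.locus_key: _FakeFlank(same)}
        pairs = reciprocal_best_hits(
            [(a1, b1), (a1, b2)], flanks_a, flanks_b,
            min_identity=0.0, min_aln_len=0,
        )
        assert pairs == []

    def test_rbh_symmetric_under_reversal(self, bundle):
        sp_a, sp_b = bundle.cfg.species[:2]
        recs = {}
        for sp in (sp_a, sp_b):
            rs = merge_calls(bundle.calls[sp], bundle.samples[sp])
            classify_records(rs, bundle.genes[sp], bundle.repeats[sp])
            recs[sp] = [r for r in rs if r.host_gene]
        cands = restrict_to_ortholog_genes(recs[sp_a], recs[sp_b], bundle.gene_pairs[(sp_a, sp_b)])
        genes_by_sp = {sp: {g.gene_id: g for g in bundle.genes[sp]} for sp in (sp_a, sp_b)}
        fa = _flank_dict([c for c, _ in cands], bundle.genomes, genes_by_sp)
        fb = _flank_dict([c for _, c in cands], bundle.genomes, genes_by_sp)
        fwd = reciprocal_best_hits(cands, fa, fb)
        rev = reciprocal_best_hits([(b, a) for a, b in cands], fb, fa)
        assert {(p.circ_a, p.circ_b) for p in fwd} == {(p.circ_b, p.circ_a) for p in rev}


class _FakeFlank:
    def __init__(self, seq):
        self.sequence = seq


def _rbh(a, b, sa, sb, score):
    return RbhPair(a, b, sa, sb, score, 1.0)


class TestGroupBuilder:
    def test_perfect_triangle(self):
        pairs = [
            [_rbh("A1", "B1", "hsa", "mmu", 90.0)],
            [_rbh("A1", "C1", "hsa", "rno", 88.0)],
            [_rbh("B1", "C1", "mmu", "rno", 87.0)],
        ]
        groups = build_ortholog_groups(pairs)
        multi = [g for g in groups if g.n_s > 0]
        assert len(multi) == 1
        assert multi[0].n_s == 2 and len(multi[0].members) == 3

    def test_same_species_conflict_expels_lower(self):
        pairs = [
            [_rbh("A1", "B1", "hsa", "mmu", 90.0)],
            [_rbh("A2", "B1", "hsa", "mmu", 50.0)],
        ]
        groups = build_ortholog_groups(pairs)
        ns = ns_by_locus(groups)
        assert ns["A1"] == 1 and ns["B1"] == 1
        assert ns["A2"] == 0  # expelled to its own group

    def test_no_edges_all_singletons(self):
        circs = [circ(0, 10), circ(20, 30, sp="mmu")]
        groups = build_ortholog_groups([], all_circs=circs)
        assert all(g.n_s == 0 for g in groups) and len(groups) == 2

    def test_no_group_holds_two_members_of_one_species(self, rng):
        for trial in range(30):
            nodes, species, edges, rbh = _random_component(rng, max_nodes=6)
            groups = build_ortholog_groups([rbh])
            for g in groups:
                sp = [s for s in g.members]
                assert len(sp) == len(set(sp))
            covered = sorted(lk for g in groups for lk in g.members.values())
            with_edges = sorted({n for p in rbh for n in (p.circ_a, p.circ_b)})
            assert covered == with_edges  # partition of every edge-bearing circle

    def test_exact_solver_matches_exhaustive_oracle(self, rng):
        for trial in range(30):
            nodes, species, edges, rbh = _random_component(rng, max_nodes=6)
            groups = build_ortholog_groups([rbh])
            best = max((g.score for g in groups), default=0.0)
            assert best == pytest.approx(best_group_score_oracle(nodes, species, edges))


def _random_component(rng, max_nodes=6):
    n = int(rng.integers(2, max_nodes + 1))
    species_pool = ["hsa", "mmu", "rno", "ssc"]
    nodes = [f"N{i}" for i in range(n)]
    species = {nd: species_pool[int(rng.integers(0, 4))] for nd in nodes}
    edges = {}
    rbh = []
    for u, v in itertools.combinations(nodes, 2):
        if species[u] == species[v] or rng.random() < 0.4:
            continue
        w = float(np.round(rng.uniform(1, 100), 1))
        edges[(u, v)] = w
        rbh.append(_rbh(u, v, species[u], species[v], w))
    return nodes, species, edges, rbh
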