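import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from circkit.core import CircRecord, Sample, reverse_complement
from circkit.io import BedInterval
from circkit.network import (
    build_network,
    coexpression_edges,
    import_external_targets,
    mirna_seed_sites,
    propagate_function,
    rank_interactors,
    rbp_edges,
    tissue_mean_expression,
)

from oracles import hypergeom_tail_mc

LET7 = "TGAGGTAGTAGGTTGTATAGTT"  # positions 2-8 = GAGGUAG


def circ(start, end, strand="+", chrom="chr1"):
    return CircRecord(species_code="hsa", chrom=chrom, start=start, end=end, strand=strand)


def tissue_frame(rows, tissues):
    return pd.DataFrame(rows, columns=tissues)


class TestCoexpression:
    TISSUES = ["t1", "t2", "t3", "t4", "t5"]

    def test_identical_profiles_make_edge(self):
        df = tissue_frame(
            {"circA": [1, 2, 3, 4, 5], "gene1": [2, 4, 6, 8, 10]}, self.TISSUES
        ).T.T  # rows are index entries
        df = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]],
            index=["circA", "gene1"], columns=self.TISSUES, dtype=float,
        )
        edges = coexpression_edges(df, {"circA"})
        assert len(edges) == 1 and edges[0].r == pytest.approx(1.0)

    def test_anticorrelated_dropped_unless_flagged(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
            index=["circA", "gene1"], columns=self.TISSUES, dtype=float,
        )
        assert coexpression_edges(df, {"circA"}) == []
        kept = coexpression_edges(df, {"circA"}, keep_anticorrelated=True)
        assert len(kept) == 1 and kept[0].r == pytest.approx(-1.0)

    def test_sparse_node_excluded_before_correlation(self):
        df = pd.DataFrame(
            [[1, 2, 0, 0, 0], [1, 2, 3, 4, 5]],
            index=["circA", "gene1"], columns=self.TISSUES, dtype=float,
        )
        assert coexpression_edges(df, {"circA"}) == []  # circA in only 2 tissues

    def test_mrna_only_pairs_skipped(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]],
            index=["gene1", "gene2"], columns=self.TISSUES, dtype=float,
        )
        assert coexpression_edges(df, set()) == []

    def test_constant_profile_warns_and_skips(self):
        df = pd.DataFrame(
            [[3, 3, 3, 3, 3], [1, 2, 3, 4, 5]],
            index=["circA", "gene1"], columns=self.TISSUES, dtype=float,
        )
        with pytest.warns(UserWarning, match="constant"):
            assert coexpression_edges(df, {"circA"}) == []

    def test_needs_min_tissue_columns(self):
        df = pd.DataFrame([[1, 2]], index=["circA"], columns=["t1", "t2"], dtype=float)
        with pytest.raises(ValueError):
            coexpression_edges(df, {"circA"})

    def test_tissue_mean_collapse(self):
        samples = [
            Sample("s1", "hsa", "brain", "i1", 10**6),
            Sample("s2", "hsa", "brain", "i2", 10**6),
            Sample("s3", "hsa", "liver", "i1", 10**6),
        ]
        expr = pd.DataFrame(
            [[2.0, 4.0, 6.0]], index=["circA"], columns=["s1", "s2", "s3"]
        )
        means = tissue_mean_expression(expr, samples)
        assert means.loc["circA", "brain"] == pytest.approx(3.0)
        assert means.loc["circA", "liver"] == pytest.approx(6.0)


class TestSeedSites:
    def test_let7_8mer(self):
        seq = "GGGG" + "CTACCTCA" + "GGGG"
        sites = mirna_seed_sites(seq, {"let-7": LET7})
        assert len(sites) == 1
        site = sites[0]
        assert site.site_type == "8mer"
        assert site.site_seq == "CTACCTCA"
        assert site.position == 4

    def test_site_types_classified_by_specificity(self):
        core = reverse_complement(LET7[1:7])          # 6mer match
        m8 = reverse_complement(LET7[1:8])            # 7mer-m8 match
        assert mirna_seed_sites("GG" + core + "G" + "GGGG", {"m": LET7})[0].site_type == "6mer"
        assert mirna_seed_sites("GG" + core + "A" + "GGGG", {"m": LET7})[0].site_type == "7mer-A1"
        sites = mirna_seed_sites("GG" + m8 + "GTTTT", {"m": LET7})
        assert sites[0].site_type == "7mer-m8"

    def test_empty_mirna_list(self):
        assert mirna_seed_sites("ACGTACGTACGT", {}) == []

    def test_short_mirna_errors(self):
        with pytest.raises(ValueError):
            mirna_seed_sites("ACGTACGTACGT", {"m": "ACGTACG"})

    def test_site_across_bsj_found_by_rotation(self):
        site = "CTACCTCA"
        # split the site across the junction: last 3 nt at the start,
        # first 5 nt at the end of the linear representation
        seq = site[5:] + "GGGGGGGGGG" + site[:5]
        sites = mirna_seed_sites(seq, {"let-7": LET7})
        assert any(s.site_type == "8mer" for s in sites)
        # brute force: some rotation shows the site contiguously
        assert any(
            site in (seq[i:] + seq[:i]) for i in range(len(seq))
        )

    def test_sites_reproduce_seed_on_reverse_complement(self, bundle):
        sp = bundle.cfg.species[0]
        for t in bundle.truth_for_species(sp):
            seq = bundle.circ_sequence(sp, t)
            for s in mirna_seed_sites(seq, bundle.mirnas):
                mir = bundle.mirnas[s.mirna_id].replace("U", "T")
                core = s.site_seq[:-1] if s.site_type.endswith("A1") or s.site_type == "8mer" else s.site_seq
                rc = reverse_complement(core)
                assert rc in mir[1:8] or mir[1:8] in rc

    def test_planted_site_recovered(self, bundle):
        sp = bundle.cfg.species[0]
        for lk, mirna, pos in bundle.planted_seed_sites:
            truth = next(t for t in bundle.truth_for_species(sp) if t.key(sp) == lk)
            seq = bundle.circ_sequence(sp, truth)
            sites = mirna_seed_sites(seq, bundle.mirnas)
            assert any(
                s.mirna_id == mirna and s.position == pos and s.site_type == "8mer"
                for s in sites
            )

    def test_external_import_modes(self):
        ext = pd.DataFrame({"circ_id": ["c1", "c2"], "mirna_id": ["m1", "m2"]})
        internal = [("c1", "m1"), ("c3", "m1")]
        assert import_external_targets(ext, internal, "union") == {
            ("c1", "m1"), ("c2", "m2"), ("c3", "m1")
        }
        assert import_external_targets(ext, internal, "intersection") == {("c1", "m1")}


class TestRbpEdges:
    def test_peak_near_start(self):
        edges = rbp_edges([circ(5000, 9000)], [BedInterval("chr1", 5200, 5250, "RBP1")])
        assert len(edges) == 1
        assert edges[0].rbp == "RBP1" and edges[0].min_distance == 200

    def test_peaks_inside_long_circle_away_from_bsjs(self):
        c = circ(10000, 14000)  # length 4000
        peaks = [
            BedInterval("chr1", 11500, 11550, "RBP1"),  # start+1500
            BedInterval("chr1", 12450, 12500, "RBP1"),  # end-1550..-1500
        ]
        assert rbp_edges([c], peaks) == []

    def test_other_chromosome_ignored(self):
        edges = rbp_edges([circ(5000, 9000)], [BedInterval("chr9", 5200, 5250, "RBP1")])
        assert edges == []

    def test_planted_clip_edges_recovered_exactly(self, bundle):
        sp = bundle.cfg.species[0]
        records = []
        for t in bundle.truth_for_species(sp):
            chrom, s, e = t.coords[sp]
            r = CircRecord(species_code=sp, chrom=chrom, start=s, end=e, strand=t.strand)
            records.append(r)
        edges = rbp_edges(records, bundle.clip_peaks)
        assert {(e.circ, e.rbp) for e in edges} == bundle.planted_rbp_edges


class TestFunctionPropagation:
    def _network(self):
        # circ with 2 neighbors, universe of 10 annotated genes, term covers 5
        genes = [f"g{i}" for i in range(10)]
        edges = []
        from circkit.network import CoexpressionEdge

        for g in ("g0", "g1"):
            edges.append(CoexpressionEdge("circA", g, 0.9))
        net = build_network(edges, {"circA"})
        for g in genes:
            net.add_node(g, kind="mRNA")
        terms = pd.DataFrame(
            {"gene_id": genes[:5] + genes, "term_id": ["T1"] * 5 + ["ALL"] * 10}
        )
        return net, terms, set(genes)

    def test_closed_form_hypergeometric(self):
        net, terms, universe = self._network()
        calls = propagate_function(net, terms, universe=universe)
        t1 = next(c for c in calls if c.term_id == "T1")
        # both neighbors in a 5-gene term of a 10-gene universe: C(5,2)/C(10,2)
        assert t1.p_value == pytest.approx(10 / 45, abs=1e-12)
        assert t1.support == 2 and t1.neighbors == 2

    def test_term_covering_universe_gives_p_one(self):
        net, terms, universe = self._network()
        calls = propagate_function(net, terms, universe=universe)
        allterm = next(c for c in calls if c.term_id == "ALL")
        assert allterm.p_value == pytest.approx(1.0)

    def test_circ_without_neighbors_gets_no_calls(self):
        net, terms, universe = self._network()
        net.add_node("circLonely", kind="circRNA")
        calls = propagate_function(net, terms, universe=universe)
        assert all(c.circ != "circLonely" for c in calls)

    def test_bh_qvalues_bounded_and_monotone(self):
        net, terms, universe = self._network()
        calls = propagate_function(net, terms, universe=universe)
        for c in calls:
            assert c.q_value >= c.p_value - 1e-12
        by_p = sorted((c for c in calls if c.circ == "circA"), key=lambda c: c.p_value)
        qs = [c.q_value for c in by_p]
        assert qs == sorted(qs)

    def test_matches_monte_carlo(self, rng):
        p = float(hypergeom.sf(2 - 1, 10, 5, 2))
        est = hypergeom_tail_mc(10, 5, 2, 2, n_draws=20000, rng=rng)
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(est - p) < 3 * se

    def test_empty_term_table_errors(self):
        net, _, _ = self._network()
        with pytest.raises(ValueError):
            propagate_function(net, pd.DataFrame(columns=["gene_id", "term_id"]))


class TestRanking:
    def test_rank_by_circ_degree(self):
        from circkit.network import RbpEdge

        edges = [
            RbpEdge("c1", "RBP_A", 1, 0),
            RbpEdge("c2", "RBP_A", 1, 0),
            RbpEdge("c3", "RBP_A", 1, 0),
            RbpEdge("c1", "RBP_B", 2, 10),
        ]
        net = build_network(rbp=edges, circ_ids={"c1", "c2", "c3"})
        ranking = rank_interactors(net)
        assert ranking[0][:1] == ("RBP_A",) and ranking[0][2] == 3
        # degree equals a brute-force recount of incident circRNA edges
        for node, kind, deg in ranking:
            recount = sum(
                1 for nb in net.neighbors(node)
                if net.nodes[nb]["kind"] == "circRNA"
            )
            assert deg == recount

    def test_empty_network(self):
        import networkx as nx

        assert rank_interactors(nx.Graph()) == []
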