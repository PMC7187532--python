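"""Integrated circRNA-mRNA-miRNA-RBP annotation network.

The network is built in three passes: (1) a co-expression backbone from
Pearson correlation of per-tissue mean expression between circRNAs and
mRNAs, keeping pairs with r >= 0.5 and restricting nodes to those expressed
in at least 3 tissues; (2) circRNA-miRNA edges from canonical seed matches
(6mer, 7mer-A1, 7mer-m8, 8mer) scanned on the circular sequence, junction
included; (3) circRNA-RBP edges from CLIP peaks falling within 1 kb of
either side of the BSJ.  GO/KEGG terms are then propagated to each circRNA
from its connected gene neighbors via a hypergeometric enrichment test with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import CircRecord, Sample, reverse_complement
from .io import BedInterval

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass
class CoexpressionEdge:
    node_a: str
    node_b: str
    r: float


@dataclass
class SeedSite:
    """A miRNA seed match on a circRNA sequence.

    ``position`` is the 0-based offset of the site's first base on the
    circle (the m8-pairing base for 8mer/7mer-m8 sites, the seed-core base
    otherwise); sites may wrap across the BSJ.
    """

    position: int
    site_type: str
    mirna_id: str
    site_seq: str

    def __post_init__(self) -> None:
        if self.site_type not in SEED_TYPES:
            raise ValueError(f"unknown seed site type {self.site_type!r}")


@dataclass
class RbpEdge:
    circ: str
    rbp: str
    peak_count: int
    min_distance: int


@dataclass
class FunctionCall:
    circ: str
    term_id: str
    support: int
    neighbors: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.support > self.neighbors:
            raise ValueError("support cannot exceed neighbor count")
        for name, v in (("p", self.p_value), ("q", self.q_value)):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}-value outside [0, 1]: {v}")


# ---------------------------------------------------------------------------
# Co-expression


def tissue_mean_expression(
    expr: pd.DataFrame, samples: Sequence[Sample]
) -> pd.DataFrame:
    """Collapse a per-sample matrix to per-tissue means."""
    tissue_of = {s.sample_id: s.tissue for s in samples}
    missing = [c for c in expr.columns if c not in tissue_of]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing}")
    return expr.T.groupby(expr.columns.map(tissue_of.get)).mean().T


def coexpression_edges(
    tissue_expr: pd.DataFrame,
    circ_ids: Iterable[str],
    r_min: float = 0.5,
    min_tissues: int = 3,
    keep_anticorrelated: bool = False,
) -> List[CoexpressionEdge]:
    """Co-expression edges between circRNAs and other profiled nodes.

    ``tissue_expr`` holds per-tissue mean expression (rows = circRNA locus
    keys and mRNA gene ids).  Nodes expressed (value > 0) in fewer than
    ``min_tissues`` tissues are removed before any correlation is computed.
    Pearson r over tissues is evaluated for every pair containing at least
    one circRNA; an edge is kept iff r >= r_min (or |r| >= r_min with
    ``keep_anticorrelated``).  Constant profiles have undefined r and are
    skipped with a warning.
    """
    if tissue_expr.shape[1] < min_tissues:
        raise ValueError(
            f"need >= {min_tissues} tissue columns, got {tissue_expr.shape[1]}"
        )
    circ_set = set(circ_ids)
    expressed = (tissue_expr > 0).sum(axis=1)
    kept = tissue_expr.loc[expressed >= min_tissues]
    ids = list(kept.index)
    values = kept.values.astype(float)
    std = values.std(axis=1)

    edges: List[CoexpressionEdge] = []
    n_constant = 0
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            if a not in circ_set and b not in circ_set:
                continue
            if std[i] == 0 or std[j] == 0:
                n_constant += 1
                continue
            r = float(np.corrcoef(values[i], values[j])[0, 1])
            keep = abs(r) >= r_min if keep_anticorrelated else r >= r_min
            if keep:
                edges.append(CoexpressionEdge(a, b, r))
    if n_constant:
        warnings.warn(
            f"{n_constant} pair(s) skipped: constant profile, correlation undefined"
        )
    return edges


# ---------------------------------------------------------------------------
# miRNA seed sites


def _seed_patterns(mirna_seq: str) -> Dict[str, str]:
    """Target-site patterns (DNA, target 5'->3') for one miRNA.

    Positions 2-7 of the miRNA form the seed core; the 7mer-m8 class adds a
    match to position 8, the A1 classes an adenosine opposite position 1.
    """
    seq = mirna_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"miRNA shorter than 8 nt: {mirna_seq!r}")
    core = reverse_complement(seq[1:7])       # matches miRNA 2-7
    with_m8 = reverse_complement(seq[1:8])    # matches miRNA 2-8
    return {
        "8mer": with_m8 + "A",
        "7mer-m8": with_m8,
        "7mer-A1": core + "A",
        "6mer": core,
    }


def mirna_seed_sites(
    circ_seq: str, mirnas: Dict[str, str]
) -> List[SeedSite]:
    """Scan a circular sequence for canonical miRNA seed-match sites.

    The sequence is extended by its own first 8 nt so that sites straddling
    the back-splice junction are found; each reported position (mod circle
    length) carries the most specific matching site class.
    """
    seq = circ_seq.upper().replace("U", "T")
    L = len(seq)
    if L < 6:
        return []
    ctx = seq + seq[:8]
    sites: List[SeedSite] = []
    for mid in sorted(mirnas):
        pat = _seed_patterns(mirnas[mid])
        core = pat["6mer"]
        for q in range(L):  # q = position of the seed-core match
            if ctx[q : q + 6] != core:
                continue
            prev = ctx[q - 1] if q > 0 else seq[-1]
            has_m8 = prev == pat["7mer-m8"][0]
            has_a1 = ctx[q + 6] == "A"
            if has_m8 and has_a1:
                stype = "8mer"
            elif has_m8:
                stype = "7mer-m8"
            elif has_a1:
                stype = "7mer-A1"
            else:
                stype = "6mer"
            if has_m8:
                pos = (q - 1) % L
                site = prev + ctx[q : q + 6] + ("A" if has_a1 else "")
            else:
                pos = q
                site = ctx[q : q + 6] + ("A" if has_a1 else "")
            sites.append(SeedSite(position=pos, site_type=stype, mirna_id=mid, site_seq=site))
    return sites


def import_external_targets(
    predictions: pd.DataFrame,
    internal: Sequence[Tuple[str, str]],
    mode: str = "union",
) -> Set[Tuple[str, str]]:
    """Combine external (circ, miRNA) predictions with internal seed calls.

    ``predictions`` needs columns circ_id and mirna_id; ``mode`` is
    ``union`` (default, emulating a multi-tool ensemble's combined output)
    or ``intersection``.
    """
    ext = {(r.circ_id, r.mirna_id) for r in predictions.itertuples(index=False)}
    internal_set = set(internal)
    if mode == "union":
        return ext | internal_set
    if mode == "intersection":
        return ext & internal_set
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# RBP edges


def rbp_edges(
    records: Sequence[CircRecord],
    peaks: Sequence[BedInterval],
    window: int = 1000,
) -> List[RbpEdge]:
    """CircRNA-RBP edges from CLIP peaks near back-splice junctions.

    An edge is created when a peak overlaps the 1-kb window on either side
    of either BSJ coordinate: [start-w, start+w) or [end-w, end+w) on the
    circle's chromosome.  Peak strand is ignored.  Records peak count and
    the minimum peak distance to the nearer junction point.
    """
    trees: Dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, pk.name)

    edges: Dict[Tuple[str, str], List[int]] = {}
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        windows = [
            (max(0, rec.start - window), rec.start + window),
            (max(0, rec.end - window), rec.end + window),
        ]
        hits = set()
        for lo, hi in windows:
            hits |= tree.overlap(lo, hi)
        for iv in hits:
            def point_dist(point: int) -> int:
                if iv.begin <= point < iv.end:
                    return 0
                return min(abs(iv.begin - point), abs(iv.end - 1 - point))
            dist = min(point_dist(rec.start), point_dist(rec.end))
            edges.setdefault((rec.locus_key, iv.data), []).append(dist)
    return [
        RbpEdge(circ=c, rbp=r, peak_count=len(d), min_distance=min(d))
        for (c, r), d in sorted(edges.items())
    ]


# ---------------------------------------------------------------------------
# Network assembly, function propagation, interactor ranking


def build_network(
    coexp: Sequence[CoexpressionEdge] = (),
    circ_ids: Iterable[str] = (),
    mirna_sites: Optional[Dict[str, Sequence[SeedSite]]] = None,
    rbp: Sequence[RbpEdge] = (),
) -> nx.Graph:
    """Assemble the typed annotation network.

    Node attribute ``kind`` in {circRNA, mRNA, miRNA, RBP}; edge attribute
    ``etype`` in {coexpression, mirna_binding, rbp_binding} with evidence
    payloads (r; site count and types; peak count and min distance).
    """
    g = nx.Graph()
    circ_set = set(circ_ids)

    def _ensure(node: str, kind: str) -> None:
        if node in g and g.nodes[node]["kind"] != kind:
            raise ValueError(
                f"node {node!r} already typed {g.nodes[node]['kind']!r}, not {kind!r}"
            )
        g.add_node(node, kind=kind)

    for e in coexp:
        for n in (e.node_a, e.node_b):
            _ensure(n, "circRNA" if n in circ_set else "mRNA")
        g.add_edge(e.node_a, e.node_b, etype="coexpression", r=e.r)
    if mirna_sites:
        for circ, sites in mirna_sites.items():
            _ensure(circ, "circRNA")
            per_mirna: Dict[str, List[SeedSite]] = {}
            for s in sites:
                per_mirna.setdefault(s.mirna_id, []).append(s)
            for mid, ss in per_mirna.items():
                _ensure(mid, "miRNA")
                g.add_edge(
                    circ,
                    mid,
                    etype="mirna_binding",
                    site_count=len(ss),
                    site_types=",".join(sorted({s.site_type for s in ss})),
                )
    for e in rbp:
        _ensure(e.circ, "circRNA")
        _ensure(e.rbp, "RBP")
        g.add_edge(
            e.circ, e.rbp, etype="rbp_binding",
            peak_count=e.peak_count, min_distance=e.min_distance,
        )
    return g


def propagate_function(
    network: nx.Graph,
    term_table: pd.DataFrame,
    universe: Optional[Set[str]] = None,
    mirna_targets: Optional[Dict[str, Set[str]]] = None,
) -> List[FunctionCall]:
    """Propagate GO/KEGG terms to circRNAs from their connected neighbors.

    For each circRNA, its neighbor gene set (mRNA and RBP node ids, plus
    genes targeted by neighboring miRNAs via ``mirna_targets``) is tested
    per term with the hypergeometric upper tail P(X >= k) against
    ``universe`` (default: every annotated gene present in the network);
    q-values are Benjamini-Hochberg within each circRNA, output sorted by
    (circ, q, term).
    """
    if term_table.empty:
        raise ValueError("term table is empty")
    term_genes: Dict[str, Set[str]] = {}
    for row in term_table.itertuples(index=False):
        term_genes.setdefault(row.term_id, set()).add(row.gene_id)
    annotated = set(term_table["gene_id"])

    gene_nodes = {
        n for n, d in network.nodes(data=True) if d.get("kind") in ("mRNA", "RBP")
    }
    if universe is None:
        universe = gene_nodes & annotated
        if mirna_targets:
            for targets in mirna_targets.values():
                universe |= targets & annotated
    M = len(universe)
    if M == 0:
        return []

    calls: List[FunctionCall] = []
    circ_nodes = sorted(
        n for n, d in network.nodes(data=True) if d.get("kind") == "circRNA"
    )
    for circ in circ_nodes:
        neigh: Set[str] = set()
        for nb in network.neighbors(circ):
            kind = network.nodes[nb].get("kind")
            if kind in ("mRNA", "RBP"):
                neigh.add(nb)
            elif kind == "miRNA" and mirna_targets:
                neigh |= mirna_targets.get(nb, set())
        neigh &= universe
        N = len(neigh)
        if N == 0:
            continue
        rows = []
        for term in sorted(term_genes):
            genes = term_genes[term] & universe
            n = len(genes)
            if n == 0:
                continue  # term absent from the universe
            k = len(genes & neigh)
            p = float(hypergeom.sf(k - 1, M, n, N))
            rows.append((term, k, p))
        if not rows:
            continue
        pvals = [p for _, _, p in rows]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for (term, k, p), q in zip(rows, qvals):
            calls.append(
                FunctionCall(
                    circ=circ, term_id=term, support=k, neighbors=N,
                    p_value=p, q_value=min(1.0, float(q)),
                )
            )
    calls.sort(key=lambda c: (c.circ, c.q_value, c.term_id))
    return calls


def rank_interactors(network: nx.Graph) -> List[Tuple[str, str, int]]:
    """RBPs and miRNAs ranked by the number of distinct circRNAs they touch.

    Returns (node, kind, circRNA-degree) sorted descending, ties broken
    lexicographically by node name.
    """
    rows = []
    for n, d in network.nodes(data=True):
        if d.get("kind") not in ("miRNA", "RBP"):
            continue
        deg = sum(
            1 for nb in network.neighbors(n)
            if network.nodes[nb].get("kind") == "circRNA"
        )
        rows.append((n, d["kind"], deg))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows


def write_network(network: nx.Graph, graphml_path=None, edges_tsv_path=None) -> None:
    """Write the network as GraphML and/or a TSV edge list."""
    if graphml_path is not None:
        nx.write_graphml(network, str(graphml_path))
    if edges_tsv_path is not None:
        rows = []
        for u, v, d in sorted(network.edges(data=True)):
            attrs = {k: val for k, val in d.items() if k != "etype"}
            rows.append(
                {
                    "node_a": u,
                    "node_b": v,
                    "kind_a": network.nodes[u]["kind"],
                    "kind_b": network.nodes[v]["kind"],
                    "etype": d["etype"],
                    "evidence": ";".join(f"{k}={attrs[k]}" for k in sorted(attrs)),
                }
            )
        pd.DataFrame(
            rows,
            columns=["node_a", "node_b", "kind_a", "kind_b", "etype", "evidence"],
        ).to_csv(edges_tsv_path, sep="\t", index=False)
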