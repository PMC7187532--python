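"""Cross-species orthologous circRNA detection.

Workflow: restrict candidate pairs to orthologous host-gene pairs where both
genes express circRNAs; verify cirexon boundary correspondence through
pairwise genome coordinate maps (advisory); represent each BSJ by up to
50 nt of cirexon sequence on each side of the junction, read 5'->3' on the
mature circular transcript; align all flank sequences between two species
with an optimal local aligner (Smith-Waterman, affine gaps); keep reciprocal
best hits passing identity/length thresholds; and integrate pairwise RBH
sets over >= 2 species into ortholog groups with at most one member per
species.  A member's species-conservation count N_s is its group size - 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
from Bio import Align

from .core import (
    CircRecord,
    CirckitError,
    CoordinateMap,
    GeneModel,
    GenomeRef,
    reverse_complement,
)


@dataclass
class AlignmentScoring:
    """Local alignment scoring scheme (defaults: +1/-1, gap open/extend -2/-1)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass
class BsjFlankSeq:
    """BSJ-representing sequence: 3'-side flank joined to 5'-side flank.

    ``len_upstream`` is the length taken from the 3'-terminal cirexon (the
    side ending at the junction donor) and ``len_downstream`` from the
    5'-terminal cirexon (the acceptor side), both on the mature transcript.
    """

    locus_key: str
    sequence: str
    len_upstream: int
    len_downstream: int

    def __post_init__(self) -> None:
        if not (2 <= len(self.sequence) <= 100):
            raise ValueError(
                f"flank sequence length {len(self.sequence)} outside [2, 100]"
            )
        if self.len_upstream + self.len_downstream != len(self.sequence):
            raise ValueError("recorded flank lengths do not sum to sequence length")


@dataclass
class AlignmentHit:
    query: str
    subject: str
    score: float
    identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("negative alignment score")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")


@dataclass
class RbhPair:
    circ_a: str
    circ_b: str
    species_a: str
    species_b: str
    score: float
    identity: float
    boundary_verified: Optional[bool] = None


@dataclass
class OrthologGroup:
    """Orthologous circRNAs across species, at most one member per species."""

    members: Dict[str, str]  # species_code -> locus_key
    score: float = 0.0

    @property
    def n_s(self) -> int:
        return len(self.members) - 1


# ---------------------------------------------------------------------------
# Candidate restriction


def restrict_to_ortholog_genes(
    circs_a: Sequence[CircRecord],
    circs_b: Sequence[CircRecord],
    gene_pairs: Sequence[Tuple[str, str]],
) -> List[Tuple[CircRecord, CircRecord]]:
    """Candidate cross-species pairs restricted to orthologous host genes.

    Only gene pairs where both members host circRNAs contribute; for each
    such pair the full cross product of hosted circles is returned.
    """
    by_gene_a: Dict[str, List[CircRecord]] = {}
    for c in circs_a:
        if c.host_gene:
            by_gene_a.setdefault(c.host_gene, []).append(c)
    by_gene_b: Dict[str, List[CircRecord]] = {}
    for c in circs_b:
        if c.host_gene:
            by_gene_b.setdefault(c.host_gene, []).append(c)
    out: List[Tuple[CircRecord, CircRecord]] = []
    for ga, gb in gene_pairs:
        for ca in by_gene_a.get(ga, []):
            for cb in by_gene_b.get(gb, []):
                out.append((ca, cb))
    return out


# ---------------------------------------------------------------------------
# Liftover


def liftover_interval(
    chrom: str, start: int, end: int, cmap: CoordinateMap
) -> Optional[Tuple[str, int, int, str]]:
    """Map an interval through a pairwise coordinate map.

    Both endpoints must fall inside mapping blocks (the end is mapped via
    its last covered base); returns ``(chrom, start, end, strand)`` in the
    target genome or None when either endpoint is unmapped or the endpoints
    land on different target chromosomes/strands.
    """
    if start >= end:
        raise ValueError("empty interval")
    b1 = cmap.block_containing(chrom, start)
    b2 = cmap.block_containing(chrom, end - 1)
    if b1 is None or b2 is None:
        return None

    def map_pos(block, pos: int) -> int:
        off = pos - block.src_start
        if block.dst_strand == "+":
            return block.dst_start + off
        return block.dst_end - 1 - off

    p1 = map_pos(b1, start)
    p2 = map_pos(b2, end - 1)
    if b1.dst_chrom != b2.dst_chrom or b1.dst_strand != b2.dst_strand:
        return None
    lo, hi = min(p1, p2), max(p1, p2)
    return (b1.dst_chrom, lo, hi + 1, b1.dst_strand)


# ---------------------------------------------------------------------------
# Flank extraction


def terminal_cirexons(
    circ: CircRecord, gene: GeneModel
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Genomic intervals of the circle's first and last cirexons.

    Returns ``(exon_at_start, exon_at_end)`` — the exon containing the
    circle's genomic start and the exon containing its genomic end — on the
    transcript agreeing best with the circle.  Falls back to the circle's
    own terminal coordinates clipped to the exon when boundaries do not
    coincide with annotated splice sites.
    """
    def agreement(exons):
        overlap = sum(max(0, min(e, circ.end) - max(s, circ.start)) for s, e in exons)
        boundary = sum(1 for s, e in exons if s == circ.start) + sum(
            1 for s, e in exons if e == circ.end
        )
        return (boundary, overlap)

    tid = max(sorted(gene.transcripts), key=lambda t: agreement(gene.transcripts[t]))
    exons = gene.transcripts[tid]
    ex_start = next((iv for iv in exons if iv[0] <= circ.start < iv[1]), None)
    ex_end = next((iv for iv in exons if iv[0] < circ.end <= iv[1]), None)
    if ex_start is None or ex_end is None:
        raise CirckitError(
            f"cirexons unknown for {circ.locus_key}: run classification against "
            "the annotation first"
        )
    # clip to the circle so flanks never reach outside it
    ex_start = (max(ex_start[0], circ.start), min(ex_start[1], circ.end))
    ex_end = (max(ex_end[0], circ.start), min(ex_end[1], circ.end))
    return ex_start, ex_end


def extract_bsj_flanks(
    circ: CircRecord,
    genome: GenomeRef,
    gene: Optional[GeneModel] = None,
    cirexons: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None,
    k: int = 50,
) -> BsjFlankSeq:
    """Extract the (up to) 2x50 nt sequence representing a BSJ.

    The sequence is the last ``min(k, exon)`` nt of the 3'-terminal cirexon
    followed by the first ``min(k, exon)`` nt of the 5'-terminal cirexon,
    read 5'->3' on the mature circular transcript (reverse-complemented for
    minus-strand circles), exactly the context a read crossing the junction
    would show.
    """
    if cirexons is None:
        if gene is None:
            raise CirckitError(
                f"cirexons unknown for {circ.locus_key}: provide the host gene "
                "model or explicit cirexons (run classification first)"
            )
        cirexons = terminal_cirexons(circ, gene)
    ex_start, ex_end = cirexons

    if circ.strand == "+":
        # 3'-terminal cirexon ends at circ.end; 5'-terminal starts at circ.start
        len_up = min(k, ex_end[1] - ex_end[0])
        len_down = min(k, ex_start[1] - ex_start[0])
        upstream = genome.fetch(circ.chrom, ex_end[1] - len_up, ex_end[1])
        downstream = genome.fetch(circ.chrom, ex_start[0], ex_start[0] + len_down)
        seq = upstream + downstream
    else:
        # mature transcript runs end -> start; the 3'-terminal cirexon is the
        # genomic-start exon, the 5'-terminal the genomic-end exon
        len_up = min(k, ex_start[1] - ex_start[0])
        len_down = min(k, ex_end[1] - ex_end[0])
        upstream = reverse_complement(
            genome.fetch(circ.chrom, ex_start[0], ex_start[0] + len_up)
        )
        downstream = reverse_complement(
            genome.fetch(circ.chrom, ex_end[1] - len_down, ex_end[1])
        )
        seq = upstream + downstream
    return BsjFlankSeq(
        locus_key=circ.locus_key,
        sequence=seq,
        len_upstream=len_up,
        len_downstream=len_down,
    )


# ---------------------------------------------------------------------------
# Alignment


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_flanks(
    a: str,
    b: str,
    scoring: Optional[AlignmentScoring] = None,
    query: str = "a",
    subject: str = "b",
) -> AlignmentHit:
    """Optimal local alignment of two BSJ flank sequences.

    Smith-Waterman with affine gaps; identity is matched columns over
    alignment columns (gaps included) of one optimal alignment.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentHit(query, subject, 0.0, 0.0, 0)
    aln = next(iter(aligner.align(a, b)))
    matches = 0
    columns = 0
    seq_a, seq_b = aln[0], aln[1]
    for ca, cb in zip(seq_a, seq_b):
        columns += 1
        if ca == cb and ca != "-":
            matches += 1
    identity = matches / columns if columns else 0.0
    return AlignmentHit(query, subject, float(score), identity, columns)


# ---------------------------------------------------------------------------
# Reciprocal best hits


def reciprocal_best_hits(
    candidates: Sequence[Tuple[CircRecord, CircRecord]],
    flanks_a: Dict[str, BsjFlankSeq],
    flanks_b: Dict[str, BsjFlankSeq],
    min_identity: float = 0.7,
    min_aln_len: int = 60,
    scoring: Optional[AlignmentScoring] = None,
    boundary_checks: Optional[Dict[Tuple[str, str], bool]] = None,
) -> List[RbhPair]:
    """Reciprocal best hits over the candidate pair universe.

    A pair (x, y) is reported iff y is x's unique top-scoring hit among x's
    candidates and vice versa, and the hit passes the identity and aligned
    length thresholds.  A tie for the top score disqualifies the sequence
    (conservative).  ``boundary_checks`` optionally carries the advisory
    liftover verification flag per (locus_a, locus_b).
    """
    scoring = scoring or AlignmentScoring()
    hits: Dict[Tuple[str, str], AlignmentHit] = {}
    species: Dict[str, str] = {}
    for ca, cb in candidates:
        ka, kb = ca.locus_key, cb.locus_key
        species[ka] = ca.species_code
        species[kb] = cb.species_code
        if (ka, kb) in hits:
            continue
        fa, fb = flanks_a.get(ka), flanks_b.get(kb)
        if fa is None or fb is None:
            continue
        hits[(ka, kb)] = align_flanks(
            fa.sequence, fb.sequence, scoring, query=ka, subject=kb
        )

    def best_unique(by_query: Dict[str, List[AlignmentHit]]) -> Dict[str, AlignmentHit]:
        out = {}
        for q, hs in by_query.items():
            top = max(h.score for h in hs)
            winners = [h for h in hs if h.score == top]
            if len(winners) == 1:
                out[q] = winners[0]
        return out

    fwd: Dict[str, List[AlignmentHit]] = {}
    rev: Dict[str, List[AlignmentHit]] = {}
    for (ka, kb), h in hits.items():
        fwd.setdefault(ka, []).append(h)
        rev.setdefault(kb, []).append(h)
    best_fwd = best_unique(fwd)
    best_rev = best_unique(rev)

    pairs: List[RbhPair] = []
    for ka, h in sorted(best_fwd.items()):
        kb = h.subject
        back = best_rev.get(kb)
        if back is None or back.query != ka:
            continue
        if h.identity < min_identity or h.aligned_length < min_aln_len:
            continue
        pairs.append(
            RbhPair(
                circ_a=ka,
                circ_b=kb,
                species_a=species[ka],
                species_b=species[kb],
                score=h.score,
                identity=h.identity,
                boundary_verified=(
                    boundary_checks.get((ka, kb)) if boundary_checks else None
                ),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Multi-species group integration


def _component_groups_exact(
    graph: nx.Graph, nodes: List[str]
) -> List[FrozenSet[str]]:
    """Maximum-score consistent subsets of one connected component.

    Enumerates subsets with <= 1 member per species in which every member
    keeps at least one incident edge, picks the subset maximizing summed
    induced edge score (ties: larger subset, then lexicographic members),
    removes it, and repeats on the remainder.
    """
    groups: List[FrozenSet[str]] = []
    remaining = set(nodes)
    while True:
        sub = graph.subgraph(remaining)
        if sub.number_of_edges() == 0:
            break
        comp_nodes = sorted(remaining)
        best_set: Optional[FrozenSet[str]] = None
        best_key = None
        for r in range(2, len(comp_nodes) + 1):
            for combo in itertools.combinations(comp_nodes, r):
                sp = [graph.nodes[n]["species"] for n in combo]
                if len(set(sp)) != len(sp):
                    continue
                induced = graph.subgraph(combo)
                if induced.number_of_edges() == 0:
                    continue
                if any(induced.degree(n) == 0 for n in combo):
                    continue
                score = sum(d["score"] for _, _, d in induced.edges(data=True))
                key = (score, len(combo), tuple(sorted(combo, reverse=True)))
                if best_key is None or key > best_key:
                    best_key = key
                    best_set = frozenset(combo)
        if best_set is None:
            break
        groups.append(best_set)
        remaining -= best_set
    return groups


def _component_groups_greedy(
    graph: nx.Graph, nodes: List[str]
) -> List[FrozenSet[str]]:
    """Greedy edge-merge fallback for large components.

    Edges are taken in descending score order; two clusters merge when the
    merged member set keeps <= 1 circle per species.
    """
    cluster: Dict[str, FrozenSet[str]] = {n: frozenset([n]) for n in nodes}
    edges = sorted(
        graph.subgraph(nodes).edges(data=True),
        key=lambda e: (-e[2]["score"], e[0], e[1]),
    )
    for u, v, _d in edges:
        cu, cv = cluster[u], cluster[v]
        if cu is cv or cu == cv:
            continue
        merged = cu | cv
        sp = [graph.nodes[n]["species"] for n in merged]
        if len(set(sp)) != len(sp):
            continue
        for n in merged:
            cluster[n] = merged
    seen = set()
    out = []
    for c in cluster.values():
        if c not in seen and len(c) > 1:
            seen.add(c)
            out.append(c)
    return out


def build_ortholog_groups(
    rbh_sets: Sequence[Sequence[RbhPair]],
    all_circs: Optional[Sequence[CircRecord]] = None,
    exact_max_nodes: int = 10,
) -> List[OrthologGroup]:
    """Integrate pairwise RBH sets over >= 2 species into ortholog groups.

    Builds the RBH graph and, per connected component, selects consistent
    member sets (<= 1 circle per species, every member supported by >= 1 RBH
    edge) maximizing the summed pairwise alignment score.  Components up to
    ``exact_max_nodes`` nodes are solved exactly; larger ones by greedy
    edge merging.  Circles carrying no group membership (including any in
    ``all_circs`` with no RBH edge at all) become singleton groups with
    N_s = 0.
    """
    graph = nx.Graph()
    for pairs in rbh_sets:
        for p in pairs:
            graph.add_node(p.circ_a, species=p.species_a)
            graph.add_node(p.circ_b, species=p.species_b)
            graph.add_edge(p.circ_a, p.circ_b, score=p.score)

    groups: List[OrthologGroup] = []
    grouped: set = set()
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        nodes = sorted(comp)
        if len(nodes) <= exact_max_nodes:
            member_sets = _component_groups_exact(graph, nodes)
        else:
            member_sets = _component_groups_greedy(graph, nodes)
        for ms in member_sets:
            induced = graph.subgraph(ms)
            score = sum(d["score"] for _, _, d in induced.edges(data=True))
            groups.append(
                OrthologGroup(
                    members={graph.nodes[n]["species"]: n for n in sorted(ms)},
                    score=score,
                )
            )
            grouped |= set(ms)
    for n in sorted(graph.nodes):
        if n not in grouped:
            groups.append(
                OrthologGroup(members={graph.nodes[n]["species"]: n}, score=0.0)
            )
            grouped.add(n)
    if all_circs is not None:
        for c in all_circs:
            if c.locus_key not in grouped:
                groups.append(
                    OrthologGroup(members={c.species_code: c.locus_key}, score=0.0)
                )
                grouped.add(c.locus_key)
    return groups


def ns_by_locus(groups: Sequence[OrthologGroup]) -> Dict[str, int]:
    """N_s (ortholog count = group size - 1) per member locus key."""
    out: Dict[str, int] = {}
    for g in groups:
        for lk in g.members.values():
            out[lk] = g.n_s
    return out
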