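"""Host-gene assignment, subclass labels, ID assignment and circular ORFs.

Each consensus circRNA is attributed to a host gene (the annotated gene
whose locus it is transcribed from) and placed into exactly one of six
subclasses — exonic, intronic, 5utr, 3utr, antisense, intergenic — by a
fixed decision cascade.  An orthogonal ``non_repeat`` flag marks circles
whose two flanking introns carry no annotated repeat element, the signature
of RBP-driven (rather than intron-pairing-driven) circularization.

IDs follow the ``<species>-<gene symbol>_<NNNN>`` scheme with the ordinal
ranked by conservation score (most conserved = _0001); circles without a
gene symbol fall back to ``<species>-<locus key>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .core import CircRecord, GeneModel, SUBCLASSES
from .io import BedInterval

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Cascade order for loci matching several categories.  UTR classes outrank
# exonic so that 5'-UTR/3'-UTR circles are counted separately from plain
# exonic ones; the order is configurable via classify_subclass(precedence=).
DEFAULT_PRECEDENCE = ("5utr", "3utr", "exonic", "intronic")


@dataclass
class HostAssignment:
    gene_id: Optional[str]
    orientation: Optional[str]  # "sense" | "antisense" | None
    transcript_id: Optional[str] = None


@dataclass
class SubclassCall:
    subclass: str
    non_repeat: Optional[bool]
    flanking_introns: Tuple[Optional[Tuple[int, int]], Optional[Tuple[int, int]]] = (None, None)
    # whether both BSJ coordinates coincide with annotated splice sites
    boundary_exact: bool = False

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r}")


@dataclass
class CircOrf:
    """An open reading frame on the circular sequence.

    ``start`` is the 0-based offset of the ATG on the circle; ``length`` the
    nucleotide length including the stop codon (or 3x the circle length for a
    stop-free rolling-circle frame, flagged by ``no_stop``).
    """

    start: int
    length: int
    spans_bsj: bool
    no_stop: bool = False

    @property
    def peptide_length(self) -> int:
        return self.length // 3 - (0 if self.no_stop else 1)


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: Dict[str, GeneModel] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for gm in genes:
            if gm.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gm.gene_id}")
            self.genes[gm.gene_id] = gm
            s, e = gm.span
            self._trees.setdefault(gm.chrom, IntervalTree()).addi(s, e, gm.gene_id)

    def containing(self, chrom: str, start: int, end: int) -> List[GeneModel]:
        """Genes whose span contains the whole interval [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [
            self.genes[iv.data]
            for iv in tree.overlap(start, end)
            if iv.begin <= start and end <= iv.end
        ]
        return sorted(hits, key=lambda g: g.gene_id)


def _exonic_overlap(gene: GeneModel, start: int, end: int) -> int:
    return sum(
        max(0, min(e, end) - max(s, start)) for s, e in gene.exon_union()
    )


def assign_host_gene(
    circ: CircRecord, index: GeneIndex
) -> HostAssignment:
    """Attribute a circRNA to its host gene.

    Preference order: a same-strand gene containing both BSJ coordinates;
    failing that, an opposite-strand containing gene (antisense); else no
    host (intergenic).  Ties are broken by largest exonic overlap with the
    circle, then lexicographic gene_id.
    """
    candidates = index.containing(circ.chrom, circ.start, circ.end)
    sense = [g for g in candidates if g.strand == circ.strand]
    anti = [g for g in candidates if g.strand != circ.strand]

    def best(genes: List[GeneModel]) -> GeneModel:
        return max(
            genes,
            key=lambda g: (_exonic_overlap(g, circ.start, circ.end), _neg_id(g.gene_id)),
        )

    def _neg_id(gid: str):
        # invert lexicographic order so max() prefers the smaller gene_id
        return tuple(-ord(c) for c in gid)

    if sense:
        return HostAssignment(best(sense).gene_id, "sense")
    if anti:
        return HostAssignment(best(anti).gene_id, "antisense")
    return HostAssignment(None, None)


def _pick_transcript(gene: GeneModel, start: int, end: int) -> Tuple[str, List[Tuple[int, int]]]:
    """Transcript whose exons best agree with the circle interval."""

    def agreement(exons: List[Tuple[int, int]]) -> Tuple[int, int]:
        overlap = sum(max(0, min(e, end) - max(s, start)) for s, e in exons)
        boundary = sum(1 for s, e in exons if s == start) + sum(
            1 for s, e in exons if e == end
        )
        return (boundary, overlap)

    tid = max(
        sorted(gene.transcripts),
        key=lambda t: agreement(gene.transcripts[t]),
    )
    return tid, gene.transcripts[tid]


def _flanking_introns(
    exons: List[Tuple[int, int]], start: int, end: int
) -> Tuple[Optional[Tuple[int, int]], Optional[Tuple[int, int]]]:
    """Intron immediately upstream of ``start`` and downstream of ``end``.

    "Upstream"/"downstream" are genomic here; the pair is what flanks the
    circle on the chosen host transcript.  Either side may be None when the
    circle reaches the transcript's terminal exon.
    """
    introns = [
        (e1, s2) for (s1, e1), (s2, e2) in zip(exons, exons[1:]) if e1 < s2
    ]
    up = None
    down = None
    for ivs, ive in introns:
        if ive <= start and (up is None or ivs > up[0]):
            up = (ivs, ive)
        if ivs >= end and (down is None or ivs < down[0]):
            down = (ivs, ive)
    return up, down


def _in_any(pos: int, intervals: Sequence[Tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_subclass(
    circ: CircRecord,
    host: HostAssignment,
    genes: Dict[str, GeneModel],
    repeats: Optional[Sequence[BedInterval]] = None,
    strict_exonic: bool = False,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> SubclassCall:
    """Assign exactly one subclass plus the non-repeat flag.

    Cascade: intergenic (no host) -> antisense (opposite-strand host) ->
    then, on the sense host, the first matching label in ``precedence``
    (default 5utr, 3utr, exonic, intronic).  ``strict_exonic`` requires both
    BSJ coordinates to coincide with annotated exon boundaries; the default
    lenient mode only requires them to lie within exons.  A circle spanning
    an exon/intron boundary that matches no label is classed exonic (it
    contains exonic sequence).

    ``non_repeat`` is defined only when both flanking introns exist on the
    host transcript: True iff neither overlaps a repeat interval.
    """
    if host.gene_id is None:
        return SubclassCall("intergenic", None)
    gene = genes[host.gene_id]
    tid, exons = _pick_transcript(gene, circ.start, circ.end)
    up, down = _flanking_introns(exons, circ.start, circ.end)
    exon_starts = {s for tr in gene.transcripts.values() for s, _ in tr}
    exon_ends = {e for tr in gene.transcripts.values() for _, e in tr}
    boundary_exact = circ.start in exon_starts and circ.end in exon_ends

    non_repeat: Optional[bool] = None
    if up is not None and down is not None:
        non_repeat = True
        if repeats:
            for rep in repeats:
                if rep.chrom != circ.chrom:
                    continue
                for ivs, ive in (up, down):
                    if rep.start < ive and ivs < rep.end:
                        non_repeat = False
    flanks = (up, down)

    if host.orientation == "antisense":
        return SubclassCall("antisense", non_repeat, flanks, boundary_exact)

    first, last = circ.start, circ.end - 1  # the two junction bases

    def is_5utr() -> bool:
        return _in_any(first, gene.utr5) or _in_any(last, gene.utr5)

    def is_3utr() -> bool:
        return _in_any(first, gene.utr3) or _in_any(last, gene.utr3)

    def is_exonic() -> bool:
        if strict_exonic:
            return boundary_exact
        union = gene.exon_union()
        return _in_any(first, union) and _in_any(last, union)

    def is_intronic() -> bool:
        introns = [
            (e1, s2) for (s1, e1), (s2, e2) in zip(exons, exons[1:]) if e1 < s2
        ]
        return any(s <= circ.start and circ.end <= e for s, e in introns)

    tests = {"5utr": is_5utr, "3utr": is_3utr, "exonic": is_exonic, "intronic": is_intronic}
    for label in precedence:
        if tests[label]():
            return SubclassCall(label, non_repeat, flanks, boundary_exact)
    # mixed exon/intron span (or off-boundary exonic under strict mode)
    return SubclassCall("exonic", non_repeat, flanks, boundary_exact)


def classify_records(
    records: Sequence[CircRecord],
    genes: Sequence[GeneModel],
    repeats: Optional[Sequence[BedInterval]] = None,
    strict_exonic: bool = False,
) -> None:
    """Run host assignment + subclass call over records, in place."""
    index = GeneIndex(genes)
    by_id = index.genes
    for rec in records:
        host = assign_host_gene(rec, index)
        call = classify_subclass(rec, host, by_id, repeats, strict_exonic)
        rec.host_gene = host.gene_id
        rec.host_orientation = host.orientation
        rec.subclass = call.subclass
        rec.non_repeat = call.non_repeat
        rec.flanking_introns = call.flanking_introns


def assign_ids(
    records: Sequence[CircRecord],
    genes: Dict[str, GeneModel],
) -> None:
    """Assign circAtlas-style IDs in place.

    Gene-hosted records get ``<species>-<symbol>_<NNNN>`` with the 4-digit
    ordinal ranking records of that gene by MCS descending (ties by
    chrom/start/end); records without a gene symbol get
    ``<species>-<locus_key>``.  Requires MCS to be computed.
    """
    seen = set()
    for rec in records:
        if rec.locus_key in seen:
            raise ValueError(f"duplicate locus_key {rec.locus_key}")
        seen.add(rec.locus_key)

    by_gene: Dict[Tuple[str, str], List[CircRecord]] = {}
    for rec in records:
        if rec.host_gene is not None and rec.host_gene in genes:
            by_gene.setdefault((rec.species_code, rec.host_gene), []).append(rec)
        else:
            rec.circ_id = f"{rec.species_code}-{rec.locus_key}"
    for (species, gid), recs in by_gene.items():
        symbol = genes[gid].symbol
        recs.sort(
            key=lambda r: (
                -(r.mcs if r.mcs is not None else 0.0),
                r.chrom,
                r.start,
                r.end,
            )
        )
        for ordinal, rec in enumerate(recs, start=1):
            rec.circ_id = f"{species}-{symbol}_{ordinal:04d}"


def find_circular_orfs(seq: str, max_laps: int = 3) -> List[CircOrf]:
    """Find ATG...stop open reading frames on a circular sequence.

    Translation may run around the back-splice junction (rolling-circle
    style), so codons are read on the circularized sequence for up to
    ``max_laps`` laps.  Reported ORFs are maximal: per stop codon position
    (and per frame class for stop-free reads) only the longest ORF — the
    first ATG after the previous stop — is kept.  ORFs whose read extends
    past the sequence end are flagged ``spans_bsj``; a frame with no stop at
    all is reported once at the cap length with ``no_stop=True``.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 nt")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    L = len(seq)
    cap = max_laps * L
    extended = seq * (max_laps + 1)

    candidates: List[CircOrf] = []
    for p in range(L):
        if extended[p : p + 3] != "ATG":
            continue
        length = None
        q = p
        while q + 3 <= p + cap:
            if extended[q : q + 3] in STOP_CODONS:
                length = q + 3 - p
                break
            q += 3
        if length is None:
            length = cap - (cap % 3)
            candidates.append(
                CircOrf(start=p, length=length, spans_bsj=True, no_stop=True)
            )
        else:
            candidates.append(
                CircOrf(start=p, length=length, spans_bsj=(p + length > L))
            )

    # Maximality: group by the circular position of the stop codon (or, for
    # stop-free frames, by reading-frame class) and keep the earliest ATG.
    best: Dict[Tuple, CircOrf] = {}
    for orf in candidates:
        if orf.no_stop:
            key = ("nostop", orf.start % math.gcd(3, L))
        else:
            key = ("stop", (orf.start + orf.length - 3) % L, (orf.start + orf.length) // L)
        cur = best.get(key)
        if cur is None or orf.length > cur.length:
            best[key] = orf
    out = sorted(best.values(), key=lambda o: (o.start, -o.length))
    return out
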