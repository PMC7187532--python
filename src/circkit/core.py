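"""Core domain types and coordinate conventions.

All internal coordinates are 0-based, half-open ``[start, end)``.  GTF input
(1-based, closed) is converted on read; BED input passes through unchanged.
A circRNA is identified by its back-splice junction (BSJ): ``start`` is the
first base of the circle and ``end`` is one past the last base, on ``chrom``
and ``strand``.  The canonical string form is the *locus key*
``"chrom:start|end:strand"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

VALID_STRANDS = ("+", "-")
SUBCLASSES = ("exonic", "intronic", "5utr", "3utr", "antisense", "intergenic")

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


class CirckitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(CirckitError):
    """Raised when an input file cannot be interpreted."""


def locus_key(chrom: str, start: int, end: int, strand: str) -> str:
    """Canonical circRNA identifier ``chrom:start|end:strand``.

    Bijective with its inputs for valid coordinates (``start < end``).
    """
    if start >= end:
        raise ValueError(f"invalid interval: start {start} >= end {end}")
    if strand not in VALID_STRANDS:
        raise ValueError(f"invalid strand {strand!r}")
    return f"{chrom}:{start}|{end}:{strand}"


_LOCUS_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)\|(?P<end>\d+):(?P<strand>[+-])$")


def parse_locus_key(key: str) -> Tuple[str, int, int, str]:
    """Inverse of :func:`locus_key`."""
    m = _LOCUS_RE.match(key)
    if m is None:
        raise ValueError(f"malformed locus key: {key!r}")
    chrom, start, end = m.group("chrom"), int(m.group("start")), int(m.group("end"))
    strand = m.group("strand")
    if start >= end:
        raise ValueError(f"malformed locus key (start >= end): {key!r}")
    return chrom, start, end, strand


@dataclass
class GenomeRef:
    """A reference genome for one species.

    species_code
        Three-letter species prefix (e.g. ``hsa``, ``mmu``, ``gga``).
    chroms
        Mapping chromosome name -> DNA sequence (alphabet A/C/G/T/N).
    """

    species_code: str
    chroms: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice ``[start, end)`` of ``chrom`` (forward strand, upper case)."""
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.chroms[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"slice [{start},{end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end].upper()


@dataclass
class GeneModel:
    """One gene with its transcript exon structure.

    Exon intervals are 0-based half-open tuples sorted by start within each
    transcript; UTR intervals must be contained in the exon union.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> Tuple[int, int]:
        starts = [s for exons in self.transcripts.values() for s, _ in exons]
        ends = [e for exons in self.transcripts.values() for _, e in exons]
        if not starts:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return min(starts), max(ends)

    def exon_union(self) -> List[Tuple[int, int]]:
        """Merged exonic intervals over all transcripts, sorted."""
        ivs = sorted(
            iv for exons in self.transcripts.values() for iv in exons
        )
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def validate(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        for tid, exons in self.transcripts.items():
            if exons != sorted(exons):
                raise ValueError(f"transcript {tid}: exons not sorted")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"transcript {tid}: overlapping exons")
            for s, e in exons:
                if s >= e:
                    raise ValueError(f"transcript {tid}: empty exon [{s},{e})")
        union = self.exon_union()
        for name, utrs in (("5'-UTR", self.utr5), ("3'-UTR", self.utr3)):
            for s, e in utrs:
                if not any(us <= s and e <= ue for us, ue in union):
                    raise ValueError(
                        f"gene {self.gene_id}: {name} [{s},{e}) outside exon union"
                    )


@dataclass(frozen=True)
class BsjCall:
    """One detector's call of one back-splice junction in one sample."""

    sample_id: str
    tool: str
    chrom: str
    start: int
    end: int
    strand: str
    bsj_reads: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"BsjCall: start {self.start} >= end {self.end}")
        if self.bsj_reads < 0:
            raise ValueError(f"BsjCall: negative read count {self.bsj_reads}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"BsjCall: invalid strand {self.strand!r}")

    @property
    def locus_key(self) -> str:
        return locus_key(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Sample:
    """One RNA-seq library: species, tissue, individual and sequencing depth."""

    sample_id: str
    species_code: str
    tissue: str
    individual: str
    mapped_fragments: int

    def __post_init__(self) -> None:
        if self.mapped_fragments <= 0:
            raise ValueError(
                f"sample {self.sample_id}: mapped_fragments must be positive"
            )


@dataclass
class CircRecord:
    """A consensus circRNA locus with evidence, annotation and expression."""

    species_code: str
    chrom: str
    start: int
    end: int
    strand: str
    tools: Set[str] = field(default_factory=set)
    sample_reads: Dict[str, int] = field(default_factory=dict)
    host_gene: Optional[str] = None
    host_orientation: Optional[str] = None  # "sense" | "antisense" | None
    subclass: Optional[str] = None
    non_repeat: Optional[bool] = None
    flanking_introns: Optional[
        Tuple[Optional[Tuple[int, int]], Optional[Tuple[int, int]]]
    ] = None
    circ_id: Optional[str] = None
    fpm: Dict[str, float] = field(default_factory=dict)
    mcs: Optional[float] = None

    @property
    def locus_key(self) -> str:
        return locus_key(self.chrom, self.start, self.end, self.strand)

    @property
    def total_bsj_reads(self) -> int:
        return sum(self.sample_reads.values())

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MapBlock:
    """One ungapped block of a pairwise genome coordinate map.

    Source and target intervals have equal length; gaps live between blocks.
    ``dst_strand == "-"`` means the block maps with orientation reversal.
    """

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    dst_strand: str = "+"

    def __post_init__(self) -> None:
        if (self.src_end - self.src_start) != (self.dst_end - self.dst_start):
            raise ValueError(
                "coordinate map block length mismatch: "
                f"src [{self.src_start},{self.src_end}) vs "
                f"dst [{self.dst_start},{self.dst_end})"
            )
        if self.src_start >= self.src_end:
            raise ValueError("empty coordinate map block")
        if self.dst_strand not in VALID_STRANDS:
            raise ValueError(f"invalid block strand {self.dst_strand!r}")


@dataclass
class CoordinateMap:
    """Ordered ungapped blocks mapping one genome's coordinates onto another."""

    blocks: List[MapBlock]

    def __post_init__(self) -> None:
        by_chrom: Dict[str, List[MapBlock]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.src_chrom, []).append(b)
        for chrom, blist in by_chrom.items():
            blist.sort(key=lambda b: b.src_start)
            for b1, b2 in zip(blist, blist[1:]):
                if b2.src_start < b1.src_end:
                    raise ValueError(
                        f"overlapping source blocks on {chrom}: "
                        f"[{b1.src_start},{b1.src_end}) and "
                        f"[{b2.src_start},{b2.src_end})"
                    )
        self._by_chrom = by_chrom

    def block_containing(self, chrom: str, pos: int) -> Optional[MapBlock]:
        for b in self._by_chrom.get(chrom, []):
            if b.src_start <= pos < b.src_end:
                return b
        return None


def samples_by_id(samples: Sequence[Sample]) -> Dict[str, Sample]:
    out: Dict[str, Sample] = {}
    for s in samples:
        if s.sample_id in out:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        out[s.sample_id] = s
    return out
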