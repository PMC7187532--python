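"""Readers and writers for every external format the toolkit touches.

Formats: GTF (gene models), BED6 (repeats, CLIP peaks), FASTA (genomes,
miRNAs), header-ed TSV (BSJ calls, sample sheets, expression matrices,
ortholog gene pairs, GO/KEGG tables) and a chain-like TSV for pairwise
genome coordinate maps (columns src_chrom, src_start, src_end, dst_chrom,
dst_start, dst_end, dst_strand).

Parsers are total on their dialects: every line is either converted or
reported in a rejects list, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gffutils
import pandas as pd
from Bio import SeqIO

from .core import (
    BsjCall,
    CoordinateMap,
    GeneModel,
    GenomeRef,
    MapBlock,
    ParseError,
    Sample,
    VALID_STRANDS,
)

PathLike = Union[str, Path]

BSJ_COLUMNS = ["sample_id", "tool", "chrom", "start", "end", "strand", "bsj_reads"]
SAMPLE_COLUMNS = ["sample_id", "species_code", "tissue", "individual", "mapped_fragments"]
MAP_COLUMNS = ["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end", "dst_strand"]

_UTR5_TYPES = {"five_prime_utr", "5UTR", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "3UTR", "three_prime_UTR"}


# ---------------------------------------------------------------------------
# GTF


def _prevalidate_gtf(path: PathLike) -> None:
    """Cheap line-level validation so parse errors carry a line number.

    gffutils reports attribute problems without file positions; this pass
    checks field count and the mandatory gene_id/transcript_id attributes on
    exon/UTR lines before handing the file over.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            feature = fields[2]
            if feature in {"exon"} | _UTR5_TYPES | _UTR3_TYPES:
                attrs = fields[8]
                if "gene_id" not in attrs or "transcript_id" not in attrs:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed attributes "
                        f"(gene_id/transcript_id required): {attrs!r}"
                    )


def parse_gtf(path: PathLike) -> List[GeneModel]:
    """Read gene models from a GTF2.2 file.

    Exon coordinates are converted from GTF 1-based closed intervals to
    0-based half-open.  Features on strand ``.`` are rejected with a warning
    (strand is part of circRNA identity).  Returns one :class:`GeneModel`
    per ``gene_id``, sorted by gene_id.
    """
    _prevalidate_gtf(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: Dict[str, GeneModel] = {}
    wanted = {"exon"} | _UTR5_TYPES | _UTR3_TYPES
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        if feat.strand not in VALID_STRANDS:
            warnings.warn(
                f"{path}: {feat.featuretype} with unknown strand "
                f"{feat.strand!r} rejected ({feat.seqid}:{feat.start}-{feat.end})"
            )
            continue
        gene_id = feat.attributes["gene_id"][0]
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        start, end = feat.start - 1, feat.end  # 1-based closed -> 0-based half-open
        gm = genes.get(gene_id)
        if gm is None:
            gm = GeneModel(gene_id=gene_id, symbol=symbol, chrom=feat.seqid, strand=feat.strand)
            genes[gene_id] = gm
        if feat.featuretype == "exon":
            tid = feat.attributes["transcript_id"][0]
            gm.transcripts.setdefault(tid, []).append((start, end))
        elif feat.featuretype in _UTR5_TYPES:
            gm.utr5.append((start, end))
        else:
            gm.utr3.append((start, end))
    out = []
    for gid in sorted(genes):
        gm = genes[gid]
        for exons in gm.transcripts.values():
            exons.sort()
        gm.validate()
        out.append(gm)
    return out


def write_gtf(genes: Sequence[GeneModel], path: PathLike, source: str = "circkit") -> None:
    """Write gene models as GTF (exon + UTR features)."""
    with open(path, "w") as fh:
        for gm in genes:
            for tid in sorted(gm.transcripts):
                for s, e in gm.transcripts[tid]:
                    attrs = (
                        f'gene_id "{gm.gene_id}"; transcript_id "{tid}"; '
                        f'gene_name "{gm.symbol}";'
                    )
                    fh.write(
                        f"{gm.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t{attrs}\n"
                    )
            tid0 = sorted(gm.transcripts)[0] if gm.transcripts else gm.gene_id
            for ftype, ivs in (("five_prime_utr", gm.utr5), ("three_prime_utr", gm.utr3)):
                for s, e in ivs:
                    attrs = (
                        f'gene_id "{gm.gene_id}"; transcript_id "{tid0}"; '
                        f'gene_name "{gm.symbol}";'
                    )
                    fh.write(
                        f"{gm.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# BSJ call tables


@dataclass
class BsjCallTable:
    """Parsed BSJ calls plus the rejects report.

    Iterating or ``len()`` sees only the accepted calls; ``rejects`` lists
    ``(line_number, reason)`` for every rejected row, so accepted + rejected
    equals the input row count.
    """

    calls: List[BsjCall] = field(default_factory=list)
    rejects: List[Tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def read_bsj_calls(
    path: PathLike, genome: Optional[GenomeRef] = None
) -> BsjCallTable:
    """Read the normalized per-sample, per-tool BSJ call TSV.

    Rows with ``start >= end`` or strand ``.`` are rejected (reported, not
    fatal); a negative read count is an error.  If ``genome`` is given,
    coordinates are validated against its chromosome lengths.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in BSJ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    table = BsjCallTable()
    lengths = genome.lengths if genome is not None else None
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        start, end, reads = int(row.start), int(row.end), int(row.bsj_reads)
        if reads < 0:
            raise ParseError(f"{path}: line {idx}: negative bsj_reads {reads}")
        if start >= end:
            table.rejects.append((idx, f"start {start} >= end {end}"))
            continue
        if row.strand not in VALID_STRANDS:
            table.rejects.append((idx, f"invalid strand {row.strand!r}"))
            continue
        if lengths is not None:
            if row.chrom not in lengths:
                table.rejects.append((idx, f"unknown chromosome {row.chrom!r}"))
                continue
            if end > lengths[row.chrom]:
                table.rejects.append(
                    (idx, f"end {end} beyond {row.chrom} length {lengths[row.chrom]}")
                )
                continue
        table.calls.append(
            BsjCall(
                sample_id=row.sample_id,
                tool=row.tool,
                chrom=row.chrom,
                start=start,
                end=end,
                strand=row.strand,
                bsj_reads=reads,
            )
        )
    return table


def write_bsj_calls(calls: Sequence[BsjCall], path: PathLike) -> None:
    rows = [
        (c.sample_id, c.tool, c.chrom, c.start, c.end, c.strand, c.bsj_reads)
        for c in calls
    ]
    pd.DataFrame(rows, columns=BSJ_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheets


def read_samples(path: PathLike) -> List[Sample]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return [
        Sample(
            sample_id=r.sample_id,
            species_code=r.species_code,
            tissue=r.tissue,
            individual=r.individual,
            mapped_fragments=int(r.mapped_fragments),
        )
        for r in df.itertuples(index=False)
    ]


def write_samples(samples: Sequence[Sample], path: PathLike) -> None:
    rows = [
        (s.sample_id, s.species_code, s.tissue, s.individual, s.mapped_fragments)
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Name -> sequence mapping from a FASTA file (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_genome(path: PathLike, species_code: str) -> GenomeRef:
    return GenomeRef(species_code=species_code, chroms=read_fasta(path))


def write_fasta(seqs: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6 (repeats, CLIP peaks)


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."  # "." tolerated: repeat/peak overlap is strand-agnostic


def read_bed(path: PathLike) -> List[BedInterval]:
    out: List[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED fields")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            out.append(
                BedInterval(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else ".",
                    score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
    return out


def write_bed(intervals: Sequence[BedInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Coordinate maps, ortholog gene pairs, expression matrices, term tables


def read_coordinate_map(path: PathLike) -> CoordinateMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    blocks = [
        MapBlock(
            src_chrom=r.src_chrom,
            src_start=int(r.src_start),
            src_end=int(r.src_end),
            dst_chrom=r.dst_chrom,
            dst_start=int(r.dst_start),
            dst_end=int(r.dst_end),
            dst_strand=r.dst_strand,
        )
        for r in df.itertuples(index=False)
    ]
    return CoordinateMap(blocks=blocks)


def write_coordinate_map(cmap: CoordinateMap, path: PathLike) -> None:
    rows = [
        (b.src_chrom, b.src_start, b.src_end, b.dst_chrom, b.dst_start, b.dst_end, b.dst_strand)
        for b in cmap.blocks
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ortholog_pairs(path: PathLike) -> List[Tuple[str, str]]:
    """Two-column TSV of pairwise orthologous gene ids (gene_a, gene_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected >= 2 columns")
    pairs = list(dict.fromkeys(zip(df.iloc[:, 0], df.iloc[:, 1])))
    return pairs


def write_ortholog_pairs(pairs: Sequence[Tuple[str, str]], path: PathLike) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: PathLike) -> pd.DataFrame:
    """Rows = circRNA locus keys or gene ids, columns = sample ids, values >= 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative expression values")
    return df


def write_expression_matrix(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_term_table(path: PathLike) -> pd.DataFrame:
    """Gene -> functional term table; columns gene_id, term_id (extra kept)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "term_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df
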