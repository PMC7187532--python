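"""Deterministic synthetic-fixture generator with planted ground truth.

Emulates, at desk scale, a multi-species / multi-tissue circRNA profiling
study: a set of vertebrate genomes diverged from a common ancestor by
per-base substitution, annotated genes with orthologous pairs and pairwise
coordinate maps, planted circRNAs of every subclass, four-detector BSJ call
tables with per-sample Poisson read counts and single-tool decoy calls,
per-sample expression matrices with planted housekeeping / one-tissue /
co-expressed profiles, miRNA sequences with planted seed sites, CLIP peaks
near (and away from) BSJs, and a GO-style term table.

Every draw derives from one seed, so two runs with the same configuration
produce byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as ckio
from .core import (
    BsjCall,
    CoordinateMap,
    GeneModel,
    GenomeRef,
    MapBlock,
    Sample,
    locus_key,
    reverse_complement,
)
from .io import BedInterval

SPECIES_CODES = ("hsa", "mmu", "rno", "ssc", "gga", "mcc")

# the 19 normal tissues of the emulated study design
TISSUES_19 = (
    "brain", "cerebellum", "heart", "kidney", "liver", "lung", "muscle",
    "spleen", "testis", "ovary", "stomach", "intestine", "colon", "skin",
    "blood", "thymus", "pancreas", "adrenal", "bladder",
)

TOOLS = ("CIRI2", "DCC", "CIRCexplorer2", "find_circ")

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    """Study-design parameters for one synthetic bundle."""

    seed: int = 7
    n_species: int = 3
    genes_per_species: int = 8
    exons_per_gene: int = 4
    exon_len: int = 120
    intron_len: int = 90
    spacer_len: int = 200
    tail_len: int = 2500
    tissues: Tuple[str, ...] = TISSUES_19
    individuals_per_tissue: int = 3
    flank_divergence: float = 0.05
    tool_sensitivity: Dict[str, float] = field(
        default_factory=lambda: {
            "CIRI2": 0.95, "DCC": 0.90, "CIRCexplorer2": 0.90, "find_circ": 0.85,
        }
    )
    mean_bsj_reads: float = 8.0
    decoy_rate: float = 0.05  # decoy single-tool calls per truth circ per sample
    repeat_name: str = "SimRepeat"

    def __post_init__(self) -> None:
        if not (0.0 <= self.flank_divergence <= 1.0):
            raise ValueError("flank_divergence must be in [0, 1]")
        for tool, s in self.tool_sensitivity.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"sensitivity for {tool} outside [0, 1]")
        if not (2 <= self.n_species <= len(SPECIES_CODES)):
            raise ValueError(f"n_species must be in [2, {len(SPECIES_CODES)}]")

    @property
    def species(self) -> Tuple[str, ...]:
        return SPECIES_CODES[: self.n_species]


@dataclass
class TruthCirc:
    """One planted circRNA with its ground-truth labels."""

    template_id: str
    gene_index: Optional[int]
    strand: str
    subclass: str
    non_repeat: Optional[bool]
    species: List[str]
    group_id: Optional[str]
    # species -> (chrom, start, end)
    coords: Dict[str, Tuple[str, int, int]]
    # expression design shared across species: tissue -> expressing individuals
    expressing: Dict[str, Set[str]] = field(default_factory=dict)
    role: str = ""

    def key(self, sp: str) -> str:
        chrom, s, e = self.coords[sp]
        return locus_key(chrom, s, e, self.strand)


@dataclass
class FixtureBundle:
    """A complete in-memory fixture set plus writers for every file format."""

    cfg: FixtureConfig
    genomes: Dict[str, GenomeRef]
    genes: Dict[str, List[GeneModel]]
    gene_pairs: Dict[Tuple[str, str], List[Tuple[str, str]]]
    maps: Dict[Tuple[str, str], CoordinateMap]
    repeats: Dict[str, List[BedInterval]]
    truth_circs: List[TruthCirc]
    samples: Dict[str, List[Sample]]
    calls: Dict[str, List[BsjCall]]
    expected_consensus: Dict[str, Set[str]]
    circ_expr: pd.DataFrame     # species[0] per-sample FPM-like values
    joint_expr: pd.DataFrame    # circ + mRNA rows, same columns
    coexpressed_pairs: List[Tuple[str, str]]
    uncorrelated_pairs: List[Tuple[str, str]]
    mirnas: Dict[str, str]
    planted_seed_sites: List[Tuple[str, str, int]]  # (locus_key, mirna, position)
    clip_peaks: List[BedInterval]
    planted_rbp_edges: Set[Tuple[str, str]]
    term_table: pd.DataFrame

    def truth_for_species(self, sp: str) -> List[TruthCirc]:
        return [t for t in self.truth_circs if sp in t.species]

    def circ_sequence(self, sp: str, truth: TruthCirc) -> str:
        """Mature (spliced, 5'->3') circular sequence of a planted circle."""
        chrom, start, end = truth.coords[sp]
        genome = self.genomes[sp]
        if truth.gene_index is None:
            seq = genome.fetch(chrom, start, end)
            return seq if truth.strand == "+" else reverse_complement(seq)
        gene = self.genes[sp][truth.gene_index]
        exons = next(iter(gene.transcripts.values()))
        pieces = [
            genome.fetch(chrom, max(s, start), min(e, end))
            for s, e in exons
            if min(e, end) > max(s, start)
        ]
        seq = "".join(pieces)
        if not seq:
            seq = genome.fetch(chrom, start, end)
        return seq if truth.strand == "+" else reverse_complement(seq)

    def write(self, outdir) -> List[str]:
        """Emit every fixture file; returns the written relative paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: List[str] = []

        def _w(name: str) -> Path:
            written.append(name)
            return outdir / name

        for sp in self.cfg.species:
            ckio.write_fasta(self.genomes[sp].chroms, _w(f"genome_{sp}.fa"))
            ckio.write_gtf(self.genes[sp], _w(f"genes_{sp}.gtf"))
            ckio.write_bed(self.repeats[sp], _w(f"repeats_{sp}.bed"))
            ckio.write_samples(self.samples[sp], _w(f"samples_{sp}.tsv"))
            ckio.write_bsj_calls(self.calls[sp], _w(f"calls_{sp}.tsv"))
        for (a, b), pairs in sorted(self.gene_pairs.items()):
            ckio.write_ortholog_pairs(pairs, _w(f"ortho_genes_{a}_{b}.tsv"))
        for (a, b), cmap in sorted(self.maps.items()):
            ckio.write_coordinate_map(cmap, _w(f"map_{a}_{b}.tsv"))
        ckio.write_expression_matrix(self.circ_expr, _w("circ_expr.tsv"))
        ckio.write_expression_matrix(self.joint_expr, _w("joint_expr.tsv"))
        ckio.write_fasta(self.mirnas, _w("mirnas.fa"))
        ckio.write_bed(self.clip_peaks, _w("clip_peaks.bed"))
        self.term_table.to_csv(_w("terms.tsv"), sep="\t", index=False)

        rows = []
        for t in self.truth_circs:
            for sp in t.species:
                rows.append(
                    {
                        "template_id": t.template_id,
                        "species_code": sp,
                        "locus_key": t.key(sp),
                        "subclass": t.subclass,
                        "non_repeat": "" if t.non_repeat is None else str(t.non_repeat),
                        "group_id": t.group_id or "",
                        "role": t.role,
                    }
                )
        pd.DataFrame(rows).to_csv(_w("truth_circs.tsv"), sep="\t", index=False)
        for sp, keys in sorted(self.expected_consensus.items()):
            pd.DataFrame({"locus_key": sorted(keys)}).to_csv(
                _w(f"truth_consensus_{sp}.tsv"), sep="\t", index=False
            )
        return written


# ---------------------------------------------------------------------------
# genome / annotation simulation


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, body: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability ``rate`` (never to itself)."""
    out = body.copy()
    hit = rng.random(len(body)) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift each hit base by 1..3 positions in the A<C<G<T cycle
        base_idx = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(base_idx + rng.integers(1, 4, size=idx.size)) % 4]
    return out


def _gene_layout(cfg: FixtureConfig, i: int) -> Tuple[int, List[Tuple[int, int]]]:
    """Gene start and exon intervals (species-1 coordinates) for gene i."""
    unit = cfg.spacer_len + cfg.exons_per_gene * cfg.exon_len + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_len
    gs = cfg.spacer_len + i * unit
    exons = [
        (
            gs + j * (cfg.exon_len + cfg.intron_len),
            gs + j * (cfg.exon_len + cfg.intron_len) + cfg.exon_len,
        )
        for j in range(cfg.exons_per_gene)
    ]
    return gs, exons


_GENE_STRANDS = ("+", "-", "+", "-", "+", "+", "-", "+")


def simulate_species_set(
    cfg: FixtureConfig, rng: np.random.Generator
) -> Tuple[
    Dict[str, GenomeRef],
    Dict[str, List[GeneModel]],
    Dict[Tuple[str, str], List[Tuple[str, str]]],
    Dict[Tuple[str, str], CoordinateMap],
    np.ndarray,
]:
    """Genomes, GTF-style gene models, ortholog gene pairs and coordinate maps.

    The first species' genome is random; every other species is derived from
    it by per-base substitution at ``flank_divergence`` with a species-
    specific offset pad, so coordinate maps are exact identity-plus-offset
    blocks and the ortholog gene pairing is known by construction.
    """
    species = cfg.species
    n_genes = cfg.genes_per_species
    unit = cfg.spacer_len + cfg.exons_per_gene * cfg.exon_len + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_len
    body_len = cfg.spacer_len + n_genes * unit + cfg.tail_len
    body0 = _random_dna(rng, body_len)

    pads = {sp: 10 * i for i, sp in enumerate(species)}
    bodies = {species[0]: body0}
    for sp in species[1:]:
        bodies[sp] = _mutate(rng, body0, cfg.flank_divergence)

    genomes: Dict[str, GenomeRef] = {}
    genes: Dict[str, List[GeneModel]] = {}
    for sp in species:
        pad = pads[sp]
        chrom_seq = "".join(_random_dna(rng, pad)) + "".join(bodies[sp])
        genomes[sp] = GenomeRef(species_code=sp, chroms={"chr1": chrom_seq})
        models = []
        for i in range(n_genes):
            _, exons = _gene_layout(cfg, i)
            strand = _GENE_STRANDS[i % len(_GENE_STRANDS)]
            gm = GeneModel(
                gene_id=f"{sp}_g{i}",
                symbol=f"G{i}",
                chrom="chr1",
                strand=strand,
                transcripts={f"{sp}_g{i}_t1": [(s + pad, e + pad) for s, e in exons]},
            )
            if i == 5:  # the UTR-carrying gene
                e0, e_last = exons[0], exons[-1]
                gm.utr5 = [(e0[0] + pad, e0[0] + 30 + pad)]
                gm.utr3 = [(e_last[1] - 30 + pad, e_last[1] + pad)]
            models.append(gm)
        genes[sp] = models

    gene_pairs: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    maps: Dict[Tuple[str, str], CoordinateMap] = {}
    for a, b in itertools.combinations(species, 2):
        gene_pairs[(a, b)] = [
            (f"{a}_g{i}", f"{b}_g{i}") for i in range(n_genes)
        ]
        maps[(a, b)] = CoordinateMap(
            blocks=[
                MapBlock("chr1", pads[a], pads[a] + body_len,
                         "chr1", pads[b], pads[b] + body_len, "+")
            ]
        )
        maps[(b, a)] = CoordinateMap(
            blocks=[
                MapBlock("chr1", pads[b], pads[b] + body_len,
                         "chr1", pads[a], pads[a] + body_len, "+")
            ]
        )
    return genomes, genes, gene_pairs, maps, body0


def _plant_truth_circs(cfg: FixtureConfig, rng: np.random.Generator) -> List[TruthCirc]:
    """Define the planted circRNA set on the shared gene layout."""
    species = list(cfg.species)
    pads = {sp: 10 * i for i, sp in enumerate(species)}
    tissues = list(cfg.tissues)
    inds = [f"ind{j + 1}" for j in range(cfg.individuals_per_tissue)]

    def coords(start: int, end: int, sp_list: Sequence[str]) -> Dict[str, Tuple[str, int, int]]:
        return {sp: ("chr1", start + pads[sp], end + pads[sp]) for sp in sp_list}

    def all_tissues() -> Dict[str, Set[str]]:
        return {t: set(inds) for t in tissues}

    def random_expressing() -> Dict[str, Set[str]]:
        n_t = int(rng.integers(3, 7))
        chosen = sorted(rng.choice(len(tissues), size=n_t, replace=False))
        out = {}
        for ti in chosen:
            n_i = int(rng.integers(1, len(inds) + 1))
            picked = sorted(rng.choice(len(inds), size=n_i, replace=False))
            out[tissues[ti]] = {inds[j] for j in picked}
        return out

    ex = {i: _gene_layout(cfg, i)[1] for i in range(cfg.genes_per_species)}
    truth: List[TruthCirc] = []

    # g0: two exonic ortholog circles shared by every species
    truth.append(
        TruthCirc(
            "g0.c1", 0, _GENE_STRANDS[0], "exonic", True, species, "G1",
            coords(ex[0][1][0], ex[0][2][1], species),
            expressing=all_tissues(), role="housekeeping;mirna_host;rbp_host",
        )
    )
    truth.append(
        TruthCirc(
            "g0.c2", 0, _GENE_STRANDS[0], "exonic", None, species, "G2",
            coords(ex[0][2][0], ex[0][3][1], species),
            expressing={tissues[0]: set(inds)}, role="one_tissue",
        )
    )
    # g1 (minus strand): exonic ortholog circle, co-expressed with its host mRNA
    truth.append(
        TruthCirc(
            "g1.c1", 1, _GENE_STRANDS[1], "exonic", True, species, "G3",
            coords(ex[1][1][0], ex[1][2][1], species),
            expressing={
                tissues[0]: set(inds), tissues[2]: set(inds[:2]),
                tissues[4]: set(inds[:1]), tissues[3]: set(inds),
                tissues[5]: set(inds[:2]),
            },
            role="coexpressed;rbp_host",
        )
    )
    # g2: exonic circle with a repeat planted in its upstream flanking intron
    truth.append(
        TruthCirc(
            "g2.c1", 2, _GENE_STRANDS[2], "exonic", False, species[:1], None,
            coords(ex[2][1][0], ex[2][2][1], species[:1]),
            expressing=random_expressing(), role="repeat_flank",
        )
    )
    # g3: intronic circle inside intron 2
    intron = (ex[3][1][1], ex[3][2][0])
    truth.append(
        TruthCirc(
            "g3.c1", 3, _GENE_STRANDS[3], "intronic", True, species[:1], None,
            coords(intron[0] + 10, intron[0] + 70, species[:1]),
            expressing=random_expressing(), role="",
        )
    )
    # g4: antisense circle (opposite strand of its host)
    anti_strand = "-" if _GENE_STRANDS[4] == "+" else "+"
    truth.append(
        TruthCirc(
            "g4.c1", 4, anti_strand, "antisense", True, species[:1], None,
            coords(ex[4][1][0], ex[4][2][1], species[:1]),
            expressing=random_expressing(), role="",
        )
    )
    # g5: a 5'-UTR circle and a 3'-UTR circle
    truth.append(
        TruthCirc(
            "g5.c1", 5, _GENE_STRANDS[5], "5utr", None, species[:1], None,
            coords(ex[5][0][0] + 10, ex[5][2][1], species[:1]),
            expressing=random_expressing(), role="",
        )
    )
    truth.append(
        TruthCirc(
            "g5.c2", 5, _GENE_STRANDS[5], "3utr", None, species[:1], None,
            coords(ex[5][1][0], ex[5][3][1] - 5, species[:1]),
            expressing=random_expressing(), role="",
        )
    )
    # g6: exonic circle conserved in the first two species only
    truth.append(
        TruthCirc(
            "g6.c1", 6, _GENE_STRANDS[6], "exonic", True, species[:2], "G4",
            coords(ex[6][1][0], ex[6][2][1], species[:2]),
            expressing=random_expressing(), role="",
        )
    )
    # intergenic circle in the tail region
    unit = cfg.spacer_len + cfg.exons_per_gene * cfg.exon_len + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_len
    tail_start = cfg.spacer_len + cfg.genes_per_species * unit
    truth.append(
        TruthCirc(
            "ig.c1", None, "+", "intergenic", None, species[:1], None,
            coords(tail_start + 100, tail_start + 250, species[:1]),
            expressing=random_expressing(), role="",
        )
    )
    return truth


def simulate_circ_calls(
    cfg: FixtureConfig,
    truth: Sequence[TruthCirc],
    rng: np.random.Generator,
) -> Tuple[Dict[str, List[Sample]], Dict[str, List[BsjCall]], Dict[str, Set[str]]]:
    """Per-species sample sheets, four-tool BSJ call tables and the literal
    consensus truth table.

    Each tool detects each (circle, expressing sample) independently with
    its sensitivity; detected calls carry ``1 + Poisson(mean - 1)`` reads.
    Decoy single-tool, single-read calls (the detector false-positive mode
    the two-tool filter targets) are injected at ``decoy_rate`` per truth
    circle per sample.  The returned truth table applies the
    ">= 2 tools and >= 2 total reads" filter literally, call by call.
    """
    samples: Dict[str, List[Sample]] = {}
    calls: Dict[str, List[BsjCall]] = {}
    expected: Dict[str, Set[str]] = {}
    unit = cfg.spacer_len + cfg.exons_per_gene * cfg.exon_len + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_len
    tail_start = cfg.spacer_len + cfg.genes_per_species * unit

    for si, sp in enumerate(cfg.species):
        sp_samples = []
        for tissue in cfg.tissues:
            for j in range(cfg.individuals_per_tissue):
                sp_samples.append(
                    Sample(
                        sample_id=f"{sp}_{tissue}_ind{j + 1}",
                        species_code=sp,
                        tissue=tissue,
                        individual=f"ind{j + 1}",
                        mapped_fragments=int(1_000_000 + rng.integers(0, 100_000)),
                    )
                )
        samples[sp] = sp_samples
        sp_truth = [t for t in truth if sp in t.species]
        sp_calls: List[BsjCall] = []
        for t in sp_truth:
            chrom, start, end = t.coords[sp]
            for s in sp_samples:
                if s.individual not in t.expressing.get(s.tissue, set()):
                    continue
                for tool in TOOLS:
                    if rng.random() >= cfg.tool_sensitivity.get(tool, 0.0):
                        continue
                    reads = 1 + int(rng.poisson(max(cfg.mean_bsj_reads - 1, 0.0)))
                    sp_calls.append(
                        BsjCall(s.sample_id, tool, chrom, start, end, t.strand, reads)
                    )
        # decoys: unique low-evidence single-tool calls in the tail region
        pad = 10 * si
        for s in sp_samples:
            n_decoys = int(rng.poisson(cfg.decoy_rate * max(len(sp_truth), 1)))
            for _ in range(n_decoys):
                start = pad + tail_start + 300 + int(rng.integers(0, cfg.tail_len - 1500))
                tool = TOOLS[int(rng.integers(0, len(TOOLS)))]
                sp_calls.append(
                    BsjCall(s.sample_id, tool, "chr1", start, start + 150, "+", 1)
                )
        calls[sp] = sp_calls

        # literal application of the consensus filter, call by call
        by_locus: Dict[str, Dict[str, Dict[str, int]]] = {}
        for c in sp_calls:
            per = by_locus.setdefault(c.locus_key, {}).setdefault(c.sample_id, {})
            per[c.tool] = max(per.get(c.tool, 0), c.bsj_reads)
        surviving = set()
        for lk, per_sample in by_locus.items():
            tools = {t for d in per_sample.values() for t in d}
            total = sum(max(d.values()) for d in per_sample.values())
            if len(tools) >= 2 and total >= 2:
                surviving.add(lk)
        expected[sp] = surviving
    return samples, calls, expected


def simulate_expression(
    cfg: FixtureConfig,
    truth: Sequence[TruthCirc],
    samples: Sequence[Sample],
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[Tuple[str, str]], List[Tuple[str, str]]]:
    """First-species expression matrices with planted statistical structure.

    Returns (circ matrix, joint circ+mRNA matrix, planted co-expressed
    pairs, planted uncorrelated pairs).  Housekeeping circles are exactly
    uniform (tau = 0); one-tissue circles are nonzero in a single tissue
    (tau = 1); each co-expressed (circle, mRNA) pair shares a latent
    per-tissue profile with small multiplicative noise, giving population
    correlation >= 0.9 over tissue means.
    """
    sp = cfg.species[0]
    sample_ids = [s.sample_id for s in samples]
    tissue_of = {s.sample_id: s.tissue for s in samples}
    tissues = list(cfg.tissues)
    sp_truth = [t for t in truth if sp in t.species]

    def blank() -> Dict[str, float]:
        return {sid: 0.0 for sid in sample_ids}

    circ_rows: Dict[str, Dict[str, float]] = {}
    coexpressed: List[Tuple[str, str]] = []
    uncorrelated: List[Tuple[str, str]] = []
    latent: Dict[str, Dict[str, float]] = {}  # template -> tissue -> level

    for t in sp_truth:
        key = t.key(sp)
        row = blank()
        if "housekeeping" in t.role:
            for sid in sample_ids:
                row[sid] = 10.0
        elif "one_tissue" in t.role:
            only = next(iter(t.expressing))
            for sid in sample_ids:
                row[sid] = 8.0 if tissue_of[sid] == only else 0.0
        elif "coexpressed" in t.role:
            prof = {ti: float(rng.lognormal(1.0, 0.8)) for ti in tissues}
            latent[t.template_id] = prof
            for sid in sample_ids:
                row[sid] = 5.0 * prof[tissue_of[sid]] * float(
                    1.0 + rng.normal(0.0, 0.03)
                )
        else:
            levels = {ti: float(rng.uniform(2.0, 8.0)) for ti in t.expressing}
            for sid in sample_ids:
                s_t = tissue_of[sid]
                samp = next(s for s in samples if s.sample_id == sid)
                if samp.individual in t.expressing.get(s_t, set()):
                    row[sid] = levels[s_t] * float(1.0 + rng.normal(0.0, 0.05))
        circ_rows[key] = row

    mrna_rows: Dict[str, Dict[str, float]] = {}
    for i in range(cfg.genes_per_species):
        gid = f"{sp}_g{i}"
        row = blank()
        if i == 1:  # partner of the planted co-expressed circle
            prof = latent.get("g1.c1")
            if prof is not None:
                for sid in sample_ids:
                    row[sid] = 3.0 * prof[tissue_of[sid]] * float(
                        1.0 + rng.normal(0.0, 0.03)
                    )
                circ = next(t for t in sp_truth if t.template_id == "g1.c1")
                coexpressed.append((circ.key(sp), gid))
        else:
            prof = {ti: float(rng.lognormal(1.0, 0.8)) for ti in tissues}
            for sid in sample_ids:
                row[sid] = prof[tissue_of[sid]] * float(1.0 + rng.normal(0.0, 0.05))
        mrna_rows[gid] = row

    # planted null pairs: a tissue-varying circle against independent mRNAs
    varying = [t for t in sp_truth if "coexpressed" in t.role]
    if varying:
        ck = varying[0].key(sp)
        for i in (2, 3, 4):
            uncorrelated.append((ck, f"{sp}_g{i}"))

    circ_df = pd.DataFrame.from_dict(circ_rows, orient="index")[sample_ids]
    circ_df = circ_df.clip(lower=0.0)
    circ_df.index.name = "id"
    joint = pd.concat(
        [circ_df, pd.DataFrame.from_dict(mrna_rows, orient="index")[sample_ids]]
    ).clip(lower=0.0)
    joint.index.name = "id"
    return circ_df, joint, coexpressed, uncorrelated


def _plant_mirna_and_peaks(
    cfg: FixtureConfig,
    truth: Sequence[TruthCirc],
    genomes: Dict[str, GenomeRef],
    rng: np.random.Generator,
) -> Tuple[
    Dict[str, str], List[Tuple[str, str, int]], List[BedInterval], Set[Tuple[str, str]]
]:
    """Plant an 8mer seed site and CLIP peaks; return miRNAs, site truth,
    peaks and the expected (circ, RBP) edge set."""
    sp = cfg.species[0]
    genome = genomes[sp]
    chrom_list = list(genome.chroms["chr1"])

    mirnas = {
        "sim-miR-1": "".join(_random_dna(rng, 22)),
        "sim-miR-2": "".join(_random_dna(rng, 22)),
    }
    host = next(t for t in truth if "mirna_host" in t.role)
    chrom, start, end = host.coords[sp]
    seed27 = mirnas["sim-miR-1"][1:8]
    site = reverse_complement(seed27) + "A"  # 8mer target site
    site_genome_pos = start + 20  # inside the circle's first cirexon
    chrom_list[site_genome_pos : site_genome_pos + 8] = list(site)
    genome.chroms["chr1"] = "".join(chrom_list)
    planted_sites = [(host.key(sp), "sim-miR-1", 20)]

    peaks: List[BedInterval] = []
    rbp_hosts = [t for t in truth if "rbp_host" in t.role and sp in t.species]
    rbp_names = ("PTBP1", "U2AF2")
    for t, rbp in zip(rbp_hosts, rbp_names):
        c, s, e = t.coords[sp]
        offset = 200 if rbp == "PTBP1" else -300
        peaks.append(BedInterval(c, s + offset, s + offset + 50, rbp, 100.0, "."))
    # a far-away negative peak (> 1 kb from every planted BSJ)
    unit = cfg.spacer_len + cfg.exons_per_gene * cfg.exon_len + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_len
    far = cfg.spacer_len + cfg.genes_per_species * unit + cfg.tail_len - 120
    peaks.append(BedInterval("chr1", far, far + 50, "ELAVL1", 100.0, "."))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.name))

    # geometric edge truth: a peak within 1 kb of either BSJ coordinate of
    # any planted circle makes an edge (neighbouring circles included)
    expected_edges: Set[Tuple[str, str]] = set()
    for t in truth:
        if sp not in t.species:
            continue
        c, s, e = t.coords[sp]
        for pk in peaks:
            if pk.chrom != c:
                continue
            for point in (s, e):
                if pk.start < point + 1000 and point - 1000 < pk.end:
                    expected_edges.add((t.key(sp), pk.name))
    return mirnas, planted_sites, peaks, expected_edges


def _term_table(cfg: FixtureConfig) -> pd.DataFrame:
    sp = cfg.species[0]
    rows = []
    for i in range(cfg.genes_per_species):
        rows.append({"gene_id": f"{sp}_g{i}", "term_id": "GO:0000001" if i < 5 else "GO:0000002"})
        if i % 2 == 0:
            rows.append({"gene_id": f"{sp}_g{i}", "term_id": "KEGG:hsa04010"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def generate_bundle(cfg: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Generate the complete fixture bundle from one seed."""
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    genomes, genes, gene_pairs, maps, _body = simulate_species_set(cfg, rng)
    truth = _plant_truth_circs(cfg, rng)
    mirnas, planted_sites, peaks, rbp_edges = _plant_mirna_and_peaks(
        cfg, truth, genomes, rng
    )
    samples, calls, expected = simulate_circ_calls(cfg, truth, rng)
    circ_expr, joint_expr, coexp, uncorr = simulate_expression(
        cfg, truth, samples[cfg.species[0]], rng
    )

    repeats: Dict[str, List[BedInterval]] = {}
    rep_host = next(t for t in truth if "repeat_flank" in t.role)
    gi = rep_host.gene_index
    _, exons = _gene_layout(cfg, gi)
    for i, sp in enumerate(cfg.species):
        pad = 10 * i
        # inside the intron upstream of the circle's start (between exons 1, 2)
        rep_start = exons[0][1] + 10 + pad
        repeats[sp] = [
            BedInterval("chr1", rep_start, rep_start + 30, cfg.repeat_name, 0.0, ".")
        ]
    return FixtureBundle(
        cfg=cfg,
        genomes=genomes,
        genes=genes,
        gene_pairs=gene_pairs,
        maps=maps,
        repeats=repeats,
        truth_circs=truth,
        samples=samples,
        calls=calls,
        expected_consensus=expected,
        circ_expr=circ_expr,
        joint_expr=joint_expr,
        coexpressed_pairs=coexp,
        uncorrelated_pairs=uncorr,
        mirnas=mirnas,
        planted_seed_sites=planted_sites,
        clip_peaks=peaks,
        planted_rbp_edges=rbp_edges,
        term_table=_term_table(cfg),
    )
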