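"""Consensus circRNA calling from multi-detector BSJ evidence.

Detectors (CIRI2, DCC, find_circ, CIRCexplorer2 or any configured set) each
emit per-sample BSJ calls.  A locus is retained as a consensus circRNA when
it was detected by at least ``min_tools`` distinct tools and supported by at
least ``min_reads`` independent BSJ reads.  Within a sample, the read count
for a locus is the *maximum* over tools — two detectors looking at the same
library see the same fragments, so summing would double-count; the maximum
is the largest set of distinct junction fragments any one tool evidenced.

Expression is quantified as FPM: back-spliced junction reads per million
mapped fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .core import BsjCall, CircRecord, Sample, parse_locus_key, samples_by_id


@dataclass
class ConsensusConfig:
    """Thresholds and aggregation rules for consensus calling.

    min_tools
        Minimum number of distinct detection tools across all samples.
    min_reads
        Minimum supporting BSJ reads.  Applied to the total over samples by
        default; with ``per_sample_reads=True`` at least one single sample
        must reach it instead.
    coordinate_slack
        Maximum coordinate disagreement (bp, per endpoint) merged into one
        locus.  0 means detectors must agree exactly.
    """

    min_tools: int = 2
    min_reads: int = 2
    coordinate_slack: int = 0
    per_sample_reads: bool = False

    def __post_init__(self) -> None:
        if self.min_tools < 1:
            raise ValueError("min_tools must be >= 1")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.coordinate_slack < 0:
            raise ValueError("coordinate_slack must be >= 0")


def compute_fpm(bsj_reads: int, mapped_fragments: int) -> float:
    """BSJ reads per million mapped fragments."""
    if mapped_fragments <= 0:
        raise ValueError(f"mapped_fragments must be positive, got {mapped_fragments}")
    if bsj_reads < 0:
        raise ValueError(f"bsj_reads must be >= 0, got {bsj_reads}")
    return bsj_reads / (mapped_fragments / 1e6)


def _cluster_slack(
    keys: List[Tuple[str, int, int, str]], slack: int
) -> Dict[Tuple[str, int, int, str], Tuple[str, int, int, str]]:
    """Map each locus to a cluster representative under +/- slack agreement.

    Loci on the same chrom/strand whose start and end both differ by at most
    ``slack`` are chained into one cluster; the representative is the
    smallest (start, end) member.  With slack 0 this is the identity.
    """
    rep: Dict[Tuple[str, int, int, str], Tuple[str, int, int, str]] = {}
    by_cs: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for chrom, start, end, strand in keys:
        by_cs.setdefault((chrom, strand), []).append((start, end))
    for (chrom, strand), ivs in by_cs.items():
        ivs = sorted(set(ivs))
        cluster: List[Tuple[int, int]] = []
        for iv in ivs:
            if cluster and (
                abs(iv[0] - cluster[-1][0]) <= slack
                and abs(iv[1] - cluster[-1][1]) <= slack
            ):
                cluster.append(iv)
            else:
                for member in cluster:
                    rep[(chrom, *member, strand)] = (chrom, *cluster[0], strand)
                cluster = [iv]
        for member in cluster:
            rep[(chrom, *member, strand)] = (chrom, *cluster[0], strand)
    return rep


def merge_calls(
    calls: Sequence[BsjCall],
    samples: Sequence[Sample],
    cfg: ConsensusConfig | None = None,
) -> List[CircRecord]:
    """Merge per-tool, per-sample BSJ calls into consensus circRNA records.

    Returns one :class:`CircRecord` per surviving locus, sorted by
    (chrom, start, end, strand).  Raises on a call whose sample_id is not in
    the sample sheet.
    """
    cfg = cfg or ConsensusConfig()
    sample_map = samples_by_id(samples)
    species = {s.species_code for s in samples}

    keys = []
    for c in calls:
        if c.sample_id not in sample_map:
            raise ValueError(f"unknown sample_id {c.sample_id!r} in calls")
        keys.append((c.chrom, c.start, c.end, c.strand))
    if cfg.coordinate_slack > 0:
        rep = _cluster_slack(keys, cfg.coordinate_slack)
    else:
        rep = {k: k for k in keys}

    # locus -> sample -> tool -> max reads over that tool's (possibly
    # slack-merged) calls
    evidence: Dict[Tuple[str, int, int, str], Dict[str, Dict[str, int]]] = {}
    for c in calls:
        locus = rep[(c.chrom, c.start, c.end, c.strand)]
        per_tool = evidence.setdefault(locus, {}).setdefault(c.sample_id, {})
        per_tool[c.tool] = max(per_tool.get(c.tool, 0), c.bsj_reads)

    records: List[CircRecord] = []
    for locus in sorted(evidence):
        chrom, start, end, strand = locus
        per_sample = evidence[locus]
        tools = {t for tools_ in per_sample.values() for t in tools_}
        sample_reads = {
            sid: max(tool_reads.values()) for sid, tool_reads in per_sample.items()
        }
        total = sum(sample_reads.values())
        if len(tools) < cfg.min_tools:
            continue
        if cfg.per_sample_reads:
            if max(sample_reads.values(), default=0) < cfg.min_reads:
                continue
        elif total < cfg.min_reads:
            continue
        sp = sample_map[next(iter(per_sample))].species_code
        if len(species) == 1:
            sp = next(iter(species))
        records.append(
            CircRecord(
                species_code=sp,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                tools=tools,
                sample_reads=sample_reads,
            )
        )
    return records


def expression_matrix(
    records: Sequence[CircRecord], samples: Sequence[Sample]
) -> pd.DataFrame:
    """Per-sample FPM matrix (rows = locus keys, columns = sample ids).

    Absent (locus, sample) pairs are 0.  Also fills each record's ``fpm``
    mapping in place.
    """
    sample_map = samples_by_id(samples)
    sample_ids = [s.sample_id for s in samples]
    data = {}
    for rec in records:
        row = {}
        for sid in sample_ids:
            reads = rec.sample_reads.get(sid, 0)
            row[sid] = compute_fpm(reads, sample_map[sid].mapped_fragments)
        rec.fpm = row
        data[rec.locus_key] = row
    df = pd.DataFrame.from_dict(data, orient="index", columns=sample_ids)
    if df.empty:
        df = pd.DataFrame(index=pd.Index([], dtype=str), columns=sample_ids, dtype=float)
    df.index.name = "id"
    return df.astype(float)


def records_to_frame(records: Sequence[CircRecord]) -> pd.DataFrame:
    """Tabular summary of consensus records (one row per locus)."""
    rows = []
    for r in records:
        rows.append(
            {
                "circ_id": r.circ_id or "",
                "species_code": r.species_code,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "locus_key": r.locus_key,
                "tools": ",".join(sorted(r.tools)),
                "n_tools": len(r.tools),
                "total_bsj_reads": r.total_bsj_reads,
                "host_gene": r.host_gene or "",
                "host_orientation": r.host_orientation or "",
                "subclass": r.subclass or "",
                "non_repeat": "" if r.non_repeat is None else str(r.non_repeat),
                "mcs": "" if r.mcs is None else f"{r.mcs:.6g}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "circ_id", "species_code", "chrom", "start", "end", "strand",
            "locus_key", "tools", "n_tools", "total_bsj_reads", "host_gene",
            "host_orientation", "subclass", "non_repeat", "mcs",
        ],
    )


def frame_to_records(df: pd.DataFrame) -> List[CircRecord]:
    """Rebuild CircRecords from a TSV written by :func:`records_to_frame`."""
    def _clean(value) -> str:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return ""
        return str(value)

    out = []
    for r in df.itertuples(index=False):
        chrom, start, end, strand = parse_locus_key(r.locus_key)
        tools_str = _clean(getattr(r, "tools", ""))
        rec = CircRecord(
            species_code=r.species_code,
            chrom=chrom,
            start=int(start),
            end=int(end),
            strand=strand,
            tools=set(tools_str.split(",")) if tools_str else set(),
        )
        rec.circ_id = _clean(getattr(r, "circ_id", "")) or None
        rec.host_gene = _clean(getattr(r, "host_gene", "")) or None
        rec.host_orientation = _clean(getattr(r, "host_orientation", "")) or None
        rec.subclass = _clean(getattr(r, "subclass", "")) or None
        mcs = _clean(getattr(r, "mcs", ""))
        rec.mcs = float(mcs) if mcs else None
        out.append(rec)
    return out
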