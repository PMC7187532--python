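"""Multiple Conservation Score (MCS) and companion expression metrics.

MCS = N_s + N_t x N_i.  The integer part N_s is the circRNA's ortholog
count across species (group size - 1).  The decimal part comes from a
two-layer hierarchical expression tree over the species' samples:

* tissue layer — one node per tissue; marked when any individual in that
  tissue expresses the circle;
* individual layer — one node per (tissue, individual); marked when any of
  that individual's samples exceeds the expression threshold.

N_t = (# marked tissue nodes) / (# tissue nodes).
N_i = (# marked tissue nodes + # marked individual nodes)
      / (2 x # individuals belonging to marked tissues).

Both lie in [0, 1], so MCS in [N_s, N_s + 1]; the decimal part encodes how
broadly and consistently the circle is expressed, the integer part how many
species share it.

Companion metrics: the tissue-specificity index tau (Yanai) and the
junction ratio 2*BSJ / (2*BSJ + linear), the CIRI-family convention for the
circular fraction of junction-spanning evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import CircRecord, Sample


@dataclass
class McsProfile:
    n_s: int
    n_t: float
    n_i: float

    def __post_init__(self) -> None:
        if self.n_s < 0:
            raise ValueError("N_s must be >= 0")
        for name, v in (("N_t", self.n_t), ("N_i", self.n_i)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")

    @property
    def mcs(self) -> float:
        return self.n_s + self.n_t * self.n_i


class ExpressionTree:
    """Two-layer (tissue / individual) expression hierarchy for one species."""

    def __init__(
        self,
        expr: pd.DataFrame,
        samples: Sequence[Sample],
        expressed_threshold: float = 0.0,
    ):
        """Mark nodes from a per-sample FPM matrix.

        An individual node (tissue, individual) is marked for a circle when
        any of its samples has FPM strictly above ``expressed_threshold``
        (default 0: any supported BSJ read counts as expression).
        """
        if expressed_threshold < 0:
            raise ValueError("expressed_threshold must be >= 0")
        by_id = {}
        for s in samples:
            if not s.tissue or not s.individual:
                raise ValueError(f"sample {s.sample_id}: missing tissue/individual")
            by_id[s.sample_id] = s
        unknown = [c for c in expr.columns if c not in by_id]
        if unknown:
            raise ValueError(f"expression columns not in sample sheet: {unknown}")

        self.tissues: List[str] = sorted({s.tissue for s in samples})
        self.individuals: Dict[str, Set[str]] = {}
        for s in samples:
            self.individuals.setdefault(s.tissue, set()).add(s.individual)

        self._marked_individuals: Dict[str, Set[Tuple[str, str]]] = {}
        for circ in expr.index:
            row = expr.loc[circ]
            marked: Set[Tuple[str, str]] = set()
            for sid in expr.columns:
                if row[sid] > expressed_threshold:
                    s = by_id[sid]
                    marked.add((s.tissue, s.individual))
            self._marked_individuals[circ] = marked

    def marked_individuals(self, circ: str) -> Set[Tuple[str, str]]:
        return self._marked_individuals.get(circ, set())

    def marked_tissues(self, circ: str) -> Set[str]:
        return {t for t, _ in self.marked_individuals(circ)}

    @property
    def n_tissue_nodes(self) -> int:
        return len(self.tissues)


def build_expression_tree(
    expr: pd.DataFrame,
    samples: Sequence[Sample],
    expressed_threshold: float = 0.0,
) -> ExpressionTree:
    """Construct the hierarchical expression tree (see :class:`ExpressionTree`)."""
    return ExpressionTree(expr, samples, expressed_threshold)


def compute_nt(tree: ExpressionTree, circ: str) -> float:
    """Fraction of tissue-layer nodes expressing the circle."""
    if tree.n_tissue_nodes == 0:
        raise ValueError("expression tree has no tissues")
    return len(tree.marked_tissues(circ)) / tree.n_tissue_nodes


def compute_ni(tree: ExpressionTree, circ: str) -> float:
    """Expression consistency within expressing tissues.

    (# marked tissue nodes + # marked individual nodes) over
    (2 x # individuals in the expressing tissues).  Undefined (error) for a
    circle expressed nowhere.
    """
    tissues = tree.marked_tissues(circ)
    if not tissues:
        raise ValueError(f"N_i undefined: {circ!r} is expressed in no tissue")
    marked_nodes = len(tissues) + len(tree.marked_individuals(circ))
    denom = 2 * sum(len(tree.individuals[t]) for t in tissues)
    return marked_nodes / denom


def compute_mcs(n_s: int, tree: ExpressionTree, circ: str) -> McsProfile:
    """MCS profile for one circle; unexpressed circles get decimal part 0."""
    n_t = compute_nt(tree, circ)
    n_i = compute_ni(tree, circ) if n_t > 0 else 0.0
    return McsProfile(n_s=n_s, n_t=n_t, n_i=n_i)


def score_records(
    records: Sequence[CircRecord],
    tree: ExpressionTree,
    n_s: Dict[str, int],
    count_species: bool = False,
) -> Dict[str, McsProfile]:
    """Compute MCS for every record and store it on the record.

    ``n_s`` maps locus keys to ortholog counts (group size - 1); missing
    keys default to 0.  ``count_species=True`` switches the integer part to
    the group size (species count) instead.
    """
    out = {}
    for rec in records:
        base = n_s.get(rec.locus_key, 0)
        if count_species:
            base += 1
        profile = compute_mcs(base, tree, rec.locus_key)
        rec.mcs = profile.mcs
        out[rec.locus_key] = profile
    return out


def tissue_specificity_tau(tissue_means: Sequence[float]) -> float:
    """Yanai's tissue-specificity index tau.

    tau = sum_i (1 - x_i / x_max) / (N - 1) over the per-tissue mean
    expression vector; 0 for uniform expression, 1 for single-tissue.
    """
    x = np.asarray(tissue_means, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression values")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def junction_ratio(bsj_reads: int, linear_junction_reads: int) -> Optional[float]:
    """Circular fraction of junction evidence: 2b / (2b + l).

    Returns None when there is no junction evidence at all.
    """
    if bsj_reads < 0 or linear_junction_reads < 0:
        raise ValueError("read counts must be >= 0")
    if bsj_reads == 0 and linear_junction_reads == 0:
        return None
    return 2 * bsj_reads / (2 * bsj_reads + linear_junction_reads)


def prioritize(
    profiles: Dict[str, McsProfile]
) -> List[Tuple[str, McsProfile]]:
    """Rank circles by MCS descending; ties by N_s descending, locus key."""
    return sorted(
        profiles.items(),
        key=lambda kv: (-kv[1].mcs, -kv[1].n_s, kv[0]),
    )
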