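"""Independent brute-force oracles used by the test suite.

These re-derive expected results by literal enumeration or recursion,
deliberately sharing no code with the implementation they check.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Sequence, Set, Tuple


def consensus_oracle(
    calls: Sequence, min_tools: int = 2, min_reads: int = 2
) -> Dict[Tuple[str, int, int, str], Tuple[Set[str], int]]:
    """Literal application of the two consensus filters.

    Returns surviving locus -> (tool set, total reads), where the per-sample
    read count is the maximum over tools and the total the sum over samples.
    """
    per_locus: Dict[Tuple, Dict[str, Dict[str, int]]] = {}
    for c in calls:
        locus = (c.chrom, c.start, c.end, c.strand)
        sample = per_locus.setdefault(locus, {}).setdefault(c.sample_id, {})
        sample[c.tool] = max(sample.get(c.tool, 0), c.bsj_reads)
    out = {}
    for locus, samples in per_locus.items():
        tools = set()
        total = 0
        for tool_reads in samples.values():
            tools |= set(tool_reads)
            total += max(tool_reads.values())
        if len(tools) >= min_tools and total >= min_reads:
            out[locus] = (tools, total)
    return out


def local_align_oracle(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal local alignment score by exhaustive recursion.

    Considers every pair of substrings and recursively scores every affine-
    gapped alignment between them.  Exponential; only for tiny sequences.
    """

    @lru_cache(maxsize=None)
    def align(sub_a: str, sub_b: str, state: str) -> float:
        # best score aligning all of sub_a against all of sub_b, given the
        # previous column type ('m' = diagonal, 'a'/'b' = gap in a/b)
        if not sub_a and not sub_b:
            return 0.0
        options = []
        if sub_a and sub_b:
            step = match if sub_a[0] == sub_b[0] else mismatch
            options.append(step + align(sub_a[1:], sub_b[1:], "m"))
        if sub_a:  # consume a base of sub_a against a gap
            cost = gap_extend if state == "a" else gap_open + gap_extend
            options.append(cost + align(sub_a[1:], sub_b, "a"))
        if sub_b:
            cost = gap_extend if state == "b" else gap_open + gap_extend
            options.append(cost + align(sub_a, sub_b[1:], "b"))
        return max(options)

    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    best = max(best, align(a[i:k], b[j:l], "m"))
    align.cache_clear()
    return best


def circular_orf_candidates(seq: str, max_laps: int = 3) -> List[Tuple[int, int, bool]]:
    """All ATG->stop reads on a circular sequence by position-wise scanning.

    Returns (start, length, found_stop) for every ATG start, walking codons
    over the concatenated laps.
    """
    stops = {"TAA", "TAG", "TGA"}
    L = len(seq)
    cap = max_laps * L
    tape = seq * (max_laps + 1)
    out = []
    for p in range(L):
        if tape[p : p + 3] != "ATG":
            continue
        q = p
        found = False
        while q + 3 <= p + cap:
            if tape[q : q + 3] in stops:
                out.append((p, q + 3 - p, True))
                found = True
                break
            q += 3
        if not found:
            out.append((p, cap - cap % 3, False))
    return out


def best_group_score_oracle(
    nodes: Sequence[str],
    species: Dict[str, str],
    edges: Dict[Tuple[str, str], float],
) -> float:
    """Maximum summed edge score of a consistent ortholog group.

    Exhaustive include/exclude recursion over nodes; a valid group has at
    most one node per species, >= 2 members, and every member incident to at
    least one retained edge.
    """
    nodes = list(nodes)

    def edge(u: str, v: str) -> float:
        return edges.get((u, v), edges.get((v, u), 0.0))

    best = 0.0
    n = len(nodes)
    for mask in range(1, 1 << n):
        chosen = [nodes[i] for i in range(n) if mask >> i & 1]
        if len(chosen) < 2:
            continue
        sp = [species[c] for c in chosen]
        if len(set(sp)) != len(sp):
            continue
        score = 0.0
        touched = set()
        for i, u in enumerate(chosen):
            for v in chosen[i + 1 :]:
                w = edge(u, v)
                if w:
                    score += w
                    touched |= {u, v}
        if touched == set(chosen) and score > best:
            best = score
    return best


def hypergeom_tail_mc(
    universe: int, term: int, draw: int, threshold: int,
    n_draws: int, rng,
) -> float:
    """Monte-Carlo estimate of P(X >= threshold) for a hypergeometric draw."""
    hits = 0
    pool = [1] * term + [0] * (universe - term)
    import numpy as np

    pool = np.array(pool)
    for _ in range(n_draws):
        take = rng.choice(pool, size=draw, replace=False)
        if take.sum() >= threshold:
            hits += 1
    return hits / n_draws
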