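"""End-to-end pipeline: simulate -> merge -> classify -> conserve -> mcs -> network.

Each stage writes its tabular output plus a small JSON report (record
counts in/out and the parameters used).  All randomness flows from one
seed, so a rerun with the same configuration produces identical files.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import classify as ck_classify
from . import conservation as ck_cons
from . import consensus as ck_consensus
from . import mcs as ck_mcs
from . import network as ck_net
from .core import CircRecord
from .simulate import FixtureConfig, generate_bundle


def _report(outdir: Path, stage: str, payload: Dict) -> None:
    path = outdir / f"report_{stage}.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_demo(outdir, seed: int = 7, cfg: Optional[FixtureConfig] = None) -> Dict:
    """Run the full pipeline on generated fixtures; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or FixtureConfig(seed=seed)
    bundle = generate_bundle(cfg)
    fixture_dir = outdir / "fixtures"
    bundle.write(fixture_dir)
    species = list(cfg.species)
    _report(outdir, "simulate", {
        "species": species,
        "n_truth_circs": len(bundle.truth_circs),
        "seed": cfg.seed,
    })

    # ---- merge ------------------------------------------------------------
    merge_cfg = ck_consensus.ConsensusConfig()
    records: Dict[str, List[CircRecord]] = {}
    expr: Dict[str, pd.DataFrame] = {}
    for sp in species:
        recs = ck_consensus.merge_calls(bundle.calls[sp], bundle.samples[sp], merge_cfg)
        records[sp] = recs
        expr[sp] = ck_consensus.expression_matrix(recs, bundle.samples[sp])
        ck_consensus.records_to_frame(recs).to_csv(
            outdir / f"circles_{sp}.tsv", sep="\t", index=False
        )
        expr[sp].to_csv(outdir / f"fpm_{sp}.tsv", sep="\t")
    _report(outdir, "merge", {
        "min_tools": merge_cfg.min_tools,
        "min_reads": merge_cfg.min_reads,
        "calls_in": {sp: len(bundle.calls[sp]) for sp in species},
        "records_out": {sp: len(records[sp]) for sp in species},
    })

    # ---- classify ---------------------------------------------------------
    for sp in species:
        ck_classify.classify_records(records[sp], bundle.genes[sp], bundle.repeats[sp])
    _report(outdir, "classify", {
        "records": {sp: len(records[sp]) for sp in species},
        "subclass_counts": {
            sp: {
                k: int(v)
                for k, v in pd.Series([r.subclass for r in records[sp]])
                .value_counts()
                .sort_index()
                .items()
            }
            for sp in species
        },
    })

    # ---- conserve ---------------------------------------------------------
    rbh_sets = []
    n_candidates = 0
    for a, b in itertools.combinations(species, 2):
        circs_a, circs_b = records[a], records[b]
        candidates = ck_cons.restrict_to_ortholog_genes(
            circs_a, circs_b, bundle.gene_pairs[(a, b)]
        )
        n_candidates += len(candidates)
        genes_a = {g.gene_id: g for g in bundle.genes[a]}
        genes_b = {g.gene_id: g for g in bundle.genes[b]}

        def flanks_for(circs, genes, genome):
            out = {}
            for c in circs:
                if c.host_gene and c.host_gene in genes:
                    try:
                        out[c.locus_key] = ck_cons.extract_bsj_flanks(
                            c, genome, gene=genes[c.host_gene]
                        )
                    except Exception:
                        continue
            return out

        fa = flanks_for(circs_a, genes_a, bundle.genomes[a])
        fb = flanks_for(circs_b, genes_b, bundle.genomes[b])
        boundary = {}
        cmap = bundle.maps.get((a, b))
        if cmap is not None:
            for ca, cb in candidates:
                lifted = ck_cons.liftover_interval(ca.chrom, ca.start, ca.end, cmap)
                boundary[(ca.locus_key, cb.locus_key)] = (
                    lifted is not None
                    and lifted[0] == cb.chrom
                    and lifted[1] == cb.start
                    and lifted[2] == cb.end
                )
        rbh_sets.append(
            ck_cons.reciprocal_best_hits(candidates, fa, fb, boundary_checks=boundary)
        )
    all_records = [r for sp in species for r in records[sp]]
    groups = ck_cons.build_ortholog_groups(rbh_sets, all_circs=all_records)
    group_rows = []
    for gi, g in enumerate(groups):
        for sp, lk in sorted(g.members.items()):
            group_rows.append(
                {"group": f"OG{gi:04d}", "species_code": sp, "locus_key": lk,
                 "n_s": g.n_s, "score": f"{g.score:.3f}"}
            )
    pd.DataFrame(group_rows).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    _report(outdir, "conserve", {
        "candidate_pairs": n_candidates,
        "rbh_pairs": sum(len(s) for s in rbh_sets),
        "groups_multi": sum(1 for g in groups if g.n_s > 0),
        "groups_total": len(groups),
    })

    # ---- mcs --------------------------------------------------------------
    ns = ck_cons.ns_by_locus(groups)
    mcs_rows = []
    for sp in species:
        tree = ck_mcs.build_expression_tree(expr[sp], bundle.samples[sp])
        profiles = ck_mcs.score_records(records[sp], tree, ns)
        genes_by_id = {g.gene_id: g for g in bundle.genes[sp]}
        ck_classify.assign_ids(records[sp], genes_by_id)
        for lk, prof in ck_mcs.prioritize(profiles):
            rec = next(r for r in records[sp] if r.locus_key == lk)
            mcs_rows.append(
                {"circ_id": rec.circ_id, "species_code": sp, "locus_key": lk,
                 "n_s": prof.n_s, "n_t": f"{prof.n_t:.6f}",
                 "n_i": f"{prof.n_i:.6f}", "mcs": f"{prof.mcs:.6f}"}
            )
        ck_consensus.records_to_frame(records[sp]).to_csv(
            outdir / f"classified_{sp}.tsv", sep="\t", index=False
        )
    pd.DataFrame(mcs_rows).to_csv(outdir / "mcs.tsv", sep="\t", index=False)
    _report(outdir, "mcs", {"scored": len(mcs_rows)})

    # ---- network (first species) -----------------------------------------
    sp0 = species[0]
    tissue_expr = ck_net.tissue_mean_expression(bundle.joint_expr, bundle.samples[sp0])
    circ_ids = set(bundle.circ_expr.index)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        coexp = ck_net.coexpression_edges(tissue_expr, circ_ids)
    truth_by_key = {t.key(sp0): t for t in bundle.truth_for_species(sp0)}
    sites = {}
    for lk, t in truth_by_key.items():
        seq = bundle.circ_sequence(sp0, t)
        found = ck_net.mirna_seed_sites(seq, bundle.mirnas)
        if found:
            sites[lk] = found
    sp0_records = [r for r in records[sp0] if r.locus_key in truth_by_key]
    rbp = ck_net.rbp_edges(sp0_records, bundle.clip_peaks)
    net = ck_net.build_network(coexp, circ_ids, sites, rbp)
    ck_net.write_network(net, edges_tsv_path=outdir / "network_edges.tsv")
    calls = ck_net.propagate_function(net, bundle.term_table)
    pd.DataFrame(
        [
            {"circ": c.circ, "term_id": c.term_id, "support": c.support,
             "neighbors": c.neighbors, "p": f"{c.p_value:.6g}", "q": f"{c.q_value:.6g}"}
            for c in calls
        ],
        columns=["circ", "term_id", "support", "neighbors", "p", "q"],
    ).to_csv(outdir / "functions.tsv", sep="\t", index=False)
    ranking = ck_net.rank_interactors(net)
    pd.DataFrame(ranking, columns=["node", "kind", "circ_degree"]).to_csv(
        outdir / "interactors.tsv", sep="\t", index=False
    )
    _report(outdir, "network", {
        "coexpression_edges": len(coexp),
        "mirna_edges": sum(len(v) > 0 for v in sites.values()),
        "rbp_edges": len(rbp),
        "function_calls": len(calls),
    })

    summary = {
        "seed": cfg.seed,
        "species": species,
        "consensus_records": {sp: len(records[sp]) for sp in species},
        "ortholog_groups_multi": sum(1 for g in groups if g.n_s > 0),
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
    }
    _report(outdir, "summary", summary)
    return summary
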