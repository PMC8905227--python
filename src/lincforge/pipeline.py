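"""End-to-end orchestration of the analysis stages with a run manifest.

Stage order: simulate (optional) → classify → filter → coding → feature
summary → differential expression → subgenome homology → co-expression
network → clustering/enrichment/function transfer → amplicon editing scan →
group statistics.  Every stage writes sorted, headered TSV before the next
begins; the manifest records the seed, a config hash, every threshold used
and per-stage record counts, and contains nothing run-dependent beyond
those, so re-running with the same inputs reproduces identical bytes.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classify as mclassify
from . import cluster as mcluster
from . import coding as mcoding
from . import de as mde
from . import editing as mediting
from . import homology as mhomology
from . import network as mnetwork
from . import stats as mstats
from .io import ensure_dir
from .models import FilterParams
from .synthetic import (
    SimulationConfig,
    config_hash,
    generate_amplicons,
    generate_counts,
    generate_genome,
    make_amplicon,
)

DEFAULT_CONFIG = {
    "simulate": True,
    "seed": 1,
    "filter": {"min_length": 200, "min_fpkm": 0.5, "min_gene_distance": 500,
               "allowed_codes": ["u"], "require_est_support": True},
    "de": {"lfc_threshold": 2.0, "alpha": 0.05},
    "homology": {"min_identity": 0.85, "min_coverage": 0.8, "flank_k": 5, "min_shared": 2},
    "network": {"beta": 8, "edge_cutoff": 0.9},
    "cluster": {"k": 10, "preset": "cluster"},
    "editing": {"window_bp": 10, "min_sub_count": 2, "min_reads": 50},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages under one config; returns the manifest dict."""
    cfg = _merge(DEFAULT_CONFIG, config)
    if not cfg.get("simulate"):
        for key in ("genome_fasta", "reference_gtf", "assembled_gtf", "counts_tsv", "design_tsv"):
            if key not in cfg or not Path(cfg[key]).exists():
                raise FileNotFoundError(f"missing required input '{key}' (validated before any stage)")
        raise NotImplementedError("external-input mode wiring is limited to validation; use simulate: true")
    out = ensure_dir(outdir)
    seed = int(cfg["seed"])
    manifest: dict = {
        "tool": "lincforge",
        "version": __version__,
        "seed": seed,
        "stages": {},
    }

    # ---- simulate ----------------------------------------------------------
    sim_cfg = SimulationConfig(seed=seed, **cfg.get("simulation", {}))
    genome = generate_genome(sim_cfg)
    counts = generate_counts(genome)
    simdir = ensure_dir(out / "simulated")
    genome.write(simdir)
    counts.to_tsv(simdir / "counts.tsv")
    counts.design.to_csv(simdir / "design.tsv", sep="\t")
    manifest["config_hash"] = config_hash(sim_cfg)
    manifest["stages"]["simulate"] = {
        "params": {k: v for k, v in sim_cfg.__dict__.items() if k != "design"},
        "n_transcripts": len(genome.assembled),
        "n_genes": len(genome.reference),
        "n_samples": len(counts.sample_ids),
    }

    # ---- classify ----------------------------------------------------------
    assignments, errors = mclassify.assign_class_codes(genome.assembled, genome.reference)
    codes = pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in assignments],
            "class_code": [a.class_code for a in assignments],
            "nearest_gene_id": [a.nearest_gene_id for a in assignments],
            "distance_to_nearest_gene": [a.distance_to_nearest_gene for a in assignments],
        }
    ).sort_values("transcript_id")
    n = _write(codes, out / "class_codes.tsv")
    manifest["stages"]["classify"] = {"n_in": len(genome.assembled), "n_out": n, "n_errors": len(errors)}

    # ---- filter ------------------------------------------------------------
    fpar = cfg["filter"]
    params = FilterParams(
        min_length=fpar["min_length"],
        min_fpkm=fpar["min_fpkm"],
        min_gene_distance=fpar["min_gene_distance"],
        allowed_codes=frozenset(fpar["allowed_codes"]),
        require_est_support=fpar["require_est_support"],
    )
    fpkm = mde.counts_to_fpkm(counts)
    survivors, ledger = mclassify.filter_candidates(
        assignments, genome.assembled, fpkm, params, genome.est_support
    )
    _write(pd.DataFrame({"transcript_id": survivors}), out / "candidates.tsv")
    _write(ledger, out / "filter_ledger.tsv")
    manifest["stages"]["filter"] = {
        "params": {**fpar, "allowed_codes": sorted(fpar["allowed_codes"])},
        "n_in": len(assignments),
        "n_survivors": len(survivors),
        "n_rejected": len(ledger),
    }

    # ---- coding potential --------------------------------------------------
    rng = np.random.default_rng(seed + 7)
    tmap = {t.id: t for t in genome.assembled}
    coding_train = [t.sequence for t in genome.assembled if t.id.endswith(".t1")]
    noncoding_train = [_shuffled(s, rng) for s in coding_train]
    model = mcoding.train_hexamer_model(coding_train, noncoding_train)
    scores = [mcoding.score_coding(tmap[t].sequence, model, transcript_id=t) for t in survivors]
    peptides = {}
    for t in survivors:
        orfs = mcoding.find_orfs(tmap[t].sequence, min_peptide_aa=20)
        if orfs:
            peptides[t] = orfs[0].peptide
    protein_db = {
        f"{t.id}_p": str(orfs0.peptide)
        for t in genome.reference[:20]
        if (orfs0 := next(iter(mcoding.find_orfs(tmap[t.id + ".t1"].sequence, 20)), None))
    }
    hits = mcoding.protein_hits(peptides, protein_db, min_score=60.0)
    hit_ids = mcoding.coding_evidence_flags(hits)
    score_df = pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in scores],
            "orf_coverage": [s.orf_coverage for s in scores],
            "hexamer_log_ratio": [s.hexamer_log_ratio for s in scores],
            "combined_score": [s.combined_score for s in scores],
            "label": [s.label for s in scores],
            "protein_hit": [s.transcript_id in hit_ids for s in scores],
        }
    ).sort_values("transcript_id")
    _write(score_df, out / "coding_scores.tsv")
    lnc_ids = sorted(
        s.transcript_id for s in scores if s.label == "noncoding" and s.transcript_id not in hit_ids
    )
    _write(pd.DataFrame({"transcript_id": lnc_ids}), out / "lncrnas.tsv")
    manifest["stages"]["coding"] = {
        "n_in": len(survivors),
        "n_noncoding": len(lnc_ids),
        "n_protein_hits": int(len(hit_ids)),
    }

    # ---- feature summary ---------------------------------------------------
    lnc_models = [tmap[t] for t in lnc_ids]
    mrna_models = [t for t in genome.assembled if t.id.endswith(".t1")]
    summary, comparisons = mclassify.summarize_features(lnc_models, mrna_models, fpkm)
    _write(summary.sort_values("transcript_id"), out / "feature_summary.tsv")
    _write(comparisons, out / "feature_comparisons.tsv")
    manifest["stages"]["summary"] = {"n_lncrna": len(lnc_models), "n_mrna": len(mrna_models)}

    # ---- differential expression ------------------------------------------
    dcfg = cfg["de"]
    de_frames, sig_lnc, sig_mrna = [], {}, {}
    timepoints = sorted(t for t in counts.design.timepoint_h.unique() if t > 0)
    for geno in sorted(counts.design.genotype.unique()):
        ctrl = counts.samples_where(genotype=geno, timepoint_h=0)
        for tp in timepoints:
            trt = counts.samples_where(genotype=geno, timepoint_h=tp)
            name = f"{geno}_{tp}h_vs_0h"
            res = mde.call_de(
                counts, trt, ctrl, contrast=name,
                lfc_threshold=dcfg["lfc_threshold"], alpha=dcfg["alpha"],
            )
            de_frames.append(mde.de_results_frame(res))
            sig_lnc[name] = {r.feature_id for r in res if r.significant and r.feature_id in set(lnc_ids)}
            sig_mrna[name] = {
                r.feature_id for r in res if r.significant and r.feature_id.endswith(".t1")
            }
    de_all = pd.concat(de_frames, ignore_index=True).sort_values(["contrast", "feature_id"])
    _write(de_all, out / "de_results.tsv")
    del_ids = sorted(set().union(*sig_lnc.values()))
    deg_ids = sorted(set().union(*sig_mrna.values()))
    ratio_df = pd.DataFrame(
        [
            {"feature_class": "lncRNA", "universe": len(lnc_ids), "n_significant": len(del_ids),
             "ratio": len(del_ids) / max(len(lnc_ids), 1)},
            {"feature_class": "mRNA", "universe": len(mrna_models), "n_significant": len(deg_ids),
             "ratio": len(deg_ids) / max(len(mrna_models), 1)},
        ]
    )
    _write(ratio_df, out / "del_ratios.tsv")
    _write(mde.timepoint_overlaps(sig_lnc), out / "del_timepoint_overlaps.tsv")
    manifest["stages"]["de"] = {
        "params": dcfg, "n_contrasts": len(de_frames), "n_del": len(del_ids), "n_deg": len(deg_ids)
    }

    # ---- subgenome homology ------------------------------------------------
    hcfg = cfg["homology"]
    at_seqs = {t: tmap[t].sequence for t in lnc_ids if tmap[t].subgenome == "At"}
    dt_seqs = {t: tmap[t].sequence for t in lnc_ids if tmap[t].subgenome == "Dt"}
    pairs = mhomology.reciprocal_best_pairs(
        at_seqs, dt_seqs, min_identity=hcfg["min_identity"], min_coverage=hcfg["min_coverage"]
    )
    at_order = {c: ids for c, ids in genome.feature_order.items() if c.startswith("A")}
    dt_order = {c: ids for c, ids in genome.feature_order.items() if c.startswith("D")}
    pairs = mhomology.synteny_filter(
        pairs, at_order, dt_order, genome.anchor_partner,
        flank_k=hcfg["flank_k"], min_shared=hcfg["min_shared"],
    )
    pair_df = pd.DataFrame(
        {
            "at_id": [p.at_id for p in pairs],
            "dt_id": [p.dt_id for p in pairs],
            "score": [p.alignment_score for p in pairs],
            "identity": [round(p.identity, 6) for p in pairs],
            "coverage": [round(p.coverage, 6) for p in pairs],
            "syntenic": [p.syntenic for p in pairs],
        }
    ).sort_values("at_id")
    _write(pair_df, out / "homolog_pairs.tsv")
    contrast0 = f"{sorted(counts.design.genotype.unique())[0]}_{timepoints[-1]}h_vs_0h"
    lfc_map = dict(
        de_all.loc[de_all.contrast == contrast0, ["feature_id", "log2_fold_change"]].itertuples(
            index=False, name=None
        )
    )
    syn_pairs = [p for p in pairs if p.syntenic]
    try:
        bias = mhomology.pair_expression_bias(syn_pairs, lfc_map)
    except ValueError:
        bias = {"n_pairs": 0, "note": "no complete pairs"}
    (out / "pair_expression_bias.json").write_text(json.dumps(bias, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["homology"] = {
        "params": hcfg, "n_pairs": len(pairs), "n_syntenic": len(syn_pairs)
    }

    # ---- co-expression network --------------------------------------------
    ncfg = cfg["network"]
    net_ids = sorted(set(lnc_ids) | set(deg_ids))
    kinds = {i: ("lncRNA" if i in set(lnc_ids) else "PCG") for i in net_ids}
    net_expr = fpkm.values.loc[net_ids]
    net = mnetwork.build_network(net_expr, beta=ncfg["beta"], edge_cutoff=ncfg["edge_cutoff"],
                                 node_kinds=kinds)
    _write(net.edge_frame(), out / "network_edges.tsv")
    try:
        hubs = mnetwork.find_hubs(net, top_n=3)
    except ValueError:
        hubs = pd.DataFrame(columns=["node", "degree", "neighbor_count"])
    _write(hubs, out / "network_hubs.tsv")
    manifest["stages"]["network"] = {
        "params": ncfg, "n_nodes": net.graph.number_of_nodes(), "n_edges": net.graph.number_of_edges()
    }

    # ---- clustering / enrichment / function transfer -----------------------
    ccfg = cfg["cluster"]
    clus_expr = fpkm.values.loc[net_ids]
    k = min(ccfg["k"], max(len(net_ids) - 1, 1))
    clusters, inertia = mcluster.kmeans_profiles(clus_expr, k=k, seed=seed)
    cdf = clusters.rename_axis("feature_id").reset_index().sort_values("feature_id")
    _write(cdf, out / "clusters.tsv")
    gene_clusters = clusters[[i for i in clusters.index if i.endswith(".t1")]]
    gene_clusters.index = [i.rsplit(".", 1)[0] for i in gene_clusters.index]
    enr = mcluster.cluster_enrichments(gene_clusters, genome.annotation, preset=ccfg["preset"])
    enr_df = pd.concat(
        [df.assign(cluster=c) for c, df in sorted(enr.items()) if len(df)], ignore_index=True
    ) if any(len(df) for df in enr.values()) else pd.DataFrame(
        columns=["term", "a", "b", "c", "d", "odds_ratio", "p_value", "fdr", "significant", "cluster"]
    )
    _write(enr_df.sort_values(["cluster", "term"]), out / "cluster_enrichment.tsv")
    transfer = mcluster.transfer_function(set(lnc_ids), clusters, enr)
    _write(transfer, out / "lncrna_function_transfer.tsv")
    manifest["stages"]["cluster"] = {
        "params": {**ccfg, "k_effective": int(k)},
        "inertia": round(float(inertia), 4),
        "n_clustered": int(len(clusters)),
        "n_transferred": int(len(transfer)),
    }

    # ---- amplicon editing scan (independent stage) --------------------------
    ecfg = cfg["editing"]
    ref, guide = make_amplicon(seed + 11)
    mix = [("WT", 0, 0.4), ("deletion", 5, 0.3), ("deletion", 12, 0.1),
           ("insertion", 1, 0.1), ("substitution", 2, 0.1)]
    reads, read_truth = generate_amplicons(ref, guide, mix, n_reads=200, seed=seed + 12)
    site = mediting.locate_guide(ref, guide)
    calls = [
        mediting.classify_read(seq, ref, site, window_bp=ecfg["window_bp"],
                               min_sub_count=ecfg["min_sub_count"], read_id=rid)
        for rid, seq in reads
    ]
    _write(mediting.calls_frame(calls), out / "edit_calls.tsv")
    esum = mediting.summarize_editing(calls, min_reads=ecfg["min_reads"])
    (out / "edit_summary.json").write_text(json.dumps(esum, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["editing"] = {
        "params": ecfg, "n_reads": esum["n_reads"], "efficiency_pct": esum["efficiency_pct"]
    }

    # ---- group statistics (independent stage) -------------------------------
    srng = np.random.default_rng(seed + 13)
    groups = {
        "control": list(np.round(srng.normal(30, 4, 4), 3)),
        "line1": list(np.round(srng.normal(48, 4, 4), 3)),
        "line2": list(np.round(srng.normal(46, 4, 4), 3)),
    }
    comp = mstats.anova_lsd(groups)
    stats_payload = {
        "groups": groups,
        "F": comp.statistic,
        "p_value": comp.p_value,
        "star": comp.star,
        "letters": comp.letters,
        "pairwise_lsd": {f"{a}|{b}": p for (a, b), p in sorted(comp.pairwise_lsd.items())},
    }
    (out / "group_stats.json").write_text(json.dumps(stats_payload, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["stats"] = {"test": "anova_lsd", "n_groups": len(groups)}

    manifest_json = json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    (out / "manifest.json").write_text(manifest_json)
    manifest["manifest_sha256"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    return manifest
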