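"""Soft-threshold scan and weighted co-expression network with hub lncRNAs."""
from common import identify_lncrnas, load_cohort, outdir

from lincforge import de as mde
from lincforge import network as mnetwork


def main() -> None:
    out = outdir("05_network")
    genome, counts = load_cohort()
    _, fpkm, *_, lnc_ids = identify_lncrnas(genome, counts)
    # nodes: identified lncRNAs plus genes responding in any contrast
    deg_ids: set[str] = set()
    for geno in sorted(counts.design.genotype.unique()):
        ctrl = counts.samples_where(genotype=geno, timepoint_h=0)
        for tp in sorted(t for t in counts.design.timepoint_h.unique() if t > 0):
            res = mde.call_de(counts, counts.samples_where(genotype=geno, timepoint_h=tp), ctrl)
            deg_ids |= {r.feature_id for r in res if r.significant and r.feature_id.endswith(".t1")}
    node_ids = sorted(set(lnc_ids) | deg_ids)
    expr = fpkm.values.loc[node_ids]

    beta, scan = mnetwork.pick_soft_threshold(expr)
    scan.to_csv(out / "soft_threshold_scan.tsv", sep="\t", index=False, float_format="%.6g")

    # looser edge cutoff than the pipeline default: this is an exploratory view
    kinds = {i: ("lncRNA" if i in set(lnc_ids) else "PCG") for i in node_ids}
    net = mnetwork.build_network(expr, beta=8, edge_cutoff=0.5, node_kinds=kinds)
    net.edge_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False,
                            float_format="%.6g")
    hubs = mnetwork.find_hubs(net, top_n=10)
    hubs.to_csv(out / "network_hubs.tsv", sep="\t", index=False)
    print(f"scan suggests beta={beta}; network has {net.graph.number_of_nodes()} nodes, "
          f"{net.graph.number_of_edges()} edges; tables in {out}")


if __name__ == "__main__":
    main()
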