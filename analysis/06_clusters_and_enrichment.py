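"""Expression-profile clustering, Fisher enrichment, lncRNA function transfer."""
import pandas as pd
from common import SEED, identify_lncrnas, load_cohort, outdir

from lincforge import cluster as mcluster


def main() -> None:
    out = outdir("06_clusters")
    genome, counts = load_cohort()
    _, fpkm, *_, lnc_ids = identify_lncrnas(genome, counts)
    mrna_ids = [t.id for t in genome.assembled if t.id.endswith(".t1")]
    node_ids = sorted(set(lnc_ids) | set(mrna_ids))

    clusters, inertia = mcluster.kmeans_profiles(fpkm.values.loc[node_ids], k=10, seed=SEED)
    clusters.rename_axis("feature_id").reset_index().sort_values("feature_id").to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )

    gene_clusters = clusters[[i for i in clusters.index if i.endswith(".t1")]]
    gene_clusters.index = [i.rsplit(".", 1)[0] for i in gene_clusters.index]
    enr = mcluster.cluster_enrichments(gene_clusters, genome.annotation, preset="cluster")
    frames = [df.assign(cluster=c) for c, df in sorted(enr.items()) if len(df)]
    enr_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    enr_df.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    transfer = mcluster.transfer_function(set(lnc_ids), clusters, enr)
    transfer.to_csv(out / "lncrna_function_transfer.tsv", sep="\t", index=False,
                    float_format="%.6g")
    print(f"k=10 clustering (inertia {inertia:.1f}); {len(enr_df)} enriched terms; "
          f"{len(transfer)} transferred annotations; tables in {out}")


if __name__ == "__main__":
    main()
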