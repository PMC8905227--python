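"""Per-genotype, per-timepoint differential expression and DEL ratios."""
import pandas as pd
from common import identify_lncrnas, load_cohort, outdir

from lincforge import de as mde


def main() -> None:
    out = outdir("03_differential_expression")
    genome, counts = load_cohort()
    *_, lnc_ids = identify_lncrnas(genome, counts)
    lnc_set = set(lnc_ids)

    frames, sig_lnc = [], {}
    by_class = {"lncRNA": [], "mRNA": []}
    timepoints = sorted(t for t in counts.design.timepoint_h.unique() if t > 0)
    for geno in sorted(counts.design.genotype.unique()):
        ctrl = counts.samples_where(genotype=geno, timepoint_h=0)
        for tp in timepoints:
            name = f"{geno}_{tp}h_vs_0h"
            res = mde.call_de(counts, counts.samples_where(genotype=geno, timepoint_h=tp),
                              ctrl, contrast=name)
            frames.append(mde.de_results_frame(res))
            sig_lnc[name] = {r.feature_id for r in res if r.significant and r.feature_id in lnc_set}
            by_class["lncRNA"].extend(r for r in res if r.feature_id in lnc_set)
            by_class["mRNA"].extend(r for r in res if r.feature_id.endswith(".t1"))

    de_all = pd.concat(frames, ignore_index=True).sort_values(["contrast", "feature_id"])
    de_all.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    n_mrna = sum(1 for t in genome.assembled if t.id.endswith(".t1"))
    n_contrasts = len(frames)
    ratios = mde.summarize_del(
        by_class, {"lncRNA": len(lnc_ids) * n_contrasts, "mRNA": n_mrna * n_contrasts}
    )
    ratios.to_csv(out / "del_ratios.tsv", sep="\t", index=False)
    mde.timepoint_overlaps(sig_lnc).to_csv(out / "del_timepoint_overlaps.tsv", sep="\t",
                                           index=False)
    n_del = len(set().union(*sig_lnc.values()))
    print(f"{len(frames)} contrasts; {n_del} differentially expressed lncRNAs; tables in {out}")


if __name__ == "__main__":
    main()
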