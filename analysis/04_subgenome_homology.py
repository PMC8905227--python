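"""At/Dt reciprocal-best homolog pairs, synteny flags and expression bias."""
import json

import pandas as pd
from common import identify_lncrnas, load_cohort, outdir

from lincforge import de as mde
from lincforge import homology as mhomology


def main() -> None:
    out = outdir("04_homology")
    genome, counts = load_cohort()
    *_, lnc_ids = identify_lncrnas(genome, counts)
    tmap = {t.id: t for t in genome.assembled}

    at = {t: tmap[t].sequence for t in lnc_ids if tmap[t].subgenome == "At"}
    dt = {t: tmap[t].sequence for t in lnc_ids if tmap[t].subgenome == "Dt"}
    pairs = mhomology.reciprocal_best_pairs(at, dt)
    at_order = {c: ids for c, ids in genome.feature_order.items() if c.startswith("A")}
    dt_order = {c: ids for c, ids in genome.feature_order.items() if c.startswith("D")}
    pairs = mhomology.synteny_filter(pairs, at_order, dt_order, genome.anchor_partner)
    pd.DataFrame(
        {
            "at_id": [p.at_id for p in pairs],
            "dt_id": [p.dt_id for p in pairs],
            "identity": [round(p.identity, 6) for p in pairs],
            "coverage": [round(p.coverage, 6) for p in pairs],
            "syntenic": [p.syntenic for p in pairs],
        }
    ).sort_values("at_id").to_csv(out / "homolog_pairs.tsv", sep="\t", index=False)

    geno = sorted(counts.design.genotype.unique())[0]
    tp = sorted(counts.design.timepoint_h.unique())[-1]
    res = mde.call_de(counts, counts.samples_where(genotype=geno, timepoint_h=tp),
                      counts.samples_where(genotype=geno, timepoint_h=0))
    lfc = {r.feature_id: r.log2_fold_change for r in res}
    syn = [p for p in pairs if p.syntenic]
    bias = mhomology.pair_expression_bias(syn, lfc) if syn else {"n_pairs": 0}
    (out / "pair_expression_bias.json").write_text(json.dumps(bias, indent=2, sort_keys=True) + "\n")
    print(f"{len(pairs)} pairs ({len(syn)} syntenic); tables in {out}")


if __name__ == "__main__":
    main()
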