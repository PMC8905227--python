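"""Run the lncRNA identification cascade: class codes, filters, coding potential."""
import pandas as pd
from common import identify_lncrnas, load_cohort, outdir

from lincforge import classify as mclassify


def main() -> None:
    out = outdir("02_identification")
    genome, counts = load_cohort()
    assignments, fpkm, survivors, ledger, scores, lnc_ids = identify_lncrnas(genome, counts)

    pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in assignments],
            "class_code": [a.class_code for a in assignments],
            "nearest_gene_id": [a.nearest_gene_id for a in assignments],
            "distance_to_nearest_gene": [a.distance_to_nearest_gene for a in assignments],
        }
    ).sort_values("transcript_id").to_csv(out / "class_codes.tsv", sep="\t", index=False)
    ledger.to_csv(out / "filter_ledger.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in scores],
            "combined_score": [s.combined_score for s in scores],
            "label": [s.label for s in scores],
        }
    ).sort_values("transcript_id").to_csv(out / "coding_scores.tsv", sep="\t", index=False)
    pd.DataFrame({"transcript_id": lnc_ids}).to_csv(out / "lncrnas.tsv", sep="\t", index=False)

    tmap = {t.id: t for t in genome.assembled}
    lnc_models = [tmap[t] for t in lnc_ids]
    mrna_models = [t for t in genome.assembled if t.id.endswith(".t1")]
    summary, comparisons = mclassify.summarize_features(lnc_models, mrna_models, fpkm)
    summary.sort_values("transcript_id").to_csv(out / "feature_summary.tsv", sep="\t", index=False)
    comparisons.to_csv(out / "feature_comparisons.tsv", sep="\t", index=False)
    print(f"{len(assignments)} transcripts -> {len(survivors)} candidates -> "
          f"{len(lnc_ids)} lncRNAs; tables in {out}")


if __name__ == "__main__":
    main()
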