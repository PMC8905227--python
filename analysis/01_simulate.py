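"""Generate the synthetic allotetraploid cohort and write its ground truth."""
from common import load_cohort, outdir


def main() -> None:
    out = outdir("01_simulation")
    genome, counts = load_cohort()
    genome.write(out)
    counts.to_tsv(out / "counts.tsv")
    counts.design.to_csv(out / "design.tsv", sep="\t")
    print(f"wrote {len(genome.assembled)} transcripts, "
          f"{counts.values.shape[1]} samples -> {out}")


if __name__ == "__main__":
    main()
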