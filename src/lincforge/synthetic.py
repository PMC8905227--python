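"""Synthetic two-subgenome fixtures with known ground truth.

Emulates an allotetraploid cotton-like genome: paired At/Dt chromosomes
carrying protein-coding anchor genes in conserved order, planted intergenic
(u), intronic (i) and antisense (x) non-coding transcripts, homologous
lncRNA pairs at syntenic (and deliberately relocated, non-syntenic)
positions, per-rule filter decoys, a genotype × timepoint × replicate count
matrix with negative-binomial noise and planted differential expression,
and CRISPR amplicon read sets with planted editing outcomes.

Every generator is deterministic under the configured seed.  Coding
sequences are sampled codon-wise (no internal stops, GC ≈ 0.44); non-coding
sequences are AT-richer (GC ≈ 0.36) and rejection-sampled so no ORF covers
more than a third of the transcript, mirroring the GC and coding-potential
contrasts real lncRNA sets show without asserting any published value.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lio
from .de import ExpressionMatrix
from .models import GeneModel, TranscriptModel

STOPS = ("TAA", "TAG", "TGA")
UNIT = 5000  # bp per gene+intergenic unit
GENE_EXON = 450
GENE_INTRON = 600
DEFAULT_DESIGN = [
    (g, t, r) for g in ("HR", "ZS") for t in (0, 4, 12, 24, 48) for r in (1, 2, 3)
]


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chromosomes_per_subgenome: int = 2
    chromosome_length: int = 200_000
    n_genes: int = 50  # per subgenome
    n_lnc_u: int = 70  # planted passing intergenic lncRNAs (incl. pair members)
    n_lnc_i: int = 6
    n_lnc_x: int = 6
    n_homolog_pairs: int = 10  # syntenic pairs
    n_shuffled_pairs: int = 4  # relocated (non-syntenic) decoy pairs
    n_decoy_length: int = 5
    n_decoy_proximity: int = 5
    n_decoy_lowexpr: int = 5
    n_decoy_coding: int = 5
    n_decoy_est: int = 5
    design: list = field(default_factory=lambda: list(DEFAULT_DESIGN))
    de_fraction: float = 0.25
    de_log2fc: float = 3.0
    dispersion: float = 0.05
    read_error_rate: float = 0.0
    library_size: float = 2e7

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if 2 * (self.n_homolog_pairs + self.n_shuffled_pairs) > self.n_lnc_u:
            raise ValueError("n_lnc_u must cover both members of every planted pair")
        if self.n_shuffled_pairs and self.n_chromosomes_per_subgenome < 2:
            raise ValueError("relocated pairs need >= 2 chromosomes per subgenome")


@dataclass
class SyntheticGenome:
    genome: dict  # chrom -> sequence
    reference: list  # GeneModel
    assembled: list  # TranscriptModel (with sequences)
    truth: pd.DataFrame
    est_support: dict  # chrom -> [(start, end)]
    feature_order: dict  # chrom -> positional id list (genes + lncRNAs)
    anchor_partner: dict  # gene <-> homoeologous gene (both directions)
    annotation: pd.DataFrame  # gene -> term table
    config: SimulationConfig

    def write(self, outdir) -> None:
        out = lio.ensure_dir(outdir)
        lio.write_fasta(self.genome, out / "genome.fa")
        gene_ts = [
            TranscriptModel(id=g.id, chromosome=g.chromosome, strand=g.strand, exons=g.exons,
                            gene_id=g.id)
            for g in self.reference
        ]
        lio.write_gtf(gene_ts, out / "reference.gtf")
        lio.write_gtf(self.assembled, out / "assembled.gtf")
        self.truth.sort_values("feature_id").to_csv(out / "truth.tsv", sep="\t", index=False)
        lio.write_bed3(self.est_support, out / "est_support.bed")
        self.annotation.sort_values(["feature_id", "term"]).to_csv(
            out / "annotation.tsv", sep="\t", index=False
        )


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _coding_seq(rng: np.random.Generator, n_nt: int, gc: float = 0.44) -> str:
    """ATG + stop-free codons + stop; one ORF covering the whole sequence."""
    n_codons = max(n_nt // 3, 4)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _rand_seq(rng, 3, gc)
        if c not in STOPS and c != "ATG":
            codons.append(c)
    codons.append(STOPS[rng.integers(3)])
    return "".join(codons)


def _longest_orf_frac(seq: str) -> float:
    best = 0
    for f in range(3):
        start = None
        for pos in range(f, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOPS:
                if start is not None:
                    best = max(best, pos + 3 - start)
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
    return best / len(seq) if seq else 0.0


def _noncoding_seq(rng: np.random.Generator, n: int, gc: float = 0.36, max_orf_frac: float = 0.35) -> str:
    for _ in range(200):
        s = _rand_seq(rng, n, gc)
        if _longest_orf_frac(s) < max_orf_frac:
            return s
    raise RuntimeError("could not sample an ORF-poor non-coding sequence")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    bases = "ACGT"
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = bases[(bases.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def _splice(seq: str, exons: list[tuple[int, int]], offset: int) -> list[tuple[int, int]]:
    """Exon coordinates relative to genome given a transcript start offset."""
    return [(offset + s, offset + e) for s, e in exons]


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build genome FASTA, reference and assembled annotations and the truth table."""
    rng = np.random.default_rng(config.seed)
    n_chr = config.n_chromosomes_per_subgenome
    genes_per_chr = -(-config.n_genes // n_chr)  # ceil

    # ---- job bookkeeping: intergenic features to place, per subgenome ----
    n_pairs_total = config.n_homolog_pairs + config.n_shuffled_pairs
    n_plain_u = config.n_lnc_u - 2 * n_pairs_total
    plain_a = n_plain_u // 2
    plain_d = n_plain_u - plain_a

    jobs_a: list[tuple[str, dict]] = []
    jobs_d: list[tuple[str, dict]] = []
    for i in range(config.n_homolog_pairs):
        jobs_a.append(("pair_syntenic", {"pair": i}))
    for i in range(config.n_shuffled_pairs):
        jobs_a.append(("pair_shuffled", {"pair": config.n_homolog_pairs + i}))
    jobs_a += [("lnc_u", {})] * plain_a
    jobs_d += [("lnc_u", {})] * plain_d
    decoy_jobs = (
        [("decoy_length", {})] * config.n_decoy_length
        + [("decoy_lowexpr", {})] * config.n_decoy_lowexpr
        + [("decoy_coding", {})] * config.n_decoy_coding
        + [("decoy_est", {})] * config.n_decoy_est
    )
    for j, job in enumerate(decoy_jobs):  # alternate subgenomes
        (jobs_a if j % 2 == 0 else jobs_d).append(job)

    per_chr_a = -(-len(jobs_a) // n_chr)
    per_chr_d = -(-(len(jobs_d) + 2 * n_pairs_total) // n_chr)  # pair partners land on D
    units_per_chr = max(genes_per_chr, per_chr_a, per_chr_d) + 1
    needed = units_per_chr * UNIT + 1000
    if config.chromosome_length < needed:
        raise ValueError(
            f"chromosome_length={config.chromosome_length} too short: "
            f"{units_per_chr} units of {UNIT} bp (+1000 margin) need {needed} bp"
        )

    genome: dict[str, np.ndarray] = {}
    for s in "AD":
        for c in range(1, n_chr + 1):
            genome[f"{s}{c:02d}"] = np.array(
                list(_rand_seq(rng, config.chromosome_length, 0.38)), dtype="<U1"
            )

    def paste(chrom: str, start: int, seq: str) -> None:
        genome[chrom][start : start + len(seq)] = list(seq)

    reference: list[GeneModel] = []
    assembled: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    est: dict[str, list[tuple[int, int]]] = {}
    order: dict[str, list[tuple[int, str]]] = {ch: [] for ch in genome}
    anchor_partner: dict[str, str] = {}

    def add_truth(fid, ftype, chrom, code, coding, fail, partner="", syntenic="", cluster=0):
        truth_rows.append(
            {
                "feature_id": fid,
                "feature_type": ftype,
                "chromosome": chrom,
                "true_class_code": code,
                "true_coding": bool(coding),
                "fail_rule": fail,
                "true_de": False,
                "true_log2fc": 0.0,
                "homolog_partner": partner,
                "syntenic_truth": syntenic,
                "cluster_label": cluster,
            }
        )

    # ---- genes: same rank on Axx and Dxx (anchor homoeologs) ----
    gene_slots: dict[str, list[tuple[str, int]]] = {}  # chrom -> [(gene_id, unit_start)]
    gid_counter = 0
    for c in range(1, n_chr + 1):
        n_here = min(genes_per_chr, config.n_genes - (c - 1) * genes_per_chr)
        for rank in range(max(n_here, 0)):
            gid_counter += 1
            seq = _coding_seq(rng, 2 * GENE_EXON)
            for sub in "AD":
                chrom = f"{sub}{c:02d}"
                gid = f"Gh{chrom}G{gid_counter:04d}"
                unit_start = rank * UNIT
                gstart = unit_start + 500
                exons = [
                    (gstart, gstart + GENE_EXON),
                    (gstart + GENE_EXON + GENE_INTRON, gstart + 2 * GENE_EXON + GENE_INTRON),
                ]
                gseq = seq if sub == "A" else _mutate(rng, seq, 0.02)
                paste(chrom, exons[0][0], gseq[:GENE_EXON])
                paste(chrom, exons[1][0], gseq[GENE_EXON:])
                reference.append(GeneModel(id=gid, chromosome=chrom, strand="+", exons=exons))
                assembled.append(
                    TranscriptModel(
                        id=f"{gid}.t1", chromosome=chrom, strand="+", exons=exons, gene_id=gid
                    )
                )
                add_truth(f"{gid}.t1", "mRNA", chrom, "overlapping_other", True, "code")
                gene_slots.setdefault(chrom, []).append((gid, unit_start))
                order[chrom].append((gstart, gid))
            a_id = f"GhA{c:02d}G{gid_counter:04d}"
            d_id = f"GhD{c:02d}G{gid_counter:04d}"
            anchor_partner[a_id] = d_id
            anchor_partner[d_id] = a_id

    # ---- intronic / antisense planted lncRNAs, attached to genes ----
    lnc_counter = 0

    def host_gene(idx: int) -> GeneModel:
        return reference[idx % len(reference)]

    for j in range(config.n_lnc_i):
        g = host_gene(2 * j)
        lnc_counter += 1
        fid = f"linc{g.chromosome}.{lnc_counter:04d}"
        istart = g.exons[0][1] + 150
        exons = [(istart, istart + 250)]
        seq = _noncoding_seq(rng, 250)
        paste(g.chromosome, istart, seq)
        assembled.append(TranscriptModel(id=fid, chromosome=g.chromosome, strand="+", exons=exons))
        add_truth(fid, "lnc_i", g.chromosome, "i", False, "code")
        order[g.chromosome].append((istart, fid))
    for j in range(config.n_lnc_x):
        g = host_gene(2 * j + 1)
        lnc_counter += 1
        fid = f"linc{g.chromosome}.{lnc_counter:04d}"
        exons = [(g.start + 50, g.start + 350)]
        assembled.append(
            TranscriptModel(id=fid, chromosome=g.chromosome, strand="-", exons=exons)
        )
        add_truth(fid, "lnc_x", g.chromosome, "x", False, "code")
        order[g.chromosome].append((g.start + 50, fid))

    # ---- proximity decoys: 300 bp downstream of a gene span ----
    for j in range(config.n_decoy_proximity):
        g = reference[(3 * j) % len(reference)]
        lnc_counter += 1
        fid = f"linc{g.chromosome}.{lnc_counter:04d}"
        start = g.end + 300
        seq = _noncoding_seq(rng, 300)
        paste(g.chromosome, start, seq)
        assembled.append(
            TranscriptModel(id=fid, chromosome=g.chromosome, strand="+", exons=[(start, start + 300)])
        )
        add_truth(fid, "decoy_proximity", g.chromosome, "u", False, "distance")
        order[g.chromosome].append((start, fid))

    # ---- intergenic slots ----
    slot_cursor: dict[str, int] = {ch: 0 for ch in genome}

    def next_slot(chrom: str) -> int:
        """Unit-aligned intergenic start, > 500 bp from both flanking genes."""
        u = slot_cursor[chrom]
        slot_cursor[chrom] += 1
        if u >= units_per_chr:
            raise ValueError(f"chromosome {chrom} too short for requested features")
        return u * UNIT + 3200

    def place_lnc(chrom, ftype, seq=None, length=400, n_exons=1, fail="", partner="",
                  syntenic="", coding=False):
        nonlocal lnc_counter
        lnc_counter += 1
        fid = f"linc{chrom}.{lnc_counter:04d}"
        start = next_slot(chrom)
        if seq is None:
            seq = (_coding_seq(rng, length) if coding else _noncoding_seq(rng, length))
        if n_exons == 2:
            half = len(seq) // 2
            exons = [(start, start + half), (start + half + 120, start + len(seq) + 120)]
            paste(chrom, start, seq[:half])
            paste(chrom, start + half + 120, seq[half:])
        else:
            exons = [(start, start + len(seq))]
            paste(chrom, start, seq)
        assembled.append(TranscriptModel(id=fid, chromosome=chrom, strand="+", exons=exons))
        add_truth(fid, ftype, chrom, "u", coding, fail, partner, syntenic)
        order[chrom].append((start, fid))
        if fail != "est":  # EST support for everything except est decoys
            for ex in exons:
                est.setdefault(chrom, []).append((ex[0] - 10, ex[1] + 10))
        return fid, seq

    def a_chrom(i: int) -> str:
        return f"A{(i % n_chr) + 1:02d}"

    def d_chrom(i: int) -> str:
        return f"D{(i % n_chr) + 1:02d}"

    pair_ids: list[tuple[str, str, bool]] = []
    chrom_rr = 0
    for kind, info in jobs_a:
        if kind == "pair_syntenic":
            ca = a_chrom(info["pair"])
            fid_a, seq = place_lnc(ca, "lnc_u_pair", length=420)
            cd = "D" + ca[1:]
            # syntenic position: same unit on the partner chromosome
            slot_cursor[cd] = max(slot_cursor[cd], slot_cursor[ca] - 1)
            fid_d, _ = place_lnc(cd, "lnc_u_pair", seq=_mutate(rng, seq, 0.03))
            pair_ids.append((fid_a, fid_d, True))
        elif kind == "pair_shuffled":
            ca = a_chrom(info["pair"])
            fid_a, seq = place_lnc(ca, "lnc_u_pair", length=420)
            # relocate the partner to a different chromosome: flanking anchors
            # there are homoeologs of OTHER genes, so collinearity is broken
            cd = "D" + a_chrom(info["pair"] + 1)[1:]
            fid_d, _ = place_lnc(cd, "lnc_u_pair", seq=_mutate(rng, seq, 0.03))
            pair_ids.append((fid_a, fid_d, False))
        else:
            chrom = a_chrom(chrom_rr)
            chrom_rr += 1
            _dispatch_job(kind, chrom, place_lnc)
    for kind, info in jobs_d:
        chrom = d_chrom(chrom_rr)
        chrom_rr += 1
        _dispatch_job(kind, chrom, place_lnc)

    truth = pd.DataFrame(truth_rows)
    for fid_a, fid_d, syn in pair_ids:
        truth.loc[truth.feature_id == fid_a, ["homolog_partner", "syntenic_truth"]] = [fid_d, str(syn)]
        truth.loc[truth.feature_id == fid_d, ["homolog_partner", "syntenic_truth"]] = [fid_a, str(syn)]

    # ---- planted DE among passing lncRNAs and mRNAs ----
    eligible = truth.index[
        truth.feature_type.isin(["lnc_u", "lnc_u_pair", "mRNA"])
    ].to_numpy()
    n_de = int(round(config.de_fraction * len(eligible)))
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    truth.loc[de_idx, "true_de"] = True
    truth.loc[de_idx, "true_log2fc"] = signs * config.de_log2fc
    truth.loc[de_idx, "cluster_label"] = np.where(signs > 0, 1, 2)

    # ---- synthetic functional annotation: up-regulated genes share a term ----
    ann_rows = []
    terms_pool = [f"GO:{i:07d}" for i in range(1, 9)]
    for _, r in truth[truth.feature_type == "mRNA"].iterrows():
        gene = r.feature_id.rsplit(".", 1)[0]
        if r.true_de and r.true_log2fc > 0:
            ann_rows.append({"feature_id": gene, "term": "GO:defense_response"})
        for t in rng.choice(terms_pool, size=rng.integers(1, 3), replace=False):
            ann_rows.append({"feature_id": gene, "term": t})
    annotation = pd.DataFrame(ann_rows, columns=["feature_id", "term"])

    genome_str = {ch: "".join(arr) for ch, arr in genome.items()}
    # attach spliced sequences to assembled transcripts
    for t in assembled:
        t.sequence = "".join(genome_str[t.chromosome][s:e] for s, e in t.exons)

    feature_order = {ch: [fid for _, fid in sorted(lst)] for ch, lst in order.items()}
    return SyntheticGenome(
        genome=genome_str,
        reference=reference,
        assembled=assembled,
        truth=truth,
        est_support={ch: sorted(iv) for ch, iv in est.items()},
        feature_order=feature_order,
        anchor_partner=anchor_partner,
        annotation=annotation,
        config=config,
    )


def _dispatch_job(kind: str, chrom: str, place_lnc) -> None:
    if kind == "lnc_u":
        place_lnc(chrom, "lnc_u", length=400)
    elif kind == "decoy_length":
        place_lnc(chrom, "decoy_length", length=150, fail="length")
    elif kind == "decoy_lowexpr":
        place_lnc(chrom, "decoy_lowexpr", length=400, fail="fpkm")
    elif kind == "decoy_coding":
        place_lnc(chrom, "decoy_coding", length=399, fail="coding", coding=True)
    elif kind == "decoy_est":
        place_lnc(chrom, "decoy_est", length=400, fail="est")
    else:  # pragma: no cover
        raise ValueError(kind)


def generate_counts(genome: SyntheticGenome, config: SimulationConfig | None = None) -> ExpressionMatrix:
    """Negative-binomial counts over the design (variance = mu + alpha*mu^2).

    Non-DE features share one mean across all conditions; DE features are
    shifted by their planted log2FC in every infested (timepoint > 0) sample
    of both genotypes.  Low-expression decoys get a near-zero mean so their
    FPKM never clears the abundance rule.
    """
    config = config or genome.config
    if not config.design:
        raise ValueError("empty design")
    rng = np.random.default_rng(config.seed + 1)
    truth = genome.truth.set_index("feature_id")
    sample_ids = [f"{g}_{t}h_r{r}" for g, t, r in config.design]
    design = pd.DataFrame(
        {
            "genotype": [g for g, _, _ in config.design],
            "timepoint_h": [t for _, t, _ in config.design],
            "replicate": [r for _, _, r in config.design],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    infested = design.timepoint_h.to_numpy() > 0

    fids = [t.id for t in genome.assembled]
    lengths = pd.Series({t.id: t.spliced_length for t in genome.assembled})
    base = np.empty(len(fids))
    for i, fid in enumerate(fids):
        row = truth.loc[fid]
        if row.feature_type == "decoy_lowexpr":
            base[i] = 0.05
        elif row.feature_type == "mRNA":
            base[i] = float(rng.lognormal(np.log(150), 0.4))
        else:
            base[i] = float(rng.lognormal(np.log(60), 0.4))
    lfc = truth.loc[fids, "true_log2fc"].to_numpy(dtype=float)
    mu = np.tile(base[:, None], (1, len(sample_ids)))
    mu[:, infested] *= 2.0 ** lfc[:, None]
    counts = _nb_sample(rng, mu, config.dispersion)
    values = pd.DataFrame(counts, index=pd.Index(fids, name="feature_id"), columns=sample_ids)
    return ExpressionMatrix(
        values=values,
        design=design,
        kind="counts",
        feature_lengths=lengths,
        library_sizes=pd.Series(config.library_size, index=sample_ids),
    )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def generate_null_counts(
    n_features: int, n_per_group: int, dispersion: float, seed: int, mean_log: float = np.log(150)
) -> ExpressionMatrix:
    """Two-group counts with no planted effect (type-I error studies)."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean_log, 0.5, size=n_features)
    mu = np.tile(base[:, None], (1, 2 * n_per_group))
    counts = _nb_sample(rng, mu, dispersion)
    samples = [f"t_r{i}" for i in range(n_per_group)] + [f"c_r{i}" for i in range(n_per_group)]
    design = pd.DataFrame(
        {"group": ["t"] * n_per_group + ["c"] * n_per_group},
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame(counts, index=[f"f{i:05d}" for i in range(n_features)], columns=samples)
    return ExpressionMatrix(values=values, design=design, kind="counts")


def generate_module_counts(
    n_modules: int = 3,
    features_per_module: int = 12,
    n_background: int = 30,
    n_samples: int = 30,
    seed: int = 0,
    amplitude_log2: float = 2.5,
    dispersion: float = 0.002,
    mean: float = 2000.0,
) -> tuple[pd.DataFrame, dict]:
    """Co-expression preset: tight modules sharing a latent profile.

    Module members follow one multiplicative latent time profile with very
    low dispersion, so within-module |correlation| stays above the default
    adjacency threshold; background features are independent noise.
    Returns (expression frame, truth dict feature -> module or 0).
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i:02d}" for i in range(n_samples)]
    rows, truthd = {}, {}
    for m in range(1, n_modules + 1):
        profile = 2.0 ** (amplitude_log2 * np.sin(np.linspace(0, 2 * np.pi, n_samples) + m))
        for j in range(features_per_module):
            fid = f"mod{m}_f{j:02d}"
            rows[fid] = _nb_sample(rng, mean * profile, dispersion)
            truthd[fid] = m
    for j in range(n_background):
        fid = f"bg_f{j:02d}"
        rows[fid] = _nb_sample(rng, np.full(n_samples, mean), 0.3)
        truthd[fid] = 0
    return pd.DataFrame(rows, index=samples).T, truthd


def generate_profile_counts(
    n_per_group: int = 30, n_samples: int = 20, seed: int = 0, separation: float = 3.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Two well-separated expression-profile groups (clustering fixture)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_samples)
    prof_a, prof_b = np.sin(2 * np.pi * t), -np.sin(2 * np.pi * t)
    rows, labels = {}, {}
    for g, prof in (("a", prof_a), ("b", prof_b)):
        for j in range(n_per_group):
            fid = f"{g}{j:03d}"
            rows[fid] = separation * prof + rng.normal(0, 0.3, n_samples)
            labels[fid] = g
    expr = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)]).T
    return expr, pd.Series(labels)


def make_amplicon(seed: int, length: int = 240, guide_offset: int = 90) -> tuple[str, str]:
    """Random amplicon carrying exactly one guide+NGG site on the plus strand."""
    from .editing import locate_guide

    rng = np.random.default_rng(seed)
    for _ in range(100):
        ref = _rand_seq(rng, length, 0.45)
        guide = ref[guide_offset : guide_offset + 20]
        ref = ref[: guide_offset + 20] + "TGG" + ref[guide_offset + 23 :]
        try:
            locate_guide(ref, guide)
            return ref, guide
        except ValueError:
            continue
    raise RuntimeError("could not construct a single-site amplicon")


def generate_amplicons(
    amplicon_ref: str,
    guide: str,
    outcome_mix: list[tuple[str, int, float]],
    n_reads: int,
    seed: int,
    read_error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Reads with planted editing outcomes at the predicted cut site.

    ``outcome_mix`` rows are (type, length, proportion) with type in
    {WT, deletion, insertion, substitution}; proportions are realised exactly
    up to largest-remainder rounding.  Deletions are centred on the cut;
    insertions are placed at the cut; substitutions change ``length``
    consecutive bases starting just left of the cut.  Returns (reads, truth).
    """
    from .editing import locate_guide

    site = locate_guide(amplicon_ref, guide)
    if abs(sum(p for _, _, p in outcome_mix) - 1.0) > 1e-9:
        raise ValueError("outcome proportions must sum to 1")
    rng = np.random.default_rng(seed)
    raw = [p * n_reads for _, _, p in outcome_mix]
    counts = [int(np.floor(x)) for x in raw]
    for i in np.argsort([c - r for c, r in zip(counts, raw)])[: n_reads - sum(counts)]:
        counts[int(i)] += 1

    cut = site.cut_pos
    bases = "ACGT"
    reads, rows = [], []
    ridx = 0
    for (otype, length, _), n in zip(outcome_mix, counts):
        for _ in range(n):
            if otype == "WT":
                seq = amplicon_ref
            elif otype == "deletion":
                s = cut - length // 2
                seq = amplicon_ref[:s] + amplicon_ref[s + length :]
            elif otype == "insertion":
                ins = _rand_seq(rng, length, 0.5)
                seq = amplicon_ref[:cut] + ins + amplicon_ref[cut:]
            elif otype == "substitution":
                s = cut - length // 2
                sub = list(amplicon_ref[s : s + length])
                for k in range(length):
                    sub[k] = bases[(bases.index(sub[k]) + 1 + int(rng.integers(3))) % 4]
                seq = amplicon_ref[:s] + "".join(sub) + amplicon_ref[s + length :]
            else:
                raise ValueError(f"unknown outcome type {otype}")
            if read_error_rate > 0:
                seq = _mutate(rng, seq, read_error_rate)
            rid = f"read{ridx:05d}"
            ridx += 1
            reads.append((rid, seq))
            rows.append({"read_id": rid, "true_outcome": otype, "true_length": length})
    truth = pd.DataFrame(rows, columns=["read_id", "true_outcome", "true_length"])
    return reads, truth


def config_hash(config: SimulationConfig) -> str:
    payload = repr(sorted(config.__dict__.items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
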