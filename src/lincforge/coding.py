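"""Protein-coding potential: ORF enumeration, hexamer-usage scoring and
local protein-database alignment.

The coding/non-coding decision is a transparent two-feature score —
z-standardised ORF coverage plus z-standardised in-frame hexamer log-ratio —
trained on labelled coding and non-coding sequence sets, with an optional
protein-alignment evidence flag.  Forward three-frame scanning is the
default because the underlying RNA-seq library is non-strand-specific and
assembled lncRNA strand is nominal; six-frame mode is available.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass
class OrfRecord:
    frame: int
    start: int  # nt within the transcript, 0-based half-open
    end: int
    peptide: str
    open_ended: bool = False

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs(
    sequence: str,
    min_peptide_aa: int = 20,
    six_frame: bool = False,
    allow_open_ended: bool = False,
) -> list[OrfRecord]:
    """Enumerate ATG→stop ORFs, longest first.

    Per (frame, stop codon) only the longest ORF (earliest ATG) is kept.
    N-containing codons neither start nor extend an ORF.  Frames 3–5 (when
    ``six_frame``) index the reverse strand; coordinates stay on the given
    sequence's reverse complement.
    """
    seq = sequence.upper()
    strands = [(0, seq)]
    if six_frame:
        strands.append((3, _revcomp(seq)))
    orfs: list[OrfRecord] = []
    for frame_offset, s in strands:
        for f in range(3):
            start = None
            for pos in range(f, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if "N" in codon:
                    start = None
                    continue
                if codon in STOP_CODONS:
                    if start is not None:
                        pep = str(Seq(s[start:pos]).translate())
                        if len(pep) >= min_peptide_aa:
                            orfs.append(
                                OrfRecord(frame=frame_offset + f, start=start, end=pos + 3, peptide=pep)
                            )
                        start = None
                elif codon == START_CODON and start is None:
                    start = pos
            if start is not None and allow_open_ended:
                end = start + 3 * ((len(s) - start) // 3)
                pep = str(Seq(s[start:end]).translate())
                if len(pep) >= min_peptide_aa:
                    orfs.append(
                        OrfRecord(
                            frame=frame_offset + f, start=start, end=end, peptide=pep, open_ended=True
                        )
                    )
    orfs.sort(key=lambda o: (-o.peptide_length, o.start, o.frame))
    return orfs


ALL_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]


@dataclass
class HexamerModel:
    """In-frame hexamer log-ratio table with score standardisation stats."""

    log_ratio: dict = field(default_factory=dict)
    coding_freq: dict = field(default_factory=dict)
    noncoding_freq: dict = field(default_factory=dict)
    # z-standardisation of (orf_coverage, hexamer score) over the training sets
    cov_mean: float = 0.0
    cov_sd: float = 1.0
    hex_mean: float = 0.0
    hex_sd: float = 1.0
    trained: bool = False


def _hexamer_counts(seqs: list[str], pseudocount: float) -> dict:
    counts = dict.fromkeys(ALL_HEXAMERS, pseudocount)
    for s in seqs:
        s = s.upper()
        if set(s) - set("ACGTN"):
            raise ValueError("sequence contains characters outside ACGTN")
        for i in range(0, len(s) - 5, 3):
            h = s[i : i + 6]
            if "N" not in h:
                counts[h] += 1
    total = sum(counts.values())
    return {h: c / total for h, c in counts.items()}


def hexamer_score(sequence: str, model: HexamerModel) -> float:
    """Mean in-frame (step 3) hexamer log-ratio; 0 for sequences < 6 nt."""
    if not model.trained:
        raise ValueError("hexamer model is untrained")
    s = sequence.upper()
    vals = [
        model.log_ratio[s[i : i + 6]]
        for i in range(0, len(s) - 5, 3)
        if "N" not in s[i : i + 6]
    ]
    return float(np.mean(vals)) if vals else 0.0


def _orf_coverage(sequence: str) -> float:
    orfs = find_orfs(sequence, min_peptide_aa=1)
    if not orfs or not sequence:
        return 0.0
    longest = orfs[0]
    return (longest.end - longest.start) / len(sequence)


def train_hexamer_model(
    coding_seqs: list[str], noncoding_seqs: list[str], pseudocount: float = 1.0
) -> HexamerModel:
    """Fit the hexamer log-ratio table and standardisation statistics."""
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")
    cf = _hexamer_counts(coding_seqs, pseudocount)
    nf = _hexamer_counts(noncoding_seqs, pseudocount)
    model = HexamerModel(
        log_ratio={h: math.log(cf[h] / nf[h]) for h in ALL_HEXAMERS},
        coding_freq=cf,
        noncoding_freq=nf,
        trained=True,
    )
    train = list(coding_seqs) + list(noncoding_seqs)
    covs = np.array([_orf_coverage(s) for s in train])
    hexs = np.array([_longest_orf_hexamer(s, model) for s in train])
    model.cov_mean, model.cov_sd = float(covs.mean()), float(covs.std() or 1.0)
    model.hex_mean, model.hex_sd = float(hexs.mean()), float(hexs.std() or 1.0)
    return model


def _longest_orf_hexamer(sequence: str, model: HexamerModel) -> float:
    orfs = find_orfs(sequence, min_peptide_aa=1)
    if not orfs:
        return 0.0
    o = orfs[0]
    return hexamer_score(sequence[o.start : o.end], model)


@dataclass
class CodingScore:
    transcript_id: str
    orf_coverage: float
    hexamer_log_ratio: float
    combined_score: float
    label: str  # "coding" / "noncoding"


def score_coding(
    sequence: str,
    hexamer_model: HexamerModel,
    threshold: float = 0.0,
    transcript_id: str = "",
    w1: float = 1.0,
    w2: float = 1.0,
) -> CodingScore:
    """Combined coding score on the longest forward-frame ORF.

    combined = w1·z(orf_coverage) + w2·z(hexamer log-ratio); label is
    ``coding`` iff combined > threshold.  Both terms are 0 when no ORF.
    """
    if not hexamer_model.trained:
        raise ValueError("hexamer model is untrained")
    cov = _orf_coverage(sequence)
    hx = _longest_orf_hexamer(sequence, hexamer_model)
    z_cov = (cov - hexamer_model.cov_mean) / hexamer_model.cov_sd
    z_hex = (hx - hexamer_model.hex_mean) / hexamer_model.hex_sd
    combined = w1 * z_cov + w2 * z_hex
    return CodingScore(
        transcript_id=transcript_id,
        orf_coverage=cov,
        hexamer_log_ratio=hx,
        combined_score=float(combined),
        label="coding" if combined > threshold else "noncoding",
    )


def make_protein_aligner() -> Align.PairwiseAligner:
    """Local Smith–Waterman, BLOSUM62, affine gaps (open 11, extend 1).

    A gap of length k costs 11 + (k−1)·1.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def protein_hits(
    peptides: dict[str, str], protein_db: dict[str, str], min_score: float = 50.0
) -> pd.DataFrame:
    """Best local alignment score per (peptide, protein); hit iff >= min_score."""
    cols = ["peptide_id", "protein_id", "score", "hit"]
    if not peptides:
        return pd.DataFrame(columns=cols)
    if not protein_db:
        warnings.warn("empty protein database: no hits possible")
        return pd.DataFrame(columns=cols)
    aligner = make_protein_aligner()
    rows = []
    for pid, pep in sorted(peptides.items()):
        for prot_id, prot in sorted(protein_db.items()):
            score = float(aligner.score(pep, prot)) if pep and prot else 0.0
            rows.append(
                {"peptide_id": pid, "protein_id": prot_id, "score": score, "hit": score >= min_score}
            )
    return pd.DataFrame(rows, columns=cols)


def coding_evidence_flags(hits: pd.DataFrame) -> set[str]:
    """Peptide/transcript ids with at least one protein-database hit."""
    if hits.empty:
        return set()
    return set(hits.loc[hits.hit, "peptide_id"])
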