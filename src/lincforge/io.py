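"""File I/O: FASTA, FASTQ, GTF and TSV tables.

FASTA/FASTQ go through Biopython.  GTF (v2.2, 1-based inclusive) is read and
written here directly — the files the pipeline exchanges carry only gene and
exon records with ``gene_id``/``transcript_id`` attributes, and conversion to
the internal 0-based half-open convention happens at this boundary.
"""
from __future__ import annotations

import re
from collections import OrderedDict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_fasta(path) -> "OrderedDict[str, str]":
    """Read a FASTA file into an ordered id → sequence mapping."""
    return OrderedDict((r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta"))


def write_fasta(seqs: dict, path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path) -> list[tuple[str, str]]:
    """Read single-end FASTQ into (read_id, sequence) pairs."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 35) -> None:
    """Write reads with a constant Phred+33 quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def _parse_attributes(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def read_gtf_transcripts(path) -> list[TranscriptModel]:
    """Read exon records grouped by transcript_id into TranscriptModels.

    Strand conflicts within a transcript raise; exons are merged sorted.
    """
    exons: "OrderedDict[str, dict]" = OrderedDict()
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if f[2] != "exon":
            continue
        attrs = _parse_attributes(f[8])
        tid = attrs["transcript_id"]
        rec = exons.setdefault(
            tid,
            {"chrom": f[0], "strand": f[6], "exons": [], "gene": attrs.get("gene_id")},
        )
        if rec["chrom"] != f[0] or rec["strand"] != f[6]:
            raise ValueError(f"inconsistent chrom/strand for transcript {tid}")
        rec["exons"].append((int(f[3]) - 1, int(f[4])))  # to 0-based half-open
    return [
        TranscriptModel(
            id=tid, chromosome=r["chrom"], strand=r["strand"], exons=r["exons"], gene_id=r["gene"]
        )
        for tid, r in exons.items()
    ]


def read_gtf_genes(path) -> list[GeneModel]:
    """Read a reference annotation: exons grouped by gene_id."""
    genes: "OrderedDict[str, dict]" = OrderedDict()
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if f[2] not in ("exon", "gene"):
            continue
        attrs = _parse_attributes(f[8])
        gid = attrs["gene_id"]
        rec = genes.setdefault(gid, {"chrom": f[0], "strand": f[6], "exons": []})
        if f[2] == "exon":
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    out = []
    for gid, r in genes.items():
        if not r["exons"]:
            continue
        out.append(GeneModel(id=gid, chromosome=r["chrom"], strand=r["strand"], exons=r["exons"]))
    return out


def write_gtf(transcripts: list[TranscriptModel], path, source: str = "lincforge") -> None:
    """Write transcripts as GTF exon records (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            gid = t.gene_id or t.id
            for i, (s, e) in enumerate(t.exons, start=1):
                attrs = f'gene_id "{gid}"; transcript_id "{t.id}"; exon_number "{i}";'
                fh.write(
                    f"{t.chromosome}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_bed3(path) -> dict[str, list[tuple[int, int]]]:
    """BED3 intervals (already 0-based half-open) grouped by chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    for line in open(path):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, s, e = line.split()[:3]
        out.setdefault(chrom, []).append((int(s), int(e)))
    for iv in out.values():
        iv.sort()
    return out


def write_bed3(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
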