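"""Shared domain types.

Coordinates are 0-based half-open everywhere inside the package; GTF I/O
converts to and from the 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TranscriptModel:
    """A spliced transcript on a chromosome.

    ``exons`` are non-overlapping, sorted (start, end) pairs, 0-based
    half-open.  ``sequence`` is the spliced sequence (exons concatenated in
    genomic order; no reverse-complementing — the assembly is from a
    non-strand-specific library).
    """

    id: str
    chromosome: str
    strand: str  # "+", "-" or "."
    exons: list[tuple[int, int]]
    sequence: str = ""
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"{self.id}: empty/inverted exon ({s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.id}: overlapping exons")
        if self.sequence and len(self.sequence) != self.spliced_length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"spliced length {self.spliced_length}"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def subgenome(self) -> str:
        """At / Dt / scaffold, from the chromosome naming convention (A*/D*)."""
        c = self.chromosome.upper()
        if c.startswith("A"):
            return "At"
        if c.startswith("D"):
            return "Dt"
        return "scaffold"


@dataclass
class GeneModel:
    """A reference gene: the union span of its transcripts plus exon set."""

    id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class ClassCodeAssignment:
    transcript_id: str
    class_code: str  # "u", "i", "x" or "overlapping_other"
    nearest_gene_id: str | None
    distance_to_nearest_gene: int


@dataclass
class FilterParams:
    """Thresholds of the candidate-lncRNA filter cascade."""

    min_length: int = 200
    min_fpkm: float = 0.5
    min_gene_distance: int = 500
    allowed_codes: frozenset = frozenset({"u"})
    require_est_support: bool = False

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.min_fpkm <= 0 or self.min_gene_distance <= 0:
            raise ValueError("filter thresholds must be > 0")
        self.allowed_codes = frozenset(self.allowed_codes)


@dataclass
class HomologPair:
    at_id: str
    dt_id: str
    alignment_score: float
    identity: float
    coverage: float
    syntenic: bool | None = None


@dataclass
class GuideSite:
    guide_seq: str
    pam: str
    strand: str
    pam_start: int  # 0-based amplicon coordinate of the PAM's first base
    cut_pos: int  # cut falls between cut_pos-1 and cut_pos (0-based)


@dataclass
class EditCall:
    read_id: str
    outcome: str  # WT / deletion / insertion / substitution / mixed / unaligned
    length: int = 0
    offset_from_cut: int = 0
    allele_string: str = ""


@dataclass
class QpcrRecord:
    sample: str
    target_ct: float
    reference_ct: float
    method: str = "dct"
    delta_ct: float = field(init=False)
    rel_expression: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        self.delta_ct = self.target_ct - self.reference_ct


@dataclass
class GroupComparison:
    group_labels: list[str]
    means: list[float]
    sds: list[float]
    ns: list[int]
    statistic: float
    p_value: float
    test: str  # "t" or "anova"
    star: str = "ns"
    pairwise_lsd: dict = field(default_factory=dict)
    letters: dict = field(default_factory=dict)
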