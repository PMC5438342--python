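"""Core in-memory containers shared by the pipeline stages.

All genomic coordinates are 0-based, half-open ``[start, end)``. Conversion to
1-based inclusive (GFF3) happens only at file boundaries in :mod:`regulonexo.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
LOCALIZATIONS = ("IM", "OM", "C", "ND")


@dataclass
class Gene:
    """A protein-coding gene interval with functional annotation.

    ``cog`` is a single-letter COG functional category; ``localization`` is the
    subcellular location of the gene product (IM/OM inner/outer membrane,
    C cytosol, ND not determined).
    """

    id: str
    tu_id: str
    start: int
    end: int
    strand: str
    cog: str = "S"
    localization: str = "ND"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TU:
    """A transcription unit (operon): one TSS driving >= 1 contiguous genes."""

    id: str
    gene_ids: list[str]
    tss: int
    strand: str


@dataclass
class GenomeAnnotation:
    """Gene and transcription-unit structure of one (circular) genome."""

    genes: dict[str, Gene]
    tus: dict[str, TU]
    genome_length: int

    def validate(self) -> None:
        for g in self.genes.values():
            if not (0 <= g.start < g.end <= self.genome_length):
                raise ValueError(f"gene {g.id}: interval [{g.start},{g.end}) outside genome")
            if g.strand not in STRANDS:
                raise ValueError(f"gene {g.id}: bad strand {g.strand!r}")
            if g.tu_id not in self.tus:
                raise ValueError(f"gene {g.id}: unknown TU {g.tu_id!r}")
        for tu in self.tus.values():
            if not tu.gene_ids:
                raise ValueError(f"TU {tu.id} has no genes")
            for gid in tu.gene_ids:
                if gid not in self.genes or self.genes[gid].tu_id != tu.id:
                    raise ValueError(f"TU {tu.id}: inconsistent member {gid!r}")
            first = self.genes[tu.gene_ids[0]]
            if tu.strand == "+" and tu.tss > first.start:
                raise ValueError(f"TU {tu.id}: TSS downstream of first gene")
            if tu.strand == "-" and tu.tss < first.end - 1:
                raise ValueError(f"TU {tu.id}: TSS downstream of first gene")

    def genes_frame(self) -> pd.DataFrame:
        rows = [
            (g.id, g.tu_id, g.start, g.end, g.strand, g.length, g.cog, g.localization)
            for g in self.genes.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "tu", "start", "end", "strand", "length", "cog", "localization"],
        ).set_index("gene")


@dataclass
class BorderProfile:
    """Strand-specific 5'-end count track for one sequencing library.

    ``counts[i]`` is the number (or depth-normalized density) of read 5' ends at
    genome position ``i`` on ``strand``. For raw profiles the counts sum to
    ``library_size``; :func:`regulonexo.peak_calling.normalize_depth` rescales to
    reads-per-million and sets ``normalized``.
    """

    strand: str
    counts: np.ndarray
    library_size: int
    label: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts in border profile")

    @property
    def genome_length(self) -> int:
        return self.counts.size


@dataclass
class Peak:
    """A called binding peak delimited by a strand-paired border pair."""

    start: int
    end: int
    fwd_border: int
    rev_border: int
    sn: float | None = None
    support: str = "single"
    name: str = ""

    def __post_init__(self) -> None:
        if self.fwd_border > self.rev_border:
            raise ValueError("forward border must not exceed reverse border")
        if self.end <= self.start:
            raise ValueError("empty peak interval")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Peak") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class CountTable:
    """Gene x sample integer RNA-seq counts for a two-condition design."""

    counts: pd.DataFrame            # genes x samples, integer
    conditions: dict[str, str]      # sample -> "WT" | "KO"
    lengths: pd.Series              # per-gene length, bp
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        conds = set(self.conditions.values())
        if conds != {"WT", "KO"}:
            raise ValueError(f"need exactly conditions WT and KO, got {sorted(conds)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T with a 0-order background."""

    matrix: np.ndarray      # (width, 4) probabilities
    background: np.ndarray  # (4,) probabilities

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("PWM background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy(), self.background[::-1].copy())


@dataclass
class PlantedSite:
    """Ground-truth binding site planted by the generator."""

    center: int
    start: int
    end: int
    tu_id: str | None
    previously_known: bool = False
    has_signal: bool = True
    is_artifact: bool = False   # shared with the mock-IP track; must be filtered


@dataclass
class ScenarioTruth:
    """Everything the generator planted, for recovery checks downstream."""

    sites: list[PlantedSite]
    gene_modes: dict[str, str]          # gene -> activated|repressed|unchanged
    effect_sizes: dict[str, float]      # |log2| effect for non-unchanged genes
    pwm: PWM
    indirect_de: dict[str, float]       # gene -> signed log2 effect, no binding site
    tf_gene: str
    library_sizes: dict[str, int] = field(default_factory=dict)
    base_expression: dict[str, float] = field(default_factory=dict)

    @property
    def signal_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.has_signal and not s.is_artifact]

    @property
    def known_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.previously_known]

    @property
    def de_genes(self) -> set[str]:
        """All genes planted to change on knockout: direct targets, indirect
        responders, and the deleted TF gene itself."""
        direct = {g for g, m in self.gene_modes.items() if m in ("activated", "repressed")}
        return direct | set(self.indirect_de) | {self.tf_gene}


@dataclass
class RegulonEntry:
    """A bound TU with its causal regulatory classification."""

    tu_id: str
    gene_ids: list[str]
    peak_names: list[str]
    distance: int               # peak center -> TSS, signed, strand-aware
    location: str               # upstream | promoter | 5p_proximal
    mode: str                   # activated | repressed | not_determined | conflict


@dataclass
class GrowthCurve:
    """OD600 time course for one strain under one condition."""

    time: np.ndarray     # hours, ascending
    od: np.ndarray       # OD600
    strain: str
    condition: str       # normal | osmotic

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.size != self.od.size:
            raise ValueError("time and OD vectors differ in length")
        if self.time.size < 5:
            raise ValueError("growth curve needs >= 5 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("OD values must be positive")


@dataclass
class SyntheticDataset:
    """One fully consistent synthetic study: sequences, tracks, tables, truth."""

    genome: str
    annotation: GenomeAnnotation
    chip: dict[str, tuple[BorderProfile, BorderProfile]]   # label -> (fwd, rev)
    counts: CountTable
    membership: pd.DataFrame          # gene x TF binary (stress TFs + extra TFs)
    stress_tfs: list[str]
    focal_tf: str
    orthologs: pd.DataFrame           # gene x genome binary presence
    genome_groups: pd.Series          # genome -> taxon group
    growth: list[GrowthCurve]
    truth: ScenarioTruth
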