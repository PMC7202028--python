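"""Domain types, coordinate conventions, and annotation I/O.

All internal coordinates are 0-based, half-open ``[start, end)``. GFF3 carries
1-based closed coordinates; the readers and writers in this module convert at
the boundary, so every other module can do interval arithmetic without
off-by-one bookkeeping. The transcription start site (TSS) of a minus-strand
gene is the annotation's *end* coordinate (the internal exclusive end), which
makes promoter and flank definitions strand-symmetric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Closed set of transposable-element superfamily codes (three-letter wicker
#: codes: LTR retrotransposons RLC/RLG/RLX, LINEs RIL/RIT, SINEs RST, TIR DNA
#: transposons DTA/DTC/DTH/DTM/DTT/DTX, Helitrons DHH).
TE_SUPERFAMILIES = (
    "RLC", "RLG", "RLX", "RIL", "RIT", "RST",
    "DTA", "DTC", "DTH", "DTM", "DTT", "DTX", "DHH",
)


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input (carries the offending line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``truncated`` marks intervals that were clipped at a chromosome boundary
    (e.g. a promoter of a gene close to the start of a contig); such intervals
    are kept, not dropped, so gene counts are preserved downstream.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.end == self.start

    def intersects(self, other: "GenomicInterval") -> bool:
        """Half-open intersection test (a shared single base counts)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_bed6(self, name: str = ".", score: str = ".") -> str:
        return "\t".join(
            (self.chrom, str(self.start), str(self.end), name, score, self.strand)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TTS anchors.

    ``start < end`` always; ``tss`` is ``start`` on the plus strand and ``end``
    on the minus strand, ``tts`` is the opposite anchor.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} not < end {self.end}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TERecord:
    """A transposable element with its superfamily code and location."""

    te_id: str
    superfamily: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.superfamily not in TE_SUPERFAMILIES:
            raise ValueError(
                f"TE {self.te_id}: unknown superfamily {self.superfamily!r}"
            )


@dataclass
class AnalysisConfig:
    """Thresholds and lengths shared across pipeline stages.

    Defaults follow the study design: a twofold expression cutoff of
    |log2FC| >= 0.95 at FDR <= 0.05, a counts-per-million floor of 0.58 for
    low-abundance removal, 2-kb promoters tiled at 100 bp, and 2-kb gene
    flanks for TE context. Methylation filters: genome-wide regions need >=5x
    mean coverage and >=2 sites; promoter regions need >=2x and >=2 sites;
    level gates of 10% (CG/CHG) and 1% (CHH) decide whether a region counts
    as methylated at all. Differential promoters: >=40 percentage points
    absolute difference for CG/CHG; for CHH, the lower sample at <=5% and a
    difference of >=15 points; a CG gain of >=10 points is flagged as CG
    hypermethylation. siRNA depletion: corrected log2 fold change <= -1 with
    a binomial test at p <= 0.05, over regions with pooled CPM >= 1 in at
    least one genotype.
    """

    lfc_min: float = 0.95
    fdr_max: float = 0.05
    cpm_min: float = 0.58
    promoter_len: int = 2000
    tile_len: int = 100
    flank_len: int = 2000
    # methylation filters
    gw_min_coverage: float = 5.0
    gw_min_sites: int = 2
    promoter_min_coverage: float = 2.0
    promoter_min_sites: int = 2
    level_min: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.10, "CHG": 0.10, "CHH": 0.01}
    )
    # differential-promoter thresholds (percentage points)
    diff_cg_chg_min: float = 40.0
    diff_chh_min: float = 15.0
    diff_chh_low_max: float = 0.05
    cg_hyper_min: float = 10.0
    # siRNA depletion
    sirna_lfc_max: float = -1.0
    sirna_p_max: float = 0.05
    sirna_cpm_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_len", "tile_len", "flank_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.fdr_max <= 1:
            raise ValueError("fdr_max must be in [0, 1]")
        if self.lfc_min < 0 or self.cpm_min < 0:
            raise ValueError("lfc_min and cpm_min must be non-negative")


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

def read_gene_models(gff3_source: str | Path) -> list[GeneModel]:
    """Read gene features from GFF3 into :class:`GeneModel` records.

    Coordinates are converted from GFF3's 1-based closed convention to the
    internal 0-based half-open one. Records with an unknown strand are skipped
    with a warning; duplicated gene identifiers raise.
    """
    genes: list[GeneModel] = []
    seen: dict[str, int] = {}
    for lineno, feature in _iter_gff3(gff3_source):
        if feature.featuretype != "gene":
            continue
        gene_id = _feature_id(feature)
        if feature.strand not in {"+", "-"}:
            warnings.warn(
                f"gene {gene_id} (line {lineno}): unknown strand "
                f"{feature.strand!r}; record skipped"
            )
            continue
        if gene_id in seen:
            raise ValueError(
                f"duplicate gene_id {gene_id!r} at lines {seen[gene_id]} and "
                f"{lineno}"
            )
        seen[gene_id] = lineno
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feature.seqid,
                strand=feature.strand,
                start=feature.start - 1,
                end=feature.end,
            )
        )
    return genes


def read_te_records(
    gff3_source: str | Path, superfamily_attr: str = "superfamily"
) -> list[TERecord]:
    """Read a TE annotation; the superfamily code is taken from the named
    attribute, falling back to the first three characters of the feature type
    (the convention of structural maize TE annotations)."""
    records: list[TERecord] = []
    for lineno, feature in _iter_gff3(gff3_source):
        attrs = dict(feature.attributes)
        if superfamily_attr in attrs:
            code = attrs[superfamily_attr][0]
        else:
            code = feature.featuretype[:3]
        te_id = _feature_id(feature)
        try:
            records.append(
                TERecord(
                    te_id=te_id,
                    superfamily=code,
                    interval=GenomicInterval(
                        feature.seqid,
                        feature.start - 1,
                        feature.end,
                        feature.strand if feature.strand in "+-" else ".",
                    ),
                )
            )
        except ValueError as exc:
            raise Gff3ParseError(f"line {lineno}: {exc}") from exc
    return records


def _iter_gff3(source: str | Path) -> Iterator[tuple[int, "gffutils.Feature"]]:
    """Yield ``(line_number, feature)`` from a GFF3 file, with parse errors
    reported by line number."""
    path = Path(source)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise Gff3ParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    "fields"
                )
            try:
                feature = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions
                raise Gff3ParseError(
                    f"{path.name} line {lineno}: malformed GFF3 line"
                ) from exc
            yield lineno, feature


def _feature_id(feature: "gffutils.Feature") -> str:
    attrs = dict(feature.attributes)
    for key in ("ID", "Name", "gene_id"):
        if key in attrs:
            ident = attrs[key][0]
            return ident.split(":", 1)[1] if ident.startswith("gene:") else ident
    raise Gff3ParseError(f"feature at {feature.seqid}:{feature.start} has no ID")


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (converting back to 1-based closed)."""
    with Path(path).open("w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                "\t".join(
                    (
                        g.chrom, "abarddm", "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".",
                        f"ID={g.gene_id}",
                    )
                )
                + "\n"
            )


def write_te_records(records: Iterable[TERecord], path: str | Path) -> None:
    with Path(path).open("w") as out:
        out.write("##gff-version 3\n")
        for r in records:
            iv = r.interval
            out.write(
                "\t".join(
                    (
                        iv.chrom, "abarddm", "transposable_element",
                        str(iv.start + 1), str(iv.end), ".",
                        iv.strand if iv.strand != "." else ".", ".",
                        f"ID={r.te_id};superfamily={r.superfamily}",
                    )
                )
                + "\n"
            )


def write_genome_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_bed6(intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    """Export named intervals as BED6 with a commented header line."""
    with Path(path).open("w") as out:
        out.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv, name in intervals:
            out.write(iv.to_bed6(name=name) + "\n")


# ---------------------------------------------------------------------------
# Promoters and flanks
# ---------------------------------------------------------------------------

def promoter_region(
    gene: GeneModel,
    length: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """The ``length``-bp region immediately upstream of the TSS, strand-aware.

    Truncated (never negative) at chromosome boundaries; when ``chrom_lengths``
    is given the right edge is clipped too and unknown chromosomes raise.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    chrom_len = _chrom_len(gene, chrom_lengths)
    if gene.strand == "+":
        start, end = gene.tss - length, gene.tss
    else:
        start, end = gene.tss, gene.tss + length
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_len is not None and end > chrom_len:
        end, truncated = chrom_len, True
    end = max(end, start)
    return GenomicInterval(gene.chrom, start, end, gene.strand, truncated=truncated)


def gene_flanks(
    gene: GeneModel,
    length: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[GenomicInterval, GenomicInterval]:
    """``(upstream_of_TSS, downstream_of_TTS)`` flanks, strand-aware and
    boundary-truncated. Either flank may come back empty (and flagged) for a
    gene abutting a contig edge."""
    upstream = promoter_region(gene, length, chrom_lengths)
    chrom_len = _chrom_len(gene, chrom_lengths)
    if gene.strand == "+":
        start, end = gene.tts, gene.tts + length
    else:
        start, end = gene.tts - length, gene.tts
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_len is not None and end > chrom_len:
        end, truncated = chrom_len, True
    end = max(end, start)
    downstream = GenomicInterval(
        gene.chrom, start, end, gene.strand, truncated=truncated
    )
    return upstream, downstream


def _chrom_len(
    gene: GeneModel, chrom_lengths: Mapping[str, int] | None
) -> int | None:
    if chrom_lengths is None:
        return None
    if gene.chrom not in chrom_lengths:
        raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
    return chrom_lengths[gene.chrom]


def promoter_sequence(
    gene: GeneModel,
    genome: Mapping[str, str],
    length: int,
) -> str:
    """Promoter sequence oriented 5'->3' on the gene's strand, so that the
    final base is adjacent to the TSS."""
    region = promoter_region(
        gene, length, {c: len(s) for c, s in genome.items()}
    )
    seq = genome[gene.chrom][region.start:region.end]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()
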