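"""ABRE/CE promoter scanning and the primary-target regulatory cascade.

A *primary* ABA target is a differentially expressed gene whose 2-kb promoter
carries at least two ABRE (ABA-responsive element) sites, or one ABRE plus a
coupling element (CE). Primary targets are then used as regulators in a
tissue-specific gene regulatory network (GRN): every DEG reachable by one
regulator->target edge from a primary is a predicted *secondary* target, and
the fraction of DEGs explained is ``(primary + secondary) / total DEGs``.

The ABRE is matched as an exact degenerate-base pattern (default consensus
``CACG[TC]G[TG]C[GC]``) on both strands; no position-weight-matrix scoring is
involved, so scanning is deterministic. CE consensus sequences are not part
of the default scan set ("strict" mode); a small literature-derived CE set
(CE1, CE3) is available via :func:`literature_ce_motifs` and any motif can be
supplied explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .core import GeneModel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

ABRE_PATTERN = "CACG[TC]G[TG]C[GC]"


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate-base motif; brackets enumerate allowed bases at one
    position and single letters may be IUPAC codes."""

    name: str
    pattern: str
    both_strands: bool = True

    def positions(self) -> list[str]:
        """Allowed-base string per position (e.g. 'TC' for [TC] or Y)."""
        out: list[str] = []
        i = 0
        while i < len(self.pattern):
            ch = self.pattern[i]
            if ch == "[":
                j = self.pattern.index("]", i)
                allowed = self.pattern[i + 1 : j]
                if not allowed or any(b not in "ACGT" for b in allowed):
                    raise ValueError(f"invalid bracket set in {self.pattern!r}")
                out.append(allowed)
                i = j + 1
            elif ch.upper() in IUPAC:
                out.append(IUPAC[ch.upper()])
                i += 1
            else:
                raise ValueError(f"invalid pattern character {ch!r}")
        if len(out) < 5:
            raise ValueError("motif pattern must span at least 5 positions")
        return out

    def __len__(self) -> int:
        return len(self.positions())

    def regex(self) -> re.Pattern:
        # lookahead makes overlapping matches visible
        body = "".join(
            p if len(p) == 1 else f"[{p}]" for p in self.positions()
        )
        return re.compile(f"(?=({body}))")


def abre_motif() -> MotifSpec:
    return MotifSpec("ABRE", ABRE_PATTERN)


def literature_ce_motifs() -> list[MotifSpec]:
    """Coupling-element consensi from the cereal ABA literature (CE1 of the
    barley HVA22 promoter, CE3 of HVA1); off by default — supply explicitly
    to scan for CEs."""
    return [
        MotifSpec("CE1", "TGCCACCGG"),
        MotifSpec("CE3", "ACGCGTGTCCTC"),
    ]


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    offset: int  # match start relative to the TSS; negative = upstream
    strand: str  # strand of the match relative to the promoter orientation


@dataclass(frozen=True)
class PrimaryTargetCall:
    gene_id: str
    n_abre: int
    n_ce: int
    is_deg: bool
    is_primary: bool


@dataclass(frozen=True)
class GRNEdge:
    regulator: str
    target: str
    tissue: str = ""
    tier: str = ""


def scan_motif(
    sequence: str,
    spec: MotifSpec,
    gene_id: str = "",
    tss_offset: int | None = None,
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches in a promoter sequence.

    The sequence is taken to be promoter-oriented with its final base
    adjacent to the TSS, so a match starting at string index ``i`` lies at
    offset ``i - len(sequence)`` from the TSS. ``N`` bases never satisfy a
    constrained position. With ``both_strands`` set, the reverse complement
    is scanned too and its matches are reported in forward coordinates.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    length = len(spec)
    base = -len(seq) if tss_offset is None else tss_offset
    hits = [
        MotifHit(gene_id, spec.name, base + m.start(), "+")
        for m in spec.regex().finditer(seq)
    ]
    if spec.both_strands:
        rc = str(Seq(seq).reverse_complement())
        for m in spec.regex().finditer(rc):
            fwd_start = len(seq) - m.start() - length
            hits.append(MotifHit(gene_id, spec.name, base + fwd_start, "-"))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def scan_promoters(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    specs: Sequence[MotifSpec],
    promoter_len: int = 2000,
) -> list[MotifHit]:
    from .core import promoter_sequence

    hits: list[MotifHit] = []
    for gene in genes:
        seq = promoter_sequence(gene, genome, promoter_len)
        for spec in specs:
            hits.extend(scan_motif(seq, spec, gene_id=gene.gene_id))
    return hits


def classify_primary(
    gene_id: str,
    abre_hits: int | Sequence[MotifHit],
    ce_hits: int | Sequence[MotifHit],
    is_deg: bool,
    override_primary: Iterable[str] = (),
) -> PrimaryTargetCall:
    """Primary-target rule: a DEG with >=2 ABREs, or >=1 ABRE plus >=1 CE.

    ``override_primary`` lists curated genes forced primary regardless of the
    motif evidence (the literature-identified set) — the DEG requirement
    still applies.
    """
    n_abre = abre_hits if isinstance(abre_hits, int) else len(abre_hits)
    n_ce = ce_hits if isinstance(ce_hits, int) else len(ce_hits)
    if n_abre < 0 or n_ce < 0:
        raise ValueError("hit counts must be non-negative")
    by_motif = n_abre >= 2 or (n_abre >= 1 and n_ce >= 1)
    is_primary = is_deg and (by_motif or gene_id in set(override_primary))
    return PrimaryTargetCall(gene_id, n_abre, n_ce, is_deg, is_primary)


def classify_primaries(
    hits: Sequence[MotifHit],
    deg_set: set[str],
    gene_ids: Iterable[str],
    abre_names: set[str] = frozenset({"ABRE"}),
    override_primary: Iterable[str] = (),
) -> list[PrimaryTargetCall]:
    """Apply the primary rule to every gene given its scan hits (motifs not
    named in ``abre_names`` count as coupling elements)."""
    abre_counts: dict[str, int] = {}
    ce_counts: dict[str, int] = {}
    for h in hits:
        bucket = abre_counts if h.motif in abre_names else ce_counts
        bucket[h.gene_id] = bucket.get(h.gene_id, 0) + 1
    override = set(override_primary)
    return [
        classify_primary(
            g,
            abre_counts.get(g, 0),
            ce_counts.get(g, 0),
            g in deg_set,
            override_primary=override,
        )
        for g in gene_ids
    ]


def read_grn_edges(path) -> list[GRNEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GRNEdge(
            regulator=row["regulator"],
            target=row["target"],
            tissue=row.get("tissue", ""),
            tier=str(row.get("tier", "")),
        )
        for _, row in df.iterrows()
    ]


def predict_secondary(
    primaries: set[str],
    grn: Sequence[GRNEdge],
    deg_set: set[str],
    tissues: set[str] | None = None,
    allow_self_loops: bool = False,
    multi_step: bool = False,
) -> set[str]:
    """Predicted secondary targets: DEG targets of GRN edges whose regulator
    is a primary target, minus the primaries themselves.

    Propagation is single-step by default (``multi_step`` closes the
    expansion transitively through DEGs). Regulators absent from the GRN
    simply contribute no edges. ``tissues`` restricts to edges of those
    tissues; the default is the union over all tissues.
    """
    adjacency: dict[str, set[str]] = {}
    for e in grn:
        if tissues is not None and e.tissue not in tissues:
            continue
        if not allow_self_loops and e.regulator == e.target:
            continue
        adjacency.setdefault(e.regulator, set()).add(e.target)

    frontier = set(primaries)
    secondary: set[str] = set()
    while frontier:
        reached: set[str] = set()
        for reg in frontier:
            reached |= adjacency.get(reg, set())
        new = (reached & deg_set) - primaries - secondary
        secondary |= new
        frontier = new if multi_step else set()
    return secondary


def explained_fraction(n_primary: int, n_secondary: int, n_total_deg: int) -> float:
    """Percent of DEGs accounted for by primary targets plus their predicted
    secondary targets."""
    if n_total_deg == 0:
        raise ZeroDivisionError("no DEGs to explain")
    if min(n_primary, n_secondary) < 0 or n_primary + n_secondary > n_total_deg:
        raise ValueError("counts must be non-negative and sum to <= total DEGs")
    return 100.0 * (n_primary + n_secondary) / n_total_deg


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "motif": [h.motif for h in hits],
            "offset": [h.offset for h in hits],
            "strand": [h.strand for h in hits],
        }
    )


def calls_to_frame(calls: Sequence[PrimaryTargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "n_abre": [c.n_abre for c in calls],
            "n_ce": [c.n_ce for c in calls],
            "is_deg": [c.is_deg for c in calls],
            "is_primary": [c.is_primary for c in calls],
        }
    )
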