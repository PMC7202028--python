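"""Transposable-element superfamily context of gene flanks.

For a gene set of interest (e.g. genes up- or down-regulated by ABA in the
RdDM mutant), every TE whose interval intersects a gene's 2-kb upstream or
downstream flank is collected, the superfamily composition of those TEs is
expressed as percentages, and the composition is compared against the
genome-wide TE background as percentage-point deltas per superfamily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, TERecord, TE_SUPERFAMILIES, gene_flanks


@dataclass(frozen=True)
class TEContextRecord:
    gene_id: str
    te_id: str
    superfamily: str
    flank: str  # upstream | downstream
    distance: int  # gap to the flank-anchoring gene boundary; 0 if touching


def flanking_tes(
    genes: Sequence[GeneModel],
    tes: Sequence[TERecord],
    flank_len: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
    nearest_only: bool = False,
) -> list[TEContextRecord]:
    """All TEs intersecting each gene's upstream/downstream flank.

    A TE may be reported for several genes; distance ties are all kept. With
    ``nearest_only`` each gene/flank reports only its closest TE (the
    bedtools-closest style view).
    """
    trees: dict[str, IntervalTree] = {}
    for i, te in enumerate(tes):
        iv = te.interval
        if iv.is_empty:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    records: list[TEContextRecord] = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        upstream, downstream = gene_flanks(gene, flank_len, chrom_lengths)
        for flank_name, flank, anchor in (
            ("upstream", upstream, gene.tss),
            ("downstream", downstream, gene.tts),
        ):
            if flank.is_empty:
                continue
            found = []
            for hit in tree.overlap(flank.start, flank.end):
                te = tes[hit.data]
                iv = te.interval
                # gap to the gene boundary anchoring this flank; 0 when the
                # TE touches or spans it
                distance = max(iv.start - anchor, anchor - iv.end, 0)
                found.append(
                    TEContextRecord(
                        gene_id=gene.gene_id,
                        te_id=te.te_id,
                        superfamily=te.superfamily,
                        flank=flank_name,
                        distance=distance,
                    )
                )
            if nearest_only and found:
                dmin = min(r.distance for r in found)
                found = [r for r in found if r.distance == dmin]
            records.extend(sorted(found, key=lambda r: (r.distance, r.te_id)))
    return records


def superfamily_distribution(
    records: Sequence[TEContextRecord] | Sequence[TERecord] | set[str],
    tes_by_id: Mapping[str, TERecord] | None = None,
    deduplicate: bool = False,
) -> pd.Series:
    """Percent of TEs per superfamily over the closed code set (sums to 100).

    Accepts flank context records, TE records, or a set of TE identifiers
    (with ``tes_by_id``). ``deduplicate`` counts a TE once globally even when
    it flanks several genes.
    """
    items = list(records)
    if not items:
        raise ValueError("cannot take a distribution of an empty TE set")
    if isinstance(items[0], str):
        if tes_by_id is None:
            raise ValueError("tes_by_id required when passing TE identifiers")
        fams = [tes_by_id[t].superfamily for t in items]
    elif isinstance(items[0], TEContextRecord):
        if deduplicate:
            seen = {r.te_id: r.superfamily for r in items}
            fams = list(seen.values())
        else:
            fams = [r.superfamily for r in items]
    else:
        fams = [t.superfamily for t in items]
    counts = pd.Series(fams).value_counts()
    dist = counts.reindex(TE_SUPERFAMILIES, fill_value=0).astype(float)
    return 100.0 * dist / dist.sum()


def distribution_delta(foreground: pd.Series, background: pd.Series) -> pd.Series:
    """Foreground minus background, percentage points per superfamily."""
    fg = foreground.reindex(TE_SUPERFAMILIES, fill_value=0.0)
    bg = background.reindex(TE_SUPERFAMILIES, fill_value=0.0)
    return fg - bg


def context_table(
    foreground: pd.Series, background: pd.Series
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "superfamily": TE_SUPERFAMILIES,
            "foreground_pct": foreground.reindex(TE_SUPERFAMILIES, fill_value=0.0).to_numpy(),
            "background_pct": background.reindex(TE_SUPERFAMILIES, fill_value=0.0).to_numpy(),
            "delta_pct": distribution_delta(foreground, background).to_numpy(),
        }
    )
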