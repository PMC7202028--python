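"""Weighted methylation ratios, tiling, and differential-promoter calls.

Methylation of a region is the *weighted* (pooled) ratio
``sum(#C) / sum(#C + #T)`` over the region's cytosines of a given context —
not the mean of per-site ratios — so deeply covered sites carry more weight
and disjoint regions pool exactly. Contexts are CG, CHG and CHH (H = A, T or
C); CHH is the context laid down by RNA-directed DNA methylation and hence
the one expected to collapse in an RdDM-deficient mutant.

Two comparison scales are used throughout:

* relative difference, ``100 * (a - b) / b`` — a percentage *of* the
  reference level (a 68% CHH reduction means the mutant ratio is 0.32x);
* absolute difference, ``100 * (a - b)`` — percentage *points*, used by the
  differential-promoter thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, GeneModel, GenomicInterval, promoter_region

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

CALL_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")


@dataclass(frozen=True)
class RegionMethylation:
    """Pooled methylation of one region and context."""

    interval: GenomicInterval
    context: str
    mc: float  # pooled ratio in [0, 1]; NaN when non-evaluable
    n_sites: int
    coverage: float  # mean reads per covered site
    evaluable: bool


@dataclass(frozen=True)
class PromoterTile:
    """One 100-bp (by default) promoter tile; index 1 is TSS-proximal and
    indices increase upstream."""

    gene_id: str
    tile_index: int
    context: str
    mc: float
    n_sites: int
    coverage: float
    evaluable: bool


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    context: str
    mc_a: float
    mc_b: float
    call: str  # none | differential | CG_hypermethylated


def read_cytosine_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine call table missing columns {sorted(missing)}")
    _validate_calls(df)
    return df


def write_cytosine_calls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(CALL_COLUMNS))


def _validate_calls(df: pd.DataFrame) -> None:
    bad = df["n_meth"] > df["n_total"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"n_meth > n_total at {row['chrom']}:{row['pos']} "
            f"({row['n_meth']} > {row['n_total']})"
        )
    unknown = set(df["context"]) - set(CONTEXTS)
    if unknown:
        raise ValueError(f"unknown methylation contexts: {sorted(unknown)}")


class MethylomeIndex:
    """Position-sorted prefix-sum index over cytosine calls for O(log n)
    pooled-count queries per (chromosome, context)."""

    def __init__(self, calls: pd.DataFrame):
        _validate_calls(calls)
        self._chunks: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (chrom, context), sub in calls.groupby(["chrom", "context"], sort=False):
            sub = sub.sort_values("pos")
            pos = sub["pos"].to_numpy(dtype=np.int64)
            cum_meth = np.concatenate(
                ([0], np.cumsum(sub["n_meth"].to_numpy(dtype=np.int64)))
            )
            cum_total = np.concatenate(
                ([0], np.cumsum(sub["n_total"].to_numpy(dtype=np.int64)))
            )
            self._chunks[(chrom, context)] = (pos, cum_meth, cum_total)

    def region_counts(
        self, interval: GenomicInterval, context: str
    ) -> tuple[int, int, int]:
        """``(n_meth, n_total, n_sites)`` pooled over in-region sites."""
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        chunk = self._chunks.get((interval.chrom, context))
        if chunk is None:
            return 0, 0, 0
        pos, cum_meth, cum_total = chunk
        lo = int(np.searchsorted(pos, interval.start, side="left"))
        hi = int(np.searchsorted(pos, interval.end, side="left"))
        return (
            int(cum_meth[hi] - cum_meth[lo]),
            int(cum_total[hi] - cum_total[lo]),
            hi - lo,
        )

    def genome_counts(
        self, context: str, exclude_chroms: Sequence[str] = ()
    ) -> tuple[int, int, int]:
        n_meth = n_total = n_sites = 0
        for (chrom, ctx), (pos, cm, ct) in self._chunks.items():
            if ctx != context or chrom in exclude_chroms:
                continue
            n_meth += int(cm[-1])
            n_total += int(ct[-1])
            n_sites += len(pos)
        return n_meth, n_total, n_sites


def _as_index(calls: pd.DataFrame | MethylomeIndex) -> MethylomeIndex:
    return calls if isinstance(calls, MethylomeIndex) else MethylomeIndex(calls)


def weighted_mc(
    calls: pd.DataFrame | MethylomeIndex,
    region: GenomicInterval,
    context: str,
) -> RegionMethylation:
    """Pooled methylation ratio of one region and context.

    A region with zero in-region sites (or zero total reads) is returned
    non-evaluable with ``mc`` NaN.
    """
    index = _as_index(calls)
    n_meth, n_total, n_sites = index.region_counts(region, context)
    if n_sites == 0 or n_total == 0:
        return RegionMethylation(region, context, float("nan"), n_sites, 0.0, False)
    return RegionMethylation(
        region,
        context,
        n_meth / n_total,
        n_sites,
        n_total / n_sites,
        True,
    )


def pooled_mc(
    calls: pd.DataFrame | MethylomeIndex,
    context: str,
    exclude_chroms: Sequence[str] = (),
) -> float:
    """Genome-wide pooled ratio for one context (optionally excluding
    organellar contigs)."""
    n_meth, n_total, _ = _as_index(calls).genome_counts(context, exclude_chroms)
    if n_total == 0:
        raise ValueError(f"no covered {context} sites")
    return n_meth / n_total


def conversion_rate(
    calls: pd.DataFrame | MethylomeIndex, contig: str
) -> float:
    """Bisulfite conversion rate from a designated unmethylated contig
    (typically the chloroplast): 1 minus the pooled ratio over all contexts."""
    index = _as_index(calls)
    n_meth = n_total = 0
    for context in CONTEXTS:
        m, t, _ = index.region_counts(
            GenomicInterval(contig, 0, np.iinfo(np.int64).max - 1), context
        )
        n_meth += m
        n_total += t
    if n_total == 0:
        raise ValueError(f"no coverage on unmethylated contig {contig!r}")
    return 1.0 - n_meth / n_total


def passes_filters(
    rm: RegionMethylation,
    mode: str,
    config: AnalysisConfig | None = None,
) -> bool:
    """Coverage/site evaluability filter: genome-wide regions need >=5x mean
    coverage and >=2 sites, promoter regions >=2x and >=2 sites (boundaries
    inclusive). The 10%/1% *level* minima are a separate reporting gate, see
    :func:`is_methylated`."""
    config = config or AnalysisConfig()
    if not rm.evaluable:
        return False
    if mode == "genome_wide":
        return (
            rm.coverage >= config.gw_min_coverage
            and rm.n_sites >= config.gw_min_sites
        )
    if mode == "promoter":
        return (
            rm.coverage >= config.promoter_min_coverage
            and rm.n_sites >= config.promoter_min_sites
        )
    raise ValueError(f"unknown filter mode {mode!r}")


def is_methylated(rm: RegionMethylation, config: AnalysisConfig | None = None) -> bool:
    """Level gate deciding whether a region counts as methylated at all:
    >=10% for CG and CHG, >=1% for CHH."""
    config = config or AnalysisConfig()
    return rm.evaluable and rm.mc >= config.level_min[rm.context]


def relative_diff(mc_a: float, mc_b: float) -> float:
    """``100 * (a - b) / b`` — percent change relative to the reference b."""
    if mc_b == 0:
        raise ZeroDivisionError("relative_diff undefined for mc_b == 0")
    return 100.0 * (mc_a - mc_b) / mc_b


def absolute_diff(mc_a: float, mc_b: float) -> float:
    """``100 * (a - b)`` — difference in percentage points."""
    return 100.0 * (mc_a - mc_b)


def tile_promoter(
    gene: GeneModel,
    calls: pd.DataFrame | MethylomeIndex,
    config: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    contexts: Sequence[str] = CONTEXTS,
) -> list[PromoterTile]:
    """Split the promoter into ``tile_len`` tiles and pool methylation per
    tile and context. Tile 1 abuts the TSS; indices grow upstream. Tiles with
    no covered sites come back non-evaluable; promoters truncated at a contig
    edge simply yield fewer tiles."""
    config = config or AnalysisConfig()
    index = _as_index(calls)
    promoter = promoter_region(gene, config.promoter_len, chrom_lengths)
    n_tiles = len(promoter) // config.tile_len
    if len(promoter) % config.tile_len and promoter.truncated:
        n_tiles += 1  # keep the partial outermost tile of a clipped promoter
    tiles: list[PromoterTile] = []
    for i in range(1, n_tiles + 1):
        if gene.strand == "+":
            end = promoter.end - (i - 1) * config.tile_len
            start = max(promoter.start, end - config.tile_len)
        else:
            start = promoter.start + (i - 1) * config.tile_len
            end = min(promoter.end, start + config.tile_len)
        iv = GenomicInterval(gene.chrom, start, end, gene.strand)
        for context in contexts:
            rm = weighted_mc(index, iv, context)
            tiles.append(
                PromoterTile(
                    gene_id=gene.gene_id,
                    tile_index=i,
                    context=context,
                    mc=rm.mc,
                    n_sites=rm.n_sites,
                    coverage=rm.coverage,
                    evaluable=rm.evaluable,
                )
            )
    return tiles


def promoter_mean_mc(tiles: Iterable[PromoterTile], context: str) -> float:
    """Per-gene promoter average: mean of evaluable tile ratios (tiles with
    no data removed, per the tiling rule)."""
    values = [t.mc for t in tiles if t.context == context and t.evaluable]
    if not values:
        return float("nan")
    return float(np.mean(values))


def metagene_profile(
    genes: Sequence[GeneModel],
    calls: pd.DataFrame | MethylomeIndex,
    context: str,
    config: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Mean methylation per tile index across genes (the TSS-anchored
    metagene curve). Returns columns ``tile_index``, ``mean_mc``, ``n_genes``;
    empty input yields an empty frame."""
    config = config or AnalysisConfig()
    index = _as_index(calls)
    per_tile: dict[int, list[float]] = {}
    for gene in genes:
        for tile in tile_promoter(
            gene, index, config, chrom_lengths, contexts=(context,)
        ):
            if tile.evaluable:
                per_tile.setdefault(tile.tile_index, []).append(tile.mc)
    rows = [
        {"tile_index": i, "mean_mc": float(np.mean(v)), "n_genes": len(v)}
        for i, v in sorted(per_tile.items())
    ]
    return pd.DataFrame(rows, columns=["tile_index", "mean_mc", "n_genes"])


def call_differential_promoter(
    mc_a: float,
    mc_b: float,
    context: str,
    gene_id: str = "",
    config: AnalysisConfig | None = None,
) -> DifferentialCall:
    """Threshold rules for a differentially methylated promoter.

    CG/CHG: differential when the absolute difference reaches 40 percentage
    points. CHH: differential when the lower of the two levels is at most 5%
    and the absolute difference reaches 15 points. A CG gain of at least 10
    points is additionally labelled CG hypermethylation (which implies the
    region is reported as differential)."""
    config = config or AnalysisConfig()
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    diff = absolute_diff(mc_a, mc_b)
    call = "none"
    if context in ("CG", "CHG") and abs(diff) >= config.diff_cg_chg_min:
        call = "differential"
    if context == "CHH":
        if min(mc_a, mc_b) <= config.diff_chh_low_max and abs(diff) >= config.diff_chh_min:
            call = "differential"
    if context == "CG" and diff >= config.cg_hyper_min:
        call = "CG_hypermethylated"
    return DifferentialCall(gene_id=gene_id, context=context, mc_a=mc_a, mc_b=mc_b, call=call)


def differential_promoter_table(
    genes: Sequence[GeneModel],
    calls_a: pd.DataFrame | MethylomeIndex,
    calls_b: pd.DataFrame | MethylomeIndex,
    config: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Promoter-level differential calls between two conditions for every
    gene and context; promoters failing the promoter filters in either
    condition are excluded."""
    config = config or AnalysisConfig()
    idx_a, idx_b = _as_index(calls_a), _as_index(calls_b)
    rows = []
    for gene in genes:
        promoter = promoter_region(gene, config.promoter_len, chrom_lengths)
        for context in CONTEXTS:
            rm_a = weighted_mc(idx_a, promoter, context)
            rm_b = weighted_mc(idx_b, promoter, context)
            if not (
                passes_filters(rm_a, "promoter", config)
                and passes_filters(rm_b, "promoter", config)
            ):
                continue
            call = call_differential_promoter(
                rm_a.mc, rm_b.mc, context, gene_id=gene.gene_id, config=config
            )
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "context": context,
                    "mc_a": rm_a.mc,
                    "mc_b": rm_b.mc,
                    "call": call.call,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "context", "mc_a", "mc_b", "call"])
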